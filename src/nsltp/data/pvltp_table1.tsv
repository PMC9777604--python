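gene_name	gene_id	chromosome	start	end	strand	cds_length_bp	aa_total	sp_len	mp_len	ecm_string	mw_da	pi	intron_count	ltp_type
PvLTPI.1	Phvul.001G062200.1	Chr01	7446247	7446788	+	339	112	21	91	C-X9-C-X14-CC-X19-CXC-X22-C-X7-C	9956.67	6.39	1	I
PvLTPI.2	Phvul.001G062300.1	Chr01	7454215	7454792	+	366	121	21	100	C-X9-C-X14-CC-X19-CXC-X22-C-X13-C	10991.71	6.47	1	I
PvLTPI.3	Phvul.001G062400.1	Chr01	7469181	7469533	+	339	112	21	91	C-X9-C-X14-CC-X19-CXC-X22-C-X7-C	10048.77	6.37	1	I
PvLTPI.4	Phvul.001G062500.1	Chr01	7497470	7497805	+	336	111	21	90	C-X9-C-X14-CC-X19-CXC-X22-C-X7-C	9908.63	7.68	0	I
PvLTPI.5	Phvul.005G045100.1	Chr05	4768172	4769125	+	348	115	23	92	C-X9-C-X14-CC-X19-CXC-X21-C-X13-C	9162.50	8.49	1	I
PvLTPI.6	Phvul.005G103800.1	Chr05	32275019	32275716	+	378	125	22	103	C-X9-C-X16-CC-X19-CXC-X23-C-X13-C	11656.84	5.56	1	I
PvLTPI.7	Phvul.006G026700.1	Chr06	10142385	10142738	+	354	117	26	91	C-X9-C-X15-CC-X19-CXC-X21-C-X10-C	9849.69	8.86	0	I
PvLTPI.8	Phvul.006G026600.1	Chr06	10157925	10158278	-	354	117	26	91	C-X9-C-X15-CC-X19-CXC-X21-C-X10-C	10487.43	8.68	0	I
PvLTPI.9	Phvul.006G026400.1	Chr06	10189268	10189630	+	363	120	25	95	C-X9-C-X14-CC-X22-CXC-X21-C-X10-C	10517.50	8.85	0	I
PvLTPI.10	Phvul.006G026300.1	Chr06	10209345	10209689	-	345	114	16	98	C-X9-C-X15-CC-X19-CXC-X21-C-X10-C	10644.64	8.86	0	I
PvLTPI.11	Phvul.006G026200.1	Chr06	10224541	10224903	+	363	120	25	95	C-X9-C-X14-CC-X22-CXC-X21-C-X10-C	9762.57	8.68	0	I
PvLTPI.12	Phvul.006G026040.1	Chr06	10279348	10279692	-	345	114	23	91	C-X9-C-X15-CC-X19-CXC-X21-C-X10-C	9756.61	8.68	0	I
PvLTPI.13	Phvul.006G025800.1	Chr06	10298843	10299187	-	345	114	16	98	C-X9-C-X15-CC-X19-CXC-X21-C-X10-C	10155.73	6.65	0	I
PvLTPI.14	Phvul.006G025840.1	Chr06	10329063	10329407	-	345	114	16	98	C-X9-C-X15-CC-X19-CXC-X21-C-X10-C	10512.52	8.86	0	I
PvLTPI.15	Phvul.006G025880.1	Chr06	10335897	10336241	-	345	114	23	91	C-X9-C-X15-CC-X19-CXC-X21-C-X10-C	10152.68	5.59	0	I
PvLTPI.16	Phvul.006G026800.1	Chr06	10397866	10398287	-	369	122	26	96	C-X9-C-X14-CC-X19-CXC-X21-C-X10-C	9863.40	4.52	0	I
PvLTPI.17	Phvul.006G026900.1	Chr06	10460655	10461008	-	354	117	26	91	C-X9-C-X15-CC-X19-CXC-X21-C-X10-C	10060.47	5.04	0	I
PvLTPI.18	Phvul.006G025700.1	Chr06	11140768	11141112	-	345	114	16	98	C-X9-C-X15-CC-X19-CXC-X21-C-X10-C	10342.94	7.02	0	I
PvLTPI.19	Phvul.006G025500.1	Chr06	11156824	11157168	-	345	114	23	91	C-X9-C-X15-CC-X19-CXC-X21-C-X10-C	9810.22	6.00	0	I
PvLTPI.20	Phvul.006G078300.1	Chr06	19007898	19008577	+	354	117	23	94	C-X9-C-X13-CC-X19-CXC-X22-C-X13-C	10175.73	8.60	1	I
PvLTPI.21	Phvul.006G078400.1	Chr06	19017732	19018561	+	354	117	23	94	C-X9-C-X13-CC-X19-CXC-X22-C-X13-C	10147.72	8.77	1	I
PvLTPI.22	Phvul.006G112211.1	Chr06	22115372	22115937	-	348	115	19	96	C-X9-C-X14-CC-X19-CXC-X21-C-X14-C	10345.16	8.66	1	I
PvLTPI.23	Phvul.007G022400.1	Chr07	1575864	1576217	+	354	117	26	91	C-X9-C-X15-CC-X19-CXC-X21-C-X10-C	9900.34	5.77	0	I
PvLTPI.24	Phvul.007G067200.1	Chr07	6183402	6183764	-	363	120	28	92	C-X9-C-X16-CC-X19-CXC-X21-C-X13-C	9739.17	3.94	0	I
PvLTPI.25	Phvul.008G083400.1	Chr08	8154052	8155082	+	372	123	29	94	C-X9-C-X15-CC-X19-CXC-X22-C-X13-C	9595.25	9.07	1	I
PvLTPI.26	Phvul.008G083600.1	Chr08	8162377	8163555	-	369	122	28	94	C-X9-C-X14-CC-X19-CXC-X23-C-X13-C	10404.81	5.09	1	I
PvLTPI.27	Phvul.008G087000.1	Chr08	8524161	8525277	+	351	116	25	91	C-X9-C-X13-CC-X19-CXC-X21-C-X13-C	9540.98	8.72	1	I
PvLTPI.28	Phvul.008G087101.1	Chr08	8535136	8536072	+	351	116	25	91	C-X9-C-X13-CC-X19-CXC-X21-C-X13-C	9444.64	4.99	1	I
PvLTPI.29	Phvul.008G197700.1	Chr08	54196013	54196496	-	372	123	21	102	C-X9-C-X14-CC-X19-CXC-X22-C-X13-C	11251.25	9.07	1	I
PvLTPI.30	Phvul.008G197800.1	Chr08	54201804	54202157	-	354	117	21	96	C-X9-C-X14-CC-X19-CXC-X22-C-X13-C	10563.37	8.98	0	I
PvLTPI.31	Phvul.008G197914.1	Chr08	54214451	54214786	-	336	111	21	90	C-X9-C-X14-CC-X19-CXC-X22-C-X7-C	10021.71	8.18	0	I
PvLTPI.32	Phvul.008G198000.1	Chr08	54231141	54231476	-	336	111	21	90	C-X9-C-X14-CC-X19-CXC-X22-C-X7-C	9936.60	7.68	0	I
PvLTPI.33	Phvul.008G198200.1	Chr08	54263601	54264568	-	385	124	19	105	C-X9-C-X14-CC-X19-CXC-X22-C-X7-C	11647.61	7.64	1	I
PvLTPI.34	Phvul.008G198300.1	Chr08	54270808	54271422	-	366	121	21	100	C-X9-C-X14-CC-X19-CXC-X22-C-X13-C	10966.66	5.77	1	I
PvLTPI.35	Phvul.008G198414.1	Chr08	54281566	54282126	-	366	121	21	100	C-X9-C-X14-CC-X19-CXC-X22-C-X13-C	10575.31	8.12	1	I
PvLTPI.36	Phvul.008G198400.1	Chr08	54291418	54291771	-	354	117	20	97	C-X9-C-X14-CC-X19-CXC-X22-C-X13-C	11039.75	6.47	0	I
PvLTPI.37	Phvul.008G198500.1	Chr08	54317230	54317860	-	366	121	21	100	C-X9-C-X14-CC-X19-CXC-X22-C-X13-C	11028.73	6.12	1	I
PvLTPI.38	Phvul.008G198700.1	Chr08	54336612	54337182	-	366	121	21	100	C-X9-C-X14-CC-X19-CXC-X22-C-X13-C	11036.74	5.72	1	I
PvLTPI.39	Phvul.008G198900.1	Chr08	54353165	54353635	-	372	123	21	102	C-X9-C-X14-CC-X19-CXC-X22-C-X13-C	11302.92	5.37	1	I
PvLTPI.40	Phvul.008G199100.1	Chr08	54393051	54393632	-	363	120	21	99	C-X9-C-X14-CC-X19-CXC-X22-C-X13-C	10319.89	4.88	1	I
PvLTPI.41	Phvul.010G066500.1	Chr10	24968137	24969974	+	348	115	24	91	C-X9-C-X13-CC-X19-CXC-X22-C-X13-C	9396.85	9.22	1	I
PvLTPI.42	Phvul.010G066400.1	Chr10	25019438	25021034	+	357	118	25	93	C-X9-C-X13-CC-X19-CXC-X23-C-X13-C	9375.79	9.30	1	I
PvLTPI.43	Phvul.010G079000.2	Chr10	25151667	25158544	+	357	118	25	93	C-X9-C-X15-CC-X19-CXC-X22-C-X13-C	9221.70	9.22	1	I
PvLTPI.44	Phvul.010G069100.1	Chr10	30206639	30208294	+	357	118	25	93	C-X9-C-X13-CC-X19-CXC-X22-C-X13-C	10412.79	8.86	1	I
PvLTPI.45	Phvul.010G069500.1	Chr10	30837346	30838454	-	378	125	28	97	C-X9-C-X14-CC-X19-CXC-X26-C-X13-C	10144.63	10.34	1	I
PvLTPII.1	Phvul.004G002700.1	Chr04	126913	127490	-	267	88	19	69	C-X7-C-X13-CC-X8-CXC-X26-C-X7-C	7235.32	8.73	0	II
PvLTPII.2	Phvul.004G002600.1	Chr04	129918	130493	-	282	93	25	68	C-X7-C-X13-CC-X8-CXC-X26-C-X6-C	7282.43	8.50	0	II
PvLTPII.3	Phvul.004G154200.1	Chr04	45768730	45769379	+	279	92	24	68	C-X7-C-X13-CC-X8-CXC-X26-C-X6-C	7306.61	9.33	0	II
PvLTPII.4	Phvul.007G031600.1	Chr07	2518719	2519872	-	285	94	18	76	C-X7-C-X13-CC-X8-CXC-X26-C-X6-C	7995.24	8.66	0	II
PvLTPII.5	Phvul.008G008200.1	Chr08	734888	735748	-	297	98	30	68	C-X7-C-X13-CC-X8-CXC-X26-C-X6-C	7147.38	9.03	0	II
PvLTPIV.1	Phvul.006G050100.1	Chr06	15479738	15480395	+	315	104	27	77	C-X9-C-X15-CC-X9-CXC-X22-C-X7-C	8316.77	8.68	1	IV
PvLTPIV.2	Phvul.007G001800.1	Chr07	109767	110152	+	306	101	25	76	C-X9-C-X15-CC-X9-CXC-X24-C-X7-C	7982.32	4.34	0	IV
PvLTPIV.3	Phvul.008G112900.1	Chr08	13096130	13097071	+	306	101	27	74	C-X9-C-X15-CC-X9-CXC-X22-C-X7-C	7758.24	8.90	0	IV
PvLTPIV.4	Phvul.008G137100.1	Chr08	27792568	27793248	-	312	103	27	76	C-X9-C-X15-CC-X9-CXC-X24-C-X7-C	8031.21	4.22	0	IV
PvLTPIV.5	Phvul.011G047400.1	Chr11	4266384	4267082	-	309	102	25	77	C-X9-C-X15-CC-X9-CXC-X24-C-X7-C	8429.80	6.70	0	IV
PvLTPV.1	Phvul.003G282100.1	Chr03	51931056	51932514	+	360	119	27	92	C-X14-C-X14-CC-X12-CXC-X24-C-X10-C	9363.27	9.90	1	V
PvLTPV.2	Phvul.008G113900.1	Chr08	13258029	13259010	+	351	116	24	92	C-X15-C-X14-CC-X11-CXC-X24-C-X10-C	9501.92	8.69	1	V
PvLTPVIII.1	Phvul.002G060600.1	Chr02	6661973	6662884	-	465	154	42	112	C-X6-C-X12-CC-X12-CXC-X25-C-X8-C	12167.10	8.88	1	VIII
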