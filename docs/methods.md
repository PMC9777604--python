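# Methods

## Motif model and classification

The eight-cysteine motif (ECM) is modelled as eight cysteines in the fixed
arrangement `C / C / CC / CXC / C / C` with five variable spacings
`s1..s5` (residues between C1–C2, C2–C3, C4–C5, C6–C7, C7–C8). A motif
occurrence spans `8 + s1 + s2 + s3 + 1 + s4 + s5` residues.

**Scanning.** By default spacer segments must be cysteine-free — classical
nsLTPs have exactly eight cysteines, and the restriction makes the search
linear: the eight motif cysteines are necessarily consecutive members of the
sequence's cysteine list, so the scanner slides an 8-wide window over that
list and checks the arrangement and the per-spacing bounds. An exploratory
flag (`allow_c_in_spacers`) switches to exhaustive 8-subset enumeration.
The scanner is property-tested against an independent brute-force oracle on
short sequences.

**Classification.** The literature classifies nsLTP types by a mix of
sequence similarity and ECM spacing characteristics; this package commits to
the spacing-only rule because it is deterministic and auditable: a spacing
vector belongs to a type iff every component lies in the type's allowed set.
The shipped grammar covers types I, II, IV, V and VIII with the allowed sets
drawn from the union of the published per-type spacing summaries and the
58-member reference table (the two sources disagree on type II `s4` — 23 vs
26 — so the set takes both). `check_disjoint` verifies exhaustively that no
5-tuple is claimed by two types; classification over the reference table
reproduces all 58 published labels. Pre/post-motif offsets are recorded but
not used for classification, since their published ranges overlap across
types. Grammars serialize to YAML, so alternative or extended type sets can
be swapped in.

## Identification cascade

Stages run in a fixed order — optional homology intake (tabular hits
filtered at E ≤ 1e−5), ECM scan, signal-peptide requirement, HyPRP
exclusion, an exclusion-id-list hook for α-amylase-inhibitor/2S-albumin
look-alikes, and the mature-length ceiling — and every input protein ends
with a trace naming the single stage that rejected it (or `accepted`, or
`collapsed` for exact-duplicate sequences, which are merged to the
lexicographically smallest id before filtering). Proteins are processed in
id order, so results are independent of input order.

Choices that were genuinely open:

- **HyPRP rule.** Hybrid proline-rich proteins are conventionally excluded
  from nsLTP families but lack a crisp published definition. The
  operational rule here: the mature region before the motif's first
  cysteine, if at least 10 residues long, must stay below 20% proline.
  Both numbers are config fields.
- **Mature-length ceiling.** "More than 120 residues" is strict: 120
  passes, 121 fails.
- **Redundancy.** Identical residue strings only; no similarity clustering.
- **ECM region.** For proteins with a signal-peptide annotation the scan
  runs on the mature region; unannotated proteins are scanned whole (they
  can still fail the signal-peptide stage afterwards, which keeps the trace
  informative about *why* each decoy class falls out).

Accepted members are named `<prefix><type>.<index>` with indices assigned
within type by natural chromosome order then ascending start — re-deriving
the published names of all 58 reference genes from their coordinates alone.

## Physicochemistry

Molecular weight uses average isotopic residue masses plus one water
(18.0153 Da), matching sequence-tool convention. The theoretical pI solves
net Henderson–Hasselbalch charge = 0 with the Bjellqvist pKa set (side
chains D 4.05, E 4.45, C 9.0, Y 10.0, H 5.98, K 10.0, R 12.0; termini 7.5 /
3.55), by bisection on [0, 14] to a half-width of 0.005 pH; the net charge
is strictly decreasing in pH, so the root is unique. A grid-search oracle at
0.001 pH resolution backs the tests. Cysteines are treated as free thiols —
the four disulfide bridges of the folded scaffold are a documented
simplification; reported MW/pI therefore describe the unfolded, unmodified
chain. The pKa table is a module-level constant so an alternative set
(e.g. EMBOSS) can be substituted.

Note the reference table's printed MW/pI values cannot be recomputed here —
the underlying sequences are not part of the table — so tests reproduce the
table's *column statistics* (mean 9.82 kDa / 7.52, ranges 7.15–12.17 kDa and
3.94–10.34) rather than per-row values. Reported kDa and pI use half-up
rounding to two decimals, the table's own precision.

## Genome mapping and tandem clusters

Intron counts are CDS-based (`len(cds_spans) − 1` of the primary
transcript); UTR introns are ignored, consistent with the reference table's
0/1 values. The primary transcript of a multi-isoform gene is the `.1`
isoform when present, else the longest total CDS, ties to the smallest id.

Tandem clusters chain same-chromosome family members whose intergenic gap
(`next.start − prev.end`) is at most 100 kb (flag-exposed); overlapping
genes chain too, and `--same-type` restricts chains to one type. The
published cluster figure for this family (23 genes in 10 clusters on
chromosomes 1 and 2) is internally inconsistent with the per-gene
coordinates (chromosome 2 holds a single family member) and could not be
reproduced under any simple distance or gene-order rule, so cluster
detection is validated by invariants (maximality, order invariance,
monotonicity in the gap) and planted synthetic arrays instead of printed
counts.

## Phylogeny

Because the eight anchor cysteines are homologous by definition, a
deterministic anchored alignment replaces a heuristic progressive aligner:
each of the seven variable segments (pre, s1–s5, post) is right-padded with
gaps to its per-segment maximum. Distances are p-distances over columns
where neither row has a gap. Neighbor joining follows Saitou–Nei: join the
pair minimizing `Q(i,j) = (n−2)d(i,j) − r(i) − r(j)`, ties to the earliest
node pair in creation order; branch lengths by the standard formulas with
negative estimates clamped to zero (warned); the unrooted result is
serialized as newick with a trifurcating root and 6-significant-digit
lengths. On additive (tree-metric) input the reconstruction reproduces the
generating metric exactly (tested to 1e−9), which pins down both topology
and branch lengths. A column-resampling bootstrap is available as a seeded
convenience; it is not part of any validated result.

## Expression

Livak quantification: per replicate ΔCt = target Ct − reference Ct; ΔΔCt =
mean treatment ΔCt − mean control ΔCt; fold = 2^−ΔΔCt. Error bars recompute
the fold at ΔΔCt ∓ one SD of the treatment ΔCt values. Significance uses a
two-sided Welch t-test on replicate ΔCt values — chosen over Student's t for
robustness to unequal variance, and swappable; zero-variance degenerate
input maps to p = 1 (equal means) or 0. Technical replicates are averaged
into their biological replicate before statistics, so n = biological
replicates.

Heatmap preparation applies `log2(x + 1)` (pseudocount flag-exposed),
optional per-row z-scoring (constant rows become zeros with a warning), and
a deterministic row ordering from complete-linkage agglomeration on
Euclidean distance. Tie handling is explicit: among equidistant merges the
pair whose clusters contain the smallest original row indices merges first,
and a merged cluster lists its lower-indexed subtree first — hence an
all-constant matrix keeps its input order exactly. The ordering is
implemented directly (not via a library dendrogram) because this tie rule is
part of the contract.

## Synthetic data

Generators are pure functions of (parameters, seed); all randomness flows
from one `numpy` Generator per call.

- **Proteins.** A precursor is a hydrophobic-biased, cysteine-free signal
  peptide (length uniform on 16–42, the reference family's observed range,
  starting with M) plus a mature region: a 2–8-residue pre-offset, one
  planted ECM with spacings drawn uniformly from the requested type's
  allowed sets, and a post-offset keeping the mature length ≤ 120. Spacer
  and filler residues are uniform over the 19 non-cysteine residues — a
  deliberate simplification; real compositional bias can be swapped in.
- **Decoys** realize the four rejection classes: cysteine-free mature
  region (`no_ecm`); valid motif but no signal-peptide annotation
  (`no_sp`); valid motif behind a ≥10-residue, ≥30%-proline pre-motif
  region (`hyprp`); valid motif with mature length 121–200 (`oversize`).
- **Gene models** place members in tandem arrays with caller-specified
  intergenic gaps (1 Mb between arrays and around singletons, far above the
  100 kb default threshold); intron presence is drawn from {0, 1} and
  recorded.
- **qPCR tables** plant a fold change as a −log2(fold) shift of the
  treatment ΔCt around a base of 6 cycles with Gaussian noise per
  biological replicate and a constant reference channel (18 cycles), so at
  zero noise the Livak estimator inverts the construction exactly. Planted
  magnitudes in tests (16-, 37-, 78-, 115-, 142-fold) span the range
  reported for drought-induced nsLTPs.
- **FPKM matrices** assign genes round-robin to expression programs, each
  high (80) in its own organ block and low (2) elsewhere, with log-normal
  noise (σ = 0.3).

What the generators do *not* emulate: realistic amino-acid composition,
sequence homology between family members (every generated protein is
unrelated filler around the motif), UTR structure, amplification-efficiency
variation in qPCR, and count-based noise in FPKM. Passing the recovery tests
therefore demonstrates correctness of the algorithms under the stated model,
not robustness to every artefact of real data.

## Problem sizes and tolerances

The test suite runs synthetic proteomes of ~20–25 proteins over 20 seeds,
8-leaf trees over 20 seeds, and 400 scanner-oracle sequences of ≤60
residues — desk-scale sizes chosen so the full suite completes in seconds
while exercising every code path. Numerical tolerances: pI bisection 0.005
pH; NJ additive-metric recovery 1e−9; zero-noise fold recovery 1e−9
relative; reference-table statistics are exact after half-up rounding to
the table's printed precision.

## Known limitations

- The grammar covers only the five types present in the reference family;
  other types classify as `unclassified` until their sets are added.
- Signal-peptide *prediction* is out of scope; the pipeline consumes an
  annotation table.
- Homology intake consumes a precomputed hit table; no alignment is run.
- The pI model ignores disulfides, phosphorylation and electrostatic
  context; values are comparable across tools using the same pKa set, not
  measurements.
- Bootstrap support values are not computed; the bootstrap flag only emits
  replicate trees.
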