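"""Seeded generators with known ground truth for every pipeline stage.

These generators emulate the structure of a plant nsLTP family so the whole
pipeline is testable without genome downloads: precursor proteins are a
hydrophobic-biased signal peptide followed by a mature region carrying one
planted eight-cysteine motif with type-specific spacings; decoy proteins
reproduce the four rejection classes of the identification cascade; gene
models place family members in tandem arrays with controlled intergenic
gaps; expression tables plant organ programs and qPCR fold changes with
Gaussian replicate noise on the Ct scale.

Every generator is a pure function of its parameters and a single integer
seed; regeneration with the same seed is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .ecm_engine import SpacingVector, TypeGrammar, default_grammar
from .expression_qpcr import CtRecord
from .io_formats import GeneModel, ProteinSequenceRecord

#: The 19 non-cysteine residues; spacer/filler backgrounds draw from these
#: uniformly so a planted motif's cysteine count is exactly eight.
NON_CYS = "ADEFGHIKLMNPQRSTVWY"
HYDROPHOBIC = "LAVIFMW"

DECOY_KINDS = ("no_ecm", "no_sp", "hyprp", "oversize")

SP_LEN_RANGE = (16, 42)          # observed signal-peptide length range
MAX_MATURE_LEN = 120


@dataclass(frozen=True)
class TruthEntry:
    """Ground truth for one generated entity (fields apply as relevant)."""

    id: str
    kind: str                       # "ltp:<type>" | "decoy:<kind>" | "gene"
    sp_len: int | None = None
    spacing: SpacingVector | None = None
    cluster_id: str | None = None
    intron_count: int | None = None
    fold: float | None = None

    @property
    def is_ltp(self) -> bool:
        return self.kind.startswith("ltp:")


def _filler(rng: np.random.Generator, length: int, alphabet: str = NON_CYS) -> str:
    return "".join(rng.choice(list(alphabet), size=length)) if length else ""


def _signal_peptide(rng: np.random.Generator) -> str:
    """Hydrophobic-biased, cysteine-free signal peptide starting with M."""
    length = int(rng.integers(SP_LEN_RANGE[0], SP_LEN_RANGE[1] + 1))
    body = "".join(
        str(rng.choice(list(HYDROPHOBIC))) if rng.random() < 0.7
        else str(rng.choice(list(NON_CYS)))
        for _ in range(length - 1)
    )
    return "M" + body


def _draw_spacing(rng: np.random.Generator, grammar: TypeGrammar, ltp_type: str) -> SpacingVector:
    sets = grammar.types[ltp_type]
    return SpacingVector(*(int(rng.choice(sorted(s))) for s in sets))


def _ecm_region(rng: np.random.Generator, v: SpacingVector) -> str:
    return ("C" + _filler(rng, v.s1) + "C" + _filler(rng, v.s2) + "CC"
            + _filler(rng, v.s3) + "C" + _filler(rng, 1) + "C"
            + _filler(rng, v.s4) + "C" + _filler(rng, v.s5) + "C")


def _mature(rng: np.random.Generator, v: SpacingVector,
            pre: int | None = None, total_len: int | None = None) -> str:
    """Mature region: pre-offset + planted motif + post-offset."""
    if pre is None:
        pre = int(rng.integers(2, min(9, MAX_MATURE_LEN - v.span) + 1))
    if total_len is None:
        post_max = MAX_MATURE_LEN - v.span - pre
        post = int(rng.integers(0, min(12, post_max) + 1))
    else:
        post = total_len - v.span - pre
        if post < 0:
            raise ValueError("requested mature length shorter than motif span")
    return _filler(rng, pre) + _ecm_region(rng, v) + _filler(rng, post)


def gen_ltp_protein(
    ltp_type: str, seed: int, ident: str | None = None,
    grammar: TypeGrammar | None = None,
) -> tuple[ProteinSequenceRecord, TruthEntry]:
    """Generate one nsLTP precursor of the given type with known truth.

    Spacings are drawn uniformly from the type's allowed sets, spacers from
    the cysteine-free background; the mature region never exceeds 120
    residues, so the generated protein passes the full cascade.
    """
    grammar = grammar or default_grammar()
    if ltp_type not in grammar.types:
        raise ValueError(f"type {ltp_type!r} not in grammar")
    rng = np.random.default_rng(seed)
    sp = _signal_peptide(rng)
    v = _draw_spacing(rng, grammar, ltp_type)
    mature = _mature(rng, v)
    ident = ident or f"synLTP_{ltp_type}_{seed}"
    return (
        ProteinSequenceRecord(id=ident, residues=sp + mature,
                              description=f"synthetic type {ltp_type} nsLTP"),
        TruthEntry(id=ident, kind=f"ltp:{ltp_type}", sp_len=len(sp), spacing=v),
    )


def gen_decoy(
    kind: str, seed: int, ident: str | None = None,
    grammar: TypeGrammar | None = None,
) -> tuple[ProteinSequenceRecord, TruthEntry]:
    """Generate one decoy protein for a specific cascade rejection class.

    ``no_ecm``: cysteine-free mature region, signal peptide annotated.
    ``no_sp``: valid planted motif but no signal-peptide annotation
    (``sp_len`` is None in the truth entry).
    ``hyprp``: valid motif behind a >= 10-residue pre-motif region with
    ~40% proline.
    ``oversize``: valid motif but mature length in [121, 200].
    """
    grammar = grammar or default_grammar()
    rng = np.random.default_rng(seed)
    ident = ident or f"synDecoy_{kind}_{seed}"
    sp = _signal_peptide(rng)
    ltp_type = str(rng.choice(sorted(grammar.types)))
    if kind == "no_ecm":
        mature = _filler(rng, int(rng.integers(60, 110)))
        truth = TruthEntry(id=ident, kind="decoy:no_ecm", sp_len=len(sp))
    elif kind == "no_sp":
        v = _draw_spacing(rng, grammar, ltp_type)
        mature = _mature(rng, v)
        truth = TruthEntry(id=ident, kind="decoy:no_sp", sp_len=None, spacing=v)
    elif kind == "hyprp":
        v = _draw_spacing(rng, grammar, ltp_type)
        pre = int(rng.integers(10, min(21, MAX_MATURE_LEN - v.span) + 1))
        region = "".join(
            "P" if rng.random() < 0.4 else str(rng.choice(list(NON_CYS.replace("P", ""))))
            for _ in range(pre))
        # guarantee the planted fraction clears the 0.3 construction floor
        n_p = max(region.count("P"), int(np.ceil(0.3 * pre)))
        region = "P" * n_p + region[n_p:]
        mature = region + _ecm_region(rng, v)
        truth = TruthEntry(id=ident, kind="decoy:hyprp", sp_len=len(sp), spacing=v)
    elif kind == "oversize":
        v = _draw_spacing(rng, grammar, ltp_type)
        total = int(rng.integers(max(121, v.span + 3), 201))
        mature = _mature(rng, v, pre=2, total_len=total)
        truth = TruthEntry(id=ident, kind="decoy:oversize", sp_len=len(sp), spacing=v)
    else:
        raise ValueError(f"unknown decoy kind {kind!r}; choose from {DECOY_KINDS}")
    return (
        ProteinSequenceRecord(id=ident, residues=sp + mature,
                              description=f"synthetic decoy ({kind})"),
        truth,
    )


def gen_proteome(
    n_ltp: int, n_decoy: int, seed: int, grammar: TypeGrammar | None = None,
) -> tuple[list[ProteinSequenceRecord], dict[str, int], list[TruthEntry]]:
    """A mixed proteome: planted nsLTPs cycled over the grammar's types plus
    decoys cycled over the four rejection classes, with the signal-peptide
    annotation table the pipeline consumes.

    ``no_sp`` decoys are deliberately absent from the annotation table.
    """
    grammar = grammar or default_grammar()
    rng = np.random.default_rng(seed)
    types = sorted(grammar.types)
    records, truths = [], []
    sp_table: dict[str, int] = {}
    for i in range(n_ltp):
        sub = int(rng.integers(0, 2**31 - 1))
        rec, truth = gen_ltp_protein(
            types[i % len(types)], sub, ident=f"synLTP{i:04d}", grammar=grammar)
        records.append(rec)
        truths.append(truth)
        sp_table[rec.id] = truth.sp_len
    for i in range(n_decoy):
        sub = int(rng.integers(0, 2**31 - 1))
        kind = DECOY_KINDS[i % len(DECOY_KINDS)]
        rec, truth = gen_decoy(kind, sub, ident=f"synDecoy{i:04d}", grammar=grammar)
        records.append(rec)
        truths.append(truth)
        if truth.sp_len is not None:
            sp_table[rec.id] = truth.sp_len
    return records, sp_table, truths


def gen_gene_models(
    members: Sequence[str],
    clusters_spec: Sequence[tuple[str, Sequence[int], Sequence[int]]],
    seed: int,
) -> tuple[list[GeneModel], list[TruthEntry]]:
    """Place genes in tandem arrays with controlled intergenic gaps.

    ``clusters_spec`` lists ``(chromosome, array_sizes, gaps)`` where
    ``gaps`` supplies the intergenic distances consumed left to right within
    that chromosome's arrays (``sum(sizes) - len(sizes)`` values needed);
    arrays on the same chromosome are separated by 1 Mb. Members not
    consumed by any array become singletons, each on its own chromosome.
    Intron counts are drawn from {0, 1} and recorded in the truth table.
    """
    rng = np.random.default_rng(seed)
    placed = sum(sum(sizes) for _, sizes, _ in clusters_spec)
    if placed > len(members):
        raise ValueError(f"clusters_spec places {placed} genes, only {len(members)} members")

    models: list[GeneModel] = []
    truths: list[TruthEntry] = []
    it = iter(members)

    def make_gene(gid: str, chrom: str, start: int, cluster_id: str | None) -> int:
        length = int(rng.integers(400, 2001))
        introns = int(rng.integers(0, 2))
        end = start + length - 1
        if introns == 0:
            cds = ((start, end),)
        else:
            # intron must leave >= 100 bp of CDS on each side
            intron_len = int(rng.integers(80, min(300, length - 220) + 1))
            exon1 = int(rng.integers(100, length - intron_len - 100 + 1))
            cds = ((start, start + exon1 - 1),
                   (start + exon1 + intron_len, end))
        strand = "+" if rng.random() < 0.5 else "-"
        models.append(GeneModel(
            gene_id=gid.rsplit(".", 1)[0] if "." in gid else gid + "_g",
            transcript_id=gid, chromosome=chrom, strand=strand,
            gene_span=(start, end), exon_spans=cds, cds_spans=cds))
        truths.append(TruthEntry(
            id=gid, kind="gene", cluster_id=cluster_id, intron_count=introns))
        return end

    for chrom, sizes, gaps in clusters_spec:
        if any(s < 1 for s in sizes) or any(g <= 0 for g in gaps):
            raise ValueError("array sizes must be >= 1 and gaps > 0")
        need = sum(sizes) - len(sizes)
        if len(gaps) != need:
            raise ValueError(f"{chrom}: need {need} gaps, got {len(gaps)}")
        gap_iter = iter(gaps)
        pos = int(rng.integers(1_000_000, 2_000_000))
        for a, size in enumerate(sizes):
            cluster_id = f"{chrom}_arr{a}" if size >= 2 else None
            for g in range(size):
                gid = next(it)
                end = make_gene(gid, chrom, pos, cluster_id)
                pos = end + (next(gap_iter) + 1 if g < size - 1 else 1_000_000)

    for i, gid in enumerate(it):
        start = int(rng.integers(1_000_000, 2_000_000))
        make_gene(gid, f"ChrS{i + 1:02d}", start, None)

    spans_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for m in models:
        spans_by_chrom.setdefault(m.chromosome, []).append(m.gene_span)
    for chrom, spans in spans_by_chrom.items():
        spans.sort()
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError(f"overlapping gene placements on {chrom}")

    return models, truths


def gen_qpcr(
    genes: Sequence[str],
    folds: Mapping[str, float],
    noise_sd: float,
    n_bio: int,
    seed: int,
    control_label: str = "control",
    treatment_label: str = "treated",
    base_dct: float = 6.0,
    reference_ct: float = 18.0,
) -> tuple[list[CtRecord], list[TruthEntry]]:
    """Ct tables with planted fold changes and Gaussian replicate noise.

    Per biological replicate, the control dCt is ``base_dct`` plus
    N(0, noise_sd) noise and the treatment dCt is shifted by
    ``-log2(fold)``; the reference channel is constant, so target Ct =
    reference Ct + dCt. At zero noise the Livak estimator recovers each
    planted fold exactly.
    """
    if n_bio < 1:
        raise ValueError("need n_bio >= 1")
    rng = np.random.default_rng(seed)
    records, truths = [], []
    for gene in genes:
        fold = float(folds[gene])
        if fold <= 0:
            raise ValueError(f"{gene}: fold must be positive")
        truths.append(TruthEntry(id=gene, kind="qpcr", fold=fold))
        for rep in range(1, n_bio + 1):
            dct_c = base_dct + rng.normal(0.0, noise_sd)
            dct_t = base_dct - np.log2(fold) + rng.normal(0.0, noise_sd)
            records.append(CtRecord(gene, control_label, rep,
                                    reference_ct + dct_c, reference_ct))
            records.append(CtRecord(gene, treatment_label, rep,
                                    reference_ct + dct_t, reference_ct))
    return records, truths


def gen_fpkm(
    n_genes: int,
    seed: int,
    organs: Sequence[str] = ("root", "stem", "leaf", "flower", "seed", "pod"),
    n_programs: int = 2,
    high_fpkm: float = 80.0,
    low_fpkm: float = 2.0,
    noise_sigma: float = 0.3,
):
    """Organ-structured FPKM matrix with planted expression programs.

    Genes are assigned round-robin to ``n_programs`` programs; each program
    is highly expressed in its own block of organs and lowly expressed
    elsewhere, with multiplicative log-normal noise. Returns the matrix
    (genes x organs DataFrame) and the truth entries labelling each gene's
    program.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    organs = list(organs)
    blocks = np.array_split(np.arange(len(organs)), n_programs)
    data = np.empty((n_genes, len(organs)))
    truths = []
    index = []
    for g in range(n_genes):
        prog = g % n_programs
        gid = f"synGene{g:03d}"
        index.append(gid)
        truths.append(TruthEntry(id=gid, kind=f"program:{prog}"))
        mean = np.full(len(organs), low_fpkm)
        mean[blocks[prog]] = high_fpkm
        data[g] = mean * rng.lognormal(0.0, noise_sigma, size=len(organs))
    return pd.DataFrame(data, index=index, columns=organs), truths
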