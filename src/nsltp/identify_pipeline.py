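"""The end-to-end nsLTP candidate filter cascade and family-table statistics.

Candidate proteins pass through a fixed sequence of filters: optional
homology intake, eight-cysteine-motif scan, signal-peptide requirement,
hybrid proline-rich protein (HyPRP) exclusion, an exclusion-list hook for
alpha-amylase-inhibitor / seed-storage look-alikes, and a mature-length
ceiling. Every input protein receives a trace recording which stage accepted
or rejected it, so a run is fully auditable.

Accepted proteins are characterized (coordinates, CDS length, signal
peptide / mature lengths, ECM spacing, molecular weight, pI, introns) and
named by type and chromosomal order, e.g. ``PvLTPI.1``.
"""

from __future__ import annotations

import logging
import re
import statistics
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Sequence

from . import protein_chem
from .ecm_engine import (
    EcmMatch, TypeGrammar, UNCLASSIFIED, KNOWN_TYPE_LABELS,
    check_disjoint, classify, default_grammar, scan_ecm,
)
from .io_formats import (
    FamilyTableRow, GeneModel, ProteinSequenceRecord, spacing_to_string,
)

logger = logging.getLogger(__name__)

#: Fixed evaluation order of the cascade stages.
STAGES = (
    "homology_intake", "ecm_scan", "signal_peptide",
    "hyprp_filter", "inhibitor_filter", "mature_length",
)


@dataclass
class PipelineConfig:
    """Tunable thresholds of the identification cascade.

    ``max_mature_len`` is strict-greater: a 120-residue mature protein
    passes, 121 fails. ``hyprp_proline_fraction`` applies to the pre-motif
    mature region (see :func:`is_hyprp`). ``homology_evalue_cutoff`` only
    filters an optional intake hit table; without one the whole proteome is
    motif-scanned.
    """

    max_mature_len: int = 120
    hyprp_proline_fraction: float = 0.20
    hyprp_min_region_len: int = 10
    require_signal_peptide: bool = True
    homology_evalue_cutoff: float = 1e-5
    grammar: TypeGrammar = field(default_factory=default_grammar)

    def __post_init__(self) -> None:
        if self.max_mature_len <= 0 or self.hyprp_proline_fraction <= 0:
            raise ValueError("thresholds must be positive")
        ok, collisions = check_disjoint(self.grammar)
        if not ok:
            raise ValueError(f"grammar is not disjoint: {collisions[:3]}")


@dataclass
class CandidateTrace:
    """Per-protein record of the cascade outcome."""

    protein_id: str
    stages: dict[str, str] = field(default_factory=dict)
    final: str = "accepted"          # accepted | rejected | collapsed
    rejected_stage: str | None = None
    reason: str | None = None


@dataclass
class SummaryStats:
    """Column statistics over a family table (min, mean, max triples)."""

    n_total: int
    type_counts: dict[str, int]
    chromosome_counts: dict[str, int]
    intron_counts: dict[int, int]
    mw_da: tuple[float, float, float]
    mw_kda: tuple[float, float, float]
    pi: tuple[float, float, float]
    sp_len: tuple[float, float, float]
    mp_len: tuple[float, float, float]
    cds_length_bp: tuple[float, float, float]


@dataclass(frozen=True)
class Violation:
    """One failed internal-arithmetic rule in a family table row."""

    gene_name: str
    rule: str
    observed: int
    expected: int


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (the convention of the published table)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def natural_chrom_key(chrom: str) -> tuple:
    """Sort key putting Chr02 before Chr10 (digit runs compared numerically)."""
    return tuple(
        int(tok) if tok.isdigit() else tok
        for tok in re.split(r"(\d+)", chrom)
    )


def is_hyprp(
    mature: str,
    match: EcmMatch,
    proline_fraction: float = 0.20,
    min_region_len: int = 10,
) -> bool:
    """Heuristic hybrid proline-rich protein (HyPRP) call.

    HyPRPs carry a proline-rich N-terminal domain in front of an ECM-like
    domain. The call is positive iff the mature region before the motif's
    first cysteine is at least ``min_region_len`` residues long and its
    proline fraction reaches ``proline_fraction``. Short pre-motif regions
    are never flagged, whatever their composition.
    """
    region = mature[: match.cys_positions[0] - 1]
    if len(region) < min_region_len:
        return False
    return region.count("P") / len(region) >= proline_fraction


def _leftmost_classifiable(
    region: str, grammar: TypeGrammar
) -> tuple[EcmMatch, str] | None:
    for m in scan_ecm(region, grammar.bounds):
        label = classify(m.spacing, grammar)
        if label != UNCLASSIFIED:
            return m, label
    return None


def run_identification(
    proteome: Sequence[ProteinSequenceRecord],
    sp_table: Mapping[str, int],
    gene_models: Iterable[GeneModel],
    config: PipelineConfig | None = None,
    hits: Mapping[str, float] | None = None,
    exclusion_ids: Iterable[str] = (),
    name_prefix: str = "PvLTP",
) -> tuple[list[FamilyTableRow], list[CandidateTrace]]:
    """Run the full candidate filter cascade over a proteome.

    ``sp_table`` maps protein id to signal-peptide length (cleavage occurs
    after that many residues); prediction itself is upstream of this
    pipeline. ``gene_models`` must cover every accepted protein (matched by
    transcript id, falling back to gene id) to supply coordinates and intron
    counts. ``hits`` optionally restricts intake to proteins with a homology
    hit at E-value <= the configured cutoff.

    Identical residue strings are collapsed to the lexicographically
    smallest id before the cascade; collapsed duplicates receive a trace
    with ``final="collapsed"``. Every other protein ends ``accepted`` or
    ``rejected`` at exactly one stage, evaluated in :data:`STAGES` order.

    Returns the named family table (see :func:`assign_names`) and one trace
    per input protein. The outcome is invariant to input order up to trace
    ordering.
    """
    config = config or PipelineConfig()
    exclusion = set(exclusion_ids)
    proteome_ids = {p.id for p in proteome}
    missing_sp = [pid for pid in sp_table if pid not in proteome_ids]
    if missing_sp:
        raise ValueError(f"sp_table ids not in proteome: {sorted(missing_sp)}")

    # Redundancy collapse: identical residue strings keep the smallest id.
    keeper_for: dict[str, str] = {}
    for rec in sorted(proteome, key=lambda r: r.id):
        keeper_for.setdefault(rec.residues, rec.id)

    traces: dict[str, CandidateTrace] = {}
    kept_records: list[ProteinSequenceRecord] = []
    for rec in proteome:
        keeper = keeper_for[rec.residues]
        if rec.id != keeper:
            traces[rec.id] = CandidateTrace(
                protein_id=rec.id, final="collapsed",
                reason=f"identical sequence collapsed into {keeper}")
        else:
            kept_records.append(rec)

    accepted: list[tuple[ProteinSequenceRecord, EcmMatch, str, int, str]] = []
    stage_rejections = {s: 0 for s in STAGES}

    for rec in sorted(kept_records, key=lambda r: r.id):
        trace = CandidateTrace(protein_id=rec.id)
        traces[rec.id] = trace

        def reject(stage: str, reason: str) -> None:
            trace.stages[stage] = f"rejected: {reason}"
            trace.final = "rejected"
            trace.rejected_stage = stage
            trace.reason = reason
            stage_rejections[stage] += 1

        if hits is not None:
            ev = hits.get(rec.id)
            if ev is None or ev > config.homology_evalue_cutoff:
                reject("homology_intake",
                       f"no homology hit at E <= {config.homology_evalue_cutoff}")
                continue
            trace.stages["homology_intake"] = f"passed (E={ev:g})"

        sp_len = sp_table.get(rec.id)
        region = rec.residues[sp_len:] if sp_len else rec.residues

        found = _leftmost_classifiable(region, config.grammar)
        if found is None:
            reject("ecm_scan", "no classifiable eight-cysteine motif")
            continue
        match, label = found
        trace.stages["ecm_scan"] = f"passed (type {label}, spacing {tuple(match.spacing)})"

        if config.require_signal_peptide and sp_len is None:
            reject("signal_peptide", "no signal-peptide annotation")
            continue
        trace.stages["signal_peptide"] = f"passed (sp_len={sp_len})"

        if is_hyprp(region, match, config.hyprp_proline_fraction,
                    config.hyprp_min_region_len):
            reject("hyprp_filter", "proline-rich pre-motif region (HyPRP)")
            continue
        trace.stages["hyprp_filter"] = "passed"

        if rec.id in exclusion:
            reject("inhibitor_filter", "listed as inhibitor/storage-protein look-alike")
            continue
        trace.stages["inhibitor_filter"] = "passed"

        if len(region) > config.max_mature_len:
            reject("mature_length",
                   f"mature length {len(region)} > {config.max_mature_len}")
            continue
        trace.stages["mature_length"] = f"passed (mp_len={len(region)})"

        accepted.append((rec, match, label, sp_len or 0, region))

    for stage in STAGES:
        if stage == "homology_intake" and hits is None:
            continue
        logger.info("stage %s: %d rejected", stage, stage_rejections[stage])

    models_by_id: dict[str, GeneModel] = {}
    for gm in gene_models:
        models_by_id[gm.transcript_id] = gm
        models_by_id.setdefault(gm.gene_id, gm)

    missing = [rec.id for rec, *_ in accepted if rec.id not in models_by_id]
    if missing:
        raise ValueError(f"accepted proteins missing gene models: {missing}")

    rows: list[FamilyTableRow] = []
    for rec, match, label, sp_len, mature in accepted:
        gm = models_by_id[rec.id]
        chem = protein_chem.physicochem(mature)
        rows.append(FamilyTableRow(
            gene_name="",  # assigned below
            gene_id=rec.id,
            chromosome=gm.chromosome,
            start=gm.gene_span[0],
            end=gm.gene_span[1],
            strand=gm.strand,
            cds_length_bp=sum(e - s + 1 for s, e in gm.cds_spans),
            aa_total=len(rec.residues),
            sp_len=sp_len,
            mp_len=len(mature),
            ecm_string=spacing_to_string(match.spacing),
            mw_da=round(chem.mw_da, 2),
            pi=round_half_up(chem.pi, 2),
            intron_count=max(len(gm.cds_spans) - 1, 0),
            ltp_type=label,
        ))

    rows = assign_names(rows, prefix=name_prefix)
    return rows, [traces[rec.id] for rec in proteome]


def assign_names(rows: Iterable[FamilyTableRow], prefix: str = "PvLTP") -> list[FamilyTableRow]:
    """Name family members by type and chromosomal order.

    Within each type, rows are sorted by natural chromosome order then
    ascending start (ties broken by gene id) and numbered from 1:
    ``<prefix><type>.<index>``. Returns rows sorted in naming order.
    """
    order = {t: i for i, t in enumerate(KNOWN_TYPE_LABELS)}
    out: list[FamilyTableRow] = []
    by_type: dict[str, list[FamilyTableRow]] = {}
    for r in rows:
        by_type.setdefault(r.ltp_type, []).append(r)
    for label in sorted(by_type, key=lambda t: order.get(t, len(order))):
        members = sorted(
            by_type[label],
            key=lambda r: (natural_chrom_key(r.chromosome), r.start, r.gene_id))
        for i, r in enumerate(members, 1):
            r.gene_name = f"{prefix}{label}.{i}"
            out.append(r)
    return out


def summarize(rows: Sequence[FamilyTableRow]) -> SummaryStats:
    """Column statistics over a family table.

    Molecular weight is reported both in Daltons and in kDa rounded
    half-up to 2 decimals (matching the published precision); mean pI and
    mean kDa are likewise half-up 2-decimal values.
    """
    if not rows:
        raise ValueError("cannot summarize an empty family table")

    def trio(values, nd=None):
        lo, mean, hi = min(values), statistics.fmean(values), max(values)
        if nd is not None:
            lo, mean, hi = (round_half_up(v, nd) for v in (lo, mean, hi))
        return (lo, mean, hi)

    type_counts: dict[str, int] = {}
    chrom_counts: dict[str, int] = {}
    intron_counts: dict[int, int] = {}
    for r in rows:
        type_counts[r.ltp_type] = type_counts.get(r.ltp_type, 0) + 1
        chrom_counts[r.chromosome] = chrom_counts.get(r.chromosome, 0) + 1
        intron_counts[r.intron_count] = intron_counts.get(r.intron_count, 0) + 1

    return SummaryStats(
        n_total=len(rows),
        type_counts=dict(sorted(type_counts.items())),
        chromosome_counts=dict(
            sorted(chrom_counts.items(), key=lambda kv: natural_chrom_key(kv[0]))),
        intron_counts=dict(sorted(intron_counts.items())),
        mw_da=trio([r.mw_da for r in rows]),
        mw_kda=trio([r.mw_da / 1000.0 for r in rows], nd=2),
        pi=trio([r.pi for r in rows], nd=2),
        sp_len=trio([r.sp_len for r in rows]),
        mp_len=trio([r.mp_len for r in rows]),
        cds_length_bp=trio([r.cds_length_bp for r in rows]),
    )


def verify_fixture_consistency(rows: Iterable[FamilyTableRow]) -> list[Violation]:
    """Check each row's internal arithmetic, reporting (not fixing) failures.

    Two rules: CDS length = 3 x (AA + 1) (coding length includes the stop
    codon) and SP + MP = AA.
    """
    violations: list[Violation] = []
    for r in rows:
        expected_cds = 3 * (r.aa_total + 1)
        if r.cds_length_bp != expected_cds:
            violations.append(Violation(
                r.gene_name, "cds_length_bp == 3*(aa_total+1)",
                observed=r.cds_length_bp, expected=expected_cds))
        if r.sp_len + r.mp_len != r.aa_total:
            violations.append(Violation(
                r.gene_name, "sp_len + mp_len == aa_total",
                observed=r.sp_len + r.mp_len, expected=r.aa_total))
    return violations
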