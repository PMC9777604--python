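"""Readers and writers for the formats the nsLTP pipeline touches.

Covers multi-record protein FASTA, a GFF3 subset (gene / mRNA / exon / CDS /
UTR features with ``Parent`` attributes), the packaged family
characterization table for the common-bean nsLTP family (58 genes), and the
compact eight-cysteine-motif (ECM) spacing notation
``C-Xa-C-Xb-CC-Xc-CXC-Xd-C-Xe-C`` used throughout.

All genomic coordinates in public types are GFF3-native: 1-based, inclusive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .ecm_engine import SpacingVector

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

#: Column order of the packaged family table (mirrors the published layout).
FAMILY_TABLE_COLUMNS = [
    "gene_name", "gene_id", "chromosome", "start", "end", "strand",
    "cds_length_bp", "aa_total", "sp_len", "mp_len", "ecm_string",
    "mw_da", "pi", "intron_count", "ltp_type",
]


class FixtureIntegrityError(RuntimeError):
    """The packaged family table is damaged (wrong row count or bad cell)."""


@dataclass(frozen=True)
class ProteinSequenceRecord:
    """One protein sequence: precursor (signal peptide + mature region)."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein record id must be non-empty")
        if not self.residues:
            raise ValueError(f"protein record {self.id!r} has empty sequence")


@dataclass(frozen=True)
class GeneModel:
    """Gene locus with the feature spans of its primary transcript.

    Spans are 1-based inclusive ``(start, end)`` tuples stored in ascending
    genomic order regardless of strand.
    """

    gene_id: str
    transcript_id: str
    chromosome: str
    strand: str
    gene_span: tuple[int, int]
    exon_spans: tuple[tuple[int, int], ...]
    cds_spans: tuple[tuple[int, int], ...]
    utr_spans: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        for name in ("exon_spans", "cds_spans", "utr_spans"):
            spans = getattr(self, name)
            for (s, e) in spans:
                if s > e:
                    raise ValueError(f"{self.gene_id}: inverted span in {name}")
            for (_, e1), (s2, _) in zip(spans, spans[1:]):
                if s2 <= e1:
                    raise ValueError(
                        f"{self.gene_id}: {name} not sorted/non-overlapping")


@dataclass
class FamilyTableRow:
    """One gene's full characterization (one row of the family table)."""

    gene_name: str
    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    cds_length_bp: int
    aa_total: int
    sp_len: int
    mp_len: int
    ecm_string: str
    mw_da: float
    pi: float
    intron_count: int
    ltp_type: str


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path, allow_x: bool = False) -> list[ProteinSequenceRecord]:
    """Read a protein FASTA file, one record per header, order preserved.

    Sequences are upper-cased; characters outside the 20-letter amino-acid
    alphabet are rejected unless ``allow_x`` passes ``X`` through.
    Duplicate ids raise; an empty file returns ``[]`` with a warning.
    """
    allowed = AMINO_ACIDS | ({"X"} if allow_x else set())
    records: list[ProteinSequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id: {rec.id}")
        seen.add(rec.id)
        residues = str(rec.seq).upper()
        bad = set(residues) - allowed
        if bad:
            raise ValueError(
                f"{rec.id}: non-amino-acid characters {sorted(bad)}")
        records.append(ProteinSequenceRecord(
            id=rec.id, residues=residues,
            description=rec.description.removeprefix(rec.id).strip()))
    if not records:
        warnings.warn(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[ProteinSequenceRecord], path: str | Path) -> None:
    """Write records as multi-FASTA, sequence lines wrapped at 60 columns."""
    seqs = [
        SeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(seqs, fh, "fasta")


# ---------------------------------------------------------------------------
# GFF3

def _feature_spans(db: gffutils.FeatureDB, parent_id: str, ftype: str | tuple[str, ...]) -> tuple[tuple[int, int], ...]:
    kids = db.children(parent_id, featuretype=ftype, order_by="start")
    return tuple((f.start, f.end) for f in kids)


def _primary_transcript(mrnas: Sequence[gffutils.Feature], db: gffutils.FeatureDB) -> gffutils.Feature:
    """Pick the primary transcript: the ``.1`` isoform if present, else the
    one with the longest total CDS, ties to the lexicographically smallest id."""
    dot1 = [m for m in mrnas if m.id.endswith(".1")]
    if dot1:
        return min(dot1, key=lambda m: m.id)

    def cds_total(m: gffutils.Feature) -> int:
        return sum(e - s + 1 for s, e in _feature_spans(db, m.id, "CDS"))

    return min(mrnas, key=lambda m: (-cds_total(m), m.id))


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse a GFF3 file into one :class:`GeneModel` per gene.

    For multi-isoform genes a single primary transcript is chosen
    deterministically (see :func:`_primary_transcript`). A CDS feature whose
    ``Parent`` does not resolve to an mRNA is an error naming the feature.
    """
    db = gffutils.create_db(
        str(path), dbfn=":memory:", keep_order=True,
        merge_strategy="create_unique",
    )
    mrna_ids = {f.id for f in db.features_of_type("mRNA")}
    for cds in db.features_of_type("CDS"):
        parents = cds.attributes.get("Parent", [])
        if not parents or not set(parents) & mrna_ids:
            raise ValueError(
                f"CDS without parent mRNA at {cds.seqid}:{cds.start}-{cds.end}"
                f" (Parent={parents})")

    models: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        mrnas = list(db.children(gene.id, featuretype="mRNA"))
        if not mrnas:
            continue
        primary = _primary_transcript(mrnas, db)
        models.append(GeneModel(
            gene_id=gene.id,
            transcript_id=primary.id,
            chromosome=gene.seqid,
            strand=gene.strand,
            gene_span=(gene.start, gene.end),
            exon_spans=_feature_spans(db, primary.id, "exon"),
            cds_spans=_feature_spans(db, primary.id, "CDS"),
            utr_spans=_feature_spans(
                db, primary.id, ("five_prime_UTR", "three_prime_UTR")),
        ))
    return models


def write_gff3(models: Iterable[GeneModel], path: str | Path) -> None:
    """Serialize gene models to GFF3 (gene, mRNA, exon, CDS lines)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            gs, ge = m.gene_span
            attrs = f"ID={m.gene_id};Name={m.gene_id}"
            fh.write(f"{m.chromosome}\tnsltp\tgene\t{gs}\t{ge}\t.\t{m.strand}\t.\t{attrs}\n")
            fh.write(f"{m.chromosome}\tnsltp\tmRNA\t{gs}\t{ge}\t.\t{m.strand}\t.\t"
                     f"ID={m.transcript_id};Parent={m.gene_id}\n")
            for i, (s, e) in enumerate(m.exon_spans, 1):
                fh.write(f"{m.chromosome}\tnsltp\texon\t{s}\t{e}\t.\t{m.strand}\t.\t"
                         f"ID={m.transcript_id}.exon{i};Parent={m.transcript_id}\n")
            for i, (s, e) in enumerate(m.cds_spans, 1):
                fh.write(f"{m.chromosome}\tnsltp\tCDS\t{s}\t{e}\t.\t{m.strand}\t0\t"
                         f"ID={m.transcript_id}.cds{i};Parent={m.transcript_id}\n")
            for i, (s, e) in enumerate(m.utr_spans, 1):
                fh.write(f"{m.chromosome}\tnsltp\tfive_prime_UTR\t{s}\t{e}\t.\t{m.strand}\t.\t"
                         f"ID={m.transcript_id}.utr{i};Parent={m.transcript_id}\n")


# ---------------------------------------------------------------------------
# Family table

def _rows_from_frame(df: pd.DataFrame) -> list[FamilyTableRow]:
    rows = []
    for rec in df.to_dict("records"):
        rows.append(FamilyTableRow(
            gene_name=str(rec["gene_name"]),
            gene_id=str(rec["gene_id"]),
            chromosome=str(rec["chromosome"]),
            start=int(rec["start"]),
            end=int(rec["end"]),
            strand=str(rec["strand"]),
            cds_length_bp=int(rec["cds_length_bp"]),
            aa_total=int(rec["aa_total"]),
            sp_len=int(rec["sp_len"]),
            mp_len=int(rec["mp_len"]),
            ecm_string=str(rec["ecm_string"]),
            mw_da=float(rec["mw_da"]),
            pi=float(rec["pi"]),
            intron_count=int(rec["intron_count"]),
            ltp_type=str(rec["ltp_type"]),
        ))
    return rows


def family_rows_to_frame(rows: Iterable[FamilyTableRow]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in rows], columns=FAMILY_TABLE_COLUMNS)


def read_family_table(path: str | Path) -> list[FamilyTableRow]:
    """Read a family characterization table (TSV with the standard columns)."""
    return _rows_from_frame(pd.read_csv(path, sep="\t"))


def write_family_table(rows: Iterable[FamilyTableRow], path: str | Path) -> None:
    family_rows_to_frame(rows).to_csv(path, sep="\t", index=False)


def load_family_fixture() -> list[FamilyTableRow]:
    """Load the packaged common-bean nsLTP family table (58 genes).

    The table is a verbatim transcription of the published characterization
    of the PvLTP family, internal inconsistencies included (they are reported
    by :func:`nsltp.identify_pipeline.verify_fixture_consistency`, never
    repaired). Any parse failure or a row count other than 58 is a hard
    error, since downstream statistics assume the complete table.
    """
    ref = resources.files("nsltp") / "data" / "pvltp_table1.tsv"
    try:
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
        rows = _rows_from_frame(df)
    except (ValueError, KeyError) as exc:  # unparseable cell or column
        raise FixtureIntegrityError(f"family fixture damaged: {exc}") from exc
    if len(rows) != 58:
        raise FixtureIntegrityError(
            f"family fixture has {len(rows)} rows, expected 58")
    return rows


# ---------------------------------------------------------------------------
# ECM spacing notation

def parse_ecm_string(s: str) -> SpacingVector:
    """Parse ``C-Xa-C-Xb-CC-Xc-CXC-Xd-C-Xe-C`` into its five spacings.

    Inverse of :func:`spacing_to_string`. Malformed input raises with the
    first offending token named.
    """
    tokens = s.split("-")
    expected_c = ["C", "C", "CC", "CXC", "C", "C"]
    if len(tokens) != 11:
        raise ValueError(
            f"ECM string {s!r}: expected 11 '-'-separated tokens, got {len(tokens)}")
    gaps: list[int] = []
    for i, tok in enumerate(tokens):
        if i % 2 == 0:  # cysteine blocks at even positions
            want = expected_c[i // 2]
            if tok != want:
                raise ValueError(f"ECM string {s!r}: token {i + 1} is {tok!r}, expected {want!r}")
        else:
            if not (tok.startswith("X") and tok[1:].isdigit() and int(tok[1:]) >= 1):
                raise ValueError(f"ECM string {s!r}: token {i + 1} is {tok!r}, expected 'X<positive int>'")
            gaps.append(int(tok[1:]))
    return SpacingVector(*gaps)


def spacing_to_string(v: SpacingVector) -> str:
    """Render a spacing vector in the compact ECM notation."""
    return f"C-X{v.s1}-C-X{v.s2}-CC-X{v.s3}-CXC-X{v.s4}-C-X{v.s5}-C"
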