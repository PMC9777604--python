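"""Chromosome distribution, intron counting and tandem-duplicate clusters.

Tandem duplication — adjacent paralogous copies arising from local
duplication — is detected as distance-chained runs of family members on one
chromosome: consecutive members whose intergenic gap does not exceed a
threshold (default 100 kb) are chained, and chains with at least
``min_size`` members are reported as clusters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .identify_pipeline import natural_chrom_key
from .io_formats import FamilyTableRow, GeneModel

DEFAULT_MAX_GAP = 100_000  # bp between consecutive genes
DEFAULT_MIN_SIZE = 2


@dataclass(frozen=True)
class TandemCluster:
    """An ordered run of same-chromosome family members under the gap rule."""

    chromosome: str
    gene_ids: tuple[str, ...]
    span: tuple[int, int]
    type_composition: tuple[str, ...]  # multiset, in member order

    @property
    def size(self) -> int:
        return len(self.gene_ids)


def count_introns(model: GeneModel) -> int:
    """Introns within the coding region of the primary transcript.

    CDS-based by convention: UTR-only introns are not counted.
    """
    if not model.cds_spans:
        raise ValueError(f"{model.gene_id}: no CDS spans, cannot count introns")
    return len(model.cds_spans) - 1


def chromosome_distribution(
    rows: Iterable[FamilyTableRow],
    chromosomes: Sequence[str] | None = None,
) -> dict[str, int]:
    """Family-member count per chromosome.

    Without an explicit ``chromosomes`` list only populated chromosomes
    appear; pass the genome's full list to expose zero-count chromosomes.
    """
    counts: dict[str, int] = {c: 0 for c in chromosomes or ()}
    for r in rows:
        counts[r.chromosome] = counts.get(r.chromosome, 0) + 1
    return dict(sorted(counts.items(), key=lambda kv: natural_chrom_key(kv[0])))


def find_tandem_clusters(
    rows: Iterable[FamilyTableRow],
    max_gap: int = DEFAULT_MAX_GAP,
    min_size: int = DEFAULT_MIN_SIZE,
    same_type: bool = False,
) -> list[TandemCluster]:
    """Greedy distance-chaining of family members into tandem clusters.

    Per chromosome, members are sorted by start; a member joins the current
    chain when its gap to the previous member (``next.start - prev.end``)
    is at most ``max_gap``. Overlapping genes (negative gap) chain too.
    With ``same_type`` the chain breaks on a type change as well. Chains
    shorter than ``min_size`` are dropped. The result is deterministic and
    invariant to input row order.
    """
    by_chrom: dict[str, list[FamilyTableRow]] = {}
    for r in rows:
        by_chrom.setdefault(r.chromosome, []).append(r)

    clusters: list[TandemCluster] = []
    for chrom in sorted(by_chrom, key=natural_chrom_key):
        members = sorted(by_chrom[chrom], key=lambda r: (r.start, r.end, r.gene_id))
        chain: list[FamilyTableRow] = []

        def flush() -> None:
            if len(chain) >= min_size:
                clusters.append(TandemCluster(
                    chromosome=chrom,
                    gene_ids=tuple(r.gene_id for r in chain),
                    span=(chain[0].start, max(r.end for r in chain)),
                    type_composition=tuple(r.ltp_type for r in chain),
                ))

        for r in members:
            if chain and (
                r.start - chain[-1].end > max_gap
                or (same_type and r.ltp_type != chain[-1].ltp_type)
            ):
                flush()
                chain = []
            chain.append(r)
        flush()
    return clusters
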