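"""Expression summarization: organ FPKM heatmap preparation and qPCR
relative quantification by the Livak 2^-ddCt method.

For each replicate, dCt = target Ct - reference-gene Ct; ddCt is the mean
treatment dCt minus the mean control dCt, and the fold change is 2^-ddCt.
Replicate spread is propagated by recomputing the fold at ddCt -/+ one
standard deviation of the treatment dCt values (the conventional error-bar
construction). Technical replicates should be averaged into their
biological replicate upstream (see :func:`collapse_technical`); statistics
then run on biological replicates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist


@dataclass(frozen=True)
class CtRecord:
    """One qPCR well pair: target and reference Ct for one replicate."""

    gene: str
    condition: str
    replicate: int
    ct_target: float
    ct_reference: float

    def __post_init__(self) -> None:
        for v in (self.ct_target, self.ct_reference):
            if not (0.0 < v < 45.0):
                raise ValueError(f"{self.gene}/{self.condition}: Ct {v} outside (0, 45)")

    @property
    def dct(self) -> float:
        return self.ct_target - self.ct_reference


@dataclass(frozen=True)
class FoldChangeResult:
    gene: str
    condition: str
    fold: float
    fold_lo: float
    fold_hi: float
    sd_dct: float
    p_value: float | None


def collapse_technical(records: Iterable[CtRecord]) -> list[CtRecord]:
    """Average technical replicates of the same biological replicate.

    Records sharing (gene, condition, replicate) are averaged on both Ct
    channels into one record; n for statistics is then the number of
    biological replicates.
    """
    groups: dict[tuple, list[CtRecord]] = {}
    for r in records:
        groups.setdefault((r.gene, r.condition, r.replicate), []).append(r)
    out = []
    for (gene, cond, rep), rs in groups.items():
        out.append(CtRecord(
            gene=gene, condition=cond, replicate=rep,
            ct_target=sum(r.ct_target for r in rs) / len(rs),
            ct_reference=sum(r.ct_reference for r in rs) / len(rs)))
    return out


def welch_test(dct_treat: Sequence[float], dct_control: Sequence[float]) -> float:
    """Two-sided Welch t-test on replicate dCt values.

    Degenerate input (zero variance in both groups) returns p = 1 for equal
    means and p = 0 otherwise, rather than NaN.
    """
    if len(dct_treat) < 2 or len(dct_control) < 2:
        raise ValueError("need >= 2 replicates per group")
    a, b = np.asarray(dct_treat, float), np.asarray(dct_control, float)
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(sps.ttest_ind(a, b, equal_var=False).pvalue)


def ddct_fold(treat: Sequence[CtRecord], control: Sequence[CtRecord]) -> FoldChangeResult:
    """Livak 2^-ddCt fold change of a gene in a treatment vs its control.

    Requires all records to concern one gene; raises on a mismatch. The
    p-value is a Welch t-test on the replicate dCt values (None when either
    group has a single replicate).
    """
    if not treat or not control:
        raise ValueError("each group needs at least one replicate")
    genes = {r.gene for r in treat} | {r.gene for r in control}
    if len(genes) != 1:
        raise ValueError(f"mismatched genes in fold-change input: {sorted(genes)}")
    dct_t = [r.dct for r in treat]
    dct_c = [r.dct for r in control]
    ddct = float(np.mean(dct_t) - np.mean(dct_c))
    sd = float(np.std(dct_t, ddof=1)) if len(dct_t) > 1 else 0.0
    p = welch_test(dct_t, dct_c) if min(len(dct_t), len(dct_c)) >= 2 else None
    return FoldChangeResult(
        gene=genes.pop(),
        condition=treat[0].condition,
        fold=2.0 ** -ddct,
        fold_lo=2.0 ** -(ddct + sd),
        fold_hi=2.0 ** -(ddct - sd),
        sd_dct=sd,
        p_value=p,
    )


def fold_table(records: Iterable[CtRecord], control_label: str) -> pd.DataFrame:
    """Per-gene, per-condition fold changes against a control condition."""
    by_gene: dict[str, dict[str, list[CtRecord]]] = {}
    for r in records:
        by_gene.setdefault(r.gene, {}).setdefault(r.condition, []).append(r)
    rows = []
    for gene in sorted(by_gene):
        conds = by_gene[gene]
        if control_label not in conds:
            raise ValueError(f"{gene}: no control condition {control_label!r}")
        for cond in sorted(c for c in conds if c != control_label):
            res = ddct_fold(conds[cond], conds[control_label])
            rows.append({
                "gene": gene, "condition": cond, "fold": res.fold,
                "fold_lo": res.fold_lo, "fold_hi": res.fold_hi,
                "sd_dct": res.sd_dct, "p_value": res.p_value,
            })
    return pd.DataFrame(rows)


def heatmap_prepare(
    fpkm: pd.DataFrame,
    log2_transform: bool = True,
    pseudocount: float = 1.0,
    row_scale: bool = False,
) -> pd.DataFrame:
    """Transform and row-order an FPKM matrix for heatmap display.

    Applies ``log2(x + pseudocount)``, optional per-row z-scoring (a
    constant row becomes zeros with a warning), and deterministic row
    ordering from complete-linkage hierarchical clustering on Euclidean
    distances; equidistant rows keep their input order.
    """
    if (fpkm.to_numpy() < 0).any():
        raise ValueError("FPKM matrix must be non-negative")
    m = fpkm.astype(float)
    if log2_transform:
        m = np.log2(m + pseudocount)
    if row_scale:
        mu = m.mean(axis=1)
        sd = m.std(axis=1, ddof=0)
        constant = sd == 0.0
        if constant.any():
            warnings.warn(
                f"constant rows set to zero under z-scoring: "
                f"{list(m.index[constant])}")
            sd = sd.replace(0.0, 1.0)
        m = m.sub(mu, axis=0).div(sd, axis=0)
        m.loc[constant] = 0.0
    if len(m) > 2:
        m = m.iloc[_complete_linkage_order(m.to_numpy())]
    return m


def _complete_linkage_order(x: np.ndarray) -> list[int]:
    """Leaf order from complete-linkage agglomeration on Euclidean distance.

    Ties are broken toward the pair whose smallest original row indices come
    first, and a merged cluster lists the lower-indexed subtree first — so
    equidistant rows (e.g. an all-constant matrix) keep their input order.
    """
    n = len(x)
    D = np.zeros((n, n))
    D[np.triu_indices(n, 1)] = pdist(x)
    D += D.T
    leaves: dict[int, list[int]] = {i: [i] for i in range(n)}
    while len(leaves) > 1:
        best_key, best = None, None
        for i, j in combinations_sorted(leaves):
            d = max(D[a, b] for a in leaves[i] for b in leaves[j])
            key = (d, min(leaves[i]), min(leaves[j]))
            if best_key is None or key < best_key:
                best_key, best = key, (i, j)
        i, j = best
        first, second = (i, j) if min(leaves[i]) < min(leaves[j]) else (j, i)
        leaves[first] = leaves[first] + leaves[second]
        del leaves[second]
    return next(iter(leaves.values()))


def combinations_sorted(keys) -> list[tuple[int, int]]:
    ks = sorted(keys)
    return [(a, b) for idx, a in enumerate(ks) for b in ks[idx + 1:]]
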