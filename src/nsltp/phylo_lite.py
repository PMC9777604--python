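"""Cysteine-anchored ECM alignment, p-distances and neighbor joining.

The eight cysteines of the ECM are homologous across nsLTPs by definition,
so a deterministic anchored alignment — each inter-cysteine segment padded
to its per-segment maximum — replaces a heuristic progressive aligner for
this domain. Pairwise p-distances over the anchored columns feed a
Saitou-Nei neighbor-joining reconstruction with newick output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np

from .ecm_engine import EcmMatch

GAP = "-"


@dataclass(frozen=True)
class AnchoredAlignment:
    """Equal-length rows in which the 8 cysteine anchors share columns."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]
    anchor_columns: tuple[int, ...]

    def __post_init__(self) -> None:
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise ValueError("alignment rows differ in length")
        for col in self.anchor_columns:
            if any(r[col] != "C" for r in self.rows):
                raise ValueError(f"non-cysteine in anchor column {col}")

    @property
    def width(self) -> int:
        return len(self.rows[0])


@dataclass
class TreeNode:
    """Tree vertex; ``children`` pairs a subtree with its branch length."""

    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaf_names(self) -> list[str]:
        if self.is_leaf():
            return [self.name]
        out: list[str] = []
        for child, _ in self.children:
            out.extend(child.leaf_names())
        return out

    def to_newick(self) -> str:
        return self._newick() + ";"

    def _newick(self) -> str:
        if self.is_leaf():
            return self.name
        inner = ",".join(
            f"{child._newick()}:{length:.6g}" for child, length in self.children)
        return f"({inner})"


def _segments(seq: str, match: EcmMatch) -> list[str]:
    """Split a domain into its 7 variable segments plus the fixed CXC spacer."""
    c = [p - 1 for p in match.cys_positions]  # 0-based
    return [
        seq[: c[0]],                # pre
        seq[c[0] + 1: c[1]],        # s1
        seq[c[1] + 1: c[2]],        # s2
        seq[c[3] + 1: c[4]],        # s3
        seq[c[4] + 1: c[5]],        # the CXC spacer (always width 1)
        seq[c[5] + 1: c[6]],        # s4
        seq[c[6] + 1: c[7]],        # s5
        seq[c[7] + 1:],             # post
    ]


def anchor_align(domains: Sequence[tuple[str, str, EcmMatch]]) -> AnchoredAlignment:
    """Align ECM domains on their eight cysteines.

    ``domains`` holds ``(id, sequence, match)`` triples where ``match``
    locates the motif within ``sequence``. Each variable segment (pre,
    the five inter-cysteine spacers, post) is right-padded with gaps to the
    per-segment maximum, so the anchors line up exactly.
    """
    if not domains:
        raise ValueError("need at least one domain to align")
    segs = []
    for did, seq, match in domains:
        if match is None:
            raise ValueError(f"{did}: missing ECM match")
        segs.append(_segments(seq, match))

    maxima = [max(len(s[k]) for s in segs) for k in range(8)]
    rows = []
    for s in segs:
        padded = [s[k] + GAP * (maxima[k] - len(s[k])) for k in range(8)]
        rows.append(
            padded[0] + "C" + padded[1] + "C" + padded[2] + "CC"
            + padded[3] + "C" + padded[4] + "C" + padded[5] + "C"
            + padded[6] + "C" + padded[7])

    a = []
    pos = maxima[0]
    for extra in (maxima[1], maxima[2], 0, maxima[3], maxima[4], maxima[5], maxima[6]):
        a.append(pos)
        pos += 1 + extra
    a.append(pos)
    return AnchoredAlignment(
        ids=tuple(d[0] for d in domains),
        rows=tuple(rows),
        anchor_columns=tuple(a),
    )


def p_distance(a: AnchoredAlignment) -> np.ndarray:
    """Pairwise p-distance: mismatches over columns where neither row gaps."""
    n = len(a.rows)
    d = np.zeros((n, n))
    arr = np.array([list(r) for r in a.rows])
    gap = arr == GAP
    for i, j in combinations(range(n), 2):
        ok = ~(gap[i] | gap[j])
        if not ok.any():
            raise ValueError(
                f"no comparable columns between {a.ids[i]} and {a.ids[j]}")
        d[i, j] = d[j, i] = (arr[i, ok] != arr[j, ok]).mean()
    return d


def nj(d: np.ndarray, ids: Sequence[str]) -> TreeNode:
    """Saitou-Nei neighbor joining on a symmetric distance matrix.

    Iteratively joins the pair minimizing
    ``Q(i, j) = (n - 2) d(i, j) - r(i) - r(j)`` (``r`` = row sums over the
    active set), breaking ties toward the smallest index pair in node
    creation order. Branch lengths follow the standard formulas; negative
    estimates are clamped to zero with a warning. The result is unrooted,
    represented with a trifurcating root node.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if d.shape != (n, n) or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be square and symmetric")
    if len(ids) != n:
        raise ValueError("ids length must match matrix size")

    nodes: dict[int, TreeNode] = {i: TreeNode(name=str(ids[i])) for i in range(n)}
    D = {(i, j): d[i, j] for i in range(n) for j in range(n)}
    active = list(range(n))
    next_idx = n

    def branch(length: float, context: str) -> float:
        if length < -1e-12:
            warnings.warn(f"negative NJ branch length {length:.3g} clamped to 0 ({context})")
        return max(length, 0.0)

    while len(active) > 3:
        m = len(active)
        r = {i: sum(D[i, k] for k in active if k != i) for i in active}
        best, best_q = None, np.inf
        for i, j in combinations(active, 2):  # active ascends: creation order
            q = (m - 2) * D[i, j] - r[i] - r[j]
            if q < best_q - 1e-12:
                best, best_q = (i, j), q
        i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        parent = TreeNode(children=[
            (nodes[i], branch(li, f"join {i}")),
            (nodes[j], branch(lj, f"join {j}")),
        ])
        nodes[next_idx] = parent
        for k in active:
            if k in (i, j):
                continue
            nd = 0.5 * (D[i, k] + D[j, k] - D[i, j])
            D[next_idx, k] = D[k, next_idx] = nd
        D[next_idx, next_idx] = 0.0
        active = [k for k in active if k not in (i, j)] + [next_idx]
        del nodes[i], nodes[j]
        next_idx += 1

    i, j, k = active
    li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    return TreeNode(children=[
        (nodes[i], branch(li, "final")),
        (nodes[j], branch(lj, "final")),
        (nodes[k], branch(lk, "final")),
    ])


def bootstrap_trees(
    a: AnchoredAlignment, n_replicates: int, seed: int
) -> list[TreeNode]:
    """Column-resampling bootstrap: rebuild the NJ tree on resampled columns.

    A convenience for exploratory support assessment; replicates whose
    resampled alignment leaves a taxon pair with no comparable columns are
    skipped.
    """
    rng = np.random.default_rng(seed)
    width = a.width
    trees = []
    for _ in range(n_replicates):
        cols = rng.integers(0, width, size=width)
        rows = tuple("".join(r[c] for c in cols) for r in a.rows)
        resampled = AnchoredAlignment.__new__(AnchoredAlignment)
        object.__setattr__(resampled, "ids", a.ids)
        object.__setattr__(resampled, "rows", rows)
        object.__setattr__(resampled, "anchor_columns", ())
        try:
            trees.append(nj(p_distance(resampled), a.ids))
        except ValueError:
            continue
    return trees
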