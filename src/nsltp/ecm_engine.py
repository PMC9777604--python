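"""Eight-cysteine-motif (ECM) detection and nsLTP type classification.

The ECM is the defining scaffold of plant non-specific lipid transfer
proteins: eight cysteines arranged as ``C-Xa-C-Xb-CC-Xc-CXC-Xd-C-Xe-C``,
where C3/C4 are adjacent and C5/C6 are separated by exactly one residue.
The five variable inter-cysteine spacings ``(s1..s5)`` differ systematically
between nsLTP types, which makes spacing-set membership a deterministic,
auditable classification rule.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import yaml

UNCLASSIFIED = "unclassified"

#: Closed set of recognized nsLTP type labels (extensible grammar keys).
KNOWN_TYPE_LABELS = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X", "XI")


class SpacingVector(NamedTuple):
    """Inter-cysteine spacings of one ECM.

    ``s1, s2, s3, s4, s5`` count the residues between C1-C2, C2-C3, C4-C5,
    C6-C7 and C7-C8 respectively. The C3C4 pair is adjacent and C5-X-C6 has
    exactly one spacer residue, so the full motif spans
    ``8 + s1 + s2 + s3 + 1 + s4 + s5`` residues.
    """

    s1: int
    s2: int
    s3: int
    s4: int
    s5: int

    @property
    def span(self) -> int:
        return 8 + self.s1 + self.s2 + self.s3 + 1 + self.s4 + self.s5


@dataclass(frozen=True)
class EcmMatch:
    """One motif occurrence within a mature sequence.

    ``cys_positions`` are 1-based indices of the eight cysteines;
    ``pre``/``post`` are the residue counts before C1 and after C8.
    """

    cys_positions: tuple[int, ...]
    spacing: SpacingVector
    pre: int
    post: int

    @property
    def span(self) -> tuple[int, int]:
        return (self.cys_positions[0], self.cys_positions[-1])

    def __post_init__(self) -> None:
        p = self.cys_positions
        if len(p) != 8 or any(b <= a for a, b in zip(p, p[1:])):
            raise ValueError("need 8 strictly ascending cysteine positions")
        if p[3] != p[2] + 1:
            raise ValueError("C3/C4 must be adjacent (CC)")
        if p[5] != p[4] + 2:
            raise ValueError("C5/C6 must be separated by one residue (CXC)")


Bounds = tuple[tuple[int, int], ...]  # (min, max) per spacing, length 5


class AmbiguousTypeError(ValueError):
    """A spacing vector is claimed by more than one type (grammar bug)."""


@dataclass(frozen=True)
class TypeGrammar:
    """Allowed spacing-value sets per nsLTP type, plus global scan bounds.

    ``types`` maps a type label to five frozensets of allowed values for
    ``s1..s5``; a vector belongs to a type iff every component is in the
    corresponding set. ``bounds`` is the per-spacing (min, max) envelope used
    by the motif scanner.
    """

    types: dict[str, tuple[frozenset[int], ...]]
    bounds: Bounds

    def __post_init__(self) -> None:
        for label, sets in self.types.items():
            if label not in KNOWN_TYPE_LABELS:
                raise ValueError(f"unknown type label {label!r}")
            if len(sets) != 5 or any(not s for s in sets):
                raise ValueError(f"type {label}: need 5 non-empty allowed sets")
        if len(self.bounds) != 5:
            raise ValueError("need 5 (min, max) bound pairs")

    def to_dict(self) -> dict:
        return {
            "types": {t: [sorted(s) for s in sets] for t, sets in self.types.items()},
            "bounds": [list(b) for b in self.bounds],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TypeGrammar":
        return cls(
            types={t: tuple(frozenset(v) for v in sets) for t, sets in d["types"].items()},
            bounds=tuple((lo, hi) for lo, hi in d["bounds"]),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "TypeGrammar":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_grammar() -> TypeGrammar:
    """The shipped spacing grammar for the five common-bean nsLTP types.

    Allowed sets are the union of the published per-type spacing-diversity
    ranges and the spacings observed across the 58-member family table;
    the type II ``s4`` set takes {23, 26} because the summary table and the
    per-gene table disagree (23 vs 26) and both must validate. Global scan
    bounds are the per-spacing envelope over all types.
    """
    f = frozenset
    return TypeGrammar(
        types={
            "I": (f({9}), f(range(13, 17)), f({19, 22}), f({21, 22, 23, 26}), f({7, 10, 13, 14})),
            "II": (f({7}), f({13}), f({8}), f({23, 26}), f({6, 7})),
            "IV": (f({9}), f({15}), f({9}), f({22, 24}), f({7})),
            "V": (f({14, 15}), f({14}), f({11, 12}), f({24}), f({10})),
            "VIII": (f({6}), f({12}), f({12}), f({25}), f({8})),
        },
        bounds=((6, 15), (12, 16), (8, 22), (21, 26), (6, 14)),
    )


def scan_ecm(
    mature: str,
    bounds: Bounds | None = None,
    allow_c_in_spacers: bool = False,
) -> list[EcmMatch]:
    """Find all eight-cysteine motifs in a mature sequence.

    A match is eight cysteines in the C / C / CC / CXC / C / C arrangement
    whose five spacings fall inside ``bounds`` (default: the shipped
    grammar's envelope). By default spacer segments must be cysteine-free —
    classical nsLTPs have exactly eight cysteines, and the restriction
    removes combinatorial ambiguity; ``allow_c_in_spacers=True`` enumerates
    all 8-subsets of cysteine positions instead (exploratory scans only).

    Matches are returned left-to-right by C1 position. No match is not an
    error: the result is simply empty.
    """
    if not mature:
        raise ValueError("mature sequence must be non-empty")
    if bounds is None:
        bounds = default_grammar().bounds
    cys = [i for i, aa in enumerate(mature) if aa == "C"]

    if allow_c_in_spacers:
        candidates = itertools.combinations(cys, 8)
    else:
        # C-free spacers force the 8 motif cysteines to be consecutive
        # members of the cysteine list.
        candidates = (tuple(cys[i:i + 8]) for i in range(len(cys) - 7))

    matches = []
    for p in candidates:
        if p[3] != p[2] + 1 or p[5] != p[4] + 2:
            continue
        v = SpacingVector(
            p[1] - p[0] - 1, p[2] - p[1] - 1, p[4] - p[3] - 1,
            p[6] - p[5] - 1, p[7] - p[6] - 1)
        if any(not (lo <= s <= hi) for s, (lo, hi) in zip(v, bounds)):
            continue
        matches.append(EcmMatch(
            cys_positions=tuple(i + 1 for i in p),
            spacing=v, pre=p[0], post=len(mature) - p[7] - 1))
    matches.sort(key=lambda m: m.cys_positions)
    return matches


def classify(v: SpacingVector, grammar: TypeGrammar | None = None) -> str:
    """Assign a spacing vector to the unique type whose sets contain it.

    Returns ``"unclassified"`` when no type matches; raises
    :class:`AmbiguousTypeError` when more than one does (the shipped grammar
    is verified disjoint, so ambiguity indicates a broken custom grammar).
    """
    grammar = grammar or default_grammar()
    hits = [
        label for label, sets in grammar.types.items()
        if all(s in allowed for s, allowed in zip(v, sets))
    ]
    if len(hits) > 1:
        raise AmbiguousTypeError(
            f"spacing {tuple(v)} matches multiple types: {hits}")
    return hits[0] if hits else UNCLASSIFIED


def check_disjoint(grammar: TypeGrammar) -> tuple[bool, list[tuple[str, str, SpacingVector]]]:
    """Verify no joint 5-tuple is allowed by two types.

    Exhaustive over the finite joint sets; returns the verdict and every
    colliding ``(type_a, type_b, vector)``.
    """
    collisions = []
    labels = sorted(grammar.types)
    for a, b in itertools.combinations(labels, 2):
        inter = [
            grammar.types[a][k] & grammar.types[b][k] for k in range(5)
        ]
        if all(inter):
            for combo in itertools.product(*inter):
                collisions.append((a, b, SpacingVector(*combo)))
    return (not collisions, collisions)
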