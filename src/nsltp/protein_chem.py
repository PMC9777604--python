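"""Mature-protein derivation and physicochemical characterization.

Signal-peptide cleavage, molecular weight from average isotopic residue
masses, and the theoretical isoelectric point (pI) under the
Henderson-Hasselbalch model with the Bjellqvist pKa set (the table behind
the ExPASy Compute pI/Mw service).

Cysteines are treated as free thiols: the four disulfide bridges of the
folded nsLTP scaffold are ignored for both MW and pI. This is the usual
convention for sequence-derived physicochemistry and a documented
simplification here.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import ProteinSequenceRecord

#: Average isotopic masses of amino-acid residues (Da), i.e. the monomer
#: minus one water; protein MW = sum(residues) + one water.
AVERAGE_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}

WATER_MASS = 18.0153

#: Bjellqvist pKa values: ionizable side chains plus the peptide termini.
PKA = {
    "n_term": 7.50,
    "c_term": 3.55,
    "C": 9.00,
    "D": 4.05,
    "E": 4.45,
    "H": 5.98,
    "K": 10.00,
    "R": 12.00,
    "Y": 10.00,
}

_POSITIVE = ("n_term", "H", "K", "R")
_NEGATIVE = ("c_term", "C", "D", "E", "Y")

PI_TOLERANCE = 0.005  # pH units, bisection stopping width


@dataclass(frozen=True)
class MatureProtein:
    """Mature region of a precursor after signal-peptide removal."""

    source_id: str
    residues: str
    sp_len: int

    @property
    def mp_len(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class PhysicoChem:
    mw_da: float
    pi: float


def cleave_signal(precursor: ProteinSequenceRecord, sp_len: int) -> MatureProtein:
    """Remove the N-terminal signal peptide, returning the mature protein.

    ``sp_len`` must leave at least one mature residue.
    """
    if sp_len <= 0:
        raise ValueError(f"{precursor.id}: signal peptide length must be >= 1")
    if sp_len >= len(precursor.residues):
        raise ValueError(
            f"{precursor.id}: signal peptide length {sp_len} >= precursor "
            f"length {len(precursor.residues)}")
    return MatureProtein(
        source_id=precursor.id,
        residues=precursor.residues[sp_len:],
        sp_len=sp_len,
    )


def molecular_weight(residues: str) -> float:
    """Average-isotopic molecular weight in Daltons (residues + one water)."""
    if not residues:
        raise ValueError("cannot compute molecular weight of empty sequence")
    try:
        total = sum(AVERAGE_RESIDUE_MASS[aa] for aa in residues)
    except KeyError as exc:
        raise ValueError(f"unknown residue {exc.args[0]!r}") from None
    return total + WATER_MASS


def net_charge(residues: str, ph: float) -> float:
    """Net Henderson-Hasselbalch charge of the peptide at a given pH.

    Each ionizable group contributes its Henderson-Hasselbalch fractional
    charge; the result is strictly decreasing in pH, which makes the pI the
    unique zero crossing.
    """
    counts = {"n_term": 1, "c_term": 1}
    for aa in PKA:
        if len(aa) == 1:
            counts[aa] = residues.count(aa)
    charge = 0.0
    for group in _POSITIVE:
        charge += counts[group] / (1.0 + 10.0 ** (ph - PKA[group]))
    for group in _NEGATIVE:
        charge -= counts[group] / (1.0 + 10.0 ** (PKA[group] - ph))
    return charge


def isoelectric_point(residues: str) -> float:
    """Theoretical pI: the pH at which the net charge is zero.

    Found by bisection on [0, 14] to a half-width of ``PI_TOLERANCE``
    (0.005 pH); monotone-decreasing net charge guarantees uniqueness.
    """
    if not residues:
        raise ValueError("cannot compute pI of empty sequence")
    unknown = set(residues) - set(AVERAGE_RESIDUE_MASS)
    if unknown:
        raise ValueError(f"unknown residues {sorted(unknown)}")
    lo, hi = 0.0, 14.0
    while hi - lo > PI_TOLERANCE:
        mid = (lo + hi) / 2.0
        if net_charge(residues, mid) > 0.0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def physicochem(residues: str) -> PhysicoChem:
    """Molecular weight and pI of a mature protein in one record."""
    return PhysicoChem(mw_da=molecular_weight(residues), pi=isoelectric_point(residues))
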