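"""Deduced-peptide descriptors: molecular weight and theoretical pI.

Molecular weight is the sum of average (not monoisotopic) residue
masses plus one water, reported in kDa.  The theoretical isoelectric
point solves net charge = 0 under the Henderson-Hasselbalch equation
over the two termini and the ionizable side chains (D, E, C, Y, H, K,
R) with the Bjellqvist pKa set, including the residue-specific
N-terminal and C-terminal adjustments that set maintains.  Net charge
is strictly decreasing in pH, so the root is found by bisection on
[0, 14].
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import SequenceError

WATER_DA = 18.01524

# Average residue (amino acid minus water) masses, Da.
AVERAGE_RESIDUE_MASS_DA = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}

# Bjellqvist pKa set.
_POSITIVE_PKA = {"Nterm": 7.5, "K": 10.0, "R": 12.0, "H": 5.98}
_NEGATIVE_PKA = {"Cterm": 3.55, "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}
_NTERM_PKA_BY_RESIDUE = {"A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36, "T": 6.82, "V": 7.44, "E": 7.7}
_CTERM_PKA_BY_RESIDUE = {"D": 4.55, "E": 4.75}

PI_CHARGE_TOLERANCE = 1e-4
MAX_BISECTION_ITERATIONS = 60


@dataclass(frozen=True)
class ProteinDescriptor:
    protein_id: str
    length: int
    mw_kda: float
    pi: float


def _check_residues(seq: str, allow_x: bool) -> str:
    if not seq:
        raise SequenceError("empty protein sequence")
    seq = seq.upper()
    allowed = set(AVERAGE_RESIDUE_MASS_DA) | ({"X"} if allow_x else set())
    for ch in seq:
        if ch not in allowed:
            raise SequenceError(f"cannot handle residue {ch!r}")
    return seq


def molecular_weight(seq: str) -> float:
    """Average-mass molecular weight in kDa; rejects ambiguous residues."""
    seq = _check_residues(seq, allow_x=False)
    mass_da = sum(AVERAGE_RESIDUE_MASS_DA[ch] for ch in seq) + WATER_DA
    return mass_da / 1000.0


def net_charge(seq: str, ph: float) -> float:
    """Henderson-Hasselbalch net charge at the given pH.

    X residues are tolerated (they carry no ionizable group).
    """
    seq = _check_residues(seq, allow_x=True)
    nterm_pka = _NTERM_PKA_BY_RESIDUE.get(seq[0], _POSITIVE_PKA["Nterm"])
    cterm_pka = _CTERM_PKA_BY_RESIDUE.get(seq[-1], _NEGATIVE_PKA["Cterm"])
    positive = [(1, nterm_pka)] + [
        (seq.count(res), pka) for res, pka in _POSITIVE_PKA.items() if res != "Nterm"
    ]
    negative = [(1, cterm_pka)] + [
        (seq.count(res), pka) for res, pka in _NEGATIVE_PKA.items() if res != "Cterm"
    ]
    charge = sum(n / (1.0 + 10.0 ** (ph - pka)) for n, pka in positive)
    charge -= sum(n / (1.0 + 10.0 ** (pka - ph)) for n, pka in negative)
    return charge


def isoelectric_point(seq: str) -> float:
    """pH at which the net charge vanishes, by bisection on [0, 14]."""
    seq = _check_residues(seq, allow_x=True)
    lo, hi = 0.0, 14.0
    ph = 7.0
    # Refine by interval, not by |charge|: near the pI the charge curve can
    # be nearly flat, so a charge-based stop would leave the pH imprecise.
    for _ in range(MAX_BISECTION_ITERATIONS):
        ph = 0.5 * (lo + hi)
        if hi - lo < 1e-8:
            break
        if net_charge(seq, ph) > 0:
            lo = ph
        else:
            hi = ph
    assert abs(net_charge(seq, ph)) < PI_CHARGE_TOLERANCE
    return ph


def describe(protein_id: str, seq: str) -> ProteinDescriptor:
    return ProteinDescriptor(
        protein_id=protein_id,
        length=len(seq),
        mw_kda=molecular_weight(seq),
        pi=isoelectric_point(seq),
    )
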