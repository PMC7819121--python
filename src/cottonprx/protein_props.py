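"""Theoretical isoelectric point and molecular weight of protein sequences.

The pI is the pH at which the Henderson-Hasselbalch net charge of the
protein is zero.  Charged groups are the N- and C-termini and the D, E, C,
Y, H, K, R side chains; the packaged pKa set is the Bjellqvist table used
by the ExPASy Compute pI/Mw tool, including its residue-specific terminal
pKa values.  Masses are average (not monoisotopic) residue masses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from scipy.optimize import brentq

# Average residue masses (Da); a free water is added once per chain.
AVERAGE_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.01524


@dataclass
class PkaTable:
    """Side-chain and terminal pKa values plus residue masses.

    Swappable as data; defaults reproduce the Bjellqvist set (positive
    groups: N-terminus, K, R, H; negative groups: C-terminus, D, E, C, Y).
    """

    positive_sidechains: dict[str, float] = field(
        default_factory=lambda: {"K": 10.0, "R": 12.0, "H": 5.98}
    )
    negative_sidechains: dict[str, float] = field(
        default_factory=lambda: {"D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}
    )
    nterm_default: float = 7.5
    nterm_by_residue: dict[str, float] = field(
        default_factory=lambda: {
            "A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36,
            "T": 6.82, "V": 7.44, "E": 7.7,
        }
    )
    cterm_default: float = 3.55
    cterm_by_residue: dict[str, float] = field(
        default_factory=lambda: {"D": 4.55, "E": 4.75}
    )
    masses: dict[str, float] = field(
        default_factory=lambda: dict(AVERAGE_RESIDUE_MASS)
    )
    water_mass: float = WATER_MASS
    unknown_residue_mass: float = 110.0  # contribution of X

    def __post_init__(self) -> None:
        for pka in (
            *self.positive_sidechains.values(),
            *self.negative_sidechains.values(),
            self.nterm_default,
            self.cterm_default,
        ):
            if not 0 < pka < 14:
                raise ValueError(f"pKa {pka} outside (0, 14)")
        if any(m <= 0 for m in self.masses.values()):
            raise ValueError("residue masses must be positive")


DEFAULT_PKA_TABLE = PkaTable()


def molecular_weight(sequence: str, table: PkaTable | None = None) -> float:
    """Sum of average residue masses plus one water mass, in daltons."""
    table = table or DEFAULT_PKA_TABLE
    total = table.water_mass
    for i, aa in enumerate(sequence):
        if aa == "X":
            total += table.unknown_residue_mass
        elif aa in table.masses:
            total += table.masses[aa]
        else:
            raise ValueError(f"unknown residue {aa!r} at position {i}")
    return total


def net_charge(sequence: str, ph: float, table: PkaTable | None = None) -> float:
    """Henderson-Hasselbalch net charge of the sequence at a given pH."""
    if not sequence:
        raise ValueError("empty sequence")
    table = table or DEFAULT_PKA_TABLE
    positive = [table.nterm_by_residue.get(sequence[0], table.nterm_default)]
    negative = [table.cterm_by_residue.get(sequence[-1], table.cterm_default)]
    for aa in sequence:
        if aa in table.positive_sidechains:
            positive.append(table.positive_sidechains[aa])
        elif aa in table.negative_sidechains:
            negative.append(table.negative_sidechains[aa])
    charge = sum(1.0 / (1.0 + 10 ** (ph - pka)) for pka in positive)
    charge -= sum(1.0 / (1.0 + 10 ** (pka - ph)) for pka in negative)
    return charge


def isoelectric_point(
    sequence: str, table: PkaTable | None = None, tol: float = 1e-4
) -> float:
    """pH in [0, 14] where the net charge crosses zero (bisection).

    The net charge is strictly decreasing in pH, so the root is unique.
    """
    table = table or DEFAULT_PKA_TABLE
    return float(
        brentq(lambda ph: net_charge(sequence, ph, table), 0.0, 14.0, xtol=tol)
    )
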