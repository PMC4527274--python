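"""Amino-acid composition, biosynthetic cost and physical sequence properties.

The family-level analysis here asks whether residue usage in these
calcium sensors tracks the metabolic price of making each residue:
expensive aromatics (Trp, Tyr, Phe) should be rare and cheap residues
(Ala, Gly, Ser, Asp, Glu) common.  The association is measured as a
Spearman rank correlation between per-residue biosynthetic cost and
average abundance, so any strictly monotone re-scaling of the cost units
leaves the result unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd
from scipy.stats import spearmanr

from .core_io import AMINO_ACIDS, ProteinRecord

#: Biosynthetic energy cost per residue (arbitrary energy units); the
#: packaged default used throughout the family analysis.  Swappable.
DEFAULT_COSTS: Mapping[str, float] = {
    "A": 11.7, "C": 24.7, "D": 12.7, "E": 15.3, "F": 52.0,
    "G": 11.7, "H": 38.3, "I": 32.3, "K": 30.3, "L": 27.3,
    "M": 34.3, "N": 14.7, "P": 20.3, "Q": 16.3, "R": 27.3,
    "S": 11.7, "T": 18.7, "V": 23.3, "W": 74.3, "Y": 50.0,
}

#: Average (isotope-weighted) residue masses in Da, i.e. amino-acid mass
#: minus one water; a free chain adds one water back.
RESIDUE_MASS: Mapping[str, float] = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.0153

#: EMBOSS pKa set for net-charge / isoelectric-point calculation.
PKA_SETS: Mapping[str, Mapping[str, float]] = {
    "emboss": {
        "nterm": 8.6, "cterm": 3.6,
        "C": 8.5, "D": 3.9, "E": 4.1, "H": 6.5,
        "K": 10.8, "R": 12.5, "Y": 10.1,
    },
}

__all__ = [
    "DEFAULT_COSTS",
    "RESIDUE_MASS",
    "WATER_MASS",
    "PKA_SETS",
    "CostTable",
    "CompositionResult",
    "composition",
    "expected_counts",
    "cost_abundance_association",
    "molecular_weight",
    "net_charge",
    "isoelectric_point",
]


@dataclass(frozen=True)
class CostTable:
    """Energy cost (strictly positive) for each of the 20 residues."""

    cost: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_COSTS))

    def __post_init__(self) -> None:
        missing = set(AMINO_ACIDS) - set(self.cost)
        if missing:
            raise ValueError(f"cost table missing residues: {sorted(missing)}")
        bad = [aa for aa in AMINO_ACIDS if self.cost[aa] <= 0]
        if bad:
            raise ValueError(f"non-positive costs for: {bad}")


@dataclass(frozen=True)
class CompositionResult:
    """Average per-residue composition (percent) over a set of proteins."""

    per_residue_percent: Mapping[str, float]
    n_proteins: int

    def as_series(self) -> pd.Series:
        return pd.Series(
            {aa: self.per_residue_percent[aa] for aa in AMINO_ACIDS}, name="percent"
        )


def composition(records: Sequence[ProteinRecord]) -> CompositionResult:
    """Per-protein residue percentages averaged with equal weight per protein."""
    if not records:
        raise ValueError("composition of an empty record set is undefined")
    totals = {aa: 0.0 for aa in AMINO_ACIDS}
    for rec in records:
        length = len(rec)
        for aa in AMINO_ACIDS:
            totals[aa] += 100.0 * rec.sequence.count(aa) / length
    n = len(records)
    return CompositionResult(
        per_residue_percent={aa: totals[aa] / n for aa in AMINO_ACIDS},
        n_proteins=n,
    )


def expected_counts(comp: CompositionResult, protein_length: int) -> dict[str, float]:
    """Expected residue counts in a protein of the given length.

    The alternative reading of an "average composition" column as
    residues-per-protein rather than percent.
    """
    return {
        aa: comp.per_residue_percent[aa] / 100.0 * protein_length
        for aa in AMINO_ACIDS
    }


def cost_abundance_association(
    comp: CompositionResult, costs: Optional[CostTable] = None
) -> tuple[Optional[float], pd.DataFrame]:
    """Spearman correlation of biosynthetic cost vs. abundance over 20 residues.

    Ties get average ranks (scipy's convention).  If either variable has
    zero variance the correlation is undefined and ``None`` is returned.
    The paired per-residue table is always emitted for inspection.
    """
    if costs is None:
        costs = CostTable()
    table = pd.DataFrame({
        "residue": list(AMINO_ACIDS),
        "abundance_percent": [comp.per_residue_percent[aa] for aa in AMINO_ACIDS],
        "cost": [costs.cost[aa] for aa in AMINO_ACIDS],
    })
    if table["abundance_percent"].nunique() == 1 or table["cost"].nunique() == 1:
        return None, table
    rho = float(spearmanr(table["cost"], table["abundance_percent"]).statistic)
    return rho, table


def molecular_weight(seq: str) -> float:
    """Average molecular weight of the chain in kDa (residue masses + one water)."""
    seq = seq.upper()
    if not seq:
        raise ValueError("molecular weight of an empty sequence is undefined")
    try:
        mass = sum(RESIDUE_MASS[aa] for aa in seq) + WATER_MASS
    except KeyError as exc:
        raise ValueError(f"illegal residue {exc.args[0]!r} in sequence") from exc
    return mass / 1000.0


def net_charge(seq: str, ph: float, pka_set: str = "emboss") -> float:
    """Henderson-Hasselbalch net charge of the chain at the given pH."""
    pka = PKA_SETS[pka_set]
    seq = seq.upper()

    def pos(pk: float) -> float:
        return 1.0 / (1.0 + 10.0 ** (ph - pk))

    def neg(pk: float) -> float:
        return -1.0 / (1.0 + 10.0 ** (pk - ph))

    charge = pos(pka["nterm"]) + neg(pka["cterm"])
    for aa in "HKR":
        charge += seq.count(aa) * pos(pka[aa])
    for aa in "CDEY":
        charge += seq.count(aa) * neg(pka[aa])
    return charge


def isoelectric_point(seq: str, pka_set: str = "emboss", tol: float = 1e-4) -> float:
    """pH of zero net charge, by bisection on the monotone charge curve."""
    if not seq:
        raise ValueError("pI of an empty sequence is undefined")
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if net_charge(seq, mid, pka_set) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0
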