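"""Seeded generators for every input class the pipeline consumes.

Each generator is a pure function of its spec (seed included) and emits
a machine-readable truth sidecar, so downstream tests recover planted
ground truth instead of asserting hard-coded numbers.

``make_family`` emulates the structure of a plant CBL family: proteins
of roughly 250 residues carrying three 36-residue EF-hands, an
N-terminal lipidation region (Gly-2 plus a Cys in positions 3-6 for
groups A, C and D; neither for group B), the group-specific N-terminal
acidic motifs, the V-F-H-P-N block closing the first EF-hand and the
C-terminal P-S-F-V-F-x-S-E-V-D-E block.  Background residues are drawn
from the family's average amino-acid composition so synthetic proteins
are statistically CBL-like.  A deterministic repair pass guarantees the
planted hands are the only windows satisfying the strict scanner rule,
so recovery tests are exact.

The generators make no attempt at phylogenetic realism: there is no
substitution model, no tree, and no indel process.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core_io import AMINO_ACIDS, AlignmentBlock, ProteinRecord, records_to_block
from .efhand_motifs import (
    LOOP_CANONICAL_WINDOW_POSITIONS,
    WINDOW,
    ScanRule,
    qualifying_offsets,
)
from .expression_ddct import CtTable

#: Family-average residue composition (percent) used as the background
#: distribution, so synthetic members resemble real CBL proteins.
BACKGROUND_COMPOSITION: Mapping[str, float] = {
    "A": 5.99, "C": 1.27, "D": 8.07, "E": 8.94, "F": 7.97,
    "G": 3.96, "H": 2.12, "I": 6.25, "K": 7.03, "L": 10.84,
    "M": 2.24, "N": 3.79, "P": 3.29, "Q": 2.89, "R": 4.54,
    "S": 7.18, "T": 4.75, "V": 6.19, "W": 0.62, "Y": 1.98,
}

#: Group proportions reflecting how the reference CBL numbers split over
#: the four clades (A: 4 of 10 numbers, B: 1, C: 2, D: 3).
DEFAULT_GROUP_MIX: Mapping[str, float] = {"A": 0.4, "B": 0.1, "C": 0.2, "D": 0.3}

_CTERM_MOTIF = "PSFVF.SEVDE"  # '.' filled from background
_VFHPN = "VFHPN"

__all__ = [
    "BACKGROUND_COMPOSITION",
    "DEFAULT_GROUP_MIX",
    "FamilySpec",
    "AlignmentSpec",
    "SpecError",
    "make_family",
    "make_alignment",
    "make_trio",
    "make_ct_table",
]


class SpecError(ValueError):
    """A generator spec is internally infeasible."""


@dataclass(frozen=True)
class FamilySpec:
    """Study conditions for one synthetic CBL-like family."""

    n_proteins: int = 24
    length: int = 260
    hand_positions: tuple[int, int, int] = (40, 120, 200)
    group_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_MIX)
    )
    conservation_level: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        hands = sorted(self.hand_positions)
        if len(hands) != 3:
            raise SpecError("exactly three EF-hands must be planted")
        for h1, h2 in zip(hands, hands[1:]):
            if h2 < h1 + WINDOW + 1:
                raise SpecError(f"planted hands at {h1} and {h2} overlap or touch")
        if hands[0] < 34:
            raise SpecError("first hand must leave an N-terminal region of >= 33 aa")
        if hands[-1] + WINDOW - 1 > self.length:
            raise SpecError("last planted hand does not fit in the sequence")
        total = sum(self.group_mix.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise SpecError(f"group proportions sum to {total}, not 1")
        if not 0.0 <= self.conservation_level <= 1.0:
            raise SpecError("conservation_level must lie in [0, 1]")


def _background_sampler(rng: np.random.Generator):
    letters = np.array(list(BACKGROUND_COMPOSITION))
    weights = np.array([BACKGROUND_COMPOSITION[a] for a in letters])
    probs = weights / weights.sum()

    def draw(n: int, exclude: str = "") -> list[str]:
        if exclude:
            mask = np.array([a not in exclude for a in letters])
            p = probs * mask
            p = p / p.sum()
        else:
            p = probs
        return list(rng.choice(letters, size=n, p=p))

    return draw


def _allocate_groups(spec: FamilySpec) -> list[str]:
    """Deterministic largest-remainder allocation of members to groups."""
    groups = sorted(spec.group_mix)
    exact = {g: spec.group_mix[g] * spec.n_proteins for g in groups}
    counts = {g: int(exact[g]) for g in groups}
    short = spec.n_proteins - sum(counts.values())
    for g in sorted(groups, key=lambda g: (-(exact[g] - counts[g]), g))[:short]:
        counts[g] += 1
    out: list[str] = []
    for g in groups:
        out.extend([g] * counts[g])
    return out


def _plant_hand(seq: list[str], start: int, cl: float, rng: np.random.Generator) -> None:
    """Overwrite the loop core of the 36-aa window at 1-based ``start``.

    Mandatory positions always satisfy the strict rule; the key Asp at
    window position 14 is D with probability ``cl`` (else Glu), and
    accessory loop donors degrade from D/E to other oxygen donors as the
    conservation level drops.
    """
    base = start - 1

    def put(win_pos: int, res: str) -> None:
        seq[base + win_pos - 1] = res

    put(14, "D" if rng.random() < cl else "E")
    put(22, "E" if rng.random() < cl else "D")
    put(24, "D" if rng.random() < 0.5 else "E")  # bidentate loop-12 ligand
    # loop positions 1 and 3 are guaranteed oxygen donors (three donors
    # total with loop 12); higher conservation makes them acidic.
    for win_pos in (13, 15):
        if rng.random() < cl:
            put(win_pos, "D" if rng.random() < 0.5 else "E")
        else:
            put(win_pos, str(rng.choice(list("NQST"))))
    # loop position 5 is a donor only at conserved sites
    if rng.random() < cl:
        put(17, str(rng.choice(list("DENQST"))))


_KILL_RESIDUE = "L"  # non-donor, non-acidic, not Gly/Cys: safe everywhere


def _repair_spurious(
    seq: list[str], planted: Sequence[int], protected: set[int],
    rule: ScanRule, max_rounds: int = 200,
) -> None:
    """Mutate free residues until only the planted offsets qualify."""
    planted_set = set(planted)
    for _ in range(max_rounds):
        offenders = [o for o in qualifying_offsets("".join(seq), rule)
                     if o not in planted_set]
        if not offenders:
            return
        o = offenders[0]
        # mandatory rule positions first, then loop-donor positions
        candidates = [o + 13, o + 21, o + 23] + [
            o + wp - 1 for wp in LOOP_CANONICAL_WINDOW_POSITIONS
        ]
        for pos in candidates:
            if pos not in protected and 1 <= pos <= len(seq):
                seq[pos - 1] = _KILL_RESIDUE
                break
        else:
            raise SpecError(
                f"cannot suppress spurious EF-hand window at offset {o}: "
                "all of its rule positions are protected"
            )
    raise SpecError("spurious-window repair did not converge")


def make_family(spec: FamilySpec) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Generate a synthetic CBL-like family plus its truth table.

    Returns the protein records and a DataFrame with one row per record:
    ``record_id``, ``group``, ``hand1``/``hand2``/``hand3`` (planted
    starts), ``myristoylation_position`` and ``cys_position`` (NaN for
    group B members, which carry neither anchor).
    """
    rng = np.random.default_rng(spec.seed)
    draw = _background_sampler(rng)
    hands = tuple(sorted(spec.hand_positions))
    groups = _allocate_groups(spec)
    rule = ScanRule()

    records: list[ProteinRecord] = []
    truth_rows = []
    for idx, group in enumerate(groups, start=1):
        seq = draw(spec.length)
        seq[0] = "M"
        protected: set[int] = {1}

        # --- N-terminal lipidation region -------------------------------
        if group == "B":
            # no Gly at 2 or 7, no Cys anywhere in the first 25 residues
            seq[1] = draw(1, exclude="GC")[0]
            seq[6] = draw(1, exclude="GC")[0]
            for pos in range(2, 25):
                if seq[pos] == "C":
                    seq[pos] = draw(1, exclude="C")[0]
            myr_pos: Optional[int] = None
            cys_pos: Optional[int] = None
            protected.update(range(1, 26))
        else:
            seq[1] = "G"
            cys_pos = int(rng.integers(3, 7))  # one of 3..6
            seq[cys_pos - 1] = "C"
            myr_pos = 2
            protected.update({2, cys_pos})

        # --- group-specific N-terminal acidic motifs --------------------
        if group == "D":  # E-E/D-P at 16-18
            seq[15] = "E"
            seq[16] = "E" if rng.random() < 0.5 else "D"
            seq[17] = "P"
            protected.update({16, 17, 18})
        elif group == "A":  # D/E-x-E/D at 31-33
            seq[30] = "D" if rng.random() < 0.5 else "E"
            seq[32] = "E" if rng.random() < 0.5 else "D"
            protected.update({31, 32, 33})

        # --- three EF-hands, V-F-H-P-N and the C-terminal block ---------
        for h in hands:
            _plant_hand(seq, h, spec.conservation_level, rng)
            protected.update({h + 12, h + 13, h + 14, h + 16, h + 21, h + 23})
        # V-F-H-P-N closes the first hand (window positions 32-36)
        for i, ch in enumerate(_VFHPN):
            seq[hands[0] + 30 + i] = ch
            protected.add(hands[0] + 31 + i)
        cterm_start = hands[-1] + WINDOW + 4
        if cterm_start + len(_CTERM_MOTIF) - 1 <= spec.length:
            for i, ch in enumerate(_CTERM_MOTIF):
                if ch != ".":
                    seq[cterm_start - 1 + i] = ch
                    protected.add(cterm_start + i)

        _repair_spurious(seq, hands, protected, rule)
        rec = ProteinRecord(id=f"SYN{idx:03d}", sequence="".join(seq),
                            genus="Synthetica", species_epithet="exemplaris")
        records.append(rec)
        truth_rows.append({
            "record_id": rec.id, "group": group,
            "hand1": hands[0], "hand2": hands[1], "hand3": hands[2],
            "myristoylation_position": myr_pos, "cys_position": cys_pos,
        })
    return records, pd.DataFrame(truth_rows)


@dataclass(frozen=True)
class AlignmentSpec:
    """Conditions for a gap-free alignment with a fixed number of
    segregating columns (a desk-scale analogue of the family alignment)."""

    m: int = 20
    n: int = 100
    S: int = 40
    states_per_segregating_column: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 4:
            raise SpecError("need m >= 4 sequences")
        if not 0 <= self.S <= self.n:
            raise SpecError(f"S={self.S} outside 0..n={self.n}")
        if not 2 <= self.states_per_segregating_column <= min(self.m, 20):
            raise SpecError("states per segregating column must be in 2..min(m, 20)")


def make_alignment(spec: AlignmentSpec) -> tuple[AlignmentBlock, dict]:
    """Alignment with exactly S segregating columns, plus truth (pi, S).

    Truth pi comes from an exhaustive pair-loop count performed at
    generation time, independent of the diversity estimator under test.
    """
    rng = np.random.default_rng(spec.seed)
    letters = list(AMINO_ACIDS)
    base = rng.choice(letters, size=spec.n)
    matrix = np.tile(base, (spec.m, 1))
    seg_cols = rng.choice(spec.n, size=spec.S, replace=False)
    for col in seg_cols:
        k = spec.states_per_segregating_column
        states = rng.choice(letters, size=k, replace=False)
        # every state appears at least once -> exactly >= 2 states realized
        assignment = rng.integers(0, k, size=spec.m)
        for s in range(k):
            if not (assignment == s).any():
                assignment[rng.integers(0, spec.m)] = s
        matrix[:, col] = states[assignment]

    rows = [
        ProteinRecord(id=f"ALN{i + 1:03d}", sequence="".join(matrix[i]), aligned=True)
        for i in range(spec.m)
    ]
    block = AlignmentBlock(records=tuple(rows))

    # independent exhaustive pair loop for truth pi
    total = 0.0
    pairs = 0
    for i in range(spec.m):
        for j in range(i + 1, spec.m):
            diffs = int((matrix[i] != matrix[j]).sum())
            total += diffs / spec.n
            pairs += 1
    realized_S = int(sum(len(set(matrix[:, c])) >= 2 for c in range(spec.n)))
    if realized_S != spec.S:
        raise SpecError(f"realized {realized_S} segregating columns, wanted {spec.S}")
    truth = {"pi": total / pairs, "S": spec.S, "n": spec.n}
    return block, truth


def make_trio(
    unique_a: int, unique_b: int, unique_c: int,
    identical: int, divergent_all: int, seed: int = 0,
) -> AlignmentBlock:
    """Three-sequence gap-free alignment with the requested site-pattern counts."""
    for name, v in [("unique_a", unique_a), ("unique_b", unique_b),
                    ("unique_c", unique_c), ("identical", identical),
                    ("divergent_all", divergent_all)]:
        if v < 0:
            raise SpecError(f"{name} must be >= 0")
    rng = np.random.default_rng(seed)
    letters = list(AMINO_ACIDS)
    columns: list[tuple[str, str, str]] = []

    def distinct(k: int) -> list[str]:
        return list(rng.choice(letters, size=k, replace=False))

    for _ in range(identical):
        (x,) = distinct(1)
        columns.append((x, x, x))
    for _ in range(unique_a):
        x, y = distinct(2)
        columns.append((y, x, x))
    for _ in range(unique_b):
        x, y = distinct(2)
        columns.append((x, y, x))
    for _ in range(unique_c):
        x, y = distinct(2)
        columns.append((x, x, y))
    for _ in range(divergent_all):
        x, y, z = distinct(3)
        columns.append((x, y, z))
    if not columns:
        raise SpecError("trio with zero columns")
    rng.shuffle(columns)
    rows = ["".join(col[i] for col in columns) for i in range(3)]
    return records_to_block([
        ProteinRecord(id=name, sequence=row, aligned=True)
        for name, row in zip(("seqA", "seqB", "seqC"), rows)
    ])


def make_ct_table(
    fold_changes: Mapping[str, float],
    replicates: int = 3,
    noise_sd: float = 0.1,
    seed: int = 0,
    reference_gene: str = "ACT1",
    calibrator_condition: str = "control",
    treated_condition: str = "treated",
    timepoint: str = "t1",
    reference_ct: float = 20.0,
    baseline_ct: float = 25.0,
) -> CtTable:
    """Triplicate-style Ct table with known fold changes planted.

    Treated-condition target Ct is shifted by -log2(fold change) relative
    to the calibrator; Gaussian cycle-scale noise of ``noise_sd`` is added
    to every measured Ct (reference included), emulating replicate
    scatter.  ``noise_sd=0`` yields exact recovery of each fold change.
    """
    if replicates < 2:
        raise SpecError("need at least 2 replicates")
    for gene, fc in fold_changes.items():
        if fc <= 0:
            raise SpecError(f"fold change for {gene!r} must be > 0")
    rng = np.random.default_rng(seed)
    rows = []

    def add(gene: str, condition: str, mean_ct: float) -> None:
        for rep in range(1, replicates + 1):
            ct = mean_ct + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            rows.append({"gene": gene, "condition": condition,
                         "timepoint": timepoint, "replicate": rep, "ct": ct})

    for condition in (calibrator_condition, treated_condition):
        add(reference_gene, condition, reference_ct)
    for gene, fc in sorted(fold_changes.items()):
        add(gene, calibrator_condition, baseline_ct)
        add(gene, treated_condition, baseline_ct - math.log2(fc))
    return CtTable(
        data=pd.DataFrame(rows),
        reference_gene=reference_gene,
        calibrator_condition=calibrator_condition,
    )
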