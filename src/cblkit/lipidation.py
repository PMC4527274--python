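"""N-terminal lipidation rules for CBL calcium sensors.

Membrane targeting of these proteins uses two cooperating lipid anchors:
co-translational myristoylation of a glycine near the N-terminus
(position 2 after the initiator Met, with a secondary site at position
7) and palmitoylation of N-terminal cysteines (canonically positions
3-6; any Cys within the first 25 residues is a candidate site).
Myristoylation is the biological prerequisite for palmitoylation, so the
group summary reports — but does not enforce — the palmitoylated-but-
not-myristoylated inconsistency count.

Group B family members (the CBL10 clade) characteristically lack both
anchors; groups A, C and D carry them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from .core_io import ProteinRecord

#: Canonical palmitoylation window: Cys at any of these positions.
CANONICAL_CYS_POSITIONS = frozenset({3, 4, 5, 6})

#: Cys sites are searched within this N-terminal prefix.
NTERM_SEARCH_LENGTH = 25

#: Myristoylation Gly positions, primary then secondary.
MYRISTOYLATION_POSITIONS = (2, 7)

VALID_GROUPS = frozenset("ABCD")

__all__ = [
    "LipidationCall",
    "predict_myristoylation",
    "predict_palmitoylation",
    "call_lipidation",
    "group_pattern_check",
]


@dataclass(frozen=True)
class LipidationCall:
    record_id: str
    myristoylation: bool
    myristoylation_position: Optional[int]
    palmitoylation_positions: tuple[int, ...]
    canonical_palmitoylation: bool
    group_b_like: bool  # neither anchor present: the group-B signature
    truncated_nterm: bool = False  # sequence shorter than the 25-aa search window


def predict_myristoylation(seq: str) -> tuple[bool, Optional[int]]:
    """Gly at position 2 (primary) or position 7 (secondary myristoylation site)."""
    seq = seq.upper()
    if len(seq) < max(MYRISTOYLATION_POSITIONS):
        raise ValueError("sequence too short for N-terminal myristoylation check")
    for pos in MYRISTOYLATION_POSITIONS:
        if seq[pos - 1] == "G":
            return True, pos
    return False, None


def predict_palmitoylation(seq: str) -> tuple[bool, tuple[int, ...], bool]:
    """Cys positions within the N-terminal 25 residues.

    Returns ``(canonical, positions, truncated)`` where ``canonical`` is
    true iff a Cys sits at position 3, 4, 5 or 6, and ``truncated`` flags
    sequences shorter than the search window (positions then cover only
    the available prefix).
    """
    seq = seq.upper()
    truncated = len(seq) < NTERM_SEARCH_LENGTH
    prefix = seq[:NTERM_SEARCH_LENGTH]
    positions = tuple(i for i, ch in enumerate(prefix, start=1) if ch == "C")
    canonical = any(p in CANONICAL_CYS_POSITIONS for p in positions)
    return canonical, positions, truncated


def call_lipidation(record: ProteinRecord) -> LipidationCall:
    myr, myr_pos = predict_myristoylation(record.sequence)
    canonical, cys_positions, truncated = predict_palmitoylation(record.sequence)
    return LipidationCall(
        record_id=record.id,
        myristoylation=myr,
        myristoylation_position=myr_pos,
        palmitoylation_positions=cys_positions,
        canonical_palmitoylation=canonical,
        group_b_like=not myr and not cys_positions,
        truncated_nterm=truncated,
    )


def group_pattern_check(
    calls: Sequence[LipidationCall], groups: Mapping[str, str]
) -> pd.DataFrame:
    """Per-group lipidation fractions and expectation flags.

    Expectation: group B lacks the canonical Cys anchor; groups A, C and D
    carry it.  ``violates_expectation`` marks groups departing from that
    pattern; empty groups report NaN fractions and no violation.  The
    ``palm_without_myr`` column counts members carrying a Cys site without
    a myristoylation site (biologically inconsistent, reported only).
    """
    for call in calls:
        if call.record_id not in groups:
            raise KeyError(f"record {call.record_id!r} has no group label")
        g = groups[call.record_id].upper()
        if g not in VALID_GROUPS:
            raise ValueError(f"unknown group label {g!r} for {call.record_id!r}")
    rows = []
    by_group: dict[str, list[LipidationCall]] = {g: [] for g in sorted(VALID_GROUPS)}
    for call in calls:
        by_group[groups[call.record_id].upper()].append(call)
    for g, members in by_group.items():
        n = len(members)
        if n == 0:
            rows.append({"group": g, "n": 0, "frac_canonical_palmitoylation": float("nan"),
                         "frac_myristoylation": float("nan"), "palm_without_myr": 0,
                         "violates_expectation": False})
            continue
        frac_palm = sum(c.canonical_palmitoylation for c in members) / n
        frac_myr = sum(c.myristoylation for c in members) / n
        inconsistent = sum(
            bool(c.palmitoylation_positions) and not c.myristoylation for c in members
        )
        expected_absent = g == "B"
        violates = (frac_palm > 0) if expected_absent else (frac_palm < 1)
        rows.append({"group": g, "n": n,
                     "frac_canonical_palmitoylation": frac_palm,
                     "frac_myristoylation": frac_myr,
                     "palm_without_myr": inconsistent,
                     "violates_expectation": violates})
    return pd.DataFrame(rows)
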