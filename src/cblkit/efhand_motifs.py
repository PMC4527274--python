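"""EF-hand detection, degenerate motif matching and conservation profiling.

A canonical EF-hand is a 36-residue helix-loop-helix calcium-binding
module: a 12-residue entering helix, a 12-residue calcium-coordinating
loop, and a 12-residue exiting helix.  Within the loop, the side-chain
oxygen donors at canonical positions 1, 3, 5, 7, 9 and 12 ligate the
Ca2+ ion, with the invariant Asp/Glu at loop position 12 acting as a
bidentate ligand.  Plant calcineurin B-like (CBL) calcium sensors carry
exactly three such EF-hands — one fewer than calmodulin — and that count
is the classification rule used here.

The scanner is a transparent rule system rather than a profile HMM: it
enforces Asp/Glu at the family-critical window positions 14 and 22, the
bidentate Asp/Glu at loop position 12, and a minimum number of
oxygen-donor residues over the six canonical loop positions.  All
thresholds live in :class:`ScanRule` so the geometry can be probed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .core_io import AMINO_ACIDS, GAP, AlignmentBlock, ProteinRecord

#: Residues whose side chains donate oxygen to the coordinated Ca2+.
OXYGEN_DONORS = frozenset("DENQST")

#: Length of one helix-loop-helix EF-hand module.
WINDOW = 36

#: Window offsets (1-based) of the canonical loop positions 1,3,5,7,9,12.
#: The 12-residue loop occupies window positions 13..24.
LOOP_CANONICAL_WINDOW_POSITIONS = (13, 15, 17, 19, 21, 24)

#: Family-critical acidic positions within the 36-residue window.
KEY_POSITIONS = (7, 14, 22)

_AA_SET = frozenset(AMINO_ACIDS)

__all__ = [
    "OXYGEN_DONORS",
    "WINDOW",
    "LOOP_CANONICAL_WINDOW_POSITIONS",
    "KEY_POSITIONS",
    "MotifPattern",
    "PatternSyntaxError",
    "ScanRule",
    "EFHandHit",
    "EFHandProfile",
    "CblClassification",
    "parse_pattern",
    "find_motifs",
    "window_checks",
    "window_qualifies",
    "qualifying_offsets",
    "scan_ef_hands",
    "classify_cbl",
    "conservation_profile",
    "nterminal_motif_check",
]


class PatternSyntaxError(ValueError):
    """A degenerate-motif pattern string could not be parsed."""


@dataclass(frozen=True)
class MotifPattern:
    """A degenerate motif: one residue set (or wildcard = None) per position."""

    tokens: tuple[Optional[frozenset[str]], ...]
    label: str

    def __len__(self) -> int:
        return len(self.tokens)


def parse_pattern(spec: str) -> MotifPattern:
    """Parse a motif string such as ``"D/E-x-D"`` or ``"E/D-D-P-E-x4-E-x6-E"``.

    Tokens are dash-separated; alternatives within a token are joined by
    ``/``; ``x`` is a wildcard and ``x<k>`` (or ``x_k``) expands to ``k``
    wildcards.  A pattern consisting solely of wildcards is rejected.
    """
    raw = spec.strip()
    if not raw:
        raise PatternSyntaxError("empty pattern")
    tokens: list[Optional[frozenset[str]]] = []
    for tok in raw.split("-"):
        tok = tok.strip()
        if not tok:
            raise PatternSyntaxError(f"empty token in pattern {spec!r}")
        m = re.fullmatch(r"[xX](?:_?(\d+))?", tok)
        if m:
            repeat = int(m.group(1)) if m.group(1) else 1
            if repeat < 1:
                raise PatternSyntaxError(f"non-positive wildcard repeat in {spec!r}")
            tokens.extend([None] * repeat)
            continue
        residues = frozenset(part.strip().upper() for part in tok.split("/"))
        if not residues or any(r not in _AA_SET for r in residues):
            raise PatternSyntaxError(f"unknown residue in token {tok!r} of {spec!r}")
        tokens.append(residues)
    if all(t is None for t in tokens):
        raise PatternSyntaxError(f"pattern {spec!r} has no informative token")
    if len(tokens) < 2:
        raise PatternSyntaxError(f"pattern {spec!r} needs at least 2 positions")
    return MotifPattern(tokens=tuple(tokens), label=raw)


def find_motifs(seq: str, pattern: MotifPattern) -> list[int]:
    """All 1-based start positions where ``pattern`` matches, overlaps included."""
    seq = seq.upper()
    k = len(pattern)
    hits = []
    for start in range(len(seq) - k + 1):
        if all(
            tok is None or seq[start + i] in tok
            for i, tok in enumerate(pattern.tokens)
        ):
            hits.append(start + 1)
    return hits


@dataclass(frozen=True)
class ScanRule:
    """Thresholds for the EF-hand window rule.

    ``min_loop_matches`` is the minimum number of oxygen-donor residues
    over the six canonical loop positions; the bidentate Asp/Glu at loop
    position 12 and the acidic residues at window positions 14 and 22 are
    mandatory gates.  ``strict`` reports only fully qualifying windows;
    permissive mode additionally reports sub-threshold windows whose
    fractional score reaches ``permissive_min_score``.
    """

    min_loop_matches: int = 3
    require_loop12_acidic: bool = True
    strict: bool = True
    permissive_min_score: float = 0.5


@dataclass(frozen=True)
class EFHandHit:
    """One detected 36-residue EF-hand window."""

    start: int  # 1-based residue position of the window
    loop_start: int  # start of the 12-residue loop = start + 12
    key_matches: dict[int, Optional[str]]  # window positions 7/14/22 -> D/E or None
    loop_canonical_matches: int  # oxygen donors over the six loop positions
    score: float


def _window_residue(seq: str, start: int, window_pos: int) -> str:
    # start 1-based, window_pos 1-based within the 36-aa window
    return seq[start - 1 + window_pos - 1]


def window_checks(seq: str, start: int) -> dict[str, bool]:
    """The eight individual rule checks for the window starting at ``start``.

    Keys: ``key14``, ``key22`` (Asp/Glu at window positions 14 and 22),
    ``loop1``, ``loop3``, ``loop5``, ``loop7``, ``loop9`` (oxygen donor at
    the canonical loop position) and ``loop12`` (Asp/Glu bidentate ligand).
    """
    checks = {
        "key14": _window_residue(seq, start, 14) in "DE",
        "key22": _window_residue(seq, start, 22) in "DE",
    }
    for loop_pos, win_pos in zip((1, 3, 5, 7, 9), LOOP_CANONICAL_WINDOW_POSITIONS):
        checks[f"loop{loop_pos}"] = _window_residue(seq, start, win_pos) in OXYGEN_DONORS
    checks["loop12"] = _window_residue(seq, start, 24) in "DE"
    return checks


def _loop_donor_count(seq: str, start: int) -> int:
    return sum(
        _window_residue(seq, start, wp) in OXYGEN_DONORS
        for wp in LOOP_CANONICAL_WINDOW_POSITIONS
    )


def window_qualifies(seq: str, start: int, rule: ScanRule = ScanRule()) -> bool:
    """Does the window at 1-based ``start`` satisfy the full (strict) rule?"""
    if start < 1 or start + WINDOW - 1 > len(seq):
        return False
    c = window_checks(seq, start)
    if not (c["key14"] and c["key22"]):
        return False
    if rule.require_loop12_acidic and not c["loop12"]:
        return False
    return _loop_donor_count(seq, start) >= rule.min_loop_matches


def qualifying_offsets(seq: str, rule: ScanRule = ScanRule()) -> list[int]:
    """All 1-based offsets whose window passes the strict rule (overlaps kept)."""
    seq = seq.upper()
    return [s for s in range(1, len(seq) - WINDOW + 2) if window_qualifies(seq, s, rule)]


def _make_hit(seq: str, start: int, score: float) -> EFHandHit:
    key = {}
    for pos in KEY_POSITIONS:
        res = _window_residue(seq, start, pos)
        key[pos] = res if res in "DE" else None
    return EFHandHit(
        start=start,
        loop_start=start + 12,
        key_matches=key,
        loop_canonical_matches=_loop_donor_count(seq, start),
        score=score,
    )


def scan_ef_hands(seq: str, rule: ScanRule = ScanRule()) -> list[EFHandHit]:
    """Scan a protein for 36-residue EF-hand windows.

    Candidate windows are evaluated at every offset; overlapping
    candidates are resolved greedily left to right (smaller start wins),
    matching the first/second/third-hand ordering used to describe these
    proteins.  Strict hits carry score 1.0; permissive mode also reports
    sub-threshold windows scored by the fraction of the eight individual
    checks satisfied.
    """
    seq = seq.upper()
    if len(seq) < WINDOW:
        raise ValueError(f"sequence of {len(seq)} aa is shorter than one "
                         f"{WINDOW}-aa EF-hand")
    candidates: list[tuple[int, float]] = []
    for start in range(1, len(seq) - WINDOW + 2):
        if window_qualifies(seq, start, rule):
            candidates.append((start, 1.0))
        elif not rule.strict:
            checks = window_checks(seq, start)
            score = sum(checks.values()) / len(checks)
            if score >= rule.permissive_min_score:
                candidates.append((start, score))
    hits: list[EFHandHit] = []
    next_free = 1
    for start, score in candidates:  # already sorted by start
        if start >= next_free:
            hits.append(_make_hit(seq, start, score))
            next_free = start + WINDOW
    return hits


@dataclass(frozen=True)
class CblClassification:
    """EF-hand count based family call: a CBL carries exactly three hands."""

    record_id: str
    n_hands: int
    is_cbl: bool
    hand_starts: tuple[int, ...]


def classify_cbl(record: ProteinRecord, rule: ScanRule = ScanRule()) -> CblClassification:
    hits = scan_ef_hands(record.sequence, rule)
    starts = tuple(h.start for h in hits)
    return CblClassification(
        record_id=record.id,
        n_hands=len(hits),
        is_cbl=len(hits) == 3,
        hand_starts=starts,
    )


@dataclass(frozen=True)
class EFHandProfile:
    """Per-position Asp/Glu frequencies over a 36-column family window.

    Frequencies are computed over non-gap residues only, so a member with
    a gap at a column drops out of that column's denominator.
    """

    position_freq: tuple[dict[str, float], ...]  # 36 dicts: keys D, E, DE
    n_members: int

    def freq(self, window_pos: int, key: str) -> float:
        return self.position_freq[window_pos - 1][key]


def conservation_profile(block: AlignmentBlock, window_start_column: int) -> EFHandProfile:
    """Asp/Glu conservation over a 36-column window of a family alignment."""
    first, last = window_start_column, window_start_column + WINDOW - 1
    if first < 1 or last > block.n_columns:
        raise IndexError(
            f"window columns {first}..{last} outside 1..{block.n_columns}"
        )
    freqs = []
    for col in range(first, last + 1):
        column = block.column(col)
        residues = [c for c in column if c != GAP]
        n = len(residues)
        if n == 0:
            freqs.append({"D": 0.0, "E": 0.0, "DE": 0.0})
            continue
        d = sum(c == "D" for c in residues) / n
        e = sum(c == "E" for c in residues) / n
        freqs.append({"D": d, "E": e, "DE": d + e})
    return EFHandProfile(position_freq=tuple(freqs), n_members=len(block))


# Group-specific N-terminal motifs, anchored at fixed positions from Met=1.
_GROUP_MOTIFS = {
    # group D: E-E/D-P at positions 16-18
    "D": (16, parse_pattern("E-E/D-P")),
    # group A: D/E-x-E/D at positions 31-33
    "A": (31, parse_pattern("D/E-x-E/D")),
}


def nterminal_motif_check(seq: str, group: str) -> dict:
    """Check the group-specific N-terminal acidic motif at its fixed anchor.

    Group D proteins carry E-E/D-P at positions 16-18; group A proteins
    carry D/E-x-E/D at positions 31-33 (positions counted from Met = 1).
    """
    group = group.upper()
    if group not in _GROUP_MOTIFS:
        raise ValueError(f"no anchored N-terminal motif defined for group {group!r}")
    anchor, pattern = _GROUP_MOTIFS[group]
    seq = seq.upper()
    end = anchor + len(pattern) - 1
    if len(seq) < end:
        return {"group": group, "anchor": anchor, "match": False,
                "pattern": pattern.label, "reason": "sequence too short"}
    segment_ok = all(
        tok is None or seq[anchor - 1 + i] in tok
        for i, tok in enumerate(pattern.tokens)
    )
    return {"group": group, "anchor": anchor, "match": segment_ok,
            "pattern": pattern.label}
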