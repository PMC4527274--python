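"""Orthology-based gene nomenclature for CBL family members.

Names follow the convention <SpeciesAbbrev>CBL<n>[-p]: the species
abbreviation is the genus initial (upper case) plus a prefix of the
species epithet (lower case); <n> is the CBL number of the best-matching
reference ortholog (rice for monocots, Arabidopsis for everything else);
and -p distinguishes paralogs when several genes of one species map to
the same reference number.

Abbreviation collisions are resolved asymmetrically: the earlier species
keeps its short form and the later one jumps to a four-letter epithet
prefix, extending one letter at a time until unique — so Capsella
rubella is "Cr" while Chlamydomonas reinhardtii becomes "Crein".  A
minimal-unique alternative policy is selectable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Literal, Mapping, Optional, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .core_io import ProteinRecord

__all__ = [
    "SpeciesAbbrev",
    "ReferenceProtein",
    "NameAssignment",
    "DuplicateSpeciesError",
    "UnresolvableCollisionError",
    "make_abbrevs",
    "make_aligner",
    "alignment_score",
    "best_ortholog",
    "assign_names",
    "parse_name",
]


class DuplicateSpeciesError(ValueError):
    """Two identical (genus, epithet) pairs in the species set."""


class UnresolvableCollisionError(ValueError):
    """The species epithet ran out of letters before the abbreviation was unique."""


@dataclass(frozen=True)
class SpeciesAbbrev:
    genus: str
    species_epithet: str
    abbrev: str


def _abbrev(genus: str, epithet: str, k: int) -> str:
    return genus[0].upper() + epithet[:k].lower()


def make_abbrevs(
    species_list: Sequence[tuple[str, str]],
    policy: Literal["classic", "minimal"] = "classic",
) -> list[SpeciesAbbrev]:
    """Assign unique species abbreviations in input order.

    Every species starts with a one-letter epithet prefix.  When a new
    entry collides with an existing abbreviation, the earlier entry keeps
    its form and the later one extends its prefix — jumping straight to
    four letters under the default ``"classic"`` policy, or growing one
    letter at a time under ``"minimal"`` — until unique.
    """
    seen_species: set[tuple[str, str]] = set()
    taken: set[str] = set()
    out: list[SpeciesAbbrev] = []
    for genus, epithet in species_list:
        if not genus or not epithet:
            raise ValueError("genus and species epithet must be non-empty")
        key = (genus.lower(), epithet.lower())
        if key in seen_species:
            raise DuplicateSpeciesError(f"duplicate species {genus} {epithet}")
        seen_species.add(key)
        k = 1
        cand = _abbrev(genus, epithet, k)
        if cand in taken:
            k = 2 if policy == "minimal" else 4
            cand = _abbrev(genus, epithet, k)
            while cand in taken:
                k += 1
                if k > len(epithet):
                    raise UnresolvableCollisionError(
                        f"cannot disambiguate {genus} {epithet}: epithet exhausted"
                    )
                cand = _abbrev(genus, epithet, k)
        taken.add(cand)
        out.append(SpeciesAbbrev(genus=genus, species_epithet=epithet, abbrev=cand))
    return out


@dataclass(frozen=True)
class ReferenceProtein:
    """A reference-species CBL with its established number (e.g. AtCBL4 -> 4)."""

    id: str
    cbl_number: int
    sequence: str


def make_aligner(
    matrix_name: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> Align.PairwiseAligner:
    """Global protein aligner with affine gaps (penalties given as positive)."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix_name)
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def alignment_score(
    query: str, target: str, aligner: Optional[Align.PairwiseAligner] = None
) -> float:
    if aligner is None:
        aligner = make_aligner()
    return float(aligner.score(query, target))


def best_ortholog(
    query: ProteinRecord,
    references: Sequence[ReferenceProtein],
    aligner: Optional[Align.PairwiseAligner] = None,
) -> tuple[ReferenceProtein, float]:
    """Reference with the maximal global alignment score against ``query``.

    Ties break toward the lower reference CBL number, then the
    lexicographically smaller reference id.
    """
    if not references:
        raise ValueError("empty reference set")
    if aligner is None:
        aligner = make_aligner()
    scored = [
        (alignment_score(query.sequence, ref.sequence, aligner), ref)
        for ref in references
    ]
    best = max(scored, key=lambda t: (t[0], -t[1].cbl_number,
                                      _reversed_lex_key(t[1].id)))
    return best[1], best[0]


def _reversed_lex_key(s: str):
    # max() picks the largest key; to prefer the lexicographically smaller
    # id we invert each character's code point.
    return tuple(-ord(c) for c in s)


@dataclass(frozen=True)
class NameAssignment:
    record_id: str
    abbrev: str
    ortholog_number: int
    paralog_index: Optional[int]
    final_name: str
    reference_id: str = ""
    score: float = float("nan")


_NAME_RE = re.compile(r"^([A-Z][a-z]*)CBL(\d+)(?:-(\d+))?$")


def parse_name(name: str) -> tuple[str, int, Optional[int]]:
    """Split a final name back into (abbrev, ortholog_number, paralog_index)."""
    m = _NAME_RE.match(name)
    if not m:
        raise ValueError(f"not a valid CBL name: {name!r}")
    return m.group(1), int(m.group(2)), int(m.group(3)) if m.group(3) else None


def assign_names(
    records: Sequence[ProteinRecord],
    lineage: Mapping[tuple[str, str], str],
    rice_refs: Sequence[ReferenceProtein],
    arabidopsis_refs: Sequence[ReferenceProtein],
    aligner: Optional[Align.PairwiseAligner] = None,
    abbrev_policy: Literal["classic", "minimal"] = "classic",
) -> list[NameAssignment]:
    """Name every record by its best reference ortholog.

    ``lineage`` maps (genus, epithet) to "monocot", "dicot" or "other";
    monocots are numbered against the rice references, all others against
    Arabidopsis.  Species abbreviations are assigned alphabetically by
    (genus, epithet) so an unordered input set yields reproducible names.
    Within one species, records sharing an ortholog number get -1, -2, ...
    ordered by descending alignment score, then record id.
    """
    if aligner is None:
        aligner = make_aligner()
    species = sorted({(r.genus, r.species_epithet) for r in records})
    for sp in species:
        if sp not in lineage:
            raise KeyError(f"no lineage label for species {sp[0]} {sp[1]}")
        if lineage[sp] not in ("monocot", "dicot", "other"):
            raise ValueError(f"unknown lineage label {lineage[sp]!r} for {sp}")
    abbrevs = {
        (a.genus, a.species_epithet): a.abbrev
        for a in make_abbrevs(species, policy=abbrev_policy)
    }

    matched: list[tuple[ProteinRecord, ReferenceProtein, float]] = []
    for rec in records:
        refs = rice_refs if lineage[(rec.genus, rec.species_epithet)] == "monocot" \
            else arabidopsis_refs
        ref, score = best_ortholog(rec, refs, aligner)
        matched.append((rec, ref, score))

    # group by (species, ortholog number) for paralog suffixing
    groups: dict[tuple[tuple[str, str], int], list[tuple[ProteinRecord, ReferenceProtein, float]]] = {}
    for rec, ref, score in matched:
        groups.setdefault(((rec.genus, rec.species_epithet), ref.cbl_number), []).append(
            (rec, ref, score)
        )

    assignments: dict[str, NameAssignment] = {}
    for ((sp, number)), members in groups.items():
        abbrev = abbrevs[sp]
        members.sort(key=lambda t: (-t[2], t[0].id))
        for idx, (rec, ref, score) in enumerate(members, start=1):
            paralog = idx if len(members) >= 2 else None
            name = f"{abbrev}CBL{number}" + (f"-{paralog}" if paralog else "")
            assignments[rec.id] = NameAssignment(
                record_id=rec.id, abbrev=abbrev, ortholog_number=number,
                paralog_index=paralog, final_name=name,
                reference_id=ref.id, score=score,
            )
    return [assignments[rec.id] for rec in records]
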