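import numpy as np
import pytest

from cblkit.core_io import ProteinRecord, records_to_block
from cblkit.efhand_motifs import (
    LOOP_CANONICAL_WINDOW_POSITIONS,
    OXYGEN_DONORS,
    WINDOW,
    PatternSyntaxError,
    ScanRule,
    classify_cbl,
    conservation_profile,
    find_motifs,
    nterminal_motif_check,
    parse_pattern,
    qualifying_offsets,
    scan_ef_hands,
)
from conftest import canonical_hand_window, random_protein


class TestPatternParsing:
    def test_alternatives_and_wildcard(self):
        pat = parse_pattern("D/E-x-D")
        assert len(pat) == 3
        assert pat.tokens[0] == frozenset("DE")
        assert pat.tokens[1] is None
        assert pat.tokens[2] == frozenset("D")

    def test_cterminal_domain_has_eleven_positions(self):
        assert len(parse_pattern("P-S-F-V-F-x-S-E-V-D-E")) == 11

    def test_repeated_wildcards_expand(self):
        # E/D-D-P-E then 4 wildcards, E, 6 wildcards, E
        assert len(parse_pattern("E/D-D-P-E-x4-E-x6-E")) == 16

    @pytest.mark.parametrize("bad", ["x", "x-x4", "", "D--E", "D/Z-x-D"])
    def test_degenerate_or_malformed_patterns_rejected(self, bad):
        with pytest.raises(PatternSyntaxError):
            parse_pattern(bad)


class TestFindMotifs:
    def test_simple_match(self):
        assert find_motifs("KEADG", parse_pattern("D/E-x-D")) == [2]

    def test_overlapping_occurrences_all_reported(self):
        assert find_motifs("DDDD", parse_pattern("D-x-D")) == [1, 2]

    def test_absent_motif_gives_empty_list(self):
        assert find_motifs("GGGG", parse_pattern("D-x-D")) == []

    def test_planted_motif_found_and_agrees_with_brute_force(self):
        rng = np.random.default_rng(7)
        pattern = parse_pattern("V-F-H-P-N")
        for _ in range(20):
            seq = list(random_protein(rng, 200))
            seq[49:54] = "VFHPN"
            seq = "".join(seq)
            hits = find_motifs(seq, pattern)
            assert 50 in hits
            # independent sliding-window check
            brute = [
                i + 1
                for i in range(len(seq) - 4)
                if seq[i : i + 5] == "VFHPN"
            ]
            assert hits == brute


def plant(seq: str, start: int, window: str) -> str:
    return seq[: start - 1] + window + seq[start - 1 + len(window):]


def brute_force_hits(seq: str, min_loop: int = 3) -> list[int]:
    """Independent re-statement of the scanner rule + greedy selection."""
    donors = set("DENQST")
    qualifying = []
    for start in range(1, len(seq) - 36 + 2):
        w = seq[start - 1 : start + 35]
        if w[13] not in "DE" or w[21] not in "DE" or w[23] not in "DE":
            continue
        count = sum(w[p - 1] in donors for p in (13, 15, 17, 19, 21, 24))
        if count >= min_loop:
            qualifying.append(start)
    selected, free = [], 1
    for s in qualifying:
        if s >= free:
            selected.append(s)
            free = s + 36
    return selected


class TestScanner:
    def test_poly_ala_has_no_hands(self):
        assert scan_ef_hands("A" * 100) == []

    def test_sequence_shorter_than_window_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            scan_ef_hands("MKR")

    def test_single_planted_hand_recovered(self):
        seq = plant("A" * 150, 40, canonical_hand_window())
        hits = scan_ef_hands(seq)
        assert [h.start for h in hits] == [40]
        assert hits[0].loop_start == 52
        assert hits[0].score == 1.0
        assert hits[0].key_matches[14] == "D"
        assert hits[0].key_matches[22] == "E"

    def test_three_planted_hands_non_overlapping(self):
        seq = "A" * 250
        for start in (40, 120, 200):
            seq = plant(seq, start, canonical_hand_window())
        hits = scan_ef_hands(seq)
        assert [h.start for h in hits] == [40, 120, 200]
        for h1, h2 in zip(hits, hits[1:]):
            assert h2.start >= h1.start + WINDOW

    def test_matches_brute_force_on_random_sequences(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            seq = random_protein(rng, int(rng.integers(36, 201)))
            assert [h.start for h in scan_ef_hands(seq)] == brute_force_hits(seq)

    def test_relaxing_loop_threshold_never_removes_qualifying_offsets(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            seq = random_protein(rng, 150)
            strict3 = set(qualifying_offsets(seq, ScanRule(min_loop_matches=3)))
            strict2 = set(qualifying_offsets(seq, ScanRule(min_loop_matches=2)))
            assert strict3 <= strict2


class TestClassification:
    def test_three_hands_is_cbl(self):
        seq = "A" * 250
        for start in (40, 120, 200):
            seq = plant(seq, start, canonical_hand_window())
        cls = classify_cbl(ProteinRecord(id="p", sequence=seq))
        assert cls.is_cbl and cls.n_hands == 3

    def test_four_hands_is_calmodulin_like_not_cbl(self):
        seq = "A" * 300
        for start in (20, 80, 150, 220):
            seq = plant(seq, start, canonical_hand_window())
        cls = classify_cbl(ProteinRecord(id="cam", sequence=seq))
        assert cls.n_hands == 4 and not cls.is_cbl

    def test_zero_hands_not_cbl(self):
        cls = classify_cbl(ProteinRecord(id="r", sequence="G" * 100))
        assert cls.n_hands == 0 and not cls.is_cbl


class TestConservationProfile:
    def make_block(self, rows):
        return records_to_block(
            [ProteinRecord(id=f"m{i}", sequence=s, aligned=True)
             for i, s in enumerate(rows)]
        )

    def test_unanimous_column_frequency_one(self):
        rows = ["D" + "A" * 35] * 4
        profile = conservation_profile(self.make_block(rows), 1)
        assert profile.freq(1, "D") == 1.0
        assert profile.freq(1, "DE") == 1.0
        assert profile.n_members == 4

    def test_gapped_member_excluded_from_denominator(self):
        rows = ["D" + "A" * 35, "D" + "A" * 35, "-" + "A" * 35]
        profile = conservation_profile(self.make_block(rows), 1)
        assert profile.freq(1, "D") == 1.0  # 2 of 2 non-gap members

    def test_planted_90_percent_asp_frequency_recovered(self):
        rng = np.random.default_rng(5)
        rows = []
        for _ in range(200):
            row = list(random_protein(rng, 36))
            row[13] = "D" if rng.random() < 0.9 else "L"
            rows.append("".join(row))
        profile = conservation_profile(self.make_block(rows), 1)
        # direct counting oracle
        expected = sum(r[13] == "D" for r in rows) / 200
        assert profile.freq(14, "D") == pytest.approx(expected, abs=1e-12)
        assert abs(profile.freq(14, "D") - 0.9) < 0.05

    def test_frequency_ordering_invariant(self):
        rng = np.random.default_rng(3)
        rows = [random_protein(rng, 40) for _ in range(10)]
        profile = conservation_profile(self.make_block(rows), 2)
        for pos in range(1, 37):
            d, e, de = (profile.freq(pos, k) for k in ("D", "E", "DE"))
            assert d + e == pytest.approx(de)
            assert de <= 1.0

    def test_window_out_of_range_rejected(self):
        rows = ["A" * 40] * 3
        with pytest.raises(IndexError):
            conservation_profile(self.make_block(rows), 10)


class TestNterminalMotifs:
    def test_group_d_motif_at_16_18(self):
        seq = "M" + "A" * 14 + "EEP" + "A" * 20
        assert nterminal_motif_check(seq, "D")["match"]

    def test_group_a_motif_at_31_33(self):
        seq = "M" + "A" * 29 + "DAE" + "A" * 10
        assert nterminal_motif_check(seq, "A")["match"]

    def test_poly_gly_matches_neither_group(self):
        seq = "G" * 50
        assert not nterminal_motif_check(seq, "A")["match"]
        assert not nterminal_motif_check(seq, "D")["match"]
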