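"""Consensus pattern compilation and window scoring."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lrrscan.consensus import (
    DEFAULT_MIN_SCORE,
    PatternError,
    classify_window,
    compile_pattern,
    scan_windows,
    score_window,
)
from lrrscan.core import AMINO_ACIDS, DEFAULT_CLASSES, ProteinRecord, ValidationError

STRAND = "LxxLxLxx[NC]xL" + "x" * 17  # canonical RI-like strand motif, 28 cols


def sample_perfect(pattern, rng):
    """An independent perfect instance: any member per constrained column."""
    out = []
    for p in pattern.positions:
        pool = sorted(p.allowed) if p.constrained else list(AMINO_ACIDS)
        out.append(pool[rng.integers(len(pool))])
    return "".join(out)


class TestCompile:
    def test_strand_motif_constrained_columns(self):
        pat = compile_pattern(STRAND)
        assert pat.length == 28
        assert [p.index for p in pat.constrained_positions] == [1, 4, 6, 9, 11]

    def test_unknown_code_rejected(self):
        with pytest.raises(PatternError, match="Z"):
            compile_pattern("Zxx" + "x" * 25)

    def test_compile_is_deterministic(self):
        assert compile_pattern(STRAND) == compile_pattern(STRAND)

    def test_length_family_enforced(self):
        with pytest.raises(PatternError, match="28/29"):
            compile_pattern("LxLxLxLL")
        assert compile_pattern("LxLxLxLL", strict_length=False).length == 8

    def test_bracket_set_resolves_literally(self):
        pat = compile_pattern(STRAND)
        col9 = pat.positions[8]
        assert col9.allowed == frozenset("NC")

    def test_class_codes_resolve_in_table(self, patterns):
        for pat in patterns:
            for p in pat.constrained_positions:
                if not p.code.startswith("["):
                    assert p.code in DEFAULT_CLASSES or p.code in AMINO_ACIDS


class TestScoreWindow:
    def test_perfect_instance_scores_one(self, pattern_by_name):
        pat = pattern_by_name["type1"]
        rng = np.random.default_rng(0)
        rec = ProteinRecord("p", sample_perfect(pat, rng))
        assert score_window(rec, 1, pat).score == 1.0

    def test_all_alanine_scores_zero(self, pattern_by_name):
        # A is in no constrained class of the shipped type1 pattern
        pat = pattern_by_name["type1"]
        rec = ProteinRecord("p", "A" * 28)
        assert score_window(rec, 1, pat).score == 0.0

    def test_out_of_range_rejected(self, pattern_by_name):
        rec = ProteinRecord("p", "A" * 30)
        with pytest.raises(ValidationError, match="out of range"):
            score_window(rec, 4, pattern_by_name["type1"])

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_per_position_oracle(self, pattern_by_name, seed):
        """Score equals an independent per-column membership count."""
        pat = pattern_by_name["type1"]
        rng = np.random.default_rng(seed)
        window = "".join(
            AMINO_ACIDS[i] for i in rng.integers(len(AMINO_ACIDS), size=28)
        )
        rec = ProteinRecord("p", window)
        expected = sum(
            window[p.index - 1] in p.allowed for p in pat.positions if p.constrained
        )
        ws = score_window(rec, 1, pat)
        assert ws.matched_positions == expected
        assert ws.score == expected / pat.n_constrained

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=40, derandomize=True)
    def test_invariant_under_wildcard_substitution(self, pattern_by_name, seed):
        pat = pattern_by_name["type1"]
        rng = np.random.default_rng(seed)
        base = sample_perfect(pat, rng)
        wild = [p.index for p in pat.positions if not p.constrained]
        idx = wild[rng.integers(len(wild))]
        mutated = base[: idx - 1] + "W" + base[idx:]
        s0 = score_window(ProteinRecord("a", base), 1, pat).score
        s1 = score_window(ProteinRecord("b", mutated), 1, pat).score
        assert s0 == s1

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=40, derandomize=True)
    def test_constrained_mutation_never_raises_score(self, pattern_by_name, seed):
        pat = pattern_by_name["type1"]
        rng = np.random.default_rng(seed)
        base = sample_perfect(pat, rng)
        cons = pat.constrained_positions
        p = cons[rng.integers(len(cons))]
        outside = sorted(set(AMINO_ACIDS) - p.allowed)
        mutated = base[: p.index - 1] + outside[0] + base[p.index :]
        s0 = score_window(ProteinRecord("a", base), 1, pat).score
        s1 = score_window(ProteinRecord("b", mutated), 1, pat).score
        assert s1 < s0

    def test_required_column_hard_fail(self):
        pat = compile_pattern("!GLLLLLLL" + "x" * 20)
        good = ProteinRecord("g", "G" + "L" * 7 + "A" * 20)
        bad = ProteinRecord("b", "A" + "L" * 7 + "A" * 20)
        assert score_window(good, 1, pat).score == 1.0
        ws = score_window(bad, 1, pat)
        assert ws.hard_fail and ws.score == 0.0


class TestClassify:
    def test_perfect_type1(self, patterns, pattern_by_name):
        rng = np.random.default_rng(1)
        rec = ProteinRecord("p", sample_perfect(pattern_by_name["type1"], rng) + "A")
        assert classify_window(rec, 1, patterns) == "type1"

    def test_below_threshold_is_none(self, patterns):
        rec = ProteinRecord("p", "A" * 40)
        assert classify_window(rec, 1, patterns) is None

    def test_tie_continues_alternation(self):
        # two equal-scoring patterns; previous repeat was p1 -> pick p2
        p1 = compile_pattern("G" * 8 + "x" * 20, name="p1", strict_length=False)
        p2 = compile_pattern("x" * 20 + "G" * 8, name="p2", strict_length=False)
        rec = ProteinRecord("t", "G" * 28)
        assert classify_window(rec, 1, [p1, p2], previous_type="p1") == "p2"
        assert classify_window(rec, 1, [p1, p2], previous_type="p2") == "p1"
        # without context the first-listed pattern wins
        assert classify_window(rec, 1, [p1, p2]) == "p1"


class TestScanOracle:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_exhaustive_equivalence_short_sequences(self, patterns, seed):
        """Scan output equals brute-force enumeration of all starts (<=200 aa)."""
        rng = np.random.default_rng(seed)
        n = 200
        seq = "".join(AMINO_ACIDS[i] for i in rng.integers(len(AMINO_ACIDS), size=n))
        rec = ProteinRecord("p", seq)
        threshold = 0.4  # low cut so the oracle set is non-trivial
        got = {(w.start, w.pattern) for w in scan_windows(rec, patterns, min_score=threshold)}
        expected = set()
        for pat in patterns:
            for start in range(1, n - pat.length + 2):
                window = seq[start - 1 : start + pat.length - 1]
                matched = sum(
                    window[p.index - 1] in p.allowed
                    for p in pat.positions
                    if p.constrained
                )
                if matched / pat.n_constrained >= threshold:
                    expected.add((start, pat.name))
        assert got == expected
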