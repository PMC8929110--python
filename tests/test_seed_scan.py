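"""Seed matcher vs. a brute-force complementarity oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from utr_mirscan import MiRNA, find_seed_matches, pairs

BASES = "ACGU"
WC = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")}
WOB = {("G", "U"), ("U", "G")}


def brute_force_matches(window, mirna_seq, min_len=6, allow_wobble=True):
    """Independent oracle: enumerate every (target offset, anchor) pair and
    extend base by base; keep maximal runs >= min_len, drop runs whose
    target interval is contained in a longer reported run with the same
    anchor."""

    def ok(a, b):
        return (a, b) in WC or (allow_wobble and (a, b) in WOB)

    found = {1: set(), 2: set()}
    for anchor in (1, 2):
        for e in range(1, len(window) + 1):
            L = 0
            while (
                e - L >= 1
                and anchor + L <= len(mirna_seq)
                and ok(window[e - L - 1], mirna_seq[anchor + L - 1])
            ):
                L += 1
            if L >= min_len:
                found[anchor].add((e - L + 1, e, L))
    out = set()
    for anchor in (1, 2):
        for (s, e, L) in found[anchor]:
            contained = any(
                (s2, e2) != (s, e) and s2 <= s and e <= e2 and L2 >= L
                for (s2, e2, L2) in found[anchor]
            )
            if not contained:
                out.add((s, e, anchor, L))
    return out


def test_pairs_truth_table():
    assert pairs("G", "C", False) and pairs("G", "C", True)
    assert pairs("A", "U", False) and pairs("U", "A", True)
    assert pairs("G", "U", True) and pairs("U", "G", True)
    assert not pairs("G", "U", False) and not pairs("U", "G", False)
    assert not pairs("A", "G", True) and not pairs("C", "U", True)


def test_let7_like_example():
    mir = MiRNA("let7", "UGAGGUAGUAGGUUGUAUAGUU")
    window = "CCCCUACCUCACCC"  # CUACCUCA pairs miRNA 1-8
    ms = find_seed_matches(window, mir)
    best = max(ms, key=lambda m: m.match_len)
    assert best.mirna_start == 1
    assert best.match_len == 8
    assert best.wobble_count == 0
    assert (best.target_start, best.target_end) == (4, 11)


def test_wobble_changes_run_length():
    mir = MiRNA("let7", "UGAGGUAGUAGGUUGUAUAGUU")
    # target's U pairs miRNA G1 only as a wobble
    window = "GGGUUACCUCAGGG"
    on = find_seed_matches(window, mir, allow_wobble=True)
    off = find_seed_matches(window, mir, allow_wobble=False)
    on1 = [m for m in on if m.mirna_start == 1]
    off1 = [m for m in off if m.mirna_start == 1]
    assert max(m.match_len for m in on1) >= 8
    assert max(m.wobble_count for m in on1) >= 1
    assert max(m.match_len for m in off1) == 7
    assert all(m.wobble_count == 0 for m in off1)


def test_unpairable_window_is_empty():
    mir = MiRNA("polyA", "AAAAAAAAAAAAAAAAAA")
    assert find_seed_matches("AAAAAAAAAAAA", mir) == []
    assert find_seed_matches("ACG", mir) == []  # shorter than min_len


def test_min_len_guard():
    mir = MiRNA("m", "UGAGGUAGUAGGUUGUAUAG")
    with pytest.raises(ValueError):
        find_seed_matches("ACGUACGU", mir, min_len=5)


@settings(max_examples=300, derandomize=True)
@given(seed=st.integers(0, 10**7), wobble=st.booleans())
def test_matches_equal_brute_force_oracle(seed, wobble):
    rng = np.random.default_rng(seed)
    window = "".join(rng.choice(list(BASES), size=int(rng.integers(6, 51))))
    mir = MiRNA("f", "".join(rng.choice(list(BASES), size=int(rng.integers(16, 23)))))
    got = {
        (m.target_start, m.target_end, m.mirna_start, m.match_len)
        for m in find_seed_matches(window, mir, allow_wobble=wobble)
    }
    assert got == brute_force_matches(window, mir.sequence, allow_wobble=wobble)


@settings(max_examples=150, derandomize=True)
@given(seed=st.integers(0, 10**7))
def test_wobble_off_coverage_is_subset_of_wobble_on(seed):
    rng = np.random.default_rng(seed)
    window = "".join(rng.choice(list(BASES), size=40))
    mir = MiRNA("f", "".join(rng.choice(list(BASES), size=20)))
    on = find_seed_matches(window, mir, allow_wobble=True)
    off = find_seed_matches(window, mir, allow_wobble=False)
    for m in off:
        assert any(
            o.mirna_start == m.mirna_start
            and o.target_start <= m.target_start
            and m.target_end <= o.target_end
            for o in on
        )


def test_output_order_is_deterministic(rng):
    window = "".join(rng.choice(list(BASES), size=50))
    mir = MiRNA("f", "".join(rng.choice(list(BASES), size=22)))
    ms = find_seed_matches(window, mir)
    assert ms == sorted(ms, key=lambda m: (m.target_start, m.mirna_start))
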