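"""Nearest-neighbor scoring, the hybrid DP, and the enumeration oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from utr_mirscan import (
    DEFAULT_MODEL,
    EnergyModel,
    MiRNA,
    duplex_mfe,
    enumerate_mfe,
    find_seed_matches,
    rescore_seed_hit,
    score_structure,
)
from utr_mirscan.duplex_energy import (
    StructureError,
    _HybridDP,
    verify_site_energy,
)
from utr_mirscan.energy_params import PAIR_TYPES, STACK_37, reverse_pair

BASES = "ACGU"
M = DEFAULT_MODEL


def test_stack_table_is_complete_negative_and_strand_symmetric():
    for p1 in PAIR_TYPES:
        for p2 in PAIR_TYPES:
            e = STACK_37[(p1, p2)]
            assert e < 0
            # the same stacked motif read from the other strand
            assert e == STACK_37[(reverse_pair(p2), reverse_pair(p1))]


def test_model_rejects_nonnegative_stack():
    bad = dict(STACK_37)
    bad[("AU", "AU")] = 0.1
    with pytest.raises(ValueError):
        EnergyModel(stack_energy=bad)


def test_score_contiguous_helix_is_hand_sum():
    # helix: target 5'-CUACCUCA-3' / miRNA 5'-UGAGGUAG-3' (8 WC pairs)
    target, mirna = "CUACCUCA", "UGAGGUAG"
    # pairs ascending in target: (C,G) (U,A) (A,U) (C,G) (C,G) (U,A) (C,G) (A,U)
    steps = [("CG", "UA"), ("UA", "AU"), ("AU", "CG"), ("CG", "CG"),
             ("CG", "UA"), ("UA", "CG"), ("CG", "AU")]
    expected = M.init_penalty + sum(STACK_37[s] for s in steps)
    assert score_structure("PPPPPPPP", target, mirna, M) == pytest.approx(expected)


def test_score_zero_pairs_is_infinite():
    assert score_structure("", "", "", M) == math.inf


def test_score_helix_with_target_bulge_is_hand_sum():
    # same helix with one extra unpaired target A between pairs 4 and 5
    target = "CUACACUCA"
    mirna = "UGAGGUAG"
    full = score_structure("PPPPPPPP", "CUACCUCA", mirna, M)
    bulged = score_structure("PPPPTPPPP", target, mirna, M)
    broken_stack = STACK_37[("CG", "CG")]  # the step the bulge interrupts
    expected = full - broken_stack + M.bulge_open + 1 * M.bulge_extend_per_nt
    assert bulged == pytest.approx(expected)


def test_score_rejects_malformed_structures():
    with pytest.raises(StructureError):
        score_structure("TPPPPPPPP", "ACUACCUCA", "UGAGGUAG", M)  # dangling end
    with pytest.raises(StructureError):
        score_structure("PP", "AA", "GG", M)  # A-G cannot pair
    with pytest.raises(StructureError):
        score_structure("PW", "CU", "AG", M)  # wrong wobble annotation


def test_perfect_complement_equals_full_helix_score():
    mir = MiRNA("m", "UGAGGUAG" + "UAGGUUGU")  # 16 nt
    comp = {"A": "U", "U": "A", "C": "G", "G": "C"}
    window = "".join(comp[b] for b in reversed(mir.sequence))
    site = duplex_mfe(window, mir, M, require_seed=True)
    assert site is not None
    assert site.pairing_string == "P" * 16
    assert site.energy == pytest.approx(
        score_structure("P" * 16, window, mir.sequence, M)
    )


def test_unpairable_pair_gives_none():
    mir = MiRNA("polyA", "A" * 18)
    assert duplex_mfe("A" * 30, mir, M, require_seed=False) is None


@settings(max_examples=200, derandomize=True, deadline=None)
@given(seed=st.integers(0, 10**7), require_seed=st.booleans())
def test_dp_equals_enumeration_oracle(seed, require_seed):
    rng = np.random.default_rng(seed)
    w = "".join(rng.choice(list(BASES), size=int(rng.integers(4, 9))))
    mseq = "".join(rng.choice(list(BASES), size=int(rng.integers(4, 9))))
    mir = MiRNA("f", mseq)
    dp = _HybridDP(w, mseq, M)
    e_dp, _ = dp.best_state(require_seed)
    e_enum, _ = enumerate_mfe(w, mir, M, require_seed=require_seed)
    if math.isinf(e_enum):
        assert math.isinf(e_dp)
    else:
        assert e_dp == pytest.approx(e_enum, abs=1e-6)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(seed=st.integers(0, 10**7))
def test_traceback_energy_matches_score_structure(seed):
    rng = np.random.default_rng(seed)
    w = "".join(rng.choice(list(BASES), size=50))
    mir = MiRNA("f", "".join(rng.choice(list(BASES), size=22)))
    for require_seed in (False, True):
        site = duplex_mfe(w, mir, M, require_seed=require_seed)
        if site is not None:
            assert verify_site_energy(site, w, mir, M, tol=1e-6)
    for match in find_seed_matches(w, mir):
        site = rescore_seed_hit(match, w, mir, M)
        assert verify_site_energy(site, w, mir, M, tol=1e-6)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(seed=st.integers(0, 10**7))
def test_mfe_monotone_under_window_extension(seed):
    rng = np.random.default_rng(seed)
    w = "".join(rng.choice(list(BASES), size=30))
    mir = MiRNA("f", "".join(rng.choice(list(BASES), size=20)))
    ext = "".join(rng.choice(list(BASES), size=10))

    def energy(window):
        site = duplex_mfe(window, mir, M, require_seed=False)
        return math.inf if site is None else site.energy

    assert energy(w + ext) <= energy(w) + 1e-9
    assert energy(ext + w) <= energy(w) + 1e-9


@settings(max_examples=60, derandomize=True, deadline=None)
@given(seed=st.integers(0, 10**7))
def test_seed_constrained_energy_bounded_by_unconstrained(seed):
    rng = np.random.default_rng(seed)
    w = "".join(rng.choice(list(BASES), size=40))
    mseq = "".join(rng.choice(list(BASES), size=22))
    dp = _HybridDP(w, mseq, M)
    e_free, _ = dp.best_state(False)
    e_seed, _ = dp.best_state(True)
    assert e_seed >= e_free - 1e-9


def test_rescore_seed_only_when_no_3prime_pairing():
    # miRNA 3' tail of A's over an all-A flank: nothing to extend with
    mir = MiRNA("m", "UGAGGUAG" + "A" * 10)
    window = "A" * 20 + "CUACCUCA" + "A" * 5
    (match,) = [m for m in find_seed_matches(window, mir) if m.match_len == 8]
    site = rescore_seed_hit(match, window, mir, M)
    helix_only = score_structure("PPPPPPPP", "CUACCUCA", "UGAGGUAG", M)
    assert site.energy == pytest.approx(helix_only)
    assert site.method == "seed_scan"


def test_rescore_adds_favorable_3prime_helix():
    mir = MiRNA("m", "UGAGGUAG" + "CCCC" + "GGGGG" + "AAA")
    # target: complement of miRNA 13-17 (CCCCC), a 2/4 interior loop, seed
    window = "AAAA" + "CCCCC" + "AA" + "CUACCUCA" + "AAAA"
    (match,) = [m for m in find_seed_matches(window, mir) if m.match_len == 8]
    site = rescore_seed_hit(match, window, mir, M)
    helix_only = score_structure("PPPPPPPP", "CUACCUCA", "UGAGGUAG", M)
    assert site.energy < helix_only
    assert "M" in site.pairing_string or "T" in site.pairing_string
    assert verify_site_energy(site, window, mir, M)
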