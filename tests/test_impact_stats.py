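"""dN/dW reduction, Tukey-fence outliers, candidate selection."""

import numpy as np
import pytest

from utr_mirscan import (
    AlleleSummary,
    flag_outliers,
    select_candidates,
    summarize_allele,
    variant_impact,
)
from utr_mirscan.duplex_energy import InteractionSite


def site(mirna, energy, method="seed_scan"):
    return InteractionSite(
        variant_id="v", allele="REF", mirna_name=mirna,
        target_interval=(1, 8), mirna_interval=(1, 8),
        pairing_string="PPPPPPPP", energy=energy, seed_class="canonical_8",
        method=method,
    )


def test_summarize_allele_counts_distinct_mirnas():
    s = summarize_allele([site("miR-a", -10.0), site("miR-b", -12.0)])
    assert (s.n, s.w, s.mirnas) == (2, -22.0, frozenset({"miR-a", "miR-b"}))


def test_summarize_allele_best_site_per_mirna():
    s = summarize_allele([site("miR-a", -10.0), site("miR-a", -14.0)])
    assert (s.n, s.w) == (1, -14.0)
    s_all = summarize_allele([site("miR-a", -10.0), site("miR-a", -14.0)], "all")
    assert (s_all.n, s_all.w) == (1, -24.0)


def test_summarize_allele_empty_and_order_invariance(rng):
    assert summarize_allele([]) == AlleleSummary(0, 0.0, frozenset())
    sites = [site(f"m{i}", -float(e)) for i, e in enumerate(rng.integers(9, 30, 12))]
    shuffled = list(sites)
    rng.shuffle(shuffled)
    assert summarize_allele(sites) == summarize_allele(shuffled)


def test_variant_impact_gain_loss_and_identity():
    ref = AlleleSummary(2, -22.0, frozenset({"a", "b"}))
    alt = AlleleSummary(3, -37.0, frozenset({"a", "b", "c"}))
    imp = variant_impact(ref, alt, "v", "seed_scan")
    assert (imp.delta_n, imp.delta_w) == (1, -15.0)
    assert imp.gained == frozenset({"c"}) and imp.lost == frozenset()

    same = variant_impact(ref, ref, "v", "seed_scan")
    assert (same.delta_n, same.delta_w) == (0, 0.0)

    lost = variant_impact(
        AlleleSummary(1, -10.0, frozenset({"a"})), AlleleSummary(0, 0.0, frozenset()),
        "v", "seed_scan",
    )
    assert (lost.delta_n, lost.delta_w, lost.lost) == (-1, 10.0, frozenset({"a"}))


def test_swapping_alleles_negates_both_statistics():
    ref = AlleleSummary(2, -22.0, frozenset({"a", "b"}))
    alt = AlleleSummary(4, -55.0, frozenset({"a", "b", "c", "d"}))
    fwd = variant_impact(ref, alt, "v", "seed_scan")
    rev = variant_impact(alt, ref, "v", "seed_scan")
    assert rev.delta_n == -fwd.delta_n and rev.delta_w == -fwd.delta_w
    assert rev.gained == fwd.lost and rev.lost == fwd.gained
    assert fwd.delta_n == len(fwd.gained) - len(fwd.lost)


def make_impacts(dns, dws, method="seed_scan"):
    return [
        variant_impact(
            AlleleSummary(0, 0.0, frozenset()),
            AlleleSummary(max(dn, 0), dw, frozenset(f"m{k}" for k in range(max(dn, 0)))),
            f"v{i}", method,
        )
        for i, (dn, dw) in enumerate(zip(dns, dws))
    ]


def test_outlier_flag_with_zero_iqr():
    # dW {0 x7, -30}: Q1 = Q3 = 0, fence = 0, only -30 falls below
    imps = make_impacts([0] * 8, [0.0] * 7 + [-30.0])
    flagged = flag_outliers(imps)
    assert [i.outlier_w for i in flagged] == [False] * 7 + [True]


def test_no_outliers_when_all_equal():
    imps = make_impacts([1] * 10, [-5.0] * 10)
    flagged = flag_outliers(imps)
    assert not any(i.outlier_w for i in flagged)
    assert not any(i.outlier_n for i in flagged)


def test_dn_outlier_matches_direct_quantile_computation():
    dns = [0] * 19 + [5]
    imps = make_impacts(dns, [0.0] * 20)
    flagged = flag_outliers(imps)
    q1, q3 = np.percentile(np.array(dns, float), [25, 75])
    fence = q3 + 1.5 * (q3 - q1)
    expect = [dn > fence for dn in dns]
    assert [i.outlier_n for i in flagged] == expect
    assert flagged[-1].outlier_n


def test_outliers_invariant_under_permutation(rng):
    dws = list(rng.normal(0, 1, 30)) + [-40.0]
    imps = make_impacts([0] * 31, dws)
    ref = {i.variant_id: (i.outlier_n, i.outlier_w) for i in flag_outliers(imps)}
    shuffled = list(imps)
    rng.shuffle(shuffled)
    perm = {i.variant_id: (i.outlier_n, i.outlier_w) for i in flag_outliers(shuffled)}
    assert ref == perm


def test_small_cohort_falls_back_to_sign_flags():
    imps = make_impacts([1, 0, -1], [-9.0, 0.0, 9.0])
    with pytest.warns(UserWarning, match="degenerate"):
        flagged = flag_outliers(imps)
    assert [i.outlier_n for i in flagged] == [True, False, False]
    assert [i.outlier_w for i in flagged] == [True, False, False]


def test_flag_outliers_rejects_mixed_methods():
    imps = make_impacts([0] * 4, [0.0] * 4) + make_impacts([0] * 4, [0.0] * 4, "energy_scan")
    with pytest.raises(ValueError, match="single method"):
        flag_outliers(imps)


def test_candidate_rule_and_sort_order():
    from dataclasses import replace

    imps = make_impacts([5, -2, 1, 2], [-62.01, -40.0, 3.0, -20.0])
    imps = [replace(i, outlier_w=True) for i in imps]
    cands = select_candidates(imps)
    # dN >= 1, dW < 0, outlier: v0 and v3; sorted by ascending dW
    assert [c.variant_id for c in cands] == ["v0", "v3"]
    assert all(c.candidate for c in cands)
    assert [c.delta_w for c in cands] == [-62.01, -20.0]


def test_non_outlier_never_candidate():
    imps = make_impacts([3], [-25.0])  # flags unset
    assert select_candidates(imps) == []
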