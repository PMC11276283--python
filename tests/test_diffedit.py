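"""Weighted differential test: weights, WLS closed form, BH, direction calls."""
import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from editscape import (
    AlleleCount,
    DifferentialEditingModel,
    bh_adjust,
    call_differential,
    sample_weight,
    weighted_regression_test,
)
from editscape.diffedit import WeightedObservation, annotate_results
from editscape.errors import ContractViolationError
from conftest import make_profile


@pytest.mark.parametrize(
    "n_i, n_a, w_expected",
    [
        (5, 5, 40.0),                      # 10^3 / 25
        (1, 9, 1000.0 / 9),                # 10^3 / 9
        (0, 10, 1000.0 / (0.5 * 10.5)),    # zero-count continuity rule
        (10, 0, 1000.0 / (10.5 * 0.5)),
    ],
)
def test_sample_weight_formula(n_i, n_a, w_expected):
    obs = sample_weight(AlleleCount(n_i, n_a))
    assert obs.w == pytest.approx(w_expected)
    assert obs.w * obs.sigma2 == pytest.approx(1.0)
    assert obs.zero_corrected == (n_i == 0 or n_a == 0)


def test_sample_weight_requires_reads():
    with pytest.raises(ContractViolationError):
        sample_weight(AlleleCount(0, 0))


def obs(values, group, w=1.0):
    return [WeightedObservation(p=v, sigma2=1.0 / w, w=w, group=group) for v in values]


def test_wls_hand_oracle():
    # closed-form worked by hand: slope .4, t = 4*sqrt(2), df 2, p ~ .0299
    r = weighted_regression_test(obs([0.2, 0.3], 0) + obs([0.6, 0.7], 1))
    assert r.slope == pytest.approx(0.4)
    assert r.t == pytest.approx(4 * np.sqrt(2))
    assert r.df == 2
    assert r.p_value == pytest.approx(0.029857, abs=1e-5)
    assert (r.mean_a, r.mean_b) == (pytest.approx(0.25), pytest.approx(0.65))


def test_identical_groups_give_null_result():
    r = weighted_regression_test(obs([0.2, 0.4], 0) + obs([0.2, 0.4], 1))
    assert r.slope == 0.0
    assert r.p_value == pytest.approx(1.0)


def test_weight_scale_invariance():
    a = weighted_regression_test(obs([0.2, 0.3, 0.25], 0, w=2.0) + obs([0.5, 0.6], 1, w=4.0))
    b = weighted_regression_test(obs([0.2, 0.3, 0.25], 0, w=4.0) + obs([0.5, 0.6], 1, w=8.0))
    assert a.slope == pytest.approx(b.slope)
    assert a.t == pytest.approx(b.t)
    assert a.p_value == pytest.approx(b.p_value)


def test_degenerate_zero_variance_flagged():
    r = weighted_regression_test(obs([0.2, 0.2], 0) + obs([0.6, 0.6], 1))
    assert r.degenerate and r.p_value == np.finfo(float).tiny


def test_slope_identity_and_statsmodels_oracle():
    """Slope equals the weighted group-mean difference to 1e-12 and (t, p)
    match generic WLS to 1e-10, over 1000 random instances."""
    rng = np.random.default_rng(1234)
    for _ in range(1000):
        m0 = rng.integers(2, 8)
        m1 = rng.integers(2, 8)
        p = rng.random(m0 + m1)
        w = rng.uniform(0.1, 50, m0 + m1)
        groups = np.r_[np.zeros(m0, int), np.ones(m1, int)]
        r = weighted_regression_test(
            [WeightedObservation(p=p[i], sigma2=1 / w[i], w=w[i], group=int(groups[i]))
             for i in range(m0 + m1)]
        )
        wm1 = np.average(p[groups == 1], weights=w[groups == 1])
        wm0 = np.average(p[groups == 0], weights=w[groups == 0])
        assert abs(r.slope - (wm1 - wm0)) < 1e-12
        fit = sm.WLS(p, sm.add_constant(groups.astype(float)), weights=w).fit()
        assert abs(r.t - fit.tvalues[1]) < 1e-10
        assert abs(r.p_value - fit.pvalues[1]) < 1e-10


def test_equal_weights_reduce_to_pooled_t_test():
    rng = np.random.default_rng(99)
    for _ in range(50):
        x = rng.random(6)
        y = rng.random(5)
        r = weighted_regression_test(obs(list(x), 0) + obs(list(y), 1))
        t_cls, p_cls = stats.ttest_ind(y, x, equal_var=True)
        assert abs(r.t - t_cls) < 1e-10
        assert abs(r.p_value - p_cls) < 1e-10


def test_bh_adjust_step_up():
    q = bh_adjust([0.01, 0.02, 0.04, 0.5])
    assert q == pytest.approx([0.04, 0.04, 0.04 * 4 / 3, 0.5])
    assert (np.asarray(q) <= 0.05).sum() == 2
    assert bh_adjust([0.03]) == pytest.approx([0.03])
    assert bh_adjust([1.0, 1.0]) == pytest.approx([1.0, 1.0])
    with pytest.raises(ContractViolationError):
        bh_adjust([0.5, 1.2])


def test_group_swap_flips_directions(two_group_profile):
    _, profile, _ = two_group_profile
    fwd = call_differential(profile, "G1", "G2")
    rev = call_differential(profile, "G2", "G1")
    assert np.allclose(fwd.table["p_value"], rev.table["p_value"])
    assert np.allclose(fwd.table["slope"], -rev.table["slope"])
    sig = fwd.table["significant"]
    assert (fwd.table.loc[sig, "direction"].map({"hypo": "hyper", "hyper": "hypo"})
            == rev.table.loc[sig, "direction"]).all()


def test_differential_recovery_and_ground_truth(two_group_profile):
    _, profile, truth = two_group_profile
    results = call_differential(profile, "G1", "G2")
    sig_ids = set(results.significant.index)
    true_ids = {sid for sid, d in zip(profile.site_ids, truth.is_differential) if d}
    # most recovered sites are truly differential
    assert len(sig_ids) > 0
    assert len(sig_ids & true_ids) / len(sig_ids) > 0.8


def test_annotate_results_tallies(two_group_profile):
    _, profile, _ = two_group_profile
    results = call_differential(profile, "G1", "G2")
    table, tally = annotate_results(results.table, profile.sites)
    sig = table[table["significant"]]
    assert tally["UTR"] == ((sig["region"] == "UTR5") | (sig["region"] == "UTR3")).sum()
    assert tally["repetitive"] == sig["repeat"].sum()
    assert results.category_tally() == tally
    hypo, hyper = results.direction_split()
    assert hypo + hyper == len(sig)


def test_summary_reports_counts(two_group_profile):
    _, profile, _ = two_group_profile
    results = DifferentialEditingModel(profile, "G1", "G2").fit()
    text = results.summary()
    assert f"Sites tested:       {results.n_tested}" in text
    assert "Significant" in text
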