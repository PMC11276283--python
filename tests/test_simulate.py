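"""Generator correctness: determinism, calibration, ground-truth structure."""
import numpy as np
import pytest
from scipy import stats

from editscape import SimulationConfig, simulate_counts, simulate_expression, simulate_site_catalog
from editscape.errors import ConfigurationError, FixtureError
from editscape.simulate import ReadSpec, simulate_sam_fixture
from editscape.sites import EditingSite


def test_catalog_unique_and_deterministic():
    cfg = SimulationConfig(n_sites=100, seed=1)
    cat1 = simulate_site_catalog(cfg)
    cat2 = simulate_site_catalog(cfg)
    assert len(cat1) == 100
    assert cat1 == cat2
    assert len({(s.chrom, s.pos, s.strand) for s in cat1}) == 100


@pytest.mark.parametrize(
    "field, value",
    [
        ("n_sites", 0),
        ("n_samples_per_group", (5,)),
        ("n_samples_per_group", (1, 5)),
        ("snp_fraction", 1.5),
        ("effect_size", 2.0),
        ("coverage_mean", 0),
        ("baseline_editing_dist", (0.0, 1.0)),
    ],
)
def test_invalid_config_raises_naming_error(field, value):
    cfg = SimulationConfig(**{field: value})
    with pytest.raises(ConfigurationError):
        cfg.validate()


def test_catalog_category_counts_within_multinomial_bounds():
    # per-category 99.8% binomial bounds; Bonferroni over 5 categories -> joint >= 99%
    cfg = SimulationConfig(n_sites=1000, seed=2)
    cat = simulate_site_catalog(cfg)
    counts = {r: sum(s.region == r for s in cat) for r in cfg.region_probs}
    for region, prob in cfg.region_probs.items():
        lo = stats.binom.ppf(0.001, 1000, prob)
        hi = stats.binom.ppf(0.999, 1000, prob)
        assert lo <= counts[region] <= hi, region


def test_counts_deterministic_and_mean_matches_baseline():
    cfg = SimulationConfig(
        n_sites=1000, n_samples_per_group=(10, 10), coverage_mean=50,
        coverage_dispersion=0.0, baseline_editing_dist=(3e5, 7e5),
        n_differential=0, effect_size=0.0, snp_fraction=0.0, seed=3,
    )
    cat = simulate_site_catalog(cfg)
    p1, t1 = simulate_counts(cfg, cat)
    p2, _ = simulate_counts(cfg, cat)
    assert np.array_equal(p1.n_i, p2.n_i) and np.array_equal(p1.n_a, p2.n_a)
    # grand mean efficiency within binomial standard error of the 0.3 baseline
    grand = p1.n_i.sum() / p1.coverage.sum()
    assert abs(grand - 0.3) < 0.01
    assert not t1.is_differential.any()


def test_differential_sites_shift_second_group():
    cfg = SimulationConfig(
        n_sites=50, n_samples_per_group=(10, 10), coverage_mean=400,
        coverage_dispersion=0.0, baseline_editing_dist=(3e5, 7e5),
        n_differential=10, effect_size=0.2, snp_fraction=0.0, seed=4,
    )
    profile, truth = simulate_counts(cfg, simulate_site_catalog(cfg))
    in_b = profile.group_mask("G2")
    diff = truth.is_differential
    pooled_b = profile.n_i[diff][:, in_b].sum() / profile.coverage[diff][:, in_b].sum()
    pooled_a = profile.n_i[diff][:, ~in_b].sum() / profile.coverage[diff][:, ~in_b].sum()
    assert abs(pooled_b - 0.5) < 0.02
    assert abs(pooled_a - 0.3) < 0.02
    assert np.allclose(truth.group_efficiency[diff, 1] - truth.group_efficiency[diff, 0], 0.2)


def test_effect_recovery_converges_with_coverage():
    # pooled weighted-mean difference approaches effect_size at deep coverage
    cfg = SimulationConfig(
        n_sites=200, n_samples_per_group=(10, 10), coverage_mean=2000,
        coverage_dispersion=0.0, baseline_editing_dist=(3e5, 7e5),
        n_differential=200, effect_size=0.2, snp_fraction=0.0, seed=5,
    )
    profile, truth = simulate_counts(cfg, simulate_site_catalog(cfg))
    in_b = profile.group_mask("G2")
    diff_b = profile.n_i[:, in_b].sum(1) / profile.coverage[:, in_b].sum(1)
    diff_a = profile.n_i[:, ~in_b].sum(1) / profile.coverage[:, ~in_b].sum(1)
    assert abs(np.mean(diff_b - diff_a) - 0.2) < 0.005


def test_snp_sites_are_trimodal():
    cfg = SimulationConfig(
        n_sites=100, n_samples_per_group=(20, 20), coverage_mean=60,
        coverage_dispersion=0.0, n_differential=0, snp_fraction=1.0, seed=6,
    )
    profile, truth = simulate_counts(cfg, simulate_site_catalog(cfg))
    assert truth.is_snp_like.all()
    eff = profile.efficiency
    in_bands = ((eff <= 0.1) | ((eff >= 0.4) & (eff <= 0.6)) | (eff >= 0.9)).mean()
    assert in_bands > 0.8


def test_expression_uncoupled_rho_near_zero():
    cfg = SimulationConfig(
        n_sites=300, n_samples_per_group=(15, 15), expression_coupling=0.0, seed=7,
    )
    profile, truth = simulate_counts(cfg, simulate_site_catalog(cfg))
    expr = simulate_expression(cfg, profile, truth)
    rhos = [
        stats.spearmanr(profile.efficiency[i, :], expr.iloc[i, :]).statistic
        for i in range(300)
    ]
    # permutation-null quantile at n=30: |rho| < 0.5 for ~99% of uncoupled
    # genes; 300 genes give a stable estimate of that population fraction
    assert np.mean(np.abs(rhos) < 0.5) >= 0.98


def test_expression_strong_coupling_gives_high_rho_and_determinism():
    cfg = SimulationConfig(
        n_sites=50, n_samples_per_group=(15, 15), coverage_mean=500,
        coverage_dispersion=0.0, baseline_editing_dist=(2, 2), editing_noise_sd=0.15,
        n_differential=0, expression_coupling=25.0, expression_noise_sd=0.01, seed=8,
    )
    profile, truth = simulate_counts(cfg, simulate_site_catalog(cfg))
    expr = simulate_expression(cfg, profile, truth)
    expr2 = simulate_expression(cfg, profile, truth)
    assert expr.equals(expr2)
    rhos = [
        stats.spearmanr(profile.efficiency[i, :], expr.iloc[i, :]).statistic
        for i in range(20)
    ]
    assert np.mean(rhos) > 0.9


def test_sam_fixture_counting_and_errors(sam_fixture):
    expected = sam_fixture.expected
    assert expected.loc["chr1:110:+"].tolist() == [1, 1]  # G + one surviving A
    assert expected.loc["chr1:140:-"].tolist() == [1, 1]  # C + T
    # duplicates retained under keep_duplicates
    kd = sam_fixture.expected_counts(keep_duplicates=True)
    assert kd.loc["chr1:110:+", "n_A"] == 2
    with pytest.raises(FixtureError):
        simulate_sam_fixture(
            [EditingSite("chr1", 110, "+")],
            [ReadSpec("r", 500, "A" * 20, chr(63) * 20)],  # overlaps no site
        )
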