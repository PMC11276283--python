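"""Site selection ahead of statistical comparison.

Three per-site filters reduce the counts grid to comparison-ready sites:

* coverage rule: every sample of the comparison has at least ``min_cov``
  (default 10) reads at the site;
* mean-efficiency band: a site is dropped when the average efficiency in
  *both* groups is below 0.05 or in both groups above 0.95 — nothing is
  left to compare at near-invariant sites;
* SNP heuristic: the per-sample efficiency distribution at a genomic
  polymorphism is tri-modal (near 0, 0.5 and 1 for the AA/AG/GG genotypes)
  rather than unimodal; sites matching that pattern are flagged and removed
  without consulting any external variant database.

Each filter is a pure per-site predicate computed on the full comparison
sample set, so the surviving set does not depend on application order; the
report records one disposition per site using the fixed precedence
coverage > band > SNP.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ContractViolationError
from .profile import EditingProfile

SNP_TOTAL_FRACTION = 0.40
SNP_GENOTYPE_FRACTION = 0.05


@dataclass(frozen=True)
class SnpFilterStats:
    """Genotype-band tallies across the samples of a comparison.

    m_aa / m_ag / m_gg count samples whose efficiency falls in the closed
    intervals [0, 0.1], [0.4, 0.6] and [0.9, 1]; M is the number of samples
    considered.
    """

    m_aa: int
    m_ag: int
    m_gg: int
    m_total: int


def group_weighted_mean(n_i: np.ndarray, n: np.ndarray) -> float:
    """Pooled (coverage-weighted) average efficiency: sum(n_I) / sum(n)."""
    n_i = np.asarray(n_i, dtype=float)
    n = np.asarray(n, dtype=float)
    if n.size == 0:
        raise ContractViolationError("group_weighted_mean of an empty group")
    total = n.sum()
    if total <= 0:
        raise ContractViolationError("group_weighted_mean with zero total coverage")
    return float(n_i.sum() / total)


def _group_means(
    profile: EditingProfile, group_a: str, group_b: str, weighted: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    in_a = profile.group_mask(group_a)
    in_b = profile.group_mask(group_b)
    n = profile.coverage.astype(float)
    n_i = profile.n_i.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        if weighted:
            mean_a = n_i[:, in_a].sum(1) / n[:, in_a].sum(1)
            mean_b = n_i[:, in_b].sum(1) / n[:, in_b].sum(1)
        else:
            eff = np.where(n > 0, n_i / n, np.nan)
            mean_a = np.nanmean(eff[:, in_a], axis=1)
            mean_b = np.nanmean(eff[:, in_b], axis=1)
    return mean_a, mean_b


def coverage_filter(profile: EditingProfile, min_cov: int = 10) -> np.ndarray:
    """Boolean keep-mask: n >= min_cov in every sample of the comparison."""
    return (profile.coverage >= min_cov).all(axis=1)


def band_filter(
    profile: EditingProfile,
    group_a: str,
    group_b: str,
    low: float = 0.05,
    high: float = 0.95,
    both_groups: bool = True,
    weighted: bool = True,
) -> np.ndarray:
    """Boolean keep-mask for the mean-efficiency band.

    With ``both_groups`` (default) a site is removed only when both group
    means fall in the same extreme band; the stricter either-group reading
    is available as ``both_groups=False``.
    """
    mean_a, mean_b = _group_means(profile, group_a, group_b, weighted=weighted)
    with np.errstate(invalid="ignore"):
        if both_groups:
            extreme = ((mean_a < low) & (mean_b < low)) | ((mean_a > high) & (mean_b > high))
        else:
            extreme = (mean_a < low) | (mean_b < low) | (mean_a > high) | (mean_b > high)
    return ~extreme


def snp_stats(efficiencies: np.ndarray) -> SnpFilterStats:
    """Tally genotype-band membership over one site's per-sample efficiencies.

    NaN efficiencies (zero-coverage samples) are excluded from all tallies
    and from M.
    """
    eff = np.asarray(efficiencies, dtype=float)
    eff = eff[~np.isnan(eff)]
    return SnpFilterStats(
        m_aa=int(((eff >= 0.0) & (eff <= 0.1)).sum()),
        m_ag=int(((eff >= 0.4) & (eff <= 0.6)).sum()),
        m_gg=int(((eff >= 0.9) & (eff <= 1.0)).sum()),
        m_total=int(eff.size),
    )


def snp_filter(
    stats: SnpFilterStats,
    total_fraction: float = SNP_TOTAL_FRACTION,
    genotype_fraction: float = SNP_GENOTYPE_FRACTION,
) -> bool:
    """Apply the two-condition SNP rule to one site's tallies.

    True (potential SNP) iff more than 40% of samples sit in the three
    genotype bands combined AND at least two of the three bands individually
    hold more than 5% of samples.
    """
    if stats.m_total == 0:
        raise ContractViolationError("snp_filter with zero samples")
    m = stats.m_total
    cond1 = (stats.m_aa + stats.m_ag + stats.m_gg) / m > total_fraction
    sub = sum(
        frac > genotype_fraction
        for frac in (stats.m_aa / m, stats.m_ag / m, stats.m_gg / m)
    )
    return bool(cond1 and sub >= 2)


def snp_mask(profile: EditingProfile) -> np.ndarray:
    """Per-site boolean array: True where the SNP heuristic fires."""
    eff = profile.efficiency
    return np.array([snp_filter(snp_stats(eff[i, :])) for i in range(profile.n_sites)])


def select_comparison_sites(
    profile: EditingProfile,
    group_a: str,
    group_b: str,
    min_cov: int = 10,
    band: tuple[float, float] = (0.05, 0.95),
    band_both_groups: bool = True,
    apply_snp_filter: bool = True,
    weighted: bool = True,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Run all three filters; returns (keep mask, per-site report).

    The report has one row per input site with its disposition
    (kept / removed_coverage / removed_band / removed_snp) and the statistic
    that triggered removal.
    """
    comparison = profile.subset_samples(
        [s for s in profile.samples if profile.groups[s] in (group_a, group_b)]
    )
    cov_ok = coverage_filter(comparison, min_cov=min_cov)
    band_ok = band_filter(
        comparison, group_a, group_b, low=band[0], high=band[1],
        both_groups=band_both_groups, weighted=weighted,
    )
    if apply_snp_filter:
        not_snp = ~snp_mask(comparison)
    else:
        not_snp = np.ones(comparison.n_sites, dtype=bool)
    keep = cov_ok & band_ok & not_snp

    mean_a, mean_b = _group_means(comparison, group_a, group_b, weighted=weighted)
    min_coverage = comparison.coverage.min(axis=1)
    disposition = np.where(
        ~cov_ok, "removed_coverage", np.where(~band_ok, "removed_band", np.where(~not_snp, "removed_snp", "kept"))
    )
    statistic = np.where(
        ~cov_ok,
        min_coverage.astype(float),
        np.where(~band_ok, np.fmax(mean_a, mean_b), np.nan),
    )
    report = pd.DataFrame(
        {
            "disposition": disposition,
            "statistic": statistic,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "min_coverage": min_coverage,
        },
        index=pd.Index(comparison.site_ids, name="site"),
    )
    return keep, report
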