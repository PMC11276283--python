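"""Differential editing: coverage-weighted two-group comparison per site.

The editing efficiency estimated from ``n_I`` edited reads out of ``n`` is a
binomial proportion, so its sampling variance is ``p(1-p)/n = n_I n_A / n^3``
— samples sequenced deeper carry proportionally more information. The
two-group comparison is therefore run as a weighted least-squares regression
of per-sample efficiency on a 0/1 group indicator with inverse-variance
weights

    w = 1 / sigma^2 = n^3 / (n_I n_A),

which is the weighted analogue of the unpaired two-tailed t-test. The WLS
slope equals the difference of the coverage-weighted group means; its t
statistic uses N - 2 degrees of freedom and the two-tailed Student-t
p-value. P-values are adjusted per comparison by Benjamini-Hochberg, and a
site is called differentially edited at q <= alpha (default 0.05).

Edge rules
----------
* A sample with ``n_I = 0`` or ``n_A = 0`` has infinite nominal weight; a
  Haldane-style continuity correction replaces the weight denominator with
  ``(n_I + 0.5)(n_A + 0.5)`` for that sample only, leaving every other case
  exact. The number of corrected samples per site is reported.
* If the weighted residual variance is exactly zero the t statistic is
  undefined: p = 1 when the group means agree, otherwise p is set to the
  smallest positive float and the site is flagged ``degenerate``.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, ContractViolationError
from .profile import AlleleCount, EditingProfile
from .selection import select_comparison_sites
from .sites import EditingSite

_TINY_P = np.finfo(float).tiny


@dataclass(frozen=True)
class WeightedObservation:
    """One sample's contribution to a site's weighted comparison."""

    p: float  # editing efficiency n_I / n
    sigma2: float  # variance estimate n_I n_A / n^3 (corrected at zero counts)
    w: float  # inverse-variance weight; w * sigma2 == 1
    group: int | None = None  # 0 or 1 when attached to a comparison
    zero_corrected: bool = False


def sample_weight(count: AlleleCount, group: int | None = None) -> WeightedObservation:
    """Efficiency, binomial variance and inverse-variance weight for a sample.

    ``w = n^3 / (n_I n_A)`` exactly when both counts are positive; when
    either count is zero the denominator uses the 0.5-shifted counts.
    Requires ``n >= 1``.
    """
    n_i, n_a = count.n_i, count.n_a
    n = n_i + n_a
    if n < 1:
        raise ContractViolationError("sample_weight requires n >= 1")
    if n_i > 0 and n_a > 0:
        w = n**3 / (n_i * n_a)
        corrected = False
    else:
        w = n**3 / ((n_i + 0.5) * (n_a + 0.5))
        corrected = True
    return WeightedObservation(p=n_i / n, sigma2=1.0 / w, w=w, group=group, zero_corrected=corrected)


@dataclass(frozen=True)
class RegressionTest:
    slope: float
    t: float
    df: int
    p_value: float
    mean_a: float
    mean_b: float
    degenerate: bool = False


def _weighted_test_arrays(
    p: np.ndarray, w: np.ndarray, in_b: np.ndarray
) -> dict[str, np.ndarray]:
    """Vectorised weighted regression over S sites (rows) and M samples.

    Closed form for a dichotomous predictor: the WLS slope is the weighted
    mean difference, SE^2 = s^2 (1/W_a + 1/W_b) with
    s^2 = sum w r^2 / (M - 2).
    """
    in_a = ~in_b
    M = p.shape[1]
    if in_b.sum() < 2 or in_a.sum() < 2:
        raise ContractViolationError("both groups need >= 2 observations")
    w_a, w_b = w[:, in_a], w[:, in_b]
    W_a, W_b = w_a.sum(axis=1), w_b.sum(axis=1)
    mean_a = (w_a * p[:, in_a]).sum(axis=1) / W_a
    mean_b = (w_b * p[:, in_b]).sum(axis=1) / W_b
    slope = mean_b - mean_a
    fitted = np.where(in_b[None, :], mean_b[:, None], mean_a[:, None])
    df = M - 2
    s2 = (w * (p - fitted) ** 2).sum(axis=1) / df
    se2 = s2 * (1.0 / W_a + 1.0 / W_b)
    degenerate = s2 <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = slope / np.sqrt(se2)
    p_value = 2.0 * stats.t.sf(np.abs(t), df)
    p_value = np.where(degenerate, np.where(slope == 0.0, 1.0, _TINY_P), p_value)
    t = np.where(degenerate & (slope == 0.0), 0.0, t)
    return {
        "mean_a": mean_a,
        "mean_b": mean_b,
        "slope": slope,
        "t": t,
        "df": np.full(p.shape[0], df),
        "p_value": p_value,
        "degenerate": degenerate,
    }


def weighted_regression_test(observations: list[WeightedObservation]) -> RegressionTest:
    """Weighted dichotomous regression for a single site.

    Observations must carry group labels 0/1 with at least two per group.
    """
    if any(o.group not in (0, 1) for o in observations):
        raise ContractViolationError("every observation needs group 0 or 1")
    p = np.array([[o.p for o in observations]])
    w = np.array([[o.w for o in observations]])
    in_b = np.array([o.group == 1 for o in observations])
    r = _weighted_test_arrays(p, w, in_b)
    return RegressionTest(
        slope=float(r["slope"][0]),
        t=float(r["t"][0]),
        df=int(r["df"][0]),
        p_value=float(r["p_value"][0]),
        mean_a=float(r["mean_a"][0]),
        mean_b=float(r["mean_b"][0]),
        degenerate=bool(r["degenerate"][0]),
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ContractViolationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _weights_from_counts(n_i: np.ndarray, n_a: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = (n_i + n_a).astype(float)
    if (n < 1).any():
        raise ContractViolationError("every sample needs n >= 1 at tested sites")
    p = n_i / n
    prod = (n_i * n_a).astype(float)
    zero = prod == 0
    prod = np.where(zero, (n_i + 0.5) * (n_a + 0.5), prod)
    w = n**3 / prod
    return p, w, zero


class DifferentialEditingModel:
    """Two-group differential editing model over an editing profile.

    Parameters
    ----------
    profile
        Counts grid with group labels covering ``group_a`` and ``group_b``.
    group_a, group_b
        Labels of the two comparison groups ("group I" and "group II";
        the slope and direction are reported for group_b relative to
        group_a).
    select
        When True (default) the selection filters (coverage, band, SNP) are
        applied before testing; pass False for a pre-selected profile.
    min_cov, band, band_both_groups, apply_snp_filter
        Selection parameters, forwarded to
        :func:`editscape.selection.select_comparison_sites`.
    """

    def __init__(
        self,
        profile: EditingProfile,
        group_a: str,
        group_b: str,
        *,
        select: bool = True,
        min_cov: int = 10,
        band: tuple[float, float] = (0.05, 0.95),
        band_both_groups: bool = True,
        apply_snp_filter: bool = True,
    ) -> None:
        if profile.groups is None:
            raise ConfigurationError("profile has no group labels")
        labels = set(profile.groups[s] for s in profile.samples)
        for g in (group_a, group_b):
            if g not in labels:
                raise ConfigurationError(f"group {g!r} not present in profile labels")
        self.group_a, self.group_b = group_a, group_b
        self.profile = profile.subset_samples(
            [s for s in profile.samples if profile.groups[s] in (group_a, group_b)]
        )
        self.select = select
        self.min_cov = min_cov
        self.band = band
        self.band_both_groups = band_both_groups
        self.apply_snp_filter = apply_snp_filter

    @classmethod
    def from_counts(
        cls, counts_tsv, groups_tsv, group_a: str, group_b: str, **kwargs
    ) -> "DifferentialEditingModel":
        from .profile import read_groups

        groups = read_groups(groups_tsv)
        profile = EditingProfile.from_tsv(counts_tsv, groups=groups)
        return cls(profile, group_a, group_b, **kwargs)

    def fit(self, alpha: float = 0.05) -> "DifferentialEditingResults":
        if self.select:
            keep, report = select_comparison_sites(
                self.profile,
                self.group_a,
                self.group_b,
                min_cov=self.min_cov,
                band=self.band,
                band_both_groups=self.band_both_groups,
                apply_snp_filter=self.apply_snp_filter,
            )
            tested = self.profile.subset_sites(keep)
        else:
            report = None
            tested = self.profile

        in_b = tested.group_mask(self.group_b)
        if tested.n_sites == 0:
            table = pd.DataFrame(
                columns=[
                    "gene", "region", "repeat", "mean_a", "mean_b", "slope",
                    "t", "df", "p_value", "q_value", "direction",
                    "n_zero_corrected", "degenerate", "significant",
                ],
                index=pd.Index([], name="site"),
            )
            return DifferentialEditingResults(self, table, report, alpha)

        p, w, zero = _weights_from_counts(tested.n_i, tested.n_a)
        r = _weighted_test_arrays(p, w, in_b)
        q = bh_adjust(r["p_value"])
        direction = np.where(r["slope"] > 0, "hyper", np.where(r["slope"] < 0, "hypo", "none"))
        table = pd.DataFrame(
            {
                "gene": [s.gene for s in tested.sites],
                "region": [s.region for s in tested.sites],
                "repeat": [s.repeat for s in tested.sites],
                "mean_a": r["mean_a"],
                "mean_b": r["mean_b"],
                "slope": r["slope"],
                "t": r["t"],
                "df": r["df"],
                "p_value": r["p_value"],
                "q_value": q,
                "direction": direction,
                "n_zero_corrected": zero.sum(axis=1),
                "degenerate": r["degenerate"],
                "significant": q <= alpha,
            },
            index=pd.Index(tested.site_ids, name="site"),
        )
        return DifferentialEditingResults(self, table, report, alpha)


class DifferentialEditingResults:
    """Fitted differential-editing comparison.

    ``table`` holds one row per tested site: weighted group means, slope
    (mean_b - mean_a), t, df, two-tailed p, BH q, direction (hyper = higher
    in group_b) and edge-case flags.
    """

    def __init__(self, model, table: pd.DataFrame, selection_report, alpha: float) -> None:
        self.model = model
        self.table = table
        self.selection_report = selection_report
        self.alpha = alpha

    @property
    def n_tested(self) -> int:
        return len(self.table)

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]

    def direction_split(self) -> tuple[int, int]:
        """(hypo, hyper) counts among significant sites: hypo = lower mean in
        group_b than group_a (i.e. higher in the first group)."""
        sig = self.significant
        return int((sig["direction"] == "hypo").sum()), int((sig["direction"] == "hyper").sum())

    def category_tally(self) -> dict[str, int]:
        """Significant-site counts per region category plus repeats, with
        5'/3' UTRs also combined under "UTR"."""
        sig = self.significant
        tally = {region: int((sig["region"] == region).sum()) for region in
                 ("CDS", "UTR5", "UTR3", "intron", "intergenic")}
        tally["UTR"] = tally["UTR5"] + tally["UTR3"]
        tally["repetitive"] = int(sig["repeat"].sum())
        return tally

    def summary(self) -> str:
        hypo, hyper = self.direction_split()
        tally = self.category_tally()
        in_a = self.model.profile.group_mask(self.model.group_a).sum()
        in_b = self.model.profile.group_mask(self.model.group_b).sum()
        lines = [
            "Differential editing: weighted two-group comparison",
            "=" * 55,
            f"Groups:             {self.model.group_a} (n={in_a}) vs {self.model.group_b} (n={in_b})",
            f"Sites tested:       {self.n_tested}",
            f"Significant (q<={self.alpha:g}): {len(self.significant)}  (hypo {hypo} / hyper {hyper})",
            f"Categories:         CDS {tally['CDS']}, UTR {tally['UTR']}, intron {tally['intron']}, "
            f"intergenic {tally['intergenic']}, repetitive {tally['repetitive']}",
            "-" * 55,
        ]
        top = self.significant.sort_values("q_value").head(10)
        if len(top):
            lines.append(top[["mean_a", "mean_b", "slope", "t", "p_value", "q_value", "direction"]]
                         .to_string(float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)


def call_differential(
    profile: EditingProfile, group_a: str, group_b: str, alpha: float = 0.05, **kwargs
) -> DifferentialEditingResults:
    """Convenience wrapper: build the model, fit, return results."""
    return DifferentialEditingModel(profile, group_a, group_b, **kwargs).fit(alpha=alpha)


def annotate_results(
    table: pd.DataFrame, catalog: list[EditingSite]
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Attach region/repeat annotation from a catalog and tally significant
    sites per category. Raises if a tested site is absent from the catalog."""
    by_id = {s.site_id: s for s in catalog}
    missing = [sid for sid in table.index if sid not in by_id]
    if missing:
        from .errors import ValidationError

        raise ValidationError(f"sites missing from catalog: {missing[:5]}")
    table = table.copy()
    table["region"] = [by_id[sid].region for sid in table.index]
    table["repeat"] = [by_id[sid].repeat for sid in table.index]
    sig = table[table["significant"]] if "significant" in table else table
    tally = {region: int((sig["region"] == region).sum()) for region in
             ("CDS", "UTR5", "UTR3", "intron", "intergenic")}
    tally["UTR"] = tally["UTR5"] + tally["UTR3"]
    tally["repetitive"] = int(sig["repeat"].sum())
    return table, tally
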