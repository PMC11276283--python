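"""Correlating editing efficiency with normalized gene expression.

Expression per gene and sample is measured as exonic read count divided by
the sample's total mapped reads. For each site of interest the per-sample
editing efficiencies are correlated with the expression of a target gene
(by default the gene containing the site; alternatively designated genes
such as ADAR1/ADAR2) using Spearman's rank correlation. The alternative
hypothesis is chosen by the sign of the observed coefficient — "greater"
for rho > 0, "less" for rho < 0 — and the corresponding one-sided p-value
is reported alongside the conventional two-sided one. Samples with site
coverage below 10 are excluded before correlating; BH adjustment runs
across all tested site-gene pairs of a run.

P-value method: exact rank-permutation enumeration for n <= 9 paired
observations, the large-sample t approximation on rho otherwise (the method
used is recorded per result).
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContractViolationError, InsufficientDataError
from .profile import EditingProfile

logger = logging.getLogger(__name__)

EXACT_MAX_N = 9


def normalized_gene_coverage(exonic_reads: float, total_mapped: float) -> float:
    """Exonic read count over total mapped reads; dimensionless."""
    if total_mapped < 1:
        raise ContractViolationError("total mapped reads must be >= 1")
    return exonic_reads / total_mapped


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    alternative: str  # "greater" | "less" | "two-sided" (rho == 0)
    p_value: float  # under the sign-directed alternative
    p_two_sided: float
    n: int
    method: str  # "exact" | "t-approx"


def _rank(values: np.ndarray) -> np.ndarray:
    return stats.rankdata(values, method="average")


def _rho_of_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    if denom == 0:
        return 0.0
    return float((rx * ry).sum() / denom)


def _exact_pvalues(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> tuple[float, float, float]:
    """Enumerate all n! pairings of the y-ranks against the x-ranks.

    Returns (P(rho >= obs), P(rho <= obs), P(|rho| >= |obs|)).
    """
    n = len(rx)
    perms = np.array(list(permutations(range(n))))
    ry_c = ry - ry.mean()
    rx_c = rx - rx.mean()
    denom = np.sqrt((rx_c**2).sum() * (ry_c**2).sum())
    if denom == 0:
        return 1.0, 1.0, 1.0
    rhos = (ry_c[perms] * rx_c[None, :]).sum(axis=1) / denom
    eps = 1e-12
    p_greater = float((rhos >= rho_obs - eps).mean())
    p_less = float((rhos <= rho_obs + eps).mean())
    p_two = float((np.abs(rhos) >= abs(rho_obs) - eps).mean())
    return p_greater, p_less, p_two


def _t_approx_pvalues(rho: float, n: int) -> tuple[float, float, float]:
    if abs(rho) >= 1.0:
        one = 0.0
    else:
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
        one = float(stats.t.sf(abs(t), n - 2))
    p_greater = one if rho >= 0 else 1.0 - one
    p_less = one if rho <= 0 else 1.0 - one
    return p_greater, p_less, min(1.0, 2.0 * one)


def signed_spearman_test(x, y) -> SpearmanResult:
    """Spearman correlation with the alternative chosen by the sign of rho.

    Ties are handled by average ranks. Requires at least 5 paired values.
    A coefficient of exactly zero is reported with the two-sided p and
    flagged via ``alternative="two-sided"``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ContractViolationError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 5:
        raise InsufficientDataError(f"need >= 5 paired observations, got {n}")
    rx, ry = _rank(x), _rank(y)
    rho = _rho_of_ranks(rx, ry)
    if n <= EXACT_MAX_N:
        p_greater, p_less, p_two = _exact_pvalues(rx, ry, rho)
        method = "exact"
    else:
        p_greater, p_less, p_two = _t_approx_pvalues(rho, n)
        method = "t-approx"
    if rho > 0:
        alt, p_one = "greater", p_greater
    elif rho < 0:
        alt, p_one = "less", p_less
    else:
        alt, p_one = "two-sided", p_two
    return SpearmanResult(rho=rho, alternative=alt, p_value=p_one, p_two_sided=p_two, n=n, method=method)


def correlate_sites(
    profile: EditingProfile,
    site_ids: list[str],
    expression: pd.DataFrame,
    targets: list[str] | None = None,
    min_cov: int = 10,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Correlate editing at selected sites with gene expression.

    For each site the target genes are its containing gene, or the
    designated ``targets`` (e.g. the editing enzymes ADAR1/ADAR2). Only
    samples with site coverage >= ``min_cov`` enter a correlation; pairs
    with fewer than 5 usable samples are reported as untested. Returns the
    per-pair table and summary counts (tested / significant / positive /
    negative).
    """
    index = {sid: i for i, sid in enumerate(profile.site_ids)}
    eff = profile.efficiency
    cov = profile.coverage
    rows = []
    for sid in site_ids:
        if sid not in index:
            raise ContractViolationError(f"site {sid} not in profile")
        i = index[sid]
        genes = targets if targets is not None else [profile.sites[i].gene]
        for gene in genes:
            if gene not in expression.index:
                logger.warning("gene %s absent from expression table; skipping site %s", gene, sid)
                continue
            usable = cov[i, :] >= min_cov
            row = {"site": sid, "gene": gene, "n_used": int(usable.sum())}
            if usable.sum() < 5:
                row.update(tested=False, rho=np.nan, alternative="", p_value=np.nan,
                           p_two_sided=np.nan, method="")
            else:
                expr = expression.loc[gene, np.array(profile.samples)[usable]].to_numpy(dtype=float)
                res = signed_spearman_test(eff[i, usable], expr)
                row.update(tested=True, rho=res.rho, alternative=res.alternative,
                           p_value=res.p_value, p_two_sided=res.p_two_sided, method=res.method)
            rows.append(row)
    table = pd.DataFrame(rows)
    if len(table):
        table["q_value"] = np.nan
        tested = table["tested"].to_numpy(dtype=bool)
        if tested.any():
            from .diffedit import bh_adjust

            table.loc[tested, "q_value"] = bh_adjust(table.loc[tested, "p_value"].to_numpy())
        table["significant"] = table["q_value"] <= alpha
    summary = {
        "tested": int(table["tested"].sum()) if len(table) else 0,
        "significant": int(table["significant"].sum()) if len(table) else 0,
        "positive": int((table.get("significant", pd.Series(dtype=bool)) & (table.get("rho", pd.Series(dtype=float)) > 0)).sum()) if len(table) else 0,
        "negative": int((table.get("significant", pd.Series(dtype=bool)) & (table.get("rho", pd.Series(dtype=float)) < 0)).sum()) if len(table) else 0,
    }
    return table, summary
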