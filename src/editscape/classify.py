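"""Leave-one-out classification of samples from editing profiles alone.

For each fold one sample is held out and the full comparison pipeline —
site selection and the weighted differential test — is rerun on the
remaining samples. Sites significant in the training fold (q <= alpha) are
scored on the held-out sample: +1 when its efficiency is strictly closer to
the training mean of group I, -1 when strictly closer to group II, 0 when
the site's coverage in the held-out sample is below 10 (or the distances
tie). The summed score signs the prediction; a zero total is "Not
Determined".

Performance is summarised two ways: accuracy over all samples (Not
Determined counted as incorrect) and a 2x2 predicted-vs-actual table over
determined samples only, whose significance is evaluated with Fisher's
exact test (two-sided).
"""
from __future__ import annotations

from dataclasses import dataclass

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .diffedit import DifferentialEditingModel, DifferentialEditingResults
from .errors import ContractViolationError
from .profile import AlleleCount, EditingProfile

logger = logging.getLogger(__name__)

NOT_DETERMINED = "NotDetermined"


def score_site(
    count: AlleleCount, mean_i: float, mean_ii: float, min_cov: int = 10
) -> int:
    """Per-site vote for the held-out sample: +1 group I, -1 group II, 0 none."""
    if count.n < min_cov:
        return 0
    eff = count.efficiency
    d_i, d_ii = abs(eff - mean_i), abs(eff - mean_ii)
    # floating-point-safe tie: equidistant efficiencies score 0
    if abs(d_i - d_ii) <= 1e-9 * max(1.0, d_i, d_ii):
        return 0
    return 1 if d_i < d_ii else -1


def fisher_exact(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 table of non-negative counts."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ContractViolationError("fisher_exact requires a 2x2 table")
    if (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        if (t < 0).any() or not np.allclose(t, np.round(t)):
            raise ContractViolationError("table entries must be non-negative integers")
        t = t.astype(np.int64)
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


@dataclass
class PerformanceSummary:
    """Aggregate LOOCV outcome for one comparison."""

    table: np.ndarray  # 2x2 predicted (rows: I, II) x actual (cols: I, II), determined only
    n_total: int
    n_correct: int
    n_not_determined: int
    fisher_p: float

    @property
    def accuracy(self) -> float:
        """Correct over all samples; Not Determined counts as incorrect."""
        return self.n_correct / self.n_total

    @property
    def accuracy_determined(self) -> float:
        determined = int(self.table.sum())
        return self.n_correct / determined if determined else float("nan")


@dataclass
class LoocvResult:
    predictions: pd.DataFrame  # sample, true, predicted, score, n_sites_used
    summary: PerformanceSummary


def _training_fit(
    profile: EditingProfile,
    held_out: str,
    group_a: str,
    group_b: str,
    alpha: float,
    **model_kwargs,
) -> DifferentialEditingResults:
    """Selection + differential test on all samples except ``held_out``.

    The held-out sample contributes to no filter, mean or significance call
    in its own fold.
    """
    training = profile.drop_sample(held_out)
    return DifferentialEditingModel(training, group_a, group_b, **model_kwargs).fit(alpha=alpha)


def loocv(
    profile: EditingProfile,
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
    min_cov: int = 10,
    **model_kwargs,
) -> LoocvResult:
    """Leave-one-out cross-validation over the samples of a comparison.

    ``group_a`` plays the role of group I (positive scores), ``group_b``
    of group II. Both groups need at least 3 samples so every training fold
    retains two per group.
    """
    samples = [s for s in profile.samples if profile.groups[s] in (group_a, group_b)]
    comparison = profile.subset_samples(samples)
    for g in (group_a, group_b):
        if comparison.group_mask(g).sum() < 3:
            raise ContractViolationError(f"group {g!r} needs >= 3 samples for LOOCV")

    site_index = {sid: i for i, sid in enumerate(comparison.site_ids)}
    rows = []
    for sample in samples:
        results = _training_fit(
            comparison, sample, group_a, group_b, alpha, min_cov=min_cov, **model_kwargs
        )
        sig = results.significant
        if len(sig) == 0:
            logger.info("fold %s: no significant training sites; Not Determined", sample)
            rows.append(
                {"sample": sample, "true": profile.groups[sample],
                 "predicted": NOT_DETERMINED, "score": 0, "n_sites_used": 0}
            )
            continue
        score = 0
        for sid, site_row in sig.iterrows():
            count = comparison.allele_count(site_index[sid], sample)
            score += score_site(count, site_row["mean_a"], site_row["mean_b"], min_cov=min_cov)
        predicted = group_a if score > 0 else group_b if score < 0 else NOT_DETERMINED
        rows.append(
            {"sample": sample, "true": profile.groups[sample],
             "predicted": predicted, "score": score, "n_sites_used": len(sig)}
        )

    predictions = pd.DataFrame(rows)
    determined = predictions[predictions["predicted"] != NOT_DETERMINED]
    table = np.zeros((2, 2), dtype=np.int64)
    for _, row in determined.iterrows():
        i = 0 if row["predicted"] == group_a else 1
        j = 0 if row["true"] == group_a else 1
        table[i, j] += 1
    n_correct = int((predictions["predicted"] == predictions["true"]).sum())
    summary = PerformanceSummary(
        table=table,
        n_total=len(predictions),
        n_correct=n_correct,
        n_not_determined=int((predictions["predicted"] == NOT_DETERMINED).sum()),
        fisher_p=fisher_exact(table),
    )
    return LoocvResult(predictions=predictions, summary=summary)
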