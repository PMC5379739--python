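"""Nonparametric ROC analysis: placement AUC, DeLong variance, paired tests.

The AUC is the Mann–Whitney concordance probability: the chance that a random
event is scored higher than a random non-event, ties counting one half.  It
is computed by the placement method — for each event, the fraction of
non-events it outranks — which also yields the DeLong variance components
used for confidence intervals and for the paired comparison of two markers
evaluated on the same subjects.  A seed-fixed bootstrap is provided as a
sensitivity check on the paired comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve


@dataclass(frozen=True)
class AucResult:
    auc: float
    se: float
    ci_lower: float
    ci_upper: float
    n_events: int
    n_nonevents: int
    roc_points: np.ndarray = field(repr=False, default=None)  # (fpr, tpr, threshold)


@dataclass(frozen=True)
class AucComparison:
    auc_a: float
    auc_b: float
    difference: float
    se: float
    z: float
    p_value: float
    ci_lower: float
    ci_upper: float
    bootstrap_p: float | None = None
    bootstrap_ci: tuple[float, float] | None = None


def _placements(scores: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject placement values.

    For event i: fraction of non-events scored strictly below, plus half the
    ties.  For non-event j: fraction of events scored strictly above it...
    inverted so that the mean of either vector is the AUC.
    """
    pos = np.sort(scores[y == 1])
    neg = np.sort(scores[y == 0])
    m, n = len(pos), len(neg)
    # events placed against non-events
    below = np.searchsorted(neg, scores[y == 1], side="left")
    ties = np.searchsorted(neg, scores[y == 1], side="right") - below
    v10 = (below + 0.5 * ties) / n
    # non-events placed against events
    below_p = np.searchsorted(pos, scores[y == 0], side="left")
    ties_p = np.searchsorted(pos, scores[y == 0], side="right") - below_p
    v01 = (m - below_p - ties_p + 0.5 * ties_p) / m
    return v10, v01


def _validate(scores, y) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y).astype(int)
    if scores.shape != y.shape:
        raise ValueError("scores and outcomes must have equal length")
    if np.isnan(scores).any():
        raise ValueError("scores contain NaN; apply complete-case filtering first")
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("outcomes must be binary 0/1")
    return scores, y


def roc_auc(scores, y, alpha: float = 0.05) -> AucResult | None:
    """Placement-method AUC with a DeLong confidence interval.

    Returns None when only one outcome class is present.  The CI is the
    normal-approximation interval clipped to [0, 1]; with a degenerate
    variance (perfect or perfectly tied markers) the interval collapses to
    the point estimate.
    """
    scores, y = _validate(scores, y)
    m = int((y == 1).sum())
    n = int((y == 0).sum())
    if m == 0 or n == 0:
        return None
    v10, v01 = _placements(scores, y)
    auc = float(v10.mean())
    s10 = float(v10.var(ddof=1)) if m > 1 else 0.0
    s01 = float(v01.var(ddof=1)) if n > 1 else 0.0
    var = s10 / m + s01 / n
    se = float(np.sqrt(max(var, 0.0)))
    z = stats.norm.ppf(1 - alpha / 2)
    lo, hi = max(0.0, auc - z * se), min(1.0, auc + z * se)
    fpr, tpr, thr = roc_curve(y, scores)
    points = np.column_stack([fpr, tpr, thr])
    return AucResult(auc=auc, se=se, ci_lower=lo, ci_upper=hi,
                     n_events=m, n_nonevents=n, roc_points=points)


def compare_auc(
    scores_a,
    scores_b,
    y,
    alpha: float = 0.05,
    n_boot: int = 2000,
    seed: int | None = None,
) -> AucComparison:
    """Paired nonparametric comparison of two markers on the same subjects.

    The primary test is DeLong's: the difference in placement means with a
    variance that accounts for the pairing.  When ``seed`` is given, a
    stratified bootstrap (resampling events and non-events separately,
    ``n_boot`` resamples) is reported alongside as a sensitivity analysis.
    """
    scores_a, y = _validate(scores_a, y)
    scores_b, y2 = _validate(scores_b, y)
    if not np.array_equal(y, y2):
        raise ValueError("paired comparison requires identical outcome vectors")
    m = int((y == 1).sum())
    n = int((y == 0).sum())
    if m == 0 or n == 0:
        raise ValueError("both outcome classes must be present")

    v10_a, v01_a = _placements(scores_a, y)
    v10_b, v01_b = _placements(scores_b, y)
    auc_a, auc_b = float(v10_a.mean()), float(v10_b.mean())
    diff = auc_a - auc_b

    def _cov(u, v, size):
        if size <= 1:
            return 0.0
        return float(np.cov(u, v, ddof=1)[0, 1])

    s10 = np.array([[_cov(v10_a, v10_a, m), _cov(v10_a, v10_b, m)],
                    [_cov(v10_b, v10_a, m), _cov(v10_b, v10_b, m)]])
    s01 = np.array([[_cov(v01_a, v01_a, n), _cov(v01_a, v01_b, n)],
                    [_cov(v01_b, v01_a, n), _cov(v01_b, v01_b, n)]])
    cov = s10 / m + s01 / n
    contrast = np.array([1.0, -1.0])
    var = float(contrast @ cov @ contrast)
    se = float(np.sqrt(max(var, 0.0)))
    if se == 0.0:
        z = 0.0
        p = 1.0 if diff == 0 else 0.0
    else:
        z = diff / se
        p = float(2 * stats.norm.sf(abs(z)))
    zc = stats.norm.ppf(1 - alpha / 2)
    ci = (diff - zc * se, diff + zc * se)

    boot_p = boot_ci = None
    if seed is not None:
        rng = np.random.default_rng(seed)
        pos_idx = np.flatnonzero(y == 1)
        neg_idx = np.flatnonzero(y == 0)
        diffs = np.empty(n_boot)
        for b in range(n_boot):
            idx = np.concatenate([rng.choice(pos_idx, m, replace=True),
                                  rng.choice(neg_idx, n, replace=True)])
            ya = y[idx]
            va, _ = _placements(scores_a[idx], ya)
            vb, _ = _placements(scores_b[idx], ya)
            diffs[b] = va.mean() - vb.mean()
        boot_ci = (float(np.quantile(diffs, alpha / 2)),
                   float(np.quantile(diffs, 1 - alpha / 2)))
        shifted = diffs - diffs.mean()
        boot_p = float(min(1.0, 2 * min(np.mean(shifted >= diff), np.mean(shifted <= diff))
                           + 1.0 / n_boot)) if diff != 0 else 1.0

    return AucComparison(auc_a=auc_a, auc_b=auc_b, difference=diff, se=se, z=z,
                         p_value=p, ci_lower=ci[0], ci_upper=ci[1],
                         bootstrap_p=boot_p, bootstrap_ci=boot_ci)
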