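"""Per-feature diagnostic screening: ROC, AUC, DeLong test, Youden cutoff.

Each candidate biomarker is evaluated as a univariate classifier separating
one patient group from controls.  The ROC staircase is built over all
distinct-score midpoints; the area under it equals the Mann-Whitney
concordance probability with ties counted 1/2.  The 95% CI on the AUC is
an exact binomial (Clopper-Pearson) interval treating round(AUC*n) of n as
successes with n the total sample size — the tabulation convention of
common clinical statistics packages; the convention is isolated here so it
can be swapped.  Correlated (same-subject) AUCs are compared with DeLong's
placement-value test, and the operating point is chosen by the maximal
Youden index J = sensitivity + specificity - 1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RocCurve",
    "ScreeningResult",
    "DeLongComparison",
    "DEFAULT_ORIENTATIONS",
    "roc_curve",
    "auc_mann_whitney",
    "auc_with_exact_ci",
    "delong_test",
    "delong_auc_variance",
    "youden_cutoff",
    "screen_feature",
    "screen_features",
    "delong_matrix",
]

logger = logging.getLogger(__name__)

#: expected direction of each feature in PD relative to controls: tapping
#: scores and typing output fall with motor impairment, fluctuation
#: statistics and the composite typing index rise
DEFAULT_ORIENTATIONS = {
    "hl_sd": "cases_higher",
    "il_sd": "cases_higher",
    "pl_sd": "cases_higher",
    "rl_sd": "cases_higher",
    "sd_restricted": "cases_higher",
    "nqi": "cases_higher",
    "updrs3": "cases_higher",
    "aftap": "cases_lower",
    "stap": "cases_lower",
    "typing_speed": "cases_lower",
    "word_count": "cases_lower",
}


@dataclass(frozen=True)
class RocCurve:
    """ROC staircase: thresholds (with ±inf sentinels), sens and spec arrays."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    orientation: str
    n_cases: int
    n_controls: int


@dataclass(frozen=True)
class ScreeningResult:
    feature_name: str
    orientation: str
    roc: RocCurve
    auc: float
    auc_ci95: tuple[float, float]
    cutoff: float
    sensitivity_at_cutoff: float  # percent
    specificity_at_cutoff: float  # percent
    n_cases: int
    n_controls: int
    n_missing_excluded: int = 0


@dataclass(frozen=True)
class DeLongComparison:
    feature_a: str
    feature_b: str
    auc_a: float
    auc_b: float
    var_diff: float
    z: float
    p_value: float
    n_paired: int


def _validate(scores, labels) -> tuple[np.ndarray, np.ndarray, int]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if y.dtype.kind not in "bi":
        y = y.astype(bool)
    y = y.astype(bool)
    ok = ~np.isnan(s)
    n_missing = int((~ok).sum())
    s, y = s[ok], y[ok]
    if y.sum() == 0 or (~y).sum() == 0:
        raise ValueError("need at least one case and one control with scores")
    return s, y, n_missing


def roc_curve(scores, labels, orientation: str = "cases_higher") -> RocCurve:
    """ROC points over midpoint thresholds plus ±inf sentinels.

    Under ``cases_higher`` a subject is called positive when its score
    exceeds the threshold; under ``cases_lower`` when it falls below.
    Missing scores are excluded pairwise.
    """
    if orientation not in ("cases_higher", "cases_lower"):
        raise ValueError(f"unknown orientation {orientation!r}")
    s, y, _ = _validate(scores, labels)
    work = s if orientation == "cases_higher" else -s
    uniq = np.unique(work)
    thr = np.concatenate([[-np.inf], (uniq[:-1] + uniq[1:]) / 2.0, [np.inf]])
    cases = work[y]
    ctrls = work[~y]
    # positive call: score > threshold (in the oriented direction)
    sens = (cases[None, :] > thr[:, None]).mean(axis=1)
    spec = (ctrls[None, :] <= thr[:, None]).mean(axis=1)
    if orientation == "cases_lower":
        thr = -thr  # report thresholds on the original scale
    return RocCurve(
        thresholds=thr,
        sensitivity=sens,
        specificity=spec,
        orientation=orientation,
        n_cases=int(y.sum()),
        n_controls=int((~y).sum()),
    )


def auc_mann_whitney(scores, labels, orientation: str = "cases_higher") -> float:
    """AUC as the Mann-Whitney concordance probability, ties counted 1/2.

    Equals the trapezoidal area under the ROC staircase.
    """
    s, y, _ = _validate(scores, labels)
    if orientation == "cases_lower":
        s = -s
    ranks = stats.rankdata(s)
    n1 = int(y.sum())
    n0 = int((~y).sum())
    auc = (ranks[y].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    return float(auc)


def auc_with_exact_ci(
    scores, labels, orientation: str = "cases_higher"
) -> tuple[float, tuple[float, float]]:
    """AUC with an exact binomial (Clopper-Pearson) 95% CI.

    The interval treats ``x = round(AUC * n)`` successes in ``n`` trials,
    ``n = n_cases + n_controls``.
    """
    s, y, _ = _validate(scores, labels)
    auc = auc_mann_whitney(s, y, orientation)
    n = len(s)
    x = int(round(auc * n))
    lo = 0.0 if x == 0 else float(stats.beta.ppf(0.025, x, n - x + 1))
    hi = 1.0 if x == n else float(stats.beta.ppf(0.975, x + 1, n - x))
    return auc, (lo, hi)


def _placements(scores: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Case and control placement values and the AUC (ties 1/2)."""
    cases = scores[y]
    ctrls = scores[~y]
    m, n = len(cases), len(ctrls)
    # V10[i] = P(case_i beats a random control); V01[j] = P(a random case beats control_j)
    cmp_ = (cases[:, None] > ctrls[None, :]).astype(float)
    cmp_ += 0.5 * (cases[:, None] == ctrls[None, :])
    v10 = cmp_.mean(axis=1)
    v01 = cmp_.mean(axis=0)
    return v10, v01, float(cmp_.mean())


def delong_auc_variance(scores, labels, orientation: str = "cases_higher") -> float:
    """DeLong variance of a single AUC from placement values."""
    s, y, _ = _validate(scores, labels)
    if orientation == "cases_lower":
        s = -s
    v10, v01, _ = _placements(s, y)
    m, n = len(v10), len(v01)
    return float(np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n)


def delong_test(
    scores_a,
    scores_b,
    labels,
    feature_a: str = "a",
    feature_b: str = "b",
    orientation_a: str = "cases_higher",
    orientation_b: str = "cases_higher",
) -> DeLongComparison:
    """DeLong's paired test comparing two correlated AUCs.

    Subjects missing either score are dropped (pairwise-complete subset;
    ``n_paired`` records the size used).  The z statistic is the AUC
    difference over the square root of its placement-value variance, with a
    two-sided normal p-value.
    """
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels).astype(bool)
    if not (len(sa) == len(sb) == len(y)):
        raise ValueError("scores_a, scores_b and labels must be the same length")
    ok = ~np.isnan(sa) & ~np.isnan(sb)
    sa, sb, y = sa[ok], sb[ok], y[ok]
    if y.sum() == 0 or (~y).sum() == 0:
        raise ValueError("need at least one case and one control")
    if orientation_a == "cases_lower":
        sa = -sa
    if orientation_b == "cases_lower":
        sb = -sb

    v10a, v01a, auc_a = _placements(sa, y)
    v10b, v01b, auc_b = _placements(sb, y)
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    cov = s10 / m + s01 / n  # 2x2 covariance of (auc_a, auc_b)
    var_diff = float(cov[0, 0] + cov[1, 1] - 2 * cov[0, 1])
    diff = auc_a - auc_b
    if var_diff <= 0 or math.isclose(var_diff, 0.0, abs_tol=1e-300):
        if math.isclose(diff, 0.0, abs_tol=1e-12):
            z, p = 0.0, 1.0
        else:
            raise ValueError("degenerate DeLong comparison: zero variance, unequal AUCs")
    else:
        z = diff / math.sqrt(var_diff)
        p = float(2 * stats.norm.sf(abs(z)))
        p = min(max(p, np.nextafter(0, 1)), 1.0)
    return DeLongComparison(
        feature_a=feature_a,
        feature_b=feature_b,
        auc_a=float(auc_a),
        auc_b=float(auc_b),
        var_diff=var_diff,
        z=float(z),
        p_value=float(p),
        n_paired=int(len(y)),
    )


def youden_cutoff(roc: RocCurve) -> tuple[float, float, float]:
    """Threshold maximising J = sensitivity + specificity - 1.

    Ties in J are broken in favour of higher sensitivity, then the lower
    threshold in the case direction (the more inclusive operating point for
    a screening test).
    """
    j = roc.sensitivity + roc.specificity - 1.0
    best = np.flatnonzero(np.isclose(j, j.max(), atol=1e-12))
    # higher sensitivity first
    best = best[np.isclose(roc.sensitivity[best], roc.sensitivity[best].max(), atol=1e-12)]
    thr = roc.thresholds[best]
    pick = best[np.argmin(thr)] if roc.orientation == "cases_higher" else best[np.argmax(thr)]
    return (
        float(roc.thresholds[pick]),
        float(roc.sensitivity[pick]),
        float(roc.specificity[pick]),
    )


def screen_feature(
    scores,
    labels,
    feature_name: str = "",
    orientation: str | None = None,
    auto_orient: bool = True,
) -> ScreeningResult:
    """Full univariate screening of one feature.

    When ``orientation`` is None it is looked up in
    :data:`DEFAULT_ORIENTATIONS` (default ``cases_higher``).  With
    ``auto_orient`` the orientation is flipped — and the flip logged — if
    the oriented AUC falls below 0.5.
    """
    if orientation is None:
        orientation = DEFAULT_ORIENTATIONS.get(feature_name, "cases_higher")
    s, y, n_missing = _validate(scores, labels)
    auc = auc_mann_whitney(s, y, orientation)
    if auto_orient and auc < 0.5:
        flipped = "cases_lower" if orientation == "cases_higher" else "cases_higher"
        logger.info(
            "auto-orienting %s: AUC %.3f under %s, flipping to %s",
            feature_name or "<feature>", auc, orientation, flipped,
        )
        orientation = flipped
    roc = roc_curve(s, y, orientation)
    auc, ci = auc_with_exact_ci(s, y, orientation)
    cutoff, sens, spec = youden_cutoff(roc)
    return ScreeningResult(
        feature_name=feature_name,
        orientation=orientation,
        roc=roc,
        auc=auc,
        auc_ci95=ci,
        cutoff=cutoff,
        sensitivity_at_cutoff=100.0 * sens,
        specificity_at_cutoff=100.0 * spec,
        n_cases=roc.n_cases,
        n_controls=roc.n_controls,
        n_missing_excluded=n_missing,
    )


def screen_features(
    df: pd.DataFrame,
    features: list[str],
    case_group: str,
    control_group: str = "control",
    orientations: dict[str, str] | None = None,
    auto_orient: bool = True,
) -> list[ScreeningResult]:
    """Screen each feature for one case-vs-control contrast of a feature table."""
    sub = df[df["group"].isin([case_group, control_group])]
    labels = (sub["group"] == case_group).to_numpy()
    orientations = orientations or {}
    results = []
    for feat in features:
        results.append(
            screen_feature(
                sub[feat].to_numpy(dtype=float),
                labels,
                feature_name=feat,
                orientation=orientations.get(feat),
                auto_orient=auto_orient,
            )
        )
    return results


def delong_matrix(
    df: pd.DataFrame,
    features: list[str],
    case_group: str,
    control_group: str = "control",
    orientations: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Pairwise DeLong p-values between features for one contrast."""
    sub = df[df["group"].isin([case_group, control_group])]
    labels = (sub["group"] == case_group).to_numpy()
    orientations = orientations or {}
    out = pd.DataFrame(np.nan, index=features, columns=features, dtype=float)
    for i, fa in enumerate(features):
        out.loc[fa, fa] = 1.0
        for fb in features[i + 1:]:
            cmp_ = delong_test(
                sub[fa].to_numpy(dtype=float),
                sub[fb].to_numpy(dtype=float),
                labels,
                feature_a=fa,
                feature_b=fb,
                orientation_a=orientations.get(fa, DEFAULT_ORIENTATIONS.get(fa, "cases_higher")),
                orientation_b=orientations.get(fb, DEFAULT_ORIENTATIONS.get(fb, "cases_higher")),
            )
            out.loc[fa, fb] = out.loc[fb, fa] = cmp_.p_value
    return out
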