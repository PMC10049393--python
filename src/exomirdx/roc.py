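"""ROC curves, AUC, and AUC uncertainty for panel hit-count scores.

Hit-count scores are ordinal (0–8 for the combined four-miRNA panel), so
the ROC convention here groups tied scores onto a single operating point:
each distinct cutoff c yields the point obtained by predicting positive
iff score ≥ c, plus the (0,0) and (1,1) endpoints. AUC is the trapezoidal
area, which equals the tie-adjusted pairwise probability
P(score_case > score_control) + ½·P(tie) (the Mann–Whitney estimator).

Uncertainty: stratified bootstrap (default; resample cases and controls
separately, percentile interval, seeded) or DeLong's asymptotic normal
variance. The p-value against AUC = 0.5 (no discrimination) comes from the
same machinery as the chosen interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve as _sk_roc_curve

from .errors import InvalidParameterError, UndefinedMetricError


def _split(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(list(scores), dtype=float)
    labels = np.asarray(list(labels), dtype=bool)
    if scores.shape != labels.shape:
        raise InvalidParameterError("scores and labels must have equal length")
    if labels.all() or not labels.any():
        raise UndefinedMetricError("ROC requires both classes")
    return scores[labels], scores[~labels]


def roc_curve(scores: Sequence[float], labels: Sequence[bool]) -> np.ndarray:
    """Operating points (FPR, TPR) over all distinct score cutoffs.

    ``labels`` True = disease-positive; higher score = more disease-like.
    Returns an (k, 2) array, monotone nondecreasing in both coordinates,
    starting at (0, 0) and ending at (1, 1).
    """
    _split(scores, labels)  # validates
    fpr, tpr, _ = _sk_roc_curve(
        np.asarray(list(labels), dtype=int),
        np.asarray(list(scores), dtype=float),
        drop_intermediate=False,
    )
    pts = np.column_stack([fpr, tpr])
    if not np.allclose(pts[-1], (1.0, 1.0)):
        pts = np.vstack([pts, (1.0, 1.0)])
    return pts


def auc(points: np.ndarray) -> float:
    """Trapezoidal area under an ROC curve given as (FPR, TPR) points."""
    pts = np.asarray(points, dtype=float)
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))


def auc_from_scores(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """AUC directly from scores (equivalent to ``auc(roc_curve(...))``)."""
    _split(scores, labels)
    return float(
        roc_auc_score(
            np.asarray(list(labels), dtype=int), np.asarray(list(scores), dtype=float)
        )
    )


def _delong_variance(pos: np.ndarray, neg: np.ndarray) -> tuple[float, float]:
    """DeLong AUC and its variance via the midrank formulation."""
    m, n = len(pos), len(neg)
    all_scores = np.concatenate([pos, neg])
    tz = stats.rankdata(all_scores)  # midranks over the pooled sample
    tx = stats.rankdata(pos)
    ty = stats.rankdata(neg)
    auc_hat = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v01 = (tz[:m] - tx) / n          # structural components per case
    v10 = 1.0 - (tz[m:] - ty) / m    # per control
    var = 0.0
    if m > 1:
        var += np.var(v01, ddof=1) / m
    if n > 1:
        var += np.var(v10, ddof=1) / n
    return float(auc_hat), float(var)


@dataclass
class AucUncertainty:
    ci: tuple[float, float]
    p_value_vs_chance: float
    method: str


def auc_uncertainty(
    scores: Sequence[float],
    labels: Sequence[bool],
    method: Literal["bootstrap", "delong"] = "bootstrap",
    level: float = 0.99,
    n_boot: int = 2000,
    seed: int | None = None,
) -> AucUncertainty:
    """CI for the AUC and a p-value against AUC = 0.5.

    bootstrap: stratified percentile interval over ``n_boot`` resamples
    (clipped to [0, 1]); two-sided p from the bootstrap distribution's
    position relative to 0.5. delong: normal-approximation interval and
    test from the asymptotic variance.
    """
    pos, neg = _split(scores, labels)
    if len(pos) < 2 or len(neg) < 2:
        raise InvalidParameterError(
            "AUC uncertainty requires n >= 2 in each class"
        )
    if method == "delong":
        auc_hat, var = _delong_variance(pos, neg)
        if var <= 0:
            ci = (auc_hat, auc_hat)
            p = 1.0 if auc_hat == 0.5 else 0.0
        else:
            z = stats.norm.ppf((1.0 + level) / 2.0)
            se = np.sqrt(var)
            ci = (max(0.0, auc_hat - z * se), min(1.0, auc_hat + z * se))
            p = float(2.0 * stats.norm.sf(abs(auc_hat - 0.5) / se))
        return AucUncertainty(ci=ci, p_value_vs_chance=min(p, 1.0), method="delong")
    if method != "bootstrap":
        raise InvalidParameterError(f"unknown uncertainty method: {method}")

    rng = np.random.default_rng(seed)
    m, n = len(pos), len(neg)
    boot = np.empty(n_boot)
    y = np.concatenate([np.ones(m, int), np.zeros(n, int)])
    for b in range(n_boot):
        ps = pos[rng.integers(0, m, m)]
        ns = neg[rng.integers(0, n, n)]
        s = np.concatenate([ps, ns])
        if np.ptp(s) == 0:  # all resampled scores tied → chance AUC
            boot[b] = 0.5
        else:
            boot[b] = roc_auc_score(y, s)
    alpha = (1.0 - level) / 2.0
    ci = (
        float(np.clip(np.quantile(boot, alpha), 0.0, 1.0)),
        float(np.clip(np.quantile(boot, 1.0 - alpha), 0.0, 1.0)),
    )
    p = 2.0 * min(float(np.mean(boot <= 0.5)), float(np.mean(boot >= 0.5)))
    return AucUncertainty(
        ci=ci, p_value_vs_chance=min(p, 1.0), method="bootstrap"
    )


@dataclass
class RocResult:
    points: np.ndarray
    auc: float
    auc_ci99: tuple[float, float]
    p_value_vs_chance: float
    method: str


def analyze_scores(
    scores: Sequence[float],
    labels: Sequence[bool],
    method: Literal["bootstrap", "delong"] = "bootstrap",
    level: float = 0.99,
    n_boot: int = 2000,
    seed: int | None = None,
) -> RocResult:
    """Full ROC analysis of one score vector: curve, AUC, CI, p-value."""
    pts = roc_curve(scores, labels)
    unc = auc_uncertainty(scores, labels, method, level, n_boot, seed)
    return RocResult(
        points=pts,
        auc=auc(pts),
        auc_ci99=unc.ci,
        p_value_vs_chance=unc.p_value_vs_chance,
        method=unc.method,
    )


def plot_roc(result: RocResult, ax=None, label: str | None = None):
    """Optional matplotlib plot of an ROC curve (lazy import)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    lbl = label or f"AUC = {result.auc:.3f}"
    ax.plot(result.points[:, 0], result.points[:, 1], marker="o", label=lbl)
    ax.plot([0, 1], [0, 1], linestyle="--", color="grey", linewidth=0.8)
    ax.set_xlabel("False-positive rate (1 − specificity)")
    ax.set_ylabel("True-positive rate (sensitivity)")
    ax.legend(loc="lower right")
    return ax
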