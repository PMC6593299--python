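"""LFC-weighted polygenic risk score and ROC evaluation.

The score of sample j over a miRNA panel is the weighted sum of log-FPM
values, score_j = sum_i w_i * L_ij, with w_i the log2 fold change of panel
miRNA i.  A one-miRNA panel with unit weight reduces to ranking samples by
that miRNA's log-FPM.

ROC machinery follows the midrank (Mann-Whitney) convention: AUC is the
probability that a random case outscores a random control, ties counted
half.  The Youden index J = sensitivity + specificity - 1 picks the
operating cutoff.  The DeLong structural-components estimator provides the
AUC confidence interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .containers import ValidationError

logger = logging.getLogger("circmir")


def polygenic_score(logfpm: pd.DataFrame, weights: pd.Series | dict) -> pd.Series:
    """Per-sample weighted sum of log-FPM over the panel defined by ``weights``.

    ``logfpm`` is features x samples; ``weights`` maps panel miRNA -> LFC.
    """
    w = pd.Series(weights, dtype=float)
    if len(w) == 0:
        raise ValidationError("panel must be non-empty")
    if not np.all(np.isfinite(w)):
        raise ValidationError("weights must be finite")
    missing = [m for m in w.index if m not in logfpm.index]
    if missing:
        raise ValidationError(f"panel miRNAs absent from the matrix: {missing}")
    scores = logfpm.loc[w.index].T @ w
    scores.name = "risk_score"
    return scores


def _split(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    cases = scores[labels]
    controls = scores[~labels]
    if len(cases) == 0 or len(controls) == 0:
        raise ValidationError("both classes must be present")
    return cases, controls


def auc(scores, labels) -> float:
    """Midrank Mann-Whitney AUC: P(case > control) + 0.5 P(tie).

    No orientation flip is applied — cases are expected to score higher;
    values below 0.5 indicate an anti-oriented score.
    """
    cases, controls = _split(scores, labels)
    n1, n0 = len(cases), len(controls)
    ranks = stats.rankdata(np.concatenate([cases, controls]))
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


@dataclass
class ROCResult:
    """Full ROC curve: thresholds (midpoints between distinct scores plus
    +/- inf), sens/spec at each, AUC, and the orientation used ('>' means a
    sample is called a case when its score exceeds the cutoff)."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    orientation: str = ">"
    points: pd.DataFrame = field(init=False, repr=False)

    def __post_init__(self):
        self.points = pd.DataFrame(
            {
                "cutoff": self.thresholds,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            }
        )


def roc_curve(scores, labels, direction: str = "auto") -> ROCResult:
    """Operating points at every distinct threshold, by direct counting.

    ``direction``: '>' scores cases high, '<' scores cases low, 'auto'
    picks the direction with AUC >= 0.5 and records it.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    raw_auc = auc(scores, labels)
    if direction == "auto":
        direction = ">" if raw_auc >= 0.5 else "<"
        if direction == "<":
            logger.info("risk score anti-oriented (raw AUC %.3f); using direction '<'", raw_auc)
    if direction not in (">", "<"):
        raise ValidationError("direction must be '>', '<' or 'auto'")
    oriented = scores if direction == ">" else -scores

    cases, controls = _split(oriented, labels)
    distinct = np.unique(oriented)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.concatenate([[-np.inf], mids, [np.inf]])
    sens = np.array([(cases > t).mean() for t in thresholds])
    spec = np.array([(controls <= t).mean() for t in thresholds])
    return ROCResult(
        thresholds=thresholds if direction == ">" else -thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc(oriented, labels),
        orientation=direction,
    )


def trapezoid_auc(roc: ROCResult) -> float:
    """Area under the stored operating points (equals the midrank AUC)."""
    fpr = 1.0 - roc.specificity
    # within equal FPR the curve rises vertically: order by sensitivity too
    order = np.lexsort((roc.sensitivity, fpr))
    return float(np.trapezoid(roc.sensitivity[order], fpr[order]))


def youden_cutoff(roc: ROCResult) -> tuple[float, float, float]:
    """Cutoff maximizing J = sens + spec - 1.

    Ties are broken by higher sensitivity, then by lower cutoff (in the
    oriented scale) — a screening-friendly choice.
    """
    j = roc.sensitivity + roc.specificity - 1.0
    oriented_cut = roc.thresholds if roc.orientation == ">" else -roc.thresholds
    order = np.lexsort((oriented_cut, -roc.sensitivity, -j))
    best = order[0]
    return (
        float(roc.thresholds[best]),
        float(roc.sensitivity[best]),
        float(roc.specificity[best]),
    )


def delong_variance(scores, labels) -> float:
    """DeLong variance of the midrank AUC via structural components."""
    cases, controls = _split(scores, labels)
    m, n = len(cases), len(controls)
    # V10_i = P(case_i > control) + 0.5 P(tie); V01_j symmetric
    v10 = np.array([((c > controls).sum() + 0.5 * (c == controls).sum()) / n for c in cases])
    v01 = np.array([((cases > c).sum() + 0.5 * (cases == c).sum()) / m for c in controls])
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(s10 / m + s01 / n)


def auc_confidence_interval(
    scores,
    labels,
    level: float = 0.95,
    method: str = "delong",
    n_boot: int = 2000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Normal-approximation DeLong CI (default) or stratified bootstrap,
    truncated to [0, 1].  Degenerate AUCs (exactly 0 or 1) at tiny n give a
    zero-width DeLong variance; a widened-CI warning is logged and the
    bootstrap is the better choice there."""
    cases, controls = _split(scores, labels)
    if len(cases) < 2 or len(controls) < 2:
        raise ValidationError("need >= 2 samples per class for a CI")
    a = auc(scores, labels)
    if method == "delong":
        var = delong_variance(scores, labels)
        if var == 0.0:
            logger.warning("degenerate AUC %.3f with zero DeLong variance; CI widened", a)
            var = 1.0 / (4.0 * min(len(cases), len(controls)))
        zq = stats.norm.ppf(0.5 + level / 2.0)
        half = zq * np.sqrt(var)
        return (max(0.0, a - half), min(1.0, a + half))
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        boots = np.empty(n_boot)
        for b in range(n_boot):
            cs = rng.choice(cases, size=len(cases), replace=True)
            ct = rng.choice(controls, size=len(controls), replace=True)
            boots[b] = auc(
                np.concatenate([cs, ct]),
                np.concatenate([np.ones(len(cs), bool), np.zeros(len(ct), bool)]),
            )
        lo, hi = np.quantile(boots, [(1 - level) / 2, 0.5 + level / 2])
        return (float(max(0.0, lo)), float(min(1.0, hi)))
    raise ValidationError("method must be 'delong' or 'bootstrap'")


class PolygenicRiskScore(BaseEstimator):
    """LFC-weighted expression risk score as an sklearn-style classifier.

    Parameters
    ----------
    weights : mapping miRNA -> LFC (or an array matching X's columns).
        These are plug-in estimates from the DE stage, not learned here.
    direction : '>' | '<' | 'auto'
        Orientation of the decision rule; 'auto' records whichever way the
        fitted data discriminate (predominantly negative weights make the
        raw score anti-oriented).
    ci_method, ci_level, n_boot, random_state : CI settings.

    ``fit(X, y)`` evaluates the score on log-FPM X (n_samples x n_panel,
    column order = panel order) and stores auc_, auc_ci_, cutoff_,
    sensitivity_, specificity_, orientation_ and roc_.  ``decision_function``
    returns scores; ``predict`` applies the fitted Youden cutoff.

    Note: evaluating on the same samples whose DE contrast produced the
    weights inflates the apparent AUC; fitted results carry that caveat.
    """

    def __init__(
        self,
        weights=None,
        direction: str = "auto",
        ci_method: str = "delong",
        ci_level: float = 0.95,
        n_boot: int = 2000,
        random_state: int | None = None,
    ):
        self.weights = weights
        self.direction = direction
        self.ci_method = ci_method
        self.ci_level = ci_level
        self.n_boot = n_boot
        self.random_state = random_state

    def _weight_vector(self, X) -> np.ndarray:
        if self.weights is None:
            raise ValidationError("weights (panel LFCs) must be provided")
        if isinstance(self.weights, (pd.Series, dict)):
            w = pd.Series(self.weights, dtype=float)
            if isinstance(X, pd.DataFrame):
                missing = [m for m in w.index if m not in X.columns]
                if missing:
                    raise ValidationError(f"panel miRNAs absent from X: {missing}")
                self.panel_ = list(w.index)
                return w.to_numpy()
            return w.to_numpy()
        return np.asarray(self.weights, dtype=float)

    def decision_function(self, X):
        w = self._weight_vector(X)
        if isinstance(X, pd.DataFrame) and hasattr(self, "panel_"):
            X = X[self.panel_]
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(w):
            raise ValidationError("X has a different number of panel miRNAs than weights")
        return X @ w

    def fit(self, X, y):
        scores = self.decision_function(X)
        y = np.asarray(y, dtype=bool)
        roc = roc_curve(scores, y, direction=self.direction)
        cutoff, sens, spec = youden_cutoff(roc)
        oriented = scores if roc.orientation == ">" else -scores
        self.roc_ = roc
        self.orientation_ = roc.orientation
        self.auc_ = roc.auc
        self.auc_ci_ = auc_confidence_interval(
            oriented, y, level=self.ci_level, method=self.ci_method,
            n_boot=self.n_boot, seed=self.random_state,
        )
        self.cutoff_ = cutoff
        self.sensitivity_ = sens
        self.specificity_ = spec
        self.classes_ = np.array([False, True])
        return self

    def predict(self, X):
        check_is_fitted(self, "cutoff_")
        scores = self.decision_function(X)
        if self.orientation_ == ">":
            return scores > self.cutoff_
        return scores < self.cutoff_
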