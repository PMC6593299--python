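"""Median-of-ratios size factors, FPM and log-FPM.

FPM ("normalized fragments per million") here means size-factor-normalized
counts rescaled so that the MEAN per-sample total is one million:

    FPM_ij = 1e6 * (K_ij / s_j) / m,   m = mean_j sum_i K_ij / s_j

with s_j the median-of-ratios size factor of sample j rescaled to geometric
mean 1.  Downstream modelling uses log2(FPM + 1) by default.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .containers import CountMatrix, ValidationError

logger = logging.getLogger("circmir")


def _as_frame(cm) -> pd.DataFrame:
    return cm.counts if isinstance(cm, CountMatrix) else pd.DataFrame(cm)


def estimate_size_factors(cm, fallback: str | None = None) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    For every feature with strictly positive counts in all samples, the
    per-sample ratio to the feature's geometric mean is formed; the size
    factor is the median of those ratios.  If no feature is everywhere
    positive, ``fallback='poscounts'`` uses, per feature, the geometric mean
    over its positive samples only (zero rows dropped); otherwise an error
    points at that option.
    """
    counts = _as_frame(cm)
    values = counts.to_numpy(dtype=float)
    all_positive = (values > 0).all(axis=1)
    if all_positive.any():
        sub = values[all_positive]
        log_geomean = np.log(sub).mean(axis=1)
        ratios = np.log(sub) - log_geomean[:, None]
    elif fallback == "poscounts":
        with np.errstate(divide="ignore"):
            logv = np.where(values > 0, np.log(values), np.nan)
        log_geomean = np.nanmean(logv, axis=1)
        ok = np.isfinite(log_geomean)
        if not ok.any():
            raise ValidationError("no feature usable for size-factor estimation")
        ratios = np.where(values[ok] > 0, logv[ok] - log_geomean[ok, None], np.nan)
    else:
        raise ValidationError(
            "no feature is positive in every sample; re-run with "
            "fallback='poscounts' (config sf_fallback: poscounts)"
        )
    log_sf = np.nanmedian(ratios, axis=0)
    log_sf = log_sf - log_sf.mean()  # geometric mean 1
    sf = pd.Series(np.exp(log_sf), index=counts.columns, name="size_factor")
    if not np.all(sf > 0):
        raise ValidationError("non-positive size factor estimated")
    return sf


def fpm(cm, sf: pd.Series | None = None) -> pd.DataFrame:
    """Normalized fragments per million (mean per-sample total = 1e6)."""
    counts = _as_frame(cm)
    if sf is None:
        sf = estimate_size_factors(cm)
    if list(sf.index) != list(counts.columns):
        sf = sf.reindex(counts.columns)
        if sf.isna().any():
            raise ValidationError("size factors missing for some samples")
    normalized = counts.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    col_totals = normalized.sum(axis=0)
    if np.any(col_totals <= 0):
        bad = counts.columns[col_totals <= 0].tolist()
        raise ValidationError(f"zero total normalized count in samples {bad}")
    m = col_totals.mean()
    return pd.DataFrame(1e6 * normalized / m, index=counts.index, columns=counts.columns)


def log_fpm(fpm_matrix: pd.DataFrame, pseudocount: float = 1.0, base: float = 2.0) -> pd.DataFrame:
    """Element-wise log(FPM + pseudocount); base 2 by default."""
    if pseudocount < 0:
        raise ValidationError("pseudocount must be >= 0")
    values = np.asarray(fpm_matrix, dtype=float)
    if pseudocount == 0 and np.any(values <= 0):
        raise ValidationError("log of non-positive FPM; use pseudocount > 0")
    out = np.log(values + pseudocount) / np.log(base)
    if isinstance(fpm_matrix, pd.DataFrame):
        return pd.DataFrame(out, index=fpm_matrix.index, columns=fpm_matrix.columns)
    return out


class MedianOfRatiosNormalizer(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer: counts -> (log-)FPM.

    Follows the sklearn orientation (X is samples x features).  ``fit``
    stores the per-feature log geometric mean as the reference profile and
    the mean normalized library size; ``transform`` computes each sample's
    median-of-ratios size factor against that reference and rescales to FPM.
    On the training matrix this reproduces ``fpm(estimate_size_factors(.))``
    up to the global geometric-mean rescaling of the size factors, which
    cancels in FPM.

    Parameters
    ----------
    output : {'log', 'fpm'}
        Return log(FPM + pseudocount) (default) or raw FPM.
    pseudocount, log_base
        Passed to :func:`log_fpm`.
    """

    def __init__(self, output: str = "log", pseudocount: float = 1.0, log_base: float = 2.0):
        self.output = output
        self.pseudocount = pseudocount
        self.log_base = log_base

    def fit(self, X, y=None):
        X = validate_data(self, X, dtype=float, ensure_min_samples=2)
        positive = (X > 0).all(axis=0)
        if not positive.any():
            raise ValidationError("no feature positive in every training sample")
        self.reference_log_mean_ = np.full(X.shape[1], np.nan)
        self.reference_log_mean_[positive] = np.log(X[:, positive]).mean(axis=0)
        sf = self._size_factors(X)
        self.mean_normalized_total_ = float((X / sf[:, None]).sum(axis=1).mean())
        return self

    def _size_factors(self, X) -> np.ndarray:
        ok = np.isfinite(self.reference_log_mean_)
        with np.errstate(divide="ignore"):
            log_ratios = np.log(X[:, ok]) - self.reference_log_mean_[ok][None, :]
        log_ratios = np.where(np.isfinite(log_ratios), log_ratios, np.nan)
        log_sf = np.nanmedian(log_ratios, axis=1)
        return np.exp(log_sf)

    def transform(self, X):
        check_is_fitted(self, "mean_normalized_total_")
        X = validate_data(self, X, dtype=float, reset=False)
        sf = self._size_factors(X)
        out = 1e6 * (X / sf[:, None]) / self.mean_normalized_total_
        if self.output == "log":
            out = np.log(out + self.pseudocount) / np.log(self.log_base)
        return out
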