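"""Accuracy and precision of rhythmic ratios around isochrony.

Only ratios inside the open isochrony window 0.4 < r_k < 0.6 enter either
metric. Accuracy is the per-ratio deviance |r_k - 0.5| (smaller = closer
to a perfect 1:1 pattern); precision is the interquartile range of the
in-window ratios per individual x gait (smaller = more metronome-like).
Gait differences are tested with mixed models: accuracy at the per-ratio
level and precision at the per-individual level, each with gait as a fixed
factor and individual identity as a random intercept. The response family
is chosen by an AIC screen over candidate distributions and recorded on
the result.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .categories import CategoryTestResult
from .glmm import contrast_tests, fit_glmm, likelihood_ratio_test, quantile_residual_normality
from .rhythm import RatioSequence

__all__ = [
    "IsochronyMetrics",
    "ISOCHRONY_WINDOW",
    "compute_isochrony_metrics",
    "select_family",
    "compare_metrics_across_gaits",
]

logger = logging.getLogger(__name__)

ISOCHRONY_WINDOW = (0.4, 0.6)
#: Fewest in-window ratios for a defined interquartile range.
MIN_FOR_IQR = 4


@dataclass
class IsochronyMetrics:
    """Per individual x gait isochrony metrics.

    ``accuracy`` holds |r_k - 0.5| for every in-window ratio; ``precision``
    is the IQR (Q3 - Q1, linear-interpolation quantiles) of the in-window
    ratios, NaN when fewer than 4 ratios fall in the window.
    """

    individual_id: str
    gait: str
    accuracy: np.ndarray
    precision: float
    n_in_window: int
    window: tuple[float, float] = ISOCHRONY_WINDOW

    @property
    def precision_defined(self) -> bool:
        return np.isfinite(self.precision)


def compute_isochrony_metrics(ratios: RatioSequence) -> IsochronyMetrics:
    """Accuracy and precision of one ratio sequence around isochrony.

    The window endpoints are excluded (open interval). With no in-window
    ratios an empty result is returned with a warning, not an exception;
    with fewer than 4 the IQR is flagged undefined (NaN).
    """
    lo, hi = ISOCHRONY_WINDOW
    r = ratios.r[(ratios.r > lo) & (ratios.r < hi)]
    if r.size == 0:
        warnings.warn(
            f"{ratios.individual_id}/{ratios.gait}: no ratios inside "
            f"({lo}, {hi}); metrics empty",
            stacklevel=2,
        )
        return IsochronyMetrics(
            ratios.individual_id, ratios.gait, np.array([]), np.nan, 0
        )
    accuracy = np.abs(r - 0.5)
    if r.size >= MIN_FOR_IQR:
        q1, q3 = np.percentile(r, [25, 75])  # type-7 linear interpolation
        precision = float(q3 - q1)
    else:
        logger.info(
            "%s/%s: only %d in-window ratios; IQR undefined",
            ratios.individual_id, ratios.gait, r.size,
        )
        precision = np.nan
    return IsochronyMetrics(
        ratios.individual_id, ratios.gait, accuracy, precision, int(r.size)
    )


def metrics_frame(metrics: list[IsochronyMetrics]) -> pd.DataFrame:
    """Summary table: one row per individual x gait."""
    return pd.DataFrame(
        {
            "individual_id": [m.individual_id for m in metrics],
            "gait": [m.gait for m in metrics],
            "n_in_window": [m.n_in_window for m in metrics],
            "mean_accuracy": [
                float(np.mean(m.accuracy)) if m.accuracy.size else np.nan
                for m in metrics
            ],
            "precision": [m.precision for m in metrics],
        }
    )


def select_family(y: np.ndarray) -> str:
    """AIC screen over candidate response distributions.

    Candidates: Gamma (log link) and log-normal — considered only when all
    responses are strictly positive — and Gaussian. Returns the GLMM family
    to use ("gamma", "lognormal-gaussian" meaning Gaussian on log(y), or
    "gaussian").
    """
    y = np.asarray(y, dtype=float)
    candidates: dict[str, float] = {}
    n = y.size
    mu, sd = float(np.mean(y)), float(np.std(y, ddof=1))
    candidates["gaussian"] = 2 * 2 - 2 * np.sum(stats.norm.logpdf(y, mu, sd))
    if np.all(y > 0):
        logy = np.log(y)
        lmu, lsd = float(np.mean(logy)), float(np.std(logy, ddof=1))
        ll = np.sum(stats.norm.logpdf(logy, lmu, lsd)) - np.sum(logy)
        candidates["lognormal-gaussian"] = 2 * 2 - 2 * ll
        with np.errstate(all="ignore"):
            k = max((mu / sd) ** 2, 1e-3)
            ll = np.sum(stats.gamma.logpdf(y, k, scale=mu / k))
        candidates["gamma"] = 2 * 2 - 2 * ll
    best = min(candidates, key=candidates.get)
    logger.info("response family screen (n=%d): %s -> %s", n, candidates, best)
    return best


def compare_metrics_across_gaits(
    metrics: list[IsochronyMetrics], response: str = "accuracy"
) -> CategoryTestResult:
    """Mixed-model comparison of accuracy or precision across gaits.

    Accuracy is modeled per ratio, precision per individual, both with a
    gait fixed factor (cell means) and an individual random intercept.
    Returns the full-vs-null LRT and Tukey-adjusted pairwise gait
    contrasts; a positive ``A - B`` estimate means gait A has the larger
    response (worse accuracy / lower precision).
    """
    if response not in ("accuracy", "precision"):
        raise ValidationError("response must be 'accuracy' or 'precision'")
    ys, gaits, inds = [], [], []
    for m in metrics:
        if response == "accuracy":
            ys.append(m.accuracy)
            gaits.append(np.full(m.accuracy.size, m.gait, dtype=object))
            inds.append(np.full(m.accuracy.size, m.individual_id, dtype=object))
        elif m.precision_defined:
            ys.append([m.precision])
            gaits.append([m.gait])
            inds.append([m.individual_id])
    y = np.concatenate(ys).astype(float)
    gait = np.concatenate(gaits)
    ind = np.concatenate(inds)
    levels = sorted(set(gait))
    if len(levels) < 2 or len(set(ind)) < 2:
        raise ValidationError("need >=2 gaits and >=2 individuals")

    family = select_family(y)
    if family == "lognormal-gaussian":
        y_model, fam = np.log(y), "gaussian"
    elif family == "gamma":
        y_model, fam = y, "gamma"
    else:
        y_model, fam = y, "gaussian"

    codes = np.array([levels.index(g) for g in gait])
    X = np.eye(len(levels))[codes]
    full = fit_glmm(y_model, X, ind, family=fam)
    null = fit_glmm(y_model, np.ones((y.size, 1)), ind, family=fam)
    chisq, df, p = likelihood_ratio_test(full, null)
    L, names = [], []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            row = np.zeros(len(levels))
            row[i], row[j] = 1.0, -1.0
            L.append(row)
            names.append(f"{levels[i]} - {levels[j]}")
    return CategoryTestResult(
        gait="all",
        phase=response,
        family=family,
        chisq=chisq,
        df=df,
        pvalue=p,
        contrasts=contrast_tests(full, np.array(L), names),
        sigma_u=full.sigma_u,
        residual_normality=quantile_residual_normality(full),
        converged=full.converged and null.converged,
        notes=list(full.notes),
    )
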