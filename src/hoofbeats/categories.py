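"""Small-integer-ratio category tests and walk/trot tempo comparison.

The category question: do on-integer bins hold significantly more ratios
than their flanking off-integer bins, once counts are weighted by bin
width? For walk and trot this is a negative-binomial mixed model over six
factor levels (on and pooled-flank off per category: 1:2, 1:1, 2:1) with a
log bin-width offset and an individual random intercept. For canter each
category gets its own Poisson mixed model with on/off bin and motion-cycle
phase (r_k1, r_k2, r_k3) as crossed fixed factors. Significance is the
likelihood-ratio test of the full model against a null with only the
random intercept and offset; the per-category off-minus-on contrasts are
reported with Tukey-style single-step adjustment (negative estimate =
more mass on-integer).

The walk/trot tempo comparison is a paired t-test of per-individual median
interval durations, with Shapiro-Wilk normality checks on each median set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import PairingError, ValidationError
from .glmm import (
    ContrastRow,
    contrast_tests,
    fit_glmm,
    likelihood_ratio_test,
    pearson_dispersion,
    quantile_residual_normality,
)
from .rhythm import CATEGORIES, PHASES, RatioBinScheme, RatioSequence, count_by_bin

__all__ = [
    "CategoryTestResult",
    "DurationComparison",
    "onoff_level_counts",
    "canter_phase_level_counts",
    "fit_onoff_count_model",
    "fit_canter_phase_model",
    "compare_median_intervals",
]

#: Factor-level order for the walk/trot model (fixed for reproducibility;
#: cell-means coding makes estimates invariant to it).
LEVELS = ("1:2 on", "1:2 off", "1:1 on", "1:1 off", "2:1 on", "2:1 off")


@dataclass
class CategoryTestResult:
    """LRT + adjusted contrasts of one category GLMM (one row set of Table-style output)."""

    gait: str
    phase: str | None            # canter phase for per-phase models
    family: str
    chisq: float
    df: int
    pvalue: float
    contrasts: list[ContrastRow]
    sigma_u: float
    dispersion: float | None = None
    residual_normality: tuple[float, float] | None = None
    converged: bool = True
    notes: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gait": self.gait,
                "phase": self.phase,
                "family": self.family,
                "Chisq": self.chisq,
                "DF": self.df,
                "p": self.pvalue,
                "contrast": c.contrast,
                "estimate": c.estimate,
                "SE": c.se,
                "z_ratio": c.z,
                "p_adj": c.p_adj,
            }
            for c in self.contrasts
        ]
        return pd.DataFrame(rows)


def onoff_level_counts(
    ratio_seqs: list[RatioSequence], scheme: RatioBinScheme
) -> pd.DataFrame:
    """Per-individual counts at the six on/off factor levels (walk/trot).

    Each category's off level pools its two flanking off bins; the width
    column holds the (pooled) bin width used for the model offset. The two
    middle off bins each flank two categories and are counted in both off
    levels.
    """
    if not ratio_seqs:
        raise ValidationError("no ratio sequences given")
    rows = []
    for seq in ratio_seqs:
        binned = count_by_bin(seq, scheme).set_index("bin")
        for cat in CATEGORIES:
            on = next(b for b in scheme.on_bins if b.category == cat)
            flanks = [scheme[lbl] for lbl in scheme.off_flanks[cat]]
            rows.append(
                {
                    "individual_id": seq.individual_id,
                    "level": f"{cat} on",
                    "category": cat,
                    "kind": "on",
                    "count": int(binned.loc[on.label, "count"]),
                    "width": on.width,
                }
            )
            rows.append(
                {
                    "individual_id": seq.individual_id,
                    "level": f"{cat} off",
                    "category": cat,
                    "kind": "off",
                    "count": int(sum(binned.loc[b.label, "count"] for b in flanks)),
                    "width": float(sum(b.width for b in flanks)),
                }
            )
    return pd.DataFrame(rows)


def canter_phase_level_counts(
    ratio_seqs: list[RatioSequence], scheme: RatioBinScheme, category: str
) -> pd.DataFrame:
    """Per-individual x phase on/off counts for one canter category."""
    if category not in CATEGORIES:
        raise ValidationError(f"unknown category {category!r}")
    on = next(b for b in scheme.on_bins if b.category == category)
    flanks = [scheme[lbl] for lbl in scheme.off_flanks[category]]
    off_width = float(sum(b.width for b in flanks))
    rows = []
    for seq in ratio_seqs:
        if seq.phase is None:
            raise ValidationError(
                f"{seq.individual_id}: phase labels required for canter counts"
            )
        for ph in PHASES:
            r = seq.r[seq.phase == ph]
            n_on = int(np.sum([on.contains(x) for x in r]))
            n_off = int(np.sum([any(b.contains(x) for b in flanks) for x in r]))
            rows.append(
                {"individual_id": seq.individual_id, "phase": ph, "kind": "on",
                 "count": n_on, "width": on.width}
            )
            rows.append(
                {"individual_id": seq.individual_id, "phase": ph, "kind": "off",
                 "count": n_off, "width": off_width}
            )
    return pd.DataFrame(rows)


def _fit_with_null(y, X, groups, offset, family):
    full = fit_glmm(y, X, groups, family=family, offset=offset)
    null = fit_glmm(y, np.ones((y.size, 1)), groups, family=family, offset=offset)
    return full, null


def fit_onoff_count_model(
    counts: pd.DataFrame,
    family: str = "negative-binomial",
    gait: str = "",
) -> CategoryTestResult:
    """Width-offset count GLMM over the six on/off levels (walk or trot).

    ``counts`` is the output of :func:`onoff_level_counts`. Returns the
    full-vs-null LRT and the three off-minus-on contrasts, Tukey-adjusted.
    A Pearson dispersion ratio is reported for Poisson fits (overdispersion
    screen) and randomized-quantile-residual normality for all fits.
    """
    _require_levels(counts, "level", LEVELS)
    if counts["individual_id"].nunique() < 2:
        raise ValidationError("need >=2 individuals")
    level_codes = pd.Categorical(counts["level"], categories=LEVELS).codes
    X = np.eye(len(LEVELS))[level_codes]  # cell-means coding
    y = counts["count"].to_numpy(dtype=float)
    offset = np.log(counts["width"].to_numpy(dtype=float))
    full, null = _fit_with_null(y, X, counts["individual_id"], offset, family)
    chisq, df, p = likelihood_ratio_test(full, null)
    L, names = [], []
    for cat in CATEGORIES:
        row = np.zeros(len(LEVELS))
        row[LEVELS.index(f"{cat} off")] = 1.0
        row[LEVELS.index(f"{cat} on")] = -1.0
        L.append(row)
        names.append(f"{cat.replace(':', '')}off - {cat.replace(':', '')}on")
    result = CategoryTestResult(
        gait=gait,
        phase=None,
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
    if family == "poisson":
        result.dispersion = pearson_dispersion(full)
    return result


def fit_canter_phase_model(
    counts: pd.DataFrame,
    category: str,
    family: str = "poisson",
) -> CategoryTestResult:
    """Per-category canter GLMM: additive on/off bin + phase fixed factors.

    ``counts`` comes from :func:`canter_phase_level_counts`. The design is
    additive (bin cell means plus phase offsets): ratios of a given phase
    concentrate in one category's on bin, so a full bin-by-phase
    interaction would have structurally empty cells. The reported contrast
    is the off-minus-on bin main effect.
    """
    _require_levels(counts, "kind", ("on", "off"))
    # columns: [on mean, off mean, rk2 offset, rk3 offset]
    X = np.column_stack(
        [
            (counts["kind"] == "on").to_numpy(float),
            (counts["kind"] == "off").to_numpy(float),
            (counts["phase"] == "rk2").to_numpy(float),
            (counts["phase"] == "rk3").to_numpy(float),
        ]
    )
    y = counts["count"].to_numpy(dtype=float)
    offset = np.log(counts["width"].to_numpy(dtype=float))
    full, null = _fit_with_null(y, X, counts["individual_id"], offset, family)
    chisq, df, p = likelihood_ratio_test(full, null)
    L = np.array([-1.0, 1.0, 0.0, 0.0])
    name = f"{category.replace(':', '')}off - {category.replace(':', '')}on"
    result = CategoryTestResult(
        gait="canter",
        phase=category,
        family=family,
        chisq=chisq,
        df=df,
        pvalue=p,
        contrasts=contrast_tests(full, L, [name]),
        sigma_u=full.sigma_u,
        residual_normality=quantile_residual_normality(full),
        converged=full.converged and null.converged,
        notes=list(full.notes),
    )
    if family == "poisson":
        result.dispersion = pearson_dispersion(full)
    return result


def _require_levels(df, column, levels):
    present = set(df[column])
    missing = set(levels) - present
    if missing:
        raise ValidationError(f"missing factor level(s) in {column!r}: {sorted(missing)}")


# --------------------------------------------------------------------------
# Walk vs trot interval durations
# --------------------------------------------------------------------------

@dataclass
class DurationComparison:
    """Paired t-test of per-individual median intervals for two gaits."""

    individual_ids: list[str]
    medians_a: np.ndarray
    medians_b: np.ndarray
    gait_a: str
    gait_b: str
    t: float
    df: int
    pvalue: float
    shapiro_a: tuple[float, float]
    shapiro_b: tuple[float, float]


def compare_median_intervals(walk_seqs, trot_seqs) -> DurationComparison:
    """Paired t-test of per-individual median t_k: walk minus trot.

    A negative t means the second gait's intervals are longer. Individuals
    present in only one gait raise a :class:`PairingError` naming them.
    """
    med_a = {s.individual_id: float(np.median(s.t)) for s in walk_seqs}
    med_b = {s.individual_id: float(np.median(s.t)) for s in trot_seqs}
    unpaired = sorted(set(med_a) ^ set(med_b))
    if unpaired:
        raise PairingError(
            f"individuals not present in both gaits: {unpaired}", unpaired
        )
    ids = sorted(med_a)
    if len(ids) < 3:
        raise ValidationError("need >=3 paired individuals")
    a = np.array([med_a[i] for i in ids])
    b = np.array([med_b[i] for i in ids])
    if np.allclose(a, b):
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_rel(a, b)
    gait_a = walk_seqs[0].gait if walk_seqs else "a"
    gait_b = trot_seqs[0].gait if trot_seqs else "b"
    return DurationComparison(
        individual_ids=ids,
        medians_a=a,
        medians_b=b,
        gait_a=gait_a,
        gait_b=gait_b,
        t=float(t),
        df=len(ids) - 1,
        pvalue=float(p),
        shapiro_a=tuple(map(float, stats.shapiro(a))) if np.ptp(a) > 0 else (np.nan, np.nan),
        shapiro_b=tuple(map(float, stats.shapiro(b))) if np.ptp(b) > 0 else (np.nan, np.nan),
    )
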