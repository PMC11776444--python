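"""End-to-end orchestration of the rhythm analyses.

Thin composition layer used by the CLI, the tests, and the reproduction
script: recordings -> interval sequences -> ratios (sliding and canter
motion-cycle phase ratios) -> category GLMMs, isochrony metrics/models,
and the embedding + classification stage.
"""

from __future__ import annotations

import logging

from .categories import (
    CategoryTestResult,
    canter_phase_level_counts,
    compare_median_intervals,
    fit_canter_phase_model,
    fit_onoff_count_model,
    onoff_level_counts,
)
from .classify import embed_triplets, train_classifier
from .errors import HoofbeatsError
from .isochrony import compare_metrics_across_gaits, compute_isochrony_metrics
from .recording import FootfallRecording
from .rhythm import (
    CATEGORIES,
    RatioBinScheme,
    TripletTable,
    build_bin_scheme,
    compute_canter_phase_ratios,
    compute_intervals,
    compute_ratios,
    make_triplets,
    segment_canter_cycles,
)

logger = logging.getLogger(__name__)

__all__ = [
    "intervals_by_gait",
    "sliding_ratios_by_gait",
    "canter_phase_ratio_sequences",
    "build_triplet_table",
    "run_category_tests",
    "run_isochrony_analysis",
    "run_classification",
]


def intervals_by_gait(recordings: list[FootfallRecording]) -> dict:
    """{gait: [IntervalSequence, ...]} skipping too-short recordings (logged)."""
    out: dict[str, list] = {}
    for rec in recordings:
        try:
            seq = compute_intervals(rec)
        except HoofbeatsError as exc:
            logger.warning("skipping %s/%s: %s", rec.individual_id, rec.gait, exc)
            continue
        out.setdefault(rec.gait, []).append(seq)
    return out


def sliding_ratios_by_gait(recordings: list[FootfallRecording]) -> dict:
    """{gait: [RatioSequence, ...]} of sliding adjacent-pair ratios."""
    out: dict[str, list] = {}
    for gait, seqs in intervals_by_gait(recordings).items():
        for seq in seqs:
            try:
                out.setdefault(gait, []).append(compute_ratios(seq))
            except HoofbeatsError as exc:
                logger.warning("skipping ratios %s/%s: %s", seq.individual_id, gait, exc)
    return out


def canter_phase_ratio_sequences(canter_intervals: list) -> list:
    """Motion-cycle phase ratios (r_k1/r_k2/r_k3) per canter individual."""
    out = []
    for seq in canter_intervals:
        cycles = segment_canter_cycles(seq)
        out.append(
            compute_canter_phase_ratios(cycles, individual_id=seq.individual_id)
        )
    return out


def build_triplet_table(
    recordings: list[FootfallRecording], normalize: bool = False
) -> TripletTable:
    tables = []
    for gait, seqs in intervals_by_gait(recordings).items():
        for seq in seqs:
            tables.append(make_triplets(seq, normalize=normalize))
    return TripletTable.concat(tables)


def run_category_tests(
    recordings: list[FootfallRecording],
    scheme: RatioBinScheme | None = None,
) -> dict[str, CategoryTestResult]:
    """The five category GLMMs: walk, trot (negative-binomial over six
    on/off levels) and the three per-category canter models (Poisson,
    bin x phase). Keys: "walk", "trot", "canter 1:1", "canter 1:2",
    "canter 2:1"."""
    scheme = scheme or build_bin_scheme()
    by_gait = intervals_by_gait(recordings)
    results: dict[str, CategoryTestResult] = {}
    for gait in ("walk", "trot"):
        if gait not in by_gait:
            continue
        ratio_seqs = [compute_ratios(s) for s in by_gait[gait]]
        counts = onoff_level_counts(ratio_seqs, scheme)
        results[gait] = fit_onoff_count_model(
            counts, family="negative-binomial", gait=gait
        )
    if "canter" in by_gait:
        phase_seqs = canter_phase_ratio_sequences(by_gait["canter"])
        for cat in CATEGORIES:
            counts = canter_phase_level_counts(phase_seqs, scheme, cat)
            results[f"canter {cat}"] = fit_canter_phase_model(
                counts, cat, family="poisson"
            )
    return results


def run_isochrony_analysis(recordings: list[FootfallRecording]):
    """(metrics list, accuracy model result, precision model result)."""
    metrics = []
    for gait, ratio_seqs in sliding_ratios_by_gait(recordings).items():
        for rs in ratio_seqs:
            metrics.append(compute_isochrony_metrics(rs))
    accuracy = compare_metrics_across_gaits(metrics, response="accuracy")
    precision = compare_metrics_across_gaits(metrics, response="precision")
    return metrics, accuracy, precision


def run_classification(
    recordings: list[FootfallRecording],
    n_trees: int = 1000,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    train_fraction: float = 0.7,
    seed: int = 0,
    labels: tuple[str, ...] = ("gait", "individual"),
):
    """(EmbeddingResult, {label_kind: ClassifierReport}). One shared
    embedding feeds both the gait- and the individual-supervised forest."""
    triplets = build_triplet_table(recordings, normalize=False)
    embedding = embed_triplets(
        triplets, n_neighbors=n_neighbors, min_dist=min_dist, seed=seed
    )
    reports = {
        lab: train_classifier(
            embedding, label=lab, n_trees=n_trees,
            train_fraction=train_fraction, seed=seed,
        )
        for lab in labels
    }
    return embedding, reports


def run_duration_comparison(recordings: list[FootfallRecording]):
    """Paired walk-vs-trot comparison of per-individual median intervals."""
    by_gait = intervals_by_gait(recordings)
    return compare_median_intervals(by_gait.get("walk", []), by_gait.get("trot", []))
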