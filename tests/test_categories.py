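"""Category GLMMs: count tables, recovery, degenerate inputs, tempo test."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import hoofbeats as hb
from hoofbeats import pipeline
from hoofbeats.categories import (
    LEVELS,
    canter_phase_level_counts,
    fit_canter_phase_model,
    fit_onoff_count_model,
    onoff_level_counts,
)
from hoofbeats.errors import PairingError, ValidationError
from hoofbeats.rhythm import RatioSequence, compute_canter_phase_ratios, segment_canter_cycles


def test_onoff_level_counts_manual_tally(scheme):
    # one ratio per region: below-range, each off bin, each on bin
    r = np.array([0.25, 0.28, 0.35, 0.40, 0.50, 0.60, 0.67, 0.72])
    counts = onoff_level_counts([RatioSequence("a", "walk", r)], scheme)
    c = counts.set_index("level")["count"]
    assert c["1:2 on"] == 1 and c["1:1 on"] == 1 and c["2:1 on"] == 1
    # off levels pool the two flanking off bins
    assert c["1:2 off"] == 2  # 0.28 and 0.40
    assert c["1:1 off"] == 2  # 0.40 and 0.60
    assert c["2:1 off"] == 2  # 0.60 and 0.72
    w = counts.set_index("level")["width"]
    assert np.isclose(w["1:1 off"], scheme["off[0.400]"].width + scheme["off[0.600]"].width)
    assert set(counts["level"]) == set(LEVELS)


def test_walk_trot_models_find_isochrony(small_population):
    results = pipeline.run_category_tests(small_population)
    for gait in ("walk", "trot"):
        res = results[gait]
        assert res.pvalue < 1e-6 and res.df == 5
        iso = next(c for c in res.contrasts if c.contrast == "11off - 11on")
        assert iso.estimate < 0  # more mass on-integer
        assert iso.p_adj < 0.001


def test_canter_phase_models_find_their_categories(small_population):
    results = pipeline.run_category_tests(small_population)
    for cat, name in [("1:1", "11off - 11on"), ("1:2", "12off - 12on"), ("2:1", "21off - 21on")]:
        res = results[f"canter {cat}"]
        (c,) = res.contrasts
        assert c.contrast == name
        assert c.estimate < 0 and c.p_adj < 0.001
        assert res.dispersion is not None  # overdispersion screen for Poisson


def test_estimates_invariant_to_row_order_and_relabeling(small_population):
    by_gait = pipeline.intervals_by_gait(small_population)
    seqs = [hb.compute_ratios(s) for s in by_gait["walk"]]
    counts = onoff_level_counts(seqs, hb.build_bin_scheme())
    shuffled = counts.sample(frac=1.0, random_state=0).reset_index(drop=True)
    shuffled["individual_id"] = "x" + shuffled["individual_id"]
    a = fit_onoff_count_model(counts, gait="walk")
    b = fit_onoff_count_model(shuffled, gait="walk")
    assert np.isclose(a.chisq, b.chisq, rtol=1e-3)
    for ca, cb in zip(a.contrasts, b.contrasts):
        # tolerance reflects optimizer path noise, scaled to the contrast SE
        assert abs(ca.estimate - cb.estimate) < 0.02 * max(ca.se, 0.1)


def test_all_mass_in_one_bin_returns_finite_estimates(scheme):
    rows = []
    for ind in ("a", "b", "c"):
        for lvl in LEVELS:
            rows.append(
                {"individual_id": ind, "level": lvl,
                 "category": lvl.split()[0], "kind": lvl.split()[1],
                 "count": 50 if lvl == "1:1 on" else 0,
                 "width": 0.1}
            )
    res = fit_onoff_count_model(pd.DataFrame(rows), gait="trot")
    assert np.all(np.isfinite([c.estimate for c in res.contrasts]))
    assert res.chisq >= 0


def test_zero_jitter_canter_contrast_estimable(zero_jitter_specs):
    canter_spec = next(s for s in zero_jitter_specs if s.gait == "canter")
    recs = [
        hb.simulate_recording(canter_spec, seed=i, individual_id=f"h{i}")
        for i in range(3)
    ]
    phase_seqs = pipeline.canter_phase_ratio_sequences(
        [hb.compute_intervals(r) for r in recs]
    )
    counts = canter_phase_level_counts(phase_seqs, hb.build_bin_scheme(), "1:1")
    assert counts.loc[counts["kind"] == "off", "count"].sum() == 0
    res = fit_canter_phase_model(counts, "1:1")
    (c,) = res.contrasts
    assert np.isfinite(c.estimate) and c.estimate < 0  # on >> off


def test_shuffled_phase_labels_destroy_phase_alignment(small_population):
    """With correct labels each category's on-bin mass concentrates in its
    aligned motion-cycle phase; a seeded shuffle flattens that alignment."""
    by_gait = pipeline.intervals_by_gait(small_population)
    phase_seqs = pipeline.canter_phase_ratio_sequences(by_gait["canter"])
    scheme = hb.build_bin_scheme()

    def on_share(seqs, cat, phase):
        counts = canter_phase_level_counts(seqs, scheme, cat)
        on = counts[counts["kind"] == "on"].groupby("phase")["count"].sum()
        return on[phase] / max(on.sum(), 1)

    aligned = {"1:1": "rk1", "1:2": "rk2", "2:1": "rk3"}
    for cat, ph in aligned.items():
        assert on_share(phase_seqs, cat, ph) > 0.9

    rng = np.random.default_rng(0)
    shuffled = [
        RatioSequence(s.individual_id, s.gait, s.r, rng.permutation(s.phase))
        for s in phase_seqs
    ]
    for cat, ph in aligned.items():
        assert on_share(shuffled, cat, ph) < 0.6


def test_paired_t_examples():
    from hoofbeats.rhythm import IntervalSequence

    walk = [IntervalSequence(f"h{i}", "walk", np.full(10, 0.3)) for i in range(5)]
    trot = [IntervalSequence(f"h{i}", "trot", np.full(10, 0.3)) for i in range(5)]
    cmp_ = hb.compare_median_intervals(walk, trot)
    assert cmp_.t == 0.0 and cmp_.df == 4


def test_paired_t_direction_on_defaults(small_population):
    cmp_ = pipeline.run_duration_comparison(small_population)
    assert cmp_.t < 0  # trot intervals are longer than walk
    assert cmp_.pvalue < 0.001
    assert cmp_.df == 5  # 6 individuals
    assert all(np.isfinite(cmp_.shapiro_a)) and all(np.isfinite(cmp_.shapiro_b))


def test_df_is_n_minus_one_at_study_size():
    pop = hb.PopulationSpec(n_individuals=19, individual_tempo_sd=0.06, seed=31)
    recs = hb.simulate_population(pop, hb.default_specs(20.0))
    cmp_ = pipeline.run_duration_comparison(recs)
    assert cmp_.df == 18


def test_unpaired_individual_named():
    from hoofbeats.rhythm import IntervalSequence

    walk = [IntervalSequence("h1", "walk", np.full(10, 0.3))]
    trot = [
        IntervalSequence("h1", "trot", np.full(10, 0.36)),
        IntervalSequence("h2", "trot", np.full(10, 0.36)),
    ]
    with pytest.raises(PairingError, match="h2"):
        hb.compare_median_intervals(walk, trot)


def test_missing_factor_level_rejected():
    rows = [
        {"individual_id": "a", "level": "1:1 on", "category": "1:1",
         "kind": "on", "count": 5, "width": 0.1}
    ]
    with pytest.raises(ValidationError, match="missing factor level"):
        fit_onoff_count_model(pd.DataFrame(rows))
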