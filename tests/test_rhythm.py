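"""Intervals, ratios, bin scheme, canter cycles, triplets, density peaks."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hoofbeats as hb
from hoofbeats.errors import InsufficientDataError, SegmentationError
from hoofbeats.rhythm import (
    CanterCycle,
    IntervalSequence,
    RatioSequence,
    compute_canter_phase_ratios,
    segment_canter_cycles,
)

# ------------------------------------------------------------ intervals


def test_intervals_simple():
    rec = hb.FootfallRecording("a", "walk", np.array([0, 0.3, 0.6]))
    assert np.allclose(hb.compute_intervals(rec).t, [0.3, 0.3])


def test_intervals_canter_peak_values():
    rec = hb.FootfallRecording("a", "canter", np.array([0, 0.148, 0.296, 0.563]))
    assert np.allclose(hb.compute_intervals(rec).t, [0.148, 0.148, 0.267])


def test_intervals_match_bruteforce_oracle(rng):
    onsets = np.sort(rng.uniform(0, 60, 200))
    onsets = onsets[np.concatenate([[True], np.diff(onsets) > 0])]
    rec = hb.FootfallRecording("a", "walk", onsets)
    expected = [onsets[i + 1] - onsets[i] for i in range(len(onsets) - 1)]
    assert np.allclose(hb.compute_intervals(rec).t, expected)


def test_intervals_need_two_onsets():
    with pytest.raises(InsufficientDataError):
        hb.compute_intervals(hb.FootfallRecording("a", "walk", np.array([1.0])))


# ------------------------------------------------------------ ratios


def test_ratios_examples():
    seq = IntervalSequence("a", "walk", np.array([1.0, 1.0]))
    assert np.allclose(hb.compute_ratios(seq).r, [0.5])
    seq = IntervalSequence("a", "walk", np.array([1.0, 2.0, 1.0]))
    assert np.allclose(hb.compute_ratios(seq).r, [1 / 3, 2 / 3])


def test_ratios_match_bruteforce_oracle(rng):
    t = rng.uniform(0.05, 1.0, 50)
    seq = IntervalSequence("a", "walk", t)
    expected = [t[i] / (t[i] + t[i + 1]) for i in range(len(t) - 1)]
    r = hb.compute_ratios(seq).r
    assert len(r) == len(t) - 1
    assert np.allclose(r, expected)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    st.lists(st.floats(min_value=0.01, max_value=10.0, allow_nan=False), min_size=2, max_size=40)
)
def test_ratio_mirror_symmetry(t):
    """Reversing the interval sequence maps each ratio r to 1 - r."""
    t = np.asarray(t)
    fwd = hb.compute_ratios(IntervalSequence("a", "walk", t)).r
    rev = hb.compute_ratios(IntervalSequence("a", "walk", t[::-1])).r
    assert np.allclose(np.sort(fwd), np.sort(1 - rev), atol=1e-12)


# ------------------------------------------------------------ bin scheme


def test_bin_scheme_printed_boundaries(scheme):
    on12 = scheme["1:2 on"]
    on11 = scheme["1:1 on"]
    on21 = scheme["2:1 on"]
    assert round(on12.lower, 3) == 0.308
    assert round(on12.upper, 3) == 0.364
    assert round(on11.lower, 3) == 0.444
    assert round(scheme["off[0.400]"].center, 3) == 0.400
    assert round(scheme["off[0.600]"].center, 3) == 0.600
    assert np.isclose(on12.lower, 1 / 3.25)
    assert np.isclose(on11.upper, 1 - 1 / 2.25)
    assert np.isclose(on21.lower, 1 - 1 / 2.75)
    assert np.isclose(scheme.lower, 1 / 3.75)
    assert np.isclose(scheme.upper, 1 - 1 / 3.75)


def test_bin_scheme_isochrony_bin_symmetric(scheme):
    b = scheme["1:1 on"]
    assert np.isclose(b.lower + b.upper, 1.0)
    assert np.isclose(b.center, 0.5)


def test_bin_scheme_tiles_without_gaps(scheme):
    for a, b in zip(scheme.bins[:-1], scheme.bins[1:]):
        assert np.isclose(a.upper, b.lower)
    kinds = [b.kind for b in scheme.bins]
    assert kinds == ["off", "on", "off", "on", "off", "on", "off"]
    assert all(b.width > 0 for b in scheme.bins)


@pytest.mark.parametrize(
    "r,label",
    [(0.5, "1:1 on"), (0.35, "1:2 on"), (0.25, "outside"),
     (1 / 3.25, "1:2 on"), (0.60, "off[0.600]"), (0.75, "outside")],
)
def test_classify_ratio(scheme, r, label):
    assert hb.classify_ratio(r, scheme) == label


def test_count_by_bin_matches_bruteforce(scheme, rng):
    r = rng.uniform(0.01, 0.99, 500)
    seq = RatioSequence("a", "walk", r)
    counts = hb.count_by_bin(seq, scheme).set_index("bin")["count"]
    for b in scheme.bins:
        manual = sum(1 for x in r if b.contains(x))
        assert counts[b.label] == manual
    in_range = sum(1 for x in r if scheme.lower <= x <= scheme.upper)
    assert counts.sum() == in_range


def test_count_by_bin_uniform_sample_proportional_to_width(scheme):
    rng = np.random.default_rng(7)
    r = rng.uniform(0.001, 0.999, 100_000)
    counts = hb.count_by_bin(RatioSequence("a", "walk", r), scheme)
    n = len(r)
    for _, row in counts.iterrows():
        p = row["width"] / 0.998  # uniform support width
        se = np.sqrt(p * (1 - p) / n)
        assert abs(row["count"] / n - p) < 3 * se


def test_zero_jitter_ratios_all_on_integer(scheme, zero_jitter_specs):
    pop = hb.PopulationSpec(n_individuals=2, individual_tempo_sd=0.0, seed=4)
    recs = hb.simulate_population(pop, zero_jitter_specs)
    for rec in recs:
        seq = hb.compute_intervals(rec)
        if rec.gait in ("walk", "trot"):
            r = hb.compute_ratios(seq)
            assert all(hb.classify_ratio(x, scheme) == "1:1 on" for x in r.r)
        else:
            phases = compute_canter_phase_ratios(segment_canter_cycles(seq))
            want = {"rk1": "1:1 on", "rk2": "1:2 on", "rk3": "2:1 on"}
            for x, ph in zip(phases.r, phases.phase):
                assert hb.classify_ratio(x, scheme) == want[ph]


# ------------------------------------------------------------ canter cycles


def test_segmentation_exact_pattern():
    t = np.tile([0.148, 0.148, 0.267], 10)
    cycles = segment_canter_cycles(IntervalSequence("a", "canter", t))
    assert len(cycles) == 10
    for c in cycles:
        assert (c.t1, c.t2, c.t3) == (0.148, 0.148, 0.267)


def test_segmentation_mid_cycle_start():
    t = np.array([0.267, 0.148, 0.148, 0.267])
    cycles = segment_canter_cycles(IntervalSequence("a", "canter", t))
    assert len(cycles) == 1
    assert cycles[0] == CanterCycle(0.148, 0.148, 0.267, start=1)


def test_segmentation_jittered_with_ground_truth():
    spec = replace(hb.CANTER, duration_s=60.0)
    rec = hb.simulate_recording(spec, seed=13)
    seq = hb.compute_intervals(rec)
    cycles = segment_canter_cycles(seq)
    assert len(cycles) <= len(seq) // 3
    assert len(cycles) >= len(seq) // 3 - 5  # few fragments dropped
    for c in cycles:
        assert c.t3 > max(c.t1, c.t2)


def test_segmentation_fails_on_unimodal():
    rng = np.random.default_rng(0)
    t = 0.3 * np.exp(rng.normal(0, 0.03, 100))
    with pytest.raises(SegmentationError):
        segment_canter_cycles(IntervalSequence("a", "canter", t))


def test_phase_ratios_small_integers():
    cycles = [CanterCycle(1, 1, 2, 0), CanterCycle(1, 1, 2, 3)]
    rs = compute_canter_phase_ratios(cycles)
    by_phase = {ph: rs.r[rs.phase == ph] for ph in ("rk1", "rk2", "rk3")}
    assert np.allclose(by_phase["rk1"], 0.5)
    assert np.allclose(by_phase["rk2"], 1 / 3)
    assert np.allclose(by_phase["rk3"], 2 / 3)  # t3 against next cycle's t1
    assert len(by_phase["rk3"]) == 1  # last cycle has no successor


def test_phase_ratios_single_cycle_boundary():
    rs = compute_canter_phase_ratios([CanterCycle(1, 1, 2, 0)])
    assert list(rs.phase) == ["rk1", "rk2"]


def test_phase_ratio_means_near_zero_noise_values():
    rec = hb.simulate_recording(replace(hb.CANTER, duration_s=60.0), seed=21)
    rs = compute_canter_phase_ratios(
        segment_canter_cycles(hb.compute_intervals(rec))
    )
    expect = {"rk1": 0.5, "rk2": 0.148 / 0.415, "rk3": 0.267 / 0.415}
    for ph, val in expect.items():
        assert abs(rs.r[rs.phase == ph].mean() - val) < 0.02


# ------------------------------------------------------------ triplets


def test_triplets_normalized_examples():
    seq = IntervalSequence("a", "walk", np.array([1.0, 1.0, 1.0]))
    tt = hb.make_triplets(seq, normalize=True)
    assert np.allclose(tt.values, [[100 / 3] * 3])
    seq = IntervalSequence("a", "canter", np.array([1.0, 1.0, 2.0]))
    tt = hb.make_triplets(seq, normalize=True)
    assert np.allclose(tt.values, [[25, 25, 50]])


def test_triplets_row_count_and_overlap(rng):
    t = rng.uniform(0.1, 0.5, 20)
    tt = hb.make_triplets(IntervalSequence("a", "walk", t))
    assert len(tt) == 18
    assert np.allclose(tt.values[3], t[3:6])  # stride-1 sliding window


def test_triplets_need_three_intervals():
    with pytest.raises(InsufficientDataError):
        hb.make_triplets(IntervalSequence("a", "walk", np.array([1.0, 1.0])))


# ------------------------------------------------------------ density peaks


def test_single_peak_for_tight_cluster(rng):
    r = np.clip(rng.normal(0.5, 0.01, 500), 0.4, 0.6)
    ps = hb.find_density_peaks(RatioSequence("a", "trot", r))
    assert len(ps) == 1
    assert abs(ps.positions[0] - 0.5) < 0.01


def test_canter_phase_peaks_near_small_integers():
    # exact 1:1:2 pattern so the zero-noise phase ratios sit at 1/3, 1/2, 2/3
    spec = hb.GaitSpec("canter", (0.15, 0.15, 0.30), jitter_cv=0.015, duration_s=60.0)
    rec = hb.simulate_recording(spec, seed=8)
    rs = compute_canter_phase_ratios(
        segment_canter_cycles(hb.compute_intervals(rec))
    )
    ps = hb.find_density_peaks(RatioSequence("a", "canter", rs.r))
    assert len(ps) == 3
    assert np.allclose(np.sort(ps.positions), [1 / 3, 0.5, 2 / 3], atol=0.02)


def test_bimodal_mixture_gives_two_peaks(rng):
    r = np.concatenate([rng.normal(0.4, 0.015, 400), rng.normal(0.6, 0.015, 400)])
    r = np.clip(r, 0.3, 0.7)
    ps = hb.find_density_peaks(RatioSequence("a", "canter", r))
    assert len(ps) == 2
    assert np.allclose(np.sort(ps.positions), [0.4, 0.6], atol=0.02)


def test_too_few_ratios_warns_and_returns_empty():
    with pytest.warns(UserWarning):
        ps = hb.find_density_peaks(RatioSequence("a", "walk", np.full(5, 0.5)))
    assert len(ps) == 0
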