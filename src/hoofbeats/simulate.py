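"""Synthetic footfall generator.

Emulates per-individual, per-gait onset sequences with the statistical
structure the downstream analysis assumes: a repeating motion-cycle pattern
(single interval for walk/trot; short-short-long for canter, where the long
interval spans the suspension phase), multiplicative log-normal timing
jitter parameterized by a coefficient of variation, a rare "irregular step"
mixture that fattens the tails the way occasional missteps do in real
riding-surface recordings, per-individual tempo multipliers, and onset
times quantized to 1 ms to mimic manual annotation granularity.

Default tempi come from the interval-distribution peaks of the three gaits
(walk 0.287 s, trot 0.360 s, canter 0.148/0.148/0.267 s); default jitter
CVs (trot 0.03 < canter 0.05 < walk 0.06) encode that the trot is the most
metronomic gait. They are tunable defaults, not measurements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import InvalidParameterError
from .recording import GAITS, FootfallRecording

__all__ = [
    "GaitSpec",
    "PopulationSpec",
    "WALK",
    "TROT",
    "CANTER",
    "default_specs",
    "simulate_recording",
    "simulate_population",
]

#: Annotation granularity, seconds (Praat-scale manual precision).
ONSET_RESOLUTION = 1e-3


@dataclass(frozen=True)
class GaitSpec:
    """One gait's repeating interval pattern and noise level.

    Parameters
    ----------
    gait
        One of ``walk``, ``trot``, ``canter``.
    base_intervals
        Seconds defining one motion cycle: a single value for walk/trot,
        (short, short, long) for canter.
    jitter_cv
        Coefficient of variation of the multiplicative log-normal timing
        noise applied independently to every interval.
    duration_s
        Total simulated duration in seconds (onsets past this are dropped).
    p_irregular, irregular_scale
        With probability ``p_irregular`` an interval's noise SD is inflated
        by ``irregular_scale``, modelling occasional irregular steps. Both
        are inert when ``jitter_cv`` is zero.
    """

    gait: str
    base_intervals: tuple[float, ...]
    jitter_cv: float
    duration_s: float = 60.0
    p_irregular: float = 0.02
    irregular_scale: float = 4.0

    def __post_init__(self):
        if self.gait not in GAITS:
            raise InvalidParameterError(f"unknown gait {self.gait!r}")
        pattern = tuple(float(x) for x in self.base_intervals)
        object.__setattr__(self, "base_intervals", pattern)
        expected = 3 if self.gait == "canter" else 1
        if len(pattern) != expected:
            raise InvalidParameterError(
                f"{self.gait} pattern must have {expected} interval(s), got {len(pattern)}"
            )
        if any(x <= 0 for x in pattern):
            raise InvalidParameterError("base_intervals must be positive")
        if self.jitter_cv < 0:
            raise InvalidParameterError("jitter_cv must be >= 0")
        if self.duration_s <= 0:
            raise InvalidParameterError("duration_s must be positive")
        if not (0 <= self.p_irregular < 1) or self.irregular_scale < 1:
            raise InvalidParameterError("invalid irregularity parameters")


WALK = GaitSpec("walk", (0.287,), jitter_cv=0.06)
TROT = GaitSpec("trot", (0.360,), jitter_cv=0.03)
CANTER = GaitSpec("canter", (0.148, 0.148, 0.267), jitter_cv=0.05)


def default_specs(duration_s: float = 60.0) -> tuple[GaitSpec, ...]:
    """The three study gaits at their default tempo/jitter settings."""
    return tuple(replace(s, duration_s=duration_s) for s in (WALK, TROT, CANTER))


@dataclass(frozen=True)
class PopulationSpec:
    """How many individuals to simulate and how their tempi differ.

    Each individual gets one log-normal tempo multiplier (median 1, SD of
    the log equal to ``individual_tempo_sd``) shared across its gaits:
    tempo is treated as an individual trait driven by morphology.
    """

    n_individuals: int = 19
    individual_tempo_sd: float = 0.06
    seed: int = 0

    def __post_init__(self):
        if self.n_individuals < 1:
            raise InvalidParameterError("n_individuals must be >= 1")
        if self.individual_tempo_sd < 0:
            raise InvalidParameterError("individual_tempo_sd must be >= 0")


def _lognormal_sigma(cv: float) -> float:
    # sigma of log X such that CV(X) = cv for X = exp(N(0, sigma^2))
    return math.sqrt(math.log1p(cv * cv))


def simulate_recording(
    spec: GaitSpec,
    tempo_multiplier: float = 1.0,
    seed: int = 0,
    individual_id: str = "sim",
) -> FootfallRecording:
    """Simulate one individual x gait onset sequence.

    Each realized interval is ``pattern[k mod m] * tempo_multiplier *
    exp(N(0, sigma))`` with sigma set so the interval CV equals
    ``jitter_cv``. Onsets start at 0, are rounded to 1 ms, and are
    truncated at ``duration_s``.
    """
    if tempo_multiplier <= 0:
        raise InvalidParameterError("tempo_multiplier must be positive")
    rng = np.random.default_rng(seed)
    pattern = np.asarray(spec.base_intervals)
    mean_iv = float(pattern.mean()) * tempo_multiplier
    n = int(spec.duration_s / mean_iv * 1.5) + len(pattern) + 8
    base = np.tile(pattern, n // len(pattern) + 1)[:n] * tempo_multiplier
    if spec.jitter_cv > 0:
        sigma = _lognormal_sigma(spec.jitter_cv)
        sig = np.full(n, sigma)
        if spec.p_irregular > 0:
            irregular = rng.random(n) < spec.p_irregular
            sig[irregular] *= spec.irregular_scale
        intervals = base * np.exp(rng.normal(0.0, 1.0, n) * sig)
    else:
        intervals = base
    # quantize each interval to the annotation resolution; onsets (their
    # cumulative sums) then live on the same 1 ms grid, and zero-noise
    # sequences stay exactly periodic under any tempo multiplier
    intervals = np.round(intervals / ONSET_RESOLUTION) * ONSET_RESOLUTION
    onsets = np.concatenate([[0.0], np.cumsum(intervals)])
    onsets = np.round(onsets, 9)
    onsets = onsets[onsets <= spec.duration_s + 1e-12]
    return FootfallRecording(individual_id=individual_id, gait=spec.gait, onsets=onsets)


def simulate_population(
    pop: PopulationSpec, specs: list[GaitSpec] | tuple[GaitSpec, ...]
) -> list[FootfallRecording]:
    """Simulate every individual x gait combination.

    One recording per (individual, spec); the tempo multiplier is drawn
    once per individual and shared across that individual's gaits. Output
    is bit-identical under a fixed ``pop.seed``.
    """
    if not specs:
        raise InvalidParameterError("specs must be nonempty")
    rng = np.random.default_rng(pop.seed)
    multipliers = np.exp(rng.normal(0.0, pop.individual_tempo_sd, pop.n_individuals))
    width = max(2, len(str(pop.n_individuals)))
    recordings = []
    for i, mult in enumerate(multipliers):
        ind = f"h{i + 1:0{width}d}"
        for spec in specs:
            child_seed = int(rng.integers(0, 2**31 - 1))
            recordings.append(
                simulate_recording(spec, float(mult), seed=child_seed, individual_id=ind)
            )
    return recordings
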