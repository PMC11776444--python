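"""Interval sequences, rhythmic ratios, and small-integer-ratio machinery.

Definitions. The inter-onset interval ``t_k`` is the time between two
successive footfalls. The rhythmic ratio of two adjacent intervals is

    r_k = t_k / (t_k + t_{k+1}),

a value in (0, 1): 1/2 denotes isochrony (1:1), 1/3 a short-long (1:2)
pair, 2/3 a long-short (2:1) pair. Ratios are classified into on-integer
acceptance bins centered on those small-integer values, flanked by
off-integer control bins; category structure is present when on-bins hold
more ratios than off-bins after weighting by bin width.

The canter motion cycle is three footfalls plus a suspension phase; its
three phase ratios are r_k1 = t1/(t1+t2), r_k2 = t2/(t2+t3), and
r_k3 = t3/(t3+t1') with t1' taken from the next cycle.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal, stats

from .errors import InsufficientDataError, SegmentationError, ValidationError
from .recording import FootfallRecording

__all__ = [
    "IntervalSequence",
    "RatioSequence",
    "RatioBin",
    "RatioBinScheme",
    "CanterCycle",
    "TripletTable",
    "PeakSet",
    "compute_intervals",
    "compute_ratios",
    "segment_canter_cycles",
    "compute_canter_phase_ratios",
    "build_bin_scheme",
    "classify_ratio",
    "count_by_bin",
    "make_triplets",
    "find_density_peaks",
]

logger = logging.getLogger(__name__)

CATEGORIES = ("1:2", "1:1", "2:1")
PHASES = ("rk1", "rk2", "rk3")


@dataclass
class IntervalSequence:
    """Ordered inter-onset intervals t_k for one individual x gait."""

    individual_id: str
    gait: str
    t: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        if t.ndim != 1:
            raise ValidationError("t must be 1-D")
        if t.size and np.any(t <= 0):
            raise ValidationError("all intervals must be positive")
        self.t = t

    def __len__(self) -> int:
        return int(self.t.size)


@dataclass
class RatioSequence:
    """Rhythmic ratios r_k in (0,1); canter carries per-ratio phase labels."""

    individual_id: str
    gait: str
    r: np.ndarray
    phase: np.ndarray | None = None  # entries from PHASES, canter only

    def __post_init__(self):
        r = np.asarray(self.r, dtype=float)
        if r.size and (np.any(r <= 0) or np.any(r >= 1)):
            raise ValidationError("ratios must lie strictly inside (0, 1)")
        self.r = r
        if self.phase is not None:
            phase = np.asarray(self.phase, dtype=object)
            if phase.shape != r.shape:
                raise ValidationError("phase labels must align with ratios")
            unknown = set(phase) - set(PHASES)
            if unknown:
                raise ValidationError(f"unknown phase label(s) {unknown}")
            self.phase = phase

    def __len__(self) -> int:
        return int(self.r.size)


def compute_intervals(rec: FootfallRecording) -> IntervalSequence:
    """t_k = onset_{k+1} - onset_k."""
    if rec.n_onsets < 2:
        raise InsufficientDataError(
            f"{rec.individual_id}/{rec.gait}: need >=2 onsets, got {rec.n_onsets}"
        )
    return IntervalSequence(rec.individual_id, rec.gait, np.diff(rec.onsets))


def compute_ratios(seq: IntervalSequence) -> RatioSequence:
    """Sliding adjacent-pair ratios r_k = t_k / (t_k + t_{k+1})."""
    if len(seq) < 2:
        raise InsufficientDataError(
            f"{seq.individual_id}/{seq.gait}: need >=2 intervals, got {len(seq)}"
        )
    r = seq.t[:-1] / (seq.t[:-1] + seq.t[1:])
    return RatioSequence(seq.individual_id, seq.gait, r)


# --------------------------------------------------------------------------
# Canter motion cycles
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CanterCycle:
    """One short-short-long canter cycle; ``start`` indexes into t."""

    t1: float
    t2: float
    t3: float
    start: int


def _two_cluster_threshold(x: np.ndarray) -> float:
    """Optimal 1-D two-cluster split (minimal within-class SS), on input scale."""
    xs = np.sort(x)
    n = xs.size
    cs = np.cumsum(xs)
    cs2 = np.cumsum(xs**2)
    best_k, best_ss = None, np.inf
    for k in range(1, n):  # left cluster xs[:k], right xs[k:]
        ssl = cs2[k - 1] - cs[k - 1] ** 2 / k
        ssr = (cs2[-1] - cs2[k - 1]) - (cs[-1] - cs[k - 1]) ** 2 / (n - k)
        if ssl + ssr < best_ss:
            best_ss, best_k = ssl + ssr, k
    return float((xs[best_k - 1] + xs[best_k]) / 2)


def segment_canter_cycles(
    seq: IntervalSequence, min_separation: float = 1.3
) -> list[CanterCycle]:
    """Partition a canter interval sequence into short-short-long cycles.

    The suspension-spanning interval is identified by a two-cluster split of
    log t_k (the long cluster); cycles are the (short, short, long) runs
    ending at each long interval. Leading/trailing fragments and runs not
    matching short-short-long are dropped (logged). If the two clusters'
    geometric means are closer than ``min_separation``, no bimodal
    structure is detectable and a :class:`SegmentationError` is raised.
    """
    if seq.gait != "canter":
        raise ValidationError("cycle segmentation is defined for canter only")
    if len(seq) < 3:
        raise InsufficientDataError("need >=3 intervals to segment cycles")
    logt = np.log(seq.t)
    thr = _two_cluster_threshold(logt)
    is_long = logt > thr
    if is_long.all() or not is_long.any():
        raise SegmentationError(
            "no bimodal interval structure detectable",
            {"threshold": float(np.exp(thr)), "n": len(seq)},
        )
    sep = float(np.exp(logt[is_long].mean() - logt[~is_long].mean()))
    if sep < min_separation:
        raise SegmentationError(
            f"long/short interval separation {sep:.2f} below {min_separation}",
            {"separation": sep, "threshold": float(np.exp(thr)), "n": len(seq)},
        )
    cycles: list[CanterCycle] = []
    dropped = 0
    prev_long = -1
    for j in np.flatnonzero(is_long):
        run = j - prev_long - 1  # number of shorts since the previous long
        if run == 2:
            cycles.append(CanterCycle(seq.t[j - 2], seq.t[j - 1], seq.t[j], int(j - 2)))
        else:
            dropped += run + 1
        prev_long = j
    dropped += len(seq) - 1 - prev_long  # trailing shorts
    if dropped:
        logger.info(
            "%s/%s: dropped %d interval(s) not forming short-short-long cycles",
            seq.individual_id, seq.gait, dropped,
        )
    if not cycles:
        raise SegmentationError(
            "no complete short-short-long cycle found",
            {"separation": sep, "dropped": dropped, "n": len(seq)},
        )
    return cycles


def compute_canter_phase_ratios(
    cycles: Sequence[CanterCycle],
    individual_id: str = "",
    gait: str = "canter",
) -> RatioSequence:
    """Per-cycle phase ratios r_k1, r_k2, r_k3 with phase labels.

    r_k3 spans cycle boundaries (t3 against the next cycle's t1) and is
    only emitted when the next cycle is temporally contiguous; the last
    cycle therefore yields no r_k3.
    """
    if not cycles:
        raise InsufficientDataError("need >=1 cycle")
    r, phase = [], []
    for i, c in enumerate(cycles):
        r.append(c.t1 / (c.t1 + c.t2)); phase.append("rk1")
        r.append(c.t2 / (c.t2 + c.t3)); phase.append("rk2")
        if i + 1 < len(cycles) and cycles[i + 1].start == c.start + 3:
            nxt = cycles[i + 1]
            r.append(c.t3 / (c.t3 + nxt.t1)); phase.append("rk3")
    return RatioSequence(individual_id, gait, np.asarray(r), np.asarray(phase, dtype=object))


# --------------------------------------------------------------------------
# On-/off-integer bin scheme
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RatioBin:
    """One half-open ratio bin [lower, upper); the last off bin is closed."""

    label: str
    kind: str                  # "on" | "off"
    category: str | None       # for on bins: "1:2" | "1:1" | "2:1"
    center: float              # reference (on) or off-center value
    lower: float
    upper: float
    closed_upper: bool = False

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def contains(self, r: float) -> bool:
        if self.closed_upper:
            return self.lower <= r <= self.upper
        return self.lower <= r < self.upper


@dataclass(frozen=True)
class RatioBinScheme:
    """Disjoint on/off bins tiling [1/3.75, 1 - 1/3.75].

    Edges are reciprocals of denominators offset by 0.25 around each
    reference denominator; exact fractions are used throughout (printed
    decimals like 0.308 are display roundings only). Each on bin is
    flanked by off bins; ``off_flanks`` records which off bins flank each
    category (the shared middle off bins flank two categories).
    """

    bins: tuple[RatioBin, ...]
    reference: dict = field(default_factory=dict)   # category -> exact ratio
    off_flanks: dict = field(default_factory=dict)  # category -> (off label, off label)

    @property
    def lower(self) -> float:
        return self.bins[0].lower

    @property
    def upper(self) -> float:
        return self.bins[-1].upper

    @property
    def on_bins(self) -> tuple[RatioBin, ...]:
        return tuple(b for b in self.bins if b.kind == "on")

    @property
    def off_bins(self) -> tuple[RatioBin, ...]:
        return tuple(b for b in self.bins if b.kind == "off")

    def __getitem__(self, label: str) -> RatioBin:
        for b in self.bins:
            if b.label == label:
                return b
        raise KeyError(label)

    def to_dict(self) -> dict:
        """JSON-serializable dump for audit."""
        return {
            "bins": [
                {
                    "label": b.label, "kind": b.kind, "category": b.category,
                    "center": b.center, "lower": b.lower, "upper": b.upper,
                    "width": b.width, "closed_upper": b.closed_upper,
                }
                for b in self.bins
            ],
            "reference": dict(self.reference),
            "off_flanks": {k: list(v) for k, v in self.off_flanks.items()},
        }


def build_bin_scheme() -> RatioBinScheme:
    """The on-/off-integer ratio bin scheme.

    On bins: [1/3.25, 1/2.75) for 1:2; [1/2.25, 1-1/2.25) for 1:1 and the
    mirrored [1-1/2.75, 1-1/3.25) for 2:1. Off bins are centered at 1/3.5,
    1/2.5 and their mirror images, with edges at reciprocal denominators
    +-0.25 around each center (outermost edges 1/3.75 and 1-1/3.75).
    """
    f = Fraction
    inv = lambda d: f(4, int(d * 4))        # 1/d as an exact fraction
    mir = lambda x: 1 - x
    lo_off = RatioBin("off[0.286]", "off", None, float(inv(3.5)),
                      float(inv(3.75)), float(inv(3.25)))
    on_12 = RatioBin("1:2 on", "on", "1:2", float(f(1, 3)),
                     float(inv(3.25)), float(inv(2.75)))
    mid_lo = RatioBin("off[0.400]", "off", None, float(inv(2.5)),
                      float(inv(2.75)), float(inv(2.25)))
    on_11 = RatioBin("1:1 on", "on", "1:1", 0.5,
                     float(inv(2.25)), float(mir(inv(2.25))))
    mid_hi = RatioBin("off[0.600]", "off", None, float(mir(inv(2.5))),
                      float(mir(inv(2.25))), float(mir(inv(2.75))))
    on_21 = RatioBin("2:1 on", "on", "2:1", float(f(2, 3)),
                     float(mir(inv(2.75))), float(mir(inv(3.25))))
    hi_off = RatioBin("off[0.714]", "off", None, float(mir(inv(3.5))),
                      float(mir(inv(3.25))), float(mir(inv(3.75))), closed_upper=True)
    return RatioBinScheme(
        bins=(lo_off, on_12, mid_lo, on_11, mid_hi, on_21, hi_off),
        reference={"1:2": float(f(1, 3)), "1:1": 0.5, "2:1": float(f(2, 3))},
        off_flanks={
            "1:2": (lo_off.label, mid_lo.label),
            "1:1": (mid_lo.label, mid_hi.label),
            "2:1": (mid_hi.label, hi_off.label),
        },
    )


def classify_ratio(r: float, scheme: RatioBinScheme) -> str:
    """Bin label for r, or ``"outside"`` beyond the outermost off edges."""
    if not 0 < r < 1:
        raise ValidationError(f"ratio {r} outside (0, 1)")
    for b in scheme.bins:
        if b.contains(r):
            return b.label
    return "outside"


def count_by_bin(ratios: RatioSequence, scheme: RatioBinScheme) -> pd.DataFrame:
    """Per-bin counts for one ratio sequence, with bin widths.

    Returns one row per bin (individual_id, gait, bin, kind, category,
    count, width); counts sum to the number of in-range ratios. Ratios
    outside the outermost edges are excluded here but are retained by the
    density/peak utilities.
    """
    if len(ratios) == 0:
        raise ValidationError("empty ratio sequence")
    edges = [b.lower for b in scheme.bins] + [scheme.upper]
    idx = np.searchsorted(edges, ratios.r, side="right") - 1
    # the closed upper edge of the final off bin
    idx[ratios.r == scheme.upper] = len(scheme.bins) - 1
    rows = []
    for i, b in enumerate(scheme.bins):
        rows.append(
            {
                "individual_id": ratios.individual_id,
                "gait": ratios.gait,
                "bin": b.label,
                "kind": b.kind,
                "category": b.category,
                "count": int(np.sum((idx == i) & (ratios.r >= scheme.lower)
                                    & (ratios.r <= scheme.upper))),
                "width": b.width,
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Adjacent-interval triplets
# --------------------------------------------------------------------------

@dataclass
class TripletTable:
    """Sliding windows of three adjacent intervals (stride 1).

    ``values`` holds raw durations (t1, t2, t3) or, when normalized,
    proportions summing to 100 along each row.
    """

    values: np.ndarray           # (n, 3)
    individual_id: np.ndarray    # (n,)
    gait: np.ndarray             # (n,)
    normalized: bool = False

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValidationError("triplet values must be (n, 3)")
        if self.normalized and v.size and not np.allclose(v.sum(axis=1), 100, atol=1e-9):
            raise ValidationError("normalized triplet rows must sum to 100")
        self.values = v
        self.individual_id = np.asarray(self.individual_id)
        self.gait = np.asarray(self.gait)

    def __len__(self) -> int:
        return int(self.values.shape[0])

    def to_frame(self) -> pd.DataFrame:
        cols = ("p1", "p2", "p3") if self.normalized else ("t1", "t2", "t3")
        df = pd.DataFrame(self.values, columns=list(cols))
        df.insert(0, "individual_id", self.individual_id)
        df.insert(1, "gait", self.gait)
        return df

    @staticmethod
    def concat(tables: Sequence["TripletTable"]) -> "TripletTable":
        if not tables:
            raise ValidationError("nothing to concatenate")
        if len({t.normalized for t in tables}) != 1:
            raise ValidationError("cannot mix raw and normalized triplet tables")
        return TripletTable(
            np.vstack([t.values for t in tables]),
            np.concatenate([t.individual_id for t in tables]),
            np.concatenate([t.gait for t in tables]),
            normalized=tables[0].normalized,
        )


def make_triplets(seq: IntervalSequence, normalize: bool = False) -> TripletTable:
    """Overlapping (t_k, t_k+1, t_k+2) windows; n intervals -> n-2 rows."""
    if len(seq) < 3:
        raise InsufficientDataError(
            f"{seq.individual_id}/{seq.gait}: need >=3 intervals, got {len(seq)}"
        )
    v = np.lib.stride_tricks.sliding_window_view(seq.t, 3).astype(float)
    if normalize:
        v = 100.0 * v / v.sum(axis=1, keepdims=True)
    n = v.shape[0]
    return TripletTable(
        v.copy(),
        np.full(n, seq.individual_id, dtype=object),
        np.full(n, seq.gait, dtype=object),
        normalized=normalize,
    )


# --------------------------------------------------------------------------
# Per-individual ratio-density peaks
# --------------------------------------------------------------------------

@dataclass
class PeakSet:
    """Local maxima of one individual x gait ratio density."""

    individual_id: str
    gait: str
    positions: np.ndarray  # ratio units, sorted ascending
    heights: np.ndarray    # density units

    def __len__(self) -> int:
        return int(self.positions.size)


#: Fewest ratios for which a kernel density estimate is attempted.
MIN_RATIOS_FOR_DENSITY = 10
DENSITY_GRID_SIZE = 512


def find_density_peaks(
    ratios: RatioSequence,
    bw_method: str | float = "silverman",
    min_prominence: float = 0.05,
) -> PeakSet:
    """Strict local maxima of the Gaussian-kernel ratio density.

    The density (Silverman bandwidth by default) is evaluated on a 512-point
    grid over (0, 1); peaks need a prominence of ``min_prominence`` times
    the maximum density. Below 10 ratios an empty set is returned with a
    warning rather than an unstable estimate.
    """
    if len(ratios) < MIN_RATIOS_FOR_DENSITY:
        warnings.warn(
            f"{ratios.individual_id}/{ratios.gait}: only {len(ratios)} ratio(s); "
            "no density peaks estimated",
            stacklevel=2,
        )
        return PeakSet(ratios.individual_id, ratios.gait, np.array([]), np.array([]))
    if np.ptp(ratios.r) < 1e-12:  # degenerate: all ratios identical
        return PeakSet(
            ratios.individual_id, ratios.gait,
            np.array([float(ratios.r[0])]), np.array([np.inf]),
        )
    grid = np.linspace(0.0, 1.0, DENSITY_GRID_SIZE + 2)[1:-1]
    density = stats.gaussian_kde(ratios.r, bw_method=bw_method)(grid)
    peaks, _ = signal.find_peaks(density, prominence=min_prominence * density.max())
    return PeakSet(ratios.individual_id, ratios.gait, grid[peaks], density[peaks])
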