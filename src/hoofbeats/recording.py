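"""Core container for an annotated footfall sequence.

A :class:`FootfallRecording` holds the onset times (seconds) of successive
hoof strikes for one individual performing one gait, the atomic unit of the
whole analysis. Gait transitions are assumed to be excised upstream, so each
recording is a single-gait segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import ValidationError

#: Closed set of gait labels. walk: 4-beat; trot: 2-beat diagonal;
#: canter: 3-beat with a suspension phase.
GAITS = ("walk", "trot", "canter")


@dataclass
class FootfallRecording:
    individual_id: str
    gait: str
    onsets: np.ndarray
    metadata: Mapping | None = field(default=None)

    def __post_init__(self):
        if self.gait not in GAITS:
            raise ValidationError(
                f"unknown gait {self.gait!r}; expected one of {GAITS}"
            )
        onsets = np.asarray(self.onsets, dtype=float)
        if onsets.ndim != 1:
            raise ValidationError("onsets must be a 1-D sequence of seconds")
        if onsets.size and not np.all(np.isfinite(onsets)):
            raise ValidationError("onsets must be finite")
        if onsets.size and np.any(np.diff(onsets) <= 0):
            bad = onsets[1:][np.diff(onsets) <= 0]
            raise ValidationError(
                f"onsets must be strictly increasing; offending times: {bad[:5]}"
            )
        if onsets.size and onsets[0] < 0:
            raise ValidationError("onsets must be non-negative")
        self.onsets = onsets

    @property
    def n_onsets(self) -> int:
        return int(self.onsets.size)

    @property
    def duration(self) -> float:
        """Span from first to last onset, seconds."""
        if self.onsets.size < 2:
            return 0.0
        return float(self.onsets[-1] - self.onsets[0])

    def __len__(self) -> int:
        return self.n_onsets
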