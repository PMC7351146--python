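"""Amplitude rescaling and cubic-spline length standardization of segments.

Raw single-period segments differ in amplitude and in duration.  Before
classification each segment is (1) min-max rescaled so its values span
[0, 1] and (2) resampled with an interpolating cubic spline to a fixed
standard length L, so that the n-th standardized value ("feature point"
x_n, 1-based) is comparable across segments.  L = 15 is the published
operating length; L = 100 retains all clinically useful bandwidth and is
used for full-feature training sweeps.

Order of operations is rescale-then-resample; spline overshoot can push
interior values slightly outside [0, 1] and is deliberately not clipped,
since clipping would distort the peak-shape features the classifier uses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import (
    DegenerateInputError,
    DegenerateSegmentError,
    TooShortSegmentError,
    ValidationError,
)
from .segmentation import Segment

DEFAULT_STANDARD_LENGTH = 15
FULL_STANDARD_LENGTH = 100


@dataclass(frozen=True)
class SegmentSource:
    """Provenance of a standardized segment."""

    record_id: str
    start: int
    end: int
    alpha: Optional[float]


@dataclass
class StandardizedSegment:
    """A segment rescaled to [0,1] amplitude and resampled to L points."""

    values: np.ndarray
    standard_length: int
    source: SegmentSource

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != self.standard_length:
            raise ValidationError("values length must equal standard_length")

    def __len__(self) -> int:
        return len(self.values)

    def feature(self, index: int) -> float:
        """Feature point x_index (1-based, matching the x_1..x_L numbering)."""
        if not (1 <= index <= self.standard_length):
            raise ValidationError(f"feature index {index} outside [1, {self.standard_length}]")
        return float(self.values[index - 1])


def rescale(values: Sequence[float]) -> np.ndarray:
    """Min-max rescale so min -> 0 and max -> 1."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise DegenerateInputError("need at least 2 samples to rescale")
    lo = x.min()
    hi = x.max()
    if hi == lo:
        raise DegenerateSegmentError("constant segment has zero amplitude")
    return (x - lo) / (hi - lo)


def resample(values: Sequence[float], length: int, bc_type: str = "not-a-knot") -> np.ndarray:
    """Cubic-spline resample to ``length`` equally spaced points.

    The spline interpolates (i, values[i]) for i = 0..n-1 and is evaluated on
    the closed interval [0, n-1], so both endpoints are reproduced exactly.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 4:
        raise TooShortSegmentError("cubic-spline resampling needs at least 4 samples")
    if length < 2:
        raise ValidationError("standard length must be at least 2")
    spline = CubicSpline(np.arange(n), x, bc_type=bc_type)
    out = np.asarray(spline(np.linspace(0.0, n - 1.0, length)), dtype=float)
    # the spline passes through its knots; pin endpoints to avoid fp jitter
    out[0] = x[0]
    out[-1] = x[-1]
    return out


def standardize(
    segment: Segment,
    standard_length: int = DEFAULT_STANDARD_LENGTH,
    bc_type: str = "not-a-knot",
) -> StandardizedSegment:
    """Rescale then resample one segment, preserving provenance."""
    values = resample(rescale(segment.values), standard_length, bc_type=bc_type)
    return StandardizedSegment(
        values=values,
        standard_length=standard_length,
        source=SegmentSource(
            record_id=segment.record_id,
            start=segment.start,
            end=segment.end,
            alpha=segment.alpha,
        ),
    )
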