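"""Single-period segmentation of pulse-wave records by derivative thresholding.

The pulse onset (foot of the systolic upstroke) is a local minimum of the
pressure signal, but slow baseline wander makes amplitude thresholds on the
raw signal unreliable.  The first derivative is essentially wander-free, so
segmentation points are found there: for a threshold ``M * alpha`` (M = the
record's maximum derivative), each upward threshold crossing is traced
backward to the first non-positive derivative sample, and the original-signal
sample just after it is the period segmentation point.  Segments are the
spans of the raw signal between adjacent segmentation points, inclusive of
both boundary minima.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np

from .errors import DegenerateInputError, NoPulseError, ValidationError
from .io import PulseRecord

DEFAULT_ALPHAS = (0.1, 0.3, 0.5, 0.7, 0.9)


@dataclass(frozen=True)
class DerivativeSignal:
    """First derivative of a pulse record (units: pressure per second)."""

    values: np.ndarray
    max_value: float

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.values)


@dataclass
class SegmentationConfig:
    """Thresholds and sampling caps for segment extraction.

    Defaults follow the published protocol: five thresholds at
    alpha = 0.1, 0.3, 0.5, 0.7, 0.9, at most 5 randomly chosen segments
    per threshold, and at most 25 segments per record.
    """

    alphas: Sequence[float] = DEFAULT_ALPHAS
    per_threshold_cap: int = 5
    per_record_cap: int = 25
    rng_seed: int = 0
    keep_duplicates: bool = False

    def __post_init__(self) -> None:
        if len(self.alphas) == 0:
            raise ValidationError("alphas must be non-empty")
        for a in self.alphas:
            if not (0.0 < a < 1.0):
                raise ValidationError(f"alpha must lie strictly in (0,1), got {a}")
        if self.per_threshold_cap < 1:
            raise ValidationError("per_threshold_cap must be positive")
        if self.per_record_cap < self.per_threshold_cap:
            raise ValidationError("per_record_cap must be >= per_threshold_cap")


@dataclass
class Segment:
    """One candidate single-period slice of a record.

    ``start``/``end`` are 0-based inclusive sample indices into the parent
    record; ``values`` is a verbatim copy of the raw samples over that span.
    ``alpha`` records which threshold produced the segment (None for
    synthetic segments that were never produced by thresholding).
    """

    record_id: str
    start: int
    end: int
    alpha: Optional[float]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.end <= self.start:
            raise ValidationError("segment end must exceed start")
        if len(self.values) != self.end - self.start + 1:
            raise ValidationError("segment values length must equal end - start + 1")

    def __len__(self) -> int:
        return len(self.values)


def differentiate(record: PulseRecord) -> DerivativeSignal:
    """Forward first difference scaled by the sampling rate."""
    samples = np.asarray(record.samples, dtype=float)
    if samples.size < 2:
        raise DegenerateInputError("record must contain at least 2 samples")
    values = np.diff(samples) * record.sampling_rate_hz
    return DerivativeSignal(values=values, max_value=float(values.max()))


def compute_threshold(deriv: DerivativeSignal, alpha: float) -> float:
    """Threshold = M * alpha, with M the maximum derivative value."""
    if not (0.0 < alpha < 1.0):
        raise ValidationError(f"alpha must lie strictly in (0,1), got {alpha}")
    if deriv.max_value <= 0:
        raise NoPulseError(
            "derivative maximum is non-positive: no systolic upstroke to threshold"
        )
    return deriv.max_value * alpha


def find_threshold_crossings(deriv: DerivativeSignal, threshold: float) -> np.ndarray:
    """Indices i with deriv[i-1] < threshold <= deriv[i] (upward crossings).

    If the record opens mid-upstroke (deriv[0] already at or above the
    threshold), index 0 counts as a crossing clipped at the boundary, so the
    first cycle is not lost.
    """
    if threshold <= 0:
        raise ValidationError("threshold must be positive")
    v = deriv.values
    crossings = np.flatnonzero((v[:-1] < threshold) & (v[1:] >= threshold)) + 1
    if v[0] >= threshold:
        crossings = np.concatenate(([0], crossings))
    return crossings


def locate_onset(deriv: DerivativeSignal, crossing: int) -> int:
    """Period segmentation point for one threshold crossing.

    Scans backward from the crossing for the last derivative sample <= 0 and
    returns the index (into the original record) of the sample that follows
    it -- the local minimum at the foot of the upstroke.  Returns 0 when the
    derivative is positive all the way back to the record start.
    """
    v = deriv.values
    if not (0 <= crossing < v.size):
        raise ValidationError("crossing index out of range")
    nonpos = np.flatnonzero(v[:crossing] <= 0)
    if nonpos.size == 0:
        return 0
    return int(nonpos[-1]) + 1


def segment_record(record: PulseRecord, alpha: float) -> List[Segment]:
    """All segments of ``record`` at threshold M * alpha.

    Onsets from distinct crossings that trace back to the same zero point are
    deduplicated; fewer than two distinct onsets yield an empty list.
    """
    deriv = differentiate(record)
    threshold = compute_threshold(deriv, alpha)
    crossings = find_threshold_crossings(deriv, threshold)
    onsets = sorted({locate_onset(deriv, int(c)) for c in crossings})
    samples = np.asarray(record.samples, dtype=float)
    segments = []
    for lo, hi in zip(onsets[:-1], onsets[1:]):
        segments.append(
            Segment(
                record_id=record.record_id,
                start=lo,
                end=hi,
                alpha=alpha,
                values=samples[lo : hi + 1].copy(),
            )
        )
    return segments


def sample_segments(
    per_alpha: Mapping[float, Sequence[Segment]], config: SegmentationConfig
) -> List[Segment]:
    """Random per-threshold subsampling and the per-record cap.

    For each alpha (in sorted order, for determinism) draws at most
    ``per_threshold_cap`` segments uniformly without replacement, keeping
    temporal order; concatenates across alphas; drops exact duplicates
    (same start and end) unless ``keep_duplicates``; truncates to
    ``per_record_cap``.
    """
    rng = np.random.default_rng(config.rng_seed)
    chosen: List[Segment] = []
    for alpha in sorted(per_alpha):
        segs = list(per_alpha[alpha])
        k = min(config.per_threshold_cap, len(segs))
        if k == 0:
            continue
        idx = rng.choice(len(segs), size=k, replace=False)
        chosen.extend(segs[i] for i in sorted(idx))
    if not config.keep_duplicates:
        seen = set()
        unique = []
        for seg in chosen:
            key = (seg.start, seg.end)
            if key not in seen:
                seen.add(key)
                unique.append(seg)
        chosen = unique
    return chosen[: config.per_record_cap]


def run_segmentation(record: PulseRecord, config: SegmentationConfig) -> List[Segment]:
    """Segment at every configured threshold, then subsample and cap."""
    per_alpha: Dict[float, List[Segment]] = {
        alpha: segment_record(record, alpha) for alpha in config.alphas
    }
    return sample_segments(per_alpha, config)
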