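"""Seeded synthetic pulse records and labeled segment corpora.

The clinical corpus behind the published classifier is not deposited, so
this module generates quasi-periodic radial-pulse surrogates with the
structure the classifier assumes, plus ground truth for every quantity the
other modules estimate (cycle onsets, normal/abnormal labels, anomaly
kinds).

A normal cycle on [0, 1) of the period is piecewise:

* systolic rise: raised cosine from ~0 up to the peak at ``systolic_peak_position``;
* systolic fall: raised cosine from the peak down to a diastolic shoulder
  (``shoulder_level``) reached at ``systolic_end``;
* diastolic runoff: linear decay from the shoulder to ``end_level`` at the
  cycle end, so the diastolic derivative stays strictly negative -- the
  property that makes derivative-threshold segmentation robust to slow
  baseline wander;
* an optional Gaussian dicrotic bump near mid-cycle.

Abnormal segments realize the two failure sources the quality model is
meant to catch -- segmentation error (truncated or merged cycles) and
interference (elevated endpoints, bursts, baseline jumps) -- each violating
at least one of the expert labeling criteria by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .errors import ValidationError
from .io import PulseRecord
from .segmentation import Segment
from .standardize import standardize
from .training import LabeledCorpus

ANOMALY_KINDS = (
    "truncated_cycle",
    "merged_cycles",
    "elevated_endpoint",
    "interference_burst",
    "baseline_jump",
)

DEFAULT_ANOMALY_MIX = {
    "truncated_cycle": 0.25,
    "merged_cycles": 0.25,
    "elevated_endpoint": 0.20,
    "interference_burst": 0.20,
    "baseline_jump": 0.10,
}


@dataclass
class SyntheticConfig:
    """Waveform morphology, interference levels, and anomaly mixture.

    Fractions are relative to the unit pulse amplitude (cycle peak minus
    onset) and to the period where noted.  Defaults describe a clean-ish
    clinical recording: ~100-sample periods with 5% beat-to-beat jitter,
    peak at 19% of the cycle, a modest dicrotic wave, slow baseline wander
    at 20% of the pulse amplitude, and 1% additive noise.
    """

    n_cycles: int = 10
    period_samples: int = 100
    period_jitter: float = 0.05
    systolic_peak_position: float = 0.19
    systolic_end: float = 0.45
    shoulder_level: float = 0.35
    end_level: float = 0.02
    dicrotic_amplitude: float = 0.12
    dicrotic_position: float = 0.62
    dicrotic_width: float = 0.08
    morph_jitter: float = 0.02
    baseline_wander_amplitude: float = 0.2
    baseline_wander_period: float = 1000.0
    noise_sd: float = 0.01
    noise_smoothing_sigma: float = 3.0
    anomaly_mix: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ANOMALY_MIX)
    )
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cycles < 1:
            raise ValidationError("n_cycles must be positive")
        if self.period_samples < 8:
            raise ValidationError("period_samples must be at least 8")
        if not (0.0 < self.systolic_peak_position < 0.5):
            raise ValidationError("systolic_peak_position must lie in (0, 0.5)")
        if not (self.systolic_peak_position < self.systolic_end < 1.0):
            raise ValidationError("systolic_end must lie between the peak and 1")
        total = 0.0
        for kind, p in self.anomaly_mix.items():
            if kind not in ANOMALY_KINDS:
                raise ValidationError(f"unknown anomaly kind {kind!r}")
            if not (0.0 <= p <= 1.0):
                raise ValidationError("anomaly probabilities must lie in [0,1]")
            total += p
        if total > 1.0 + 1e-12:
            raise ValidationError("anomaly probabilities must sum to at most 1")


@dataclass
class GroundTruth:
    """Exact cycle onsets and per-segment labels for a generated record."""

    onsets: np.ndarray
    segment_labels: List[str]
    anomaly_kinds: Optional[List[Optional[str]]] = None

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=int)
        if np.any(np.diff(self.onsets) <= 0):
            raise ValidationError("onsets must be strictly increasing")


def _measurement_noise(
    rng: np.random.Generator, n: int, config: SyntheticConfig
) -> np.ndarray:
    """Band-limited additive noise with the configured standard deviation.

    Pulse acquisition chains low-pass filter before sampling, so sample-level
    noise is correlated; Gaussian-smoothed white noise (rescaled to the
    target sd) models that.  ``noise_smoothing_sigma = 0`` gives white noise.
    """
    white = rng.normal(0.0, 1.0, size=n)
    if config.noise_smoothing_sigma > 0:
        white = gaussian_filter1d(white, config.noise_smoothing_sigma)
        sd = white.std()
        if sd > 0:
            white = white / sd
    return config.noise_sd * white


def _jitter(rng: np.random.Generator, value: float, frac: float) -> float:
    if frac <= 0:
        return value
    return value * (1.0 + rng.uniform(-frac, frac))


def gen_normal_cycle(
    config: SyntheticConfig,
    rng: np.random.Generator,
    period: Optional[int] = None,
) -> np.ndarray:
    """One noise-free normal cycle of unit amplitude.

    ``period`` overrides the jittered period draw (used when concatenating
    cycles whose lengths were decided by the caller).
    """
    if period is None:
        period = max(
            8, int(round(_jitter(rng, config.period_samples, config.period_jitter)))
        )
    p = _jitter(rng, config.systolic_peak_position, config.morph_jitter)
    d = config.systolic_end
    b = _jitter(rng, config.shoulder_level, config.morph_jitter)
    a_dic = config.dicrotic_amplitude * (
        1.0 + config.morph_jitter * rng.uniform(-1.0, 1.0)
    )
    t = np.arange(period) / period
    v = np.empty(period)
    rise = t < p
    fall = (t >= p) & (t < d)
    dias = t >= d
    v[rise] = 0.5 * (1.0 - np.cos(np.pi * t[rise] / p))
    v[fall] = b + (1.0 - b) * 0.5 * (1.0 + np.cos(np.pi * (t[fall] - p) / (d - p)))
    v[dias] = b + (config.end_level - b) * (t[dias] - d) / (1.0 - d)
    if a_dic > 0:
        v += a_dic * np.exp(
            -0.5 * ((t - config.dicrotic_position) / config.dicrotic_width) ** 2
        )
    return v


def gen_pulse_record(
    config: SyntheticConfig, record_id: str = "synthetic"
) -> Tuple[PulseRecord, GroundTruth]:
    """Concatenated jittered cycles + baseline wander + additive noise.

    Ground-truth onsets are the exact concatenation boundaries (the first
    sample of each cycle).
    """
    if config.n_cycles < 2:
        raise ValidationError("a record needs at least 2 cycles")
    rng = np.random.default_rng(config.rng_seed)
    cycles = []
    onsets = []
    pos = 0
    for _ in range(config.n_cycles):
        cycle = gen_normal_cycle(config, rng)
        onsets.append(pos)
        pos += len(cycle)
        cycles.append(cycle)
    samples = np.concatenate(cycles)
    n = samples.size
    if config.baseline_wander_amplitude > 0:
        phase = rng.uniform(0.0, 2.0 * np.pi)
        samples = samples + config.baseline_wander_amplitude * np.sin(
            2.0 * np.pi * np.arange(n) / config.baseline_wander_period + phase
        )
    if config.noise_sd > 0:
        samples = samples + _measurement_noise(rng, n, config)
    record = PulseRecord(
        record_id=record_id, samples=samples, sampling_rate_hz=float(config.period_samples)
    )
    truth = GroundTruth(
        onsets=np.asarray(onsets),
        segment_labels=["normal"] * (config.n_cycles - 1),
    )
    return record, truth


def _cosine_ramp(t: np.ndarray, start: float, width: float) -> np.ndarray:
    """Smooth 0 -> 1 ramp over [start, start + width]."""
    ramp = np.zeros_like(t)
    mask = t >= start
    ramp[mask] = 0.5 * (1.0 - np.cos(np.pi * np.minimum((t[mask] - start) / width, 1.0)))
    return ramp


def gen_abnormal_segment(
    kind: str, config: SyntheticConfig, rng: np.random.Generator
) -> Tuple[Segment, str]:
    """One abnormal segment of the requested kind, labeled "abnormal".

    Kinds and the labeling criterion each violates:

    * ``truncated_cycle``: a random sub-span covering 30-75% of one cycle,
      starting away from the onset (not one complete cardiac cycle);
    * ``merged_cycles``: 2-5 whole cycles as one segment (more than one
      cycle, premature first peak);
    * ``elevated_endpoint``: last 20% raised by 0.6-0.95 of the amplitude
      (violates the horizontal-baseline rule);
    * ``interference_burst``: localized transient of 1-2x the pulse
      amplitude (serious interference);
    * ``baseline_jump``: a +-0.6-1.2 step mid-segment (interference /
      baseline rule).
    """
    if kind == "truncated_cycle":
        cycle = gen_normal_cycle(config, rng)
        n = len(cycle)
        frac = rng.uniform(0.30, 0.75)
        span = max(4, int(round(frac * n)))
        # a truncation produced by a segmentation error is bounded by a
        # spurious derivative zero point; those exist only at or after the
        # systolic peak (pre-dicrotic notch, diastole), never on the upstroke
        start_lo = max(1, int(round(0.2 * n)))
        start = int(rng.integers(start_lo, n - span + 1))
        values = cycle[start : start + span].copy()
    elif kind == "merged_cycles":
        k = int(rng.integers(2, 6))
        values = np.concatenate([gen_normal_cycle(config, rng) for _ in range(k)])
    elif kind == "elevated_endpoint":
        values = gen_normal_cycle(config, rng)
        t = np.arange(len(values)) / len(values)
        h = rng.uniform(0.60, 0.95)
        # motion/contact artifacts shift the level abruptly: ramp up over
        # [0.8, 0.9] of the cycle, then hold the elevated plateau
        values = values + h * _cosine_ramp(t, 0.8, 0.1)
    elif kind == "interference_burst":
        values = gen_normal_cycle(config, rng)
        t = np.arange(len(values)) / len(values)
        amp = rng.uniform(1.0, 2.0)
        center = rng.uniform(0.3, 0.9)
        width = rng.uniform(0.02, 0.05)
        values = values + amp * np.exp(-0.5 * ((t - center) / width) ** 2)
    elif kind == "baseline_jump":
        values = gen_normal_cycle(config, rng)
        t = np.arange(len(values)) / len(values)
        pos = rng.uniform(0.2, 0.8)
        step = float(rng.choice([-1.0, 1.0])) * rng.uniform(0.6, 1.2)
        values = values + np.where(t >= pos, step, 0.0)
    else:
        raise ValidationError(f"unknown anomaly kind {kind!r}")
    if config.noise_sd > 0:
        values = values + _measurement_noise(rng, len(values), config)
    seg = Segment(
        record_id=f"synthetic-{kind}",
        start=0,
        end=len(values) - 1,
        alpha=None,
        values=values,
    )
    return seg, "abnormal"


def gen_normal_segment(
    config: SyntheticConfig, rng: np.random.Generator
) -> Tuple[Segment, str]:
    """One clean single-period segment, labeled "normal"."""
    values = gen_normal_cycle(config, rng)
    if config.noise_sd > 0:
        values = values + _measurement_noise(rng, len(values), config)
    seg = Segment(
        record_id="synthetic-normal",
        start=0,
        end=len(values) - 1,
        alpha=None,
        values=values,
    )
    return seg, "normal"


def gen_labeled_corpus(
    config: SyntheticConfig,
    n_segments: int,
    normal_fraction: float = 0.582,
    standard_length: int = 15,
) -> LabeledCorpus:
    """Seeded mixture corpus of standardized normal and abnormal segments.

    ``normal_fraction`` defaults to the 58.2% normal prevalence of the
    study's training corpus; labels are ground truth by construction.
    """
    if n_segments < 2:
        raise ValidationError("n_segments must be at least 2")
    if not (0.0 < normal_fraction < 1.0):
        raise ValidationError("normal_fraction must lie strictly in (0,1)")
    n_normal = int(round(n_segments * normal_fraction))
    n_abnormal = n_segments - n_normal
    if n_normal < 1 or n_abnormal < 1:
        raise ValidationError("corpus must contain both classes")
    rng = np.random.default_rng(config.rng_seed)
    kinds = list(config.anomaly_mix)
    probs = np.asarray([config.anomaly_mix[k] for k in kinds], dtype=float)
    if probs.sum() <= 0:
        raise ValidationError("anomaly_mix must have positive total probability")
    probs = probs / probs.sum()

    segments = []
    labels: List[str] = []
    anomaly_kinds: List[Optional[str]] = []
    for _ in range(n_normal):
        seg, label = gen_normal_segment(config, rng)
        segments.append(standardize(seg, standard_length))
        labels.append(label)
        anomaly_kinds.append(None)
    for _ in range(n_abnormal):
        kind = str(rng.choice(kinds, p=probs))
        seg, label = gen_abnormal_segment(kind, config, rng)
        segments.append(standardize(seg, standard_length))
        labels.append(label)
        anomaly_kinds.append(kind)
    order = rng.permutation(n_segments)
    return LabeledCorpus(
        segments=[segments[i] for i in order],
        labels=[labels[i] for i in order],
        anomaly_kinds=[anomaly_kinds[i] for i in order],
    )
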