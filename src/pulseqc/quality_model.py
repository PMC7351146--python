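"""The four-feature logistic signal-quality classifier.

The published classifier scores a standardized segment (L = 15) with

    P = sigmoid(-9.6919 x1 + 8.2570 x3 + 8.9216 x4 - 7.9818 x14 - 10.8732)

where x_n is the n-th feature point (1-based) and P is the probability that
the segment is a normal single-period pulse wave.  The sign pattern encodes
the physiology: a normal radial pulse rises rapidly from a near-zero onset
(x1 small), peaks near the third feature point (x3 close to 1, x4 still
large on the slow systolic decay), and returns to a low, steady diastolic
level before the next onset (x14 small).  Segments with P >= 0.5 are
labeled normal.

Of the manual labeling criteria, only the horizontal-baseline rule
(|start - end| no more than half the amplitude) is machine-checkable on an
isolated segment; it is exposed here as :func:`check_baseline_rule`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Optional, Sequence, Union

import numpy as np
from scipy.special import expit

from .errors import DegenerateSegmentError, ValidationError
from .segmentation import Segment
from .standardize import SegmentSource, StandardizedSegment

NORMAL = "normal"
ABNORMAL = "abnormal"


@dataclass
class QualityModelSpec:
    """Intercept + sparse per-feature weights + decision threshold."""

    standard_length: int
    intercept: float
    weights: Dict[int, float]
    decision_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.standard_length < 1:
            raise ValidationError("standard_length must be positive")
        for idx in self.weights:
            if not (1 <= idx <= self.standard_length):
                raise ValidationError(
                    f"feature index {idx} outside [1, {self.standard_length}]"
                )
        if not (0.0 < self.decision_threshold < 1.0):
            raise ValidationError("decision_threshold must lie strictly in (0,1)")

    @property
    def feature_indices(self) -> tuple:
        return tuple(sorted(self.weights))


@dataclass
class FeatureVector:
    """Feature-point values keyed by 1-based index."""

    values: Dict[int, float]


@dataclass
class QualityReport:
    """Classification outcome for one standardized segment."""

    probability: float
    label: str
    features: FeatureVector
    source: Optional[SegmentSource] = None


def reference_model() -> QualityModelSpec:
    """The published four-feature classifier (immutable reference)."""
    text = resources.files("pulseqc").joinpath("data/reference_model.json").read_text()
    obj = json.loads(text)
    return QualityModelSpec(
        standard_length=int(obj["standard_length"]),
        intercept=float(obj["intercept"]),
        weights={int(k): float(v) for k, v in obj["weights"].items()},
        decision_threshold=float(obj["decision_threshold"]),
    )


def extract_features(
    seg: StandardizedSegment, indices: Sequence[int]
) -> FeatureVector:
    """Pick feature points x_k (1-based) from a standardized segment."""
    values = {}
    for k in indices:
        if not (1 <= k <= seg.standard_length):
            raise ValidationError(
                f"feature index {k} outside [1, {seg.standard_length}]"
            )
        values[int(k)] = float(seg.values[k - 1])
    return FeatureVector(values=values)


def predict_probability(model: QualityModelSpec, fv: FeatureVector) -> float:
    """P(normal) under the logistic model."""
    z = model.intercept
    for k, w in model.weights.items():
        if k not in fv.values:
            raise ValidationError(f"feature vector is missing index {k}")
        z += w * fv.values[k]
    return float(expit(z))


def classify(model: QualityModelSpec, seg: StandardizedSegment) -> QualityReport:
    """Score one standardized segment; ties at the threshold are normal."""
    if seg.standard_length != model.standard_length:
        raise ValidationError(
            f"segment length {seg.standard_length} != model length "
            f"{model.standard_length}"
        )
    fv = extract_features(seg, model.feature_indices)
    p = predict_probability(model, fv)
    label = NORMAL if p >= model.decision_threshold else ABNORMAL
    return QualityReport(probability=p, label=label, features=fv, source=seg.source)


def check_baseline_rule(seg: Union[Segment, Sequence[float]]) -> bool:
    """Horizontal-baseline labeling rule on a raw segment.

    True when the start-to-end level difference is no more than half the
    segment amplitude (boundary inclusive).
    """
    values = np.asarray(seg.values if isinstance(seg, Segment) else seg, dtype=float)
    amplitude = values.max() - values.min()
    if amplitude == 0:
        raise DegenerateSegmentError("constant segment has zero amplitude")
    return bool(abs(values[0] - values[-1]) <= 0.5 * amplitude)
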