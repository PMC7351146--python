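"""Reading and writing pulse records, segment corpora, and model specs.

Stable text formats only:

* pulse record -- plain text, one value per line, or a two-column ``t,value``
  CSV with a header; the sampling rate is always supplied out-of-band.
* segment corpus -- JSON Lines, one segment per line, fields ``record_id``,
  ``start``, ``end``, ``alpha``, ``values`` and optionally ``label``
  (standardized corpora additionally carry ``standard_length``).
* model spec -- JSON with ``standard_length``, ``intercept``, ``weights``
  (1-based feature index, stored as string keys, to real weight) and
  ``decision_threshold``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .errors import (
    DegenerateInputError,
    FormatError,
    ParseError,
    SchemaError,
    ValidationError,
)


@dataclass
class PulseRecord:
    """A raw single-channel pulse-wave series with its sampling rate."""

    record_id: str
    samples: np.ndarray
    sampling_rate_hz: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size < 2:
            raise DegenerateInputError("a pulse record needs at least 2 samples")
        if not self.sampling_rate_hz > 0:
            raise ValidationError("sampling_rate_hz must be positive")

    def __len__(self) -> int:
        return len(self.samples)


def _parse_float(token: str, lineno: int) -> float:
    try:
        return float(token)
    except ValueError:
        raise ParseError(f"non-numeric value {token!r} at line {lineno}", line=lineno)


def read_pulse_record(
    path: str | Path, sampling_rate_hz: float, record_id: Optional[str] = None
) -> PulseRecord:
    """Read a record from one-column text or two-column ``t,value`` CSV.

    For two-column input the value column is used and the time column is
    verified to be monotonically increasing.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    samples: List[float] = []
    times: List[float] = []
    two_column: Optional[bool] = None
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = [p.strip() for p in line.split(",")]
        if two_column is None:
            two_column = len(parts) == 2
            # a non-numeric first row is a header (e.g. "t,value"); skip it
            try:
                float(parts[0])
            except ValueError:
                continue
        if two_column:
            if len(parts) != 2:
                raise FormatError(
                    f"expected two columns at line {lineno}", line=lineno
                )
            times.append(_parse_float(parts[0], lineno))
            samples.append(_parse_float(parts[1], lineno))
        else:
            if len(parts) != 1:
                raise FormatError(
                    f"expected one column at line {lineno}", line=lineno
                )
            samples.append(_parse_float(parts[0], lineno))
    if len(samples) < 2:
        raise DegenerateInputError(f"{path}: fewer than 2 samples")
    if times and np.any(np.diff(times) <= 0):
        raise FormatError(f"{path}: time column is not monotonically increasing")
    return PulseRecord(
        record_id=record_id or path.stem,
        samples=np.asarray(samples),
        sampling_rate_hz=sampling_rate_hz,
    )


def write_pulse_record(record: PulseRecord, path: str | Path) -> None:
    """Write a record as a two-column ``t,value`` CSV."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("t,value\n")
        dt = 1.0 / record.sampling_rate_hz
        for i, v in enumerate(record.samples):
            fh.write(f"{i * dt!r},{float(v)!r}\n")


# ---------------------------------------------------------------------------
# Segment corpora (JSONL)
# ---------------------------------------------------------------------------


def write_segments(
    segments: Sequence["Segment"],  # noqa: F821 - forward ref to segmentation
    path: str | Path,
    labels: Optional[Sequence[Optional[str]]] = None,
) -> None:
    """Write raw segments as JSONL; ``labels`` (if given) is parallel."""
    if labels is not None and len(labels) != len(segments):
        raise ValidationError("labels must be parallel to segments")
    path = Path(path)
    with path.open("w") as fh:
        for i, seg in enumerate(segments):
            obj = {
                "record_id": seg.record_id,
                "start": int(seg.start),
                "end": int(seg.end),
                "alpha": None if seg.alpha is None else float(seg.alpha),
                "values": [float(v) for v in seg.values],
            }
            if labels is not None and labels[i] is not None:
                obj["label"] = labels[i]
            fh.write(json.dumps(obj) + "\n")


def _read_jsonl(path: Path) -> List[Tuple[int, dict]]:
    rows = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        if not raw.strip():
            continue
        try:
            obj = json.loads(raw)
        except json.JSONDecodeError:
            raise ParseError(f"{path}: invalid JSON at line {lineno}", line=lineno)
        rows.append((lineno, obj))
    return rows


def read_segments(
    path: str | Path,
) -> Tuple[List["Segment"], List[Optional[str]]]:  # noqa: F821
    """Read a raw-segment JSONL corpus; returns (segments, labels)."""
    from .segmentation import Segment

    path = Path(path)
    segments: List[Segment] = []
    labels: List[Optional[str]] = []
    for lineno, obj in _read_jsonl(path):
        try:
            seg = Segment(
                record_id=obj["record_id"],
                start=obj["start"],
                end=obj["end"],
                alpha=obj["alpha"],
                values=np.asarray(obj["values"], dtype=float),
            )
        except KeyError as exc:
            raise SchemaError(f"{path}: missing field {exc} at line {lineno}")
        segments.append(seg)
        labels.append(obj.get("label"))
    return segments, labels


def write_standardized_segments(
    segments: Sequence["StandardizedSegment"],  # noqa: F821
    path: str | Path,
    labels: Optional[Sequence[Optional[str]]] = None,
) -> None:
    """Write standardized segments (with provenance + length) as JSONL."""
    if labels is not None and len(labels) != len(segments):
        raise ValidationError("labels must be parallel to segments")
    path = Path(path)
    with path.open("w") as fh:
        for i, seg in enumerate(segments):
            obj = {
                "record_id": seg.source.record_id,
                "start": int(seg.source.start),
                "end": int(seg.source.end),
                "alpha": None if seg.source.alpha is None else float(seg.source.alpha),
                "standard_length": int(seg.standard_length),
                "values": [float(v) for v in seg.values],
            }
            if labels is not None and labels[i] is not None:
                obj["label"] = labels[i]
            fh.write(json.dumps(obj) + "\n")


def read_standardized_segments(
    path: str | Path,
) -> Tuple[List["StandardizedSegment"], List[Optional[str]]]:  # noqa: F821
    """Read a standardized-segment JSONL corpus; returns (segments, labels)."""
    from .standardize import SegmentSource, StandardizedSegment

    path = Path(path)
    segments: List[StandardizedSegment] = []
    labels: List[Optional[str]] = []
    for lineno, obj in _read_jsonl(path):
        try:
            seg = StandardizedSegment(
                values=np.asarray(obj["values"], dtype=float),
                standard_length=obj["standard_length"],
                source=SegmentSource(
                    record_id=obj["record_id"],
                    start=obj["start"],
                    end=obj["end"],
                    alpha=obj["alpha"],
                ),
            )
        except KeyError as exc:
            raise SchemaError(f"{path}: missing field {exc} at line {lineno}")
        segments.append(seg)
        labels.append(obj.get("label"))
    return segments, labels


# ---------------------------------------------------------------------------
# Model specs (JSON)
# ---------------------------------------------------------------------------

_MODEL_FIELDS = ("standard_length", "intercept", "weights", "decision_threshold")


def read_model_spec(path: str | Path) -> "QualityModelSpec":  # noqa: F821
    from .quality_model import QualityModelSpec

    path = Path(path)
    try:
        obj = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: invalid JSON ({exc})")
    for field_name in _MODEL_FIELDS:
        if field_name not in obj:
            raise SchemaError(f"{path}: missing field {field_name!r}")
    try:
        weights = {int(k): float(v) for k, v in obj["weights"].items()}
    except (AttributeError, ValueError):
        raise SchemaError(f"{path}: weights must map feature indices to reals")
    return QualityModelSpec(
        standard_length=int(obj["standard_length"]),
        intercept=float(obj["intercept"]),
        weights=weights,
        decision_threshold=float(obj["decision_threshold"]),
    )


def write_model_spec(model: "QualityModelSpec", path: str | Path) -> None:  # noqa: F821
    obj = {
        "standard_length": int(model.standard_length),
        "intercept": float(model.intercept),
        "weights": {str(k): float(v) for k, v in sorted(model.weights.items())},
        "decision_threshold": float(model.decision_threshold),
    }
    Path(path).write_text(json.dumps(obj, indent=2) + "\n")
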