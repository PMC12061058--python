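"""Open interchange formats for fixation streams, landmarks, scan lines and results.

The native exports of the acquisition devices (microperimeter SLO printouts,
OCT infrared en-face images, autofluorescence frames) are proprietary, so this
package defines plain-text equivalents:

* tabular data are CSV files with a ``#``-prefixed ``key: value`` metadata
  header followed by a normal header row;
* result records are UTF-8 JSON with explicit ``units`` fields;
* images are 8- or 16-bit grayscale PNG or TIFF, handled by :mod:`imageio`
  / :mod:`tifffile` at the call sites that need pixels.

Coordinate conventions
----------------------
Pixel coordinates are 0-based, origin at the top-left corner, ``x`` rightward
and ``y`` downward; sub-pixel positions are real-valued.  Fixation files store
visual degrees centered on the exam's fixation target with ``y`` positive
*upward* (the orientation the microperimeter displays); the reader flips the
sign of ``y`` on load so every in-memory table shares the image (y-down)
convention, and the writer flips it back.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, MetadataError, ValidationError

__all__ = [
    "FixationSampleTable",
    "LandmarkPairTable",
    "ScanLineAnnotation",
    "ResultRecord",
    "read_fixation_csv",
    "write_fixation_csv",
    "read_landmark_csv",
    "write_landmark_csv",
    "read_scanline_csv",
    "write_scanline_csv",
    "read_result_json",
    "write_result_json",
]

_LATERALITIES = ("OD", "OS")


# ---------------------------------------------------------------------------
# low-level CSV-with-metadata plumbing


def _write_csv_with_meta(path: Path, meta: Mapping[str, object], df: pd.DataFrame) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=False)


def _read_csv_with_meta(path: Path) -> tuple[dict[str, str], pd.DataFrame]:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    meta: dict[str, str] = {}
    body_start = 0
    with open(path, encoding="utf-8") as fh:
        lines = fh.readlines()
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            body_start = i
            break
        stripped = line.lstrip("#").strip()
        if not stripped:
            continue
        if ":" not in stripped:
            raise FormatError(f"{path}: malformed metadata line {i + 1}: {line.rstrip()!r}")
        key, _, value = stripped.partition(":")
        meta[key.strip()] = value.strip()
    else:
        raise FormatError(f"{path}: no data rows after metadata header")
    from io import StringIO

    df = pd.read_csv(StringIO("".join(lines[body_start:])))
    return meta, df


def _require_columns(df: pd.DataFrame, columns: tuple[str, ...], path: object) -> None:
    for col in columns:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")


def _require_meta(meta: Mapping[str, str], keys: tuple[str, ...], path: object) -> None:
    for key in keys:
        if key not in meta:
            raise MetadataError(f"{path}: missing metadata key {key!r}")


# ---------------------------------------------------------------------------
# FixationSampleTable


@dataclass
class FixationSampleTable:
    """Timestamped gaze samples for one exam of one eye.

    ``samples`` has columns ``t`` (seconds), ``x``, ``y`` (visual degrees in
    the in-memory y-down convention).  Metadata carry laterality, subject,
    visit, the device's fixation-loss percentage and the total test duration.
    """

    samples: pd.DataFrame
    eye: str
    subject_id: str
    visit: str
    fixation_loss_pct: float
    test_duration: float

    def __post_init__(self) -> None:
        self.samples = self.samples.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        df = self.samples
        for col in ("t", "x", "y"):
            if col not in df.columns:
                raise ValidationError(f"fixation table missing column {col!r}")
        if len(df) < 1:
            raise ValidationError("fixation table must contain at least one sample")
        arr = df[["t", "x", "y"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            bad = int(np.argwhere(~np.isfinite(arr))[0, 0])
            raise ValidationError(f"non-finite coordinate at row {bad}")
        t = arr[:, 0]
        if t[0] < 0:
            raise ValidationError("timestamps must be >= 0")
        decreases = np.nonzero(np.diff(t) < 0)[0]
        if decreases.size:
            raise ValidationError(
                f"timestamps must be nondecreasing; first decrease at row {decreases[0] + 1}"
            )
        if self.eye not in _LATERALITIES:
            raise MetadataError(f"eye must be one of {_LATERALITIES}, got {self.eye!r}")
        if not (0.0 <= float(self.fixation_loss_pct) <= 100.0):
            raise ValidationError(
                f"fixation_loss_pct must lie in [0, 100], got {self.fixation_loss_pct}"
            )
        if not math.isfinite(float(self.test_duration)) or self.test_duration <= 0:
            raise ValidationError(f"test_duration must be finite and positive, got {self.test_duration}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def xy(self) -> np.ndarray:
        """Sample coordinates as an (n, 2) float array."""
        return self.samples[["x", "y"]].to_numpy(dtype=float)


def write_fixation_csv(table: FixationSampleTable, path: Path | str) -> None:
    """Write a fixation table, flipping y back to the file's y-up convention."""
    table.validate()
    df = table.samples[["t", "x", "y"]].copy()
    df["y"] = -df["y"]
    meta = {
        "eye": table.eye,
        "subject_id": table.subject_id,
        "visit": table.visit,
        "fixation_loss_pct": repr(float(table.fixation_loss_pct)),
        "test_duration": repr(float(table.test_duration)),
    }
    _write_csv_with_meta(Path(path), meta, df)


def read_fixation_csv(path: Path | str) -> FixationSampleTable:
    """Read a fixation CSV, converting degrees to the in-memory y-down convention."""
    meta, df = _read_csv_with_meta(Path(path))
    _require_columns(df, ("t", "x", "y"), path)
    _require_meta(meta, ("eye", "subject_id", "visit", "fixation_loss_pct", "test_duration"), path)
    df = df[["t", "x", "y"]].astype(float)
    df["y"] = -df["y"]
    try:
        loss = float(meta["fixation_loss_pct"])
        duration = float(meta["test_duration"])
    except ValueError as exc:
        raise MetadataError(f"{path}: non-numeric metadata: {exc}") from exc
    return FixationSampleTable(
        samples=df,
        eye=meta["eye"],
        subject_id=meta["subject_id"],
        visit=meta["visit"],
        fixation_loss_pct=loss,
        test_duration=duration,
    )


# ---------------------------------------------------------------------------
# LandmarkPairTable


@dataclass
class LandmarkPairTable:
    """Corresponding points between two image frames.

    Landmarks computationally replace the manual vessel / optic-nerve
    silhouette match used when overlaying modalities by hand.
    """

    pairs: pd.DataFrame
    src_frame: str
    dst_frame: str

    def __post_init__(self) -> None:
        self.pairs = self.pairs.reset_index(drop=True)
        self.validate()

    def validate(self, min_pairs: int = 2) -> None:
        for col in ("x_src", "y_src", "x_dst", "y_dst"):
            if col not in self.pairs.columns:
                raise ValidationError(f"landmark table missing column {col!r}")
        if len(self.pairs) < min_pairs:
            raise ValidationError(
                f"need at least {min_pairs} landmark pairs, got {len(self.pairs)}"
            )
        arr = self.pairs[["x_src", "y_src", "x_dst", "y_dst"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            bad = int(np.argwhere(~np.isfinite(arr))[0, 0])
            raise ValidationError(f"non-finite landmark coordinate at row {bad}")

    def src(self) -> np.ndarray:
        return self.pairs[["x_src", "y_src"]].to_numpy(dtype=float)

    def dst(self) -> np.ndarray:
        return self.pairs[["x_dst", "y_dst"]].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.pairs)


def write_landmark_csv(table: LandmarkPairTable, path: Path | str) -> None:
    table.validate()
    meta = {"src_frame": table.src_frame, "dst_frame": table.dst_frame}
    _write_csv_with_meta(Path(path), meta, table.pairs[["x_src", "y_src", "x_dst", "y_dst"]])


def read_landmark_csv(path: Path | str) -> LandmarkPairTable:
    meta, df = _read_csv_with_meta(Path(path))
    _require_columns(df, ("x_src", "y_src", "x_dst", "y_dst"), path)
    _require_meta(meta, ("src_frame", "dst_frame"), path)
    return LandmarkPairTable(
        pairs=df[["x_src", "y_src", "x_dst", "y_dst"]].astype(float),
        src_frame=meta["src_frame"],
        dst_frame=meta["dst_frame"],
    )


# ---------------------------------------------------------------------------
# ScanLineAnnotation


@dataclass
class ScanLineAnnotation:
    """One transfoveal OCT scan line, annotated as a segment in a named frame.

    ``orientation`` records whether the annotator intended a horizontal or a
    vertical scan; the endpoint geometry must agree with that label within
    ``angle_tolerance_deg`` so that mislabelled annotations are caught early.
    """

    orientation: str  # "horizontal" | "vertical"
    p0: tuple[float, float]
    p1: tuple[float, float]
    frame: str
    scan_id: str = ""
    angle_tolerance_deg: float = 15.0

    def __post_init__(self) -> None:
        self.p0 = (float(self.p0[0]), float(self.p0[1]))
        self.p1 = (float(self.p1[0]), float(self.p1[1]))
        self.validate()

    def validate(self) -> None:
        if self.orientation not in ("horizontal", "vertical"):
            raise ValidationError(f"orientation must be horizontal or vertical, got {self.orientation!r}")
        dx = self.p1[0] - self.p0[0]
        dy = self.p1[1] - self.p0[1]
        if not all(math.isfinite(v) for v in (*self.p0, *self.p1)):
            raise ValidationError("scan-line endpoints must be finite")
        if dx == 0.0 and dy == 0.0:
            raise ValidationError("scan-line endpoints must be distinct")
        # angle of the segment relative to the image x axis, folded to [0, 90]
        angle = math.degrees(math.atan2(abs(dy), abs(dx)))
        expected = 0.0 if self.orientation == "horizontal" else 90.0
        if abs(angle - expected) > self.angle_tolerance_deg:
            raise ValidationError(
                f"segment at {angle:.1f} deg from horizontal is inconsistent with "
                f"orientation {self.orientation!r} (tolerance {self.angle_tolerance_deg} deg)"
            )

    def direction(self) -> np.ndarray:
        """Unit direction vector of the segment."""
        d = np.array([self.p1[0] - self.p0[0], self.p1[1] - self.p0[1]], dtype=float)
        return d / np.linalg.norm(d)


def write_scanline_csv(line: ScanLineAnnotation, path: Path | str) -> None:
    line.validate()
    meta = {"orientation": line.orientation, "frame": line.frame, "scan_id": line.scan_id}
    df = pd.DataFrame({"x": [line.p0[0], line.p1[0]], "y": [line.p0[1], line.p1[1]]})
    _write_csv_with_meta(Path(path), meta, df)


def read_scanline_csv(path: Path | str) -> ScanLineAnnotation:
    meta, df = _read_csv_with_meta(Path(path))
    _require_columns(df, ("x", "y"), path)
    _require_meta(meta, ("orientation", "frame"), path)
    if len(df) != 2:
        raise FormatError(f"{path}: scan-line file must contain exactly 2 endpoint rows, got {len(df)}")
    xs = df["x"].astype(float).tolist()
    ys = df["y"].astype(float).tolist()
    return ScanLineAnnotation(
        orientation=meta["orientation"],
        p0=(xs[0], ys[0]),
        p1=(xs[1], ys[1]),
        frame=meta["frame"],
        scan_id=meta.get("scan_id", ""),
    )


# ---------------------------------------------------------------------------
# ResultRecord


def _check_finite(obj: object, trail: str = "") -> None:
    if isinstance(obj, bool):
        return
    if isinstance(obj, (int, float)):
        if not math.isfinite(float(obj)):
            raise ValidationError(f"non-finite numeric field{' at ' + trail if trail else ''}: {obj!r}")
        return
    if isinstance(obj, Mapping):
        for key, value in obj.items():
            _check_finite(value, f"{trail}.{key}" if trail else str(key))
        return
    if isinstance(obj, (list, tuple)):
        for i, value in enumerate(obj):
            _check_finite(value, f"{trail}[{i}]")


@dataclass
class ResultRecord:
    """Headline metrics for one eye/visit plus the provenance to reproduce them.

    ``metrics`` is the serialized per-eye metric set (DFC, DPRL, quadrant,
    BCEA, P1/P2, stability class, validity), ``units`` maps every numeric
    metric to its unit string, and ``provenance`` records input digests,
    transform parameters, the ruler value and the software version.
    """

    metrics: dict
    units: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not self.metrics:
            raise ValidationError("result record has no metrics")
        _check_finite(self.metrics, "metrics")
        _check_finite(self.provenance, "provenance")


def write_result_json(record: ResultRecord, path: Path | str) -> None:
    """Serialize a validated result record to UTF-8 JSON.

    Refuses records containing non-finite numerics so a NaN metric can never
    silently reach disk.
    """
    record.validate()
    payload = {
        "metrics": record.metrics,
        "units": record.units,
        "provenance": record.provenance,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, allow_nan=False)
        fh.write("\n")


def read_result_json(path: Path | str) -> ResultRecord:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    for key in ("metrics", "units", "provenance"):
        if key not in payload:
            raise FormatError(f"{path}: missing top-level key {key!r}")
    record = ResultRecord(
        metrics=payload["metrics"], units=payload["units"], provenance=payload["provenance"]
    )
    record.validate()
    return record
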