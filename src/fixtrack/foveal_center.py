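"""Anatomic foveal-center localization from two transfoveal scan lines.

The foveal center (FC) is defined as the crossing of the vertical and the
horizontal OCT scan lines judged most topographically accurate of the fovea
(the foveal reflex guides that judgement upstream; here the chosen lines
arrive as annotations).  Each line is registered into the common frame
through its modality transform, and the FC is the intersection of the two
infinite lines through the transformed endpoints — the scan lines are chords
through the fovea, so their crossing, not any segment midpoint, is the
anatomic reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ChainingError, DegeneracyError
from .io_formats import ScanLineAnnotation
from .registration import PlanarTransform, apply_transform

__all__ = ["FovealCenter", "intersect_scanlines"]

MIN_SEPARATION_DEG = 5.0
GOOD_SEPARATION_RANGE = (60.0, 120.0)


@dataclass(frozen=True)
class FovealCenter:
    """The anatomic reference point in the common frame.

    ``angular_separation`` is the angle between the two registered scan lines
    in degrees; intersections from lines closer than 30° to parallel (outside
    60°–120°) carry ``reliable=False`` because the crossing becomes
    ill-conditioned.
    """

    position: tuple[float, float]
    angular_separation: float
    source_scan_ids: tuple[str, str] = ("", "")
    frame: str = "common"
    reliable: bool = True

    @property
    def x(self) -> float:
        return self.position[0]

    @property
    def y(self) -> float:
        return self.position[1]


def _line_angle_separation(d1: np.ndarray, d2: np.ndarray) -> float:
    """Angle between two undirected lines, in (0, 90] degrees folded to [0, 180)."""
    cross = abs(d1[0] * d2[1] - d1[1] * d2[0])
    dot = abs(float(d1 @ d2))
    return math.degrees(math.atan2(cross, dot))


def intersect_scanlines(
    h: ScanLineAnnotation,
    v: ScanLineAnnotation,
    Th: PlanarTransform,
    Tv: PlanarTransform,
    max_distance: float | None = None,
) -> FovealCenter:
    """Intersect the registered horizontal and vertical scan lines.

    ``Th`` and ``Tv`` map each annotation's frame into the same common frame.
    Raises :class:`DegeneracyError` when the registered lines are within 5° of
    parallel, and :class:`ChainingError` on frame mismatches.  When
    ``max_distance`` is given (typically 1.5× the image diagonal), an
    intersection farther than that from both segments raises
    :class:`DegeneracyError` as an out-of-frame crossing.
    """
    if Th.src_frame != h.frame:
        raise ChainingError(
            f"transform for horizontal line maps from {Th.src_frame!r} but line is in {h.frame!r}"
        )
    if Tv.src_frame != v.frame:
        raise ChainingError(
            f"transform for vertical line maps from {Tv.src_frame!r} but line is in {v.frame!r}"
        )
    if Th.dst_frame != Tv.dst_frame:
        raise ChainingError(
            f"scan lines registered into different frames: {Th.dst_frame!r} vs {Tv.dst_frame!r}"
        )

    p0h = np.array(apply_transform(h.p0, Th))
    p1h = np.array(apply_transform(h.p1, Th))
    p0v = np.array(apply_transform(v.p0, Tv))
    p1v = np.array(apply_transform(v.p1, Tv))

    dh = p1h - p0h
    dv = p1v - p0v
    sep = _line_angle_separation(dh, dv)
    if sep < MIN_SEPARATION_DEG:
        raise DegeneracyError(
            f"scan lines are within {MIN_SEPARATION_DEG} deg of parallel "
            f"(separation {sep:.2f} deg); no reliable intersection"
        )

    # Solve p0h + s*dh = p0v + u*dv for (s, u).
    a = np.column_stack([dh, -dv])
    rhs = p0v - p0h
    s, _u = np.linalg.solve(a, rhs)
    fc = p0h + s * dh

    if max_distance is not None:
        d_h = _point_segment_distance(fc, p0h, p1h)
        d_v = _point_segment_distance(fc, p0v, p1v)
        if d_h > max_distance and d_v > max_distance:
            raise DegeneracyError(
                f"intersection at ({fc[0]:.1f}, {fc[1]:.1f}) lies {min(d_h, d_v):.1f} px from "
                f"the nearer segment, beyond the allowed {max_distance:.1f} px"
            )

    lo, hi = GOOD_SEPARATION_RANGE
    return FovealCenter(
        position=(float(fc[0]), float(fc[1])),
        angular_separation=float(sep),
        source_scan_ids=(h.scan_id, v.scan_id),
        frame=Th.dst_frame,
        reliable=lo <= sep <= hi,
    )


def _point_segment_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    d = b - a
    t = float(np.clip((p - a) @ d / (d @ d), 0.0, 1.0))
    return float(np.linalg.norm(p - (a + t * d)))
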