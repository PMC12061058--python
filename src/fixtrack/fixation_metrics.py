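"""Fixation metrics for one eye and exam.

Given the gaze-sample cloud from microperimetry fundus tracking and the
anatomic foveal center (FC) registered into a common frame, this module
computes the quantities used to characterize eccentric fixation:

* **PRLi / PRLf** — the preferred retinal locus at the start and end of the
  exam, each the centroid of a cluster of fixation samples.  PRLi averages
  the samples of the initial window (default 10 s, matching the device's
  grid-centering phase); PRLf averages the whole exam and is the reference
  point for every stability metric.
* **DFC** — distance from foveal center: the Euclidean (shortest-line)
  distance between FC and PRLf, in microns.
* **DPRL** — distance between PRLi and PRLf, in microns: a point-to-point
  proxy for how far fixation wandered during the exam.
* **Quadrant** — the retinal quadrant of the PRLf relative to two
  perpendicular lines crossing at the FC, mapped to anatomic labels
  (superotemporal, ...) by eye laterality.
* **BCEA** — bivariate contour ellipse area in squared degrees at a chosen
  coverage probability, from the second moments of the sample cloud.
* **P1 / P2** — the percentage of samples within 1° and 2° of PRLf, and the
  stable / relatively-unstable / unstable classification they imply.

Boundary conventions (documented and tested): P1/P2 radii are inclusive
(distance ≤ r counts); the stability rules use strict ``> 75%``, so an exam
sitting exactly at 75/75 classifies as unstable; exam validity uses the
inclusive fixation-loss criterion ≤ 15%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .calibration import DegreeScale, ScaleRuler, px_to_um
from .errors import (
    ChainingError,
    DomainError,
    InsufficientDataError,
    MetadataError,
    ValidationError,
)
from .foveal_center import FovealCenter
from .io_formats import FixationSampleTable

__all__ = [
    "PRLPair",
    "EyeMetrics",
    "compute_prl_pair",
    "dfc",
    "dprl",
    "quadrant",
    "bcea",
    "p1_p2",
    "stability_class",
    "exam_valid",
    "dfc_change",
    "compute_eye_metrics",
]

INITIAL_WINDOW_SECONDS = 10.0
FIXATION_LOSS_LIMIT_PCT = 15.0
STABILITY_THRESHOLD_PCT = 75.0
DEFAULT_BCEA_COVERAGE = 0.95
_TIE_EPS = 1e-9


@dataclass(frozen=True)
class PRLPair:
    """Initial and final preferred retinal locus, tagged with their coordinate space.

    ``space`` is ``"degrees"`` (visual degrees, y-down in-memory convention)
    or ``"pixels"`` (common-frame raster pixels); both points share the tag.
    """

    prl_initial: tuple[float, float]
    prl_final: tuple[float, float]
    space: str = "degrees"
    window_initial: float = INITIAL_WINDOW_SECONDS

    def __post_init__(self) -> None:
        if self.space not in ("degrees", "pixels"):
            raise DomainError(f"space must be 'degrees' or 'pixels', got {self.space!r}")
        if not all(math.isfinite(v) for v in (*self.prl_initial, *self.prl_final)):
            raise ValidationError("PRL coordinates must be finite")


@dataclass(frozen=True)
class EyeMetrics:
    """Headline fixation metrics for one eye and visit."""

    dfc: float  # µm
    dprl: float  # µm
    quadrant: str
    bcea: float  # deg^2
    bcea_coverage: float
    p1: float  # percent
    p2: float  # percent
    stability: str
    valid_exam: bool
    bcea_degenerate: bool = False

    def __post_init__(self) -> None:
        if self.dfc < 0 or self.dprl < 0 or self.bcea < 0:
            raise ValidationError("distances and areas must be nonnegative")
        if not (0.0 <= self.p1 <= self.p2 <= 100.0):
            raise ValidationError(f"need 0 <= p1 <= p2 <= 100, got p1={self.p1}, p2={self.p2}")

    def to_dict(self) -> dict:
        return {
            "dfc": self.dfc,
            "dprl": self.dprl,
            "quadrant": self.quadrant,
            "bcea": self.bcea,
            "bcea_coverage": self.bcea_coverage,
            "p1": self.p1,
            "p2": self.p2,
            "stability": self.stability,
            "valid_exam": self.valid_exam,
            "bcea_degenerate": self.bcea_degenerate,
        }

    UNITS = {
        "dfc": "um",
        "dprl": "um",
        "bcea": "deg^2",
        "p1": "percent",
        "p2": "percent",
    }


# ---------------------------------------------------------------------------
# PRL estimation


def compute_prl_pair(
    samples: FixationSampleTable,
    window_initial: float = INITIAL_WINDOW_SECONDS,
    center: str = "mean",
) -> PRLPair:
    """Centroids of the initial-window and whole-exam fixation clouds.

    ``center`` selects the cluster-center estimator: the arithmetic
    ``"mean"`` (default, matching the moment basis of the BCEA) or the
    coordinate-wise ``"median"`` for robustness to excursions.
    """
    if center not in ("mean", "median"):
        raise DomainError(f"center must be 'mean' or 'median', got {center!r}")
    t = samples.samples["t"].to_numpy(dtype=float)
    xy = samples.xy()
    in_window = t <= window_initial
    if not np.any(in_window):
        raise InsufficientDataError(
            f"no samples inside the initial {window_initial} s window (first t = {t[0]})"
        )
    estimator = np.mean if center == "mean" else np.median
    prli = estimator(xy[in_window], axis=0)
    prlf = estimator(xy, axis=0)
    return PRLPair(
        prl_initial=(float(prli[0]), float(prli[1])),
        prl_final=(float(prlf[0]), float(prlf[1])),
        space="degrees",
        window_initial=window_initial,
    )


# ---------------------------------------------------------------------------
# distances


def dfc(fc: FovealCenter, prlf: tuple[float, float], ruler: ScaleRuler) -> float:
    """Distance from foveal center: |FC − PRLf| in the common frame, in µm.

    Both points must be expressed in common-frame pixels.
    """
    d_px = math.hypot(prlf[0] - fc.x, prlf[1] - fc.y)
    return px_to_um(d_px, ruler)


def dprl(
    pair: PRLPair,
    ruler: ScaleRuler | None = None,
    degree_scale: DegreeScale | None = None,
) -> float:
    """Distance between PRLi and PRLf in µm.

    The conversion used depends on the pair's coordinate space: a pixel-space
    pair needs the per-eye ``ruler``, a degree-space pair needs the
    ``degree_scale`` (defaulting to the schematic-eye 288 µm/°).
    """
    d = math.hypot(
        pair.prl_final[0] - pair.prl_initial[0], pair.prl_final[1] - pair.prl_initial[1]
    )
    if pair.space == "pixels":
        if ruler is None:
            raise ChainingError("pixel-space PRL pair requires a ScaleRuler")
        return px_to_um(d, ruler)
    scale = degree_scale if degree_scale is not None else DegreeScale()
    return d * scale.microns_per_degree


def dfc_change(
    prlf_baseline: tuple[float, float],
    prlf_followup: tuple[float, float],
    ruler: ScaleRuler,
) -> float:
    """Longitudinal fixation shift: |PRLf(t1) − PRLf(t0)| in µm.

    With both visits registered to the same common frame, FC, PRLf(t0) and
    PRLf(t1) form a triangle whose third side is the shift of the preferred
    locus itself — independent of where the FC sits.  When the three points
    are collinear it reduces to |DFC(t1) − DFC(t0)|.
    """
    d_px = math.hypot(
        prlf_followup[0] - prlf_baseline[0], prlf_followup[1] - prlf_baseline[1]
    )
    return px_to_um(d_px, ruler)


# ---------------------------------------------------------------------------
# quadrant


def quadrant(fc: FovealCenter, prlf: tuple[float, float], eye: str) -> str:
    """Retinal quadrant of the PRLf relative to perpendicular axes through the FC.

    Assumes the standard fundus display (superior up): with y-down raster
    coordinates, superior means ``prlf.y < fc.y``.  Laterality fixes the
    horizontal mapping — for a right eye (OD) the optic disc sits nasally on
    the image right, so image-left of the FC is temporal; for a left eye (OS)
    the mapping mirrors.  Coordinates tied with the FC within 1e-9 px on
    either axis give ``on_axis``.
    """
    if eye not in ("OD", "OS"):
        raise MetadataError(f"laterality must be OD or OS, got {eye!r}")
    dx = prlf[0] - fc.x
    dy = prlf[1] - fc.y
    if abs(dx) <= _TIE_EPS or abs(dy) <= _TIE_EPS:
        return "on_axis"
    vertical = "supero" if dy < 0 else "infero"
    image_left = dx < 0
    if eye == "OD":
        horizontal = "temporal" if image_left else "nasal"
    else:
        horizontal = "nasal" if image_left else "temporal"
    return vertical + horizontal


# ---------------------------------------------------------------------------
# stability metrics


def bcea(
    samples: FixationSampleTable,
    coverage: float = DEFAULT_BCEA_COVERAGE,
) -> tuple[float, bool]:
    """Bivariate contour ellipse area, in squared degrees.

    BCEA(P) = chi2_2(P) * pi * sx * sy * sqrt(1 - rho^2), with sx, sy the
    sample standard deviations of the horizontal and vertical eye positions
    and rho their sample correlation.  chi2_2(P) is the coverage quantile of
    the chi-squared distribution with 2 degrees of freedom (5.991 at 95%).

    Returns ``(area, degenerate)``: a cloud with zero variance on an axis, or
    perfectly correlated axes, has zero area and is flagged degenerate.
    """
    if not (0.0 < coverage < 1.0):
        raise DomainError(f"coverage must lie in (0, 1), got {coverage}")
    xy = samples.xy()
    if len(xy) < 3:
        raise InsufficientDataError(f"BCEA needs >= 3 samples, got {len(xy)}")
    sx = float(np.std(xy[:, 0], ddof=1))
    sy = float(np.std(xy[:, 1], ddof=1))
    if sx == 0.0 or sy == 0.0:
        return 0.0, True
    rho = float(np.corrcoef(xy[:, 0], xy[:, 1])[0, 1])
    rho = max(-1.0, min(1.0, rho))
    if (1.0 - abs(rho)) < 1e-12:  # numerically collinear cloud
        return 0.0, True
    k = float(stats.chi2.ppf(coverage, df=2))
    area = k * math.pi * sx * sy * math.sqrt(1.0 - rho * rho)
    return area, False


def p1_p2(
    samples: FixationSampleTable,
    prlf: tuple[float, float],
    radii: tuple[float, float] = (1.0, 2.0),
) -> tuple[float, float]:
    """Percentage of samples within 1° (P1) and 2° (P2) of the PRLf, inclusive."""
    xy = samples.xy()
    if len(xy) < 1:
        raise InsufficientDataError("P1/P2 need at least one sample")
    d = np.hypot(xy[:, 0] - prlf[0], xy[:, 1] - prlf[1])
    p1 = 100.0 * float(np.mean(d <= radii[0]))
    p2 = 100.0 * float(np.mean(d <= radii[1]))
    return p1, p2


def stability_class(p1: float, p2: float) -> str:
    """Classify fixation from P1/P2 with strict 75% thresholds.

    stable if P1 > 75; relatively_unstable if P1 ≤ 75 < P2; else unstable.
    An exam at exactly P1 = P2 = 75 is unstable under this strict reading.
    """
    if not (0.0 <= p1 <= p2 <= 100.0):
        raise ValidationError(f"need 0 <= p1 <= p2 <= 100, got p1={p1}, p2={p2}")
    if p1 > STABILITY_THRESHOLD_PCT:
        return "stable"
    if p2 > STABILITY_THRESHOLD_PCT:
        return "relatively_unstable"
    return "unstable"


def exam_valid(samples: FixationSampleTable) -> bool:
    """Device reliability criterion: fixation loss ≤ 15% (inclusive)."""
    loss = samples.fixation_loss_pct
    if loss is None or not math.isfinite(float(loss)):
        raise MetadataError("fixation_loss_pct metadata missing or non-finite")
    return float(loss) <= FIXATION_LOSS_LIMIT_PCT


# ---------------------------------------------------------------------------
# one-shot per-eye summary


def compute_eye_metrics(
    samples: FixationSampleTable,
    fc: FovealCenter,
    prlf_px: tuple[float, float],
    prli_px: tuple[float, float],
    ruler: ScaleRuler,
    bcea_coverage: float = DEFAULT_BCEA_COVERAGE,
) -> EyeMetrics:
    """Assemble the full per-eye metric record.

    The PRL positions must already be registered into the common pixel frame
    (``prlf_px``, ``prli_px``); the degree-space sample cloud is used for the
    BCEA and P1/P2, which are defined in visual degrees.
    """
    pair_deg = compute_prl_pair(samples)
    pair_px = PRLPair(prl_initial=prli_px, prl_final=prlf_px, space="pixels")
    area, degenerate = bcea(samples, coverage=bcea_coverage)
    p1, p2 = p1_p2(samples, pair_deg.prl_final)
    return EyeMetrics(
        dfc=dfc(fc, prlf_px, ruler),
        dprl=dprl(pair_px, ruler=ruler),
        quadrant=quadrant(fc, prlf_px, samples.eye),
        bcea=area,
        bcea_coverage=bcea_coverage,
        p1=p1,
        p2=p2,
        stability=stability_class(p1, p2),
        valid_exam=exam_valid(samples),
        bcea_degenerate=degenerate,
    )
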