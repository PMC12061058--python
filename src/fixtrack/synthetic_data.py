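"""Synthetic inputs for every pipeline stage.

Real inputs are device exports that cannot be redistributed, so this module
fabricates geometrically faithful stand-ins:

* **Vessel phantoms** — procedural random-walk vessel trees rendered with
  Gaussian intensity profiles on a reference ("common") frame, then warped
  into each modality frame (OCT infrared, microperimeter SLO, FAF) by known
  similarity transforms.  The trees give a human enough texture to click
  landmarks on, but the landmark tables are emitted analytically from the
  true transforms, so downstream tests never depend on rendered pixels.
* **Scan-line annotations** — a horizontal and a vertical transfoveal line in
  the OCT frame whose registered intersection is exactly the programmed
  foveal center.
* **Fixation clouds** — bivariate-normal gaze samples at the microperimeter's
  25 Hz cadence with programmed center offset, spread, correlation and drift.
  An optional two-cluster mixture covers the non-normal fixation patterns
  seen in real exams.

Everything is deterministic given the spec seeds, and every generated file
passes the interchange-format validators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .calibration import DegreeScale, ScaleRuler, make_ruler
from .errors import DomainError, ValidationError
from .io_formats import FixationSampleTable, LandmarkPairTable, ScanLineAnnotation
from .registration import PlanarTransform, apply_transform, compose, invert

__all__ = [
    "PhantomSpec",
    "FixationCloudSpec",
    "PhantomBundle",
    "make_phantom",
    "make_fixation_exam",
    "programmed_prl_truth",
    "write_bundle",
    "random_phantom_spec",
]

MODALITIES = ("oct_ir", "maia", "faf")
COMMON_FRAME = "faf"


def _default_transforms() -> dict[str, PlanarTransform]:
    """Modest rotation/scale/shift between modalities, as a manual overlay sees."""
    return {
        "oct_ir": PlanarTransform.from_params(
            scale=1.08, rotation=math.radians(3.0), translation=(14.0, -9.0),
            src_frame="oct_ir", dst_frame="maia",
        ),
        "maia": PlanarTransform.from_params(
            scale=0.94, rotation=math.radians(-2.0), translation=(-6.0, 11.0),
            src_frame="maia", dst_frame="faf",
        ),
    }


@dataclass
class PhantomSpec:
    """Recipe for one synthetic eye: images, transforms, FC, scale bar.

    ``transforms`` maps each non-reference modality to the similarity that
    carries it one step along the registration chain
    (``oct_ir`` → ``maia`` → ``faf``); the FAF frame is the common frame.
    ``true_fc`` is in common-frame pixels.
    """

    image_size: int = 512
    n_vessels: int = 7
    vessel_seed: int = 0
    true_fc: tuple[float, float] = (256.0, 240.0)
    transforms: dict[str, PlanarTransform] = field(default_factory=_default_transforms)
    scale_bar_px: float = 23.0
    scale_bar_um: float = 200.0
    eye: str = "OD"
    microns_per_degree: float = 288.0
    n_landmarks: int = 10

    def __post_init__(self) -> None:
        if not (0 <= self.true_fc[0] < self.image_size and 0 <= self.true_fc[1] < self.image_size):
            raise ValidationError(
                f"true_fc {self.true_fc} lies outside the {self.image_size} px image"
            )
        if self.n_landmarks < 2:
            raise ValidationError("need at least 2 landmarks")
        for key in ("oct_ir", "maia"):
            if key not in self.transforms:
                raise ValidationError(f"transforms must include {key!r}")


@dataclass
class FixationCloudSpec:
    """Recipe for one fixation exam.

    ``center_offset_from_fc`` displaces the cloud center from the foveal
    center, in microns (image convention: x rightward, y downward) — the
    programmed eccentric fixation.  ``drift`` is the programmed expected
    distance between initial and final PRL, in microns, realised as a linear
    positional drift along the x axis whose velocity is calibrated so the
    expected PRLi→PRLf separation equals ``drift`` exactly.
    ``cluster2_weight``/``cluster2_offset_deg`` optionally mix in a second
    fixation cluster for non-normal clouds.
    """

    n_samples: int = 750
    rate: float = 25.0
    center_offset_from_fc: tuple[float, float] = (1000.0, -700.0)
    sigma: tuple[float, float] = (0.8, 0.8)
    rho: float = 0.0
    drift: float = 0.0
    rng_seed: int = 0
    cluster2_weight: float = 0.0
    cluster2_offset_deg: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValidationError("n_samples must be >= 1")
        if not (abs(self.rho) < 1.0):
            raise ValidationError(f"|rho| must be < 1, got {self.rho}")
        if self.sigma[0] <= 0 or self.sigma[1] <= 0:
            raise ValidationError(f"sigma must be positive, got {self.sigma}")
        if self.rate <= 0:
            raise ValidationError("rate must be positive")
        if not (0.0 <= self.cluster2_weight < 1.0):
            raise ValidationError("cluster2_weight must lie in [0, 1)")


@dataclass
class PhantomBundle:
    """Everything :func:`make_phantom` produces for one synthetic eye."""

    images: dict[str, np.ndarray]
    landmarks: dict[str, LandmarkPairTable]  # keyed "src->dst"
    scanline_h: ScanLineAnnotation
    scanline_v: ScanLineAnnotation
    ruler: ScaleRuler
    ground_truth: dict


def _render_vessel_tree(spec: PhantomSpec, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Random-walk vessel tree on the common frame; returns (image, walk points)."""
    size = spec.image_size
    canvas = np.zeros((size, size), dtype=float)
    # vessels radiate from a disc-like origin nasal to the fovea
    disc = np.array([size * 0.85 if spec.eye == "OD" else size * 0.15, size * 0.45])
    all_points = []
    for _ in range(spec.n_vessels):
        pos = disc + rng.normal(scale=8.0, size=2)
        heading = rng.uniform(0.0, 2.0 * math.pi)
        n_steps = int(rng.integers(150, 260))
        for _step in range(n_steps):
            heading += rng.normal(scale=0.18)
            pos = pos + 2.2 * np.array([math.cos(heading), math.sin(heading)])
            if not (2 <= pos[0] < size - 2 and 2 <= pos[1] < size - 2):
                break
            canvas[int(round(pos[1])), int(round(pos[0]))] += 1.0
            all_points.append(pos.copy())
    canvas = ndimage.gaussian_filter(canvas, sigma=1.6)
    peak = canvas.max()
    if peak > 0:
        canvas = canvas / peak
    return canvas, np.array(all_points) if all_points else np.empty((0, 2))


def _warp_to_modality(reference: np.ndarray, T_to_common: PlanarTransform) -> np.ndarray:
    """Render the reference scene as seen in a modality frame."""
    from skimage import transform as sktf

    # warp's inverse_map takes output (modality) coords to input (common) coords,
    # which is exactly the modality->common matrix
    h = np.vstack([T_to_common.matrix, [0.0, 0.0, 1.0]])
    return sktf.warp(reference, sktf.AffineTransform(matrix=h), preserve_range=True, order=1)


def make_phantom(spec: PhantomSpec) -> PhantomBundle:
    """Generate images, exact landmark tables, scan lines and ground truth.

    Landmark pairs relate consecutive frames of the registration chain and
    are exact under the true transforms; the two scan lines are drawn in the
    OCT frame so that their registered intersection is exactly ``true_fc``.
    """
    rng = np.random.default_rng(spec.vessel_seed)
    reference, walk = _render_vessel_tree(spec, rng)

    T_oct_to_maia = spec.transforms["oct_ir"]
    T_maia_to_faf = spec.transforms["maia"]
    T_oct_to_faf = compose(T_oct_to_maia, T_maia_to_faf)
    to_common = {"oct_ir": T_oct_to_faf, "maia": T_maia_to_faf}

    images = {COMMON_FRAME: reference}
    for modality, T in to_common.items():
        images[modality] = _warp_to_modality(reference, T)

    # landmark points: vessel-walk locations spread over the frame, analytic
    if len(walk) >= spec.n_landmarks:
        idx = rng.choice(len(walk), size=spec.n_landmarks, replace=False)
        pts_common = walk[idx]
    else:  # sparse tree: fall back to a jittered grid
        g = np.linspace(spec.image_size * 0.2, spec.image_size * 0.8, spec.n_landmarks)
        pts_common = np.column_stack([g, g[::-1]]) + rng.normal(scale=3.0, size=(spec.n_landmarks, 2))

    landmarks: dict[str, LandmarkPairTable] = {}
    for src, dst, T_src, T_dst in (
        ("oct_ir", "maia", T_oct_to_faf, T_maia_to_faf),
        ("maia", "faf", T_maia_to_faf, None),
    ):
        p_src = apply_transform(pts_common, invert(T_src))
        p_dst = pts_common if T_dst is None else apply_transform(pts_common, invert(T_dst))
        landmarks[f"{src}->{dst}"] = LandmarkPairTable(
            pairs=pd.DataFrame(
                {
                    "x_src": p_src[:, 0],
                    "y_src": p_src[:, 1],
                    "x_dst": p_dst[:, 0],
                    "y_dst": p_dst[:, 1],
                }
            ),
            src_frame=src,
            dst_frame=dst,
        )

    # transfoveal scan lines in the OCT frame, crossing exactly at true_fc
    fc_oct = apply_transform(spec.true_fc, invert(T_oct_to_faf))
    half = spec.image_size * 0.3
    scan_h = ScanLineAnnotation(
        orientation="horizontal",
        p0=(fc_oct[0] - half, fc_oct[1]),
        p1=(fc_oct[0] + half, fc_oct[1]),
        frame="oct_ir",
        scan_id="bscan-h",
    )
    scan_v = ScanLineAnnotation(
        orientation="vertical",
        p0=(fc_oct[0], fc_oct[1] - half),
        p1=(fc_oct[0], fc_oct[1] + half),
        frame="oct_ir",
        scan_id="bscan-v",
    )

    ruler = make_ruler(spec.scale_bar_px, spec.scale_bar_um)
    # pixel pitch of the SLO frame implied by the common-frame ruler and the
    # maia->common scale: 1 maia px = s common px = s * um_per_px microns
    um_per_maia_px = ruler.microns_per_pixel * T_maia_to_faf.scale
    maia_px_per_deg = spec.microns_per_degree / um_per_maia_px
    target_px = (spec.image_size / 2.0, spec.image_size / 2.0)  # maia frame
    fc_maia = apply_transform(spec.true_fc, invert(T_maia_to_faf))
    fc_deg = (
        (fc_maia[0] - target_px[0]) / maia_px_per_deg,
        (fc_maia[1] - target_px[1]) / maia_px_per_deg,
    )

    ground_truth = {
        "true_fc": list(spec.true_fc),
        "eye": spec.eye,
        "scale_bar_px": spec.scale_bar_px,
        "scale_bar_um": spec.scale_bar_um,
        "microns_per_pixel": ruler.microns_per_pixel,
        "microns_per_degree": spec.microns_per_degree,
        "maia_px_per_deg": maia_px_per_deg,
        "fixation_target_px": list(target_px),
        "fc_in_maia_px": [float(fc_maia[0]), float(fc_maia[1])],
        "fc_in_degrees": [float(fc_deg[0]), float(fc_deg[1])],
        "transforms": {name: T.to_dict() for name, T in spec.transforms.items()},
    }
    return PhantomBundle(
        images=images,
        landmarks=landmarks,
        scanline_h=scan_h,
        scanline_v=scan_v,
        ruler=ruler,
        ground_truth=ground_truth,
    )


def random_phantom_spec(rng: np.random.Generator, image_size: int = 512) -> PhantomSpec:
    """Draw a random but realistic phantom spec (FC near the posterior pole,
    modest inter-modality scale/rotation/shift, scale bars around 20-30 px)."""
    fc = tuple(rng.uniform(0.3 * image_size, 0.7 * image_size, size=2))
    transforms = {
        "oct_ir": PlanarTransform.from_params(
            scale=rng.uniform(0.85, 1.2),
            rotation=math.radians(rng.uniform(-8.0, 8.0)),
            translation=tuple(rng.uniform(-25.0, 25.0, size=2)),
            src_frame="oct_ir",
            dst_frame="maia",
        ),
        "maia": PlanarTransform.from_params(
            scale=rng.uniform(0.85, 1.2),
            rotation=math.radians(rng.uniform(-8.0, 8.0)),
            translation=tuple(rng.uniform(-25.0, 25.0, size=2)),
            src_frame="maia",
            dst_frame="faf",
        ),
    }
    return PhantomSpec(
        image_size=image_size,
        vessel_seed=int(rng.integers(0, 2**31 - 1)),
        true_fc=fc,
        transforms=transforms,
        scale_bar_px=float(rng.uniform(18.0, 30.0)),
        eye=str(rng.choice(["OD", "OS"])),
    )


def write_bundle(phantom: PhantomBundle, exam: FixationSampleTable, out_dir) -> dict:
    """Write a phantom + exam as interchange files; returns run-config kwargs.

    Images are not written here (they are not needed to compute metrics);
    the command-line ``simulate`` subcommand adds them for visualisation.
    """
    from pathlib import Path

    from .io_formats import write_fixation_csv, write_landmark_csv, write_scanline_csv

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_landmark_csv(phantom.landmarks["oct_ir->maia"], out / "landmarks_oct_maia.csv")
    write_landmark_csv(phantom.landmarks["maia->faf"], out / "landmarks_maia_faf.csv")
    write_scanline_csv(phantom.scanline_h, out / "scanline_h.csv")
    write_scanline_csv(phantom.scanline_v, out / "scanline_v.csv")
    write_fixation_csv(exam, out / "fixation.csv")
    t = phantom.ground_truth
    return {
        "landmarks_oct_maia": str(out / "landmarks_oct_maia.csv"),
        "landmarks_maia_faf": str(out / "landmarks_maia_faf.csv"),
        "scanline_h": str(out / "scanline_h.csv"),
        "scanline_v": str(out / "scanline_v.csv"),
        "fixation": str(out / "fixation.csv"),
        "bar_px": t["scale_bar_px"],
        "bar_um": t["scale_bar_um"],
        "microns_per_degree": t["microns_per_degree"],
        "maia_px_per_deg": t["maia_px_per_deg"],
        "fixation_target_px": tuple(t["fixation_target_px"]),
    }


def _drift_velocity(t: np.ndarray, window_initial: float, drift_deg: float) -> float:
    """x-velocity (deg/s) making E[PRLf] − E[PRLi] equal ``drift_deg`` exactly."""
    in_window = t <= window_initial
    if not np.any(in_window):
        raise DomainError("no samples in the initial window; cannot calibrate drift")
    lever = float(t.mean() - t[in_window].mean())
    if lever <= 0:
        if drift_deg != 0:
            raise DomainError(
                "drift requires the exam to extend beyond the initial window"
            )
        return 0.0
    return drift_deg / lever


def make_fixation_exam(
    spec: FixationCloudSpec,
    fc_deg: tuple[float, float] = (0.0, 0.0),
    degree_scale: DegreeScale = DegreeScale(),
    eye: str = "OD",
    subject_id: str = "synthetic",
    visit: str = "baseline",
    fixation_loss_pct: float = 5.0,
    window_initial: float = 10.0,
) -> FixationSampleTable:
    """Draw a fixation exam around ``fc_deg`` + the programmed offset.

    Samples are in visual degrees in the in-memory (y-down) convention, at
    ``spec.rate`` Hz for ``n_samples / rate`` seconds.  The cloud is
    bivariate normal with the spec's moments; a second cluster is mixed in
    when ``cluster2_weight`` > 0; linear drift is calibrated so the expected
    PRLi→PRLf separation equals ``spec.drift`` microns.
    """
    rng = np.random.default_rng(spec.rng_seed)
    n = spec.n_samples
    t = np.arange(n, dtype=float) / spec.rate

    offset_deg = (
        spec.center_offset_from_fc[0] / degree_scale.microns_per_degree,
        spec.center_offset_from_fc[1] / degree_scale.microns_per_degree,
    )
    center = np.array([fc_deg[0] + offset_deg[0], fc_deg[1] + offset_deg[1]])

    sx, sy = spec.sigma
    cov = np.array([[sx * sx, spec.rho * sx * sy], [spec.rho * sx * sy, sy * sy]])
    xy = rng.multivariate_normal(center, cov, size=n, method="cholesky")

    if spec.cluster2_weight > 0.0:
        pick = rng.random(n) < spec.cluster2_weight
        xy[pick] += np.asarray(spec.cluster2_offset_deg)

    drift_deg = spec.drift / degree_scale.microns_per_degree
    v = _drift_velocity(t, window_initial, drift_deg)
    xy[:, 0] += v * t

    df = pd.DataFrame({"t": t, "x": xy[:, 0], "y": xy[:, 1]})
    return FixationSampleTable(
        samples=df,
        eye=eye,
        subject_id=subject_id,
        visit=visit,
        fixation_loss_pct=fixation_loss_pct,
        test_duration=n / spec.rate,
    )


def programmed_prl_truth(
    spec: FixationCloudSpec,
    fc_deg: tuple[float, float] = (0.0, 0.0),
    degree_scale: DegreeScale = DegreeScale(),
    window_initial: float = 10.0,
) -> dict:
    """Expected PRL positions and distances implied by a cloud spec.

    Deterministic (no sampling): the expectations of PRLi and PRLf under the
    generator's model, plus the programmed DFC and DPRL in microns.
    """
    mpd = degree_scale.microns_per_degree
    t = np.arange(spec.n_samples, dtype=float) / spec.rate
    in_window = t <= window_initial
    center = np.array(
        [
            fc_deg[0] + spec.center_offset_from_fc[0] / mpd,
            fc_deg[1] + spec.center_offset_from_fc[1] / mpd,
        ]
    )
    if spec.cluster2_weight > 0.0:
        center = center + spec.cluster2_weight * np.asarray(spec.cluster2_offset_deg)
    v = _drift_velocity(t, window_initial, spec.drift / mpd)
    prli = center + np.array([v * t[in_window].mean(), 0.0])
    prlf = center + np.array([v * t.mean(), 0.0])
    return {
        "prl_initial_deg": prli.tolist(),
        "prl_final_deg": prlf.tolist(),
        "dfc_um": float(np.hypot(*(prlf - np.asarray(fc_deg))) * mpd),
        "dprl_um": float(np.hypot(*(prlf - prli)) * mpd),
    }
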