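"""Landmark-based planar registration between en-face retinal frames.

The acquisition protocol produces the same fundus in three frames — the OCT
infrared en-face image, the microperimeter SLO image, and the 30° fundus
autofluorescence frame.  Rather than overlaying them by hand with a
transparency tool, this module estimates the planar map between two frames
from corresponding landmarks (vessel bifurcations, the optic-nerve
silhouette) by closed-form least squares and composes maps along the chain
OCT-IR → SLO → FAF into one common frame.

The default family is the 4-parameter similarity (uniform scale, rotation,
translation) — the degrees of freedom a manual overlay with zoom permits.
An affine fit (6 parameters) is available where modality distortion calls
for it.  Estimation is the closed-form orthogonal-Procrustes-with-scale
solution, so results are deterministic and exactly reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ArityError, ChainingError, DegeneracyError, DomainError
from .io_formats import LandmarkPairTable

__all__ = [
    "PlanarTransform",
    "estimate_transform",
    "apply_transform",
    "compose",
    "invert",
    "overlay_quality",
    "identity_transform",
]

_SINGULARITY_EPS = 1e-9


@dataclass(frozen=True)
class PlanarTransform:
    """A planar similarity or affine map between two named image frames.

    The map is stored as a 2×3 matrix ``M`` acting on homogeneous pixel
    coordinates: ``[x', y'] = M @ [x, y, 1]``.  For similarity transforms the
    scale/rotation/translation decomposition is exposed as properties.
    ``rms_residual`` is the root-mean-square landmark misfit after the fit
    (0 for transforms that were constructed rather than estimated).
    """

    kind: str  # "similarity" | "affine"
    matrix: np.ndarray
    src_frame: str = "src"
    dst_frame: str = "dst"
    rms_residual: float = 0.0
    n_landmarks: int = 0

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (2, 3):
            raise DomainError(f"transform matrix must be 2x3, got {m.shape}")
        object.__setattr__(self, "matrix", m)
        if self.kind not in ("similarity", "affine"):
            raise DomainError(f"kind must be similarity or affine, got {self.kind!r}")
        if not np.all(np.isfinite(m)):
            raise DomainError("transform matrix must be finite")
        if abs(np.linalg.det(m[:, :2])) <= _SINGULARITY_EPS:
            raise DegeneracyError("linear part of transform is singular")
        if not math.isfinite(self.rms_residual) or self.rms_residual < 0:
            raise DomainError(f"rms_residual must be finite and >= 0, got {self.rms_residual}")

    # -- similarity decomposition ------------------------------------------
    @property
    def scale(self) -> float:
        a = self.matrix[:, :2]
        return float(math.sqrt(abs(np.linalg.det(a))))

    @property
    def rotation(self) -> float:
        """Rotation angle in radians (y-down raster convention)."""
        return float(math.atan2(self.matrix[1, 0], self.matrix[0, 0]))

    @property
    def translation(self) -> tuple[float, float]:
        return float(self.matrix[0, 2]), float(self.matrix[1, 2])

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "matrix": self.matrix.tolist(),
            "src_frame": self.src_frame,
            "dst_frame": self.dst_frame,
            "rms_residual": float(self.rms_residual),
            "n_landmarks": int(self.n_landmarks),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "PlanarTransform":
        return cls(
            kind=payload["kind"],
            matrix=np.asarray(payload["matrix"], dtype=float),
            src_frame=payload.get("src_frame", "src"),
            dst_frame=payload.get("dst_frame", "dst"),
            rms_residual=float(payload.get("rms_residual", 0.0)),
            n_landmarks=int(payload.get("n_landmarks", 0)),
        )

    @classmethod
    def from_params(
        cls,
        scale: float = 1.0,
        rotation: float = 0.0,
        translation: tuple[float, float] = (0.0, 0.0),
        src_frame: str = "src",
        dst_frame: str = "dst",
    ) -> "PlanarTransform":
        """Build a similarity transform from its parameters."""
        if scale <= 0:
            raise DomainError(f"similarity scale must be positive, got {scale}")
        c, s = math.cos(rotation), math.sin(rotation)
        m = np.array(
            [[scale * c, -scale * s, translation[0]], [scale * s, scale * c, translation[1]]]
        )
        return cls(kind="similarity", matrix=m, src_frame=src_frame, dst_frame=dst_frame)


def identity_transform(frame: str = "common") -> PlanarTransform:
    return PlanarTransform.from_params(src_frame=frame, dst_frame=frame)


def _fit_similarity(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Closed-form least-squares similarity (Procrustes with scale, no reflection)."""
    mu_s = src.mean(axis=0)
    mu_d = dst.mean(axis=0)
    sc = src - mu_s
    dc = dst - mu_d
    var_s = float((sc**2).sum()) / len(src)
    if var_s <= _SINGULARITY_EPS:
        raise DegeneracyError("source landmarks have zero spread")
    cov = dc.T @ sc / len(src)
    u, sv, vt = np.linalg.svd(cov)
    d = np.ones(2)
    if np.linalg.det(u @ vt) < 0:
        d[-1] = -1.0
    rot = u @ np.diag(d) @ vt
    scale = float((sv * d).sum()) / var_s
    if scale <= 0:
        raise DegeneracyError("estimated similarity scale is nonpositive")
    t = mu_d - scale * rot @ mu_s
    return np.hstack([scale * rot, t[:, None]])


def _fit_affine(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    centered = src - src.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-7) < 2:
        raise DegeneracyError("affine estimation requires >= 3 non-collinear source landmarks")
    h = np.hstack([src, np.ones((len(src), 1))])
    coeffs, *_ = np.linalg.lstsq(h, dst, rcond=None)
    return coeffs.T  # 2x3


def estimate_transform(pairs: LandmarkPairTable, kind: str = "similarity") -> PlanarTransform:
    """Least-squares planar transform mapping source landmarks onto destination.

    Requires ≥ 2 pairs for a similarity and ≥ 3 non-collinear pairs for an
    affine fit.  On noise-free pairs generated by a transform of the requested
    family the parameters are recovered to machine precision and the residual
    is zero.
    """
    if kind not in ("similarity", "affine"):
        raise DomainError(f"kind must be similarity or affine, got {kind!r}")
    min_pairs = 2 if kind == "similarity" else 3
    if len(pairs) < min_pairs:
        raise ArityError(
            f"{kind} estimation needs at least {min_pairs} landmark pairs, got {len(pairs)}"
        )
    src = pairs.src()
    dst = pairs.dst()
    m = _fit_similarity(src, dst) if kind == "similarity" else _fit_affine(src, dst)
    mapped = src @ m[:, :2].T + m[:, 2]
    rms = float(np.sqrt(np.mean(np.sum((mapped - dst) ** 2, axis=1))))
    return PlanarTransform(
        kind=kind,
        matrix=m,
        src_frame=pairs.src_frame,
        dst_frame=pairs.dst_frame,
        rms_residual=rms,
        n_landmarks=len(pairs),
    )


def apply_transform(p, T: PlanarTransform):
    """Map a point ``(x, y)`` — or an (n, 2) array of points — through ``T``."""
    arr = np.asarray(p, dtype=float)
    single = arr.ndim == 1
    pts = np.atleast_2d(arr)
    if pts.shape[1] != 2:
        raise DomainError(f"points must be (x, y) pairs, got shape {arr.shape}")
    out = pts @ T.matrix[:, :2].T + T.matrix[:, 2]
    if single:
        return float(out[0, 0]), float(out[0, 1])
    return out


def compose(A: PlanarTransform, B: PlanarTransform) -> PlanarTransform:
    """The transform equivalent to applying ``A`` then ``B``.

    Frames must chain: ``A.dst_frame == B.src_frame``.  The result is affine
    if either input is affine.
    """
    if A.dst_frame != B.src_frame:
        raise ChainingError(
            f"cannot chain: first transform ends in frame {A.dst_frame!r} "
            f"but second starts in frame {B.src_frame!r}"
        )
    ha = np.vstack([A.matrix, [0.0, 0.0, 1.0]])
    hb = np.vstack([B.matrix, [0.0, 0.0, 1.0]])
    m = (hb @ ha)[:2, :]
    kind = "affine" if "affine" in (A.kind, B.kind) else "similarity"
    return PlanarTransform(kind=kind, matrix=m, src_frame=A.src_frame, dst_frame=B.dst_frame)


def invert(T: PlanarTransform) -> PlanarTransform:
    h = np.vstack([T.matrix, [0.0, 0.0, 1.0]])
    m = np.linalg.inv(h)[:2, :]
    return PlanarTransform(kind=T.kind, matrix=m, src_frame=T.dst_frame, dst_frame=T.src_frame)


def overlay_quality(T: PlanarTransform, max_rms: float = 2.0) -> str:
    """Accept or reject a registration by its residual: ``pass`` iff rms ≤ max_rms."""
    if max_rms < 0:
        raise DomainError(f"max_rms must be >= 0, got {max_rms}")
    return "pass" if T.rms_residual <= max_rms else "fail"
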