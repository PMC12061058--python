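"""Per-eye pixel-to-micron calibration from the image scale bar.

Distances are measured in pixels on the final common frame and must be
reported in microns.  The bridge is the 200 µm scale bar burned into the
autofluorescence export: measuring the bar's pixel length yields a "custom
ruler" (µm/px) for that eye.  A separate degree scale converts the
microperimeter's visual-degree radii (the 1° and 2° stability circles) into
the same micron space; the default of 288 µm/° is the emmetropic
schematic-eye approximation and is configurable because the device's internal
conversion is not published.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import DomainError

__all__ = ["ScaleRuler", "DegreeScale", "make_ruler", "px_to_um", "deg_to_um", "um_to_deg"]

DEFAULT_BAR_MICRONS = 200.0
DEFAULT_MICRONS_PER_DEGREE = 288.0


@dataclass(frozen=True)
class ScaleRuler:
    """Pixels-to-microns conversion derived from a scale bar.

    ``microns_per_pixel`` is exactly ``source_bar_microns / source_bar_pixels``.
    """

    microns_per_pixel: float
    source_bar_microns: float = DEFAULT_BAR_MICRONS
    source_bar_pixels: float = 0.0

    def __post_init__(self) -> None:
        for name in ("microns_per_pixel", "source_bar_microns"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise DomainError(f"{name} must be finite and positive, got {v}")
        if self.source_bar_pixels:
            if not math.isfinite(self.source_bar_pixels) or self.source_bar_pixels <= 0:
                raise DomainError(f"source_bar_pixels must be positive, got {self.source_bar_pixels}")


@dataclass(frozen=True)
class DegreeScale:
    """Visual degrees to microns on the retina (global, not per-eye)."""

    microns_per_degree: float = DEFAULT_MICRONS_PER_DEGREE

    def __post_init__(self) -> None:
        if not math.isfinite(self.microns_per_degree) or self.microns_per_degree <= 0:
            raise DomainError(
                f"microns_per_degree must be finite and positive, got {self.microns_per_degree}"
            )


def make_ruler(bar_pixels: float, bar_microns: float = DEFAULT_BAR_MICRONS) -> ScaleRuler:
    """Build the per-eye ruler from the measured pixel length of the scale bar.

    With the published example of a 200 µm bar spanning 23 px, the ruler is
    200/23 ≈ 8.696 µm/px.
    """
    if not math.isfinite(bar_pixels) or bar_pixels <= 0:
        raise DomainError(f"bar_pixels must be positive, got {bar_pixels}")
    if not math.isfinite(bar_microns) or bar_microns <= 0:
        raise DomainError(f"bar_microns must be positive, got {bar_microns}")
    return ScaleRuler(
        microns_per_pixel=bar_microns / bar_pixels,
        source_bar_microns=float(bar_microns),
        source_bar_pixels=float(bar_pixels),
    )


def px_to_um(d: float, ruler: ScaleRuler) -> float:
    """Convert a nonnegative pixel distance to microns with the per-eye ruler."""
    if not math.isfinite(d) or d < 0:
        raise DomainError(f"pixel distance must be finite and >= 0, got {d}")
    return d * ruler.microns_per_pixel


def deg_to_um(d: float, scale: DegreeScale = DegreeScale()) -> float:
    """Convert a nonnegative visual-degree distance to microns."""
    if not math.isfinite(d) or d < 0:
        raise DomainError(f"degree distance must be finite and >= 0, got {d}")
    return d * scale.microns_per_degree


def um_to_deg(d: float, scale: DegreeScale = DegreeScale()) -> float:
    """Inverse of :func:`deg_to_um`."""
    if not math.isfinite(d) or d < 0:
        raise DomainError(f"micron distance must be finite and >= 0, got {d}")
    return d / scale.microns_per_degree
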