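"""Inter-grader repeatability statistics.

Two graders independently measure the distance from foveal center (DFC) on
the same eyes; agreement is summarized by per-grader descriptives, the
Pearson product-moment correlation, and Bland–Altman bias with 95% limits of
agreement.  Conventions: differences are taken grader 2 minus grader 1,
standard deviations use the sample (n−1) denominator, and the limits of
agreement sit at bias ± 1.96 · SD(differences).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, InsufficientDataError, ValidationError

__all__ = ["PairedMeasurements", "AgreementResult", "summarize", "pearson", "bland_altman_plot"]

LOA_MULTIPLIER = 1.96


@dataclass
class PairedMeasurements:
    """The same quantity measured on each unit by two graders (µm)."""

    pairs: pd.DataFrame  # columns: id, g1, g2

    def __post_init__(self) -> None:
        for col in ("g1", "g2"):
            if col not in self.pairs.columns:
                raise ValidationError(f"paired table missing column {col!r}")
        if "id" not in self.pairs.columns:
            self.pairs = self.pairs.copy()
            self.pairs.insert(0, "id", [str(i + 1) for i in range(len(self.pairs))])
        arr = self.pairs[["g1", "g2"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValidationError("paired measurements must be finite")

    def __len__(self) -> int:
        return len(self.pairs)

    @classmethod
    def from_arrays(cls, g1, g2, ids=None) -> "PairedMeasurements":
        g1 = np.asarray(g1, dtype=float)
        g2 = np.asarray(g2, dtype=float)
        if g1.shape != g2.shape:
            raise ValidationError(f"grader arrays differ in length: {g1.shape} vs {g2.shape}")
        data = {"g1": g1, "g2": g2}
        if ids is not None:
            data = {"id": list(map(str, ids)), **data}
        return cls(pairs=pd.DataFrame(data))


@dataclass(frozen=True)
class AgreementResult:
    """Per-grader descriptives plus correlation and Bland–Altman agreement."""

    n: int
    mean_g1: float
    sd_g1: float
    range_g1: tuple[float, float]
    mean_g2: float
    sd_g2: float
    range_g2: tuple[float, float]
    pearson_r: float
    pearson_p: float
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mean_g1": self.mean_g1,
            "sd_g1": self.sd_g1,
            "range_g1": list(self.range_g1),
            "mean_g2": self.mean_g2,
            "sd_g2": self.sd_g2,
            "range_g2": list(self.range_g2),
            "pearson_r": self.pearson_r,
            "pearson_p": self.pearson_p,
            "bias": self.bias,
            "sd_diff": self.sd_diff,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
        }


def pearson(x, y) -> float:
    """Standard product-moment correlation of two equal-length sequences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DomainError(f"sequences differ in length: {x.shape} vs {y.shape}")
    if len(x) < 3:
        raise InsufficientDataError(f"correlation needs >= 3 pairs, got {len(x)}")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise DomainError("correlation undefined: a sequence has zero variance")
    r, _p = stats.pearsonr(x, y)
    return float(r)


def summarize(pairs: PairedMeasurements) -> AgreementResult:
    """Full agreement summary for a paired-grader table.

    Differences are grader 2 − grader 1; with identical measurements the
    bias, SD of differences and both limits of agreement are exactly zero
    and r = 1 (unless a grader has zero variance, which leaves the
    correlation undefined).
    """
    if len(pairs) < 3:
        raise InsufficientDataError(f"agreement summary needs >= 3 pairs, got {len(pairs)}")
    g1 = pairs.pairs["g1"].to_numpy(dtype=float)
    g2 = pairs.pairs["g2"].to_numpy(dtype=float)
    if np.std(g1) == 0.0 or np.std(g2) == 0.0:
        raise DomainError("correlation undefined: a grader has zero variance")
    diff = g2 - g1
    bias = float(np.mean(diff))
    sd_diff = float(np.std(diff, ddof=1))
    r, p = stats.pearsonr(g1, g2)
    return AgreementResult(
        n=len(pairs),
        mean_g1=float(np.mean(g1)),
        sd_g1=float(np.std(g1, ddof=1)),
        range_g1=(float(np.min(g1)), float(np.max(g1))),
        mean_g2=float(np.mean(g2)),
        sd_g2=float(np.std(g2, ddof=1)),
        range_g2=(float(np.min(g2)), float(np.max(g2))),
        pearson_r=float(r),
        pearson_p=float(p),
        bias=bias,
        sd_diff=sd_diff,
        loa_low=bias - LOA_MULTIPLIER * sd_diff,
        loa_high=bias + LOA_MULTIPLIER * sd_diff,
    )


def bland_altman_plot(pairs: PairedMeasurements, ax=None, units: str = "µm"):
    """Difference-versus-mean plot with the bias and 95% limits of agreement."""
    import matplotlib.pyplot as plt

    result = summarize(pairs)
    g1 = pairs.pairs["g1"].to_numpy(dtype=float)
    g2 = pairs.pairs["g2"].to_numpy(dtype=float)
    if ax is None:
        _fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter((g1 + g2) / 2.0, g2 - g1, color="k", zorder=3)
    ax.axhline(result.bias, color="tab:blue", label=f"bias = {result.bias:.2f} {units}")
    for loa in (result.loa_low, result.loa_high):
        ax.axhline(loa, color="tab:blue", linestyle=":")
    ax.set_xlabel(f"Mean of graders ({units})")
    ax.set_ylabel(f"Grader 2 − grader 1 ({units})")
    ax.legend(loc="best", frameon=False)
    return ax
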