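"""Small example datasets shipped with the package."""

from importlib import resources

import pandas as pd

from ..agreement_stats import PairedMeasurements

__all__ = ["load_grader_dfc", "load_paired_csv"]


def load_paired_csv(path) -> PairedMeasurements:
    """Read an ``id,g1,g2`` paired-measurement CSV (``#`` lines are comments)."""
    df = pd.read_csv(path, comment="#")
    return PairedMeasurements(pairs=df)


def load_grader_dfc() -> PairedMeasurements:
    """Distance-from-foveal-center measurements (µm) for nine eyes by two graders.

    The published inter-grader repeatability table for the eccentric-fixation
    measurement method; the basis of the agreement-statistics worked example.
    """
    with resources.as_file(
        resources.files(__package__) / "grader_dfc_pairs.csv"
    ) as p:
        return load_paired_csv(p)
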