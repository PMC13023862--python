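"""Packaged reference data.

Two small fixtures ship with the package: the combined normative summary of
the 180-participant neurotypical control cohort tested on the same
extraversion face-trait IAT (M = 0.082, SD = 0.405), and the published
per-case D-scores of the 36-participant developmental-prosopagnosia cohort,
used for single-case arithmetic.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .iat_io import NormativeSample, read_norms

__all__ = ["load_combined_control_norms", "load_dp_case_dscores"]


def _data_path(name: str):
    return resources.files("dpiat.data").joinpath(name)


def load_combined_control_norms() -> NormativeSample:
    """Normative D-score summary of the combined control cohort."""
    with resources.as_file(_data_path("combined_control_norms.yaml")) as p:
        return read_norms(p)


def load_dp_case_dscores() -> list[tuple[str, float]]:
    """Published (participant, D) pairs for the 36 DP cases."""
    with resources.as_file(_data_path("dp_case_dscores.tsv")) as p:
        df = pd.read_csv(p, sep="\t", dtype={"participant": str})
    return list(zip(df["participant"], df["d"].astype(float)))
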