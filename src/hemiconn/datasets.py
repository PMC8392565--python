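"""Packaged reference tables from the single-hemisphere case series.

Three small plain-text tables ship with the package: per-case demographics
and IQ indices, per-run temporal-mean framewise displacement, and
behavioral z-scores against published norms.  They are the inputs for the
descriptive-statistics and screening stages and let those stages be
exercised without access to the restricted imaging data.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _read(name: str) -> pd.DataFrame:
    with resources.files("hemiconn.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_demographics() -> pd.DataFrame:
    """Per-case demographics: group, etiology, age, FSIQ, VCI, POI."""
    return _read("demographics.tsv")


def load_fd_means() -> pd.DataFrame:
    """Per-case, per-run temporal-mean framewise displacement (mm).

    Single-run cases have NaN in the run2 column.
    """
    return _read("fd_means.tsv")


def load_screening_zscores() -> pd.DataFrame:
    """Behavioral z-scores (long form: case, measure, z); NaN where a
    measure was not administered."""
    wide = _read("screening_zscores.tsv")
    long = wide.melt(id_vars="case", var_name="measure", value_name="z")
    return long.dropna(subset=["z"]).reset_index(drop=True)
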