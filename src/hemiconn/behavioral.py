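"""Normative z-score screening and group descriptive statistics.

Behavioral instrument scores (mood, anxiety, social responsiveness,
empathizing/systemizing, emotional intelligence) are converted to z-scores
against user-supplied published normative means and SDs.  A score is
flagged atypical when it falls strictly more than 1.5 normative SDs from
the normative mean — "within 1.5 SD" is the typical range, boundary
included.  Group descriptives use the sample SD (n-1 denominator) and are
reported rounded to two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

ATYPICAL_SD_THRESHOLD = 1.5


@dataclass
class NormTable:
    """Measure name -> (normative mean, normative SD)."""

    norms: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for measure, (_, sd) in self.norms.items():
            if sd <= 0:
                raise ValueError(f"normative SD for {measure!r} must be positive")

    @classmethod
    def from_tsv(cls, path) -> "NormTable":
        df = pd.read_csv(path, sep="\t")
        required = {"measure", "mean", "sd"}
        if not required.issubset(df.columns):
            raise ValueError(f"norm table needs columns {sorted(required)}")
        return cls({str(r["measure"]): (float(r["mean"]), float(r["sd"])) for _, r in df.iterrows()})

    def to_tsv(self, path) -> None:
        rows = [(m, mu, sd) for m, (mu, sd) in self.norms.items()]
        pd.DataFrame(rows, columns=["measure", "mean", "sd"]).to_csv(path, sep="\t", index=False)


def to_zscore(score: float, measure: str, norms: NormTable) -> float:
    """z = (score - normative mean) / normative SD."""
    if measure not in norms.norms:
        raise KeyError(f"no norms for measure {measure!r}")
    mean, sd = norms.norms[measure]
    return (float(score) - mean) / sd


def flag_atypical(z: float, threshold: float = ATYPICAL_SD_THRESHOLD) -> bool:
    """True iff |z| strictly exceeds the threshold (default 1.5 SD)."""
    z = float(z)
    if not np.isfinite(z):
        raise ValueError("z-score must be finite")
    return abs(z) > threshold


def describe_group(values) -> tuple[float, float]:
    """Arithmetic mean and sample SD (n-1 denominator) of a group."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise ValueError("sample SD needs at least 2 values")
    return float(arr.mean()), float(arr.std(ddof=1))


def screen_scores(
    scores: pd.DataFrame, norms: NormTable, threshold: float = ATYPICAL_SD_THRESHOLD
) -> pd.DataFrame:
    """Screening table from raw scores: one row per case x measure.

    ``scores`` is long-form with columns case, measure, score.  Output adds
    z, atypical (bool) and an asterisk flag column.
    """
    required = {"case", "measure", "score"}
    if not required.issubset(scores.columns):
        raise ValueError(f"scores table needs columns {sorted(required)}")
    out = scores.copy()
    out["z"] = [
        to_zscore(r["score"], r["measure"], norms) for _, r in scores.iterrows()
    ]
    out["atypical"] = [flag_atypical(z, threshold) for z in out["z"]]
    out["flag"] = np.where(out["atypical"], "*", "")
    return out


def screen_zscores(
    zscores: pd.DataFrame, threshold: float = ATYPICAL_SD_THRESHOLD
) -> pd.DataFrame:
    """Apply the atypicality rule to already-computed z-scores.

    ``zscores`` is long-form with columns case, measure, z; missing entries
    (NaN) pass through unflagged.
    """
    required = {"case", "measure", "z"}
    if not required.issubset(zscores.columns):
        raise ValueError(f"z-score table needs columns {sorted(required)}")
    out = zscores.copy()
    out["atypical"] = [
        bool(flag_atypical(z, threshold)) if np.isfinite(z) else False for z in out["z"]
    ]
    out["flag"] = np.where(out["atypical"], "*", "")
    return out
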