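"""Inter-region correlation, Fisher z, run averaging, network summaries.

The core statistic of the analysis: Pearson correlations between ROI mean
time series are Fisher z transformed (z = arctanh r) before any averaging
or differencing, per-run matrices are averaged in z space when a subject
has two runs, and connectivity is summarized as the mean z over unordered
within-network pairs (ToM–ToM, PAIN–PAIN), over between-network pairs
(ToM–PAIN), and their difference (pooled within minus between) — one value
per subject, the quantity that indexes how distinct the two social-brain
networks are.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

NetworkMembership = dict  # roi name -> "ToM" | "PAIN"


@dataclass
class ZMatrix:
    """Symmetric Fisher-z matrix; the diagonal is undefined (NaN) and is
    excluded from every summary."""

    values: np.ndarray
    roi_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.roi_names)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match roi_names")
        off = ~np.eye(n, dtype=bool)
        if not np.isfinite(self.values[off]).all():
            raise ValueError("off-diagonal z values must be finite")
        if not np.allclose(self.values[off], self.values.T[off], atol=1e-12):
            raise ValueError("z matrix must be symmetric")
        vals = self.values.copy()
        np.fill_diagonal(vals, np.nan)
        self.values = vals

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.roi_names, columns=self.roi_names).to_csv(
            path, sep="\t"
        )

    @classmethod
    def from_tsv(cls, path) -> "ZMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(float), list(df.columns))


@dataclass
class NetworkSummary:
    """Mean Fisher-z within each network, between networks, and the
    pooled-within minus between difference."""

    within_tom: float
    within_pain: float
    between: float
    diff: float

    @property
    def within_tom_minus_between(self) -> float:
        return self.within_tom - self.between

    @property
    def within_pain_minus_between(self) -> float:
        return self.within_pain - self.between

    def as_dict(self) -> dict[str, float]:
        return {
            "within_tom": self.within_tom,
            "within_pain": self.within_pain,
            "between": self.between,
            "diff": self.diff,
        }


def correlation_matrix(values: np.ndarray, roi_names: list[str]) -> np.ndarray:
    """Pearson correlation across ROI columns (symmetric, unit diagonal)."""
    values = np.asarray(values, dtype=float)
    if values.shape[0] < 3:
        raise ValueError("correlation needs at least 3 volumes")
    sds = values.std(axis=0)
    flat = np.flatnonzero(sds == 0)
    if flat.size:
        raise ValueError(
            f"zero-variance ROI column(s): {[roi_names[i] for i in flat]}"
        )
    r = np.corrcoef(values, rowvar=False)
    return (r + r.T) / 2.0


def fisher_z(r: np.ndarray, roi_names: list[str]) -> ZMatrix:
    """Elementwise arctanh of the off-diagonal correlations.

    Correlations within 1e-12 of ±1 (legitimate on zero-noise synthetic
    fixtures) are clipped to ±(1 - 1e-12) with a warning; anything beyond
    ±1 is an error.
    """
    r = np.asarray(r, dtype=float)
    off = ~np.eye(r.shape[0], dtype=bool)
    if np.any(np.abs(r[off]) > 1 + 1e-12):
        raise ValueError("correlations outside [-1, 1]")
    clip_needed = np.abs(r[off]) > 1 - 1e-12
    if clip_needed.any():
        warnings.warn(
            f"{int(clip_needed.sum())} correlation(s) at ±1 clipped before arctanh",
            stacklevel=2,
        )
    z = np.arctanh(np.clip(r, -(1 - 1e-12), 1 - 1e-12))
    np.fill_diagonal(z, np.nan)
    return ZMatrix(z, list(roi_names))


def zmatrix_from_timeseries(ts) -> ZMatrix:
    """Convenience: Pearson matrix then Fisher z for one run."""
    return fisher_z(correlation_matrix(ts.values, ts.roi_names), ts.roi_names)


def average_runs(zs: list[ZMatrix]) -> ZMatrix:
    """Elementwise mean in z space across runs with identical ROI labels."""
    if not zs:
        raise ValueError("no matrices to average")
    names = zs[0].roi_names
    for z in zs[1:]:
        if z.roi_names != names:
            raise ValueError("ROI labels differ across runs")
    if len(zs) == 1:
        return replace(zs[0])
    stacked = np.stack([z.values for z in zs])
    return ZMatrix(stacked.mean(axis=0), list(names))


def _pair_indices(names: list[str], membership: NetworkMembership):
    unmapped = [n for n in names if n not in membership]
    if unmapped:
        raise ValueError(f"ROIs without network membership: {unmapped}")
    nets = [membership[n] for n in names]
    within = {"ToM": [], "PAIN": []}
    between = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if nets[i] == nets[j]:
                within[nets[i]].append((i, j))
            else:
                between.append((i, j))
    return within, between


def summarize_networks(z: ZMatrix, membership: NetworkMembership) -> NetworkSummary:
    """Unweighted pair means: within-ToM, within-PAIN, between, and the
    pooled within-minus-between difference.

    With 6 ToM and 7 PAIN regions the three means run over 15, 21 and 42
    unordered pairs respectively.
    """
    within, between = _pair_indices(z.roi_names, membership)
    for net, pairs in within.items():
        if not pairs:
            raise ValueError(f"network {net!r} has fewer than 2 ROIs; within mean undefined")
    if not between:
        raise ValueError("no between-network pairs")
    vals = z.values

    def mean_over(pairs):
        return float(np.mean([vals[i, j] for i, j in pairs]))

    within_tom = mean_over(within["ToM"])
    within_pain = mean_over(within["PAIN"])
    between_mean = mean_over(between)
    pooled_within = mean_over(within["ToM"] + within["PAIN"])
    return NetworkSummary(within_tom, within_pain, between_mean, pooled_within - between_mean)


@dataclass
class SubjectRecord:
    """Run-averaged connectivity bundle for one subject and ROI-set variant."""

    subject: str
    variant: str
    zmatrix: ZMatrix
    summary: NetworkSummary
    membership: NetworkMembership = field(default_factory=dict)
    qc: dict[str, float] = field(default_factory=dict)
    n_runs: int = 1

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "subject": self.subject,
                    "variant": self.variant,
                    "roi_names": self.zmatrix.roi_names,
                    "zmatrix": self.zmatrix.values.tolist(),
                    "summary": self.summary.as_dict(),
                    "membership": dict(self.membership),
                    "qc": dict(self.qc),
                    "n_runs": self.n_runs,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "SubjectRecord":
        with open(path) as fh:
            payload = json.load(fh)
        values = np.asarray(payload["zmatrix"], dtype=float)
        np.fill_diagonal(values, 0.0)  # placeholder; ZMatrix re-marks it NaN
        zm = ZMatrix(values, payload["roi_names"])
        s = payload["summary"]
        return cls(
            subject=payload["subject"],
            variant=payload["variant"],
            zmatrix=zm,
            summary=NetworkSummary(**s),
            membership=payload.get("membership", {}),
            qc=payload.get("qc", {}),
            n_runs=payload.get("n_runs", 1),
        )


def subject_report(
    run_tables: list,
    membership: NetworkMembership,
    variant: str,
    subject: str = "subject",
    qc: dict[str, float] | None = None,
) -> SubjectRecord:
    """Assemble one subject's record from per-run time-series tables."""
    if not run_tables:
        raise ValueError("at least one run is required")
    zs = [zmatrix_from_timeseries(ts) for ts in run_tables]
    zavg = average_runs(zs)
    summary = summarize_networks(zavg, membership)
    return SubjectRecord(
        subject=subject,
        variant=variant,
        zmatrix=zavg,
        summary=summary,
        membership=dict(membership),
        qc=dict(qc or {}),
        n_runs=len(run_tables),
    )


def summary_table(records: list[SubjectRecord]) -> pd.DataFrame:
    """One row per subject x variant: within_tom, within_pain, between, diff."""
    rows = [
        {
            "subject": r.subject,
            "variant": r.variant,
            **r.summary.as_dict(),
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=["subject", "variant", "within_tom", "within_pain", "between", "diff"])
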