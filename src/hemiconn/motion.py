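"""Head-motion quality control: framewise displacement and DVARS.

Two framewise-displacement (FD) conventions are implemented:

* Power — sum of absolute frame-to-frame changes of the six rigid
  parameters, rotations converted to arc length on a 50 mm head sphere:
  ``FD(t) = sum|Δtrans| + r_head * sum|Δrot|``.
* Jenkinson — root-mean-square displacement implied by the relative affine
  between consecutive volumes, averaged over an 80 mm sphere: with
  ``A = M_rel - I`` (linear deviation) and effective translation
  ``b = t_rel + A @ center``, ``FD(t) = sqrt(r²/5 · tr(AᵀA) + bᵀb)``.

Traces follow the FSL ``.par`` dialect: one row per volume, three rotations
in radians then three translations in mm, whitespace-separated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

POWER_HEAD_RADIUS_MM = 50.0
JENKINSON_SPHERE_RADIUS_MM = 80.0


@dataclass
class MotionTrace:
    """Six rigid-body parameters per volume (rot x/y/z rad, trans x/y/z mm)."""

    params: np.ndarray

    def __post_init__(self) -> None:
        self.params = np.atleast_2d(np.asarray(self.params, dtype=float))
        if self.params.shape[1] != 6:
            raise ValueError(f"expected 6 parameters per volume, got {self.params.shape[1]}")
        if self.params.shape[0] < 2:
            raise ValueError("a motion trace needs at least 2 volumes")
        if not np.isfinite(self.params).all():
            raise ValueError("motion parameters must be finite")

    @property
    def n_volumes(self) -> int:
        return self.params.shape[0]

    @property
    def rotations(self) -> np.ndarray:
        return self.params[:, :3]

    @property
    def translations(self) -> np.ndarray:
        return self.params[:, 3:]


@dataclass
class FDSeries:
    """Per-volume framewise displacement in mm; first element is 0."""

    values: np.ndarray
    method: str  # "power" | "jenkinson"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("FD series must be one-dimensional")
        if self.values.size and self.values[0] != 0:
            raise ValueError("FD of the first volume is 0 by convention")
        if np.any(self.values < 0):
            raise ValueError("framewise displacement is nonnegative")


def read_par(path) -> MotionTrace:
    return MotionTrace(np.loadtxt(path, ndmin=2))


def write_par(trace: MotionTrace, path) -> None:
    np.savetxt(path, trace.params, fmt="%.10g")


# ---------------------------------------------------------------------------
# rigid parameter <-> affine conversion

def _rotation_matrix(rx: float, ry: float, rz: float) -> np.ndarray:
    """R = Rz @ Ry @ Rx (x rotation applied first)."""
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def params_to_affines(
    trace: MotionTrace, center: tuple[float, float, float] = (0.0, 0.0, 0.0)
) -> np.ndarray:
    """(T, 4, 4) rigid affines: rotation about ``center``, then translation."""
    c = np.asarray(center, dtype=float)
    out = np.empty((trace.n_volumes, 4, 4))
    for t, (rx, ry, rz, tx, ty, tz) in enumerate(trace.params):
        R = _rotation_matrix(rx, ry, rz)
        A = np.eye(4)
        A[:3, :3] = R
        A[:3, 3] = np.array([tx, ty, tz]) + c - R @ c
        out[t] = A
    return out


def affines_to_params(
    affines: np.ndarray, center: tuple[float, float, float] = (0.0, 0.0, 0.0)
) -> MotionTrace:
    """Invert :func:`params_to_affines` (Euler extraction, |ry| < pi/2)."""
    affines = np.asarray(affines, dtype=float)
    c = np.asarray(center, dtype=float)
    params = np.empty((affines.shape[0], 6))
    for t, A in enumerate(affines):
        R = A[:3, :3]
        ry = np.arcsin(np.clip(-R[2, 0], -1.0, 1.0))
        rx = np.arctan2(R[2, 1], R[2, 2])
        rz = np.arctan2(R[1, 0], R[0, 0])
        trans = A[:3, 3] - c + R @ c
        params[t] = [rx, ry, rz, *trans]
    return MotionTrace(params)


# ---------------------------------------------------------------------------
# framewise displacement

def fd_power(trace: MotionTrace, head_radius: float = POWER_HEAD_RADIUS_MM) -> FDSeries:
    """Power FD: absolute sum of relative motions, rotations as arc length."""
    d = np.diff(trace.params, axis=0)
    fd = np.abs(d[:, 3:]).sum(axis=1) + head_radius * np.abs(d[:, :3]).sum(axis=1)
    return FDSeries(np.concatenate([[0.0], fd]), "power")


def fd_jenkinson(
    affines: np.ndarray,
    sphere_radius: float = JENKINSON_SPHERE_RADIUS_MM,
    center: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> FDSeries:
    """Jenkinson FD: RMS displacement of the relative affine over a sphere."""
    affines = np.asarray(affines, dtype=float)
    c = np.asarray(center, dtype=float)
    fd = np.zeros(affines.shape[0])
    for t in range(1, affines.shape[0]):
        try:
            rel = affines[t] @ np.linalg.inv(affines[t - 1])
        except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
            raise ValueError(f"singular affine at volume {t - 1}") from exc
        A = rel[:3, :3] - np.eye(3)
        b = rel[:3, 3] + A @ c
        fd[t] = np.sqrt(sphere_radius**2 / 5.0 * np.trace(A.T @ A) + b @ b)
    return FDSeries(fd, "jenkinson")


def dvars(bold: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """RMS of the temporal intensity difference over mask voxels; first 0."""
    bold = np.asarray(bold)
    mask = np.asarray(mask, dtype=bool)
    if bold.shape[:3] != mask.shape:
        raise ValueError("BOLD and mask grids do not match")
    if not mask.any():
        raise ValueError("DVARS mask is empty")
    series = bold[mask].astype(np.float64)  # (n_voxels, T)
    diffs = np.diff(series, axis=1)
    out = np.zeros(bold.shape[3])
    out[1:] = np.sqrt(np.mean(diffs**2, axis=0))
    return out


# ---------------------------------------------------------------------------
# summaries

def temporal_mean_fd(fd: FDSeries) -> float:
    """Arithmetic mean of the FD series (including the leading 0)."""
    if fd.values.size == 0:
        raise ValueError("empty FD series")
    return float(fd.values.mean())


def mean_over_runs(values: list[float]) -> float:
    """Cross-run mean of per-run temporal-mean FD values."""
    if not values:
        raise ValueError("no per-run values supplied")
    return float(np.mean(values))


def qc_table(per_case_runs: dict[str, list[float]]) -> pd.DataFrame:
    """Per-case motion table: run1, run2, mean over runs (2-decimal report).

    Cases with a single run get NaN in the run2 and mean columns, mirroring
    how single-run subjects are reported.
    """
    rows = []
    for case, runs in per_case_runs.items():
        if not runs:
            raise ValueError(f"case {case!r} has no runs")
        run1 = runs[0]
        run2 = runs[1] if len(runs) > 1 else np.nan
        mean = mean_over_runs(runs) if len(runs) > 1 else np.nan
        rows.append((case, run1, run2, mean))
    df = pd.DataFrame(rows, columns=["case", "run1", "run2", "mean_runs"])
    return df.round(2)
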