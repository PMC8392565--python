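"""Synthetic BOLD phantom with a planted two-network covariance structure.

Real single-hemisphere patient data are access-restricted, so every
downstream stage of the pipeline is exercised against a phantom with known
ground truth:

* an ellipsoidal "brain" on a symmetric RAS+ grid, optionally with one
  hemisphere removed (hemispherectomy);
* 13 sphere ROIs — 6 Theory-of-Mind, 7 pain-matrix — at anatomically
  plausible world coordinates, bilateral pairs being exact x-mirrors;
* BOLD runs in which every voxel of ROI *i* carries
  ``signal_i(t) + voxel noise + slow drift`` where
  ``signal_i = sqrt(w)·latent_network + sqrt(1-w)·private_i``.  Choosing
  ``w = within_corr`` makes every same-network ROI-signal pair correlate at
  exactly ``within_corr``, and the latent ToM–PAIN correlation is set so
  cross-network ROI pairs correlate at ``between_corr``;
* random-walk head-motion traces with matching rigid-body affines.

Averaging an ROI over *n* voxels attenuates the measurable correlation by
``1/(1 + sd²/n)`` (independent voxel noise of variance sd² against
unit-variance signal); :func:`expected_pairwise_correlation` is the
closed-form oracle the recovery tests compare against.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .grid import ImageGrid
from .motion import MotionTrace, params_to_affines
from .rois import ROIDefinition, ROISet

HEMISPHERE_CHOICES = ("none", "left", "right")

#: Canonical ROI centers (world mm) for the default phantom, MNI-flavored but
#: shrunk so a 9 mm sphere fits inside the default ellipsoid semiaxes.
_CANONICAL_ROIS: list[tuple[str, str, str, tuple[float, float, float]]] = [
    ("dMPFC", "ToM", "midline", (0.0, 48.0, 28.0)),
    ("mMPFC", "ToM", "midline", (0.0, 50.0, 10.0)),
    ("vMPFC", "ToM", "midline", (0.0, 44.0, -12.0)),
    ("PC", "ToM", "midline", (0.0, -52.0, 30.0)),
    ("LTPJ", "ToM", "left", (-40.0, -44.0, 12.0)),
    ("RTPJ", "ToM", "right", (40.0, -44.0, 12.0)),
    ("AMCC", "PAIN", "midline", (0.0, 14.0, 36.0)),
    ("LInsula", "PAIN", "left", (-34.0, 8.0, 2.0)),
    ("RInsula", "PAIN", "right", (34.0, 8.0, 2.0)),
    ("LMFG", "PAIN", "left", (-35.0, 30.0, 22.0)),
    ("RMFG", "PAIN", "right", (35.0, 30.0, 22.0)),
    ("LS2", "PAIN", "left", (-42.0, -20.0, 16.0)),
    ("RS2", "PAIN", "right", (42.0, -20.0, 16.0)),
]

_DEFAULT_SEMIAXES = (70.0, 85.0, 65.0)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of the synthetic head.

    The grid is symmetric about the world plane x = 0 (odd default dims put
    a voxel plane exactly on the midline), matching the functional space's
    2.5 mm isotropic resolution.
    """

    grid_dims: tuple[int, int, int] = (61, 73, 57)
    voxel_size: float = 2.5
    brain_semiaxes: tuple[float, float, float] = _DEFAULT_SEMIAXES
    removed_hemisphere: str = "none"

    def __post_init__(self) -> None:
        if self.removed_hemisphere not in HEMISPHERE_CHOICES:
            raise ValueError(
                f"removed_hemisphere must be one of {HEMISPHERE_CHOICES}, "
                f"got {self.removed_hemisphere!r}"
            )
        if any(a <= 0 for a in self.brain_semiaxes):
            raise ValueError("brain semiaxes must be positive")
        grid = self.grid
        half_extent = [
            (d - 1) / 2.0 * self.voxel_size for d in self.grid_dims
        ]
        if any(a > h for a, h in zip(self.brain_semiaxes, half_extent)):
            raise ValueError(
                f"brain semiaxes {self.brain_semiaxes} exceed grid half-extents "
                f"{tuple(half_extent)}"
            )
        if not grid.is_x_symmetric:
            raise ValueError("phantom grid must be symmetric about x = 0")

    @property
    def grid(self) -> ImageGrid:
        return ImageGrid.symmetric(self.grid_dims, self.voxel_size)


@dataclass
class Phantom:
    """Binary brain mask plus hemisphere labels on a shared grid.

    ``hemi_labels``: 0 outside brain, 1 left (x<0), 2 right (x>0),
    3 midline plane (x == 0).
    """

    grid: ImageGrid
    brain_mask: np.ndarray
    hemi_labels: np.ndarray
    spec: PhantomSpec

    @property
    def n_brain_voxels(self) -> int:
        return int(self.brain_mask.sum())


def generate_phantom(spec: PhantomSpec, seed: int | None = None) -> Phantom:
    """Ellipsoidal brain mask with hemisphere labels; optionally one-sided.

    The seed is accepted for interface symmetry; the phantom itself is
    deterministic geometry.
    """
    grid = spec.grid
    x, y, z = grid.coordinate_volumes()
    a, b, c = spec.brain_semiaxes
    brain = (x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2 <= 1.0

    labels = np.zeros(grid.dims, dtype=np.uint8)
    labels[brain & (x < 0)] = 1
    labels[brain & (x > 0)] = 2
    labels[brain & (x == 0)] = 3

    if spec.removed_hemisphere != "none":
        code = 1 if spec.removed_hemisphere == "left" else 2
        removed = labels == code
        brain = brain & ~removed
        labels[removed] = 0
    return Phantom(grid, brain, labels, spec)


def generate_roi_definitions(spec: PhantomSpec) -> list[ROIDefinition]:
    """The 13 packaged social-brain ROI definitions, scaled to the phantom.

    Centers are scaled with the ellipsoid semiaxes so spheres always fit in
    the brain; bilateral pairs stay exact x-mirrors under that scaling.
    """
    scale = np.asarray(spec.brain_semiaxes) / np.asarray(_DEFAULT_SEMIAXES)
    defs = []
    for name, network, laterality, center in _CANONICAL_ROIS:
        scaled = tuple(float(c * s) for c, s in zip(center, scale))
        defs.append(ROIDefinition(name, network, laterality, scaled, radius=9.0))
    return defs


@dataclass(frozen=True)
class SignalModel:
    """Parameters of the planted two-network BOLD signal.

    within_corr may be one value for both networks or a ``{network: value}``
    mapping; between_corr is the target correlation between ROI signals of
    different networks (the latent-latent correlation is derived from it).
    Noise and drift amplitudes are in units of the ROI signal SD (1.0).
    """

    n_volumes: int = 400
    tr: float = 0.7
    within_corr: float | dict[str, float] = 0.6
    between_corr: float = 0.1
    voxel_noise_sd: float = 1.0
    drift_amplitude: float = 1.0
    drift_period: float | None = None  # volumes; default 4 * n_volumes

    def __post_init__(self) -> None:
        if self.n_volumes < 2:
            raise ValueError("n_volumes must be at least 2")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        for net, w in self.within_by_network().items():
            if not 0 <= w < 1:
                raise ValueError(f"within_corr[{net}] must lie in [0, 1), got {w}")
        w1, w2 = self.within_by_network().values()
        limit = np.sqrt(w1 * w2)
        if abs(self.between_corr) > limit + 1e-12:
            raise ValueError(
                f"|between_corr| cannot exceed sqrt(w_ToM*w_PAIN) = {limit:.4f}"
            )
        if self.voxel_noise_sd < 0 or self.drift_amplitude < 0:
            raise ValueError("noise and drift amplitudes must be nonnegative")

    def within_by_network(self) -> dict[str, float]:
        if isinstance(self.within_corr, dict):
            out = {"ToM": float(self.within_corr["ToM"]), "PAIN": float(self.within_corr["PAIN"])}
        else:
            out = {"ToM": float(self.within_corr), "PAIN": float(self.within_corr)}
        return out

    @property
    def latent_corr(self) -> float:
        """ToM–PAIN latent correlation yielding ``between_corr`` ROI pairs."""
        w1, w2 = self.within_by_network().values()
        denom = np.sqrt(w1 * w2)
        return 0.0 if denom == 0 else float(self.between_corr / denom)

    @property
    def effective_drift_period(self) -> float:
        # A sub-cycle drift within one run: slow enough that the sigma=143
        # running-line highpass removes it almost entirely.
        return float(self.drift_period if self.drift_period else 4 * self.n_volumes)


@dataclass
class GroundTruth:
    """What was planted: latent signals, mixing weights, expected correlations."""

    latent_signals: np.ndarray  # (2, T): row 0 ToM, row 1 PAIN
    roi_mixing: dict[str, float]  # name -> sqrt(within_corr) shared-signal weight
    expected_corr: np.ndarray  # signal-level (noise-free) ROI-pair correlations
    roi_names: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "roi_names": self.roi_names,
                    "roi_mixing": self.roi_mixing,
                    "latent_signals": self.latent_signals.tolist(),
                    "expected_corr": self.expected_corr.tolist(),
                },
                fh,
            )


def _signal_level_corr(model: SignalModel, networks: list[str]) -> np.ndarray:
    w = model.within_by_network()
    n = len(networks)
    rho = np.empty((n, n))
    for i, ni in enumerate(networks):
        for j, nj in enumerate(networks):
            if i == j:
                rho[i, j] = 1.0
            elif ni == nj:
                rho[i, j] = w[ni]
            else:
                rho[i, j] = model.between_corr
    return rho


def expected_pairwise_correlation(
    model: SignalModel,
    voxels_per_roi: int | np.ndarray,
    networks: list[str] | None = None,
) -> np.ndarray:
    """Closed-form expected Pearson correlation between extracted ROI means.

    Averaging *n* voxels with iid noise of variance sd² against unit-variance
    signal leaves residual noise variance sd²/n, shrinking each pair's
    correlation by ``1/sqrt((1+sd²/n_i)(1+sd²/n_j))`` — the attenuation
    vanishes as the voxel count grows.
    """
    if networks is None:
        networks = [net for _, net, _, _ in _CANONICAL_ROIS]
    nvox = np.atleast_1d(np.asarray(voxels_per_roi, dtype=float))
    if nvox.size == 1:
        nvox = np.full(len(networks), nvox[0])
    if nvox.size != len(networks) or np.any(nvox <= 0):
        raise ValueError("voxels_per_roi must be positive, one value or one per ROI")
    atten = 1.0 / np.sqrt(1.0 + model.voxel_noise_sd**2 / nvox)
    rho = _signal_level_corr(model, networks)
    out = rho * np.outer(atten, atten)
    np.fill_diagonal(out, 1.0)
    return out


def simulate_bold(
    phantom: Phantom,
    roi_set: ROISet,
    model: SignalModel,
    seed: int,
) -> tuple[np.ndarray, GroundTruth]:
    """4-D BOLD (x, y, z, t) float32 with the planted network structure.

    Every in-ROI voxel carries its ROI's signal plus iid voxel noise plus a
    slow sinusoidal drift (one drift phase per ROI, so that at zero noise
    all voxels of an ROI are identical); out-of-ROI brain voxels carry noise
    plus drift with per-voxel phase; out-of-brain voxels are zero.
    """
    grid = phantom.grid
    names = roi_set.names
    roi_arrays = [roi_set.masks[n].data for n in names]
    networks = [roi_set.masks[n].network for n in names]

    stacked = np.zeros(grid.dims, dtype=np.int16)
    for arr in roi_arrays:
        if not np.all(phantom.brain_mask[arr]):
            raise ValueError("ROI masks must lie inside the phantom brain")
        stacked += arr
    if np.any(stacked > 1):
        raise ValueError("overlapping ROIs: planted covariance is undefined")

    rng = np.random.default_rng(seed)
    T = model.n_volumes
    w = model.within_by_network()

    # latents with the derived ToM-PAIN correlation via a 2x2 Cholesky factor
    raw = rng.standard_normal((2, T))
    rho_l = model.latent_corr
    chol = np.linalg.cholesky(np.array([[1.0, rho_l], [rho_l, 1.0]]))
    latents = chol @ raw

    private = rng.standard_normal((len(names), T))
    net_index = {"ToM": 0, "PAIN": 1}
    signals = np.empty((len(names), T))
    mixing: dict[str, float] = {}
    for i, (name, net) in enumerate(zip(names, networks)):
        wi = w[net]
        signals[i] = np.sqrt(wi) * latents[net_index[net]] + np.sqrt(1.0 - wi) * private[i]
        mixing[name] = float(np.sqrt(wi))

    roi_phases = rng.uniform(0.0, 2.0 * np.pi, size=len(names))

    brain_idx = np.nonzero(phantom.brain_mask)
    n_brain = brain_idx[0].size
    voxel_phases = rng.uniform(0.0, 2.0 * np.pi, size=n_brain)

    # per-voxel series assembled in (voxel, time) layout
    series = rng.standard_normal((n_brain, T), dtype=np.float32)
    series *= np.float32(model.voxel_noise_sd)

    t = np.arange(T)
    omega = 2.0 * np.pi / model.effective_drift_period
    sin_t = np.sin(omega * t).astype(np.float32)
    cos_t = np.cos(omega * t).astype(np.float32)

    flat_roi = np.zeros(n_brain, dtype=np.int32)  # 0 = background, i+1 = ROI i
    flat_index = np.full(grid.dims, -1, dtype=np.int64)
    flat_index[brain_idx] = np.arange(n_brain)
    for i, arr in enumerate(roi_arrays):
        flat_roi[flat_index[arr]] = i + 1
        voxel_phases[flat_index[arr]] = roi_phases[i]

    amp = np.float32(model.drift_amplitude)
    series += amp * (
        np.cos(voxel_phases)[:, None].astype(np.float32) * sin_t[None, :]
        + np.sin(voxel_phases)[:, None].astype(np.float32) * cos_t[None, :]
    )
    for i in range(len(names)):
        sel = flat_roi == i + 1
        series[sel] += signals[i].astype(np.float32)[None, :]

    bold = np.zeros(grid.dims + (T,), dtype=np.float32)
    bold[brain_idx] = series

    truth = GroundTruth(
        latent_signals=latents,
        roi_mixing=mixing,
        expected_corr=_signal_level_corr(model, networks),
        roi_names=list(names),
    )
    return bold, truth


def simulate_motion(
    n_volumes: int,
    step_sd_trans: float = 0.03,
    step_sd_rot: float = 3e-4,
    spike_prob: float = 0.01,
    seed: int = 0,
) -> tuple[MotionTrace, np.ndarray]:
    """Random-walk 6-parameter head motion plus the per-volume rigid affines.

    Step SDs give a temporal-mean framewise displacement on the order of
    0.1 mm, matching quiet adult subjects; occasional spikes are 10x steps.
    Returns the trace (rotations rad, translations mm, FSL .par order) and a
    (T, 4, 4) stack of affines composed from the parameters at each volume.
    """
    if n_volumes < 2:
        raise ValueError("n_volumes must be at least 2")
    if step_sd_trans < 0 or step_sd_rot < 0:
        raise ValueError("step standard deviations must be nonnegative")
    if not 0 <= spike_prob <= 1:
        raise ValueError("spike_prob must be a probability")
    rng = np.random.default_rng(seed)
    sds = np.array([step_sd_rot] * 3 + [step_sd_trans] * 3)
    steps = rng.standard_normal((n_volumes, 6)) * sds
    spikes = rng.random(n_volumes) < spike_prob
    steps[spikes] *= 10.0
    steps[0] = 0.0
    params = np.cumsum(steps, axis=0)
    trace = MotionTrace(params)
    return trace, params_to_affines(trace)
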