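"""Shared fixtures: small geometry grids, the default phantom, and one
session-scoped planted-covariance recovery study reused by the connectivity
and acceptance tests (simulating it once keeps the suite fast)."""

from __future__ import annotations

import numpy as np
import pytest

import hemiconn as hc


def brute_force_correlation(values: np.ndarray) -> np.ndarray:
    """Independent two-pass Pearson correlation oracle.

    Deliberately written with explicit per-pair loops and two passes
    (means first, then cross-products) so it shares no code path with the
    package's matrix implementation.
    """
    values = np.asarray(values, dtype=float)
    T, n = values.shape
    means = [sum(values[:, j]) / T for j in range(n)]
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            xi = values[:, i] - means[i]
            xj = values[:, j] - means[j]
            cov = sum(xi * xj)
            sdi = sum(xi * xi) ** 0.5
            sdj = sum(xj * xj) ** 0.5
            out[i, j] = out[j, i] = cov / (sdi * sdj)
    return out


@pytest.fixture(scope="session")
def small_grid() -> hc.ImageGrid:
    """Tiny symmetric grid for geometry tests (odd dims: a voxel plane at x=0)."""
    return hc.ImageGrid.symmetric((11, 9, 7), voxel_size=2.0)


@pytest.fixture(scope="session")
def phantom() -> hc.Phantom:
    return hc.generate_phantom(hc.PhantomSpec())


@pytest.fixture(scope="session")
def roi_definitions(phantom):
    return hc.generate_roi_definitions(phantom.spec)


@pytest.fixture(scope="session")
def bilateral_set(phantom, roi_definitions) -> hc.ROISet:
    return hc.build_roi_set(roi_definitions, phantom.grid, "bilateral")


@pytest.fixture(scope="session")
def mini_phantom() -> hc.Phantom:
    """Small head phantom for long-run simulations that would not fit in
    memory on the full-size grid."""
    spec = hc.PhantomSpec(grid_dims=(31, 37, 29), brain_semiaxes=(34.0, 42.0, 32.0))
    return hc.generate_phantom(spec)


@pytest.fixture(scope="session")
def mini_roiset(mini_phantom) -> hc.ROISet:
    """Six compact ROIs (3 ToM, 3 PAIN) fitting inside the mini phantom."""
    defs = [
        hc.ROIDefinition("tom_mid", "ToM", "midline", (0.0, 20.0, 10.0), radius=6.0),
        hc.ROIDefinition("tom_L", "ToM", "left", (-15.0, -20.0, 5.0), radius=6.0),
        hc.ROIDefinition("tom_R", "ToM", "right", (15.0, -20.0, 5.0), radius=6.0),
        hc.ROIDefinition("pain_mid", "PAIN", "midline", (0.0, -25.0, -5.0), radius=6.0),
        hc.ROIDefinition("pain_L", "PAIN", "left", (-15.0, 15.0, 8.0), radius=6.0),
        hc.ROIDefinition("pain_R", "PAIN", "right", (15.0, 15.0, 8.0), radius=6.0),
    ]
    return hc.build_roi_set(defs, mini_phantom.grid, "bilateral")


@pytest.fixture(scope="session")
def planted_recovery(phantom, roi_definitions, bilateral_set):
    """Ten-seed planted-covariance study at the study conditions:
    within-network correlation 0.6, between 0.1, 13 ROIs (~200 voxels each),
    400 volumes.  Returns per-seed network summaries for the bilateral,
    left and right ROI-set variants plus the analytic expectations."""
    model = hc.SignalModel()  # defaults are the study conditions
    variant_sets = {
        v: hc.make_lateralized_set(bilateral_set, v) for v in ("bilateral", "left", "right")
    }
    summaries: dict[str, list[hc.NetworkSummary]] = {v: [] for v in variant_sets}
    for seed in range(10):
        bold, _ = hc.simulate_bold(phantom, bilateral_set, model, seed=seed)
        for variant, vset in variant_sets.items():
            ts = hc.extract_mean_timeseries(bold, vset, tr=model.tr)
            ts = hc.gaussian_highpass(ts)
            z = hc.zmatrix_from_timeseries(ts)
            summaries[variant].append(hc.summarize_networks(z, vset.membership))
        del bold

    nvox = np.array([m.n_voxels for m in bilateral_set.masks.values()])
    expected_r = hc.expected_pairwise_correlation(model, nvox)
    names = bilateral_set.names
    nets = [bilateral_set.masks[n].network for n in names]
    within_pairs = [
        (i, j) for i in range(len(names)) for j in range(i + 1, len(names)) if nets[i] == nets[j]
    ]
    between_pairs = [
        (i, j) for i in range(len(names)) for j in range(i + 1, len(names)) if nets[i] != nets[j]
    ]
    expected_within_z = float(np.mean([np.arctanh(expected_r[i, j]) for i, j in within_pairs]))
    expected_between_z = float(np.mean([np.arctanh(expected_r[i, j]) for i, j in between_pairs]))
    return {
        "summaries": summaries,
        "expected_within_z": expected_within_z,
        "expected_between_z": expected_between_z,
        "n_within_tom_pairs": sum(1 for i, j in within_pairs if nets[i] == "ToM"),
        "n_within_pain_pairs": sum(1 for i, j in within_pairs if nets[i] == "PAIN"),
    }


def pooled_within(summary: hc.NetworkSummary, n_tom_pairs: int = 15, n_pain_pairs: int = 21) -> float:
    """Pair-weighted pooled within-network mean from the two within means."""
    total = n_tom_pairs + n_pain_pairs
    return (n_tom_pairs * summary.within_tom + n_pain_pairs * summary.within_pain) / total
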