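"""Config-driven end-to-end execution of the connectivity analysis.

One YAML (or dict) config drives: phantom/BOLD generation or file
ingestion, ROI-set variant construction, extraction and temporal
filtering, motion QC, Fisher-z connectivity with network summaries, and
behavioral screening.  All randomness flows from a single seed; rerunning
with the same config reproduces every output byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, behavioral, connectivity, datasets, motion, rois, synthetic, timeseries

log = logging.getLogger(__name__)

_VALID_VARIANTS = set(rois.VARIANTS)


@dataclass
class RunConfig:
    """Everything one pipeline run needs; see ``validate_config``."""

    mode: str = "synthetic"  # "synthetic" | "files"
    out_dir: str = "hemiconn_out"
    seed: int = 0
    subject: str = "SYN1"
    variants: list[str] = field(default_factory=lambda: ["bilateral", "left", "right"])
    n_runs: int = 2
    # synthetic mode
    phantom: dict = field(default_factory=dict)  # PhantomSpec overrides
    signal: dict = field(default_factory=dict)  # SignalModel overrides
    motion: dict = field(default_factory=dict)  # simulate_motion overrides
    save_bold: bool = False
    # files mode
    bold_paths: list[str] = field(default_factory=list)
    par_paths: list[str] = field(default_factory=list)
    roi_table: str | None = None
    tr: float = 0.7
    # filtering
    highpass: bool = True
    highpass_sigma: float = 143.0
    regress_motion: bool = False
    # screening
    screening_zscores: str | None = None  # TSV path; None -> packaged table

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        problems = validate_config(payload)
        if problems:
            raise ValueError("invalid config:\n" + "\n".join(f"- {p}" for p in problems))
        return cls(**payload)


_KNOWN_KEYS = set(RunConfig.__dataclass_fields__)


def validate_config(payload: dict) -> list[str]:
    """List configuration problems; an empty list means the config is usable.

    Purely a reporting operation: never mutates state or touches outputs.
    """
    problems: list[str] = []
    unknown = set(payload) - _KNOWN_KEYS
    for key in sorted(unknown):
        problems.append(f"unknown config key {key!r}")
    mode = payload.get("mode", "synthetic")
    if mode not in ("synthetic", "files"):
        problems.append(f"mode must be 'synthetic' or 'files', got {mode!r}")
    for variant in payload.get("variants", []):
        if variant not in _VALID_VARIANTS:
            problems.append(
                f"unknown ROI-set variant {variant!r}; allowed: {sorted(_VALID_VARIANTS)}"
            )
    if payload.get("n_runs", 1) < 1:
        problems.append("n_runs must be >= 1")
    if payload.get("highpass_sigma", 143.0) <= 0:
        problems.append("highpass_sigma must be positive")
    if payload.get("tr", 0.7) <= 0:
        problems.append("tr must be positive")
    phantom = payload.get("phantom", {})
    signal = payload.get("signal", {})
    for spec_cls, overrides, label in (
        (synthetic.PhantomSpec, phantom, "phantom"),
        (synthetic.SignalModel, signal, "signal"),
    ):
        try:
            spec_cls(**overrides)
        except (TypeError, ValueError) as exc:
            problems.append(f"{label}: {exc}")
    if mode == "files":
        if not payload.get("bold_paths"):
            problems.append("files mode requires bold_paths")
        for key in ("bold_paths", "par_paths"):
            for p in payload.get(key, []):
                if not Path(p).exists():
                    problems.append(f"{key}: missing file {p}")
        roi_table = payload.get("roi_table")
        if roi_table and not Path(roi_table).exists():
            problems.append(f"roi_table: missing file {roi_table}")
    screening = payload.get("screening_zscores")
    if screening and not Path(screening).exists():
        problems.append(f"screening_zscores: missing file {screening}")
    return problems


class StageError(RuntimeError):
    """Pipeline failure tagged with the stage that raised it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _stage(stage: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write the output bundle; returns the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    if config.mode == "synthetic":
        runs, traces, grid, roi_defs, brain_mask, variants = _stage(
            "simulate", _synthesize_runs, config, out, outputs
        )
    else:
        runs, traces, grid, roi_defs, brain_mask = _stage(
            "ingest", _load_runs, config
        )
        variants = list(config.variants)

    variant_sets = _stage("build-rois", _build_variants, variants, roi_defs, grid, out, outputs)

    qc_summary = _stage("qc", _run_qc, config, runs, traces, brain_mask, out, outputs)

    records = _stage(
        "connect", _run_connectivity, config, runs, variant_sets, qc_summary, out, outputs
    )

    _stage("screen", _run_screening, config, out, outputs)

    provenance = {
        "package": "hemiconn",
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "outputs": outputs,
        "n_subject_records": len(records),
    }
    prov_path = out / "provenance.json"
    with open(prov_path, "w") as fh:
        json.dump(provenance, fh, indent=2, default=str)
    log.info("pipeline finished; provenance at %s", prov_path)
    return provenance


# ---------------------------------------------------------------------------
# stages

def _synthesize_runs(config: RunConfig, out: Path, outputs: dict):
    spec = synthetic.PhantomSpec(**config.phantom)
    phantom = synthetic.generate_phantom(spec)
    model = synthetic.SignalModel(**config.signal)
    roi_defs = synthetic.generate_roi_definitions(spec)

    # On a hemispherectomized phantom only the intact hemisphere's variant
    # is simulable (and analyzable): lateral ROIs of the removed side fall
    # outside the brain, so their columns would have zero variance.
    sim_variant = "bilateral"
    variants = list(config.variants)
    if spec.removed_hemisphere != "none":
        sim_variant = "left" if spec.removed_hemisphere == "right" else "right"
        if variants != [sim_variant]:
            log.info(
                "restricting variants to %r on a %s-hemispherectomized phantom",
                sim_variant,
                spec.removed_hemisphere,
            )
            variants = [sim_variant]
    grid = phantom.grid
    sim_set = rois.build_roi_set(roi_defs, grid, sim_variant)

    ss = np.random.SeedSequence(config.seed)
    run_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(2 * config.n_runs)]

    runs, traces = [], []
    for r in range(config.n_runs):
        bold, truth = synthetic.simulate_bold(phantom, sim_set, model, run_seeds[2 * r])
        trace, _ = synthetic.simulate_motion(
            model.n_volumes, seed=run_seeds[2 * r + 1], **config.motion
        )
        run_id = f"run{r + 1}"
        truth_path = out / f"ground_truth_{run_id}.json"
        truth.to_json(truth_path)
        outputs[f"ground_truth_{run_id}"] = str(truth_path)
        par_path = out / f"motion_{run_id}.par"
        motion.write_par(trace, par_path)
        outputs[f"motion_{run_id}"] = str(par_path)
        if config.save_bold:
            bold_path = out / f"bold_{run_id}.nii.gz"
            rois.save_volume(bold, grid, bold_path)
            outputs[f"bold_{run_id}"] = str(bold_path)
        runs.append((run_id, bold))
        traces.append(trace)

    anat_path = out / "phantom_brain.nii.gz"
    rois.save_volume(phantom.brain_mask, grid, anat_path)
    outputs["phantom_brain"] = str(anat_path)
    return runs, traces, grid, roi_defs, phantom.brain_mask, variants


def _load_runs(config: RunConfig):
    runs, traces = [], []
    grid = None
    for i, path in enumerate(config.bold_paths):
        if not Path(path).exists():
            raise StageError("ingest", f"missing BOLD file {path}")
        bold, g = rois.load_volume(path)
        if bold.ndim != 4:
            raise StageError("ingest", f"{path} is not a 4-D BOLD image")
        if grid is None:
            grid = g
        elif (g.dims, g.voxel_size, g.origin) != (grid.dims, grid.voxel_size, grid.origin):
            raise StageError("ingest", f"{path} grid differs from the first run")
        runs.append((f"run{i + 1}", bold))
    for path in config.par_paths:
        if not Path(path).exists():
            raise StageError("ingest", f"missing motion file {path}")
        traces.append(motion.read_par(path))
    if config.roi_table is None:
        raise StageError("ingest", "files mode requires roi_table")
    roi_defs = rois.read_roi_definitions(config.roi_table)
    brain_mask = np.any([b.std(axis=3) > 0 for _, b in runs], axis=0)
    return runs, traces, grid, roi_defs, brain_mask


def _build_variants(variants: list[str], roi_defs, grid, out: Path, outputs: dict):
    bilateral = rois.build_roi_set(roi_defs, grid, "bilateral")
    variant_sets = {}
    for variant in variants:
        vset = rois.make_lateralized_set(bilateral, variant)
        variant_sets[variant] = vset
        manifest_path = out / f"roiset_{variant}.json"
        vset.write_manifest(manifest_path)
        outputs[f"roiset_{variant}"] = str(manifest_path)
    return variant_sets


def _run_qc(config: RunConfig, runs, traces, brain_mask, out: Path, outputs: dict):
    qc_rows = []
    fd_means = []
    for (run_id, bold), trace in zip(runs, traces):
        fdp = motion.fd_power(trace)
        fdj = motion.fd_jenkinson(motion.params_to_affines(trace))
        dv = motion.dvars(bold, brain_mask)
        qc_rows.append(
            {
                "run": run_id,
                "mean_fd_power": motion.temporal_mean_fd(fdp),
                "mean_fd_jenkinson": motion.temporal_mean_fd(fdj),
                "mean_dvars": float(dv[1:].mean()) if dv.size > 1 else 0.0,
            }
        )
        fd_means.append(motion.temporal_mean_fd(fdp))
    qc = pd.DataFrame(qc_rows)
    if fd_means:
        qc.loc[len(qc)] = {
            "run": "mean",
            "mean_fd_power": motion.mean_over_runs(fd_means),
            "mean_fd_jenkinson": np.nan,
            "mean_dvars": np.nan,
        }
    qc_path = out / "qc_motion.tsv"
    qc.to_csv(qc_path, sep="\t", index=False, float_format="%.6g")
    outputs["qc_motion"] = str(qc_path)
    return {"mean_fd_power": motion.mean_over_runs(fd_means) if fd_means else np.nan}


def _run_connectivity(config: RunConfig, runs, variant_sets, qc_summary, out: Path, outputs: dict):
    records = []
    for variant, vset in variant_sets.items():
        run_tables = []
        for run_id, bold in runs:
            ts = timeseries.extract_mean_timeseries(bold, vset, config.tr, run_id)
            if config.highpass:
                ts = timeseries.gaussian_highpass(ts, config.highpass_sigma)
            if config.regress_motion:
                ts = _regress_motion(ts, runs, run_id, config)
            ts_path = out / f"timeseries_{variant}_{run_id}.tsv"
            ts.to_tsv(ts_path)
            outputs[f"timeseries_{variant}_{run_id}"] = str(ts_path)
            run_tables.append(ts)
        record = connectivity.subject_report(
            run_tables,
            vset.membership,
            variant,
            subject=config.subject,
            qc=qc_summary,
        )
        z_path = out / f"zmatrix_{variant}.tsv"
        record.zmatrix.to_tsv(z_path)
        outputs[f"zmatrix_{variant}"] = str(z_path)
        rec_path = out / f"record_{variant}.json"
        record.to_json(rec_path)
        outputs[f"record_{variant}"] = str(rec_path)
        records.append(record)
    table = connectivity.summary_table(records)
    table_path = out / "network_summary.tsv"
    table.to_csv(table_path, sep="\t", index=False, float_format="%.6g")
    outputs["network_summary"] = str(table_path)
    return records


def _regress_motion(ts, runs, run_id, config: RunConfig):
    # motion confounds come from the matching .par written during simulation
    # or supplied in files mode; absent trace -> no-op
    par = Path(config.out_dir) / f"motion_{run_id}.par"
    if config.par_paths:
        idx = int(run_id.replace("run", "")) - 1
        if idx < len(config.par_paths):
            par = Path(config.par_paths[idx])
    if not par.exists():
        return ts
    trace = motion.read_par(par)
    conf = timeseries.expand_confounds(
        timeseries.ConfoundTable(trace.params, ["rx", "ry", "rz", "tx", "ty", "tz"])
    )
    return timeseries.regress_out(ts, conf)


def _run_screening(config: RunConfig, out: Path, outputs: dict):
    if config.screening_zscores:
        zs = pd.read_csv(config.screening_zscores, sep="\t")
    else:
        zs = datasets.load_screening_zscores()
    screened = behavioral.screen_zscores(zs)
    path = out / "screening.tsv"
    screened.to_csv(path, sep="\t", index=False)
    outputs["screening"] = str(path)
    return screened
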