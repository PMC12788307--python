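"""End-to-end orchestration: simulate -> preprocess -> features -> stats.

A single :class:`PipelineConfig` drives every stage; ``run_all`` executes
them in order into a run directory, writing each intermediate table as
CSV plus a manifest (config hash, seed, stage wall times) sufficient to
reproduce any output.  All stages are pure functions of (inputs, config,
seed), so a rerun with an identical config reproduces the numeric outputs
bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import network, preprocess, spectral, stats
from .connectivity import cross_spectra, imaginary_coherence
from .errors import ConfigurationError
from .io import Recording, load_recording, save_recording
from .montage import ChannelMontage, default_montage
from .simulate import (
    ArtifactRates,
    BandGains,
    SimulationConfig,
    SubjectRecord,
    blink_reference,
    generate_cohort,
    write_cohort,
)
from .spectral import BANDS

__all__ = ["PipelineConfig", "validate_config", "run_all", "PipelineError"]

logger = logging.getLogger("fceeg")


class PipelineError(RuntimeError):
    """A stage failed; partial outputs are preserved in the run directory."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    montage_file: str | None = None  # CSV of name,x,y,z[,region]; None = built-in
    # preprocessing
    filter_low: float = 0.5
    filter_high: float = 45.0
    filter_order: int = preprocess.DEFAULT_FILTER_ORDER
    resting_crop_s: float = 120.0
    remove_artifacts: bool = True
    artifact_threshold: float = 0.8
    # spectral
    welch_window_s: float = 2.0
    welch_overlap: float = 0.5
    #: "channels" = average per-channel relative power into lobes (default);
    #: "psd" = average member-channel PSDs first, then take relative power.
    region_average: str = "channels"
    write_topomaps: bool = True
    topomap_grid: int = 41
    # connectivity / networks
    compute_connectivity: bool = True
    signed_imcoh: bool = False
    weighted_networks: bool = False
    sparsity_grid: tuple[float, ...] = network.DEFAULT_SPARSITY_GRID
    write_connectivity_matrices: bool = False
    # statistics
    alpha: float = 0.05
    fdr_power: bool = True
    fdr_network: bool = False
    # misc
    seed: int = 0
    save_recordings: bool = False

    # -- (de)serialization ------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        sim = d["simulation"]
        sim.pop("montage", None)
        sim["task_schedule"] = [list(t) for t in self.simulation.task_schedule]
        sim["band_gains"] = {
            "base": dict(self.simulation.band_gains.base),
            "overrides": {
                "/".join(k): v
                for k, v in self.simulation.band_gains.overrides.items()
            },
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = dict(d.pop("simulation", {}))
        if "task_schedule" in sim:
            sim["task_schedule"] = tuple(
                (str(n), float(s)) for n, s in sim["task_schedule"]
            )
        if "band_gains" in sim:
            bg = sim["band_gains"]
            sim["band_gains"] = BandGains(
                base=dict(bg.get("base", {})) or dict(BandGains().base),
                overrides={
                    tuple(k.split("/")): float(v)
                    for k, v in bg.get("overrides", {}).items()
                },
            )
        if "artifact_rates" in sim:
            sim["artifact_rates"] = ArtifactRates(**sim["artifact_rates"])
        if "age_ranges" in sim:
            sim["age_ranges"] = {
                g: tuple(v) for g, v in sim["age_ranges"].items()
            }
        if sim.get("cycle_timing") is not None:
            sim["cycle_timing"] = tuple(sim["cycle_timing"])
        d["simulation"] = SimulationConfig(**sim)
        if "sparsity_grid" in d:
            d["sparsity_grid"] = tuple(float(s) for s in d["sparsity_grid"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    def resolved_montage(self) -> ChannelMontage:
        if self.montage_file is None:
            return self.simulation.resolved_montage()
        return load_montage_file(self.montage_file)


def load_montage_file(path: str | Path) -> ChannelMontage:
    """Read a montage CSV (columns name,x,y,z and optional region)."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"montage_file: {path} does not exist")
    df = pd.read_csv(path)
    pos = df[["x", "y", "z"]].to_numpy(dtype=float)
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    regions = (
        dict(zip(df["name"], df["region"])) if "region" in df.columns else {}
    )
    return ChannelMontage(
        names=tuple(df["name"]), positions=pos, regions=regions
    )


def validate_config(config: PipelineConfig) -> list[str]:
    """All invariant violations across every section (empty when valid)."""
    problems = [f"simulation.{p}" for p in config.simulation.validate()]
    if config.montage_file is not None and not Path(config.montage_file).exists():
        problems.append(f"montage_file: {config.montage_file} does not exist")
    if not 0 < config.filter_low < config.filter_high:
        problems.append("filter: need 0 < filter_low < filter_high")
    if config.filter_high >= config.simulation.sampling_rate / 2:
        problems.append("filter_high: must be below Nyquist")
    if config.welch_window_s <= 0:
        problems.append("welch_window_s: must be > 0")
    if not 0 <= config.welch_overlap < 1:
        problems.append("welch_overlap: must be in [0, 1)")
    if config.region_average not in ("channels", "psd"):
        problems.append("region_average: must be 'channels' or 'psd'")
    grid = config.sparsity_grid
    if len(grid) < 2 or any(b <= a for a, b in zip(grid, grid[1:])):
        problems.append("sparsity_grid: must be >= 2 strictly ascending values")
    if any(not 0 < s <= 1 for s in grid):
        problems.append("sparsity_grid: thresholds must be in (0, 1]")
    if not 0 < config.alpha < 1:
        problems.append("alpha: must be in (0, 1)")
    for a, b in zip(BANDS, BANDS[1:]):
        if a.f_high != b.f_low:
            problems.append(f"bands: {a.name} and {b.name} do not tile the range")
    return problems


# --------------------------------------------------------------------------
# In-memory stage helpers (shared by run_all and the CLI stage commands)

def preprocess_subject(
    subj: SubjectRecord, config: PipelineConfig, montage: ChannelMontage
) -> tuple[dict[str, Recording], list[preprocess.PreprocessReport]]:
    cleaned: dict[str, Recording] = {}
    reports = []
    for task, rec in subj.recordings.items():
        if task == "resting":
            rec = preprocess.crop_resting(rec, config.resting_crop_s)
        ref = None
        if config.remove_artifacts:
            ref = blink_reference(rec)
            if not np.any(ref):
                ref = None
        out, report = preprocess.preprocess_recording(
            rec,
            montage,
            low=config.filter_low,
            high=config.filter_high,
            order=config.filter_order,
            artifact_reference=ref,
            artifact_threshold=config.artifact_threshold,
            seed=config.seed,
            subject_id=subj.subject_id,
            task=task,
        )
        cleaned[task] = out
        reports.append(report)
    return cleaned, reports


def features_for_subject(
    subj_id: str,
    group: str,
    age: float,
    recordings: dict[str, Recording],
    config: PipelineConfig,
    montage: ChannelMontage,
):
    """Band-power and network feature rows for one subject."""
    power_rows = []
    region_rows = []
    net_auc_rows = []
    net_thr_rows = []
    conn_mats = {}
    for task, rec in recordings.items():
        ps = spectral.welch_psd(rec, config.welch_window_s, config.welch_overlap)
        rp = spectral.relative_power(ps)
        tbl = spectral.band_power_table(
            rp, ps.channel_names, subject_id=subj_id, task=task,
            group=group, age=age,
        )
        power_rows.append(tbl)
        if config.region_average == "psd":
            region_rows.append(
                _psd_first_region_table(ps, montage, subj_id, task, group, age)
            )
        else:
            region_rows.append(spectral.aggregate_regions(tbl, montage))
        if config.compute_connectivity:
            cs = cross_spectra(rec, config.welch_window_s, config.welch_overlap)
            for band in BANDS:
                conn = imaginary_coherence(
                    cs, band, signed=config.signed_imcoh,
                    subject_id=subj_id, task=task,
                )
                conn_mats[(subj_id, task, band.name)] = conn
                feats = network.topology_features(
                    conn,
                    config.sparsity_grid,
                    weighted=config.weighted_networks,
                )
                for metric, auc in feats.auc.items():
                    net_auc_rows.append(
                        {
                            "subject_id": subj_id, "group": group, "age": age,
                            "task": task, "band": band.name,
                            "metric": metric, "value": auc,
                        }
                    )
                for metric, vals in feats.per_threshold.items():
                    for s, v in zip(config.sparsity_grid, vals):
                        net_thr_rows.append(
                            {
                                "subject_id": subj_id, "group": group,
                                "age": age, "task": task, "band": band.name,
                                "metric": metric, "sparsity": s, "value": v,
                            }
                        )
    return power_rows, region_rows, net_auc_rows, net_thr_rows, conn_mats


def _psd_first_region_table(ps, montage, subj_id, task, group, age):
    rows = []
    for region in ("frontal", "central", "temporal", "parietal", "occipital"):
        idx = [
            i for i, nm in enumerate(ps.channel_names)
            if montage.region_of(nm) == region
        ]
        if not idx:
            continue
        mean_ps = spectral.PowerSpectrum(
            frequencies=ps.frequencies,
            power=ps.power[idx].mean(axis=0, keepdims=True),
            channel_names=[region],
            window_s=ps.window_s, overlap=ps.overlap,
            taper=ps.taper, n_segments=ps.n_segments,
        )
        rp = spectral.relative_power(mean_ps)[0]
        for b, v in zip(BANDS, rp):
            rows.append(
                {
                    "subject_id": subj_id, "task": task, "group": group,
                    "age": age, "band": b.name, "region": region,
                    "relative_power": v,
                }
            )
    return pd.DataFrame(rows)


def _write_topomaps(power_table: pd.DataFrame, montage, config, out: Path) -> None:
    pos2d = montage.positions_2d()
    name_to_idx = {n: i for i, n in enumerate(montage.names)}
    grid_dir = out / "topomaps"
    grid_dir.mkdir(exist_ok=True)
    for (group, task, band), sub in power_table.groupby(["group", "task", "band"]):
        mean_rp = sub.groupby("channel")["relative_power"].mean()
        chans = [c for c in montage.names if c in mean_rp.index]
        vals = mean_rp.loc[chans].to_numpy()
        pts = pos2d[[name_to_idx[c] for c in chans]]
        _x, _y, grid = spectral.topographic_grid(vals, pts, config.topomap_grid)
        np.savetxt(
            grid_dir / f"{group}_{task}_{band}.csv", grid, delimiter=",",
            fmt="%.6g",
        )


# --------------------------------------------------------------------------
# run_all

def run_all(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute every stage into ``out_dir`` and write the manifest.

    The configuration is validated before any computation; a stage failure
    raises :class:`PipelineError` naming the stage, with the outputs of
    completed stages preserved on disk.
    """
    problems = validate_config(config)
    if problems:
        raise ConfigurationError("; ".join(problems))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    montage = config.resolved_montage()
    sim = replace(config.simulation, montage=montage, seed=config.simulation.seed)
    timings: dict[str, float] = {}

    def _stage(name):
        logger.info("stage %s ...", name)
        return time.perf_counter()

    # -- simulate ---------------------------------------------------------
    t0 = _stage("simulate")
    try:
        subjects, meta = generate_cohort(sim)
        meta.to_csv(out / "metadata.csv", index=False)
        if config.save_recordings:
            write_cohort(subjects, meta, out / "recordings")
    except Exception as exc:
        raise PipelineError("simulate", exc) from exc
    timings["simulate"] = time.perf_counter() - t0

    # -- preprocess -------------------------------------------------------
    t0 = _stage("preprocess")
    try:
        cleaned: dict[str, dict[str, Recording]] = {}
        all_reports = []
        for subj in subjects:
            recs, reports = preprocess_subject(subj, config, montage)
            cleaned[subj.subject_id] = recs
            all_reports.extend(reports)
            logger.info("  preprocessed %s", subj.subject_id)
        qc_table, qc_agg = preprocess.qc_summary(all_reports)
        qc_table.to_csv(out / "qc_reports.csv", index=False)
        (out / "qc_summary.json").write_text(json.dumps(qc_agg, indent=1))
        for name, (m, sd) in qc_agg.items():
            logger.info("  %s: %.2f%% +/- %.2f%%", name, m, sd)
    except Exception as exc:
        raise PipelineError("preprocess", exc) from exc
    timings["preprocess"] = time.perf_counter() - t0

    # -- features ---------------------------------------------------------
    t0 = _stage("features")
    try:
        power_all, region_all, auc_all, thr_all = [], [], [], []
        meta_by_id = meta.set_index("subject_id")
        for subj in subjects:
            row = meta_by_id.loc[subj.subject_id]
            p, r, a, th, mats = features_for_subject(
                subj.subject_id, row["group"], float(row["age"]),
                cleaned[subj.subject_id], config, montage,
            )
            power_all.extend(p)
            region_all.extend(r)
            auc_all.extend(a)
            thr_all.extend(th)
            if config.write_connectivity_matrices:
                mat_dir = out / "connectivity"
                mat_dir.mkdir(exist_ok=True)
                for (sid, task, band), conn in mats.items():
                    pd.DataFrame(
                        conn.values, index=conn.channel_names,
                        columns=conn.channel_names,
                    ).to_csv(mat_dir / f"{sid}_{task}_{band}.csv")
        power_table = pd.concat(power_all, ignore_index=True)
        region_table = pd.concat(region_all, ignore_index=True)
        power_table.to_csv(out / "band_power_channels.csv", index=False)
        region_table.to_csv(out / "band_power_regions.csv", index=False)
        if auc_all:
            pd.DataFrame(auc_all).to_csv(out / "network_auc.csv", index=False)
            pd.DataFrame(thr_all).to_csv(
                out / "network_per_threshold.csv", index=False
            )
        if config.write_topomaps:
            _write_topomaps(power_table, montage, config, out)
    except Exception as exc:
        raise PipelineError("features", exc) from exc
    timings["features"] = time.perf_counter() - t0

    # -- stats ------------------------------------------------------------
    t0 = _stage("stats")
    try:
        obs = region_table.rename(columns={"relative_power": "value"})
        power_stats = stats.run_group_comparison(
            obs, feature_column="region",
            fdr_within_family=config.fdr_power, alpha=config.alpha,
        )
        power_stats.to_csv(out / "group_stats_power.csv", index=False)
        report_lines = [stats.summary_report(power_stats, config.alpha)]
        if auc_all:
            net_stats = stats.run_group_comparison(
                pd.DataFrame(auc_all), feature_column="metric",
                fdr_within_family=config.fdr_network, alpha=config.alpha,
            )
            net_stats.to_csv(out / "group_stats_network.csv", index=False)
            report_lines.append(stats.summary_report(net_stats, config.alpha))
        (out / "summary.txt").write_text("\n\n".join(report_lines) + "\n")
    except Exception as exc:
        raise PipelineError("stats", exc) from exc
    timings["stats"] = time.perf_counter() - t0

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "simulation_seed": config.simulation.seed,
        "package_version": _package_version(),
        "stage_seconds": {k: round(v, 3) for k, v in timings.items()},
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    config.to_yaml(out / "config.yaml")
    return out


def _package_version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("fceeg")
    except PackageNotFoundError:  # pragma: no cover
        return "unknown"


# --------------------------------------------------------------------------
# File-based stage entry points (used by the CLI subcommands)

def stage_simulate(config: PipelineConfig, out_dir: str | Path) -> Path:
    problems = validate_config(config)
    if problems:
        raise ConfigurationError("; ".join(problems))
    sim = replace(config.simulation, montage=config.resolved_montage())
    subjects, meta = generate_cohort(sim)
    return write_cohort(subjects, meta, out_dir)


def _load_cohort(in_dir: str | Path):
    in_dir = Path(in_dir)
    meta = pd.read_csv(in_dir / "metadata.csv")
    subjects = []
    for _, row in meta.iterrows():
        recs = {}
        for edf in sorted(in_dir.glob(f"{row['subject_id']}_*.edf")):
            task = edf.stem[len(row["subject_id"]) + 1 :]
            recs[task] = load_recording(edf)
        subjects.append(
            SubjectRecord(
                subject_id=row["subject_id"], group=row["group"],
                age=float(row["age"]), sex=row.get("sex", "F"),
                recordings=recs,
            )
        )
    return subjects, meta


def stage_preprocess(in_dir, out_dir, config: PipelineConfig) -> Path:
    subjects, meta = _load_cohort(in_dir)
    montage = config.resolved_montage()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    all_reports = []
    for subj in subjects:
        recs, reports = preprocess_subject(subj, config, montage)
        for task, rec in recs.items():
            save_recording(rec, out / f"{subj.subject_id}_{task}")
        all_reports.extend(reports)
    qc_table, qc_agg = preprocess.qc_summary(all_reports)
    qc_table.to_csv(out / "qc_reports.csv", index=False)
    (out / "qc_summary.json").write_text(json.dumps(qc_agg, indent=1))
    meta.to_csv(out / "metadata.csv", index=False)
    return out


def stage_features(in_dir, out_dir, config: PipelineConfig) -> Path:
    subjects, meta = _load_cohort(in_dir)
    montage = config.resolved_montage()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    power_all, region_all, auc_all, thr_all = [], [], [], []
    for subj in subjects:
        p, r, a, th, _mats = features_for_subject(
            subj.subject_id, subj.group, subj.age, subj.recordings,
            config, montage,
        )
        power_all.extend(p)
        region_all.extend(r)
        auc_all.extend(a)
        thr_all.extend(th)
    pd.concat(power_all, ignore_index=True).to_csv(
        out / "band_power_channels.csv", index=False
    )
    pd.concat(region_all, ignore_index=True).to_csv(
        out / "band_power_regions.csv", index=False
    )
    if auc_all:
        pd.DataFrame(auc_all).to_csv(out / "network_auc.csv", index=False)
        pd.DataFrame(thr_all).to_csv(out / "network_per_threshold.csv", index=False)
    meta.to_csv(out / "metadata.csv", index=False)
    return out


def stage_stats(in_dir, out_dir, config: PipelineConfig) -> Path:
    in_dir = Path(in_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    region_table = pd.read_csv(in_dir / "band_power_regions.csv")
    obs = region_table.rename(columns={"relative_power": "value"})
    power_stats = stats.run_group_comparison(
        obs, feature_column="region",
        fdr_within_family=config.fdr_power, alpha=config.alpha,
    )
    power_stats.to_csv(out / "group_stats_power.csv", index=False)
    lines = [stats.summary_report(power_stats, config.alpha)]
    auc_path = in_dir / "network_auc.csv"
    if auc_path.exists():
        net_stats = stats.run_group_comparison(
            pd.read_csv(auc_path), feature_column="metric",
            fdr_within_family=config.fdr_network, alpha=config.alpha,
        )
        net_stats.to_csv(out / "group_stats_network.csv", index=False)
        lines.append(stats.summary_report(net_stats, config.alpha))
    (out / "summary.txt").write_text("\n\n".join(lines) + "\n")
    return out
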