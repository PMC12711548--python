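"""End-to-end orchestration: simulate/ingest -> preprocess -> PSD -> PLV ->
graph metrics -> group statistics -> classification.

A :class:`PipelineConfig` fully determines a run; identical configs and
seeds produce identical artifacts, and every output file is listed with a
checksum in the :class:`RunManifest`.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classification, connectivity, group_stats, io, network_metrics, spectral
from .preprocessing import (
    CONDITIONS,
    DEFAULT_BANDS,
    bandpass,
    reject_channels,
    split_conditions_and_bands,
)
from .synthetic_data import (
    CouplingSpec,
    FvcAssociation,
    ParadigmSpec,
    default_coupling,
    default_paradigm,
    generate_cohort,
)

log = logging.getLogger("respconn")


@dataclass
class PipelineConfig:
    """Everything a run needs; see field names for the stage each controls."""

    out_dir: Path
    n_subjects: int = 12
    paradigm: ParadigmSpec = field(default_factory=default_paradigm)
    coupling: CouplingSpec | None = None
    fvc_assoc: FvcAssociation | None = None
    input_dir: Path | None = None  # ingest instead of simulate when set
    bands: tuple = DEFAULT_BANDS
    broadband: tuple[float, float] = (1.0, 45.0)
    filter_order: int = 4
    reject_epoch_len: float = 2.0
    reject_amplitude: float = 100.0
    reject_fraction: float = 0.20
    psd_window: int = 128
    psd_overlap: float = 0.5
    psd_nfft: int = 256
    edge_trim: float = 0.05
    length_map: str = "inverse"
    ge_variant: str = "latora"
    density_sweep: bool = False
    densities: tuple = (0.1, 0.2, 0.3, 0.4)
    fwe_method: str = "maxT"
    fwe_alpha: float = 0.01
    n_perm: int = 5000
    paired: bool = False
    fdr_alpha: float = 0.01
    vectorization: str = "unique"
    classifier: classification.ClassifierSpec = field(
        default_factory=classification.ClassifierSpec
    )
    cv_folds: int = 10
    cv_repeats: int = 10
    classify: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        kwargs = dict(raw)
        kwargs["out_dir"] = Path(kwargs["out_dir"])
        if "paradigm" in kwargs and isinstance(kwargs["paradigm"], dict):
            kwargs["paradigm"] = default_paradigm(**kwargs["paradigm"])
        if "fvc_assoc" in kwargs and isinstance(kwargs["fvc_assoc"], dict):
            fa = dict(kwargs["fvc_assoc"])
            fa["edge"] = tuple(fa["edge"])
            kwargs["fvc_assoc"] = FvcAssociation(**fa)
        if "classifier" in kwargs and isinstance(kwargs["classifier"], dict):
            kwargs["classifier"] = classification.ClassifierSpec(**kwargs["classifier"])
        return cls(**kwargs)


@dataclass
class RunManifest:
    """Outputs, checksums, timings and provenance of one pipeline run."""

    files: dict[str, str] = field(default_factory=dict)  # path -> sha256
    stage_seconds: dict[str, float] = field(default_factory=dict)
    rejected_channels: dict[str, list[str]] = field(default_factory=dict)
    config_hash: str = ""
    warnings: list[str] = field(default_factory=list)

    def register(self, path: Path) -> None:
        self.files[str(path)] = hashlib.sha256(path.read_bytes()).hexdigest()

    def write(self, path: Path) -> None:
        path.write_text(
            json.dumps(
                {
                    "config_hash": self.config_hash,
                    "files": self.files,
                    "stage_seconds": self.stage_seconds,
                    "rejected_channels": self.rejected_channels,
                    "warnings": self.warnings,
                },
                indent=1,
                sort_keys=True,
            )
        )


def _stage(manifest: RunManifest, name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            manifest.stage_seconds[name] = round(time.perf_counter() - self.t0, 3)
            if exc_type is not None:
                log.error("stage %s: failed (%s)", name, exc)
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            log.info("stage %s: done in %.2fs", name, manifest.stage_seconds[name])

    return _Timer()


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute every stage and return the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest()
    cfg_repr = repr(config).encode()
    manifest.config_hash = hashlib.sha256(cfg_repr).hexdigest()[:16]
    band_names = [b.name for b in config.bands]

    # --- simulate or ingest -------------------------------------------------
    with _stage(manifest, "simulate"):
        if config.input_dir is not None:
            stems = sorted(Path(config.input_dir).glob("*.json"))
            subjects = []
            for stem in stems:
                rec = io.read_recording(stem.with_suffix(".tsv"))
                subjects.append(
                    type("Ingested", (), {"recording": rec, "fvc": None, "subject_id": stem.stem})()
                )
            seeds = [-1] * len(subjects)
        else:
            coupling = config.coupling or default_coupling(config.paradigm.channel_names)
            subjects = generate_cohort(
                config.n_subjects, config.paradigm, coupling, config.fvc_assoc, config.seed
            )
            seeds = list(range(len(subjects)))
            sim_dir = out / "recordings"
            sim_dir.mkdir(exist_ok=True)
            for s in subjects:
                for p in io.write_recording(s.recording, sim_dir / s.subject_id):
                    manifest.register(p)
        manifest.register(io.write_cohort_manifest(subjects, seeds, out / "cohort.tsv"))

    # --- preprocess ---------------------------------------------------------
    with _stage(manifest, "preprocess"):
        per_subject_blocks = {}
        for s in subjects:
            rec = bandpass(s.recording, *config.broadband, order=config.filter_order)
            rec, rejected = reject_channels(
                rec, config.reject_epoch_len, config.reject_amplitude, config.reject_fraction
            )
            manifest.rejected_channels[s.subject_id] = rejected
            per_subject_blocks[s.subject_id] = split_conditions_and_bands(
                rec,
                config.bands,
                filter_order=config.filter_order,
                rejected_channels=rejected,
            )

    # --- PSD ----------------------------------------------------------------
    with _stage(manifest, "psd"):
        tables = [
            spectral.band_power_table(
                blocks,
                config.bands,
                sid,
                config.psd_window,
                config.psd_overlap,
                config.psd_nfft,
            )
            for sid, blocks in per_subject_blocks.items()
        ]
        band_power = pd.concat(tables, ignore_index=True)
        manifest.register(io.write_table(band_power, out / "band_power.tsv"))

    # --- PLV ----------------------------------------------------------------
    with _stage(manifest, "plv"):
        plv_dir = out / "plv"
        plv_dir.mkdir(exist_ok=True)
        conns: dict[str, dict[tuple[str, str], connectivity.ConnectivityMatrix]] = {}
        edge_frames = []
        for sid, blocks in per_subject_blocks.items():
            mats = connectivity.plv_matrices(blocks, sid, config.edge_trim)
            conns[sid] = mats
            for (cond, band), conn in mats.items():
                p = io.write_matrix(conn.values, blocks.channel_names, plv_dir / f"{sid}_{cond}_{band}.tsv")
                manifest.register(p)
                edge_frames.append(connectivity.edge_table(conn, blocks.channel_names))
        manifest.register(io.write_table(pd.concat(edge_frames, ignore_index=True), out / "plv_edges.tsv"))

    # --- graph metrics ------------------------------------------------------
    with _stage(manifest, "graph"):
        metric_frames = []
        for sid, mats in conns.items():
            metrics = {
                key: network_metrics.network_metrics(
                    network_metrics.WeightedGraph.from_plv(conn),
                    config.length_map,
                    config.ge_variant,
                )
                for key, conn in mats.items()
            }
            metric_frames.append(network_metrics.metrics_table(metrics, sid))
        metric_table = pd.concat(metric_frames, ignore_index=True)
        manifest.register(io.write_table(metric_table, out / "network_metrics.tsv"))
        if config.density_sweep:
            sweep_frames = []
            for sid, mats in conns.items():
                for (cond, band), conn in mats.items():
                    df = network_metrics.density_sweep(
                        network_metrics.WeightedGraph.from_plv(conn),
                        config.densities,
                        seed=config.seed,
                        length_map=config.length_map,
                        ge_variant=config.ge_variant,
                    )
                    df.insert(0, "subject", sid)
                    df.insert(1, "condition", cond)
                    df.insert(2, "band", band)
                    sweep_frames.append(df)
            manifest.register(
                io.write_table(pd.concat(sweep_frames, ignore_index=True), out / "density_sweep.tsv")
            )

    # --- group statistics ---------------------------------------------------
    with _stage(manifest, "stats"):
        sids = list(conns)
        first_blocks = per_subject_blocks[sids[0]]
        ch_names = first_blocks.channel_names
        elabels = connectivity.edge_labels(ch_names, config.vectorization)
        contrast_frames = []
        for band in band_names:
            feats = {
                cond: np.array(
                    [
                        connectivity.vectorize_matrix(conns[sid][(cond, band)].values, config.vectorization)
                        for sid in sids
                    ]
                )
                for cond in CONDITIONS
            }
            for ca, cb in (("SB", "BH"), ("PB", "BH"), ("SB", "PB")):
                res = group_stats.fwe_correct(
                    feats[ca],
                    feats[cb],
                    method=config.fwe_method,
                    alpha=config.fwe_alpha,
                    n_perm=config.n_perm,
                    seed=config.seed,
                    paired=config.paired,
                )
                res.label, res.band, res.feature_names = f"{ca}-{cb}", band, tuple(elabels)
                contrast_frames.append(group_stats.contrast_table(res))
        manifest.register(
            io.write_table(pd.concat(contrast_frames, ignore_index=True), out / "plv_contrasts.tsv")
        )

        fvc = np.array([s.fvc if s.fvc is not None else np.nan for s in subjects], dtype=float)
        if np.isnan(fvc).any():
            msg = "FVC missing for some or all subjects; correlation stage skipped"
            log.warning(msg)
            manifest.warnings.append(msg)
        else:
            plv_vectors = {
                (cond, band): np.array(
                    [
                        connectivity.vectorize_matrix(conns[sid][(cond, band)].values, config.vectorization)
                        for sid in sids
                    ]
                )
                for cond in CONDITIONS
                for band in band_names
            }
            corr = group_stats.fvc_correlation(
                plv_vectors, fvc, alpha=config.fdr_alpha, edge_names=elabels
            )
            manifest.register(io.write_table(corr, out / "fvc_correlations.tsv"))

    # --- classification -----------------------------------------------------
    if config.classify:
        with _stage(manifest, "classify"):
            reports = {}
            for band in band_names:
                rows, labels = [], []
                for sid in sids:
                    for cond in CONDITIONS:
                        rows.append(connectivity.vectorize_matrix(conns[sid][(cond, band)].values, "unique"))
                        labels.append(cond)
                # ReliefF neighbours bounded by the per-class count in a training fold
                per_class_train = len(sids) * (config.cv_folds - 1) // config.cv_folds
                reports[band] = classification.cross_validate(
                    np.array(rows),
                    np.array(labels),
                    config.classifier,
                    folds=config.cv_folds,
                    repeats=config.cv_repeats,
                    seed=config.seed,
                    k_neighbors=max(1, min(10, per_class_train - 1)),
                )
            ranges = {b.name: (b.lo, b.hi) for b in config.bands}
            manifest.register(
                io.write_table(classification.report_table(reports, ranges), out / "classification.tsv")
            )

    manifest.write(out / "manifest.json")
    return manifest
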