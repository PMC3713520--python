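"""End-to-end runs driven by a flat configuration.

Each pipeline stage writes delimited tables, TIFF masks/labels and a
run-log YAML echoing every effective parameter, the seed and a hash of the
configuration, so a run is reproducible from its own outputs. Reruns with
an identical configuration and inputs are byte-identical (output paths are
excluded from the hash).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .errors import ConfigError, GroupCountError, MissingChannelError
from .kinetics import MetricsParams, average_traces, metrics_table
from .quantify import (
    ClusterTable,
    cluster_metrics,
    compare_groups,
    metric_histogram,
    pool_clusters,
    segment_cells,
    spot_recovery,
    total_cell_fluorescence,
)
from .segmentation import SegmentationParams, segment_image
from .simulate import (
    TirfSimParams,
    TraceSimParams,
    simulate_cell_field,
    simulate_fura_trace,
    simulate_group_fixtures,
)
from .types import A555, YFP, FieldOfView

__all__ = ["RunConfig", "run_cluster_pipeline", "run_fura_pipeline", "run_transferrin_pipeline"]

#: Per-cluster metrics compared between groups by default.
DEFAULT_METRICS = ("area_px", "ratio_cfp_yfp", "mean_cfp", "mean_yfp")


@dataclass
class RunConfig:
    """Flat configuration of one pipeline run."""

    mode: str = "all"
    out_dir: str = "cracquant_out"
    seed: int = 0
    manifest: Optional[str] = None
    trace_table: Optional[str] = None
    t_tg: float = 60.0
    t_ca: float = 360.0
    n_cells: int = 9
    area_scale: float = 1.5
    ratio_scale: float = 0.7
    n_traces_per_group: int = 20
    trace_delta_r_scale: float = 0.3
    compare_metrics: tuple[str, ...] = DEFAULT_METRICS
    write_images: bool = False
    tirf: TirfSimParams = field(default_factory=lambda: TirfSimParams(n_spots=110))
    trace: TraceSimParams = field(default_factory=TraceSimParams)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    metrics_params: MetricsParams = field(default_factory=MetricsParams)

    @classmethod
    def from_mapping(cls, cfg: dict[str, Any]) -> "RunConfig":
        """Build a config from a flat key-value mapping.

        Keys matching a RunConfig field are set directly; keys matching a
        TirfSimParams / TraceSimParams / SegmentationParams / MetricsParams
        field update the corresponding nested parameter block.
        """
        base = cls()
        own = {f.name for f in dataclasses.fields(cls)}
        nested = {
            "tirf": base.tirf,
            "trace": base.trace,
            "segmentation": base.segmentation,
            "metrics_params": base.metrics_params,
        }
        nested_fields = {
            name: {f.name for f in dataclasses.fields(type(obj))} for name, obj in nested.items()
        }
        updates: dict[str, Any] = {}
        nested_updates: dict[str, dict[str, Any]] = {n: {} for n in nested}
        for key, value in cfg.items():
            if key in ("compare_metrics",) and isinstance(value, list):
                value = tuple(value)
            if key in own and key not in nested:
                updates[key] = value
                continue
            placed = False
            for name, names in nested_fields.items():
                if key in names:
                    nested_updates[name][key] = (
                        tuple(value) if isinstance(value, list) else value
                    )
                    placed = True
                    break
            if not placed:
                raise ConfigError(f"unknown configuration key {key!r}")
        for name, obj in nested.items():
            if nested_updates[name]:
                updates[name] = replace(obj, **nested_updates[name])
        return replace(base, **updates)

    def content_hash(self) -> str:
        """Hash of all parameters that influence output content (not paths)."""
        d = dataclasses.asdict(self)
        d.pop("out_dir", None)
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: configuration must be a flat mapping")
    return RunConfig.from_mapping(cfg)


def _provenance(config: RunConfig) -> str:
    return f"config_sha256={config.content_hash()} seed={config.seed}"


def _write_table(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# {_provenance(config)}\n")
        df.to_csv(fh, index=False)


def _write_run_log(config: RunConfig, out: Path, extra: dict | None = None) -> None:
    log = dataclasses.asdict(config)
    # output location is provenance of the copy, not of the content
    log.pop("out_dir", None)
    log["config_sha256"] = config.content_hash()
    if extra:
        log.update(extra)
    with open(out / "run_log.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(log, fh, sort_keys=True, default_flow_style=False)


def _load_or_simulate_fovs(config: RunConfig):
    """Return list of (FieldOfView, GroundTruth-or-None)."""
    if config.manifest is not None:
        entries = cio.read_manifest(config.manifest)
        base = Path(config.manifest).parent
        return [(cio.load_fov(e, base_dir=base), None) for e in entries]
    arms = simulate_group_fixtures(
        control=config.tirf,
        n_cells=config.n_cells,
        area_scale=config.area_scale,
        ratio_scale=config.ratio_scale,
        seed=config.seed,
    )
    return [fg for fields in arms.values() for fg in fields]


def run_cluster_pipeline(config: RunConfig) -> dict[str, Any]:
    """Segment every field of view, quantify clusters, pool and compare.

    Writes per-cell masks/labels (optional), per-cell and pooled cluster
    tables, a histogram table and a comparison report; returns the pooled
    table, per-metric comparisons and (for simulated inputs) spot-recovery
    scores keyed by cell.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fovs = _load_or_simulate_fovs(config)
    seg = config.segmentation
    tables: list[ClusterTable] = []
    recovery: dict[str, tuple[float, float]] = {}
    for fov, truth in fovs:
        if seg.mask_channel not in fov.images:
            raise MissingChannelError(
                f"cell {fov.cell_id!r} lacks the mask channel {seg.mask_channel!r}"
            )
        labels = segment_image(fov[seg.mask_channel], seg)
        tables.append(cluster_metrics(labels, fov))
        if truth is not None and truth.spots is not None and len(truth.spots):
            recovery[fov.cell_id] = spot_recovery(labels, truth.spots)
        if config.write_images:
            cio.write_image(labels.mask.astype(float) * 255.0, out / f"{fov.cell_id}_mask.tif", bit_depth=8)
            cio.write_image(labels.labels.astype(float), out / f"{fov.cell_id}_labels.tif", bit_depth=16)
    pooled = pool_clusters(tables)
    _write_table(pooled.records, out / "clusters_pooled.csv", config)

    conditions = sorted(pooled.records["condition"].unique())
    comparisons = {}
    if len(conditions) == 2:
        rows = []
        for metric in config.compare_metrics:
            cmp = compare_groups(pooled, metric)
            comparisons[metric] = cmp
            rows.append(cmp.as_dict())
        _write_table(pd.DataFrame(rows), out / "group_comparison.csv", config)
        areas = pooled.records["area_px"].to_numpy(dtype=float)
        edges = np.linspace(0.0, float(np.quantile(areas, 0.99)) + 1.0, 41)
        hist = metric_histogram(pooled, "area_px", edges)
        _write_table(hist, out / "area_histogram.csv", config)
    _write_run_log(config, out, extra={"n_fields": len(fovs), "n_clusters_pooled": len(pooled)})
    return {"pooled": pooled, "comparisons": comparisons, "recovery": recovery, "out_dir": out}


def _simulate_trace_groups(config: RunConfig):
    traces = []
    for gi, (label, scale) in enumerate(
        (("control", 1.0), ("perturbed", config.trace_delta_r_scale))
    ):
        for i in range(config.n_traces_per_group):
            seed = int(
                np.random.SeedSequence(entropy=config.seed, spawn_key=(100 + gi, i)).generate_state(1)[0]
                % 2**31
            )
            p = replace(config.trace, delta_r=config.trace.delta_r * scale, seed=seed)
            tr, _ = simulate_fura_trace(p, cell_id=f"{label}_{i}", condition=label)
            traces.append(tr)
    return traces


def run_fura_pipeline(config: RunConfig, require_two_groups: bool = True) -> dict[str, Any]:
    """Per-cell SOCE metrics, per-group averaged traces and group comparison."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.trace_table is not None:
        traces = cio.read_trace_table(config.trace_table, t_tg=config.t_tg, t_ca=config.t_ca)
    else:
        traces = _simulate_trace_groups(config)
    per_cell = metrics_table(traces, config.metrics_params)
    _write_table(per_cell, out / "trace_metrics.csv", config)
    averaged = average_traces(traces)
    _write_table(averaged, out / "traces_averaged.csv", config)
    groups = sorted(per_cell["condition"].unique())
    comparisons = {}
    if len(groups) == 2:
        rows = []
        for metric in ("max_rate_rise", "soce_amplitude"):
            cmp = compare_groups(per_cell, metric)
            comparisons[metric] = cmp
            rows.append(cmp.as_dict())
        _write_table(pd.DataFrame(rows), out / "trace_comparison.csv", config)
    elif require_two_groups:
        raise GroupCountError(
            f"group comparison requested but found {len(groups)} group(s): {groups}"
        )
    _write_run_log(config, out, extra={"n_traces": len(traces)})
    return {"metrics": per_cell, "averaged": averaged, "comparisons": comparisons, "out_dir": out}


def run_simulation(config: RunConfig) -> dict[str, Any]:
    """Write simulated fixtures to disk: TIFF pairs, manifest, truth, traces.

    Image pairs go out as 16-bit grayscale TIFF with a YAML manifest listing
    per-field paths, cell_id and condition; ground-truth spot tables and the
    simulated trace table are written as CSV.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    arms = simulate_group_fixtures(
        control=config.tirf,
        n_cells=config.n_cells,
        area_scale=config.area_scale,
        ratio_scale=config.ratio_scale,
        seed=config.seed,
    )
    entries = []
    truth_frames = []
    for fields in arms.values():
        for fov, truth in fields:
            cfp_name = f"{fov.cell_id}_cfp.tif"
            yfp_name = f"{fov.cell_id}_yfp.tif"
            cio.write_image(fov["CFP"], out / cfp_name)
            cio.write_image(fov["YFP"], out / yfp_name)
            entries.append(
                {
                    "cell_id": fov.cell_id,
                    "condition": fov.condition,
                    "cfp_path": cfp_name,
                    "yfp_path": yfp_name,
                }
            )
            spots = truth.spots.copy()
            spots.insert(0, "cell_id", fov.cell_id)
            spots.insert(1, "condition", fov.condition)
            truth_frames.append(spots)
    cio.write_manifest(entries, out / "manifest.yaml")
    _write_table(pd.concat(truth_frames, ignore_index=True), out / "ground_truth_spots.csv", config)
    traces = _simulate_trace_groups(config)
    cio.write_trace_table(traces, out / "traces.csv", header_comment=_provenance(config))
    _write_run_log(config, out, extra={"n_fields": len(entries)})
    return {"manifest": out / "manifest.yaml", "out_dir": out}


def run_transferrin_pipeline(config: RunConfig) -> dict[str, Any]:
    """Per-cell total target fluorescence with YFP-derived cell boundaries."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.manifest is not None:
        entries = cio.read_manifest(config.manifest)
        base = Path(config.manifest).parent
        fovs = [cio.load_fov(e, base_dir=base) for e in entries]
        truth = None
    else:
        fov, truth = simulate_cell_field(seed=config.seed)
        fovs = [fov]
    frames = []
    for fov in fovs:
        cells = segment_cells(fov[YFP])
        target = fov[A555] if A555 in fov.images else fov[YFP]
        bg = float(np.median(target.pixels))
        df = total_cell_fluorescence(cells, target, background=bg)
        df.insert(0, "field", fov.cell_id)
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    _write_table(table, out / "cell_fluorescence.csv", config)
    _write_run_log(config, out, extra={"n_fields": len(fovs)})
    return {"cells": table, "truth": truth, "out_dir": out}
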