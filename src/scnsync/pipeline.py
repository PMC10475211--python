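"""End-to-end orchestration: traces → coherence → inference → search space.

A pipeline run processes one or more slices (simulated presets or trace CSV
files), estimates per-slice coherence and one-community bounds, pools
per-condition order parameters into two-community K–L lines, and — when all
four age × photoperiod conditions are present — runs the search-space
analysis. Every stage output carries the config hash and master seed, and a
fixed seed makes the whole summary byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from scnsync import coherence as _coh
from scnsync import communities as _comm
from scnsync import one_community as _one
from scnsync import search_space as _ss
from scnsync import simulate as _sim
from scnsync import traces as _tr
from scnsync import two_community as _two

__all__ = ["PipelineConfig", "SliceSpec", "run_all"]

log = logging.getLogger("scnsync.pipeline")

SUMMARY_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class SliceSpec:
    """One slice input: either a simulation preset or a trace CSV."""

    condition: str  # young_LP | young_SP | old_LP | old_SP
    preset: str | None = None  # simulate this preset (same vocabulary)
    trace_csv: str | None = None
    labels_csv: str | None = None
    n_per_community: int = 100
    n_cycles: int = 8

    def __post_init__(self):
        if (self.preset is None) == (self.trace_csv is None):
            raise ValueError("give exactly one of preset or trace_csv")


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration for a full pipeline run."""

    slices: tuple = ()
    order_parameters: dict | str | None = None  # bypass: condition -> (r1, r2)
    outdir: str = "scnsync_out"
    seed: int = 0
    cycle_index: int = _coh.DEFAULT_CYCLE_INDEX
    delta_convention: str = "plain"
    search_method: str = "monte_carlo"
    mc_samples: int = 1_000_000
    survivor_target: int = 200_000
    smoothing_window_h: float = _tr.DEFAULT_SMOOTHING_WINDOW_H

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        slices = tuple(SliceSpec(**s) for s in raw.pop("slices", []))
        return cls(slices=slices, **raw)

    def canonical_json(self) -> str:
        def default(o):
            if isinstance(o, SliceSpec):
                return o.__dict__
            raise TypeError(type(o))

        # outdir is deployment detail, not science: identical analyses written
        # to different directories share a hash
        payload = {k: v for k, v in self.__dict__.items() if k != "outdir"}
        return json.dumps(payload, sort_keys=True, default=default)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]


def _load_or_simulate(spec: SliceSpec, seed: int):
    """Return (TraceMatrix, labels or None) for one slice spec."""
    if spec.trace_csv is not None:
        traces = _tr.TraceMatrix.read_csv(spec.trace_csv)
        labels = None
        if spec.labels_csv is not None:
            df = pd.read_csv(spec.labels_csv)
            by_id = dict(zip(df["cell_id"], df["community"]))
            labels = np.array([by_id[c] for c in traces.cell_ids])
        return traces, labels
    r1, r2 = _sim.CONDITION_PRESETS[spec.preset]
    params = _sim.calibrate_condition(
        r1, r2, n_per_community=spec.n_per_community, n_cycles=spec.n_cycles, seed=seed
    )
    age, photoperiod = spec.condition.split("_")
    fixture = _sim.make_slice_fixture(
        params, metadata={"age": age, "photoperiod": photoperiod}
    )
    return fixture.trace_matrix(), fixture.community_labels


def run_all(config: PipelineConfig) -> dict:
    """Execute every configured stage; write stage outputs and a summary JSON.

    Raises on the first stage failure, naming the stage and slice.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    provenance = {"config_hash": chash, "seed": config.seed}
    summary = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        **provenance,
        "slices": [],
    }

    per_condition = {}
    for i, spec in enumerate(config.slices):
        t0 = time.perf_counter()
        stage = f"slice[{i}] ({spec.condition})"
        try:
            traces, labels = _load_or_simulate(spec, seed=config.seed + i)
            series = _tr.process_traces(traces, window_h=config.smoothing_window_h)
            if labels is None:
                assignment = _comm.detect_communities(traces)
                labels_all = assignment.labels
            else:
                labels_all = np.asarray(labels)
            by_id = dict(zip(traces.cell_ids, labels_all))
            kept_labels = np.array([by_id[c] for c in series.cell_ids])
            coh = _coh.slice_coherence(series, config.cycle_index, labels=kept_labels)
            bounds = _one.one_community_bounds_from_series(series, coh.r)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage failed: {stage}: {exc}") from exc
        log.info("%s done in %.2f s", stage, time.perf_counter() - t0)
        entry = {
            "condition": spec.condition,
            "n_cells": coh.n_cells,
            "coherence": coh.to_dict(),
            "one_community_bounds": bounds.to_dict(),
            **provenance,
        }
        summary["slices"].append(entry)
        per_condition.setdefault(spec.condition, []).append((coh.r1, coh.r2))

    # condition-level lines
    order_params = None
    if config.order_parameters == "builtin":
        order_params = _two.SCN_ORDER_PARAMETERS
    elif isinstance(config.order_parameters, dict):
        order_params = {k: tuple(v) for k, v in config.order_parameters.items()}
    elif per_condition:
        order_params = {
            cond: _two.average_order_parameters(pairs)
            for cond, pairs in per_condition.items()
            if all(r is not None for pair in pairs for r in pair)
        }

    if order_params:
        lines = {}
        for cond, (r1, r2) in sorted(order_params.items()):
            ln = _two.condition_lines(r1, r2, condition=cond)
            lines[cond] = ln
            summary.setdefault("condition_lines", {})[cond] = {
                **ln.to_dict(),
                **provenance,
            }
        if set(_ss.CONDITIONS) <= set(lines):
            t0 = time.perf_counter()
            ss_config = _ss.SearchSpaceConfig(
                method=config.search_method,
                mc_samples=config.mc_samples,
                survivor_target=config.survivor_target,
                seed=config.seed,
                delta_convention=config.delta_convention,
            )
            report = _ss.analyze_search_space(lines, ss_config)
            summary["search_space"] = {**report.to_dict(), **provenance}
            log.info("search space done in %.2f s", time.perf_counter() - t0)

    out_path = outdir / "summary.json"
    with open(out_path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    log.info("summary written to %s", out_path)
    return summary
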