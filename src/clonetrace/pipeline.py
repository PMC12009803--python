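"""End-to-end orchestration: simulate -> extract -> diversity -> compare.

A run is driven by a single config mapping (typically loaded from YAML),
with all randomness flowing through one seeded generator hierarchy — one
child stream per pipeline stage — so any stage is individually
reproducible and two runs with the same config and seed are byte-identical
on every count table and on the report.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import yaml

from . import __version__
from .extraction import (
    CloneCountTable,
    ReadLayout,
    extract_clone_counts,
    write_count_table,
    write_whitelist,
)
from .retention import bottleneck_report
from .simulate import (
    STAGE_PLANS,
    SimulationConfig,
    default_layout,
    build_library,
    generate_reads,
    simulate_stage,
    simulate_transduction,
)


class ConfigError(ValueError):
    """Invalid or incomplete run configuration (CLI exit code 2)."""


_SIM_KEYS = {
    "seed", "n_bc14", "n_bc30", "n_founder_cells", "transduction_rate",
    "moi_model", "expansion_doublings", "stage_plan", "reads_per_cell",
    "per_base_error", "scale", "growth_model",
}
_RUN_KEYS = {"protocol", "layout", "clone_key", "min_reads", "plots", "founder_label"}


def resolve_config(config: Mapping) -> tuple:
    """Validate a run-config mapping into (SimulationConfig, run options).

    Desk-scale by default: ``scale`` falls back to 0.01 so a full run fits
    on a laptop; set ``scale: 1.0`` to simulate the experiment's actual
    cell numbers.
    """
    if not isinstance(config, Mapping):
        raise ConfigError(f"config must be a mapping, got {type(config).__name__}")
    unknown = set(config) - _SIM_KEYS - _RUN_KEYS
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    if "seed" not in config:
        raise ConfigError("config key 'seed' is required")

    sim_kwargs = {k: config[k] for k in _SIM_KEYS if k in config}
    sim_kwargs.setdefault("scale", 0.01)
    protocol = config.get("protocol")
    if protocol is not None:
        if protocol not in STAGE_PLANS:
            raise ConfigError(f"unknown protocol {protocol!r}; choose from {sorted(STAGE_PLANS)}")
        if "stage_plan" in sim_kwargs:
            raise ConfigError("give either 'protocol' or 'stage_plan', not both")
        sim_kwargs["stage_plan"] = list(STAGE_PLANS[protocol])
    layout_spec = config.get("layout")
    if layout_spec is not None:
        if isinstance(layout_spec, str):
            sim_kwargs["layout"] = ReadLayout.with_spacer(layout_spec)
        elif isinstance(layout_spec, Mapping):
            try:
                sim_kwargs["layout"] = ReadLayout(**layout_spec)
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"invalid layout: {exc}") from exc
        else:
            raise ConfigError("layout must be a spacer string or a mapping of ReadLayout fields")
    try:
        sim = SimulationConfig(**sim_kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc

    clone_key = config.get("clone_key", "pair")
    if clone_key not in ("pair", "bc30_only"):
        raise ConfigError(f"clone_key must be 'pair' or 'bc30_only', got {clone_key!r}")
    min_reads = int(config.get("min_reads", 1))
    if min_reads < 1:
        raise ConfigError("min_reads must be >= 1")
    opts = {
        "clone_key": clone_key,
        "min_reads": min_reads,
        "plots": bool(config.get("plots", False)),
        "founder_label": str(config.get("founder_label", "hiPSC")),
    }
    return sim, opts


def load_config(path) -> Mapping:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        loaded = yaml.safe_load(fh)
    if loaded is None:
        raise ConfigError(f"config file is empty: {path}")
    return loaded


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    seed: int
    tool_version: str
    config: dict
    outputs: dict = field(default_factory=dict)
    started: float = 0.0
    finished: float = 0.0

    def add_output(self, name: str, path: Path) -> None:
        self.outputs[name] = {"path": str(path), "sha256": _sha256(path)}

    def validate(self) -> None:
        for name, entry in self.outputs.items():
            p = Path(entry["path"])
            if not p.exists():
                raise RuntimeError(f"manifest output {name!r} missing: {p}")
            if _sha256(p) != entry["sha256"]:
                raise RuntimeError(f"manifest output {name!r} checksum mismatch: {p}")

    def as_dict(self) -> dict:
        return {
            "seed": self.seed,
            "tool_version": self.tool_version,
            "config": self.config,
            "outputs": self.outputs,
            "started": self.started,
            "finished": self.finished,
        }

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _config_snapshot(sim: SimulationConfig, opts: dict) -> dict:
    layout = sim.layout
    return {
        "seed": sim.seed,
        "scale": sim.scale,
        "n_bc14": sim.n_bc14,
        "n_bc30": sim.n_bc30,
        "n_founder_cells": sim.n_founder_cells,
        "transduction_rate": sim.transduction_rate,
        "moi_model": sim.moi_model,
        "expansion_doublings": sim.expansion_doublings,
        "stage_plan": [list(e) for e in sim.stage_plan],
        "reads_per_cell": sim.reads_per_cell,
        "per_base_error": sim.per_base_error,
        "growth_model": sim.growth_model,
        "layout": {
            "bc14_offset": layout.bc14_offset,
            "spacer": layout.spacer,
            "bc30_offset": layout.bc30_offset,
            "min_read_length": layout.min_read_length,
        },
        **opts,
    }


def simulate_experiment(sim: SimulationConfig, opts: dict, out_dir: Path) -> tuple:
    """Simulation half of a run: whitelist, populations, FASTQs, truth tables.

    Returns (whitelist, labels, fastq paths).  Child seed streams, in
    order: library, transduction, then per sequenced stage one stream for
    bottleneck sampling and one for read generation.
    """
    out_dir.mkdir(parents=True, exist_ok=True)
    n_stages = 1 + len(sim.stage_plan)
    streams = [np.random.default_rng(s)
               for s in np.random.SeedSequence(sim.seed).spawn(2 + 2 * n_stages)]
    rng_lib, rng_trans = streams[0], streams[1]
    stage_rngs = streams[2::2]
    read_rngs = streams[3::2]

    whitelist = build_library(sim, rng_lib)
    write_whitelist(whitelist, out_dir / "whitelist_bc14.txt", out_dir / "whitelist_bc30.txt")

    pool = simulate_transduction(sim, whitelist, rng_trans)
    founder = simulate_stage(
        pool, sim.founder_sample_cells, sim.expansion_doublings,
        stage_rngs[0], sim.growth_model, stage_label=opts["founder_label"],
    )
    populations = [founder]
    current = founder
    for i, (label, cells, doublings) in enumerate(sim.stage_plan, start=1):
        current = simulate_stage(
            current, sim.scaled(cells), doublings, stage_rngs[i],
            sim.growth_model, stage_label=label,
        )
        populations.append(current)

    labels, fastqs = [], []
    for pop, rng in zip(populations, read_rngs):
        fq = out_dir / f"{pop.stage_label}.fastq"
        generate_reads(pop, sim, rng, fastq_path=fq)
        with open(out_dir / f"truth_{pop.stage_label}.tsv", "w") as fh:
            fh.write("clone_id\tcells\n")
            for key in sorted(pop.clone_cells):
                fh.write(f"{key}\t{pop.clone_cells[key]}\n")
        labels.append(pop.stage_label)
        fastqs.append(fq)
    return whitelist, labels, fastqs


def run_all(config: Mapping, out_dir) -> RunManifest:
    """Execute the full tracked experiment as one reproducible run.

    Simulates every sequenced stage, extracts clone counts from the
    generated FASTQs, computes diversity and founder-retention statistics,
    and writes count tables, a JSON report and a provenance manifest to
    ``out_dir``.  Idempotent under identical config + seed.
    """
    sim, opts = resolve_config(config)
    out_dir = Path(out_dir)
    manifest = RunManifest(seed=sim.seed, tool_version=__version__,
                           config=_config_snapshot(sim, opts), started=time.time())

    stage = "simulate"
    try:
        whitelist, labels, fastqs = simulate_experiment(sim, opts, out_dir)
        manifest.add_output("whitelist_bc14", out_dir / "whitelist_bc14.txt")
        manifest.add_output("whitelist_bc30", out_dir / "whitelist_bc30.txt")

        stage = "extract"
        tables = []
        for label, fq in zip(labels, fastqs):
            table = extract_clone_counts(
                fq, sim.layout, whitelist,
                clone_key_mode=opts["clone_key"], sample_id=label,
            )
            tsv = out_dir / f"counts_{label}.tsv"
            write_count_table(table, tsv)
            manifest.add_output(f"fastq_{label}", fq)
            manifest.add_output(f"counts_{label}", tsv)
            tables.append(table)

        stage = "report"
        bottleneck_report(tables, labels, min_reads=opts["min_reads"],
                          out_dir=out_dir, plots=opts["plots"], seed=sim.seed)
        for name in ("report.json", "diversity.tsv", "retention.tsv"):
            manifest.add_output(name, out_dir / name)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest.finished = time.time()
    manifest.write(out_dir / "manifest.json")
    with open(out_dir / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(manifest.config, fh, sort_keys=True)
    manifest.validate()
    return manifest
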