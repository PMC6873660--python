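"""Replicated experiments over the scenario grid.

A grid cell is one (scheme, SB rounds, crossing scheme [, variant])
combination; the full study design is 4 scenarios x 3 SB-round counts
x 2 crossing schemes = 24 cells.  Replicates share nothing but the
master seed hierarchy: master seed -> base-population seed +
per-replicate seeds -> per-cell streams, so any run is reproducible
bit-for-bit from its manifest and results are independent of execution
order.

Within a replicate, all cells branch from the same phenotypic warm-up
snapshot (paired replicates), mirroring the study design where every
scenario commences from the same conventional program.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import presets
from .basepop import Population, derive_cultivars, run_forward
from .breeding import (SchemeConfig, World, continue_program, run_warmup)
from .metrics import compare_scenarios
from .prediction import build_snp_panel
from .traits import TraitState, assign_qtl

__all__ = [
    "ExperimentConfig",
    "full_grid",
    "build_base",
    "build_world",
    "run_experiment",
    "summarize",
    "pairwise_tests",
]

_CELL_KEYS = ["scheme", "sb_rounds", "crossing", "design", "synthetic_size"]


@dataclass(frozen=True)
class GridCell:
    scheme: str
    sb_rounds: int = 1
    crossing_scheme: tuple[int, int] | None = None
    overrides: tuple = ()   # ((field, value), ...) e.g. initial_pop_design

    def config(self, preset: str) -> SchemeConfig:
        return presets.scheme_config(self.scheme, preset,
                                     sb_rounds=self.sb_rounds,
                                     crossing_scheme=self.crossing_scheme,
                                     **dict(self.overrides))

    def label(self) -> str:
        parts = [self.scheme, f"sb{self.sb_rounds}"]
        if self.crossing_scheme:
            parts.append(f"{self.crossing_scheme[0]}x"
                         f"{self.crossing_scheme[1]}")
        parts += [f"{k}={v}" for k, v in self.overrides]
        return "_".join(parts)


@dataclass(frozen=True)
class ExperimentConfig:
    cells: tuple[GridCell, ...]
    replicates: int = 10
    master_seed: int = 0
    preset: str = "desk"

    def __post_init__(self) -> None:
        if self.replicates < 1 or not self.cells:
            raise ValueError("need at least one replicate and one cell")


def full_grid(preset: str = "full") -> tuple[GridCell, ...]:
    """The complete scenario grid: 4 schemes x 3 SB rounds x 2 crossing
    schemes = 24 cells."""
    pool = presets.scheme_config("S4", preset).gs_pool_size
    crossings = [(pool, 1), (pool // 10, 10)]
    return tuple(GridCell(scheme=s, sb_rounds=sb, crossing_scheme=cr)
                 for s in ("S1", "S2", "S3", "S4")
                 for sb in (1, 2, 3)
                 for cr in crossings)


def build_base(preset: str, rng: np.random.Generator,
               he_history: list | None = None) -> Population:
    """Run the forward base-population simulation for a preset."""
    return run_forward(presets.sim_params(preset),
                       presets.event_schedule(preset), rng=rng,
                       he_history=he_history)


def build_world(base: Population, preset: str,
                rng: np.random.Generator) -> World:
    """Cultivars, QTL, panel and trait state for one replicate."""
    cp = presets.cultivar_params(preset)
    cultivars = derive_cultivars(base, cp["n_cultivars"],
                                 cp["founders_per_cultivar"],
                                 cp["generations"], rng)
    specs = presets.trait_specs(preset)
    targets = presets.correlation_targets(preset)
    qtl = assign_qtl(base, specs, targets, rng)
    panel = build_snp_panel(base, qtl, presets.panel_size(preset), rng)
    return World(cultivars=cultivars, qtl=qtl, panel=panel,
                 trait_state=TraitState(specs),
                 brr=presets.brr_settings(preset))


def run_experiment(config: ExperimentConfig,
                   base: Population | None = None
                   ) -> tuple[pd.DataFrame, dict]:
    """Execute all grid cells x replicates; return (ledger, manifest).

    Per-cell failures are recorded in the manifest and skipped with a
    warning; aggregation proceeds over completed cells.
    """
    t0 = time.time()
    ss = np.random.SeedSequence(config.master_seed)
    base_ss, *rep_ss = ss.spawn(config.replicates + 1)
    if base is None:
        base = build_base(config.preset, np.random.default_rng(base_ss))
    ps_cfg = presets.scheme_config("PS", config.preset)
    cell_cfgs = [(cell, cell.config(config.preset))
                 for cell in config.cells]
    frames: list[pd.DataFrame] = []
    status: dict[str, str] = {}
    for r, rseq in enumerate(rep_ss):
        world_ss, warm_ss, *cell_ss = rseq.spawn(2 + len(cell_cfgs))
        world = build_world(base, config.preset,
                            np.random.default_rng(world_ss))
        warm = run_warmup(ps_cfg, world,
                          np.random.default_rng(warm_ss))
        for (cell, cfg), cseq in zip(cell_cfgs, cell_ss):
            key = f"rep{r}:{cell.label()}"
            try:
                ledger = continue_program(cfg, ps_cfg, warm.copy(), world,
                                          np.random.default_rng(cseq))
            except Exception as err:  # pragma: no cover - defensive
                warnings.warn(f"cell {key} failed: {err}")
                status[key] = f"failed: {err}"
                continue
            ledger.insert(0, "replicate", r)
            frames.append(ledger)
            status[key] = "ok"
    ledger = pd.concat(frames, ignore_index=True) if frames \
        else pd.DataFrame()
    manifest = {
        "preset": presets.preset_summary(config.preset),
        "master_seed": config.master_seed,
        "replicates": config.replicates,
        "cells": [cell.label() for cell in config.cells],
        "schemes": {cell.label(): presets.scheme_to_dict(cfg)
                    for cell, cfg in cell_cfgs},
        "replicate_seeds": [{"entropy": int(s.entropy),
                             "spawn_key": [int(k) for k in s.spawn_key]}
                            for s in rep_ss],
        "status": status,
        "elapsed_s": round(time.time() - t0, 2),
    }
    return ledger, manifest


def summarize(ledger: pd.DataFrame) -> pd.DataFrame:
    """Replicate mean/SD/count of every metric per cell, cycle and trait."""
    if ledger.empty:
        raise ValueError("empty ledger")
    keys = _CELL_KEYS + ["cycle", "year", "round", "trait", "metric"]
    g = ledger.groupby(keys, dropna=False)["value"]
    out = g.agg(["mean", "std", "count"]).reset_index()
    return out


def pairwise_tests(ledger: pd.DataFrame, metric: str,
                   cycle: int | None = None, trait: str | None = None,
                   alpha: float = 0.01) -> pd.DataFrame:
    """All pairwise scenario contrasts for one metric.

    Replicate-level values are averaged within replicate over any
    remaining dimensions (e.g. rounds) before the two-sample t-test;
    significance at p < ``alpha`` (study convention 0.01).
    """
    sub = ledger[ledger["metric"] == metric]
    if cycle is not None:
        sub = sub[sub["cycle"] == cycle]
    if trait is not None:
        sub = sub[sub["trait"] == trait]
    if sub.empty:
        raise ValueError(f"no ledger rows for metric {metric!r}")
    per_rep = (sub.groupby(_CELL_KEYS + ["replicate"])["value"]
               .mean().reset_index())
    cells = per_rep[_CELL_KEYS].drop_duplicates().itertuples(index=False)
    cells = [tuple(c) for c in cells]
    rows = []
    for i in range(len(cells)):
        for j in range(i + 1, len(cells)):
            a = per_rep[(per_rep[_CELL_KEYS] == cells[i]).all(axis=1)]
            b = per_rep[(per_rep[_CELL_KEYS] == cells[j]).all(axis=1)]
            if len(a) < 2 or len(b) < 2:
                continue
            res = compare_scenarios(a["value"], b["value"], alpha=alpha)
            rows.append({"cell_a": cells[i], "cell_b": cells[j],
                         "metric": metric, "mean_a": a["value"].mean(),
                         "mean_b": b["value"].mean(),
                         "t": res.statistic, "p": res.pvalue,
                         "significant": res.significant})
    return pd.DataFrame(rows)
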