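"""Shared fixtures.

Session-scoped fixtures carry the expensive simulation state: the
reduced-scale ("desk") base population at mutation--drift equilibrium,
a replicate world built on it, and the directional scenario grid (20
paired replicates of scenario four under varying SB rounds, crossing
schemes and initial-population designs) that the statistical-recovery
and directional tests read from.
"""

from __future__ import annotations

import numpy as np
import pytest

from allobreed import presets
from allobreed.basepop import Population
from allobreed.breeding import run_warmup
from allobreed.experiment import (ExperimentConfig, GridCell, build_base,
                                  build_world, run_experiment)


def make_population(freqs, n, rng, n_chromosomes=1, length=100.0,
                    lineage="test") -> Population:
    """Haplotypes drawn independently from per-locus allele frequencies."""
    freqs = np.asarray(freqs, dtype=float)
    L = freqs.size // n_chromosomes
    haps = (rng.random((n, n_chromosomes, 2, L))
            < freqs.reshape(n_chromosomes, 1, L)).astype(np.int8)
    return Population(haplotypes=haps, chromosome_length=length,
                      lineage=lineage)


@pytest.fixture(scope="session")
def micro_base():
    return build_base("micro", np.random.default_rng(101))


@pytest.fixture(scope="session")
def micro_world(micro_base):
    return build_world(micro_base, "micro", np.random.default_rng(303))


@pytest.fixture(scope="session")
def desk_base():
    return build_base("desk", np.random.default_rng(202))


@pytest.fixture(scope="session")
def desk_world(desk_base):
    return build_world(desk_base, "desk", np.random.default_rng(404))


@pytest.fixture(scope="session")
def desk_warm(desk_world):
    """Warm-up snapshot on the desk world (mutates its trait state)."""
    ps = presets.scheme_config("PS", "desk")
    return run_warmup(ps, desk_world, np.random.default_rng(505))


GRID_CELLS = (
    GridCell("S4", 1, (500, 1)),
    GridCell("S4", 2, (500, 1)),
    GridCell("S4", 3, (500, 1)),
    GridCell("S4", 3, (50, 10)),
    GridCell("S4", 3, (500, 1),
             overrides=(("initial_pop_design", (500, 1)),)),
)


@pytest.fixture(scope="session")
def grid_ledger(desk_base):
    """20 paired desk replicates of the scenario-four comparison grid."""
    cfg = ExperimentConfig(cells=GRID_CELLS, replicates=20,
                           master_seed=501, preset="desk")
    ledger, manifest = run_experiment(cfg, base=desk_base)
    assert all(v == "ok" for v in manifest["status"].values())
    return ledger
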