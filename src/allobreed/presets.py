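"""Study presets: scheme definitions at full study scale ("full") and a
reduced scale ("desk") that keeps every code path, rate and ratio but
shrinks cohort sizes so a complete replicate runs on a laptop core.

Full-scale presets follow the commercial tall-fescue program: an
11-year phenotypic-selection (PS) cycle and four SpeedGS scenarios that
replace the crossing + topcross stages with a one-year genomic
selection / speed-breeding stage and optionally drop the small-plots
and/or single-row stages (S1: 9 y, S2: 6 y, S3: 7 y, S4: 4 y).

Desk scaling: cohort sizes shrink (topcross 1,000, 50 small plots of
60, 500 single rows, SpeedGS pool 500, 800-SNP panel, 2 PS warm-up
cycles) while the quantities that set per-cycle drift and selection
pressure keep their full-scale values or ratios: synthetics of 10
parents, a 50% row-selection fraction, a top-pair cap near 2% of all
candidate pairs, and crosses at ~4-5% of the pool.  The base
population keeps 4*N*mu = 0.4 (N = 100, mu = 1e-3) so equilibrium
heterozygosity is unchanged, and the event schedule is shortened in
proportion to the faster drift/mutation time scale.
"""

from __future__ import annotations

from dataclasses import asdict

from .basepop import ConfigError, EventSchedule, SimParams
from .breeding import SchemeConfig, StageDef
from .prediction import BRRSettings
from .traits import CorrelationTargets, default_trait_specs

__all__ = [
    "PRESET_NAMES",
    "SCHEME_IDS",
    "sim_params",
    "event_schedule",
    "scheme_config",
    "trait_specs",
    "correlation_targets",
    "panel_size",
    "brr_settings",
    "cultivar_params",
    "preset_summary",
    "scheme_to_dict",
    "scheme_from_dict",
]

PRESET_NAMES = ("full", "desk", "micro")
SCHEME_IDS = ("PS", "S1", "S2", "S3", "S4")

_STAGE_YEARS = {"crossing": 1, "topcross": 2, "speedgs": 1,
                "small_plots": 2, "single_rows": 3, "synthetics": 1,
                "field_trial": 2}

_SCHEME_STAGES = {
    "PS": ("crossing", "topcross", "small_plots", "single_rows",
           "synthetics", "field_trial"),
    "S1": ("speedgs", "small_plots", "single_rows", "synthetics",
           "field_trial"),
    "S2": ("speedgs", "small_plots", "synthetics", "field_trial"),
    "S3": ("speedgs", "single_rows", "synthetics", "field_trial"),
    "S4": ("speedgs", "synthetics", "field_trial"),
}

# scenarios without small plots double the field trial (2 plots per
# synthetic) to partially compensate the lost reference plots
_DOUBLE_FIELD = {"S3", "S4"}


def _check_preset(preset: str) -> None:
    if preset not in PRESET_NAMES:
        raise ConfigError(f"unknown preset {preset!r}")


def sim_params(preset: str = "full", seed: int | None = None) -> SimParams:
    _check_preset(preset)
    if preset == "full":
        return SimParams(rng_seed=seed)
    if preset == "desk":
        return SimParams(n_individuals=100, n_chromosomes=1,
                         loci_per_chromosome=2_500, mutation_rate=1e-3,
                         expansion_generations=20, rng_seed=seed)
    return SimParams(n_individuals=60, n_chromosomes=1,
                     loci_per_chromosome=400, mutation_rate=5e-3 / 3,
                     expansion_generations=10, rng_seed=seed)


def event_schedule(preset: str = "full") -> EventSchedule:
    _check_preset(preset)
    if preset == "full":
        return EventSchedule()
    if preset == "desk":
        return EventSchedule(speciation_generations=(150, 160, 300),
                             tetraploid_hybridization=330,
                             hexaploid_hybridization=520,
                             end_generation=1_000,
                             equilibrium_check_interval=80)
    return EventSchedule(speciation_generations=(60, 65, 120),
                        tetraploid_hybridization=130,
                        hexaploid_hybridization=200,
                        end_generation=420,
                        equilibrium_check_interval=40)


def cultivar_params(preset: str = "full") -> dict:
    """Founders per cultivar and generations of closed random mating.

    Scaled to keep the drift fraction generations / (2 N) at the
    full-scale value (100 / 2000 = 5%).
    """
    _check_preset(preset)
    if preset == "full":
        return {"n_cultivars": 20, "founders_per_cultivar": 1_000,
                "generations": 100}
    if preset == "desk":
        return {"n_cultivars": 20, "founders_per_cultivar": 80,
                "generations": 8}
    return {"n_cultivars": 20, "founders_per_cultivar": 40,
            "generations": 4}


def trait_specs(preset: str = "full"):
    _check_preset(preset)
    n_qtl = {"full": 1_000, "desk": 500, "micro": 100}[preset]
    return default_trait_specs(n_qtl=n_qtl)


def correlation_targets(preset: str = "full") -> CorrelationTargets:
    _check_preset(preset)
    n = {"full": 500, "desk": 250, "micro": 50}[preset]
    return CorrelationTargets(n_shared=n)


def panel_size(preset: str = "full") -> int:
    _check_preset(preset)
    return {"full": 100_000, "desk": 800, "micro": 120}[preset]


def brr_settings(preset: str = "full") -> BRRSettings:
    _check_preset(preset)
    if preset == "full":
        return BRRSettings(method="gibbs", iterations=50_000,
                           burn_in=10_000)
    return BRRSettings(method="ridge")


def _stage_tuple(scheme_id: str) -> tuple[StageDef, ...]:
    return tuple(StageDef(name, _STAGE_YEARS[name])
                 for name in _SCHEME_STAGES[scheme_id])


def scheme_config(scheme_id: str, preset: str = "full",
                  sb_rounds: int = 1,
                  crossing_scheme: tuple[int, int] | None = None,
                  **overrides) -> SchemeConfig:
    """Build a SchemeConfig for one scenario at one scale.

    ``crossing_scheme`` is the SpeedGS-stage (crosses, progeny-per-
    cross) rule; defaults to all-distinct crosses (1000 x 1 at full
    scale).  ``overrides`` replace any SchemeConfig field (used for the
    inbreeding-mitigation variants, e.g. ``initial_pop_design`` or
    ``synthetic_size``).
    """
    _check_preset(preset)
    if scheme_id not in SCHEME_IDS:
        raise ConfigError(f"unknown scheme {scheme_id!r}")
    stages = _stage_tuple(scheme_id)
    common = dict(scheme_id=scheme_id, stages=stages, sb_rounds=sb_rounds,
                  plots_per_synthetic=2 if scheme_id in _DOUBLE_FIELD else 1)
    if preset == "full":
        kw = dict(
            crossing_scheme=crossing_scheme or (1_000, 1),
            f1_pops_per_pair=5, seeds_per_f1=100,
            topcross_select=100, seeds_per_plot=500, plots_selected=40,
            clones_per_plot=25, rows_selected=500,
            n_synthetics=50, synthetic_size=10, field_plot_size=100,
            cultivars_selected=20, gs_pool_size=1_000, pair_cap=10_000,
            initial_pop_design=(50, 20), n_warmup_cycles=4,
            n_gs_cycles=4, **common)
    elif preset == "desk":
        kw = dict(
            crossing_scheme=crossing_scheme or (500, 1),
            f1_pops_per_pair=5, seeds_per_f1=20,
            topcross_select=50, seeds_per_plot=60, plots_selected=20,
            clones_per_plot=25, rows_selected=250,
            n_synthetics=25, synthetic_size=10, field_plot_size=60,
            cultivars_selected=20, gs_pool_size=500, pair_cap=2_500,
            initial_pop_design=(20, 25), n_warmup_cycles=2,
            n_gs_cycles=2, **common)
    else:  # micro: smallest internally consistent sizes, for smoke runs
        kw = dict(
            crossing_scheme=crossing_scheme or (60, 1),
            f1_pops_per_pair=3, seeds_per_f1=12,
            topcross_select=30, seeds_per_plot=30, plots_selected=12,
            clones_per_plot=5, rows_selected=48,
            n_synthetics=24, synthetic_size=2, field_plot_size=30,
            cultivars_selected=20, gs_pool_size=60, pair_cap=120,
            initial_pop_design=(10, 6), n_warmup_cycles=1,
            n_gs_cycles=2, **common)
    kw.update(overrides)
    return SchemeConfig(**kw)


def preset_summary(preset: str) -> dict:
    """Everything a manifest needs to identify the scale unambiguously."""
    _check_preset(preset)
    return {
        "preset": preset,
        "sim": asdict(sim_params(preset)),
        "schedule": {k: v for k, v in asdict(event_schedule(preset)).items()},
        "cultivars": cultivar_params(preset),
        "n_qtl": trait_specs(preset)[0].n_qtl,
        "n_shared_qtl": correlation_targets(preset).n_shared,
        "panel_size": panel_size(preset),
        "brr": asdict(brr_settings(preset)),
    }


def scheme_to_dict(cfg: SchemeConfig) -> dict:
    d = asdict(cfg)
    d["stages"] = [{"name": s.name, "duration_years": s.duration_years}
                   for s in cfg.stages]
    d["crossing_scheme"] = list(cfg.crossing_scheme)
    d["initial_pop_design"] = list(cfg.initial_pop_design)
    return d


def scheme_from_dict(d: dict) -> SchemeConfig:
    d = dict(d)
    d["stages"] = tuple(StageDef(s["name"], int(s["duration_years"]))
                        for s in d["stages"])
    d["crossing_scheme"] = tuple(d["crossing_scheme"])
    d["initial_pop_design"] = tuple(d["initial_pop_design"])
    return SchemeConfig(**d)
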