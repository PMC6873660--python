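"""Breeding-program engine: the conventional phenotypic program and the
SpeedGS scenarios, run as configurable stage pipelines.

The phenotypic program (one cycle, 11 years at full scale) is
crossing (20 cultivars -> 5,000 F1) -> topcross (HD cull, SY selection
-> 100 plants) -> small plots (100 plots of 500; FY+Per plot index ->
40 plots -> 1,000 clones) -> single rows (Q -> 500 rows) -> synthetics
(50 groups of 10 HD-similar rows) -> field trial (FY+Per plot index ->
20 cultivars).

SpeedGS scenarios replace crossing + topcross with a one-year stage of
1-3 (extensible to 6) speed-breeding rounds.  Each round genotypes the
candidate pool, predicts GEBVs for the five traits, ranks all
parent-pair averages of the weighted selection index, and draws the
configured number of crosses from the top of that ranking.  Downstream
stages follow the phenotypic program, with GEBV-based stand-ins where a
scenario omits the stage that would have produced phenotypes.

All selection uses cohort-standardized values; ties break by a seeded
uniform draw.  No mutation occurs during the breeding program.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .basepop import ConfigError, Population, mate_pairs
from .metrics import BaselineFreqs, delta_F
from .prediction import (BRRSettings, ReferencePopulation, SNPPanel,
                         TraitModel, fit_brr, panel_dosages,
                         pool_plot_genotype, predict_gebv, gebv_accuracy)
from .traits import QTLSet, TraitState, phenotype, tbv_matrix

__all__ = [
    "StageDef",
    "SchemeConfig",
    "Cohort",
    "PlotRecord",
    "World",
    "WarmupState",
    "candidate_pairs",
    "stage_crossing",
    "make_initial_population",
    "stage_topcross",
    "stage_small_plots",
    "stage_single_rows",
    "stage_synthetics",
    "stage_field_trial",
    "speedgs_stage",
    "run_warmup",
    "continue_program",
    "run_program",
]

LAM = 1.0  # crossovers per chromosome per meiosis throughout the program


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StageDef:
    name: str
    duration_years: int


@dataclass(frozen=True)
class SchemeConfig:
    """Declarative description of one breeding scheme.

    Field defaults are the full-scale phenotypic program; presets build
    internally consistent reduced-scale variants.  ``crossing_scheme``
    and ``initial_pop_design`` are (crosses, progeny-per-cross) pairs
    whose product must equal ``gs_pool_size``.
    """

    scheme_id: str = "PS"
    stages: tuple[StageDef, ...] = ()
    sb_rounds: int = 1
    crossing_scheme: tuple[int, int] = (1_000, 1)
    n_cultivars: int = 20
    f1_pops_per_pair: int = 5
    seeds_per_f1: int = 100
    topcross_select: int = 100
    hd_cull_frac: float = 0.2
    sy_pool_frac: float = 0.6
    seeds_per_plot: int = 500
    plots_selected: int = 40
    clones_per_plot: int = 25
    within_plot_top_frac: float = 0.8
    rows_selected: int = 500
    n_synthetics: int = 50
    synthetic_size: int = 10
    plots_per_synthetic: int = 1
    field_plot_size: int = 100
    cultivars_selected: int = 20
    gs_pool_size: int = 1_000
    pair_cap: int = 10_000
    initial_pop_design: tuple[int, int] = (50, 20)
    n_warmup_cycles: int = 4
    n_gs_cycles: int = 4

    def __post_init__(self) -> None:
        if self.n_cultivars % 2:
            raise ConfigError("cultivar count must be even (pairing)")
        if self.scheme_id != "PS":
            if not (1 <= self.sb_rounds <= 6):
                raise ConfigError("sb_rounds must be in 1..6")
            for label, (k, m) in (("crossing_scheme", self.crossing_scheme),
                                  ("initial_pop_design",
                                   self.initial_pop_design)):
                if k * m != self.gs_pool_size:
                    raise ConfigError(
                        f"{label} {k}x{m} must produce exactly "
                        f"{self.gs_pool_size} plants")
            if self.crossing_scheme[0] > self.pair_cap:
                raise ConfigError("more crosses requested than the top-pair "
                                  "cap")
        n_top = self.topcross_entries
        cull = int(round(self.hd_cull_frac * n_top))
        pool = int(round(self.sy_pool_frac * n_top))
        if pool > n_top - cull or self.topcross_select > pool:
            raise ConfigError("topcross selection sizes are inconsistent")
        if self.clones_per_plot > int(self.within_plot_top_frac
                                      * self.seeds_per_plot):
            raise ConfigError("plot size too small for the within-plot cut")
        if self.n_synthetics * self.synthetic_size > self.rows_selected:
            raise ConfigError("not enough selected rows to fill synthetics")
        if self.cultivars_selected > self.n_synthetics:
            raise ConfigError("fewer synthetics than cultivars to select")
        names = self.stage_names
        if "single_rows" in names or "small_plots" in names:
            produced = (self.plots_selected * self.clones_per_plot
                        if "small_plots" in names else self.gs_pool_size)
            if self.rows_selected > produced:
                raise ConfigError("row selection exceeds rows produced")

    @property
    def stage_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.stages)

    @property
    def cycle_length_years(self) -> int:
        return sum(s.duration_years for s in self.stages)

    @property
    def topcross_entries(self) -> int:
        return (self.n_cultivars // 2) * self.f1_pops_per_pair \
            * self.seeds_per_f1

    @property
    def reference_plots_per_gs_cycle(self) -> int:
        n = self.n_synthetics * self.plots_per_synthetic
        if "small_plots" in self.stage_names:
            n += self.topcross_select
        return n

    def crossing_label(self) -> str:
        return f"{self.crossing_scheme[0]}x{self.crossing_scheme[1]}"

    def design_label(self) -> str:
        return f"{self.initial_pop_design[0]}x{self.initial_pop_design[1]}"


def candidate_pairs(k: int) -> int:
    """Number of unordered parent pairs among k candidates."""
    return k * (k - 1) // 2


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    """A stage cohort: genomes plus ground-truth and predicted values."""

    pop: Population
    tbv: np.ndarray                       # (n, p)
    gebv: np.ndarray | None = None        # (n, p)
    family: np.ndarray | None = None      # full-sib family label per plant

    @property
    def n(self) -> int:
        return self.pop.n_individuals

    def subset(self, idx: np.ndarray) -> "Cohort":
        return Cohort(pop=self.pop.subset(idx), tbv=self.tbv[idx],
                      gebv=None if self.gebv is None else self.gebv[idx],
                      family=None if self.family is None
                      else self.family[idx])


@dataclass
class PlotRecord:
    """One plot kept for reference-population genotyping."""

    members: Population
    phenos: np.ndarray       # plot-level phenotype per trait
    mean_tbv: np.ndarray


def _standardized(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0.0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def _ranked_desc(values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Indices sorted by descending value; ties broken by seeded draw."""
    values = np.asarray(values, dtype=float)
    return np.lexsort((rng.random(values.size), -values))


def _plot_level_phenotypes(mean_tbv: np.ndarray, specs,
                           rng: np.random.Generator) -> np.ndarray:
    """Plot phenotypes: plot-mean TBV plus error with plot-level h2 equal
    to the trait h2 (error variance from the between-plot TBV variance)."""
    h2 = np.array([s.h2 for s in specs])
    var_g = mean_tbv.var(axis=0, ddof=1) if len(mean_tbv) > 1 \
        else np.zeros(len(h2))
    sd = np.sqrt(var_g * (1.0 - h2) / h2)
    return mean_tbv + rng.standard_normal(mean_tbv.shape) * sd


def _progeny(mother_haps: np.ndarray, father_haps: np.ndarray,
             qtl: QTLSet, rng: np.random.Generator,
             family: np.ndarray | None = None,
             template: Population | None = None) -> Cohort:
    haps = mate_pairs(mother_haps, father_haps, LAM, rng)
    pop = replace(template, haplotypes=haps, pedigree=None,
                  lineage="progeny")
    return Cohort(pop=pop, tbv=tbv_matrix(pop, qtl), family=family)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _paired_cultivar_crosses(cultivars: list[Population],
                             crosses_per_pair: int,
                             progeny_per_cross: int, qtl: QTLSet,
                             rng: np.random.Generator) -> Cohort:
    """Shared machinery of crossing stages.

    Cultivars are matched into a uniformly random disjoint perfect
    matching (redrawn every cycle).  Within a pair, ``crosses_per_pair``
    distinct plants are drawn from each cultivar and crossed one-to-one,
    each cross yielding ``progeny_per_cross`` full-sib seeds.
    """
    n_cult = len(cultivars)
    if n_cult % 2:
        raise ConfigError("need an even number of cultivars")
    order = rng.permutation(n_cult)
    mothers, fathers, fams = [], [], []
    fam = 0
    for p in range(n_cult // 2):
        a, b = cultivars[order[2 * p]], cultivars[order[2 * p + 1]]
        if crosses_per_pair > min(a.n_individuals, b.n_individuals):
            raise ConfigError("cultivar too small for the requested number "
                              "of distinct parents")
        ia = rng.choice(a.n_individuals, size=crosses_per_pair,
                        replace=False)
        ib = rng.choice(b.n_individuals, size=crosses_per_pair,
                        replace=False)
        rep = np.repeat(np.arange(crosses_per_pair), progeny_per_cross)
        mothers.append(a.haplotypes[ia[rep]])
        fathers.append(b.haplotypes[ib[rep]])
        fams.append(fam + rep)
        fam += crosses_per_pair
    family = np.concatenate(fams)
    cohort = _progeny(np.concatenate(mothers), np.concatenate(fathers),
                      qtl, rng, family=family, template=cultivars[0])
    return cohort


def stage_crossing(cultivars: list[Population], config: SchemeConfig,
                   qtl: QTLSet, rng: np.random.Generator) -> Cohort:
    """Crossing stage of the phenotypic program.

    20 cultivars -> 10 random disjoint pairs -> ``f1_pops_per_pair``
    plant-to-plant crosses per pair, each producing ``seeds_per_f1``
    full-sib seeds (full scale: 50 F1 populations of 100 = 5,000).
    """
    if len(cultivars) != config.n_cultivars:
        raise ConfigError(f"expected {config.n_cultivars} cultivars, "
                          f"got {len(cultivars)}")
    return _paired_cultivar_crosses(cultivars, config.f1_pops_per_pair,
                                    config.seeds_per_f1, qtl, rng)


def make_initial_population(cultivars: list[Population],
                            config: SchemeConfig, qtl: QTLSet,
                            rng: np.random.Generator,
                            design: tuple[int, int] | None = None) -> Cohort:
    """SpeedGS-cycle initial population from the current cultivars.

    Same pairwise cultivar scheme as the crossing stage, but with the
    configured number of distinct crosses and full-sib progeny per
    cross; more crosses draw more distinct plants per cultivar.
    """
    if len(cultivars) != config.n_cultivars:
        raise ConfigError(f"expected {config.n_cultivars} cultivars")
    k, m = design if design is not None else config.initial_pop_design
    if k * m != config.gs_pool_size:
        raise ConfigError(f"design {k}x{m} must produce "
                          f"{config.gs_pool_size} plants")
    n_pairs = config.n_cultivars // 2
    if k % n_pairs:
        raise ConfigError(f"crosses ({k}) must spread evenly over "
                          f"{n_pairs} cultivar pairs")
    return _paired_cultivar_crosses(cultivars, k // n_pairs, m, qtl, rng)


def stage_topcross(cohort: Cohort, config: SchemeConfig,
                   trait_state: TraitState, rng: np.random.Generator
                   ) -> tuple[Cohort, Cohort]:
    """Topcross selection on HD then SY.

    Discards the earliest-heading ``hd_cull_frac`` (lowest HD
    phenotype), keeps the top ``sy_pool_frac`` of the original count by
    SY phenotype among survivors, and draws ``topcross_select`` plants
    uniformly from that pool.  Returns (selected, HD-survivors); the
    survivors pollinate the small plots.
    """
    n = cohort.n
    cull = int(round(config.hd_cull_frac * n))
    pool_n = int(round(config.sy_pool_frac * n))
    if n - cull < pool_n or pool_n < config.topcross_select:
        raise ConfigError("too few plants for the topcross selection sizes")
    pheno = phenotype(cohort.tbv, trait_state, rng)
    names = [s.name for s in trait_state.specs]
    hd, sy = pheno[:, names.index("HD")], pheno[:, names.index("SY")]
    survivors = np.sort(_ranked_desc(hd, rng)[:n - cull])
    sy_rank = _ranked_desc(sy[survivors], rng)
    pool = survivors[sy_rank[:pool_n]]
    chosen = rng.choice(pool, size=config.topcross_select, replace=False)
    return cohort.subset(np.sort(chosen)), cohort.subset(survivors)


def stage_small_plots(mothers: Cohort, pollen: Cohort,
                      config: SchemeConfig, qtl: QTLSet,
                      trait_state: TraitState, rng: np.random.Generator
                      ) -> tuple[Cohort, list[PlotRecord]]:
    """Small-plot trial: one plot of ``seeds_per_plot`` half-sib seeds
    per selected mother, open-pollinated by the topcross survivors.

    Plots are phenotyped at plot level; the top ``plots_selected`` by
    the equal-weight standardized FY + Per index are kept, and within
    each kept plot ``clones_per_plot`` random plants from the top
    ``within_plot_top_frac`` (individual FY + Per index) are cloned
    into single rows.  All plots are retained for reference
    genotyping.
    """
    specs = trait_state.specs
    names = [s.name for s in specs]
    i_fy, i_per = names.index("FY"), names.index("Per")
    n_plots, sz = mothers.n, config.seeds_per_plot
    midx = np.repeat(np.arange(n_plots), sz)
    fidx = rng.integers(0, pollen.n, size=n_plots * sz)
    prog = _progeny(mothers.pop.haplotypes[midx],
                    pollen.pop.haplotypes[fidx], qtl, rng,
                    family=midx, template=mothers.pop)
    mean_tbv = prog.tbv.reshape(n_plots, sz, -1).mean(axis=1)
    plot_pheno = _plot_level_phenotypes(mean_tbv, specs, rng)
    index = (_standardized(plot_pheno[:, i_fy])
             + _standardized(plot_pheno[:, i_per]))
    keep_plots = _ranked_desc(index, rng)[:config.plots_selected]

    plots = [PlotRecord(members=prog.pop.subset(
                            np.arange(p * sz, (p + 1) * sz)),
                        phenos=plot_pheno[p], mean_tbv=mean_tbv[p])
             for p in range(n_plots)]

    ind_pheno = phenotype(prog.tbv, trait_state, rng)
    clone_rows = []
    n_top = int(config.within_plot_top_frac * sz)
    for p in keep_plots:
        sl = slice(p * sz, (p + 1) * sz)
        ind_index = (_standardized(ind_pheno[sl, i_fy])
                     + _standardized(ind_pheno[sl, i_per]))
        top = _ranked_desc(ind_index, rng)[:n_top]
        chosen = rng.choice(top, size=config.clones_per_plot, replace=False)
        clone_rows.append(p * sz + chosen)
    rows = prog.subset(np.sort(np.concatenate(clone_rows)))
    return rows, plots


def stage_single_rows(rows: Cohort, config: SchemeConfig,
                      trait_state: TraitState, rng: np.random.Generator,
                      include_sy: bool = False
                      ) -> tuple[Cohort, np.ndarray, np.ndarray]:
    """Single-row selection: top ``rows_selected`` by Q phenotype (the
    phenotypic program) or by the equal-weight standardized SY + Q
    index (SpeedGS scenarios, ``include_sy``).

    Returns (selected rows, their HD phenotypes, their ranking scores);
    both arrays feed the synthetics stage.
    """
    if rows.n < config.rows_selected:
        raise ConfigError("fewer rows than the selection target")
    pheno = phenotype(rows.tbv, trait_state, rng)
    names = [s.name for s in trait_state.specs]
    score = _standardized(pheno[:, names.index("Q")])
    if include_sy:
        score = score + _standardized(pheno[:, names.index("SY")])
    top = _ranked_desc(score, rng)[:config.rows_selected]
    top = np.sort(top)
    return rows.subset(top), pheno[top, names.index("HD")], score[top]


def stage_synthetics(rows: Cohort, rank_score: np.ndarray,
                     hd_score: np.ndarray, config: SchemeConfig,
                     rng: np.random.Generator) -> list[Cohort]:
    """Group rows into synthetic populations of HD-similar parents.

    The top ``n_synthetics * synthetic_size`` rows by ``rank_score``
    are sorted by ``hd_score`` (phenotype where available, GEBV
    otherwise) and partitioned consecutively, so each synthetic's
    parents head at similar times.
    """
    need = config.n_synthetics * config.synthetic_size
    if rows.n < need:
        raise ConfigError("not enough rows for the synthetics")
    keep = _ranked_desc(rank_score, rng)[:need]
    order = keep[_ranked_desc(-np.asarray(hd_score)[keep], rng)]
    return [rows.subset(np.sort(order[g * config.synthetic_size:
                                      (g + 1) * config.synthetic_size]))
            for g in range(config.n_synthetics)]


def stage_field_trial(synthetics: list[Cohort], config: SchemeConfig,
                      qtl: QTLSet, trait_state: TraitState,
                      rng: np.random.Generator
                      ) -> tuple[list[Population], list[PlotRecord]]:
    """Field trial: large plots of random-mated synthetic seed.

    Each synthetic sows ``plots_per_synthetic`` plots of
    ``field_plot_size`` plants (random mating among its parents).
    Synthetics are ranked by the mean over their plots of the
    equal-weight standardized FY + Per plot index; the top
    ``cultivars_selected`` become next-cycle cultivars (their plot
    plants pooled).  All plots are retained for reference genotyping.
    """
    if len(synthetics) != config.n_synthetics:
        raise ConfigError(f"expected {config.n_synthetics} synthetics")
    specs = trait_state.specs
    names = [s.name for s in specs]
    i_fy, i_per = names.index("FY"), names.index("Per")
    plot_pops, mean_tbvs, owner = [], [], []
    for s_idx, syn in enumerate(synthetics):
        for _ in range(config.plots_per_synthetic):
            mo = rng.integers(0, syn.n, size=config.field_plot_size)
            fa = rng.integers(0, syn.n - 1, size=config.field_plot_size)
            fa[fa >= mo] += 1
            prog = _progeny(syn.pop.haplotypes[mo], syn.pop.haplotypes[fa],
                            qtl, rng, template=syn.pop)
            plot_pops.append(prog)
            mean_tbvs.append(prog.tbv.mean(axis=0))
            owner.append(s_idx)
    mean_tbv = np.vstack(mean_tbvs)
    plot_pheno = _plot_level_phenotypes(mean_tbv, specs, rng)
    index = (_standardized(plot_pheno[:, i_fy])
             + _standardized(plot_pheno[:, i_per]))
    owner = np.asarray(owner)
    syn_score = np.array([index[owner == s].mean()
                          for s in range(config.n_synthetics)])
    best = _ranked_desc(syn_score, rng)[:config.cultivars_selected]
    cultivars = []
    for s in best:
        members = [plot_pops[i].pop.haplotypes
                   for i in np.flatnonzero(owner == s)]
        pop = replace(plot_pops[0].pop,
                      haplotypes=np.concatenate(members),
                      lineage=f"cultivar_s{s}")
        cultivars.append(pop)
    plots = [PlotRecord(members=plot_pops[i].pop, phenos=plot_pheno[i],
                        mean_tbv=mean_tbv[i])
             for i in range(len(plot_pops))]
    return cultivars, plots


# ---------------------------------------------------------------------------
# SpeedGS stage
# ---------------------------------------------------------------------------

def _index_gebv(gebv: np.ndarray, specs) -> np.ndarray:
    """Weighted selection index on cohort-standardized per-trait GEBVs."""
    return sum(s.index_weight * _standardized(gebv[:, j])
               for j, s in enumerate(specs))


def _predict_cohort(cohort: Cohort, models: dict[str, TraitModel],
                    panel: SNPPanel, trait_names) -> np.ndarray:
    Z = panel_dosages(cohort.pop, panel).astype(float)
    return np.column_stack([predict_gebv(models[t], Z)
                            for t in trait_names])


def speedgs_stage(pool: Cohort, models: dict[str, TraitModel],
                  config: SchemeConfig, qtl: QTLSet, panel: SNPPanel,
                  trait_state: TraitState, rng: np.random.Generator
                  ) -> tuple[Cohort, list[dict]]:
    """One year of speed-breeding rounds driven by genomic selection.

    Per round: genotype the pool, predict per-trait GEBVs, form the
    weighted index on standardized GEBVs, rank all parent-pair index
    averages, draw ``crossing_scheme`` crosses uniformly from the top
    ``pair_cap`` pairs, and produce the next pool of full-sib progeny.
    SNP effects are estimated once per cycle and reused across rounds.
    Returns the final pool (with its GEBVs attached) and per-round,
    per-trait accuracy records.
    """
    if not (1 <= config.sb_rounds <= 6):
        raise ConfigError("sb_rounds must be in 1..6")
    specs = trait_state.specs
    names = [s.name for s in specs]
    n_cross, n_prog = config.crossing_scheme
    acc_records: list[dict] = []
    cohort = pool
    for rnd in range(1, config.sb_rounds + 1):
        gebv = _predict_cohort(cohort, models, panel, names)
        cohort = Cohort(pop=cohort.pop, tbv=cohort.tbv, gebv=gebv,
                        family=cohort.family)
        for j, t in enumerate(names):
            acc_records.append({
                "round": rnd, "trait": t,
                "accuracy": gebv_accuracy(gebv[:, j], cohort.tbv[:, j])})
        idx = _index_gebv(gebv, specs)
        k = cohort.n
        iu = np.triu_indices(k, k=1)
        pair_avg = (idx[iu[0]] + idx[iu[1]]) / 2.0
        top = _ranked_desc(pair_avg, rng)[:config.pair_cap]
        chosen = rng.choice(top, size=n_cross, replace=False)
        mo, fa = iu[0][chosen], iu[1][chosen]
        rep = np.repeat(np.arange(n_cross), n_prog)
        cohort = _progeny(cohort.pop.haplotypes[mo[rep]],
                          cohort.pop.haplotypes[fa[rep]], qtl, rng,
                          family=rep, template=cohort.pop)
    gebv = _predict_cohort(cohort, models, panel, names)
    cohort = Cohort(pop=cohort.pop, tbv=cohort.tbv, gebv=gebv,
                    family=cohort.family)
    return cohort, acc_records


# ---------------------------------------------------------------------------
# program orchestration
# ---------------------------------------------------------------------------

@dataclass
class World:
    """Everything a breeding run needs besides the scheme itself."""

    cultivars: list[Population]
    qtl: QTLSet
    panel: SNPPanel
    trait_state: TraitState
    brr: BRRSettings = field(default_factory=lambda: BRRSettings(
        method="ridge"))

    @property
    def trait_names(self) -> tuple[str, ...]:
        return self.qtl.trait_names


@dataclass
class WarmupState:
    """Snapshot after the phenotypic warm-up cycles.

    ``init_cohort`` is the crossing output that opens the first
    genomic-selection cycle; scenario runs branching from the same
    warm-up state are paired replicates.
    """

    cultivars: list[Population]
    reference: ReferencePopulation
    trait_state: TraitState
    init_cohort: Cohort
    n_warmup_cycles: int

    def copy(self) -> "WarmupState":
        ref = ReferencePopulation(self.reference.n_markers,
                                  self.reference.trait_names)
        ref._Z = list(self.reference._Z)
        ref._y = list(self.reference._y)
        ref._prov = list(self.reference._prov)
        return WarmupState(cultivars=list(self.cultivars), reference=ref,
                           trait_state=_copy.deepcopy(self.trait_state),
                           init_cohort=self.init_cohort,
                           n_warmup_cycles=self.n_warmup_cycles)


def _add_plots_to_reference(reference: ReferencePopulation,
                            plots: list[PlotRecord], panel: SNPPanel,
                            cycle: int, stage: str,
                            rng: np.random.Generator) -> None:
    for plot in plots:
        z = pool_plot_genotype(plot.members, panel, rng)
        reference.add_plot(z, plot.phenos, cycle, stage)


def _ps_cycle_rest(init: Cohort, config: SchemeConfig, world: World,
                   rng: np.random.Generator
                   ) -> tuple[list[Population], list[PlotRecord]]:
    """Phenotypic cycle from the crossing output to new cultivars."""
    selected, survivors = stage_topcross(init, config, world.trait_state,
                                         rng)
    rows, small_plots = stage_small_plots(selected, survivors, config,
                                          world.qtl, world.trait_state, rng)
    sel_rows, hd, score = stage_single_rows(rows, config, world.trait_state,
                                            rng, include_sy=False)
    synthetics = stage_synthetics(sel_rows, score, hd, config, rng)
    cultivars, _ = stage_field_trial(synthetics, config, world.qtl,
                                     world.trait_state, rng)
    return cultivars, small_plots


def run_warmup(ps_config: SchemeConfig, world: World,
               rng: np.random.Generator) -> WarmupState:
    """Run the phenotypic warm-up cycles and bank their small plots as
    the starting reference population."""
    if ps_config.scheme_id != "PS":
        raise ConfigError("warm-up must use the phenotypic scheme")
    reference = ReferencePopulation(world.panel.size, world.trait_names)
    cultivars = world.cultivars
    for cycle in range(1, ps_config.n_warmup_cycles + 1):
        init = stage_crossing(cultivars, ps_config, world.qtl, rng)
        world.trait_state.refresh(init.tbv)
        cultivars, small_plots = _ps_cycle_rest(init, ps_config, world, rng)
        _add_plots_to_reference(reference, small_plots, world.panel,
                                cycle, "small_plots", rng)
    init_cohort = stage_crossing(cultivars, ps_config, world.qtl, rng)
    return WarmupState(cultivars=cultivars, reference=reference,
                       trait_state=world.trait_state,
                       init_cohort=init_cohort,
                       n_warmup_cycles=ps_config.n_warmup_cycles)


class _Recorder:
    """Per-cycle metrics ledger builder."""

    def __init__(self, config: SchemeConfig, world: World,
                 rng: np.random.Generator):
        self.config = config
        self.world = world
        self.rng = rng
        self.rows: list[dict] = []
        self.baseline_stats = None
        self.baseline_freqs: BaselineFreqs | None = None
        self.prev_F: float | None = None

    def _emit(self, cycle, year, metric, value, trait="", rnd=np.nan):
        c = self.config
        self.rows.append({
            "scheme": c.scheme_id, "sb_rounds": c.sb_rounds,
            "crossing": c.crossing_label(), "design": c.design_label(),
            "synthetic_size": c.synthetic_size, "cycle": cycle,
            "year": year, "round": rnd, "trait": trait,
            "metric": metric, "value": value})

    def record_cycle(self, cohort: Cohort, cycle: int, year: float) -> None:
        """Metrics of a cycle's initial population (and h2 refresh)."""
        w = self.world
        names = w.trait_names
        specs = w.trait_state.specs
        w.trait_state.refresh(cohort.tbv)
        pheno = phenotype(cohort.tbv, w.trait_state, self.rng)
        Z = panel_dosages(cohort.pop, w.panel).astype(float)
        p_now = Z.mean(axis=0) / 2.0
        if self.baseline_stats is None:
            self.baseline_stats = (cohort.tbv.mean(axis=0),
                                   cohort.tbv.std(axis=0, ddof=1))
            self.baseline_freqs = BaselineFreqs(p_now)
            corr = np.corrcoef(cohort.tbv, rowvar=False)
            for i in range(len(names)):
                for j in range(i + 1, len(names)):
                    self._emit(cycle, year, "tbv_corr", corr[i, j],
                               trait=f"{names[i]}:{names[j]}")
        mu0, sd0 = self.baseline_stats
        gains = (cohort.tbv.mean(axis=0) - mu0) / sd0
        W = Z - 2.0 * self.baseline_freqs.freqs
        denom = 2.0 * float(np.sum(self.baseline_freqs.freqs
                                   * (1 - self.baseline_freqs.freqs)))
        F = float(np.mean((W ** 2).sum(axis=1)) / denom - 1.0)
        he = float(np.mean(2.0 * p_now * (1.0 - p_now)))
        var_ratio = cohort.tbv.var(axis=0, ddof=1) \
            / pheno.var(axis=0, ddof=1)
        index_gain = sum(s.index_weight * g for s, g in zip(specs, gains))
        for j, t in enumerate(names):
            self._emit(cycle, year, "tbv_mean", cohort.tbv[:, j].mean(), t)
            self._emit(cycle, year, "tbv_sd",
                       cohort.tbv[:, j].std(ddof=1), t)
            self._emit(cycle, year, "gain", gains[j], t)
            self._emit(cycle, year, "realized_h2", var_ratio[j], t)
        self._emit(cycle, year, "index_gain", index_gain)
        self._emit(cycle, year, "F", F)
        self._emit(cycle, year, "he_panel", he)
        if self.prev_F is not None:
            self._emit(cycle, year, "delta_F", delta_F(F, self.prev_F))
        self.prev_F = F

    def record_accuracy(self, acc_records: list[dict], cycle: int,
                        year: float) -> None:
        for rec in acc_records:
            self._emit(cycle, year, "accuracy", rec["accuracy"],
                       trait=rec["trait"], rnd=rec["round"])

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


def _train_models(reference: ReferencePopulation, world: World,
                  rng: np.random.Generator) -> dict[str, TraitModel]:
    if reference.n_rows < 2:
        raise ConfigError("reference population is too small to train on")
    Z = reference.Z().astype(float)
    models = {}
    for t in world.trait_names:
        h2 = world.qtl.spec(t).h2
        settings = replace(world.brr, h2_prior=h2)
        models[t] = fit_brr(Z, reference.y(t), settings, rng)
    return models


def _gs_cycle_rest(out: Cohort, config: SchemeConfig, world: World,
                   models: dict[str, TraitModel],
                   rng: np.random.Generator
                   ) -> tuple[list[Population], list[PlotRecord]]:
    """From the SpeedGS-stage output to new cultivars, following the
    scenario's remaining stages with GEBV stand-ins where a stage that
    would have produced phenotypes is omitted."""
    specs = world.trait_state.specs
    names = list(world.trait_names)
    stage_names = config.stage_names
    plots_out: list[PlotRecord] = []
    current = out
    if "small_plots" in stage_names:
        idx = _index_gebv(current.gebv, specs)
        mother_rows = np.sort(_ranked_desc(idx, rng)
                              [:config.topcross_select])
        mothers = current.subset(mother_rows)
        rows, small_plots = stage_small_plots(mothers, current, config,
                                              world.qtl, world.trait_state,
                                              rng)
        plots_out.extend(small_plots)
        current = rows
    if "single_rows" in stage_names:
        current, hd_score, rank_score = stage_single_rows(
            current, config, world.trait_state, rng, include_sy=True)
    else:
        if current.gebv is None:
            gebv = _predict_cohort(current, models, world.panel, names)
            current = Cohort(pop=current.pop, tbv=current.tbv, gebv=gebv,
                             family=current.family)
        score = (_standardized(current.gebv[:, names.index("SY")])
                 + _standardized(current.gebv[:, names.index("Q")]))
        keep = np.sort(_ranked_desc(score, rng)[:config.rows_selected])
        hd_score = current.gebv[keep, names.index("HD")]
        rank_score = score[keep]
        current = current.subset(keep)
    synthetics = stage_synthetics(current, rank_score, hd_score, config,
                                  rng)
    cultivars, field_plots = stage_field_trial(
        synthetics, config, world.qtl, world.trait_state, rng)
    plots_out.extend(field_plots)
    return cultivars, plots_out


def continue_program(config: SchemeConfig, ps_config: SchemeConfig,
                     warm: WarmupState, world: World,
                     rng: np.random.Generator) -> pd.DataFrame:
    """Run the evaluated cycles of one scheme from a warm-up snapshot.

    The warm-up crossing output is the baseline cohort (standardized
    gain 0, F reference); the program then runs ``n_gs_cycles`` cycles
    of the configured scheme plus one final initial population
    generated purely to track gain, exactly mirroring the study's
    accounting.  Returns the tidy metrics ledger.
    """
    world = replace(world, trait_state=warm.trait_state)
    rec = _Recorder(config, world, rng)
    ps_years = ps_config.cycle_length_years
    year0 = warm.n_warmup_cycles * ps_years
    first_cycle = warm.n_warmup_cycles + 1
    if config.scheme_id == "PS":
        init = warm.init_cohort
        cultivars = warm.cultivars
        for i in range(config.n_gs_cycles):
            cycle = first_cycle + i
            rec.record_cycle(init, cycle, year0 + i * ps_years)
            cultivars, _ = _ps_cycle_rest(init, config, world, rng)
            init = stage_crossing(cultivars, config, world.qtl, rng)
        rec.record_cycle(init, first_cycle + config.n_gs_cycles,
                         year0 + config.n_gs_cycles * ps_years)
        return rec.frame()

    # SpeedGS: the first GS cycle's pool is a random draw from the
    # phenotypic crossing output; later cycles build their own pools
    reference = warm.reference
    take = rng.choice(warm.init_cohort.n, size=config.gs_pool_size,
                      replace=False)
    init = warm.init_cohort.subset(np.sort(take))
    cultivars = warm.cultivars
    cyc_years = config.cycle_length_years
    for i in range(config.n_gs_cycles):
        cycle = first_cycle + i
        year = year0 + i * cyc_years
        rec.record_cycle(init, cycle, year)
        models = _train_models(reference, world, rng)
        out, acc = speedgs_stage(init, models, config, world.qtl,
                                 world.panel, world.trait_state, rng)
        rec.record_accuracy(acc, cycle, year)
        cultivars, plots = _gs_cycle_rest(out, config, world, models, rng)
        _add_plots_to_reference(reference, plots, world.panel, cycle,
                                "gs_cycle", rng)
        init = make_initial_population(cultivars, config, world.qtl, rng)
    rec.record_cycle(init, first_cycle + config.n_gs_cycles,
                     year0 + config.n_gs_cycles * cyc_years)
    return rec.frame()


def run_program(config: SchemeConfig, ps_config: SchemeConfig,
                world: World, rng: np.random.Generator) -> pd.DataFrame:
    """Warm-up plus evaluated cycles in one call (single-scheme runs)."""
    warm = run_warmup(ps_config, world, rng)
    return continue_program(config, ps_config, warm, world, rng)
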