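"""Breeding engine: stage cardinalities, selection-rule oracles and
program orchestration."""

import dataclasses

import numpy as np
import pytest

from allobreed import presets
from allobreed.basepop import ConfigError
from allobreed.breeding import (Cohort, SchemeConfig, candidate_pairs,
                                make_initial_population, run_program,
                                speedgs_stage, stage_crossing,
                                stage_field_trial, stage_single_rows,
                                stage_small_plots, stage_synthetics,
                                stage_topcross)
from allobreed.prediction import TraitModel
from allobreed.traits import TRAIT_ORDER, TraitSpec, TraitState, tbv_matrix
from conftest import make_population

# deterministic phenotypes: h2 = 1 makes every selection rule a pure
# function of the true breeding values, so brute-force oracles apply
SPECS_H2_1 = tuple(
    TraitSpec(name, h2=1.0, n_qtl=10, index_weight=w)
    for name, w in zip(TRAIT_ORDER, (0.25, 0.10, 0.15, 0.15, 0.35)))

I_FY, I_HD, I_SY, I_Q, I_PER = range(5)


def toy_config(**over) -> SchemeConfig:
    base = dict(scheme_id="PS",
                stages=presets.scheme_config("PS", "micro").stages,
                n_cultivars=4, f1_pops_per_pair=1, seeds_per_f1=10,
                topcross_select=5, seeds_per_plot=10, plots_selected=4,
                clones_per_plot=5, rows_selected=20, n_synthetics=4,
                synthetic_size=5, field_plot_size=10,
                cultivars_selected=4, gs_pool_size=20,
                pair_cap=50, crossing_scheme=(20, 1),
                initial_pop_design=(20, 1))
    base.update(over)
    return SchemeConfig(**base)


def toy_cohort(tbv, rng, n_loci=20):
    tbv = np.asarray(tbv, dtype=float)
    pop = make_population(np.full(n_loci, 0.5), len(tbv), rng)
    return Cohort(pop=pop, tbv=tbv)


def fresh_state(tbv):
    state = TraitState(SPECS_H2_1)
    state.refresh(np.asarray(tbv, dtype=float))
    return state


class TestConfigValidation:
    def test_cycle_lengths_follow_stage_durations(self):
        years = {s: presets.scheme_config(s, "full").cycle_length_years
                 for s in presets.SCHEME_IDS}
        assert years == {"PS": 11, "S1": 9, "S2": 6, "S3": 7, "S4": 4}

    def test_speedgs_products_enforced(self):
        with pytest.raises(ConfigError):
            presets.scheme_config("S4", "full",
                                  crossing_scheme=(999, 1))
        with pytest.raises(ConfigError):
            presets.scheme_config("S4", "full",
                                  initial_pop_design=(30, 30))
        with pytest.raises(ConfigError):
            presets.scheme_config("S4", "full", sb_rounds=7)

    def test_candidate_pair_count(self):
        cfg = presets.scheme_config("S4", "full")
        assert candidate_pairs(cfg.gs_pool_size) == 499_500
        assert candidate_pairs(4) == 6


class TestCrossing:
    def test_full_scale_cardinality(self, micro_world):
        # 20 cultivars -> 10 pairs x 5 crosses x 100 seeds = 5,000
        cfg = dataclasses.replace(
            presets.scheme_config("PS", "full"),
            topcross_select=30)  # keep later stages out of play
        rng = np.random.default_rng(1)
        cohort = stage_crossing(micro_world.cultivars, cfg,
                                micro_world.qtl, rng)
        assert cohort.n == 5_000
        fams, sizes = np.unique(cohort.family, return_counts=True)
        assert len(fams) == 50 and np.all(sizes == 100)

    def test_toy_cardinality(self, micro_world):
        # 4 cultivars, 1 F1 population per pair, 10 seeds -> 20 plants
        cfg = toy_config()
        rng = np.random.default_rng(2)
        cohort = stage_crossing(micro_world.cultivars[:4], cfg,
                                micro_world.qtl, rng)
        assert cohort.n == 20
        assert len(np.unique(cohort.family)) == 2

    def test_wrong_cultivar_count_rejected(self, micro_world):
        with pytest.raises(ConfigError):
            stage_crossing(micro_world.cultivars[:6], toy_config(),
                           micro_world.qtl, np.random.default_rng(3))

    def test_deterministic_under_seed(self, micro_world):
        cfg = presets.scheme_config("PS", "micro")
        a = stage_crossing(micro_world.cultivars, cfg, micro_world.qtl,
                           np.random.default_rng(4))
        b = stage_crossing(micro_world.cultivars, cfg, micro_world.qtl,
                           np.random.default_rng(4))
        assert np.array_equal(a.pop.haplotypes, b.pop.haplotypes)


class TestInitialPopulation:
    @pytest.mark.parametrize("design", [(60, 1), (10, 6), (20, 3)])
    def test_family_structure(self, micro_world, design):
        cfg = presets.scheme_config("S4", "micro")
        pop = make_initial_population(micro_world.cultivars, cfg,
                                      micro_world.qtl,
                                      np.random.default_rng(5),
                                      design=design)
        assert pop.n == cfg.gs_pool_size
        fams, sizes = np.unique(pop.family, return_counts=True)
        assert len(fams) == design[0] and np.all(sizes == design[1])

    def test_bad_designs_rejected(self, micro_world):
        cfg = presets.scheme_config("S4", "micro")
        rng = np.random.default_rng(6)
        with pytest.raises(ConfigError):
            make_initial_population(micro_world.cultivars, cfg,
                                    micro_world.qtl, rng, design=(7, 7))
        with pytest.raises(ConfigError):
            # 15 crosses cannot spread evenly over 10 cultivar pairs
            make_initial_population(micro_world.cultivars, cfg,
                                    micro_world.qtl, rng, design=(15, 4))


class TestTopcross:
    def test_selection_respects_hd_then_sy(self):
        rng = np.random.default_rng(7)
        tbv = rng.standard_normal((50, 5))
        cohort = toy_cohort(tbv, rng)
        sel, survivors = stage_topcross(cohort, toy_config(),
                                        fresh_state(tbv), rng)
        assert sel.n == 5 and survivors.n == 40
        # brute force: cull the 10 lowest HD, keep SY top-30 of the rest
        hd_rank = np.argsort(tbv[:, I_HD])
        culled = set(hd_rank[:10])
        surviving = [i for i in range(50) if i not in culled]
        sy_pool = set(sorted(surviving,
                             key=lambda i: -tbv[i, I_SY])[:30])
        sel_ids = {tuple(row) for row in sel.tbv}
        pool_ids = {tuple(tbv[i]) for i in sy_pool}
        assert sel_ids <= pool_ids

    def test_too_small_cohort_rejected(self):
        rng = np.random.default_rng(8)
        tbv = rng.standard_normal((6, 5))
        with pytest.raises(ConfigError):
            stage_topcross(toy_cohort(tbv, rng), toy_config(),
                           fresh_state(tbv), rng)


class TestSmallPlots:
    def _run(self, rng, micro_world, cfg):
        pop = make_population(rng.uniform(0.3, 0.7, 1_200),
                              n=cfg.topcross_select + 50, rng=rng,
                              n_chromosomes=3)
        tbv = tbv_matrix(pop, micro_world.qtl)
        mothers = Cohort(pop=pop.subset(np.arange(cfg.topcross_select)),
                         tbv=tbv[:cfg.topcross_select])
        pollen = Cohort(pop=pop.subset(np.arange(cfg.topcross_select,
                                                 pop.n_individuals)),
                        tbv=tbv[cfg.topcross_select:])
        state = TraitState(SPECS_H2_1)
        state.refresh(tbv)
        return stage_small_plots(mothers, pollen, cfg, micro_world.qtl,
                                 state, rng)

    def test_counts_and_plot_ranking_oracle(self, micro_world):
        cfg = toy_config(topcross_select=10, seeds_per_plot=50,
                         plots_selected=4, clones_per_plot=5,
                         rows_selected=20)
        rows, plots = self._run(np.random.default_rng(9), micro_world,
                                cfg)
        assert len(plots) == 10
        assert rows.n == 4 * 5
        assert all(p.members.n_individuals == 50 for p in plots)
        # with h2=1 the plot phenotype equals the plot-mean TBV, so the
        # selected plots are the brute-force top-4 by the FY+Per index
        phen = np.array([p.phenos for p in plots])
        mean_tbv = np.array([p.mean_tbv for p in plots])
        assert np.allclose(phen, mean_tbv)

        def z(x):
            return (x - x.mean()) / x.std()

        index = z(phen[:, I_FY]) + z(phen[:, I_PER])
        top4 = set(np.argsort(-index)[:4])
        assert set(np.unique(rows.family)) == top4

    def test_full_scale_cardinality(self, micro_world):
        # 100 plots of 500 -> 40 selected -> 1,000 single-row plants
        cfg = dataclasses.replace(presets.scheme_config("PS", "full"),
                                  seeds_per_plot=60)  # keep memory sane
        rows, plots = self._run(np.random.default_rng(10),
                                micro_world,
                                dataclasses.replace(cfg,
                                                    topcross_select=100))
        assert len(plots) == 100
        assert rows.n == 1_000


class TestSingleRows:
    def test_monotone_q_selects_upper_half(self, micro_world):
        rng = np.random.default_rng(11)
        tbv = np.zeros((40, 5))
        tbv[:, I_Q] = np.arange(40, dtype=float)
        cohort = toy_cohort(tbv, rng)
        sel, hd, score = stage_single_rows(cohort, toy_config(),
                                           fresh_state(tbv), rng)
        assert sel.n == 20
        assert set(sel.tbv[:, I_Q]) == set(np.arange(20, 40, dtype=float))

    def test_sy_q_index_matches_brute_force(self, micro_world):
        rng = np.random.default_rng(12)
        tbv = rng.standard_normal((40, 5))
        cohort = toy_cohort(tbv, rng)
        cfg = toy_config(rows_selected=10, n_synthetics=2,
                         cultivars_selected=2)
        sel, hd, score = stage_single_rows(cohort, cfg, fresh_state(tbv),
                                           rng, include_sy=True)

        def z(x):
            return (x - x.mean()) / x.std()

        oracle = z(tbv[:, I_Q]) + z(tbv[:, I_SY])
        want = set(np.argsort(-oracle)[:10])
        got = {tuple(r) for r in sel.tbv}
        assert got == {tuple(tbv[i]) for i in want}
        # HD values returned alongside are the selected rows' phenotypes
        assert hd == pytest.approx(sel.tbv[:, I_HD])


class TestSynthetics:
    def test_groups_are_hd_contiguous(self, micro_world):
        rng = np.random.default_rng(13)
        tbv = rng.standard_normal((20, 5))
        cohort = toy_cohort(tbv, rng)
        hd = tbv[:, I_HD]
        score = np.zeros(20)  # all rows eligible; grouping by HD only
        cfg = toy_config()
        syns = stage_synthetics(cohort, score, hd, cfg, rng)
        assert len(syns) == 4
        assert all(s.n == 5 for s in syns)
        ranges = sorted((s.tbv[:, I_HD].min(), s.tbv[:, I_HD].max())
                        for s in syns)
        for (lo1, hi1), (lo2, hi2) in zip(ranges, ranges[1:]):
            assert hi1 <= lo2

    def test_smaller_synthetic_size_uses_top_rows(self, micro_world):
        rng = np.random.default_rng(14)
        tbv = rng.standard_normal((20, 5))
        cohort = toy_cohort(tbv, rng)
        score = np.arange(20, dtype=float)
        cfg = toy_config(synthetic_size=2)
        syns = stage_synthetics(cohort, score, tbv[:, I_HD], cfg, rng)
        used = np.concatenate([s.tbv for s in syns])
        kept_scores = {tuple(r) for r in used}
        top8 = {tuple(tbv[i]) for i in range(12, 20)}
        assert kept_scores == top8


class TestFieldTrial:
    def test_counts_and_cultivar_pooling(self, micro_world):
        rng = np.random.default_rng(15)
        cfg = toy_config(n_synthetics=6, cultivars_selected=4,
                         plots_per_synthetic=2, field_plot_size=10,
                         plots_selected=6, rows_selected=30,
                         synthetic_size=5)
        tbv = tbv_matrix(micro_world.cultivars[0], micro_world.qtl)
        state = TraitState(SPECS_H2_1)
        state.refresh(tbv)
        syns = [Cohort(pop=micro_world.cultivars[0].subset(
                           np.arange(i * 5, i * 5 + 5)),
                       tbv=tbv[i * 5:i * 5 + 5]) for i in range(6)]
        cultivars, plots = stage_field_trial(syns, cfg, micro_world.qtl,
                                             state, rng)
        assert len(cultivars) == 4
        assert len(plots) == 12  # 6 synthetics x 2 plots
        # a cultivar pools the plants of its synthetic's plots
        assert all(c.n_individuals == 20 for c in cultivars)


class TestSpeedGS:
    def _zero_models(self, panel):
        return {t: TraitModel(0.0, np.zeros(panel.size), 1.0, 1.0)
                for t in TRAIT_ORDER}

    def test_pool_size_conserved_for_both_crossing_schemes(
            self, micro_world, micro_base):
        cfg0 = presets.scheme_config("S4", "micro", sb_rounds=2)
        state = TraitState(micro_world.qtl.specs)
        pool = Cohort(pop=micro_base.subset(np.arange(60)),
                      tbv=tbv_matrix(micro_base, micro_world.qtl)[:60])
        state.refresh(pool.tbv)
        for crossing in [(60, 1), (12, 5)]:
            cfg = dataclasses.replace(cfg0, crossing_scheme=crossing)
            out, acc = speedgs_stage(pool, self._zero_models(
                micro_world.panel), cfg, micro_world.qtl,
                micro_world.panel, state, np.random.default_rng(16))
            assert out.n == 60
            assert len(acc) == 5 * cfg.sb_rounds

    def test_toy_candidate_pairs(self, micro_world, micro_base):
        cfg = dataclasses.replace(
            presets.scheme_config("S4", "micro"),
            gs_pool_size=4, crossing_scheme=(4, 1), pair_cap=6,
            initial_pop_design=(4, 1))
        assert candidate_pairs(cfg.gs_pool_size) == 6
        state = TraitState(micro_world.qtl.specs)
        pool = Cohort(pop=micro_base.subset(np.arange(4)),
                      tbv=tbv_matrix(micro_base, micro_world.qtl)[:4])
        state.refresh(pool.tbv)
        out, acc = speedgs_stage(pool, self._zero_models(
            micro_world.panel), cfg, micro_world.qtl, micro_world.panel,
            state, np.random.default_rng(17))
        assert out.n == 4
        # zero-effect models: GEBVs are constant, accuracy undefined
        assert all(np.isnan(r["accuracy"]) for r in acc)


class TestProgram:
    def test_ps_program_years_and_cycles(self, micro_world):
        ps = presets.scheme_config("PS", "micro")
        world = dataclasses.replace(
            micro_world, trait_state=TraitState(micro_world.qtl.specs))
        ledger = run_program(ps, ps, world, np.random.default_rng(18))
        gains = ledger[ledger.metric == "index_gain"]
        assert gains["cycle"].tolist() == [2, 3, 4]
        assert gains["year"].tolist() == [11.0, 22.0, 33.0]
        assert gains["value"].iloc[0] == 0.0
        # F exists for every recorded cycle, delta_F for the later ones
        assert (ledger.metric == "F").sum() == 3
        assert (ledger.metric == "delta_F").sum() == 2

    def test_s4_program_years(self, micro_world):
        ps = presets.scheme_config("PS", "micro")
        s4 = presets.scheme_config("S4", "micro", sb_rounds=2)
        world = dataclasses.replace(
            micro_world, trait_state=TraitState(micro_world.qtl.specs))
        ledger = run_program(s4, ps, world, np.random.default_rng(19))
        gains = ledger[ledger.metric == "index_gain"]
        assert gains["year"].tolist() == [11.0, 15.0, 19.0]
        acc = ledger[ledger.metric == "accuracy"]
        assert sorted(acc["round"].unique()) == [1, 2]


class TestExtendedSbRounds:
    def test_six_round_run_declines_in_accuracy(self, desk_warm,
                                                desk_world):
        """A six-round scenario-four run: accuracy erodes from the
        first to the last SB round as the candidates recombine away
        from the reference population.  (The late-round plateau seen at
        full scale is not resolvable at this reduced population size;
        only the overall decline is asserted.)"""
        import pandas as pd
        from allobreed.breeding import continue_program
        ps = presets.scheme_config("PS", "desk")
        cfg = presets.scheme_config("S4", "desk", sb_rounds=6,
                                    crossing_scheme=(500, 1))
        frames = []
        for seed in (21, 22, 23):
            frames.append(continue_program(cfg, ps, desk_warm.copy(),
                                           desk_world,
                                           np.random.default_rng(seed)))
        acc = pd.concat(frames)
        acc = acc[acc.metric == "accuracy"]
        by = acc.groupby("round")["value"].mean()
        assert sorted(by.index) == [1, 2, 3, 4, 5, 6]
        assert by[6] < by[1]
        assert by.loc[[4, 5, 6]].mean() < by.loc[[1, 2, 3]].mean()
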