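"""Batching, incubation-time rules, sweeps, and distribution summaries."""

import math

import numpy as np
import pytest

from ldmrate import (
    BatchDesign,
    DomainError,
    EstimateResult,
    LdmError,
    SimulationConfig,
    choose_t_ldm,
    choose_t_sim,
    compare_estimates,
    geometric_mean,
    incubation_sweep,
    ldm_batch_estimates,
    mean_tstar_analytic,
    parameter_sweep,
    sim_batch_estimates,
    summarize_distribution,
)
from ldmrate.experiments import _included
from ldmrate.simulate import Ensemble, StochasticRun, run_ensemble


def _fake_run(t_star, times=(0.0, 2.0), counts=None, volume=1.0):
    times = np.asarray(times, dtype=float)
    if counts is None:
        D = np.array([100, 700], dtype=np.int64)
        R = np.array([100, 700], dtype=np.int64)
        T = np.array([0, 0 if t_star is None or t_star > times[-1] else 3],
                     dtype=np.int64)
    else:
        D, R, T = (np.asarray(c, dtype=np.int64) for c in counts)
    return StochasticRun(sample_times=times, D=D, R=R, T=T, t_star=t_star,
                         t_end=float(times[-1]),
                         final=(int(D[-1]), int(R[-1]), int(T[-1])),
                         seed=0, volume=volume, engine="hybrid")


def _fake_ensemble(t_stars, config):
    return Ensemble(config=config, master_seed=0,
                    runs=[_fake_run(ts) for ts in t_stars])


class TestBatchDesign:
    def test_block_size_must_divide(self):
        with pytest.raises(DomainError):
            BatchDesign(n_populations=150, populations_per_ldm=100)

    def test_density_run_choice_is_deterministic(self):
        d = BatchDesign(n_populations=400, populations_per_ldm=100,
                        master_seed=5)
        assert d.density_run_indices(4) == d.density_run_indices(4)


class TestBatchEstimates:
    def test_block_count(self, baseline_config, warm_engines):
        cfg = baseline_config.replace(engine="hybrid", t_max=3.0,
                                      sample_times=(0.0, 2.0))
        ens = run_ensemble(cfg, 500, master_seed=3)
        design = BatchDesign(n_populations=500, populations_per_ldm=100,
                             master_seed=3)
        ests = ldm_batch_estimates(ens, 2.0, design)
        assert len(ests) == 5

    def test_event_free_ensemble_gives_valid_zeros(self, baseline_config):
        ens = _fake_ensemble([None] * 200, baseline_config)
        design = BatchDesign(n_populations=200, populations_per_ldm=100)
        ests = ldm_batch_estimates(ens, 2.0, design)
        assert all(e.valid and e.value == 0.0 for e in ests)

    def test_all_turbid_blocks_are_flagged_not_dropped(self,
                                                       baseline_config):
        ens = _fake_ensemble([0.1] * 100, baseline_config)
        design = BatchDesign(n_populations=100, populations_per_ldm=100)
        ests = ldm_batch_estimates(ens, 2.0, design)
        assert len(ests) == 1 and not ests[0].valid
        assert ests[0].reason == "all_wells_turbid"

    def test_parameter_recovery_at_mean_tstar(self, baseline_params,
                                              baseline_init, warm_engines):
        t_bar = mean_tstar_analytic(baseline_params, baseline_init)
        cfg = SimulationConfig(params=baseline_params, init=baseline_init,
                               t_max=t_bar, engine="hybrid",
                               sample_times=(0.0, t_bar))
        ens = run_ensemble(cfg, 2000, master_seed=101)
        design = BatchDesign(n_populations=2000, populations_per_ldm=100,
                             master_seed=101)
        gm = geometric_mean(ldm_batch_estimates(ens, t_bar, design))
        assert 1e-6 / 1.5 < gm < 1e-6 * 1.5

    def test_sim_estimates_zero_when_no_transconjugants(self,
                                                        baseline_config):
        ens = _fake_ensemble([None] * 100, baseline_config)
        design = BatchDesign(n_populations=100, populations_per_ldm=100)
        ests = sim_batch_estimates(ens, 2.0, design)
        assert all(e.value == 0.0 and e.valid for e in ests)

    def test_same_seed_same_estimates(self, baseline_config, warm_engines):
        cfg = baseline_config.replace(engine="hybrid", t_max=2.5,
                                      sample_times=(0.0, 2.0))
        design = BatchDesign(n_populations=300, populations_per_ldm=100,
                             master_seed=9)
        vals = []
        for _ in range(2):
            ens = run_ensemble(cfg, 300, master_seed=9)
            vals.append([e.value for e in
                         sim_batch_estimates(ens, 2.0, design)])
        assert vals[0] == vals[1]


class TestIncubationTimeRules:
    def test_mean_of_observed_first_event_times(self, baseline_config):
        ens = _fake_ensemble([1.0, 2.0, 3.0], baseline_config)
        assert choose_t_ldm(ens) == pytest.approx(2.0)

    def test_single_event(self, baseline_config):
        ens = _fake_ensemble([0.7, None], baseline_config)
        assert choose_t_ldm(ens) == pytest.approx(0.7)

    def test_no_events_raises(self, baseline_config):
        with pytest.raises(LdmError):
            choose_t_ldm(_fake_ensemble([None, None], baseline_config))

    def test_agrees_with_analytic_mean(self, baseline_params, baseline_init,
                                       warm_engines):
        cfg = SimulationConfig(params=baseline_params, init=baseline_init,
                               t_max=6.0, engine="hybrid")
        ens = run_ensemble(cfg, 4000, master_seed=77)
        ts = ens.t_stars
        ts = ts[~np.isnan(ts)]
        se = ts.std(ddof=1) / math.sqrt(ts.size)
        assert choose_t_ldm(ens) == pytest.approx(
            mean_tstar_analytic(baseline_params, baseline_init), abs=3 * se)

    def test_threshold_crossing_is_interpolated(self, baseline_config):
        runs = [_fake_run(0.5, times=(1.0, 2.0, 3.0),
                          counts=([1, 1, 1], [1, 1, 1], [0, 30, 60]))]
        ens = Ensemble(config=baseline_config, master_seed=0, runs=runs)
        # crossing 50 on the (2 h, 30) -> (3 h, 60) segment
        assert choose_t_sim(ens, threshold=50.0) == pytest.approx(8 / 3)

    def test_unreached_threshold_raises_with_advice(self, baseline_config):
        runs = [_fake_run(None, times=(1.0, 2.0),
                          counts=([1, 1], [1, 1], [0, 3]))]
        ens = Ensemble(config=baseline_config, master_seed=0, runs=runs)
        with pytest.raises(LdmError, match="t_max"):
            choose_t_sim(ens, threshold=50.0)

    def test_end_point_readout_is_later_than_first_event_readout(
            self, baseline_params, baseline_init, warm_engines):
        # reaching 50 transconjugants necessarily takes longer than the
        # first conjugation event
        cfg = SimulationConfig(params=baseline_params, init=baseline_init,
                               t_max=6.0, engine="hybrid",
                               sample_times=tuple(np.linspace(0, 6, 61)))
        ens = run_ensemble(cfg, 1000, master_seed=31)
        assert choose_t_sim(ens) > choose_t_ldm(ens)


def _estimates(values, invalid=0):
    out = [EstimateResult("LDM", v, True) for v in values]
    out += [EstimateResult("LDM", math.nan, False, "all_wells_turbid")
            for _ in range(invalid)]
    return out


class TestDistributionSummary:
    def test_known_quantiles_with_linear_interpolation(self):
        s = summarize_distribution(_estimates(range(1, 101)))
        assert s.median == pytest.approx(50.5)
        assert s.q1 == pytest.approx(25.75)
        assert s.q3 == pytest.approx(75.25)

    def test_degenerate_distribution(self):
        s = summarize_distribution(_estimates([2.0] * 10))
        assert s.q1 == s.median == s.q3 == s.whisker_lo == s.whisker_hi

    def test_zeros_are_counted_not_dropped(self):
        s = summarize_distribution(_estimates([0.0, 0.0, 1.0, 2.0]))
        assert s.n_zero == 2 and s.n == 4
        assert s.mean == pytest.approx(0.75)

    def test_whiskers_clipped_to_data_range(self):
        s = summarize_distribution(_estimates([1, 2, 3, 4, 100]))
        assert s.whisker_lo == 1.0
        assert s.whisker_hi <= 100.0

    def test_invalid_counted_separately(self):
        s = summarize_distribution(_estimates([1.0, 2.0], invalid=3))
        assert s.n_invalid == 3 and s.n == 5
        assert s.fraction_finite_nonzero == pytest.approx(0.4)


class TestInclusionRule:
    def test_ninety_percent_boundary(self):
        # 85% finite-nonzero: excluded; 90%: included
        assert not _included(_estimates([1.0] * 85 + [0.0] * 15))
        assert _included(_estimates([1.0] * 90 + [0.0] * 10))


class TestCompareEstimates:
    def test_identical_groups_are_indistinguishable(self):
        a = _estimates([1e-6, 2e-6, 3e-6, 4e-6])
        res = compare_estimates(a, list(a))
        assert res.t_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_six_log_separation_is_significant(self):
        rng = np.random.default_rng(2)
        a = _estimates(10 ** (rng.normal(-12, 0.05, 6)))
        b = _estimates(10 ** (rng.normal(-6, 0.05, 6)))
        res = compare_estimates(a, b)
        assert res.p_value < 1e-4

    def test_zeros_excluded_and_counted(self):
        a = _estimates([1e-6, 2e-6, 3e-6, 0.0])
        b = _estimates([1e-5, 2e-5, 3e-5])
        res = compare_estimates(a, b)
        assert res.n_excluded_a == 1 and res.n_a == 3

    def test_agrees_with_permutation_oracle(self):
        rng = np.random.default_rng(3)
        a_vals = 10 ** rng.normal(-6.0, 0.3, 8)
        b_vals = 10 ** rng.normal(-6.4, 0.3, 8)
        res = compare_estimates(_estimates(a_vals), _estimates(b_vals))
        # permutation test on the difference of log-means
        la, lb = np.log10(a_vals), np.log10(b_vals)
        obs = abs(la.mean() - lb.mean())
        pooled = np.concatenate([la, lb])
        count = 0
        n_perm = 4000
        for _ in range(n_perm):
            rng.shuffle(pooled)
            if abs(pooled[:8].mean() - pooled[8:].mean()) >= obs:
                count += 1
        p_perm = count / n_perm
        se = math.sqrt(p_perm * (1 - p_perm) / n_perm)
        assert res.p_value == pytest.approx(p_perm, abs=max(5 * se, 0.02))

    def test_insufficient_data_raises(self):
        with pytest.raises(DomainError):
            compare_estimates(_estimates([1e-6]), _estimates([1e-6, 2e-6]))


class TestSweeps:
    def test_incubation_sweep_structure_and_windows(
            self, baseline_params, baseline_init, warm_engines):
        cfg = SimulationConfig(params=baseline_params, init=baseline_init,
                               t_max=4.0, engine="hybrid")
        design = BatchDesign(n_populations=300, populations_per_ldm=100,
                             master_seed=19)
        sw = incubation_sweep(cfg, design, t_grid=[1.0, 2.0, 3.0, 4.0])
        assert sw.values == [1.0, 2.0, 3.0, 4.0]
        assert all(len(c.ldm) == 3 and len(c.sim) == 3 for c in sw.cells)
        # at t=1 nearly all blocks are transconjugant-free: the
        # fluctuation estimates are mostly zero there, and by t=4 nearly
        # all wells are turbid (p0(4) ~ 3e-7), pushing blocks to invalid
        early, late = sw.cells[0], sw.cells[-1]
        assert early.ldm_summary.n_zero + early.ldm_summary.n_invalid >= 0
        assert not late.ldm_included  # all-turbid blocks are not usable
        df = sw.to_dataframe()
        assert set(df["method"]) == {"LDM", "SIM"}

    def test_incubation_sweep_is_reproducible(self, baseline_params,
                                              baseline_init, warm_engines):
        cfg = SimulationConfig(params=baseline_params, init=baseline_init,
                               t_max=3.0, engine="hybrid")
        design = BatchDesign(n_populations=200, populations_per_ldm=100,
                             master_seed=4)
        a = incubation_sweep(cfg, design, t_grid=[2.0, 2.5])
        b = incubation_sweep(cfg, design, t_grid=[2.0, 2.5])
        assert a.to_dataframe().equals(b.to_dataframe())

    def test_parameter_sweep_baseline_cell_recovers_rate(
            self, baseline_params, baseline_init, warm_engines):
        cfg = SimulationConfig(params=baseline_params, init=baseline_init,
                               t_max=6.0, engine="hybrid")
        design = BatchDesign(n_populations=600, populations_per_ldm=100,
                             master_seed=8)
        sw = parameter_sweep(cfg, "conjugation", [1e-6], design)
        cell = sw.cells[0]
        assert cell.t_sim > cell.t_ldm
        assert 0.5e-6 < cell.ldm_summary.median < 2e-6

    def test_parameter_sweep_rejects_bad_axis(self, baseline_config):
        design = BatchDesign(n_populations=100, populations_per_ldm=100)
        with pytest.raises(DomainError):
            parameter_sweep(baseline_config, "temperature", [1.0], design)

    def test_sweep_boxplot_renders(self, baseline_params, baseline_init,
                                   warm_engines):
        import matplotlib

        matplotlib.use("Agg")
        from ldmrate.plotting import sweep_boxplot

        cfg = SimulationConfig(params=baseline_params, init=baseline_init,
                               t_max=6.0, engine="hybrid")
        design = BatchDesign(n_populations=200, populations_per_ldm=100,
                             master_seed=2)
        sw = parameter_sweep(cfg, "conjugation", [1e-6], design)
        ax = sweep_boxplot(sw, true_value=1e-6)
        assert ax.get_yscale() == "log"
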