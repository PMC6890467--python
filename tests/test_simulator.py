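"""Simulator unit and property tests: event bookkeeping, fixed points,
growth-rate inheritance, determinism."""

import math

import numpy as np
import pytest
from scipy import stats

import oricycle as oc
from oricycle.simulator import _draw_truncated


def deterministic_map_oracle(dlif, dlid, n_iter=60):
    """Independent oracle: iterate the noise-free per-origin map.

    At slow growth the map is Lambda_i' = (Lambda_i + dlif)/2 with birth
    length Lb = Lambda_i + dlid evaluated at the updated state.
    """
    lam = 0.3 * dlif  # arbitrary positive start
    for _ in range(n_iter):
        lam = 0.5 * (lam + dlif)
    return lam + dlid, 2.0 * lam, lam  # Lb*, Li_abs*, Lambda_i*


def _params(**kw):
    base = dict(lambda_cv=0.0, dLif_cv=0.0, dLid_cv=0.0, ratio_sd=0.0,
                rho_lambda=0.0)
    base.update(kw)
    return oc.ModelParams(**base)


class TestDeterministicFixedPoint:
    @pytest.mark.parametrize(
        "dlif, dlid",
        [(1.0, 0.5), (1.3, 0.4), (0.9, 0.3)],
    )
    def test_matches_map_iteration_oracle(self, dlif, dlid):
        fp = oc.deterministic_fixed_point(
            _params(dLif_mean=dlif, dLid_mean=dlid)
        )
        lb, li_abs, lam_i = deterministic_map_oracle(dlif, dlid)
        assert not fp.limit_cycle
        assert fp.Lb == pytest.approx(lb, abs=1e-9)
        assert fp.Li_abs == pytest.approx(li_abs, abs=1e-9)
        assert fp.Lambda_i == pytest.approx(lam_i, abs=1e-9)

    @pytest.mark.parametrize("x", [0.7, 0.8, 1.0])
    def test_symmetric_adders_give_double_birth_length(self, x):
        # dLif = dLid puts initiation exactly at birth: the division and
        # initiation thresholds coincide, so the cell initiates with two
        # origins already present; the birth length is still 2x and the
        # per-origin initiation size x
        fp = oc.deterministic_fixed_point(
            _params(dLif_mean=x, dLid_mean=x)
        )
        assert fp.Lb == pytest.approx(2 * x, abs=1e-9)
        assert fp.Lambda_i == pytest.approx(x, abs=1e-9)

    def test_requires_double_adder_variant(self):
        p = _params()
        p.model_variant = "initiation_timer"
        p.dLid_mean = 50.0
        with pytest.raises(ValueError):
            oc.deterministic_fixed_point(p)

    def test_noise_free_simulation_converges_to_fixed_point(self):
        params = _params(dLif_mean=1.0, dLid_mean=0.5)
        config = oc.SimConfig(n_lineages=3, duration=2800.0, seed=9)
        logs = oc.simulate_lineages(params, config)
        fp = oc.deterministic_fixed_point(params)
        for log in logs:
            births = [d.daughter_length for d in log.divisions
                      if d.time > 2500.0]
            inits = [e.length for e in log.initiations if e.time > 2500.0]
            assert births and inits
            assert np.allclose(births, fp.Lb, atol=1e-6)
            assert np.allclose(inits, fp.Li_abs, atol=1e-6)


class TestStepCell:
    def test_exponential_doubling_without_events(self):
        state = oc.CellState(length=2.0, n_ori=1,
                             growth_rate=math.log(2) / 60.0,
                             init_target=100.0)
        state, events = oc.step_cell(state, 60.0, _params(), np.random.default_rng(0))
        assert events == []
        assert state.length == pytest.approx(4.0, rel=1e-12)

    def test_zero_dt_is_identity(self):
        state = oc.CellState(length=2.0, n_ori=1, growth_rate=0.01,
                             init_target=100.0)
        state, events = oc.step_cell(state, 0.0, _params(), np.random.default_rng(0))
        assert events == []
        assert state.length == 2.0

    def test_threshold_crossing_emits_one_initiation(self):
        params = _params(dLif_mean=1.0, dLid_mean=0.5)
        state = oc.CellState(length=1.999, n_ori=1, growth_rate=0.01,
                             init_target=2.0)
        state, events = oc.step_cell(state, 1.0, params, np.random.default_rng(0))
        assert len(events) == 1
        ev = events[0]
        assert isinstance(ev, oc.InitiationEvent)
        assert ev.n_pre == 1 and ev.n_post == 2
        assert ev.length == pytest.approx(2.0, rel=1e-12)
        assert state.lambda_per_origin == pytest.approx(
            state.length / 2, rel=1e-12
        )


class TestEventApplication:
    def test_initiation_halves_per_origin_size_and_sets_division_target(self):
        params = _params(dLif_mean=1.0, dLid_mean=0.5)
        state = oc.CellState(length=2.0, n_ori=1, growth_rate=0.01,
                             init_target=2.0, clock=10.0)
        ev = oc.apply_initiation(state, params, np.random.default_rng(0))
        assert state.n_ori == 2
        assert state.lambda_per_origin == pytest.approx(1.0)
        # division target: n_post * (Lambda_i + dLid) = 2 * (1.0 + 0.5)
        assert state.pending_div_targets[0].threshold_length == pytest.approx(3.0)
        assert ev.d_lif_drawn == pytest.approx(1.0)
        assert state.init_target == pytest.approx(2.0)  # 1.0 + 1.0

    def test_division_retires_trigger_and_halves_remaining(self):
        params = _params()
        state = oc.CellState(
            length=3.0, n_ori=2, growth_rate=0.01, init_target=10.0,
            pending_div_targets=[
                oc.DivisionTrigger(3.0, None, 0.5),
                oc.DivisionTrigger(4.4, None, 0.7),
            ],
        )
        ev = oc.apply_division(state, params, np.random.default_rng(0))
        assert state.n_ori == 1
        assert len(state.pending_div_targets) == 1
        assert state.pending_div_targets[0].threshold_length == pytest.approx(2.2)
        assert ev.ratio == pytest.approx(0.5)
        assert ev.daughter_length == pytest.approx(1.5)

    def test_division_conserves_length_with_asymmetric_ratio(self):
        params = _params()
        params.ratio_dist = oc.EmpiricalDistribution(values=[0.45])
        state = oc.CellState(
            length=3.0, n_ori=2, growth_rate=0.01, init_target=10.0,
            pending_div_targets=[oc.DivisionTrigger(3.0, None, 0.5)],
        )
        ev = oc.apply_division(state, params, np.random.default_rng(1))
        sisters = sorted([ev.daughter_length,
                          ev.mother_length - ev.daughter_length])
        assert sisters == pytest.approx([1.35, 1.65], rel=1e-12)

    def test_premature_trigger_counted_as_warning(self):
        params = _params()
        state = oc.CellState(
            length=3.5, n_ori=2, growth_rate=0.01, init_target=10.0,
            pending_div_targets=[oc.DivisionTrigger(3.0, None, 0.5)],
        )
        state, events = oc.step_cell(state, 1.0, params, np.random.default_rng(0))
        assert len(events) == 1 and events[0].premature

    def test_runaway_initiation_aborts_lineage(self):
        # no division can ever fire, so origins double until the cap
        params = _params(dLif_mean=0.2, dLid_mean=50.0)
        config = oc.SimConfig(n_lineages=1, duration=1800.0, seed=3)
        log = oc.simulate_lineages(params, config)[0]
        assert log.aborted and "origin count" in log.abort_reason
        assert max(log.n_oris) == oc.MAX_ORIGINS


class TestLogInvariants:
    def test_structural_invariants_on_every_log(self, da_logs):
        for log in da_logs:
            log.validate()
            assert set(np.unique(log.n_oris)) <= {1, 2, 4, 8, 16}
            # one division per initiation up to the open queue at the end
            assert abs(len(log.initiations) - len(log.divisions)) <= 4

    def test_per_origin_size_halves_at_initiation(self, da_logs):
        for log in da_logs[:50]:
            for ev in log.initiations:
                pre = ev.length / ev.n_pre
                post = ev.length / ev.n_post
                assert post == pytest.approx(pre / 2, rel=1e-12)

    def test_per_origin_size_continuous_across_symmetric_division(self):
        params = _params(lambda_cv=0.1, dLif_cv=0.17, dLid_cv=0.17,
                         rho_lambda=0.3)  # ratio_sd = 0 -> exact halving
        logs = oc.simulate_lineages(
            params, oc.SimConfig(n_lineages=5, duration=1500.0, seed=17)
        )
        for log in logs:
            for div in log.divisions:
                lam_before = div.mother_length / div.n_before
                lam_after = div.daughter_length / div.n_after
                assert lam_after == pytest.approx(lam_before, rel=1e-12)


class TestDeterminismAndDistribution:
    def test_equal_seeds_give_bit_identical_logs(self):
        params = oc.default_params()
        config = oc.SimConfig(n_lineages=5, duration=900.0, seed=77)
        a = oc.simulate_lineages(params, config)
        b = oc.simulate_lineages(params, config)
        for la, lb in zip(a, b):
            assert np.array_equal(la.lengths, lb.lengths)
            assert [e.time for e in la.initiations] == [
                e.time for e in lb.initiations
            ]
            assert [d.daughter_length for d in la.divisions] == [
                d.daughter_length for d in lb.divisions
            ]

    def test_different_seeds_agree_in_distribution(self):
        params = oc.default_params()
        lbs = []
        for seed in (5, 6):
            logs = oc.simulate_lineages(
                params, oc.SimConfig(n_lineages=80, duration=1800.0, seed=seed)
            )
            div = oc.true_division_cycles(logs)
            lbs.append(div["Lb"].to_numpy())
        assert stats.ks_2samp(*lbs).pvalue > 0.01


class TestGrowthRateInheritance:
    def test_perfect_inheritance(self, rng):
        params = oc.default_params()
        params.rho_lambda = 1.0
        mother = 0.009
        assert oc.draw_inherited_growth_rate(mother, params, rng) == mother

    def test_no_inheritance_matches_marginal(self, rng):
        params = oc.default_params()
        params.rho_lambda = 0.0
        draws = np.array([
            oc.draw_inherited_growth_rate(0.012, params, rng)
            for _ in range(10_000)
        ])
        marginal = np.array([
            _draw_truncated(params.lambda_mean, params.lambda_cv, rng)
            for _ in range(10_000)
        ])
        assert stats.ks_2samp(draws, marginal).pvalue > 0.01

    def test_lag1_correlation_along_chain(self, rng):
        params = oc.default_params()  # rho = 0.3
        chain = [params.lambda_mean]
        for _ in range(20_000):
            chain.append(
                oc.draw_inherited_growth_rate(chain[-1], params, rng)
            )
        chain = np.asarray(chain)
        lag1 = np.corrcoef(chain[:-1], chain[1:])[0, 1]
        assert lag1 == pytest.approx(0.3, abs=0.03)
        assert np.std(chain) / np.mean(chain) == pytest.approx(0.10, abs=0.01)

    def test_redraw_exhaustion_raises(self, rng):
        params = oc.default_params()
        params.rho_lambda = 0.99
        params.lambda_cv = 1e-6
        with pytest.raises(oc.SimulationError):
            # AR mean far below the 10%-of-mean floor, negligible innovation
            oc.draw_inherited_growth_rate(1e-9, params, rng)


class TestZeroGrowthAndValidation:
    def test_zero_growth_freezes_the_lineage(self):
        params = _params(lambda_mean=0.0)
        logs = oc.simulate_lineages(
            params, oc.SimConfig(n_lineages=2, duration=300.0, seed=1)
        )
        for log in logs:
            assert not log.initiations and not log.divisions
            assert np.all(log.lengths == log.lengths[0])

    @pytest.mark.parametrize(
        "bad",
        [
            {"model_variant": "nope"},
            {"dLif_mean": -1.0},
            {"ratio_sd": 0.3},
            {"lambda_cv": -0.1},
        ],
    )
    def test_invalid_params_rejected(self, bad):
        params = oc.default_params()
        for key, value in bad.items():
            setattr(params, key, value)
        with pytest.raises(ValueError):
            params.validate()

    def test_empirical_override_is_used(self):
        params = _params(dLif_mean=1.0, dLid_mean=0.5)
        params.dLif_dist = oc.EmpiricalDistribution(values=[0.9])
        state = oc.CellState(length=2.0, n_ori=1, growth_rate=0.01,
                             init_target=2.0)
        oc.apply_initiation(state, params, np.random.default_rng(0))
        assert state.init_target == pytest.approx(1.0 + 0.9)


class TestEmergentDivisionCycleBehaviour:
    """Birth-to-division statistics implied by initiation-coupled control.

    In the small-noise limit of the division adder and the division ratio
    the model reduces to the classic birth-to-division adder: added length
    independent of birth length and mother-daughter birth-length
    correlation 1/2.  At finite division noise the model predicts a
    *negative* correlation between birth length and added length (the
    division-adder and ratio fluctuations enter Lb and dL with opposite
    signs), which the suite asserts as the sign prediction.
    """

    def test_classic_adder_recovered_in_small_division_noise_limit(self):
        params = _params(lambda_cv=0.10, dLif_cv=0.17, dLid_cv=1e-4,
                         rho_lambda=0.3)
        logs = oc.simulate_lineages(
            params, oc.SimConfig(n_lineages=250, duration=1800.0, seed=19)
        )
        div = oc.true_division_cycles(logs)
        assert len(div) >= 2000
        r_adder = stats.pearsonr(div["Lb"], div["dL"])[0]
        r_md, _, _ = oc.mother_daughter_birth_correlation(div)
        assert abs(r_adder) < 0.1
        assert r_md == pytest.approx(0.5, abs=0.05)

    def test_division_noise_induces_negative_adder_correlation(self, da_logs):
        div = oc.true_division_cycles(da_logs)
        r, p = stats.pearsonr(div["Lb"], div["dL"])
        assert r < 0 and p < 1e-6
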