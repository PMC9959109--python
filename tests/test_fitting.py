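"""Flux fitting: SSR arithmetic, chi-square gating, multi-start behavior."""

import numpy as np
import pytest

from emuflux.fitting import (
    FluxFitter,
    chi_square_test,
    multistart_fit,
    pdh_interval,
    residual_ssr,
    sample_feasible_starts,
)

from conftest import (
    SPLIT_TRUTH,
    split_toy_fitter,
    split_toy_measurements,
    split_toy_model,
    split_toy_state,
)


@pytest.fixture(scope="module")
def toy_problem():
    model = split_toy_model()
    state = split_toy_state(model)
    meas = split_toy_measurements(model, state)
    return model, state, split_toy_fitter(model, meas)


class TestSSR:
    def test_perfect_fit_has_zero_ssr(self, toy_problem):
        model, state, fitter = toy_problem
        assert residual_ssr(state, fitter) == pytest.approx(0.0, abs=1e-18)

    def test_single_residual_weighting(self, toy_problem):
        """One channel off by 0.006 at sd 0.003 contributes exactly 4.

        The compensating shift lands on the fragment's dominant channel,
        which carries the sum-to-1 redundancy and is excluded from the
        residual vector.
        """
        model, state, fitter = toy_problem
        meas2 = split_toy_measurements(model, state)
        name = "E123"
        meas2.mids[name] = meas2.mids[name].copy()
        meas2.mids[name][0] += 0.006
        meas2.mids[name][1] -= 0.006  # dominant channel: keeps the row at 1
        f2 = split_toy_fitter(model, meas2)
        assert f2.ssr(f2.params_from_state(state)) == pytest.approx(4.0, rel=1e-9)

    def test_halving_sds_quadruples_ssr(self, toy_problem):
        model, state, fitter = toy_problem
        rng = np.random.default_rng(5)
        noisy = split_toy_measurements(model, state, rng=rng)
        f1 = split_toy_fitter(model, noisy)
        ssr1 = f1.ssr(f1.params_from_state(state))
        halved = split_toy_measurements(model, state)
        for k in noisy.mids:
            halved.mids[k] = noisy.mids[k]
            halved.mid_sds[k] = noisy.mid_sds[k] / 2.0
        g = noisy.growth
        halved.growth = type(g)(
            g.growth_rate, g.glucose_uptake, g.acetate_efflux,
            g.growth_rate_sd / 2, g.glucose_uptake_sd / 2, g.acetate_efflux_sd / 2,
        )
        f2 = split_toy_fitter(model, halved)
        assert f2.ssr(f2.params_from_state(state)) == pytest.approx(4 * ssr1, rel=1e-9)

    def test_row_order_invariance(self, toy_problem):
        model, state, _ = toy_problem
        meas = split_toy_measurements(model, state)
        reordered_mids = dict(reversed(list(meas.mids.items())))
        meas2 = type(meas)(reordered_mids, dict(meas.mid_sds), meas.growth)
        f1 = split_toy_fitter(model, meas)
        f2 = split_toy_fitter(model, meas2)
        p = f1.params_from_state(state)
        assert f1.ssr(p) == pytest.approx(f2.ssr(p))


class TestChiSquare:
    def test_zero_ssr_passes(self):
        passed, _ = chi_square_test(0.0, 20, 5)
        assert passed

    def test_tabulated_critical_value(self):
        _, crit = chi_square_test(1.0, 15, 5, alpha=0.05)
        assert crit == pytest.approx(18.307, abs=1e-3)

    def test_ssr_above_critical_fails(self):
        passed, crit = chi_square_test(100.0, 15, 5)
        assert not passed and 100.0 > crit

    def test_nonpositive_dof_rejected(self):
        with pytest.raises(ValueError):
            chi_square_test(1.0, 5, 5)


class TestStarts:
    def test_reproducible_and_feasible(self, wt_preset, wt_noisefree_data):
        fitter = FluxFitter(wt_preset.model, wt_noisefree_data)
        a = sample_feasible_starts(fitter, n=25, seed=11)
        b = sample_feasible_starts(fitter, n=25, seed=11)
        assert np.array_equal(a, b)
        irrev = fitter._irrev_idx
        for p in a:
            state = fitter.state_from_params(p)
            assert np.max(np.abs(wt_preset.model.S @ state.net)) < 1e-9
            assert np.min(state.net[irrev]) >= 0.0

    def test_different_seeds_differ(self, wt_preset, wt_noisefree_data):
        fitter = FluxFitter(wt_preset.model, wt_noisefree_data)
        a = sample_feasible_starts(fitter, n=5, seed=1)
        b = sample_feasible_starts(fitter, n=5, seed=2)
        assert not np.array_equal(a, b)

    def test_n_must_be_positive(self, wt_preset, wt_noisefree_data):
        fitter = FluxFitter(wt_preset.model, wt_noisefree_data)
        with pytest.raises(ValueError):
            sample_feasible_starts(fitter, n=0)


class TestMultistart:
    def test_toy_truth_recovery(self, toy_problem):
        model, state, fitter = toy_problem
        starts = sample_feasible_starts(fitter, n=5, seed=0)
        fit = multistart_fit(fitter, starts)
        assert fit.ssr < 1e-12
        for rid, v in SPLIT_TRUTH.items():
            assert fit.state[rid] == pytest.approx(v, abs=1e-5)

    def test_duplicate_starts_identical_optima(self, toy_problem):
        model, state, fitter = toy_problem
        start = sample_feasible_starts(fitter, n=1, seed=0)
        fit = multistart_fit(fitter, np.vstack([start, start]))
        assert fit.ssr_trace[0] == fit.ssr_trace[1]

    def test_start_order_invariance(self, toy_problem):
        model, state, fitter = toy_problem
        starts = sample_feasible_starts(fitter, n=4, seed=0)
        f1 = multistart_fit(fitter, starts)
        f2 = multistart_fit(fitter, starts[::-1])
        assert f1.ssr == pytest.approx(f2.ssr, abs=1e-12)
        assert f1.state.net == pytest.approx(f2.state.net, abs=1e-6)

    def test_extra_fragment_never_lowers_ssr(self, toy_problem):
        """SSR is monotone in the measurement set (superset adds terms)."""
        from conftest import SPLIT_FRAGMENTS, SPLIT_LABELING, SPLIT_EFFLUX_MAP

        model, state, _ = toy_problem
        rng = np.random.default_rng(9)
        meas_full = split_toy_measurements(model, state, rng=rng)
        meas_sub = type(meas_full)(
            {"E123": meas_full.mids["E123"]},
            {"E123": meas_full.mid_sds["E123"]},
            meas_full.growth,
        )
        f_sub = FluxFitter(model, meas_sub, labeling=SPLIT_LABELING,
                           fragments=SPLIT_FRAGMENTS, anchors={}, efflux_map=SPLIT_EFFLUX_MAP)
        f_full = FluxFitter(model, meas_full, labeling=SPLIT_LABELING,
                            fragments=SPLIT_FRAGMENTS, anchors={}, efflux_map=SPLIT_EFFLUX_MAP)
        starts = sample_feasible_starts(f_sub, n=4, seed=2)
        ssr_sub = multistart_fit(f_sub, starts).ssr
        ssr_full = multistart_fit(f_full, starts).ssr
        assert ssr_full >= ssr_sub - 1e-8

    def test_chi2_failure_is_flagged_not_silent(self, toy_problem):
        model, state, fitter = toy_problem
        bad = split_toy_measurements(model, state)
        bad.mids["E123"] = np.array([0.5, 0.1, 0.3, 0.1])  # inconsistent data
        f = split_toy_fitter(model, bad)
        starts = sample_feasible_starts(f, n=3, seed=0)
        fit = multistart_fit(f, starts)
        assert not fit.chi2_pass
        assert fit.ssr > fit.chi2_critical


class TestPdhInterval:
    def test_interval_from_acetate_routing(self, wt_preset, wt_noisefree_data):
        fitter = FluxFitter(wt_preset.model, wt_noisefree_data)
        from emuflux.fitting import FitResult

        fit = FitResult(
            state=wt_preset.truth, ssr=0.0, dof=1, chi2_pass=True,
            chi2_critical=1.0, ssr_trace=[0.0],
            params=fitter.params_from_state(wt_preset.truth),
        )
        lo, hi = pdh_interval(fit)
        norm = fit.normalized()
        assert hi - lo == pytest.approx(norm["ace_out"], abs=1e-9)
        assert lo == pytest.approx(norm["pdh"] - norm["pta"], abs=1e-9)
        # the lower bound still covers the biomass acetyl-CoA requirement
        assert lo >= norm["cs"] + norm["ms"]

    def test_zero_acetate_gives_zero_width(self, core_model):
        from emuflux.biomass import compose_biomass, drains_from_composition
        from emuflux.fitting import FitResult
        from emuflux.network import FluxState
        from emuflux.synthetic import _solve_preset_fluxes

        eq = drains_from_composition(compose_biomass(0.55, 0.20))
        model = core_model.with_biomass(eq.coefficients)
        hard = {"pts": 8.0, "biomass": 0.6, "ace_out": 0.0, "pox": 0.0,
                "ser_deam": 0.0, "fbp": 0.0, "pps": 0.0, "asp_fum": 0.0, "mae": 0.0}
        net = _solve_preset_fluxes(model, hard, {"zwf": 1.8})
        state = FluxState(model, net)
        fit = FitResult(state=state, ssr=0.0, dof=1, chi2_pass=True,
                        chi2_critical=1.0, ssr_trace=[0.0], params=np.zeros(1))
        lo, hi = pdh_interval(fit)
        assert hi - lo == pytest.approx(0.0, abs=1e-6)
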