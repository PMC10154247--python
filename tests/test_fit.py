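"""Flux fitting: parameterization, estimation, chi-square and profile CIs.

Statistical behavior (chi-square calibration, CI coverage) is exercised on
a small two-route network whose fits take milliseconds; the full KF-1
round trip lives in the acceptance suite.
"""

import numpy as np
import pytest

from comamflux.fit import (
    FitConfig,
    FitProblem,
    fit_fluxes,
    linearized_flux_sd,
    profile_ci,
)
from comamflux.fluxes import (
    InfeasibleConstraints,
    check_irreversibility,
    parameterize,
    steady_state_residual,
)
from comamflux.measurements import MeasurementSet
from comamflux.network import parse_model
from comamflux.synth import generate_mid_dataset, toy_scenario


class TestParameterize:
    def test_branch_has_one_free_flux(self):
        m = parse_model("U: Ax (a) -> A (a)\nR1: A (a) -> B (a)\n"
                        "R2: B (a) -> C (a)\nR3: B (a) -> D (a)\n"
                        "O1: C (a) -> Cx (a)\nO2: D (a) -> Dx (a)")
        basis = parameterize(m, {"U": 1.0})
        assert basis.n_free == 1
        fv = basis.fluxes(basis.free_for_targets({"R2": 0.3}))
        assert fv.net["R3"] == pytest.approx(0.7)
        assert steady_state_residual(m, fv) < 1e-12

    def test_irreversibility_reported_not_baked_in(self):
        m = parse_model("U: Ax (a) -> A (a)\nR1: A (a) -> B (a)\n"
                        "R2: B (a) -> C (a)\nR3: B (a) -> D (a)\n"
                        "O1: C (a) -> Cx (a)\nO2: D (a) -> Dx (a)")
        basis = parameterize(m, {"U": 1.0})
        u = basis.free_for_targets({"R2": 1.4})  # forces R3 (and O2) negative
        assert set(basis.violations(u)) == {"R3", "O2"}

    def test_infeasible_constraints_name_the_balance_row(self):
        m = parse_model("U: Ax (a) -> A (a)\nR1: A (a) -> B (a)\n"
                        "O: B (a) -> Bx (a)")
        with pytest.raises(InfeasibleConstraints, match="residual"):
            parameterize(m, {"U": 1.0, "R1": 2.0, "O": 1.0})


def _fit_toy(split=60.0, noise=0.005, seed=0, rp_reversible=False, **kw):
    sc = toy_scenario(split=split, noise_sd=noise,
                      rp_reversible=rp_reversible)
    ds = generate_mid_dataset(sc, seed=seed)
    cfg = FitConfig(restarts=kw.pop("restarts", 3), seed=1, fit_co2=False,
                    **kw)
    return sc, ds, fit_fluxes(sc.model, ds, cfg)


class TestFitFluxes:
    def test_zero_noise_self_consistency(self):
        sc, _, fit = _fit_toy(noise=0.0, exchange_min=1e-6)
        assert fit.fluxes.net["RP"] == pytest.approx(60.0, rel=1e-4)
        assert fit.ssr < 1e-8

    def test_noisy_fit_is_accepted_and_near_truth(self):
        _, _, fit = _fit_toy(noise=0.005, seed=5)
        assert fit.accepted
        assert fit.fluxes.net["RP"] == pytest.approx(60.0, abs=3.0)

    def test_returned_fluxes_satisfy_hard_constraints(self):
        sc, _, fit = _fit_toy(noise=0.005, seed=5)
        assert steady_state_residual(sc.model, fit.fluxes) < 1e-6
        assert not check_irreversibility(sc.model, fit.fluxes, tol=1e-6)

    def test_ssr_invariant_to_dataset_reordering(self):
        sc, ds, fit = _fit_toy(noise=0.005, seed=7)
        ds_rev = MeasurementSet(ds.experiments[::-1], ds.effluxes)
        prob = FitProblem(sc.model, ds, FitConfig(fit_co2=False))
        prob_rev = FitProblem(sc.model, ds_rev, FitConfig(fit_co2=False))
        assert prob.ssr(fit.theta) == pytest.approx(
            prob_rev.ssr(fit.theta), rel=1e-12)

    def test_fixed_seed_reproducible(self):
        _, _, fit1 = _fit_toy(noise=0.005, seed=2)
        _, _, fit2 = _fit_toy(noise=0.005, seed=2)
        assert np.array_equal(fit1.theta, fit2.theta)
        assert fit1.ssr == fit2.ssr

    def test_dof_counts_mid_vectors_minus_parameters(self):
        sc, ds, fit = _fit_toy(noise=0.005, seed=3)
        # two 3-channel MIDs -> 2x2 independent channels; 1 free net flux
        assert fit.dof == 4 - 1


class TestTwoTracerInformation:
    def test_second_tracer_tightens_confidence(self):
        # the same truth measured under one vs two tracer schemes: the CI
        # from the pooled fit can only shrink
        from dataclasses import replace

        from comamflux.emu import TracerSpec

        sc = toy_scenario(split=60.0, noise_sd=0.005)
        tr1 = {"toy": sc.tracers["toy"]}
        tr2 = {"toy": sc.tracers["toy"],
               "toy2": {"Sx": TracerSpec("Sx", (0.0, 0.99))}}
        widths = {}
        for name, tracers in (("one", tr1), ("two", tr2)):
            ds = generate_mid_dataset(replace(sc, tracers=tracers), seed=4)
            fit = fit_fluxes(sc.model, ds,
                             FitConfig(restarts=2, seed=1, fit_co2=False))
            lo, hi = profile_ci(fit, "RP")
            widths[name] = hi - lo
        assert widths["two"] <= widths["one"] + 1e-6


class TestProfileCI:
    def test_profile_matches_linearized_se_in_gaussian_regime(self):
        # identifiable toy at small noise: the SSR is locally quadratic, so
        # the profile CI must agree with +-1.96 se from the Jacobian
        sc, ds, fit = _fit_toy(noise=0.002, seed=11)
        lo, hi = profile_ci(fit, "RP")
        se = linearized_flux_sd(fit)["RP"]
        assert 0.5 * (hi - lo) == pytest.approx(1.96 * se, rel=0.01)
        assert lo < fit.fluxes.net["RP"] < hi

    def test_unidentifiable_exchange_reports_open_upper_bound(self):
        # identity-map exchange (P <-> S) leaves every MID unchanged
        sc, ds, fit = _fit_toy(noise=0.005, seed=13, rp_reversible=True)
        lo, hi = profile_ci(fit, "RP", kind="exchange")
        assert np.isinf(hi)

    def test_coverage_on_repeated_simulations(self):
        hits, n = 0, 40
        for seed in range(n):
            _, _, fit = _fit_toy(noise=0.005, seed=100 + seed, restarts=2)
            lo, hi = profile_ci(fit, "RP")
            if lo <= 60.0 <= hi:
                hits += 1
        assert hits / n >= 0.85  # 95% nominal; binomial noise at n=40
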