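"""Self-check diagnostics: oracle equivalence and statistical calibration.

These routines exercise the whole simulate/fit pipeline on small synthetic
problems and report summary statistics — the EMU solver against exhaustive
isotopomer enumeration, the chi-square acceptance rate of the fit under the
generating noise model, and the coverage of the profile-likelihood
confidence intervals.
"""

from __future__ import annotations

import numpy as np

from .emu import simulate_mids
from .fit import FitConfig, fit_fluxes, profile_ci
from .isotopomer_ref import simulate_mids_reference
from .synth import generate_mid_dataset, random_oracle_model, toy_scenario


def emu_oracle_max_dev(n_networks: int = 100, seed: int = 0) -> float:
    """Max |EMU - exhaustive-isotopomer| MID deviation over random networks."""
    worst = 0.0
    rng = np.random.default_rng(seed)
    for _ in range(n_networks):
        model, fluxes, tracer = random_oracle_model(rng)
        targets = ["P", "M", "H", "G"]
        emu = simulate_mids(model, fluxes, tracer, targets)
        ref = simulate_mids_reference(model, fluxes, tracer, targets)
        for t in targets:
            worst = max(worst, float(np.max(np.abs(emu[t] - ref[t]))))
    return worst


def chi2_acceptance_rate(n_datasets: int = 200, noise_sd: float = 0.005,
                         split: float = 60.0, seed: int = 0) -> float:
    """Fraction of simulated datasets the 95% chi-square test accepts.

    Calibrated machinery should land at ~0.95: the test statistic is the
    minimized variance-weighted SSR against chi2(dof).
    """
    sc = toy_scenario(split=split, noise_sd=noise_sd)
    cfg = FitConfig(restarts=2, seed=1, fit_co2=False)
    accepted = 0
    for i in range(n_datasets):
        ds = generate_mid_dataset(sc, seed=seed * 1_000_003 + i)
        fit = fit_fluxes(sc.model, ds, cfg)
        accepted += bool(fit.accepted)
    return accepted / n_datasets


def ci_coverage(n_datasets: int = 100, noise_sd: float = 0.005,
                split: float = 60.0, seed: int = 0) -> float:
    """Fraction of simulated datasets whose 95% profile CI covers the truth."""
    sc = toy_scenario(split=split, noise_sd=noise_sd)
    cfg = FitConfig(restarts=2, seed=1, fit_co2=False)
    hits = 0
    for i in range(n_datasets):
        ds = generate_mid_dataset(sc, seed=seed * 2_000_003 + i)
        fit = fit_fluxes(sc.model, ds, cfg)
        lo, hi = profile_ci(fit, "RP")
        hits += bool(lo <= split <= hi)
    return hits / n_datasets
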