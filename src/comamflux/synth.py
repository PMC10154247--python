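"""Synthetic-data generation for every pipeline input.

Generates steady-state MID datasets under the standard tracer schemes
([1-13C]-carboxyl-4HB, [13C6]-phenyl-4HB, [U-13C4]-succinate), fragment
MIDs, growth/secretion time series and switch-kinetics observations from a
known ground truth, so all stages are testable without any measured data.

The default KF-1 scenario is a synthetic stand-in, not a measured flux
map: a documented plausible truth vector with high 4,5-meta throughput,
malic-enzyme flux far exceeding PEP carboxykinase, a small glyoxylate
shunt, and a near-equilibrium reversible succinate<->OAA arm.  All
generators are pure functions of (scenario, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .emu import TracerSpec, simulate_mids
from .fluxes import FluxVector, parameterize
from .kinetics import PoolSizes
from .measurements import LabelingExperiment, MeasurementSet, MidMeasurement
from .natabund import apply_natural_abundance
from .network import NetworkModel, load_kf1_model, parse_model
from .physiology import GrowthSeries

# -- tracer schemes ---------------------------------------------------------

def tracer_1_13c_carboxyl_4hb(purity: float = 0.99) -> TracerSpec:
    """[1-13C]-(carboxyl)-4HB: only the carboxyl carbon is labeled."""
    return TracerSpec("FHBx", (purity,) + (0.0,) * 6)


def tracer_13c6_phenyl_4hb(purity: float = 0.99) -> TracerSpec:
    """[13C6]-(phenyl)-4HB: the six ring carbons are labeled."""
    return TracerSpec("FHBx", (0.0,) + (purity,) * 6)


def tracer_u13c4_succinate(substrate: str = "Sx",
                           purity: float = 0.99) -> TracerSpec:
    """[U-13C4]-succinate (for succinate-fed toy/switch scenarios)."""
    return TracerSpec(substrate, (purity,) * 4)


@dataclass
class SyntheticScenario:
    """Ground truth for one simulated study."""

    model: NetworkModel
    true_fluxes: FluxVector
    tracers: dict[str, dict[str, TracerSpec]]   # scheme id -> tracer map
    effluxes: dict[str, float]                  # fixed-rate reactions (truth)
    co2_purity: float = 0.0
    mid_noise_sd: float = 0.005
    rate_rel_sd: float = 0.10
    replicates: int = 3
    natural_abundance: float = 0.0107
    measured_metabolites: list[str] = field(default_factory=list)
    pools: PoolSizes | None = None
    pep_source_split: tuple[float, float] | None = None  # (from PYR, from OAA)

    def targets(self) -> list[str]:
        return list(self.measured_metabolites
                    or self.model.measured_metabolites)


# ---------------------------------------------------------------------------
# noise model
# ---------------------------------------------------------------------------

def _simplex_noise(rng: np.random.Generator, n_channels: int,
                   sd: float) -> np.ndarray:
    """Zero-sum Gaussian noise on a normalized MID.

    Sampling in the (n-1)-dimensional subspace orthogonal to the closure
    constraint keeps the measured vector normalized and makes the
    variance-weighted SSR exactly chi-square with (length - 1) degrees of
    freedom per MID — the calibration the fit statistics assume.
    """
    if sd == 0:
        return np.zeros(n_channels)
    basis = np.linalg.svd(np.eye(n_channels)
                          - np.ones((n_channels, n_channels)) / n_channels
                          )[0][:, : n_channels - 1]
    z = rng.normal(0.0, sd, size=n_channels - 1)
    return basis @ z


def noisy_mid(rng, mid: np.ndarray, sd: float) -> np.ndarray:
    y = np.asarray(mid, dtype=float) + _simplex_noise(rng, len(mid), sd)
    y = np.clip(y, 0.0, None)  # truncation; rare at default noise
    return y / y.sum()


# ---------------------------------------------------------------------------
# MID dataset generation
# ---------------------------------------------------------------------------

def generate_mid_dataset(scenario: SyntheticScenario,
                         seed: int | None = None) -> MeasurementSet:
    """Simulate, contaminate with natural abundance, and add noise.

    Returns one :class:`LabelingExperiment` per (tracer scheme, replicate),
    replicates independent given the seed stream, plus the efflux-rate
    table (noisy when ``rate_rel_sd > 0``).
    """
    rng = np.random.default_rng(seed)
    model = scenario.model
    targets = scenario.targets()
    experiments = []
    for scheme, tracers in scenario.tracers.items():
        tr = dict(tracers)
        co2_src = _co2_source(model)
        if co2_src and co2_src not in tr:
            tr[co2_src] = TracerSpec(co2_src, (scenario.co2_purity,))
        sim = simulate_mids(model, scenario.true_fluxes, tr, targets)
        for rep in range(scenario.replicates):
            mids = []
            for met in targets:
                true = apply_natural_abundance(sim[met],
                                               scenario.natural_abundance)
                y = noisy_mid(rng, true, scenario.mid_noise_sd)
                sd = np.full_like(y, scenario.mid_noise_sd
                                  if scenario.mid_noise_sd > 0 else 1e-4)
                mids.append(MidMeasurement(met, y, sd))
            experiments.append(
                LabelingExperiment(f"{scheme}/r{rep + 1}", tracers, mids))
    effluxes = {}
    for rid, val in scenario.effluxes.items():
        sd = abs(val) * scenario.rate_rel_sd
        noisy = val + rng.normal(0.0, sd) if sd > 0 else val
        effluxes[rid] = (noisy, sd if sd > 0 else max(abs(val) * 0.01, 1e-6))
    return MeasurementSet(experiments, effluxes)


def _co2_source(model: NetworkModel) -> str | None:
    rid = model.co2_input_reaction
    if not rid:
        return None
    (src, _), = model.reaction(rid).substrates
    return src


# ---------------------------------------------------------------------------
# growth series generation
# ---------------------------------------------------------------------------

def generate_growth_series(mu: float, q_map: dict[str, float],
                           conversion: float = 0.26,
                           od0: float = 0.05, t_end_h: float = 8.0,
                           n_points: int = 9, noise: float = 0.02,
                           c0: dict[str, float] | None = None,
                           seed: int | None = None) -> GrowthSeries:
    """Exponential growth with linear metabolite exchange versus biomass.

    ``q_map`` uses the exchange-rate sign convention (negative =
    consumption, positive = secretion, mmol g_CDW^-1 h^-1); concentrations
    follow ``C(t) = C0 + (q/mu) * (X(t) - X0)`` in mM with X in g_CDW/L.
    ``noise`` is the multiplicative (lognormal) sd on OD and concentrations.
    """
    if mu <= 0:
        raise ValueError("growth rate must be positive")
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, t_end_h, n_points)
    od_true = od0 * np.exp(mu * t)
    od = od_true * np.exp(rng.normal(0.0, noise, size=t.shape)) if noise \
        else od_true
    X = od_true * conversion
    conc = {}
    c0 = dict(c0 or {})
    for compound, q in q_map.items():
        span = (q / mu) * (X - X[0])
        base = c0.get(compound)
        if base is None:
            # secretions start from nothing; consumed substrates start with
            # enough headroom not to run out inside the window
            base = 0.0 if q >= 0 else -span.min() * 1.25 + 1.0
        c = base + span
        if noise:
            c = c * np.exp(rng.normal(0.0, noise, size=t.shape))
        conc[compound] = c
    return GrowthSeries(t, od, conc, conversion)


# ---------------------------------------------------------------------------
# shipped scenarios
# ---------------------------------------------------------------------------

# truth targets for the free fluxes, % of uptake: small glyoxylate shunt,
# minimal OAA->PEP, cataplerosis through ME-1, no Mqo/ME-2/OAA-decarboxylase
_KF1_FREE_TARGETS = {"AceA": 3.0, "PckG": 5.6, "ME2": 0.0, "Mqo": 0.0,
                     "OadC": 0.0, "CO2up": 5.0}

# measured secretion rates, % of uptake (magnitudes echo Fig.-1d-scale rates
# at q = 11.9 mmol/gCDW/h: PCA 0.49, PDC 0.46, pyruvate 0.62 ...)
_KF1_SECRETIONS = {"SEC_PCA": 4.1, "SEC_PDC": 3.9, "SEC_PYR": 5.2,
                   "SEC_AKG": 2.0, "SEC_MAL": 1.0, "SEC_GLU": 2.0}

# biomass precursor effluxes, % of uptake (growth-rate x demand table)
_KF1_BIOMASS = {"BM_G6P": 2.0, "BM_F6P": 1.0, "BM_R5P": 4.0, "BM_E4P": 3.0,
                "BM_GAP": 1.5, "BM_PG3": 9.0, "BM_PEP": 4.0, "BM_PYR": 12.0,
                "BM_ACA": 15.0, "BM_OAA": 9.0, "BM_AKG": 9.0}

# exchange fluxes (% of uptake): the succinate<->OAA arm is near
# equilibrium (large exchange, |dG| < 2 kJ/mol), ME-1 exchange is set so the
# malate->pyruvate step carries a modest driving force, and PEP
# carboxykinase / enolase exchange is small so the PEP pool remains an
# almost pure pyruvate+OAA two-source mixture
_KF1_EXCHANGE = {"PmdU": 20.0, "Sdh": 100.0, "FumC": 250.0, "Mdh": 400.0,
                 "PckG": 0.05, "ME1": 17.5, "ME2": 0.0, "OadC": 0.0,
                 "Eno": 2.0, "Gpm": 2.0, "Pgk": 10.0, "GapA": 10.0,
                 "Tpi": 30.0, "Fba": 5.0, "Pgi": 15.0, "RpiA": 10.0,
                 "Rpe": 10.0, "TktA": 3.0, "TktB": 3.0, "Tal": 3.0}

# quantified pools, umol g_CDW^-1: pyruvate by far the largest pool, aKG
# next, succinate ~3x below aKG, PEP an order of magnitude below pyruvate
_KF1_POOLS = {"PYR": 8.0, "AKG": 2.0, "CIT": 1.0, "MAL": 1.0, "SUC": 0.6,
              "FUM": 0.3, "OAA": 0.15, "PEP": 0.7, "ACA": 0.05,
              "PG3": 0.4, "F6P": 0.3, "G6P": 0.5}


def kf1_truth_fluxes(model: NetworkModel | None = None) -> FluxVector:
    """The documented plausible KF-1 truth vector, uptake normalized to 100."""
    model = model or load_kf1_model()
    fixed = {model.uptake_reaction: 100.0, **_KF1_SECRETIONS, **_KF1_BIOMASS,
             "ATPM": 30.0, **model.fixed_fluxes}
    basis = parameterize(model, fixed)
    u = basis.free_for_targets(_KF1_FREE_TARGETS)
    fv = basis.fluxes(u, dict(_KF1_EXCHANGE))
    bad = basis.violations(u, tol=1e-6)
    if bad:
        raise RuntimeError(f"KF-1 truth vector infeasible at {bad}")
    return fv


def generate_kf1_default_scenario(seed: int | None = None) -> SyntheticScenario:
    """Default synthetic study on the shipped KF-1 model.

    Two labeling schemes ([1-13C]-carboxyl-4HB, [13C6]-phenyl-4HB), three
    replicates each, Gaussian MID noise sd 0.005 — the standard parallel
    labeling layout with an invented but documented flux truth.
    """
    model = load_kf1_model()
    fluxes = kf1_truth_fluxes(model)
    tracers = {
        "1-13C-4HB": {"FHBx": tracer_1_13c_carboxyl_4hb()},
        "13C6-phenyl-4HB": {"FHBx": tracer_13c6_phenyl_4hb()},
    }
    effluxes = {model.uptake_reaction: 100.0, **_KF1_SECRETIONS,
                **_KF1_BIOMASS}
    pps = fluxes.net["Pps"]
    pck = fluxes.net["PckG"]
    return SyntheticScenario(
        model=model, true_fluxes=fluxes, tracers=tracers, effluxes=effluxes,
        co2_purity=0.05, pools=PoolSizes(dict(_KF1_POOLS)),
        pep_source_split=(pps / (pps + pck), pck / (pps + pck)))


# ---------------------------------------------------------------------------
# small networks: calibration toy and randomized oracle instances
# ---------------------------------------------------------------------------

_TOY_TEXT = """
U: Sx (ab) -> S (ab)
RP: S (ab) -> P (ab){rev}
RC: S (ab) -> X (a) + W (b)
RW: W (a) -> Wx (a)
RD: X (a) + X (b) -> D (ab)
RM1: P (ab) -> M (ab)
RM2: D (ab) -> M (ab)
OM: M (ab) -> Mx (ab)
"""


def toy_split_model(rp_reversible: bool = False) -> NetworkModel:
    """Two-route toy: direct transfer vs cleave-and-recombine.

    The recombination route condenses two one-carbon units from position 1
    of the substrate, so the mass distribution of the downstream pool M
    identifies the split — a minimal, fast network for calibrating the fit
    statistics.  With ``rp_reversible`` the direct route gains a
    structurally unidentifiable exchange flux (identity atom map).
    """
    text = _TOY_TEXT.format(rev=" [reversible]" if rp_reversible else "")
    return parse_model(text, {"uptake_reaction": "U"})


def toy_scenario(split: float = 60.0, noise_sd: float = 0.005,
                 rp_reversible: bool = False,
                 replicates: int = 1) -> SyntheticScenario:
    model = toy_split_model(rp_reversible)
    fixed = {"U": 100.0}
    basis = parameterize(model, fixed)
    u = basis.free_for_targets({"RP": split})
    fluxes = basis.fluxes(u, {"RP": 5.0} if rp_reversible else {})
    tracers = {"toy": {"Sx": TracerSpec("Sx", (0.99, 0.0))}}
    return SyntheticScenario(
        model=model, true_fluxes=fluxes, tracers=tracers,
        effluxes={"U": 100.0}, co2_purity=0.0, mid_noise_sd=noise_sd,
        rate_rel_sd=0.0, replicates=replicates, natural_abundance=0.0,
        measured_metabolites=["P", "M"])


_PERMS3 = ["abc", "acb", "bac", "bca", "cab", "cba"]
_PERMS2 = ["ab", "ba"]


def random_oracle_model(rng: np.random.Generator):
    """A randomized small network + random feasible fluxes and tracer.

    Branch, cleavage, condensation, optional reversibility and an optional
    symmetric two-carbon pool — the structural repertoire the EMU solver
    must handle — with every atom map drawn at random.  Metabolites stay at
    <= 3 carbons so the exhaustive isotopomer reference is cheap.
    """
    p1 = rng.choice(_PERMS3)
    p2 = rng.choice(_PERMS3)
    p3 = rng.choice(_PERMS2)
    p4 = rng.choice(_PERMS3)
    p5 = rng.choice(_PERMS3)
    rev_p = " [reversible]" if rng.random() < 0.5 else ""
    rev_g = " [reversible]" if rng.random() < 0.5 else ""
    sym = ["G"] if rng.random() < 0.5 else []
    split_q = rng.choice(["(ab) + W (c)", "(bc) + W (a)", "(ac) + W (b)"])
    text = f"""
U: Sx (abc) -> S (abc)
Rp: S (abc) -> P ({p1}){rev_p}
Rq: S ({p2}) -> Q {split_q}
Rr: Q (ab) -> G ({p3}){rev_g}
Rc: G (ab) + W (c) -> H ({p4})
Rm1: P (abc) -> M (abc)
Rm2: H (abc) -> M ({p5})
Om: M (abc) -> Mx (abc)
"""
    model = parse_model(text, {"symmetric": sym, "uptake_reaction": "U"})
    basis = parameterize(model, {"U": 100.0})
    t = rng.uniform(15.0, 85.0)
    u = basis.free_for_targets({"Rp": t})
    exchange = {}
    if rev_p:
        exchange["Rp"] = float(rng.uniform(0.0, 80.0))
    if rev_g:
        exchange["Rr"] = float(rng.uniform(0.0, 80.0))
    fluxes = basis.fluxes(u, exchange)
    purity = tuple(rng.uniform(0.0, 1.0, size=3))
    tracer = TracerSpec("Sx", purity, unlabeled_weight=float(rng.uniform(0, 0.5)))
    return model, fluxes, tracer
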