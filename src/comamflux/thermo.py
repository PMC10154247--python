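"""Flux-derived thermodynamics and the cofactor/ATP ledger.

The Gibbs free energy of a reversible reaction follows from its
unidirectional fluxes, dG = -R T ln(v_f / v_b): zero at equilibrium,
negative when net flux runs forward, and log-proportional to the
forward/backward flux ratio.  The cofactor ledger sums signed NADH/FADH2,
NADPH and ATP stoichiometries over the net fluxes, closes the NADPH pool by
transhydrogenase-equivalent transfer (in whichever direction is needed),
converts respired NADH/FADH2 to ATP at a fixed P/O ratio, and reports the
ATP surplus beyond the anabolic demand.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .fluxes import FluxVector
from .network import NetworkModel

R_KJ = 8.314e-3  # kJ mol^-1 K^-1
DEFAULT_T = 303.15  # 30 C culture temperature
DISPLAY_FLOOR = -30.0  # rendering cutoff for effectively irreversible steps


class ThermoError(ValueError):
    pass


def delta_g(v_f: float, v_b: float, T: float = DEFAULT_T) -> float:
    """dG = -R T ln(v_f / v_b) in kJ/mol; signed infinity for one-sided flux."""
    if v_f < 0 or v_b < 0:
        raise ThermoError("unidirectional fluxes must be non-negative")
    if v_f == 0 and v_b == 0:
        raise ThermoError("dG undefined: both unidirectional fluxes are zero")
    if v_b == 0:
        return -math.inf
    if v_f == 0:
        return math.inf
    return -R_KJ * T * math.log(v_f / v_b)


def delta_g_sd(v_f: float, v_b: float, sd_f: float, sd_b: float,
               T: float = DEFAULT_T) -> float:
    """First-order (delta-method) propagation of flux sds into dG."""
    if v_f <= 0 or v_b <= 0:
        return math.inf
    return R_KJ * T * math.hypot(sd_f / v_f, sd_b / v_b)


@dataclass
class ThermoResult:
    reaction: str
    v_f: float
    v_b: float
    dG: float
    T: float
    sd: float = math.nan


def reaction_thermodynamics(model: NetworkModel, fluxes: FluxVector,
                            T: float | None = None,
                            flux_sd: dict[str, float] | None = None,
                            ) -> list[ThermoResult]:
    """dG of every reversible reaction carrying any unidirectional flux."""
    T = T if T is not None else model.temperature_K
    out = []
    for r in model.reactions:
        if not r.reversible:
            continue
        vf, vb = fluxes.unidirectional(r.id)
        if vf == 0 and vb == 0:
            continue
        sd = math.nan
        if flux_sd and r.id in flux_sd:
            s = flux_sd[r.id]
            sd = delta_g_sd(vf, vb, s, s, T)
        out.append(ThermoResult(r.id, vf, vb, delta_g(vf, vb, T), T, sd))
    return out


# ---------------------------------------------------------------------------
# cofactor / ATP balance
# ---------------------------------------------------------------------------

@dataclass
class EnergyBalance:
    """Production/consumption ledger (mmol g_CDW^-1 h^-1) per cofactor pool.

    NADH and FADH2 are pooled (same P/O in this accounting).  Closure holds
    by construction for every pool:
    ``production + transfer_in == consumption + transfer_out + surplus``.
    """

    po_ratio: float
    nadh_production: float
    nadh_consumption: float          # network reactions consuming NADH/FADH2
    nadh_oxidized: float             # respired for oxidative phosphorylation
    nadph_production: float
    nadph_consumption: float         # network reactions consuming NADPH
    nadph_anabolic_demand: float
    transhydrogenase: float          # >0: NADH->NADPH, <0: excess NADPH->NADH
    atp_substrate_level: float       # net network ATP (substrate-level - sinks)
    atp_oxidative: float
    atp_anabolic_demand: float
    atp_surplus: float
    demands: dict[str, float] = field(default_factory=dict)

    def closure_residuals(self) -> dict[str, float]:
        th = self.transhydrogenase
        nadph = (self.nadph_production + max(th, 0.0)
                 - self.nadph_consumption - self.nadph_anabolic_demand
                 - max(-th, 0.0))
        nadh = (self.nadh_production + max(-th, 0.0)
                - self.nadh_consumption - max(th, 0.0) - self.nadh_oxidized)
        atp = (self.atp_substrate_level + self.atp_oxidative
               - self.atp_anabolic_demand - self.atp_surplus)
        return {"NADPH": nadph, "NADH/FADH2": nadh, "ATP": atp}


def cofactor_ledger(model: NetworkModel, fluxes: FluxVector,
                    demands: dict[str, float] | None = None,
                    po_ratio: float = 1.5) -> EnergyBalance:
    """Sum signed cofactor stoichiometry x net flux and close each pool.

    ``demands`` gives anabolic consumption rates for ``NADPH`` and ``ATP``
    (growth-rate-derived biomass stoichiometry); the NADPH pool is closed by
    transhydrogenase-equivalent electron transfer in whichever direction is
    required, remaining NADH/FADH2 is respired at ``po_ratio`` ATP per
    cofactor, and the ATP surplus is what oxidative plus substrate-level
    production leaves beyond the anabolic demand.
    """
    demands = dict(demands or {})
    prod = {"NADH": 0.0, "NADPH": 0.0, "ATP": 0.0}
    cons = {"NADH": 0.0, "NADPH": 0.0, "ATP": 0.0}
    for r in model.reactions:
        v = fluxes.net.get(r.id)
        if v is None:
            if r.cofactors:
                raise ThermoError(f"no flux value for cofactor-carrying "
                                  f"reaction {r.id}")
            continue
        for pool, s in r.cofactors.items():
            key = "NADH" if pool in ("NADH", "FADH2") else pool
            amount = s * v
            if amount >= 0:
                prod[key] += amount
            else:
                cons[key] -= amount

    nadph_net = prod["NADPH"] - cons["NADPH"] - demands.get("NADPH", 0.0)
    transhydrogenase = -nadph_net  # >0 means NADH must top up NADPH

    # signed: a negative value flags a redox-infeasible flux configuration
    # (more NADH consumed than produced) rather than silently unclosing
    nadh_oxidized = (prod["NADH"] - cons["NADH"]
                     - max(transhydrogenase, 0.0) + max(-transhydrogenase, 0.0))
    atp_ox = po_ratio * nadh_oxidized
    atp_sl = prod["ATP"] - cons["ATP"]
    atp_demand = demands.get("ATP", 0.0)
    surplus = atp_sl + atp_ox - atp_demand

    return EnergyBalance(
        po_ratio=po_ratio,
        nadh_production=prod["NADH"], nadh_consumption=cons["NADH"],
        nadh_oxidized=nadh_oxidized,
        nadph_production=prod["NADPH"], nadph_consumption=cons["NADPH"],
        nadph_anabolic_demand=demands.get("NADPH", 0.0),
        transhydrogenase=transhydrogenase,
        atp_substrate_level=atp_sl, atp_oxidative=atp_ox,
        atp_anabolic_demand=atp_demand, atp_surplus=surplus,
        demands=demands)


def funnel_nadph_balance(model: NetworkModel, route: list) -> float:
    """Net NADPH stoichiometry along a linear route at unit flux."""
    return sum(r.cofactors.get("NADPH", 0.0) for r in route)
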