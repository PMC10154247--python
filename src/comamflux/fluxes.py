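"""Flux vectors and the free-flux parameterization of the balance space.

At metabolic steady state the net fluxes satisfy ``S v = 0`` over the
balanced metabolites.  With the uptake, secretion and biomass efflux rates
fixed by measurement, the remaining degrees of freedom form an affine space
``v = v0 + N u`` whose basis ``N`` spans the null space of the constrained
stoichiometry.  Reversible reactions additionally carry a non-negative
exchange flux: the unidirectional rates are ``v_f = max(v, 0) + e`` and
``v_b = max(-v, 0) + e``, so labeling exchange can persist at any net flux.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import null_space

from .network import NetworkModel, stoichiometric_matrix


class InfeasibleConstraints(ValueError):
    pass


@dataclass
class FluxVector:
    """Net and exchange fluxes keyed by reaction id (uptake-normalized or
    absolute mmol g_CDW^-1 h^-1 — the scale is the caller's)."""

    net: dict[str, float]
    exchange: dict[str, float] = field(default_factory=dict)

    def net_array(self, order: list[str]) -> np.ndarray:
        return np.array([self.net[r] for r in order], dtype=float)

    def unidirectional(self, rid: str) -> tuple[float, float]:
        v = self.net.get(rid, 0.0)
        e = self.exchange.get(rid, 0.0)
        return max(v, 0.0) + e, max(-v, 0.0) + e

    def scaled(self, factor: float) -> "FluxVector":
        return FluxVector({k: v * factor for k, v in self.net.items()},
                          {k: v * factor for k, v in self.exchange.items()})


def steady_state_residual(model: NetworkModel, fluxes: FluxVector) -> float:
    S, _, cols = stoichiometric_matrix(model)
    v = fluxes.net_array(cols)
    return float(np.max(np.abs(S @ v))) if len(cols) else 0.0


def check_irreversibility(model: NetworkModel, fluxes: FluxVector, tol=1e-9):
    bad = []
    for r in model.reactions:
        if not r.reversible:
            if fluxes.net.get(r.id, 0.0) < -tol:
                bad.append((r.id, fluxes.net[r.id]))
            if abs(fluxes.exchange.get(r.id, 0.0)) > tol:
                bad.append((r.id, fluxes.exchange[r.id]))
    return bad


@dataclass
class FluxBasis:
    """Affine parameterization ``v = v0 + N u`` of steady-state net fluxes.

    ``u`` are the free net fluxes; irreversibility enters as the linear
    inequality ``(v0 + N u)[irrev] >= 0``.
    """

    model: NetworkModel
    reaction_order: list[str]
    fixed: dict[str, float]
    v0: np.ndarray
    N: np.ndarray
    irreversible_mask: np.ndarray

    @property
    def n_free(self) -> int:
        return self.N.shape[1]

    @property
    def reversible_ids(self) -> list[str]:
        return [r.id for r in self.model.reactions if r.reversible]

    def fluxes(self, u, exchange: dict[str, float] | None = None) -> FluxVector:
        v = self.v0 + self.N @ np.atleast_1d(np.asarray(u, dtype=float))
        return FluxVector(dict(zip(self.reaction_order, v)), dict(exchange or {}))

    def free_for_targets(self, targets: dict[str, float]) -> np.ndarray:
        """Least-squares ``u`` bringing named reactions close to target values."""
        idx = [self.reaction_order.index(r) for r in targets]
        A = self.N[idx, :]
        b = np.array(list(targets.values())) - self.v0[idx]
        u, *_ = np.linalg.lstsq(A, b, rcond=None)
        return u

    def violations(self, u, tol=1e-9) -> list[str]:
        v = self.v0 + self.N @ u
        bad = v[self.irreversible_mask] < -tol
        ids = np.array(self.reaction_order)[self.irreversible_mask]
        return list(ids[bad])


def parameterize(model: NetworkModel, fixed: dict[str, float],
                 tol: float = 1e-8) -> FluxBasis:
    """Build the free-flux basis given fixed (measured) reaction rates.

    ``fixed`` maps reaction ids to net flux values (uptake, secretions,
    biomass effluxes, and any configured fixed reactions).  Raises
    :class:`InfeasibleConstraints` naming a violated balance row when the
    constraint polytope is empty.
    """
    S, rows, cols = stoichiometric_matrix(model)
    n = len(cols)
    col_idx = {c: i for i, c in enumerate(cols)}
    fixed_idx = np.array([col_idx[r] for r in fixed], dtype=int)
    free_cols = np.array([i for i in range(n) if i not in set(fixed_idx)], dtype=int)

    v_fixed = np.array([fixed[cols[i]] for i in fixed_idx])
    rhs = -S[:, fixed_idx] @ v_fixed
    A = S[:, free_cols]
    sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
    resid = A @ sol - rhs
    if np.max(np.abs(resid)) > tol * max(1.0, np.max(np.abs(rhs)) if rhs.size else 1.0):
        worst = int(np.argmax(np.abs(resid)))
        raise InfeasibleConstraints(
            f"steady-state balance cannot be satisfied; worst row: "
            f"{rows[worst]} (residual {resid[worst]:.3g})")
    K = null_space(A)

    v0 = np.zeros(n)
    v0[fixed_idx] = v_fixed
    v0[free_cols] = sol
    N = np.zeros((n, K.shape[1]))
    N[free_cols, :] = K

    irrev = np.array([not model.reaction(c).reversible and c not in fixed
                      for c in cols])
    return FluxBasis(model, list(cols), dict(fixed), v0, N, irrev)


def default_fixed_fluxes(model: NetworkModel, uptake: float,
                         secretion: dict[str, float],
                         biomass: dict[str, float],
                         atpm: float = 0.0) -> dict[str, float]:
    """Assemble the fixed-flux map from measured rates.

    ``secretion`` keys are secretion reaction ids; ``biomass`` keys are
    biomass efflux reaction ids.  ATP maintenance carries no carbon and is
    fixed separately (it only matters for the energy ledger).
    """
    fixed = {model.uptake_reaction: uptake}
    fixed.update({r: secretion.get(r, 0.0) for r in model.secretion_reactions})
    fixed.update({r: biomass.get(r, 0.0) for r in model.biomass_reactions})
    if any(r.id == "ATPM" for r in model.reactions):
        fixed["ATPM"] = atpm
    fixed.update(model.fixed_fluxes)
    return fixed
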