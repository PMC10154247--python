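"""Flux estimation by variance-weighted least squares over parallel
labeling datasets.

The objective is the variance-weighted sum of squared residuals (SSR)
between simulated and measured mass-isotopomer fractions, pooled by simple
summation over all datasets.  Free parameters are the free net fluxes of the
constrained stoichiometry, log-scaled exchange fluxes of the reversible
reactions, and (optionally) the 13C content of the dissolved-CO2 pool.
Goodness of fit is judged against the chi-square distribution at
``dof = n_independent_measurements - n_free_parameters``; confidence
intervals come from profile likelihood (SSR threshold +3.84, the 95%
chi-square quantile with one degree of freedom).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .emu import EmuNode, TracerSpec, emu_decompose, solve_emus
from .fluxes import FluxBasis, FluxVector, parameterize
from .measurements import MeasurementSet
from .network import NetworkModel

PROFILE_THRESHOLD = 3.84  # chi2_{0.95, 1}


class FitError(RuntimeError):
    pass


@dataclass
class FitConfig:
    restarts: int = 100
    seed: int | None = None
    fit_co2: bool = True
    co2_default: float = 0.0
    exchange_min: float = 1e-3       # lower edge of the log-scaled search
    exchange_max_factor: float = 50.0  # upper bound, x uptake
    free_exchange: list[str] | None = None  # default: all reversible reactions
    extra_fixed: dict[str, float] = field(default_factory=dict)
    xtol: float = 1e-8
    ftol: float = 1e-8
    # iteration budget: each TRF iteration also costs a ~n_par-point
    # numeric jacobian, so runaway restarts are cut off early
    max_nfev_factor: int = 5


@dataclass
class FitResult:
    fluxes: FluxVector
    ssr: float
    dof: int
    chi2_cutoff: float
    accepted: bool
    theta: np.ndarray
    basis: FluxBasis
    problem: "FitProblem"
    co2_purity: float
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    sd: dict[str, float] = field(default_factory=dict)
    restart_ssr: list[float] = field(default_factory=list)


class FitProblem:
    """Compiled objective: theta -> weighted residual vector."""

    def __init__(self, model: NetworkModel, data: MeasurementSet,
                 config: FitConfig):
        self.model = model
        self.data = data
        self.config = config

        fixed = {rid: val for rid, (val, _) in data.effluxes.items()}
        fixed.update(model.fixed_fluxes)
        fixed.update(config.extra_fixed)
        # reactions carrying no tracked carbon (e.g. ATP maintenance) do not
        # influence labeling; pin them so the search space stays bounded
        for r in model.reactions:
            if not r.substrates and not r.products and r.id not in fixed:
                fixed[r.id] = 0.0
        self.basis = parameterize(model, fixed)
        self.uptake = abs(fixed.get(model.uptake_reaction, 100.0)) or 100.0

        free_ex = config.free_exchange
        if free_ex is None:
            free_ex = [r for r in self.basis.reversible_ids
                       if r not in config.extra_fixed]
        self.exchange_ids = list(free_ex)

        # one EMU graph per distinct target set (shared across replicates)
        self.graphs: dict[tuple, object] = {}
        self.exp_plan = []
        for exp in data.experiments:
            targets = tuple(m.target(model) for m in exp.mids)
            key = targets
            if key not in self.graphs:
                nodes = [t if isinstance(t, EmuNode)
                         else EmuNode(t, tuple(range(1, model.metabolites[t].n_carbons + 1)))
                         for t in targets]
                self.graphs[key] = (emu_decompose(model, nodes), nodes)
            self.exp_plan.append((exp, key))

        self.n_free_net = self.basis.n_free
        self.n_par = (self.n_free_net + len(self.exchange_ids)
                      + (1 if config.fit_co2 else 0))
        self.n_meas = data.n_independent
        self.n_channels = sum(len(m.fractions) for e in data.experiments
                              for m in e.mids)
        self.dof = self.n_meas - self.n_par

    # -- parameter packing ------------------------------------------------
    def split(self, theta):
        k = self.n_free_net
        u = theta[:k]
        loge = theta[k:k + len(self.exchange_ids)]
        co2 = theta[-1] if self.config.fit_co2 else self.config.co2_default
        return u, loge, float(co2)

    def flux_vector(self, theta) -> FluxVector:
        u, loge, _ = self.split(theta)
        exchange = {rid: 10.0 ** le for rid, le in zip(self.exchange_ids, loge)}
        return self.basis.fluxes(u, exchange)

    def bounds(self):
        lo, hi = [], []
        lo += [-np.inf] * self.n_free_net
        hi += [np.inf] * self.n_free_net
        le_lo = np.log10(self.config.exchange_min)
        le_hi = np.log10(self.config.exchange_max_factor * self.uptake)
        lo += [le_lo] * len(self.exchange_ids)
        hi += [le_hi] * len(self.exchange_ids)
        if self.config.fit_co2:
            lo.append(0.0)
            hi.append(1.0)
        return np.array(lo), np.array(hi)

    # -- residuals ---------------------------------------------------------
    @staticmethod
    def _tracer_key(tracers) -> tuple:
        return tuple(sorted((s, t.purity, t.unlabeled_weight)
                            for s, t in tracers.items()))

    def residuals(self, theta, penalty_weight: float = 1e4) -> np.ndarray:
        u, loge, co2 = self.split(theta)
        fluxes = self.flux_vector(theta)
        n_pen = int(np.sum(self.basis.irreversible_mask))
        res = []
        solutions = {}  # replicates share one solve per tracer scheme
        try:
            for exp, key in self.exp_plan:
                graph, nodes = self.graphs[key]
                cache_key = (key, self._tracer_key(exp.tracers))
                sol = solutions.get(cache_key)
                if sol is None:
                    tracers = dict(exp.tracers)
                    co2_src = self._co2_source()
                    if co2_src and self.config.fit_co2:
                        tracers[co2_src] = TracerSpec(co2_src, (co2,))
                    sol = solve_emus(graph, fluxes, tracers)
                    solutions[cache_key] = sol
                for meas, node in zip(exp.mids, nodes):
                    sim = sol[node]
                    res.append((sim - meas.fractions) / meas.sd)
        except Exception:  # singular balance deep inside an infeasible corner
            return np.full(self.n_channels + n_pen, 1e3)
        res = np.concatenate(res) if res else np.zeros(0)
        # smooth hinge keeping the search away from infeasible (negative
        # irreversible flux) regions; the accepted solution is verified and,
        # if needed, polished subject to the exact constraints
        v = self.basis.v0 + self.basis.N @ u
        viol = np.clip(-v[self.basis.irreversible_mask], 0.0, None)
        return np.concatenate([res, penalty_weight * viol])

    def ssr(self, theta) -> float:
        u, _, _ = self.split(theta)
        r = self.residuals(theta)
        if self.basis.violations(u, tol=1e-7):
            return float(np.sum(r ** 2))
        return float(np.sum(r[:self.n_channels] ** 2))

    def _co2_source(self) -> str | None:
        rid = self.model.co2_input_reaction
        if not rid:
            return None
        (src, _), = self.model.reaction(rid).substrates
        return src

    # -- feasible sampling -------------------------------------------------
    def free_box(self):
        """Per-coordinate LP bounds of the feasible free-flux polytope."""
        mask = self.basis.irreversible_mask
        cap = 10.0 * self.uptake  # generous cap; also tames futile cycles
        A_ub = [-self.basis.N[mask], self.basis.N, -self.basis.N[~mask]]
        b_ub = [self.basis.v0[mask], cap - self.basis.v0,
                cap + self.basis.v0[~mask]]
        A_ub = np.vstack(A_ub)
        b_ub = np.concatenate(b_ub)
        k = self.n_free_net
        lo, hi = np.empty(k), np.empty(k)
        for j in range(k):
            c = np.zeros(k)
            c[j] = 1.0
            r1 = optimize.linprog(c, A_ub=A_ub, b_ub=b_ub, bounds=(None, None))
            r2 = optimize.linprog(-c, A_ub=A_ub, b_ub=b_ub, bounds=(None, None))
            if not (r1.success and r2.success):
                raise FitError("free-flux polytope is empty or unbounded")
            lo[j], hi[j] = r1.x[j], r2.x[j]
        return lo, hi, (A_ub, b_ub)

    def sample_start(self, rng, box) -> np.ndarray:
        lo_u, hi_u, (A_ub, b_ub) = box
        for _ in range(1000):
            u = rng.uniform(lo_u, hi_u)
            if np.all(A_ub @ u <= b_ub + 1e-9):
                # exchanges start log-uniform over the *plausible* decades
                # (up to ~half the uptake); starting deep in the saturated
                # high-exchange regime strands the search on a plateau
                le_lo = np.log10(self.config.exchange_min)
                le_hi = np.log10(0.5 * self.uptake)
                theta = np.concatenate([
                    u,
                    rng.uniform(le_lo, le_hi, size=len(self.exchange_ids)),
                    rng.uniform(0, 1, size=1) if self.config.fit_co2 else np.zeros(0),
                ])
                return theta
        raise FitError("could not sample a feasible starting point")


def _polish_constrained(problem: FitProblem, theta: np.ndarray) -> np.ndarray:
    """Enforce irreversibility exactly via SLSQP if the TRF optimum strays."""
    u, *_ = problem.split(theta)
    if not problem.basis.violations(u, tol=1e-9):
        return theta
    k = problem.n_free_net
    mask = problem.basis.irreversible_mask
    N, v0 = problem.basis.N[mask], problem.basis.v0[mask]
    cons = [{"type": "ineq", "fun": lambda th: v0 + N @ th[:k]}]
    blo, bhi = problem.bounds()
    res = optimize.minimize(
        lambda th: np.sum(problem.residuals(th)[:problem.n_channels] ** 2),
        theta, method="SLSQP", constraints=cons,
        bounds=list(zip(np.where(np.isfinite(blo), blo, -1e6),
                        np.where(np.isfinite(bhi), bhi, 1e6))),
        options={"maxiter": 60, "ftol": 1e-10})
    return res.x


def fit_fluxes(model: NetworkModel, data: MeasurementSet,
               config: FitConfig | None = None,
               theta0: np.ndarray | None = None) -> FitResult:
    """Multi-start weighted least squares over all labeling datasets.

    ``theta0``, when given, is used as an additional (first) starting point
    — convenient for warm starts and self-consistency checks.
    """
    config = config or FitConfig()
    problem = FitProblem(model, data, config)
    rng = np.random.default_rng(config.seed)
    box = problem.free_box()
    blo, bhi = problem.bounds()

    starts = []
    if theta0 is not None:
        starts.append(np.asarray(theta0, dtype=float))
    starts += [problem.sample_start(rng, box) for _ in range(config.restarts)]
    if not starts:
        raise FitError("no starting points (restarts=0 and no theta0)")

    k = problem.n_free_net
    n_ex = len(problem.exchange_ids)
    net_idx = np.r_[np.arange(k),
                    np.arange(k + n_ex, len(blo))]  # nets (+ co2 if fitted)

    best, best_ssr, restart_ssr, failures = None, np.inf, [], []
    for th0 in starts:
        try:
            # stage 1: net fluxes (and CO2 labeling) with exchanges held at
            # their starting values — a low-dimensional, well-behaved
            # problem that places the search in the right basin
            if n_ex and k:
                th_fix = th0.copy()

                def staged(sub):
                    th = th_fix.copy()
                    th[net_idx] = sub
                    return problem.residuals(th)

                s1 = optimize.least_squares(
                    staged, th0[net_idx],
                    bounds=(blo[net_idx], bhi[net_idx]), method="trf",
                    xtol=1e-6, ftol=1e-6, max_nfev=60 * max(len(net_idx), 1))
                th0 = th0.copy()
                th0[net_idx] = s1.x
            # stage 2: all parameters
            sol = optimize.least_squares(
                problem.residuals, th0, bounds=(blo, bhi), method="trf",
                xtol=config.xtol, ftol=config.ftol,
                max_nfev=max(60, config.max_nfev_factor * len(th0)))
            th = _polish_constrained(problem, sol.x)
            ssr = problem.ssr(th)
            restart_ssr.append(ssr)
            if ssr < best_ssr:
                best, best_ssr = th, ssr
        except Exception as exc:  # noqa: BLE001 - collected as diagnostics
            failures.append(str(exc))
    if best is None:
        raise FitError("all restarts failed to converge: " + "; ".join(failures))

    dof = problem.dof
    cutoff = float(stats.chi2.ppf(0.95, dof)) if dof > 0 else np.inf
    _, _, co2 = problem.split(best)
    return FitResult(
        fluxes=problem.flux_vector(best), ssr=best_ssr, dof=dof,
        chi2_cutoff=cutoff, accepted=best_ssr <= cutoff, theta=best,
        basis=problem.basis, problem=problem, co2_purity=co2,
        restart_ssr=restart_ssr)


def linearized_flux_sd(fit: FitResult, step: float = 1e-4) -> dict[str, float]:
    """Gauss-Newton (Jacobian-based) standard deviations of the net fluxes.

    A cheap local approximation to the profile-likelihood uncertainty:
    ``cov(theta) = (J^T J)^-1`` at the optimum, propagated through the
    affine flux basis.  Flat directions give large but finite numbers (a
    small ridge regularizes the inverse).
    """
    problem = fit.problem
    th = fit.theta
    r0 = problem.residuals(th)[:problem.n_channels]
    J = np.empty((len(r0), len(th)))
    for j in range(len(th)):
        dth = th.copy()
        h = step * max(1.0, abs(th[j]))
        dth[j] += h
        J[:, j] = (problem.residuals(dth)[:problem.n_channels] - r0) / h
    jtj = J.T @ J
    cov = np.linalg.inv(jtj + 1e-9 * np.eye(len(th)) * np.trace(jtj) / len(th))
    cov_u = cov[:problem.n_free_net, :problem.n_free_net]
    out = {}
    for i, rid in enumerate(problem.basis.reaction_order):
        n_r = problem.basis.N[i]
        out[rid] = float(np.sqrt(max(n_r @ cov_u @ n_r, 0.0)))
    return out


# ---------------------------------------------------------------------------
# profile-likelihood confidence intervals
# ---------------------------------------------------------------------------

def _reoptimize_with_pin(problem: FitProblem, rid: str, value: float,
                         theta_start: np.ndarray) -> float:
    """Minimum SSR with reaction ``rid``'s net flux pinned to ``value``."""
    k = problem.n_free_net
    r_idx = problem.basis.reaction_order.index(rid)
    a = problem.basis.N[r_idx]
    j = int(np.argmax(np.abs(a)))
    if abs(a[j]) < 1e-12:
        # flux not a function of the free parameters (fixed by constraints)
        return problem.ssr(theta_start) if np.isclose(
            value, problem.basis.v0[r_idx]) else np.inf
    c = value - problem.basis.v0[r_idx]

    def expand(th_red):
        u_red = th_red[:k - 1]
        u = np.empty(k)
        u[:j] = u_red[:j]
        u[j + 1:] = u_red[j:]
        u[j] = (c - np.dot(np.delete(a, j), u_red)) / a[j]
        return np.concatenate([u, th_red[k - 1:]])

    th0 = np.delete(theta_start, j)
    blo, bhi = problem.bounds()
    blo, bhi = np.delete(blo, j), np.delete(bhi, j)
    sol = optimize.least_squares(
        lambda th: problem.residuals(expand(th)), th0, bounds=(blo, bhi),
        method="trf", xtol=1e-9, ftol=1e-9, max_nfev=200 * max(len(th0), 1))
    th = expand(sol.x)
    u, *_ = problem.split(th)
    if problem.basis.violations(u, tol=1e-6):
        return np.inf  # pinned value infeasible under irreversibility
    r = problem.residuals(th)
    return float(np.sum(r[:problem.n_channels] ** 2))


def _reoptimize_with_exchange_pin(problem, rid, log_e, theta_start) -> float:
    k = problem.n_free_net
    j = k + problem.exchange_ids.index(rid)
    th0 = np.delete(theta_start, j)
    blo, bhi = problem.bounds()
    blo, bhi = np.delete(blo, j), np.delete(bhi, j)

    def expand(th_red):
        return np.insert(th_red, j, log_e)

    sol = optimize.least_squares(
        lambda th: problem.residuals(expand(th)), th0, bounds=(blo, bhi),
        method="trf", xtol=1e-9, ftol=1e-9, max_nfev=200 * max(len(th0), 1))
    r = problem.residuals(expand(sol.x))
    return float(np.sum(r[:problem.n_channels] ** 2))


def profile_ci(fit: FitResult, rid: str,
               threshold: float = PROFILE_THRESHOLD,
               max_span_factor: float = 20.0,
               n_refine: int = 25,
               kind: str = "net") -> tuple[float, float]:
    """95% profile-likelihood CI for one net (or exchange) flux.

    Scans the target flux away from the optimum, re-optimizing all other
    parameters, until the SSR exceeds ``SSR_min + 3.84``; the crossing is
    then refined by bisection.  A side where the profile never crosses
    within ``max_span_factor`` x uptake is reported open (±inf).
    """
    problem: FitProblem = fit.problem
    if kind == "exchange":
        return _profile_exchange(fit, rid, threshold, n_refine)
    limit = threshold + fit.ssr
    v_hat = fit.fluxes.net[rid]
    span = max_span_factor * problem.uptake
    step0 = max(0.02 * problem.uptake, 0.05 * abs(v_hat))

    def profile(g):
        return _reoptimize_with_pin(problem, rid, g, fit.theta)

    out = []
    for sign in (-1.0, 1.0):
        g, step = v_hat, step0
        crossed, lo_g, hi_g = False, v_hat, v_hat
        while abs(g - v_hat) < span:
            g_next = g + sign * step
            s = profile(g_next)
            if s > limit:
                lo_g, hi_g, crossed = g, g_next, True
                break
            g = g_next
            step *= 1.6
        if not crossed:
            out.append(sign * np.inf)
            continue
        for _ in range(n_refine):
            mid = 0.5 * (lo_g + hi_g)
            if profile(mid) > limit:
                hi_g = mid
            else:
                lo_g = mid
            if abs(hi_g - lo_g) < max(1e-4, 1e-4 * abs(v_hat)):
                break
        out.append(0.5 * (lo_g + hi_g))
    lo, hi = sorted(out)
    fit.ci[rid] = (lo, hi)
    if np.isfinite(lo) and np.isfinite(hi):
        fit.sd[rid] = (hi - lo) / 3.92
    return lo, hi


def _profile_exchange(fit, rid, threshold, n_refine):
    problem = fit.problem
    limit = threshold + fit.ssr
    k = problem.n_free_net
    j = k + problem.exchange_ids.index(rid)
    le_hat = fit.theta[j]
    blo, bhi = problem.bounds()

    def profile(le):
        return _reoptimize_with_exchange_pin(problem, rid, le, fit.theta)

    out = []
    for sign, edge in ((-1.0, blo[j]), (1.0, bhi[j])):
        le, step, crossed = le_hat, 0.25, False
        lo_g = hi_g = le_hat
        while (edge - le) * sign > 0:
            le_next = le + sign * step
            if (le_next - edge) * sign > 0:
                le_next = edge
            if profile(le_next) > limit:
                lo_g, hi_g, crossed = le, le_next, True
                break
            le = le_next
            step *= 1.6
            if le == edge:
                break
        if not crossed:
            # flat to the search edge: lower edge collapses to 0 exchange,
            # upper edge is reported open
            out.append(0.0 if sign < 0 else np.inf)
            continue
        for _ in range(n_refine):
            mid = 0.5 * (lo_g + hi_g)
            if profile(mid) > limit:
                hi_g = mid
            else:
                lo_g = mid
        out.append(10.0 ** (0.5 * (lo_g + hi_g)))
    lo, hi = sorted(out)
    fit.ci[f"{rid}.exchange"] = (lo, hi)
    return lo, hi
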