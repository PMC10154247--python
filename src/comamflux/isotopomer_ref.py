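"""Exhaustive full-isotopomer steady-state reference solver.

Tracks the complete 2^n positional-isotopomer distribution of every balanced
metabolite and solves the steady-state mixing equations by fixed-point
iteration.  Exponential in carbon count, so only usable on small networks —
which is the point: it shares no code path with the EMU solver and serves as
its independent cross-check.
"""

from __future__ import annotations

import numpy as np

from .emu import TracerSpec, _inflows
from .fluxes import FluxVector
from .network import ROLE_SOURCE, NetworkModel


def tracer_isotopomers(tracer: TracerSpec, n: int) -> np.ndarray:
    """Full isotopomer distribution (bit i of the index = position i+1 heavy)."""
    p = np.array([1.0])
    for pos in range(1, n + 1):
        pi = tracer.purity[pos - 1]
        # index bit ordering: position 1 is the least significant bit
        p = np.concatenate([p * (1 - pi), p * pi])
    w = tracer.unlabeled_weight
    if w:
        p = (1 - w) * p
        p[0] += w
    return p


def mid_from_isotopomers(p: np.ndarray, n: int) -> np.ndarray:
    mid = np.zeros(n + 1)
    for idx in range(2 ** n):
        mid[bin(idx).count("1")] += p[idx]
    return mid


def _flip_index_table(n: int) -> np.ndarray:
    """Index permutation reversing carbon order (for symmetric metabolites)."""
    out = np.empty(2 ** n, dtype=int)
    for idx in range(2 ** n):
        rev = 0
        for b in range(n):
            if idx >> b & 1:
                rev |= 1 << (n - 1 - b)
        out[idx] = rev
    return out


def simulate_isotopomers(model: NetworkModel, fluxes: FluxVector,
                         tracers: TracerSpec | dict[str, TracerSpec],
                         tol: float = 1e-13, max_iter: int = 200_000,
                         ) -> dict[str, np.ndarray]:
    """Steady-state isotopomer distributions of all balanced metabolites."""
    if isinstance(tracers, TracerSpec):
        tracers = {tracers.substrate: tracers}
    nc = {m.id: m.n_carbons for m in model.metabolites.values()}

    fixed: dict[str, np.ndarray] = {}
    for m in model.metabolites.values():
        if m.role == ROLE_SOURCE:
            tr = tracers.get(m.id)
            if tr is None:
                p = np.zeros(2 ** m.n_carbons)
                p[0] = 1.0
            else:
                p = tracer_isotopomers(tr, m.n_carbons)
            fixed[m.id] = p

    vf = {}
    for r in model.reactions:
        f, b = fluxes.unidirectional(r.id)
        vf[(r.id, "f")], vf[(r.id, "b")] = f, b

    inflows = _inflows(model)
    balanced = model.balanced_metabolites()
    state = {m: np.eye(2 ** nc[m])[0].copy() for m in balanced}
    flip = {m: _flip_index_table(nc[m]) for m in balanced
            if model.metabolites[m].symmetric}

    # precompute structural info per inflow: for each product isotopomer
    # index, the substrate-occurrence patterns it requires
    plans = {}
    for met in balanced:
        met_plans = []
        for rid, d, subs, prods, occ in inflows[met]:
            _, amap = prods[occ]
            where = {}
            for si, (smet, smap) in enumerate(subs):
                for spos, letter in enumerate(smap, start=1):
                    where[letter] = (si, spos)
            groups: dict[int, list[tuple[int, int]]] = {}
            n = nc[met]
            for pos in range(1, n + 1):
                si, spos = where[amap[pos - 1]]
                groups.setdefault(si, []).append((pos, spos))
            met_plans.append(((rid, d), [(subs[si][0], pairs)
                                         for si, pairs in groups.items()]))
        plans[met] = met_plans

    def contribution(plan, dists) -> np.ndarray:
        """Distribution delivered to the product pool by one inflow."""
        n = nc_met
        q = np.ones(2 ** n)
        for smet, pairs in plan:
            ps = dists[smet]
            ns = nc[smet]
            # marginal over the needed substrate positions
            sub_positions = [spos for _, spos in pairs]
            k = len(sub_positions)
            marg = np.zeros(2 ** k)
            for iso in range(2 ** ns):
                pat = 0
                for bi, spos in enumerate(sub_positions):
                    if iso >> (spos - 1) & 1:
                        pat |= 1 << bi
                marg[pat] += ps[iso]
            # expand onto product indices
            factor = np.empty(2 ** n)
            for idx in range(2 ** n):
                pat = 0
                for bi, (pos, _) in enumerate(pairs):
                    if idx >> (pos - 1) & 1:
                        pat |= 1 << bi
                factor[idx] = marg[pat]
            q *= factor
        return q

    for _ in range(max_iter):
        delta = 0.0
        new_state = {}
        dists = {**fixed, **state}
        for met in balanced:
            nc_met = nc[met]
            total = 0.0
            acc = np.zeros(2 ** nc_met)
            for key, plan in plans[met]:
                v = vf[key]
                if v == 0.0:
                    continue
                total += v
                acc += v * contribution(plan, dists)
            if total <= 1e-12:
                raise RuntimeError(f"metabolite {met} has zero throughput")
            p = acc / total
            if met in flip:
                p = 0.5 * (p + p[flip[met]])
            delta = max(delta, float(np.max(np.abs(p - state[met]))))
            new_state[met] = p
        state = new_state
        if delta < tol:
            break
    else:
        raise RuntimeError("isotopomer fixed point did not converge")
    return state


def simulate_mids_reference(model: NetworkModel, fluxes: FluxVector,
                            tracers, targets: list[str]) -> dict[str, np.ndarray]:
    """Full-molecule MIDs via exhaustive isotopomer enumeration."""
    iso = simulate_isotopomers(model, fluxes, tracers)
    nc = {m.id: m.n_carbons for m in model.metabolites.values()}
    return {t: mid_from_isotopomers(iso[t], nc[t]) for t in targets}
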