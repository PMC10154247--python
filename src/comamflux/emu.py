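"""Steady-state mass-isotopomer simulation by EMU decomposition.

An elementary metabolite unit (EMU) is a specific subset of a metabolite's
carbon atoms.  Tracing target EMUs backward through the atom maps yields a
dependency graph partitioned by EMU size in which condensation reactions
appear as convolutions of smaller EMUs; each size level is then a linear
system in the unknown EMU mass distributions, weighted by the unidirectional
fluxes (``v_f = v_net+ + v_exch``, ``v_b = v_net- + v_exch``).

Rotationally symmetric metabolites (succinate, fumarate) scramble their
carbon backbone 50/50: every flux producing such a pool delivers half of its
material in each orientation.  The scrambling is applied structurally while
building the EMU graph, which is arithmetically identical to inserting
explicit 50/50 scrambling pseudo-reactions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fluxes import FluxVector, steady_state_residual
from .network import ROLE_BALANCED, ROLE_SOURCE, NetworkModel


class SingularBalance(RuntimeError):
    """A needed EMU has zero throughput, so its labeling is undefined."""


@dataclass(frozen=True, order=True)
class EmuNode:
    """A metabolite together with an ordered subset of its carbon positions."""

    metabolite: str
    positions: tuple[int, ...]

    def __post_init__(self):
        if list(self.positions) != sorted(set(self.positions)):
            raise ValueError("EMU positions must be distinct and sorted")

    @property
    def size(self) -> int:
        return len(self.positions)

    def __str__(self):
        return f"{self.metabolite}{{{','.join(map(str, self.positions))}}}"


@dataclass(frozen=True)
class TracerSpec:
    """Isotopic composition of a labeled substrate.

    ``purity`` gives the per-position probability of carrying 13C *beyond
    natural abundance* (natural abundance is modeled separately at the
    measurement stage).  ``unlabeled_weight`` dilutes the tracer with a
    fully unlabeled fraction, for tracer mixtures.
    """

    substrate: str
    purity: tuple[float, ...]
    unlabeled_weight: float = 0.0

    def __post_init__(self):
        if not all(0.0 <= p <= 1.0 for p in self.purity):
            raise ValueError("purities must lie in [0, 1]")
        if not 0.0 <= self.unlabeled_weight <= 1.0:
            raise ValueError("unlabeled_weight must lie in [0, 1]")

    def emu_mid(self, positions: tuple[int, ...]) -> np.ndarray:
        mid = np.array([1.0])
        for pos in positions:
            p = self.purity[pos - 1]
            mid = np.convolve(mid, [1.0 - p, p])
        w = self.unlabeled_weight
        if w:
            mid = (1.0 - w) * mid
            mid[0] += w
        return mid


def unlabeled_tracer(substrate: str, n_carbons: int) -> TracerSpec:
    return TracerSpec(substrate, (0.0,) * n_carbons)


def convolve_mids(a, b):
    """Cauchy product of two mass-isotopomer distributions."""
    return np.convolve(np.asarray(a, dtype=float), np.asarray(b, dtype=float))


# ---------------------------------------------------------------------------
# decomposition
# ---------------------------------------------------------------------------

def _inflows(model: NetworkModel):
    """Unidirectional inflow occurrences per balanced metabolite.

    Yields ``met -> [(reaction_id, direction, product_side, occurrence)]``
    where ``product_side`` is the substrate/product list acting as products
    for that direction.
    """
    inflows: dict[str, list] = {m: [] for m in model.balanced_metabolites()}
    for r in model.reactions:
        sides = [("f", r.substrates, r.products)]
        if r.reversible:
            sides.append(("b", r.products, r.substrates))
        for d, subs, prods in sides:
            for occ, (met, _) in enumerate(prods):
                if met in inflows:
                    inflows[met].append((r.id, d, subs, prods, occ))
    return inflows


def _provenance(subs, prods, occ, positions):
    """Group source atoms of ``positions`` of product occurrence ``occ``
    by substrate occurrence -> {sub_occ: (sub_met, tuple(sub_positions))}."""
    _, amap = prods[occ]
    where = {}
    for si, (smet, smap) in enumerate(subs):
        for spos, letter in enumerate(smap, start=1):
            where[letter] = (si, smet, spos)
    groups: dict[int, list[int]] = {}
    for pos in positions:
        si, smet, spos = where[amap[pos - 1]]
        groups.setdefault(si, []).append(spos)
    return {si: (subs[si][0], tuple(sorted(ps))) for si, ps in groups.items()}


@dataclass
class _Term:
    """One inflow contribution to an EMU balance: weight * flux * product
    of the referenced EMU distributions (a convolution if more than one)."""

    row: int
    flux_key: tuple[str, str]
    weight: float
    refs: list[EmuNode]          # balanced-metabolite EMUs
    src_refs: list[tuple[str, tuple[int, ...]]]  # source-metabolite EMUs


@dataclass
class EmuGraph:
    """Compiled EMU dependency graph for a fixed model and target set."""

    model: NetworkModel
    targets: list[EmuNode]
    levels: dict[int, list[EmuNode]] = field(default_factory=dict)
    index: dict[EmuNode, int] = field(default_factory=dict)
    terms: dict[int, list[_Term]] = field(default_factory=dict)

    @property
    def nodes(self) -> list[EmuNode]:
        return [e for k in sorted(self.levels) for e in self.levels[k]]

    def dependencies(self, node: EmuNode) -> set[EmuNode]:
        out = set()
        for t in self.terms[node.size]:
            if self.levels[node.size][t.row] == node:
                out.update(t.refs)
                out.update(EmuNode(m, p) for m, p in t.src_refs)
        return out


def emu_decompose(model: NetworkModel, targets: list[EmuNode]) -> EmuGraph:
    """Build the EMU dependency graph reachable backward from ``targets``."""
    for t in targets:
        n = model.metabolites[t.metabolite].n_carbons
        if not t.positions or t.positions[-1] > n:
            raise ValueError(f"target {t}: positions out of range (1..{n})")
        if model.metabolites[t.metabolite].role != ROLE_BALANCED:
            raise ValueError(f"target {t}: not a balanced metabolite")

    inflows = _inflows(model)
    graph = EmuGraph(model, list(targets))
    pending = list(dict.fromkeys(targets))
    known: set[EmuNode] = set(pending)
    raw_terms: dict[EmuNode, list] = {}

    while pending:
        node = pending.pop()
        met = model.metabolites[node.metabolite]
        n = met.n_carbons
        orientations = [(node.positions, 1.0)]
        if met.symmetric:
            flipped = tuple(sorted(n + 1 - p for p in node.positions))
            orientations = [(node.positions, 0.5), (flipped, 0.5)]
        node_terms = []
        for rid, d, subs, prods, occ in inflows[node.metabolite]:
            for positions, w in orientations:
                groups = _provenance(subs, prods, occ, positions)
                refs, src_refs = [], []
                for smet, spos in groups.values():
                    if model.metabolites[smet].role == ROLE_SOURCE:
                        src_refs.append((smet, spos))
                    else:
                        child = EmuNode(smet, spos)
                        refs.append(child)
                        if child not in known:
                            known.add(child)
                            pending.append(child)
                node_terms.append(((rid, d), w, refs, src_refs))
        raw_terms[node] = node_terms

    for node in sorted(known, key=lambda e: (e.size, e.metabolite, e.positions)):
        graph.levels.setdefault(node.size, []).append(node)
        graph.index[node] = len(graph.levels[node.size]) - 1
    for size in graph.levels:
        graph.terms[size] = []
    for node, node_terms in raw_terms.items():
        for flux_key, w, refs, src_refs in node_terms:
            graph.terms[node.size].append(
                _Term(graph.index[node], flux_key, w, refs, src_refs))
    return graph


# ---------------------------------------------------------------------------
# steady-state solve
# ---------------------------------------------------------------------------

def _flux_lookup(model: NetworkModel, fluxes: FluxVector):
    table = {}
    for r in model.reactions:
        vf, vb = fluxes.unidirectional(r.id)
        table[(r.id, "f")] = vf
        table[(r.id, "b")] = vb
    return table


def solve_emus(graph: EmuGraph, fluxes: FluxVector,
               tracers: dict[str, TracerSpec]) -> dict[EmuNode, np.ndarray]:
    """Solve the cascaded EMU balance systems; returns MIDs per EMU node."""
    model = graph.model
    flux_of = _flux_lookup(model, fluxes)

    def source_mid(smet: str, spos: tuple[int, ...]) -> np.ndarray:
        tracer = tracers.get(smet)
        if tracer is None:
            return np.eye(len(spos) + 1)[0]
        return tracer.emu_mid(spos)

    total_inflow: dict[str, float] = {}
    for met in model.balanced_metabolites():
        total = 0.0
        for r, d in model.producers(met):
            mult = sum(1 for m, _ in (r.products if d == "f" else r.substrates)
                       if m == met)
            total += flux_of[(r.id, d)] * mult
        total_inflow[met] = total

    solution: dict[EmuNode, np.ndarray] = {}
    for size in sorted(graph.levels):
        nodes = graph.levels[size]
        m = len(nodes)
        A = np.zeros((m, m))
        B = np.zeros((m, size + 1))
        for i, node in enumerate(nodes):
            total = total_inflow[node.metabolite]
            if total <= 1e-12:
                raise SingularBalance(
                    f"EMU {node} has zero throughput; its labeling is undefined")
            A[i, i] = total
        for term in graph.terms[size]:
            v = flux_of[term.flux_key]
            if v == 0.0:
                continue
            same_level = [r for r in term.refs if r.size == size]
            if same_level and not term.src_refs and len(term.refs) == 1:
                A[term.row, graph.index[term.refs[0]]] -= term.weight * v
            else:
                vec = np.array([1.0])
                for ref in term.refs:
                    vec = np.convolve(vec, solution[ref])
                for smet, spos in term.src_refs:
                    vec = np.convolve(vec, source_mid(smet, spos))
                B[term.row] += term.weight * v * vec
        X = np.linalg.solve(A, B)
        for i, node in enumerate(nodes):
            solution[node] = X[i]
    return solution


def simulate_mids(model: NetworkModel, fluxes: FluxVector,
                  tracers: TracerSpec | dict[str, TracerSpec],
                  targets: list[str | EmuNode],
                  steady_tol: float = 1e-6) -> dict:
    """Simulate steady-state MIDs of the targets under the given tracers.

    ``targets`` may mix metabolite ids (full-molecule MID) and
    :class:`EmuNode` fragments.  ``tracers`` maps source-metabolite ids to
    :class:`TracerSpec`; unlisted sources are unlabeled.
    """
    if isinstance(tracers, TracerSpec):
        tracers = {tracers.substrate: tracers}
    for smet in tracers:
        if model.metabolites[smet].role != ROLE_SOURCE:
            raise ValueError(f"tracer substrate {smet!r} is not a source metabolite")
    resid = steady_state_residual(model, fluxes)
    if resid > steady_tol:
        raise ValueError(f"fluxes violate steady state (residual {resid:.3g})")

    nodes = []
    for t in targets:
        if isinstance(t, EmuNode):
            nodes.append(t)
        else:
            n = model.metabolites[t].n_carbons
            nodes.append(EmuNode(t, tuple(range(1, n + 1))))
    graph = emu_decompose(model, nodes)
    sol = solve_emus(graph, fluxes, tracers)
    out = {}
    for t, node in zip(targets, nodes):
        mid = sol[node]
        mid = np.clip(mid, 0.0, None)
        out[t] = mid / mid.sum()
    return out
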