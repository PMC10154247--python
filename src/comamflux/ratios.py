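"""Positional 13C labeling and local flux-ratio (source partitioning) analysis.

Under a low-enrichment tracer (e.g. [1-13C]-carboxyl-4HB) metabolite pools
are dominated by M+0 and M+1, and tandem-MS fragment MIDs let the M+1
fraction be allocated to specific carbon positions.  Two-source mixing
problems — which fraction of PEP comes from pyruvate versus OAA, of
fumarate from succinate versus OAA — then reduce to small constrained
least-squares systems over the mass (and positional) channels.

The PEP partitioning uses the pair of balance equations
``PEP0 = f1*pyr0 + f2*(OAA0 + OAA1_4th)`` and
``PEP1 = f1*pyr1 + f2*OAA1_1st``: decarboxylation of OAA (position 4 lost
as CO2) turns OAA labeled at carbon 4 into unlabeled PEP, while OAA labeled
at carbon 1 keeps its label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import lsq_linear

from .network import NetworkModel

HIGH_MASS_WARN = 0.05  # tolerated M+>=2 fraction for the low-enrichment model


class RatioError(ValueError):
    pass


@dataclass
class PositionalMID:
    """Allocation of a parent's M+1 fraction to carbon-position groups.

    ``groups`` maps a tuple of positions (a minimal identifiable set) to the
    M+1 fraction located inside it; singleton groups mean full positional
    resolution.
    """

    metabolite: str
    total: np.ndarray                       # parent MID
    groups: dict[tuple[int, ...], float] = field(default_factory=dict)
    provenance: list[str] = field(default_factory=list)
    residual: float = 0.0

    @property
    def m0(self) -> float:
        return float(self.total[0])

    @property
    def m1(self) -> float:
        return float(self.total[1])

    def at(self, position: int) -> float:
        for grp, val in self.groups.items():
            if position in grp:
                if len(grp) > 1:
                    raise RatioError(
                        f"position {position} only resolved within group {grp}")
                return val
        raise RatioError(f"position {position} outside all groups")


@dataclass
class RatioResult:
    f1: float
    f2: float
    residual: float
    per_replicate: list[tuple[float, float]] = field(default_factory=list)
    sd: float = float("nan")


def _check_low_enrichment(name: str, mid: np.ndarray):
    high = float(np.sum(mid[2:])) if len(mid) > 2 else 0.0
    if high > HIGH_MASS_WARN:
        warnings.warn(
            f"{name}: M+>=2 fraction {high:.3f} exceeds the low-enrichment "
            "assumption; higher mass channels are ignored", stacklevel=3)


def infer_positional(metabolite: str, parent, fragments,
                     n_carbons: int | None = None) -> PositionalMID:
    """Allocate a parent's M+1 fraction to carbon positions from fragment MIDs.

    ``fragments`` is a list of ``(positions, MID)`` pairs; a fragment's M+1
    equals the summed positional labeling inside its position subset.
    Positions whose fragment-coverage patterns coincide cannot be separated
    and are reported as groups.
    """
    parent = np.asarray(parent, dtype=float)
    n = n_carbons if n_carbons is not None else len(parent) - 1
    _check_low_enrichment(metabolite, parent)

    rows, rhs = [np.ones(n)], [float(parent[1])]  # closure over parent M+1
    prov = []
    for positions, frag in fragments:
        frag = np.asarray(frag, dtype=float)
        _check_low_enrichment(f"{metabolite} fragment {positions}", frag)
        ind = np.zeros(n)
        for p in positions:
            if not 1 <= p <= n:
                raise RatioError(f"fragment position {p} out of range 1..{n}")
            ind[p - 1] = 1.0
        rows.append(ind)
        rhs.append(float(frag[1]))
        prov.append(f"{metabolite}{{{','.join(map(str, positions))}}}")
    A = np.vstack(rows)
    b = np.asarray(rhs)

    # identifiability groups: positions with identical coverage patterns
    patterns = {}
    for p in range(n):
        patterns.setdefault(tuple(A[:, p]), []).append(p + 1)
    groups = sorted(patterns.values())

    # collapse columns by identifiability group, solve non-negatively
    Ag = np.stack([A[:, grp[0] - 1] for grp in groups], axis=1)
    if np.linalg.matrix_rank(Ag, tol=1e-10) < Ag.shape[1]:
        raise RatioError(
            "underdetermined position system: fragment coverage does not "
            f"separate the position groups {groups}")
    sol = lsq_linear(Ag, b, bounds=(0.0, np.inf))
    alloc = {tuple(grp): float(x) for grp, x in zip(groups, sol.x)}
    residual = float(np.sqrt(np.sum((Ag @ sol.x - b) ** 2)))
    return PositionalMID(metabolite, parent, alloc, prov, residual)


def solve_pep_ratio(pep, pyr, oaa: PositionalMID,
                    replicates: list[tuple] | None = None) -> RatioResult:
    """Fraction of the PEP pool drawn from pyruvate (f1) versus OAA (f2).

    ``pep``/``pyr`` are MIDs and ``oaa`` a PositionalMID of the same
    labeling condition; with ``replicates`` a list of (pep, pyr, oaa)
    triples, the two balance equations are solved jointly across replicates
    by constrained least squares (f1 + f2 = 1, both in [0, 1]).
    """
    triples = replicates if replicates is not None else [(pep, pyr, oaa)]

    def design(pep_i, pyr_i, oaa_i):
        pep_i = np.asarray(pep_i, dtype=float)
        pyr_i = np.asarray(pyr_i, dtype=float)
        _check_low_enrichment("PEP", pep_i)
        _check_low_enrichment("pyruvate", pyr_i)
        oaa0 = oaa_i.m0
        oaa1_1st = oaa_i.at(1)
        oaa1_4th = oaa_i.at(4)
        # rows: [pyr term, OAA term], rhs: PEP channel
        A = np.array([[pyr_i[0], oaa0 + oaa1_4th],
                      [pyr_i[1], oaa1_1st]])
        b = pep_i[:2].astype(float)
        return A, b

    blocks = [design(*t) for t in triples]
    A = np.vstack([a for a, _ in blocks])
    b = np.concatenate([bb for _, bb in blocks])
    if np.linalg.matrix_rank(A, tol=1e-10) < 2 or \
            np.linalg.norm(A[:, 0] - A[:, 1]) < 1e-10:
        raise RatioError("sources indistinguishable: pyruvate and OAA "
                         "labeling signatures are collinear")
    f1, resid = _simplex_mix(A, b)
    per_rep = []
    for a_i, b_i in blocks:
        fr, _ = _simplex_mix(a_i, b_i)
        per_rep.append((fr, 1.0 - fr))
    sd = float(np.std([f for f, _ in per_rep], ddof=1)) if len(per_rep) > 1 \
        else float("nan")
    return RatioResult(f1, 1.0 - f1, resid, per_rep, sd)


def _simplex_mix(A: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Min ||A [f, 1-f] - b|| over f in [0, 1]; closed-form 1-D quadratic."""
    d = A[:, 0] - A[:, 1]
    r = b - A[:, 1]
    denom = float(d @ d)
    if denom < 1e-14:
        raise RatioError("sources indistinguishable (collinear system)")
    f = float(np.clip((d @ r) / denom, 0.0, 1.0))
    resid = float(np.sqrt(np.sum((A @ np.array([f, 1 - f]) - b) ** 2)))
    return f, resid


def project_mid(mid, keep: list[int], n_carbons: int | None = None):
    """Project a mass-only MID onto a carbon subset, assuming exchangeable
    positions (hypergeometric redistribution of the label)."""
    mid = np.asarray(mid, dtype=float)
    n = n_carbons if n_carbons is not None else len(mid) - 1
    k = len(keep)
    from math import comb
    out = np.zeros(k + 1)
    for m, frac in enumerate(mid):
        if frac == 0:
            continue
        for j in range(0, min(m, k) + 1):
            if m - j > n - k:
                continue
            out[j] += frac * comb(k, j) * comb(n - k, m - j) / comb(n, m)
    return out


def project_positional(src: PositionalMID, keep: list[int]) -> np.ndarray:
    """Project a low-enrichment PositionalMID onto retained positions.

    Label at dropped positions becomes M+0 of the projection; the result is
    a 2-channel (M+0, M+1) vector plus zeros for higher masses.
    """
    kept_label = 0.0
    for grp, val in src.groups.items():
        inside = sum(1 for p in grp if p in keep)
        kept_label += val * inside / len(grp)
    out = np.zeros(len(keep) + 1)
    out[1] = kept_label
    # label at dropped positions, and any small M+>=2 of the parent, all
    # collapse into the unlabeled channel under the low-enrichment model
    out[0] = 1.0 - kept_label
    return out


def symmetrize_positional(src: PositionalMID, n_carbons: int) -> PositionalMID:
    """Average a PositionalMID over the two orientations of a symmetric
    (reversible-backbone) target such as fumarate or succinate."""
    merged: dict[tuple[int, ...], float] = {}
    for grp, val in src.groups.items():
        flipped = tuple(sorted(n_carbons + 1 - p for p in grp))
        merged[tuple(grp)] = merged.get(tuple(grp), 0.0) + 0.5 * val
        merged[flipped] = merged.get(flipped, 0.0) + 0.5 * val
    return PositionalMID(src.metabolite, src.total.copy(), merged,
                         src.provenance, src.residual)


def solve_two_source(target, source_a, source_b) -> RatioResult:
    """Least-squares mixture fraction across all mass channels.

    ``target``, ``source_a`` and ``source_b`` are MIDs on the *same* carbon
    skeleton — apply :func:`project_mid` / :func:`project_positional` first
    when a source loses carbons or feeds a symmetric pool.  Returns the
    fractions (f_a, f_b) with f_a + f_b = 1 and both in [0, 1].
    """
    t = np.asarray(target, dtype=float)
    a = np.asarray(source_a, dtype=float)
    bvec = np.asarray(source_b, dtype=float)
    if not len(t) == len(a) == len(bvec):
        raise RatioError("target and sources must share the carbon skeleton")
    if np.linalg.norm(a - bvec) < 1e-10:
        raise RatioError("sources indistinguishable (identical MIDs)")
    A = np.stack([a, bvec], axis=1)
    f, resid = _simplex_mix(A, t)
    return RatioResult(f, 1.0 - f, resid)


def oaa_positional_from_citrate(model: NetworkModel,
                                citrate: PositionalMID) -> PositionalMID:
    """Map positional labeling of citrate back onto its OAA-derived carbons.

    Uses the model's citrate-synthase atom map rather than a hard-coded
    lookup.  Citrate identifiability groups fully contained in the
    OAA-derived moiety carry over as OAA position groups; a group straddling
    the acetyl/OAA boundary cannot be attributed and raises.
    """
    cs = next(r for r in model.reactions
              if any(m == "OAA" for m, _ in r.substrates)
              and any(m == "CIT" for m, _ in r.products))
    (_, oaa_map), = [t for t in cs.substrates if t[0] == "OAA"]
    (_, cit_map), = [t for t in cs.products if t[0] == "CIT"]
    to_oaa = {cit_map.index(letter) + 1: opos
              for opos, letter in enumerate(oaa_map, start=1)}
    moiety = set(to_oaa)
    groups: dict[tuple[int, ...], float] = {}
    for grp, val in citrate.groups.items():
        inside = [p for p in grp if p in moiety]
        if not inside:
            continue
        if len(inside) != len(grp):
            raise RatioError(
                f"citrate group {grp} straddles the acetyl/OAA boundary; "
                "add a fragment separating those positions")
        groups[tuple(sorted(to_oaa[p] for p in inside))] = val
    total = np.zeros(5)
    total[1] = sum(groups.values())
    total[0] = 1.0 - total[1]
    return PositionalMID("OAA", total, groups,
                         [f"citrate:{citrate.provenance}"], citrate.residual)
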