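"""Atom-mapped metabolic network model.

The network is a list of reactions whose substrates and products carry carbon
atom maps written as lowercase letter strings (one letter per tracked carbon,
position 1 = carboxyl carbon as conventionally drawn).  A companion
configuration assigns metabolite roles (substrate source, sink/secretion,
balanced intracellular pool), marks rotationally symmetric metabolites
(succinate, fumarate), and carries the biomass-precursor efflux table and
measurement configuration.

The shipped model describes central carbon metabolism of *Comamonas
testosteroni* KF-1 growing on 4-hydroxybenzoate (4HB): the protocatechuate
4,5-meta cleavage funnel (six enzymatic steps, no CO2 loss), the TCA cycle
with separate Mdh and Mqo steps, the glyoxylate shunt, the three cataplerotic
reactions, pyruvate dehydrogenase, PEP synthetase, the gluconeogenic EMP
chain, the non-oxidative pentose phosphate pathway, CO2 exchange, biomass
precursor effluxes and the measured metabolite secretions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

ROLE_BALANCED = "balanced"
ROLE_SOURCE = "substrate-source"
ROLE_SINK = "sink"

COFACTOR_POOLS = ("NADH", "NADPH", "FADH2", "ATP")


class ModelError(ValueError):
    """Raised for malformed model tables or inconsistent networks."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    n_carbons: int
    role: str = ROLE_BALANCED
    symmetric: bool = False

    def __post_init__(self):
        if self.n_carbons < 0:
            raise ModelError(f"metabolite {self.id}: negative carbon count")


@dataclass
class Reaction:
    """One atom-mapped reaction.

    ``substrates``/``products`` are lists of ``(metabolite_id, atom_string)``
    pairs; every atom letter must occur exactly once on each side (carbon
    conservation).  ``cofactors`` holds signed stoichiometry over the
    NADH/NADPH/FADH2/ATP pools for the reaction as written (forward
    direction); cofactors are bookkeeping metadata, not balanced rows.
    """

    id: str
    substrates: list[tuple[str, str]]
    products: list[tuple[str, str]]
    reversible: bool = False
    cofactors: dict[str, float] = field(default_factory=dict)
    enzyme: str = ""

    def carbon_balanced(self) -> bool:
        sub = sorted("".join(m for _, m in self.substrates))
        prod = sorted("".join(m for _, m in self.products))
        unique = len(sub) == len(set(sub)) and len(prod) == len(set(prod))
        return unique and sub == prod

    def atom_source_map(self) -> list[tuple[int, int, int, int]]:
        """Product atom provenance as (prod_occ, prod_pos, sub_occ, sub_pos).

        Occurrence indices refer to positions in the substrate/product lists
        (a metabolite may appear more than once, e.g. in condensations of two
        identical molecules); atom positions are 1-based.
        """
        where: dict[str, tuple[int, int]] = {}
        for si, (_, amap) in enumerate(self.substrates):
            for pos, letter in enumerate(amap, start=1):
                where[letter] = (si, pos)
        out = []
        for pi, (_, amap) in enumerate(self.products):
            for pos, letter in enumerate(amap, start=1):
                out.append((pi, pos, *where[letter]))
        return out


@dataclass
class NetworkModel:
    reactions: list[Reaction]
    metabolites: dict[str, Metabolite]
    uptake_reaction: str = ""
    co2_input_reaction: str = ""
    secretion_reactions: list[str] = field(default_factory=list)
    biomass_reactions: list[str] = field(default_factory=list)
    biomass_efflux: dict[str, float] = field(default_factory=dict)
    measured_metabolites: list[str] = field(default_factory=list)
    fixed_fluxes: dict[str, float] = field(default_factory=dict)
    natural_abundance: float = 0.0107
    temperature_K: float = 303.15

    # -- lookups ---------------------------------------------------------
    def reaction(self, rid: str) -> Reaction:
        try:
            return next(r for r in self.reactions if r.id == rid)
        except StopIteration:
            raise KeyError(rid) from None

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def balanced_metabolites(self) -> list[str]:
        return [m.id for m in self.metabolites.values() if m.role == ROLE_BALANCED]

    def producers(self, met: str) -> list[tuple[Reaction, str]]:
        """Reactions able to produce ``met``: (reaction, 'f'|'b')."""
        out = []
        for r in self.reactions:
            if any(m == met for m, _ in r.products):
                out.append((r, "f"))
            if r.reversible and any(m == met for m, _ in r.substrates):
                out.append((r, "b"))
        return out

    def consumers(self, met: str) -> list[tuple[Reaction, str]]:
        out = []
        for r in self.reactions:
            if any(m == met for m, _ in r.substrates):
                out.append((r, "f"))
            if r.reversible and any(m == met for m, _ in r.products):
                out.append((r, "b"))
        return out


# ---------------------------------------------------------------------------
# parsing / serialization
# ---------------------------------------------------------------------------

_TERM = re.compile(r"^\s*([A-Za-z0-9_]+)\s*\(([a-z]*)\)\s*$")
_FLAG = re.compile(r"\[([^\]]*)\]")


def _parse_side(text: str, lineno: int) -> list[tuple[str, str]]:
    text = text.strip()
    if not text:
        return []
    terms = []
    for chunk in text.split("+"):
        m = _TERM.match(chunk)
        if not m:
            raise ModelError(f"line {lineno}: malformed term {chunk.strip()!r} "
                             "(expected 'MET (atoms)')")
        terms.append((m.group(1), m.group(2)))
    return terms


def parse_reaction_line(line: str, lineno: int = 0) -> Reaction:
    body = line
    flags = _FLAG.findall(line)
    body = _FLAG.sub("", body)
    if ":" not in body:
        raise ModelError(f"line {lineno}: missing 'ID:' prefix")
    rid, rest = body.split(":", 1)
    if "->" not in rest:
        raise ModelError(f"line {lineno}: missing '->'")
    left, right = rest.split("->", 1)
    reversible = False
    cofactors: dict[str, float] = {}
    enzyme = ""
    for f in flags:
        f = f.strip()
        if f == "reversible":
            reversible = True
        elif f.startswith("cofactors:"):
            for item in f[len("cofactors:"):].split(","):
                k, v = item.split("=")
                k = k.strip()
                if k not in COFACTOR_POOLS:
                    raise ModelError(f"line {lineno}: unknown cofactor {k!r}")
                cofactors[k] = float(v)
        elif f.startswith("enzyme:"):
            enzyme = f[len("enzyme:"):].strip()
        else:
            raise ModelError(f"line {lineno}: unknown flag [{f}]")
    rxn = Reaction(
        id=rid.strip(),
        substrates=_parse_side(left, lineno),
        products=_parse_side(right, lineno),
        reversible=reversible,
        cofactors=cofactors,
        enzyme=enzyme,
    )
    if not rxn.carbon_balanced():
        raise ModelError(
            f"line {lineno}: reaction {rxn.id} is not carbon-balanced "
            "(atom letters must match one-to-one across sides)")
    return rxn


def parse_model(text: str, config: dict | None = None) -> NetworkModel:
    """Parse a model table (one reaction per line, ``#`` comments).

    ``config`` is the companion configuration mapping (roles, symmetry,
    biomass efflux table, measurement setup); omitted keys default sensibly.
    """
    config = dict(config or {})
    reactions: list[Reaction] = []
    seen = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        rxn = parse_reaction_line(line, lineno)
        if rxn.id in seen:
            raise ModelError(f"line {lineno}: duplicate reaction id {rxn.id!r}")
        seen.add(rxn.id)
        reactions.append(rxn)

    sources = set(config.get("sources", []))
    sinks = set(config.get("sinks", []))
    symmetric = set(config.get("symmetric", []))
    # infer sinks: metabolites never consumed; infer sources: never produced
    carbons: dict[str, int] = {}
    produced, consumed = set(), set()
    for r in reactions:
        for met, amap in r.substrates + r.products:
            n = len(amap)
            if met in carbons and carbons[met] != n:
                raise ModelError(
                    f"metabolite {met}: inconsistent carbon count "
                    f"({carbons[met]} vs {n})")
            carbons[met] = n
        consumed.update(m for m, _ in r.substrates)
        produced.update(m for m, _ in r.products)
        if r.reversible:
            consumed.update(m for m, _ in r.products)
            produced.update(m for m, _ in r.substrates)
    sources |= consumed - produced
    sinks |= produced - consumed
    forced_balanced = set(config.get("balanced", []))
    sources -= forced_balanced
    sinks -= forced_balanced

    metabolites = {}
    for met, n in carbons.items():
        role = (ROLE_SOURCE if met in sources
                else ROLE_SINK if met in sinks else ROLE_BALANCED)
        metabolites[met] = Metabolite(met, n, role, symmetric=met in symmetric)

    model = NetworkModel(
        reactions=reactions,
        metabolites=metabolites,
        uptake_reaction=config.get("uptake_reaction", ""),
        co2_input_reaction=config.get("co2_input_reaction", ""),
        secretion_reactions=list(config.get("secretion_reactions", [])),
        biomass_reactions=list(config.get("biomass_reactions", [])),
        biomass_efflux=dict(config.get("biomass_efflux", {})),
        measured_metabolites=list(config.get("measured_metabolites", [])),
        fixed_fluxes=dict(config.get("fixed_fluxes", {})),
        natural_abundance=float(config.get("natural_abundance", 0.0107)),
        temperature_K=float(config.get("temperature_K", 303.15)),
    )
    for met in model.biomass_efflux:
        if met not in metabolites:
            raise ModelError(f"biomass table references unknown metabolite {met!r}")
    for rid in (model.secretion_reactions + model.biomass_reactions
                + ([model.uptake_reaction] if model.uptake_reaction else [])):
        if rid not in seen:
            raise ModelError(f"configuration references unknown reaction {rid!r}")
    return model


def serialize_model(model: NetworkModel) -> str:
    """Write the reaction table back out in canonical form."""
    lines = []
    for r in model.reactions:
        def side(terms):
            return " + ".join(f"{m} ({a})" for m, a in terms)
        parts = [f"{r.id}: {side(r.substrates)} -> {side(r.products)}"]
        if r.reversible:
            parts.append("[reversible]")
        if r.cofactors:
            cof = ",".join(f"{k}={v:g}" for k, v in r.cofactors.items())
            parts.append(f"[cofactors: {cof}]")
        if r.enzyme:
            parts.append(f"[enzyme: {r.enzyme}]")
        lines.append(" ".join(parts))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    carbon_imbalanced: list[str]
    unreachable: list[str]
    dead_ends: list[str]
    n_reactions: int

    @property
    def violations(self) -> int:
        return len(self.carbon_imbalanced) + len(self.unreachable) + len(self.dead_ends)

    def __str__(self):
        lines = [f"reactions: {self.n_reactions}",
                 f"violations: {self.violations}"]
        for label, items in (("carbon-imbalanced", self.carbon_imbalanced),
                             ("unreachable", self.unreachable),
                             ("dead-end", self.dead_ends)):
            for x in items:
                lines.append(f"  {label}: {x}")
        return "\n".join(lines)


def validate_model(model: NetworkModel) -> ValidationReport:
    """Report-only structural checks.

    A balanced metabolite is a *dead end* if it lacks a producer or a
    consumer (counting both directions of reversible reactions), and
    *unreachable* if no directed atom path connects it to a substrate source.
    """
    imbalanced = [r.id for r in model.reactions if not r.carbon_balanced()]

    reachable = {m.id for m in model.metabolites.values() if m.role == ROLE_SOURCE}
    changed = True
    while changed:
        changed = False
        for r in model.reactions:
            subs = {m for m, _ in r.substrates}
            prods = {m for m, _ in r.products}
            if subs and subs <= reachable and not prods <= reachable:
                reachable |= prods
                changed = True
            if r.reversible and prods and prods <= reachable and not subs <= reachable:
                reachable |= subs
                changed = True
    unreachable = [m for m in model.balanced_metabolites() if m not in reachable]

    dead = []
    for met in model.balanced_metabolites():
        if not model.producers(met) or not model.consumers(met):
            dead.append(met)
    return ValidationReport(imbalanced, unreachable, dead, len(model.reactions))


def stoichiometric_matrix(model: NetworkModel):
    """Signed stoichiometry over balanced metabolites x reactions.

    Returns ``(S, row_names, col_names)``; source and sink species are
    excluded from the rows.  Coefficients count occurrences, so a
    condensation of two identical molecules contributes -2.
    """
    rows = model.balanced_metabolites()
    idx = {m: i for i, m in enumerate(rows)}
    S = np.zeros((len(rows), len(model.reactions)))
    for j, r in enumerate(model.reactions):
        for m, _ in r.substrates:
            if m in idx:
                S[idx[m], j] -= 1
        for m, _ in r.products:
            if m in idx:
                S[idx[m], j] += 1
    return S, rows, model.reaction_ids


# ---------------------------------------------------------------------------
# shipped KF-1 model
# ---------------------------------------------------------------------------

def _data_text(name: str) -> str:
    return resources.files("comamflux.data").joinpath(name).read_text()


def load_kf1_model() -> NetworkModel:
    """The shipped *C. testosteroni* KF-1 central-carbon model (57 reactions)."""
    return parse_model(_data_text("kf1_model.txt"),
                       yaml.safe_load(_data_text("kf1_config.yaml")))


def meta_cleavage_path(model: NetworkModel) -> list[Reaction]:
    """The PCA -> pyruvate + OAA 4,5-meta cleavage route, in order.

    Follows the unique chain of carbon transfer from PCA until the aldol
    split releases pyruvate and OAA.
    """
    path = []
    met = "PCA"
    guard = 0
    while guard < 20:
        guard += 1
        nxt = [r for r in model.reactions
               if any(m == met for m, _ in r.substrates)
               and not any(m == met for m, _ in r.products)
               and r.id not in model.secretion_reactions]
        if len(nxt) != 1:
            raise ModelError(f"4,5-meta route ambiguous at {met}")
        r = nxt[0]
        path.append(r)
        prods = [m for m, _ in r.products]
        if "PYR" in prods and "OAA" in prods:
            return path
        met = prods[0]
    raise ModelError("4,5-meta route does not terminate at pyruvate + OAA")


def compose_route_map(path: list[Reaction], start: str) -> dict[int, tuple[str, int]]:
    """Compose atom maps along a linear route.

    Returns, for each carbon position of ``start``, the (metabolite,
    position) it ends up in after the last reaction of ``path``.  Each
    reaction must carry the tracked carbons in a single substrate.
    """
    first = path[0]
    (sub, smap), = [t for t in first.substrates if t[0] == start]
    state: dict[int, tuple[str, int]] = {i: (start, i) for i in range(1, len(smap) + 1)}
    for r in path:
        smaps = dict(r.substrates)
        dest: dict[str, tuple[str, int]] = {}
        for met, amap in r.products:
            for pos, letter in enumerate(amap, start=1):
                dest[letter] = (met, pos)
        new_state = {}
        for orig, (met, pos) in state.items():
            amap = smaps.get(met)
            if amap is None:
                new_state[orig] = (met, pos)  # already left the route
            else:
                new_state[orig] = dest[amap[pos - 1]]
        state = new_state
    return state
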