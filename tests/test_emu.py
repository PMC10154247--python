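"""EMU decomposition and steady-state MID simulation.

The heavy check is oracle equivalence: on randomized small networks the EMU
cascade must reproduce the exhaustive 2^n full-isotopomer steady state to
numerical precision.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from comamflux.emu import (
    EmuNode,
    SingularBalance,
    TracerSpec,
    convolve_mids,
    emu_decompose,
    simulate_mids,
)
from comamflux.fluxes import FluxVector
from comamflux.isotopomer_ref import simulate_mids_reference
from comamflux.network import parse_model
from comamflux.synth import random_oracle_model


def chain_model():
    return parse_model(
        "U: Ax (ab) -> A (ab)\nR1: A (ab) -> B (ab)\n"
        "R2: B (ab) -> C (ab)\nO: C (ab) -> Cx (ab)")


class TestDecomposition:
    def test_chain_ancestry(self):
        m = chain_model()
        g = emu_decompose(m, [EmuNode("C", (1, 2))])
        names = {str(n) for n in g.nodes}
        assert names == {"C{1,2}", "B{1,2}", "A{1,2}"}
        assert all(not t.refs or len(t.refs) == 1
                   for lvl in g.terms.values() for t in lvl)

    def test_condensation_produces_convolution(self):
        m = parse_model("U: Ax (ab) -> A (ab)\n"
                        "R1: A (ab) + A (cd) -> B (abcd)\n"
                        "O: B (abcd) -> Bx (abcd)")
        g = emu_decompose(m, [EmuNode("B", (1, 2, 3, 4))])
        terms = g.terms[4]
        conv = [t for t in terms if len(t.refs) + len(t.src_refs) > 1]
        assert len(conv) == 1
        assert conv[0].refs[0] == EmuNode("A", (1, 2))
        assert conv[0].refs[1] == EmuNode("A", (1, 2))

    def test_positions_out_of_range_rejected(self, kf1_model):
        with pytest.raises(ValueError, match="out of range"):
            emu_decompose(kf1_model, [EmuNode("PYR", (1, 4))])

    def test_kf1_citrate_sources_match_ancestry_enumeration(self, kf1_model,
                                                            kf1_scenario):
        # independent oracle: exhaustive backward single-atom ancestry on the
        # same atom maps must reach exactly the metabolites whose EMUs appear
        # in the decomposition
        target = EmuNode("CIT", tuple(range(1, 7)))
        g = emu_decompose(kf1_model, [target])
        emu_mets = {n.metabolite for n in g.nodes}

        # brute-force ancestry: which balanced metabolites can pass a carbon
        # to citrate (transitively), following unidirectional atom edges?
        edges = set()
        for r in kf1_model.reactions:
            sides = [(r.substrates, r.products)]
            if r.reversible:
                sides.append((r.products, r.substrates))
            for subs, prods in sides:
                where = {}
                for smet, smap in subs:
                    for letter in smap:
                        where[letter] = smet
                for pmet, pmap in prods:
                    for letter in pmap:
                        edges.add((where[letter], pmet))
        ancestors = {"CIT"}
        changed = True
        while changed:
            changed = False
            for src, dst in edges:
                if dst in ancestors and src not in ancestors:
                    ancestors.add(src)
                    changed = True
        balanced_ancestors = {m for m in ancestors
                              if m in kf1_model.balanced_metabolites()}
        assert emu_mets == balanced_ancestors


class TestSimulation:
    def test_pass_through_single_label(self):
        m = chain_model()
        fl = FluxVector({r: 1.0 for r in m.reaction_ids})
        sim = simulate_mids(m, fl, TracerSpec("Ax", (1.0, 0.0)), ["C"])
        assert np.allclose(sim["C"], [0, 1, 0])

    def test_condensation_binomial(self):
        m = parse_model("U: Ax (ab) -> A (ab)\n"
                        "R1: A (ab) + A (cd) -> B (abcd)\n"
                        "O: B (abcd) -> Bx (abcd)")
        fl = FluxVector({"U": 2.0, "R1": 1.0, "O": 1.0})
        tracer = TracerSpec("Ax", (1.0, 0.0), unlabeled_weight=0.5)
        sim = simulate_mids(m, fl, tracer, ["B"])
        assert np.allclose(sim["B"], [0.25, 0.5, 0.25, 0, 0])

    def test_unlabeled_tracer_gives_all_m0(self, kf1_model, kf1_scenario):
        sim = simulate_mids(kf1_model, kf1_scenario.true_fluxes,
                            {}, ["CIT", "PEP", "S7P"])
        for mid in sim.values():
            assert mid[0] == pytest.approx(1.0, abs=1e-9)

    def test_fully_labeled_substrate_gives_all_mn(self):
        # no unlabeled inflow anywhere -> every pool fully labeled
        from comamflux.synth import toy_split_model
        m = toy_split_model()
        from comamflux.fluxes import parameterize
        basis = parameterize(m, {"U": 100.0})
        fl = basis.fluxes(basis.free_for_targets({"RP": 60.0}))
        sim = simulate_mids(m, fl, TracerSpec("Sx", (1.0, 1.0)),
                            ["P", "M", "D"])
        for mid in sim.values():
            assert mid[-1] == pytest.approx(1.0, abs=1e-9)

    def test_mids_normalized_and_bounded(self, kf1_model, kf1_scenario):
        from comamflux.synth import tracer_13c6_phenyl_4hb
        sim = simulate_mids(kf1_model, kf1_scenario.true_fluxes,
                            tracer_13c6_phenyl_4hb(),
                            kf1_scenario.targets())
        for mid in sim.values():
            assert abs(mid.sum() - 1.0) < 1e-9
            assert np.all(mid >= 0) and np.all(mid <= 1)

    def test_zero_throughput_emu_flagged(self):
        m = parse_model("U: Ax (a) -> A (a)\nR1: A (a) -> B (a)\n"
                        "R2: B (a) -> C (a)\nR3: D (a) -> C (a)\n"
                        "O: C (a) -> Cx (a)", {"balanced": ["D"]})
        fl = FluxVector({"U": 1, "R1": 1, "R2": 1, "R3": 0, "O": 1})
        with pytest.raises(SingularBalance, match="D"):
            simulate_mids(m, fl, TracerSpec("Ax", (1.0,)), ["C", "D"],
                          steady_tol=1e-3)

    def test_steady_state_violation_rejected(self):
        m = chain_model()
        fl = FluxVector({"U": 1.0, "R1": 0.5, "R2": 1.0, "O": 1.0})
        with pytest.raises(ValueError, match="steady state"):
            simulate_mids(m, fl, TracerSpec("Ax", (1.0, 0.0)), ["C"])


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(30))
    def test_matches_exhaustive_isotopomer_solution(self, seed):
        rng = np.random.default_rng(seed)
        model, fluxes, tracer = random_oracle_model(rng)
        targets = ["P", "M", "H", "G"]
        emu = simulate_mids(model, fluxes, tracer, targets)
        ref = simulate_mids_reference(model, fluxes, tracer, targets)
        for t in targets:
            assert np.max(np.abs(emu[t] - ref[t])) < 1e-8, t


class TestConvolution:
    @pytest.mark.parametrize("a,b,expected", [
        ([1, 0], [1, 0], [1, 0, 0]),
        ([0.5, 0.5], [0.5, 0.5], [0.25, 0.5, 0.25]),
        ([0.2, 0.8], [0.1, 0.9], [0.02, 0.26, 0.72]),
    ])
    def test_examples(self, a, b, expected):
        assert np.allclose(convolve_mids(a, b), expected)

    @given(st.lists(st.floats(0.01, 1.0), min_size=1, max_size=5),
           st.lists(st.floats(0.01, 1.0), min_size=1, max_size=5))
    @settings(deadline=None, max_examples=50)
    def test_dimension_and_normalization(self, a, b):
        a = np.array(a) / np.sum(a)
        b = np.array(b) / np.sum(b)
        c = convolve_mids(a, b)
        assert len(c) == len(a) + len(b) - 1
        assert np.isclose(c.sum(), 1.0)
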