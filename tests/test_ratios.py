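"""Positional labeling inference and two-source flux-ratio solving."""

import numpy as np
import pytest

from comamflux.emu import EmuNode, TracerSpec, simulate_mids
from comamflux.ratios import (
    PositionalMID,
    RatioError,
    infer_positional,
    oaa_positional_from_citrate,
    project_mid,
    project_positional,
    solve_pep_ratio,
    solve_two_source,
    symmetrize_positional,
)


def make_positional(m0, first, fourth, extra=None):
    total = np.zeros(5)
    total[1] = first + fourth + sum((extra or {}).values())
    total[0] = m0
    groups = {(1,): first, (4,): fourth}
    for k, v in (extra or {}).items():
        groups[k] = v
    return PositionalMID("OAA", total, groups)


class TestInferPositional:
    def test_label_confined_to_covered_positions(self):
        parent = [0.70, 0.30, 0, 0]
        frag = [0.70, 0.30, 0, 0]
        pos = infer_positional("X", parent, [((1, 2, 3), frag)])
        inside = sum(v for g, v in pos.groups.items() if set(g) <= {1, 2, 3})
        assert inside == pytest.approx(0.30, abs=1e-9)

    def test_subtraction_against_complement(self):
        # 4-carbon parent, fragment 1-3 carries 0.10 of the 0.40 M+1
        parent = [0.60, 0.40, 0, 0, 0]
        frag = [0.90, 0.10, 0, 0]
        pos = infer_positional("X", parent, [((1, 2, 3), frag)])
        assert pos.groups[(1, 2, 3)] == pytest.approx(0.10, abs=1e-9)
        assert pos.groups[(4,)] == pytest.approx(0.30, abs=1e-9)

    def test_overlapping_fragments_recover_positional_truth(self, rng):
        # forward-simulate single-position labeling on a 6-carbon parent
        truth = rng.dirichlet(np.ones(6)) * 0.4
        fragments = []
        for subset in [(1, 2, 3), (3, 4, 5), (2, 4, 6), (1, 6), (5, 6)]:
            m1 = float(sum(truth[p - 1] for p in subset))
            fragments.append((subset, [1 - m1, m1] + [0] * (len(subset) - 1)))
        parent = np.zeros(7)
        parent[1] = truth.sum()
        parent[0] = 1 - truth.sum()
        pos = infer_positional("X", parent, fragments)
        got = np.array([pos.at(p) for p in range(1, 7)])
        assert np.max(np.abs(got - truth)) < 1e-6

    def test_unresolved_position_raises_on_access(self):
        parent = [0.6, 0.4, 0, 0, 0]
        pos = infer_positional("X", parent, [((1, 2), [0.9, 0.1, 0])])
        with pytest.raises(RatioError, match="group"):
            pos.at(1)


class TestPepRatio:
    def test_pep_equals_pyruvate(self):
        oaa = make_positional(0.5, 0.3, 0.2)
        res = solve_pep_ratio([0.8, 0.2], [0.8, 0.2], oaa)
        assert res.f1 == pytest.approx(1.0, abs=1e-9)

    def test_forward_mixture_inversion(self):
        # pyr = (0.8, 0.2), OAA0 = 0.5, OAA1_1st = 0.3, OAA1_4th = 0.2,
        # truth (0.6, 0.4) -> PEP = (0.76, 0.24) -> solver recovers
        oaa = make_positional(0.5, 0.3, 0.2)
        pep = [0.6 * 0.8 + 0.4 * (0.5 + 0.2), 0.6 * 0.2 + 0.4 * 0.3]
        assert pep == pytest.approx([0.76, 0.24])
        res = solve_pep_ratio(pep, [0.8, 0.2], oaa)
        assert res.f1 == pytest.approx(0.600, abs=1e-9)
        assert res.f2 == pytest.approx(0.400, abs=1e-9)

    def test_noisy_replicates(self):
        rng = np.random.default_rng(17)
        oaa = make_positional(0.5, 0.3, 0.2)
        reps = []
        for _ in range(3):
            pep = np.array([0.76, 0.24]) + rng.normal(0, 0.01, 2)
            pyr = np.array([0.8, 0.2]) + rng.normal(0, 0.01, 2)
            reps.append((pep, pyr, oaa))
        res = solve_pep_ratio(None, None, None, replicates=reps)
        assert res.f1 == pytest.approx(0.6, abs=0.05)
        assert len(res.per_replicate) == 3
        assert np.isfinite(res.sd)

    def test_collinear_sources_rejected(self):
        oaa = make_positional(0.8, 0.2, 0.0)
        with pytest.raises(RatioError, match="indistinguishable"):
            solve_pep_ratio([0.8, 0.2], [0.8, 0.2], oaa)

    def test_invariant_to_replicate_reordering(self, rng):
        # the joint objective only sums squared residuals, so permuting the
        # replicate rows cannot move the estimate
        oaa = make_positional(0.5, 0.3, 0.2)
        reps = []
        for _ in range(3):
            pep = np.array([0.76, 0.24]) + rng.normal(0, 0.01, 2)
            pyr = np.array([0.8, 0.2]) + rng.normal(0, 0.01, 2)
            reps.append((pep, pyr, oaa))
        res = solve_pep_ratio(None, None, None, replicates=reps)
        res2 = solve_pep_ratio(None, None, None, replicates=reps[::-1])
        assert res2.f1 == pytest.approx(res.f1, abs=1e-14)

    def test_fractions_in_simplex_under_noise(self, rng):
        oaa = make_positional(0.5, 0.3, 0.2)
        for _ in range(50):
            pep = rng.uniform(0, 1, 2)
            pyr = rng.uniform(0, 1, 2)
            res = solve_pep_ratio(pep, pyr, oaa)
            assert 0.0 <= res.f1 <= 1.0
            assert res.f1 + res.f2 == pytest.approx(1.0)


class TestTwoSource:
    def test_target_equals_source(self):
        r = solve_two_source([0.1, 0.9], [0.1, 0.9], [0.7, 0.3])
        assert (r.f1, r.f2) == (pytest.approx(1.0), pytest.approx(0.0))

    def test_forward_mixture(self):
        a, b = np.array([0.1, 0.9]), np.array([0.7, 0.3])
        target = 0.4 * a + 0.6 * b
        r = solve_two_source(target, a, b)
        assert r.f1 == pytest.approx(0.400, abs=1e-9)
        assert r.f2 == pytest.approx(0.600, abs=1e-9)

    @pytest.mark.parametrize("f", np.round(np.arange(0, 1.01, 0.1), 1))
    def test_grid_round_trip(self, f, rng):
        a = rng.dirichlet(np.ones(4))
        b = rng.dirichlet(np.ones(4))
        target = f * a + (1 - f) * b
        r = solve_two_source(target, a, b)
        assert r.f1 == pytest.approx(f, abs=1e-8)

    def test_collinear_rejected(self):
        with pytest.raises(RatioError):
            solve_two_source([0.5, 0.5], [0.3, 0.7], [0.3, 0.7])

    def test_oaa_projection_onto_pyruvate_drops_position_4(self):
        pos = make_positional(0.55, 0.25, 0.20)
        proj = project_positional(pos, [1, 2, 3])
        # only the carbon-1 label survives the decarboxylation
        assert proj[1] == pytest.approx(0.25)
        assert proj[0] == pytest.approx(0.75)

    def test_fumarate_symmetry_forces_symmetric_signature(self):
        # positionally asymmetric OAA M+1 becomes orientation-averaged
        pos = make_positional(0.7, 0.3, 0.0)
        sym = symmetrize_positional(pos, 4)
        assert sym.groups[(1,)] == pytest.approx(0.15)
        assert sym.groups[(4,)] == pytest.approx(0.15)
        assert sym.m1 == pytest.approx(pos.m1)

    def test_mass_projection_hypergeometric(self):
        # dropping one of two exchangeable carbons halves the M+1 label
        proj = project_mid([0.6, 0.4], keep=[1], n_carbons=2)
        assert proj == pytest.approx([0.8, 0.2])


class TestKf1Pipeline:
    def test_citrate_fragments_recover_pep_source_split(self, kf1_scenario):
        # zero-noise pipeline on the shipped scenario: simulate citrate
        # fragments, infer OAA positional labeling through the citrate
        # synthase atom map, and solve the PEP partitioning
        sc = kf1_scenario
        tr = dict(sc.tracers["1-13C-4HB"])
        tr["CO2x"] = TracerSpec("CO2x", (sc.co2_purity,))
        targets = ["PEP", "PYR", "CIT",
                   EmuNode("CIT", (3, 4, 5, 6)), EmuNode("CIT", (5,)),
                   EmuNode("CIT", (6,))]
        sim = simulate_mids(sc.model, sc.true_fluxes, tr, targets)
        frags = [((3, 4, 5, 6), sim[EmuNode("CIT", (3, 4, 5, 6))]),
                 ((5,), sim[EmuNode("CIT", (5,))]),
                 ((6,), sim[EmuNode("CIT", (6,))])]
        pos_cit = infer_positional("CIT", sim["CIT"], frags)
        oaa = oaa_positional_from_citrate(sc.model, pos_cit)
        res = solve_pep_ratio(sim["PEP"], sim["PYR"], oaa)
        assert res.f1 == pytest.approx(sc.pep_source_split[0], abs=0.02)

    def test_fumarate_two_source_near_forty_percent_oaa(self, kf1_scenario):
        sc = kf1_scenario
        tr = dict(sc.tracers["1-13C-4HB"])
        tr["CO2x"] = TracerSpec("CO2x", (sc.co2_purity,))
        sim = simulate_mids(sc.model, sc.true_fluxes, tr,
                            ["FUM", "OAA", "SUC"])
        r = solve_two_source(sim["FUM"], sim["OAA"], sim["SUC"])
        assert 0.3 < r.f1 < 0.5


def test_underdetermined_fragment_system_raises():
    # fragments whose coverage patterns are distinct but linearly dependent
    # cannot pin a unique allocation and must refuse
    parent = [0.7, 0.3, 0, 0, 0, 0, 0]
    frags = []
    for subset in [(1, 2), (2, 3, 4), (4, 5), (1, 5, 6), (3, 6)]:
        frags.append((subset, [0.9, 0.1] + [0] * (len(subset) - 1)))
    with pytest.raises(RatioError, match="underdetermined"):
        infer_positional("X", parent, frags)
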