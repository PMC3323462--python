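"""Forward labeling simulation: EMU construction, solves, projections."""

import numpy as np
import pytest
from scipy.stats import binom

from mcmfa.fixtures import (brute_force_isotopomer_solve, default_fragments,
                            elementary, make_toy_network)
from mcmfa.isotopomer import (EMUNode, FragmentDefinition, SimulationError,
                              SubstrateMixture, build_emu_network, idv_to_mdv,
                              label_from_config, prune_zero_flux_components,
                              read_fragment_panel, simulate_cumomer,
                              simulate_emu, simulate_experiment_matrix,
                              simulate_fragments, source_metabolites,
                              write_fragment_panel)
from mcmfa.network import AtomMappedNetwork
from mcmfa.sampler import sample_flux_space


def _flux(net, assignments):
    v = np.zeros(len(net.reactions))
    for rid, x in assignments.items():
        v[net.reaction_ids.index(rid)] = x
    return v


class TestEMUConstruction:
    def test_chain_minimal_precursor_set(self):
        net = elementary("chain")  # A -> B -> C
        emu = build_emu_network(
            net, [FragmentDefinition("C12", "C", (1, 2))])
        got = {(n.metabolite, tuple(sorted(n.positions)))
               for n in emu.terms}
        assert got == {("A", (1, 2)), ("B", (1, 2)), ("C", (1, 2))}

    def test_condensation_feeds_by_convolution(self):
        net = elementary("condensation")  # A + B -> P
        emu = build_emu_network(
            net, [FragmentDefinition("P", "P", (1, 2, 3, 4))])
        node = EMUNode("P", frozenset({1, 2, 3, 4}))
        (j, srcs), = [t for t in emu.terms[node] if t[1] is not None]
        assert {(s.metabolite, tuple(sorted(s.positions))) for s in srcs} \
            == {("A", (1, 2)), ("B", (1, 2))}

    def test_node_count_bounded_by_isotopomer_count(self):
        for name in ("chain", "condensation", "ppp_branch"):
            net = elementary(name)
            emu = build_emu_network(net, default_fragments(net))
            per_met = {}
            for n in emu.nodes:
                per_met[n.metabolite] = per_met.get(n.metabolite, 0) + 1
            for met, count in per_met.items():
                assert count <= 2 ** net.metabolites[met].n_carbons

    def test_fragment_on_untracked_metabolite_raises(self):
        net = elementary("chain")
        with pytest.raises(SimulationError):
            build_emu_network(
                net, [FragmentDefinition("X", "nope", (1,))])


class TestSimulateEMU:
    def test_chain_single_label_passthrough(self):
        net = elementary("chain")
        label = SubstrateMixture({"A": [(0b1, 1.0)]}, natural_abundance_p=0.0)
        v = _flux(net, {"IN": 1, "R1": 1, "R2": 1, "OUT": 1})
        mdvs = simulate_fragments(net, v, label,
                                  [FragmentDefinition("C12", "C", (1, 2))])
        assert np.allclose(mdvs["C12"], [0, 1, 0], atol=1e-12)

    def test_self_condensation_is_self_convolution(self):
        net = elementary("self_condensation")
        label = SubstrateMixture({"A": [(0b11, 0.5), (0, 0.5)]},
                                 natural_abundance_p=0.0)
        v = _flux(net, {"AIN": 2, "C1": 1, "OUT": 1})
        frags = [FragmentDefinition("A", "A", (1, 2)),
                 FragmentDefinition("P", "P", (1, 2, 3, 4))]
        mdvs = simulate_fragments(net, v, label, frags)
        assert np.allclose(mdvs["A"], [0.5, 0, 0.5], atol=1e-12)
        assert np.allclose(mdvs["P"], [0.25, 0, 0.5, 0, 0.25], atol=1e-12)

    def test_unlabeled_input_gives_binomial_mdv(self):
        p = 0.011
        net = elementary("chain")
        label = SubstrateMixture({"A": [(0, 1.0)]}, natural_abundance_p=p)
        v = _flux(net, {"IN": 1, "R1": 1, "R2": 1, "OUT": 1})
        mdvs = simulate_fragments(net, v, label,
                                  [FragmentDefinition("C12", "C", (1, 2))])
        assert np.allclose(mdvs["C12"], binom.pmf([0, 1, 2], 2, p),
                           atol=1e-12)

    def test_flux_scaling_leaves_mdvs_unchanged(self, mixture_60_c1,
                                                any_flux):
        net = elementary("diamond")
        v = any_flux(net)
        label = mixture_60_c1(net)
        frags = default_fragments(net)
        m1 = simulate_fragments(net, v, label, frags)
        m2 = simulate_fragments(net, 3.7 * v, label, frags)
        for fid in m1:
            assert np.allclose(m1[fid], m2[fid], atol=1e-12)

    def test_relettering_atom_maps_is_invisible(self, mixture_60_c1,
                                                any_flux):
        net = elementary("ppp_branch")
        v = any_flux(net)
        rows = [("IN", "-> A", "-> xyz", 1, 1, ""),
                ("PPP", "A -> B", "xyz -> yz", 0, 10, ""),
                ("GLY", "A -> B", "qrs -> qr", 0, 10, ""),
                ("OUT", "B ->", "mn ->", 0, 10, "")]
        net2 = AtomMappedNetwork.from_rows(rows, id="ppp_relettered")
        label = mixture_60_c1(net)
        frags = [FragmentDefinition("B12", "B", (1, 2))]
        m1 = simulate_fragments(net, v, label, frags)
        m2 = simulate_fragments(net2, v, label, frags)
        assert np.allclose(m1["B12"], m2["B12"], atol=1e-12)


class TestCumomer:
    def test_one_carbon_fully_labeled(self):
        rows = [("IN", "-> A", "-> a", 0, 10, ""),
                ("R1", "A -> B", "a -> a", 0, 10, ""),
                ("OUT", "B ->", "a ->", 0, 10, "")]
        net = AtomMappedNetwork.from_rows(rows)
        label = SubstrateMixture({"A": [(0b1, 1.0)]}, natural_abundance_p=0.0)
        idvs = simulate_cumomer(net, np.array([1.0, 1.0, 1.0]), label)
        assert np.allclose(idvs["B"], [0, 1], atol=1e-12)

    @pytest.mark.parametrize("name", ["chain", "diamond", "reversible_loop",
                                      "condensation", "ppp_branch"])
    def test_cumomer_equals_emu(self, name, mixture_60_c1, any_flux):
        net = elementary(name)
        v = any_flux(net)
        label = mixture_60_c1(net)
        frags = default_fragments(net)
        mdv_emu = simulate_fragments(net, v, label, frags)
        idvs = simulate_cumomer(net, v, label)
        for f in frags:
            if f.metabolite not in idvs:
                continue
            got = idv_to_mdv(idvs[f.metabolite], f.carbons)
            assert np.abs(got - mdv_emu[f.id]).max() <= 1e-8


class TestPruning:
    def test_zero_flux_arm_pruned_and_rest_unchanged(self, mixture_60_c1):
        net = elementary("diamond")
        v_on = _flux(net, {"IN": 1, "R1": 0.5, "R2": 0.5, "R3": 0.5,
                           "R4": 0.5, "OUT": 1})
        v_off = _flux(net, {"IN": 1, "R1": 1.0, "R3": 1.0, "OUT": 1})
        active, _, report = prune_zero_flux_components(net, v_off)
        assert report["pruned_metabolites"] == ["C"]
        label = mixture_60_c1(net)
        frag = [FragmentDefinition("D", "D", (1, 2))]
        mdv = simulate_fragments(net, v_off, label, frag)["D"]
        # all flux through branch 1: D reproduces the input distribution
        expected = label.emu_mdv("A", frozenset({1, 2}), 2)
        assert np.allclose(mdv, expected, atol=1e-10)

    def test_fully_active_network_prunes_nothing(self, any_flux):
        net = elementary("diamond")
        v = any_flux(net)
        _, _, report = prune_zero_flux_components(net, v)
        assert report["pruned_metabolites"] == []

    def test_no_singular_failures_over_sampled_fluxes(self, mixture_60_c1):
        net = elementary("diamond")
        label = mixture_60_c1(net)
        frags = [FragmentDefinition("D", "D", (1, 2))]
        emu = build_emu_network(net, frags)
        rng = np.random.default_rng(0)
        s = sample_flux_space(net, n_points=100, n_steps=20, seed=9)
        for i in range(s.n_points):
            v = s.points[i].copy()
            if rng.random() < 0.5:  # kill one arm, reroute through the other
                split = v[net.reaction_ids.index("R1")] \
                    + v[net.reaction_ids.index("R2")]
                for rid in ("R2", "R4"):
                    v[net.reaction_ids.index(rid)] = 0.0
                for rid in ("R1", "R3"):
                    v[net.reaction_ids.index(rid)] = split
            mdv = simulate_emu(emu, v, label)["D"]
            assert np.isfinite(mdv).all()


class TestIdvToMdv:
    def test_fully_labeled_two_carbons(self):
        assert np.allclose(idv_to_mdv(np.array([0, 0, 0, 1.0]), (1, 2)),
                           [0, 0, 1])

    def test_uniform_idv_single_carbon_projection(self):
        idv = np.full(4, 0.25)
        assert np.allclose(idv_to_mdv(idv, (1,)), [0.5, 0.5])

    def test_projection_conserves_mass(self):
        rng = np.random.default_rng(1)
        idv = rng.dirichlet(np.ones(8))
        for carbons in [(1,), (2, 3), (1, 2, 3)]:
            assert idv_to_mdv(idv, carbons).sum() == pytest.approx(1.0)


class TestExperimentMatrix:
    def test_shape_and_column_sums(self, mixture_60_c1):
        net = elementary("chain")
        s = sample_flux_space(net, n_points=5, n_steps=10, seed=2)
        label = mixture_60_c1(net)
        M, rows, statuses = simulate_experiment_matrix(
            s, label, [FragmentDefinition("C12", "C", (1, 2))], net)
        assert M.shape == (3, 5)
        assert rows == [("C12", 0), ("C12", 1), ("C12", 2)]
        assert np.allclose(M.sum(axis=0), 1.0)
        assert statuses == [None] * 5

    def test_identical_fluxes_identical_columns(self, mixture_60_c1):
        from mcmfa.sampler import FluxSampleSet

        net = elementary("chain")
        v = _flux(net, {"IN": 1, "R1": 1, "R2": 1, "OUT": 1})
        s = FluxSampleSet(np.tile(v, (4, 1)), net.reaction_ids, 0, 0)
        label = mixture_60_c1(net)
        M, _, _ = simulate_experiment_matrix(
            s, label, [FragmentDefinition("C12", "C", (1, 2))], net)
        assert np.all(M == M[:, [0]])

    def test_bitwise_deterministic(self, mixture_60_c1):
        net = elementary("diamond")
        s = sample_flux_space(net, n_points=6, n_steps=10, seed=8)
        label = mixture_60_c1(net)
        frags = default_fragments(net)
        M1, _, _ = simulate_experiment_matrix(s, label, frags, net)
        M2, _, _ = simulate_experiment_matrix(s, label, frags, net)
        assert np.array_equal(M1, M2)


def test_fragment_panel_round_trip(tmp_path):
    frags = [FragmentDefinition("f1", "ala", (2, 3), {"C": 4, "Si": 1}),
             FragmentDefinition("f2", "gly", (1, 2))]
    p = tmp_path / "panel.csv"
    write_fragment_panel(frags, p)
    back = read_fragment_panel(p)
    assert [(f.id, f.metabolite, f.carbons) for f in back] \
        == [("f1", "ala", (2, 3)), ("f2", "gly", (1, 2))]
    assert back[0].composition["C"] == 4 and back[0].composition["Si"] == 1


def test_label_from_config_builds_bitmasks():
    label = label_from_config(
        [{"metabolite": "glc",
          "patterns": [{"positions": [1, 2], "fraction": 0.3},
                       {"positions": [], "fraction": 0.7}]}])
    assert label.patterns["glc"] == [(0b11, 0.3), (0, 0.7)]


def test_mixture_fractions_must_sum_to_one():
    with pytest.raises(ValueError):
        SubstrateMixture({"glc": [(1, 0.5), (0, 0.6)]})
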