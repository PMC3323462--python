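"""Network parsing, validation, null space, blocked reactions, FVA."""

from fractions import Fraction
from itertools import combinations

import numpy as np
import pytest

from mcmfa.network import (AtomMappedNetwork, InfeasibleError, NetworkError,
                           Reaction, compute_null_space, decompose_reversible,
                           effective_null_space, find_blocked_reactions,
                           flux_variability, load_network,
                           parse_carbon_transition, write_network)
from mcmfa.fixtures import TOPOLOGIES, make_toy_network

TOY_TSV = """\
reaction_id\tequation\tcarbon_transition\tlower\tupper\tsubsystem
A_in\t-> A\t-> ab\t0\t10\texchange
R1\tA -> B\tab -> ab\t0\t10\tcore
B_out\tB ->\t\t0\t10\texchange
"""


def test_load_toy_network_counts(tmp_path):
    p = tmp_path / "toy.tsv"
    p.write_text(TOY_TSV)
    net = load_network(p)
    assert len(net.reactions) == 3
    assert sum(r.tracks_carbon for r in net.reactions) == 2
    s = net.summary()
    assert s["n_tracked_metabolites"] == 2
    assert s["n_isotopomer_variables"] == 2 ** 2 + 2 ** 2


@pytest.mark.parametrize("name", TOPOLOGIES)
def test_round_trip_exact(tmp_path, name):
    net = make_toy_network(name)
    p = tmp_path / "net.tsv"
    write_network(net, p)
    net2 = load_network(p)
    assert net2.reaction_ids == net.reaction_ids
    for r1, r2 in zip(net.reactions, net2.reactions):
        assert r1.stoichiometry == r2.stoichiometry
        assert (r1.lower_bound, r1.upper_bound) == (r2.lower_bound,
                                                    r2.upper_bound)
        if r1.atom_map is None:
            assert r2.atom_map is None
        else:
            assert r1.atom_map.substrates == r2.atom_map.substrates
            assert r1.atom_map.products == r2.atom_map.products
            assert r1.atom_map.lost == r2.atom_map.lost


@pytest.mark.parametrize("name", TOPOLOGIES)
def test_carbon_conservation_every_mapped_reaction(name):
    net = make_toy_network(name)
    for r in net.reactions:
        if r.atom_map is None:
            continue
        n_in = sum(len(g) for _, g in r.atom_map.substrates)
        n_out = sum(len(g) for _, g in r.atom_map.products)
        if n_in:  # boundary inputs feed carbon from outside
            assert n_in == n_out + len(r.atom_map.lost)


@pytest.mark.parametrize("bad", [
    ("R", "A -> B", "ab -> abc"),        # carbon count inflated
    ("R", "A -> B", "ab -> cd"),         # product letters without source
    ("R", "A -> B", "aa -> aa"),         # duplicate letters on one side
    ("R", "A + B -> C", "ab -> ab"),     # group/instance misalignment
    ("R", "A -> B", "aB -> aB"),         # uppercase letters
])
def test_malformed_transitions_raise(bad):
    rid, eq, trans = bad
    with pytest.raises(NetworkError):
        AtomMappedNetwork.from_rows([(rid, eq, trans, 0, 10, "")])


def test_duplicate_reaction_ids_raise():
    rows = [("R1", "-> A", "-> ab", 0, 10, ""),
            ("R1", "A ->", "ab ->", 0, 10, "")]
    with pytest.raises(NetworkError):
        AtomMappedNetwork.from_rows(rows)


def test_carbon_count_mismatch_across_reactions_raises():
    rows = [("R1", "-> A", "-> ab", 0, 10, ""),
            ("R2", "A -> B", "abc -> abc", 0, 10, "")]
    with pytest.raises(NetworkError):
        AtomMappedNetwork.from_rows(rows)


class TestDecomposeReversible:
    def test_reaction_count(self):
        net = make_toy_network("reversible_loop")  # 1 reversible + 3 irrev
        elem = decompose_reversible(net)
        assert len(elem.reactions) == len(net.reactions) + 1
        assert all(r.lower_bound >= 0 for r in elem.reactions)

    def test_mirrored_atom_map(self):
        net = make_toy_network("reversible_loop")
        elem = decompose_reversible(net)
        fwd = elem.reaction("R1_f")
        rev = elem.reaction("R1_b")
        assert rev.atom_map.substrates == fwd.atom_map.products
        assert rev.atom_map.products == fwd.atom_map.substrates

    def test_net_flux_recovered(self):
        net = make_toy_network("reversible_loop")
        elem = decompose_reversible(net)
        v = np.zeros(len(elem.reactions))
        ids = elem.reaction_ids
        v[ids.index("R1_f")] = 3.0
        v[ids.index("R1_b")] = 1.0
        assert elem.net_fluxes(v)["R1"] == pytest.approx(2.0)


def _rref_rank(S):
    """Independent rank oracle: exact Gaussian elimination over rationals."""
    rows = [[Fraction(x).limit_denominator(10**6) for x in row] for row in S]
    rank, ncols = 0, len(rows[0]) if rows else 0
    for col in range(ncols):
        piv = next((i for i in range(rank, len(rows)) if rows[i][col] != 0),
                   None)
        if piv is None:
            continue
        rows[rank], rows[piv] = rows[piv], rows[rank]
        pr = rows[rank]
        for i in range(len(rows)):
            if i != rank and rows[i][col] != 0:
                f = rows[i][col] / pr[col]
                rows[i] = [a - f * b for a, b in zip(rows[i], pr)]
        rank += 1
    return rank


class TestNullSpace:
    def test_single_metabolite_in_out(self):
        net = AtomMappedNetwork.from_rows(
            [("IN", "-> A", "", 0, 10, ""), ("OUT", "A ->", "", 0, 10, "")])
        basis = compute_null_space(net)
        assert basis.dof == 1
        assert np.allclose(np.abs(basis.N.ravel()), 1 / np.sqrt(2))

    @pytest.mark.parametrize("name", TOPOLOGIES)
    def test_dof_matches_rational_rank_oracle(self, name):
        net = make_toy_network(name)
        basis = compute_null_space(net)
        S = net.stoichiometric_matrix()
        assert basis.dof == len(net.reactions) - _rref_rank(S)

    @pytest.mark.parametrize("name", TOPOLOGIES)
    def test_basis_orthonormal_and_in_kernel(self, name):
        net = make_toy_network(name)
        basis = compute_null_space(net)
        S = net.stoichiometric_matrix()
        if basis.dof:
            assert np.abs(S @ basis.N).max() <= 1e-9
            assert np.allclose(basis.N.T @ basis.N, np.eye(basis.dof),
                               atol=1e-12)

    def test_effective_null_space_respects_fixed_bounds(self):
        net = make_toy_network("ppp_branch")  # IN fixed at 1
        eff = effective_null_space(net)
        assert eff.dof == compute_null_space(net).dof - 1
        j = net.reaction_ids.index("IN")
        assert np.abs(eff.N[j]).max() <= 1e-9


def _vertices(A, b):
    """Brute-force vertex enumeration of {x : A x <= b} (tiny dims only)."""
    n = A.shape[1]
    verts = []
    for rows in combinations(range(A.shape[0]), n):
        sub = A[list(rows)]
        if abs(np.linalg.det(sub)) < 1e-10:
            continue
        x = np.linalg.solve(sub, b[list(rows)])
        if (A @ x <= b + 1e-8).all():
            verts.append(x)
    return np.array(verts)


class TestBlockedAndFVA:
    def test_dead_end_metabolite_blocked(self):
        rows = [("IN", "-> A", "", 0, 10, ""), ("OUT", "A ->", "", 0, 10, ""),
                ("DEAD", "A -> X", "", 0, 10, "")]  # X has no consumer
        net = AtomMappedNetwork.from_rows(rows)
        assert find_blocked_reactions(net) == {"DEAD"}

    def test_linear_chain_unblocked(self):
        net = make_toy_network("chain")
        assert find_blocked_reactions(net) == set()

    def test_blocked_set_matches_vertex_enumeration_oracle(self):
        # cycle A -> B -> A cut by a zero upper bound on the return step
        rows = [("IN", "-> A", "", 0, 4, ""),
                ("R1", "A -> B", "", 0, 4, ""),
                ("R2", "B -> A", "", 0, 0, ""),
                ("OUT", "B ->", "", 0, 4, "")]
        net = AtomMappedNetwork.from_rows(rows)
        blocked = find_blocked_reactions(net)

        basis = compute_null_space(net)
        lb, ub = net.bounds()
        from mcmfa.network import _solve_lp
        v0 = _solve_lp(np.zeros(4), net.stoichiometric_matrix(), lb, ub).x
        A = np.vstack([basis.N, -basis.N])
        b = np.concatenate([ub - v0, v0 - lb])
        verts = _vertices(A, b)
        V = v0 + verts @ basis.N.T  # all polytope vertices in flux space
        oracle = {rid for j, rid in enumerate(net.reaction_ids)
                  if np.abs(V[:, j]).max() < 1e-8}
        assert blocked == oracle == {"R2"}

    def test_fva_blocked_reactions_are_pointlike(self):
        rows = [("IN", "-> A", "", 0, 10, ""), ("OUT", "A ->", "", 0, 10, ""),
                ("DEAD", "A -> X", "", 0, 10, "")]
        net = AtomMappedNetwork.from_rows(rows)
        lo, hi = flux_variability(net)["DEAD"]
        assert lo == pytest.approx(0.0, abs=1e-9)
        assert hi == pytest.approx(0.0, abs=1e-9)

    def test_fva_fixed_uptake_chain(self):
        net = make_toy_network("chain")
        fva = flux_variability(net, extra_constraints={"IN": (1.0, 1.0)})
        for rid, (lo, hi) in fva.items():
            assert lo == pytest.approx(1.0, abs=1e-7)
            assert hi == pytest.approx(1.0, abs=1e-7)

    def test_fva_diamond_branches_match_vertex_oracle(self):
        net = make_toy_network("diamond")  # input fixed at 1
        fva = flux_variability(net)
        for rid in ("R1", "R2", "R3", "R4"):
            assert fva[rid][0] == pytest.approx(0.0, abs=1e-7)
            assert fva[rid][1] == pytest.approx(1.0, abs=1e-7)
        # zero-width range flags constraint-determined reactions
        assert fva["IN"][1] - fva["IN"][0] == pytest.approx(0.0, abs=1e-9)

    def test_infeasible_bounds_raise(self):
        rows = [("IN", "-> A", "", 0, 1, ""), ("OUT", "A ->", "", 5, 10, "")]
        net = AtomMappedNetwork.from_rows(rows)
        with pytest.raises(InfeasibleError):
            flux_variability(net)


def test_parse_transition_records_lost_carbons():
    t = parse_carbon_transition("A -> B", "abc -> bc")
    assert t.lost == "a"
    assert t.products == [("B", "bc")]


def test_mirroring_carbon_losing_map_raises():
    t = parse_carbon_transition("A -> B", "abc -> bc")
    with pytest.raises(NetworkError):
        t.mirrored()
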