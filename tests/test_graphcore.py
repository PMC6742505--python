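"""Flow-network engine: elementary-graph construction, exact max-flow MAP
solves and constrained min-marginal re-solves, all checked against
exhaustive enumeration and an independent max-flow implementation."""

import numpy as np
import pytest
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_flow as scipy_maximum_flow

from epiunwarp.graphcore import (
    FlowNetwork,
    PairwiseTerm,
    SubmodularityError,
    elementary_graph,
    max_flow,
    solve_constrained,
)
from tests.conftest import build_network, mrf_energy_table, random_submodular_mrf


class TestElementaryGraph:
    def test_ising_term_reproduced_by_enumeration(self):
        term = PairwiseTerm(0, 1, 1, 0)
        inc = elementary_graph(term, 0, 1)
        assert inc["cap_ij"] == 2.0
        net = FlowNetwork(2)
        net.add_pairwise(0, 1, term)
        energies = {(0, 1): term.e01, (1, 0): term.e10, (1, 1): term.e11}
        # free assignment: solve unconstrained (0,0) and constrained others
        assert net.min_energy == 0.0
        for (xi, xj), expected in energies.items():
            # constrain both nodes via a second network with huge unaries
            n2 = FlowNetwork(2)
            n2.add_pairwise(0, 1, term)
            n2.add_unary(0, 1e3 * xi, 1e3 * (1 - xi))
            n2.add_unary(1, 1e3 * xj, 1e3 * (1 - xj))
            assert n2.min_energy == pytest.approx(expected, abs=1e-9)

    def test_null_term_contributes_nothing(self):
        inc = elementary_graph(PairwiseTerm(0, 0, 0, 0), 0, 1)
        assert inc["offset"] == inc["unary1_i"] == inc["unary1_j"] == inc["cap_ij"] == 0.0

    def test_constant_term_absorbed_into_offset(self):
        net = FlowNetwork(2)
        net.add_pairwise(0, 1, PairwiseTerm(5, 5, 5, 5))
        assert net.constant_offset == 5.0
        assert net.solve().flow_value == 0.0

    def test_non_submodular_term_rejected_with_margin(self):
        with pytest.raises(SubmodularityError) as err:
            elementary_graph(PairwiseTerm(3, 0, 0, 2), 0, 1)
        assert err.value.margin == pytest.approx(5.0)


class TestMaxFlow:
    def test_single_node_takes_cheaper_terminal(self):
        net = FlowNetwork(1)
        net.add_terminal_caps(0, 3.0, 5.0)
        res = max_flow(net)
        assert res.flow_value == 3.0
        assert res.labels[0] == 1  # sink side

    def test_two_node_bridge(self):
        net = FlowNetwork(2)
        net.add_terminal_caps(0, 2.0, 0.0)
        net.add_terminal_caps(1, 0.0, 2.0)
        net.add_edge(0, 1, 1.0, 1.0)
        # cuts: (0,0)->2, (1,1)->2, (0,1)->1, (1,0)->5; minimum is 1
        assert max_flow(net).flow_value == 1.0

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            max_flow(FlowNetwork(0))

    def test_oracle_equivalence_on_random_mrfs(self):
        """Graph-cut energy equals exhaustive-enumeration minimum and the
        returned labels realise it, on random submodular MRFs."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            n, unary, pairs = random_submodular_mrf(rng, n_max=10)
            net = build_network(n, unary, pairs)
            labels_all, energies = mrf_energy_table(n, unary, pairs)
            res = net.solve()
            assert res.flow_value + net.constant_offset == energies.min()
            realised = energies[int(np.dot(res.labels, 2 ** np.arange(n)))]
            assert realised == energies.min()

    def test_agrees_with_scipy_maximum_flow(self):
        """Independent cross-check: the same capacitated graph solved by
        scipy's max-flow gives the same cut value."""
        rng = np.random.default_rng(7)
        for _ in range(25):
            n, unary, pairs = random_submodular_mrf(rng, n_max=9)
            net = build_network(n, unary, pairs)
            ours = net.solve().flow_value
            # explicit graph with terminals s=n, t=n+1, integer capacities
            scale = 2**16
            rows, cols, caps = [], [], []
            for i in range(n):
                e0, e1 = unary[i]
                m = min(e0, e1)
                rows += [n, i]
                cols += [i, n + 1]
                caps += [int((e1 - m) * scale), int((e0 - m) * scale)]
            for i, j, e in pairs:
                inc = elementary_graph(PairwiseTerm(*e), i, j)
                for node, c1 in ((i, inc["unary1_i"]), (j, inc["unary1_j"])):
                    if c1 >= 0:
                        rows.append(n)
                        cols.append(node)
                        caps.append(int(c1 * scale))
                    else:
                        rows.append(node)
                        cols.append(n + 1)
                        caps.append(int(-c1 * scale))
                rows.append(i)
                cols.append(j)
                caps.append(int(inc["cap_ij"] * scale))
            g = csr_matrix((caps, (rows, cols)), shape=(n + 2, n + 2), dtype=np.int64)
            flow = scipy_maximum_flow(g, n, n + 1).flow_value
            assert flow / scale == pytest.approx(ours, abs=1e-9)

    def test_energy_invariant_to_insertion_order(self):
        rng = np.random.default_rng(3)
        n, unary, pairs = random_submodular_mrf(rng, n_max=8)
        net1 = build_network(n, unary, pairs)
        net2 = FlowNetwork(n)
        for i in range(n - 1, -1, -1):
            net2.add_unary(i, unary[i, 0], unary[i, 1])
        for i, j, e in reversed(pairs):
            net2.add_pairwise(i, j, PairwiseTerm(*e))
        assert net1.min_energy == net2.min_energy


class TestSolveConstrained:
    def test_map_label_constraint_is_free(self):
        rng = np.random.default_rng(5)
        n, unary, pairs = random_submodular_mrf(rng)
        net = build_network(n, unary, pairs)
        res = net.solve()
        emin = res.flow_value + net.constant_offset
        for v in range(n):
            assert solve_constrained(net, v, int(res.labels[v])) == emin

    def test_two_node_toy_matches_enumeration(self):
        net = FlowNetwork(2)
        net.add_terminal_caps(0, 2.0, 0.0)
        net.add_terminal_caps(1, 0.0, 2.0)
        net.add_edge(0, 1, 1.0, 1.0)
        oracle = {  # cut costs enumerated in TestMaxFlow.test_two_node_bridge
            (0, 0): 2.0, (0, 1): 1.0, (1, 0): 5.0, (1, 1): 2.0,
        }
        for v in (0, 1):
            for lab in (0, 1):
                expected = min(c for (x0, x1), c in oracle.items() if (x0, x1)[v] == lab)
                assert solve_constrained(net, v, lab) == expected

    def test_reuse_and_cold_paths_identical(self):
        """Residual-reuse re-solves must be value-identical to cold
        re-solves on random 8-node networks."""
        rng = np.random.default_rng(11)
        for _ in range(100):
            n, unary, pairs = random_submodular_mrf(rng, n_max=8)
            net = build_network(n, unary, pairs)
            net.solve()
            for v in range(n):
                for lab in (0, 1):
                    warm = net.solve_constrained(v, lab, reuse=True)
                    cold = net.solve_constrained(v, lab, reuse=False)
                    assert warm == cold

    def test_min_marginals_bound_below_by_minimum(self):
        rng = np.random.default_rng(13)
        n, unary, pairs = random_submodular_mrf(rng)
        net = build_network(n, unary, pairs)
        emin = net.min_energy
        psi0, psi1 = net.min_marginals()
        assert np.all(psi0 >= emin - 1e-12) and np.all(psi1 >= emin - 1e-12)
        assert np.allclose(np.minimum(psi0, psi1), emin)

    def test_invalid_node_index(self):
        net = FlowNetwork(2)
        net.add_terminal_caps(0, 1.0, 0.0)
        with pytest.raises(IndexError):
            solve_constrained(net, 5, 0)
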