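"""Provesti/event distances and minimum-spanning-network construction."""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from amplityper.catalog import define_types
from amplityper.network import (DistanceMatrix, EventDistance, build_msn,
                                event_distance, export_network,
                                pairwise_matrix, primary_tree,
                                provesti_distance)
from amplityper.variants import CondensedMatrix, MatrixColumn


def brute_force_provesti(a, b):
    compared = mismatch = 0
    for x, y in zip(a, b):
        if x in ("N", "?") or y in ("N", "?"):
            continue
        compared += 1
        mismatch += x != y
    return mismatch / compared


state = st.sampled_from("ACGT-RY")
vectors = st.integers(4, 12).flatmap(
    lambda n: st.tuples(*[st.tuples(*[state] * n)] * 3))


class TestProvesti:
    def test_identical_vectors_zero(self):
        assert provesti_distance("ACGT", "ACGT") == 0.0

    def test_all_different_vectors_one(self):
        assert provesti_distance("ACGT", "TGCA") == 1.0

    def test_published_its_a_vs_b(self, its_catalog):
        a = its_catalog.types["A"].states
        b = its_catalog.types["B"].states
        assert provesti_distance(a, b) == pytest.approx(2 / 26)

    def test_missing_data_dropped_from_denominator(self):
        assert provesti_distance("ANGT", "ACGA") == pytest.approx(1 / 3)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            provesti_distance("ACG", "ACGT")

    def test_overlap_mode_matches_covering_ambiguity(self):
        assert provesti_distance("R", "A", mode="overlap") == 0.0
        assert provesti_distance("R", "A") == 1.0

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(vectors)
    def test_metric_axioms_and_oracle_equality(self, triple):
        a, b, c = triple
        dab = provesti_distance(a, b)
        assert dab == brute_force_provesti(a, b)
        assert provesti_distance(a, a) == 0.0
        assert dab == provesti_distance(b, a)
        assert dab <= provesti_distance(a, c) + provesti_distance(c, b) + 1e-12


class TestEventDistance:
    def rep(self, fixture):
        full = fixture.condensed(exclude_homopolymer=False)
        rep = {}
        for sid, states in full.rows.items():
            rep.setdefault(sid.split("-")[1], states)
        return rep, full

    def test_published_trnl_a_to_c(self, trnl):
        rep, full = self.rep(trnl)
        d = event_distance(rep["A"], rep["C"], full)
        assert (d.substitutions, d.homopolymer_attached) == (5, 1)

    def test_published_trnl_d_to_e(self, trnl):
        rep, full = self.rep(trnl)
        d = event_distance(rep["D"], rep["E"], full)
        assert (d.substitutions, d.homopolymer_attached) == (1, 1)

    def test_published_rpl32_a_to_d(self, rpl32):
        rep, full = self.rep(rpl32)
        d = event_distance(rep["A"], rep["D"], full)
        assert (d.substitutions, d.indel_events) == (3, 0)

    def test_invariant_under_column_reordering(self, trnl):
        rep, full = self.rep(trnl)
        perm = list(reversed(range(len(full.columns))))
        shuffled = CondensedMatrix(
            columns=[full.columns[i] for i in perm],
            rows={k: tuple(v[i] for i in perm) for k, v in full.rows.items()},
            excluded_columns=full.excluded_columns, species=full.species)
        a, b = rep["A"], rep["D"]
        d1 = event_distance(a, b, full)
        d2 = event_distance(tuple(a[i] for i in perm),
                            tuple(b[i] for i in perm), shuffled)
        assert d1 == d2

    def test_total_is_sum_of_components(self):
        d = EventDistance(substitutions=3, indel_events=2,
                          homopolymer_attached=1)
        assert d.total == 5


class TestPairwiseMatrix:
    def test_two_types(self):
        cols = [MatrixColumn(label="1", kind="substitution", consensus_state="A")]
        m = CondensedMatrix(columns=cols, rows={"x": ("A",), "y": ("T",)},
                            excluded_columns=frozenset())
        cat = define_types(m)
        d = pairwise_matrix(cat, metric="provesti")
        assert d.values[0, 1] == 1.0 and d.values[1, 0] == 1.0

    def test_rpl32_most_distant_pair_involves_d(self, rpl32_catalog):
        d = pairwise_matrix(rpl32_catalog, metric="events_total")
        i, j = np.unravel_index(np.argmax(d.values), d.values.shape)
        pair = {d.labels[i], d.labels[j]}
        assert "D" in pair and pair <= {"B", "C", "D"}

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(labels=["a", "b"],
                           values=np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestBuildMsn:
    def test_three_equidistant_nodes_two_primary_one_alternative(self):
        d = DistanceMatrix(labels=["x", "y", "z"],
                           values=np.array([[0., 1., 1.],
                                            [1., 0., 1.],
                                            [1., 1., 0.]]))
        net = build_msn(d)
        alts = [e for e in net.edges(data=True) if e[2]["alternative"]]
        prims = [e for e in net.edges(data=True) if not e[2]["alternative"]]
        assert len(prims) == 2 and len(alts) == 1

    def test_unique_mst_has_no_alternatives(self):
        d = DistanceMatrix(labels=["1", "2", "3"],
                           values=np.array([[0., 1., 2.],
                                            [1., 0., 1.],
                                            [2., 1., 0.]]))
        net = build_msn(d)
        assert {tuple(sorted(e)) for e in net.edges()} == {("1", "2"), ("2", "3")}
        assert all(not a["alternative"] for _, _, a in net.edges(data=True))

    def test_node_sizes_attached(self):
        d = DistanceMatrix(labels=["a", "b"], values=np.array([[0., 2.],
                                                               [2., 0.]]))
        net = build_msn(d, sizes={"a": 7, "b": 3})
        assert net.nodes["a"]["size"] == 7

    def test_disconnected_matrix_warns_and_splits(self):
        inf = np.inf
        d = DistanceMatrix(labels=["a", "b", "c", "d"],
                           values=np.array([[0., 1., inf, inf],
                                            [1., 0., inf, inf],
                                            [inf, inf, 0., 1.],
                                            [inf, inf, 1., 0.]]))
        with pytest.warns(UserWarning, match="disconnected"):
            net = build_msn(d)
        assert nx.number_connected_components(net) == 2

    def test_primary_weight_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(40):
            n = int(rng.integers(3, 7))
            vals = np.triu(rng.integers(1, 5, size=(n, n)).astype(float), 1)
            vals = vals + vals.T
            labels = [f"n{i}" for i in range(n)]
            net = build_msn(DistanceMatrix(labels=labels, values=vals))
            tree = primary_tree(net)
            w = sum(a["weight"] for _, _, a in tree.edges(data=True))
            best = min(
                sum(vals[labels.index(a), labels.index(b)] for a, b in combo)
                for combo in itertools.combinations(
                    itertools.combinations(labels, 2), n - 1)
                if nx.is_connected(nx.Graph(list(combo) + [(l, l) for l in labels]))
            )
            assert w == best


class TestExport:
    def test_graphml_round_trip_preserves_attributes(self, tmp_path):
        d = DistanceMatrix(labels=["x", "y", "z"],
                           values=np.array([[0., 1., 1.],
                                            [1., 0., 1.],
                                            [1., 1., 0.]]))
        net = build_msn(d, sizes={"x": 5, "y": 2, "z": 1})
        path = export_network(net, tmp_path / "net.graphml", format="graphml")
        back = nx.read_graphml(path)
        assert back.number_of_edges() == net.number_of_edges()
        assert int(back.nodes["x"]["size"]) == 5
        alts = [a["alternative"] for _, _, a in back.edges(data=True)]
        assert sum(map(bool, alts)) == 1

    def test_dot_marks_alternatives(self, tmp_path):
        d = DistanceMatrix(labels=["x", "y", "z"],
                           values=np.ones((3, 3)) - np.eye(3))
        net = build_msn(d)
        path = export_network(net, tmp_path / "net.dot", format="dot")
        text = path.read_text()
        assert 'alternative="true"' in text and "--" in text

    def test_unknown_format_rejected(self, tmp_path):
        net = nx.Graph()
        with pytest.raises(ValueError):
            export_network(net, tmp_path / "x", format="svg")
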