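"""Polarity prediction: categories, signed nets, edge signs, exports."""

import numpy as np
import pandas as pd
import pytest

import chansyn as cs
from chansyn.polarity import CATEGORIES


def expr_matrix(rows: dict, genes: list) -> cs.ExpressionMatrix:
    return cs.ExpressionMatrix(
        data=pd.DataFrame(rows, index=genes).T.astype(float)
    )


@pytest.fixture(scope="module")
def cat():
    return cs.synthetic_catalog()


ACH_EXC, ACH_INH = "syn-ACh-c", "syn-ACh-a"


class TestClassifyReceptors:
    def test_all_zero_row_is_none(self, cat):
        row = {ACH_EXC: 0.0, ACH_INH: 0.0}
        assert cs.classify_receptors(row, cat, "ACh") == "none"

    @pytest.mark.parametrize(
        "exc,inh,expected",
        [
            (5.0, 2.0, "both"),
            (5.0, 0.0, "excitatory_only"),
            (0.0, 2.0, "inhibitory_only"),
            (0.0, 0.0, "none"),
        ],
    )
    def test_four_membership_outcomes(self, cat, exc, inh, expected):
        assert cs.classify_receptors({ACH_EXC: exc, ACH_INH: inh}, cat, "ACh") == expected

    def test_removing_cationic_gene_flips_both_to_inhibitory(self, cat):
        row = {ACH_EXC: 3.0, ACH_INH: 2.0}
        assert cs.classify_receptors(row, cat, "ACh") == "both"
        row[ACH_EXC] = 0.0
        assert cs.classify_receptors(row, cat, "ACh") == "inhibitory_only"

    def test_unknown_transmitter_errors(self, cat):
        with pytest.raises(ValueError, match="transmitter"):
            cs.classify_receptors({ACH_EXC: 1.0}, cat, "adrenaline")

    def test_unknown_selectivity_gene_skipped(self):
        c = cs.synthetic_catalog()
        from chansyn.catalog import ChannelRecord

        c.add(ChannelRecord("myst-1", "ACC", frozenset({"ACh"}), "unknown", "measured"))
        assert cs.classify_receptors({"myst-1": 50.0}, c, "ACh") == "none"


class TestNetPolarity:
    def test_sums_net_and_ratio(self, cat):
        s = cs.net_polarity({ACH_EXC: 5.0, ACH_INH: 2.0}, cat, "ACh", cls="X")
        assert (s.sum_exc, s.sum_inh) == (5.0, 2.0)
        assert s.net == pytest.approx(3.0)
        assert s.ratio == pytest.approx(2.5)
        assert s.category == "both"

    def test_equal_sums_net_zero(self, cat):
        s = cs.net_polarity({ACH_EXC: 4.0, ACH_INH: 4.0}, cat, "ACh")
        assert s.net == 0.0 and s.ratio == pytest.approx(1.0)

    def test_one_sided_ratio_is_infinite_sentinel(self, cat):
        s = cs.net_polarity({ACH_EXC: 4.0}, cat, "ACh")
        assert np.isinf(s.ratio)

    def test_empty_complement_ratio_undefined(self, cat):
        s = cs.net_polarity({ACH_EXC: 0.0}, cat, "ACh")
        assert np.isnan(s.ratio) and s.category == "none"


def toy_connectome(edges, transmitters, gaps=()):
    return cs.Connectome(
        chemical_edges=[cs.ChemicalEdge(*e) for e in edges],
        gap_junctions=[cs.GapJunction(*g) for g in gaps],
        transmitters={k: tuple(v) for k, v in transmitters.items()},
    )


class TestPredictEdgeSigns:
    def test_single_receptor_inhibitory_edge(self, cat):
        conn = toy_connectome([("A", "B", 3)], {"A": ["ACh"], "B": ["GABA"]})
        expr = expr_matrix({"A": [0, 0], "B": [0, 4.0]}, [ACH_EXC, ACH_INH])
        signed = cs.predict_edge_signs(conn, expr, cat)
        (edge,) = signed.edges
        assert edge.sign == "inhibitory" and edge.transmitter == "ACh"

    def test_cotransmission_multi_policy_emits_one_sign_per_transmitter(self, cat):
        conn = toy_connectome([("A", "B", 2)], {"A": ["ACh", "GABA"], "B": ["ACh"]})
        expr = expr_matrix(
            {"A": [0, 0, 0], "B": [5.0, 0, 3.0]},
            [ACH_EXC, ACH_INH, "syn-GABA-a"],
        )
        signed = cs.predict_edge_signs(conn, expr, cat, policy="multi")
        by_t = {e.transmitter: e.sign for e in signed.edges}
        assert by_t == {"ACh": "excitatory", "GABA": "inhibitory"}
        major = cs.predict_edge_signs(conn, expr, cat, policy="major")
        assert [e.transmitter for e in major.edges] == ["ACh"]

    def test_missing_postsynaptic_class_gives_no_prediction(self, cat):
        conn = toy_connectome([("A", "Z", 1)], {"A": ["ACh"], "Z": ["ACh"]})
        expr = expr_matrix({"A": [1.0, 0]}, [ACH_EXC, ACH_INH])
        signed = cs.predict_edge_signs(conn, expr, cat)
        assert signed.edges[0].sign == "no_prediction"

    def test_unknown_presynaptic_transmitter_gives_no_prediction(self, cat):
        conn = toy_connectome([("A", "B", 1)], {"B": ["ACh"]})
        expr = expr_matrix({"A": [0, 0], "B": [1.0, 0]}, [ACH_EXC, ACH_INH])
        signed = cs.predict_edge_signs(conn, expr, cat)
        assert signed.edges[0].sign == "no_prediction"

    def test_tie_gives_no_prediction(self, cat):
        conn = toy_connectome([("A", "B", 1)], {"A": ["ACh"], "B": ["ACh"]})
        expr = expr_matrix({"A": [0, 0], "B": [2.0, 2.0]}, [ACH_EXC, ACH_INH])
        signed = cs.predict_edge_signs(conn, expr, cat)
        assert signed.edges[0].sign == "no_prediction"

    def test_gap_junctions_carried_unsigned(self, cat):
        conn = toy_connectome(
            [("A", "B", 1)], {"A": ["ACh"], "B": ["ACh"]}, gaps=[("A", "B", 2)]
        )
        expr = expr_matrix({"A": [1.0, 0], "B": [1.0, 0]}, [ACH_EXC, ACH_INH])
        signed = cs.predict_edge_signs(conn, expr, cat)
        assert len(signed.gap_junctions) == 1

    def test_sign_conservation_on_random_instances(self, cat, rng):
        for k in range(10):
            conn, _ = cs.gen_connectome(12, seed=int(rng.integers(2**31 - 1)))
            classes = sorted(conn.classes())
            planted = {
                c: {t: CATEGORIES[rng.integers(4)] for t in ("ACh", "glutamate", "GABA")}
                for c in classes
            }
            expr, _ = cs.gen_expression(classes, cat, planted, seed=int(rng.integers(2**31 - 1)))
            signed = cs.predict_edge_signs(conn, expr, cat)
            per_edge_labels = sum(
                len(conn.transmitters[e.pre]) for e in conn.chemical_edges
            )
            assert len(signed.edges) == per_edge_labels
            assert all(e.sign in ("excitatory", "inhibitory", "no_prediction") for e in signed.edges)

    def test_sign_matches_brute_force_recomputation(self, cat, rng):
        conn, _ = cs.gen_connectome(10, seed=42)
        classes = sorted(conn.classes())
        planted = {
            c: {t: CATEGORIES[rng.integers(4)] for t in ("ACh", "glutamate", "GABA")}
            for c in classes
        }
        expr, _ = cs.gen_expression(classes, cat, planted, seed=43)
        signed = cs.predict_edge_signs(conn, expr, cat)
        for e in signed.edges:
            s = cs.net_polarity(expr.row(e.post), cat, e.transmitter)
            if s.category == "none" or s.net == 0:
                assert e.sign == "no_prediction"
            else:
                assert e.sign == ("excitatory" if s.net > 0 else "inhibitory")

    def test_raising_cation_expression_never_flips_exc_to_inh(self, cat):
        conn = toy_connectome([("A", "B", 1)], {"A": ["ACh"], "B": ["ACh"]})
        for exc in [3.0, 5.0, 50.0, 500.0]:
            expr = expr_matrix({"A": [0, 0], "B": [exc, 2.0]}, [ACH_EXC, ACH_INH])
            sign = cs.predict_edge_signs(conn, expr, cat).edges[0].sign
            assert sign == "excitatory"


class TestFractions:
    def test_engineered_both_fraction(self, cat):
        rows = {}
        for k in range(10):
            if k < 6:
                rows[f"C{k}"] = [1.0, 1.0]
            else:
                rows[f"C{k}"] = [1.0, 0.0]
        expr = expr_matrix(rows, [ACH_EXC, ACH_INH])
        table = cs.category_fractions(expr, cat, ["ACh"])
        assert table.loc["ACh", "both"] == pytest.approx(60.0)
        assert table.loc["ACh", "excitatory_only"] == pytest.approx(40.0)

    def test_single_none_class(self, cat):
        expr = expr_matrix({"C0": [0.0, 0.0]}, [ACH_EXC, ACH_INH])
        table = cs.category_fractions(expr, cat, ["ACh"])
        assert table.loc["ACh", "none"] == pytest.approx(100.0)

    def test_fractions_sum_to_100_on_random_matrices(self, cat, rng):
        for _ in range(20):
            n = int(rng.integers(1, 15))
            data = rng.integers(0, 3, size=(n, 2)) * rng.uniform(0, 10)
            expr = cs.ExpressionMatrix(
                data=pd.DataFrame(data, index=[f"C{i}" for i in range(n)],
                                  columns=[ACH_EXC, ACH_INH]).astype(float)
            )
            table = cs.category_fractions(expr, cat, ["ACh", "GABA"])
            assert np.allclose(table.sum(axis=1), 100.0)

    def test_both_fraction_invariant_under_rescaling(self, cat, rng):
        data = rng.uniform(0, 5, size=(8, 2))
        expr = cs.ExpressionMatrix(
            data=pd.DataFrame(data, index=[f"C{i}" for i in range(8)],
                              columns=[ACH_EXC, ACH_INH])
        )
        scaled = cs.ExpressionMatrix(data=expr.data * 37.5)
        a = cs.category_fractions(expr, cat, ["ACh"])
        b = cs.category_fractions(scaled, cat, ["ACh"])
        pd.testing.assert_frame_equal(a, b)

    def test_edge_sign_fractions_all_excitatory(self, cat):
        conn = toy_connectome(
            [("A", "B", 4), ("B", "A", 1)], {"A": ["ACh"], "B": ["ACh"]}
        )
        expr = expr_matrix({"A": [5.0, 0], "B": [5.0, 0]}, [ACH_EXC, ACH_INH])
        signed = cs.predict_edge_signs(conn, expr, cat)
        table = cs.edge_sign_fractions(signed)
        assert table.loc["ACh", "excitatory"] == pytest.approx(100.0)

    def test_weighting_modes_differ_with_unequal_counts(self, cat):
        conn = toy_connectome(
            [("A", "B", 9), ("B", "C", 1)],
            {"A": ["ACh"], "B": ["ACh"], "C": ["ACh"]},
        )
        expr = expr_matrix(
            {"A": [0, 0], "B": [5.0, 0], "C": [0, 5.0]}, [ACH_EXC, ACH_INH]
        )
        signed = cs.predict_edge_signs(conn, expr, cat)
        by_syn = cs.edge_sign_fractions(signed, weight="synapse_count")
        by_edge = cs.edge_sign_fractions(signed, weight="edge")
        assert by_syn.loc["ACh", "excitatory"] == pytest.approx(90.0)
        assert by_edge.loc["ACh", "excitatory"] == pytest.approx(50.0)

    def test_edge_fraction_rows_sum_to_100(self, cat, rng):
        conn, _ = cs.gen_connectome(15, seed=9)
        classes = sorted(conn.classes())
        planted = {
            c: {t: CATEGORIES[rng.integers(4)] for t in ("ACh", "glutamate", "GABA")}
            for c in classes
        }
        expr, _ = cs.gen_expression(classes, cat, planted, seed=10)
        signed = cs.predict_edge_signs(conn, expr, cat)
        table = cs.edge_sign_fractions(signed)
        assert np.allclose(table.sum(axis=1), 100.0)


class TestExport:
    def _signed(self, cat):
        conn = toy_connectome(
            [("A", "B", 3), ("B", "A", 1)],
            {"A": ["ACh"], "B": ["GABA"]},
            gaps=[("A", "B", 2)],
        )
        expr = expr_matrix(
            {"A": [0, 0, 4.0], "B": [5.0, 2.0, 0]},
            [ACH_EXC, ACH_INH, "syn-GABA-a"],
        )
        return cs.predict_edge_signs(conn, expr, cat)

    def test_graphml_roundtrip_preserves_edges_signs_weights(self, cat, tmp_path):
        signed = self._signed(cat)
        p = tmp_path / "net.graphml"
        cs.export_signed_network(signed, p)
        back = cs.read_signed_network(p)
        assert sorted(map(repr, back.edges)) == sorted(map(repr, signed.edges))
        assert sorted(map(repr, back.gap_junctions)) == sorted(map(repr, signed.gap_junctions))

    def test_gap_junctions_have_distinct_interaction_type(self, cat, tmp_path):
        import networkx as nx

        p = tmp_path / "net.graphml"
        cs.export_signed_network(self._signed(cat), p)
        g = nx.read_graphml(p, force_multigraph=True)
        kinds = {d["interaction"] for _, _, d in g.edges(data=True)}
        assert kinds == {"chemical", "electrical"}

    def test_empty_network_valid_document(self, tmp_path):
        p = tmp_path / "empty.graphml"
        cs.export_signed_network(cs.SignedNetwork(edges=[], gap_junctions=[]), p)
        back = cs.read_signed_network(p)
        assert back.edges == [] and back.gap_junctions == []

    def test_sif_export(self, cat, tmp_path):
        p = tmp_path / "net.sif"
        cs.export_signed_network(self._signed(cat), p, format="sif")
        lines = p.read_text().strip().splitlines()
        assert any("electrical" in ln for ln in lines)
        assert (tmp_path / "net.edges.csv").exists()
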