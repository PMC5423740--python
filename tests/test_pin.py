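import logging

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import special

from pathpin import (
    PathwayCollection,
    PPINetwork,
    TargetedInputs,
    build_pin,
    differential_expression,
    edge_weight,
    pairwise_pcc,
    qualify_edge,
    reduce_top_fraction,
    standardize_expression,
)
from tests.conftest import make_study
from tests.reference_impl import (
    random_toy_instance,
    reference_pcc,
    reference_pin,
)


class TestDifferentialExpression:
    def test_identical_values_in_both_groups(self):
        values = np.vstack([
            np.array([2.0, 2, 2, 2, 2, 2]),
            np.random.default_rng(0).standard_normal(6),
        ])
        study = make_study(values, 3, 3)
        table = differential_expression(study)
        assert table.loc["g0", "t"] == 0.0
        assert table.loc["g0", "p"] == 1.0
        assert not table.loc["g0", "is_deg"]

    def test_matches_textbook_pooled_t(self):
        study = make_study(np.array([[4.0, 5, 6, 1, 2, 3]]), 3, 3)
        table = differential_expression(study)
        t = table.loc["g0", "t"]
        assert t == pytest.approx(3 / np.sqrt(2 / 3), abs=1e-6)  # 3.6742
        # two-sided p from the regularized incomplete beta, df = 4
        expected_p = special.betainc(2.0, 0.5, 4 / (4 + t ** 2))
        assert table.loc["g0", "p"] == pytest.approx(expected_p, abs=1e-12)

    def test_standardization_leaves_t_invariant(self):
        rng = np.random.default_rng(1)
        study = make_study(rng.standard_normal((50, 12)) * 3 + 5, 7, 5)
        raw = differential_expression(study)
        std = differential_expression(standardize_expression(study))
        assert np.allclose(raw["t"].values, std["t"].values, atol=1e-10)

    def test_fdr_flag_adds_bh_q_values(self):
        rng = np.random.default_rng(2)
        values = rng.standard_normal((40, 12))
        values[:5, :7] += 4.0
        study = make_study(values, 7, 5)
        table = differential_expression(study, fdr=True)
        assert "q" in table.columns
        assert (table["q"] >= table["p"] - 1e-12).all()
        assert table["is_deg"].sum() <= differential_expression(study)["is_deg"].sum()

    def test_small_group_rejected(self):
        study_values = np.random.default_rng(3).standard_normal((3, 5))
        labels_bad = make_study(study_values, 4, 1)
        with pytest.raises(ValueError, match="at least 2"):
            differential_expression(labels_bad)


class TestPairwisePcc:
    def test_identical_and_negated_vectors(self):
        base = np.random.default_rng(4).standard_normal(10)
        values = np.vstack([base, base, -base])
        study = make_study(values, 5, 5)
        net = PPINetwork()
        net.add_interaction("g0", "g1", 0.9)
        net.add_interaction("g0", "g2", 0.9)
        corr = pairwise_pcc(study, net)
        assert corr.loc[("g0", "g1"), "pcc_disease"] == pytest.approx(1.0)
        assert corr.loc[("g0", "g1"), "pcc_control"] == pytest.approx(1.0)
        assert corr.loc[("g0", "g2"), "pcc_all"] == pytest.approx(-1.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(5)
        values = rng.standard_normal((8, 13))
        study = make_study(values, 8, 5)
        net = PPINetwork()
        pairs = [("g0", "g3"), ("g1", "g7"), ("g2", "g4")]
        for a, b in pairs:
            net.add_interaction(a, b, 0.5)
        corr = pairwise_pcc(study, net)
        d_cols = study.group_samples("disease")
        for a, b in pairs:
            expected = reference_pcc(
                study.values.loc[a, d_cols].values,
                study.values.loc[b, d_cols].values,
            )
            assert corr.loc[(a, b), "pcc_disease"] == pytest.approx(
                expected, abs=1e-12
            )

    def test_zero_variance_endpoint_gives_zero_with_warning(self, caplog):
        values = np.vstack([
            np.ones(10),
            np.random.default_rng(6).standard_normal(10),
        ])
        study = make_study(values, 5, 5)
        net = PPINetwork()
        net.add_interaction("g0", "g1", 0.9)
        with caplog.at_level(logging.WARNING, logger="pathpin.pin"):
            corr = pairwise_pcc(study, net)
        assert corr.loc[("g0", "g1"), "pcc_disease"] == 0.0
        assert "zero-variance" in caplog.text

    def test_diagnostic_abs_diff_column(self):
        rng = np.random.default_rng(7)
        study = make_study(rng.standard_normal((4, 14)), 8, 6)
        net = PPINetwork()
        net.add_interaction("g0", "g1", 0.5)
        corr = pairwise_pcc(study, net)
        row = corr.iloc[0]
        assert row["abs_diff"] == pytest.approx(
            abs(abs(row["pcc_disease"]) - abs(row["pcc_control"]))
        )


def _corr_frame(rows):
    """Fabricate a correlation table for direct edge-level tests."""
    index = pd.MultiIndex.from_tuples(
        [tuple(sorted(k)) for k in rows], names=["gene_a", "gene_b"]
    )
    frame = pd.DataFrame(list(rows.values()), index=index,
                         columns=["pcc_disease", "pcc_control"])
    frame["pcc_all"] = frame["pcc_disease"]
    frame["abs_diff"] = (
        frame["pcc_disease"].abs() - frame["pcc_control"].abs()
    ).abs()
    return frame


def _deg_frame(genes, deg_genes):
    return pd.DataFrame(
        {"t": 0.0, "p": [0.01 if g in deg_genes else 0.5 for g in genes],
         "is_deg": [g in deg_genes for g in genes]},
        index=list(genes),
    )


class TestQualifyAndWeight:
    @pytest.fixture()
    def fixture(self):
        pathways = PathwayCollection({
            "A": ["g1", "g2", "g3"],
            "B": ["g3", "g4", "g5"],
            "C": ["g6", "g7"],
        })  # ids: A=0, B=1, C=2
        ppi = PPINetwork()
        ppi.add_interaction("g1", "g6", 0.9)   # crosses A-C
        ppi.add_interaction("g2", "g4", 0.9)   # crosses A-B
        ppi.add_interaction("g3", "g4", 0.9)   # crosses A-B (g3 shared)
        corr = _corr_frame({
            ("g1", "g6"): (0.95, 0.10),
            ("g2", "g4"): (0.90, 0.20),
            ("g3", "g4"): (-0.60, 0.30),
        })
        return pathways, ppi, corr

    def test_shared_deg_criterion(self, fixture):
        pathways, ppi, corr = fixture
        degs = _deg_frame([f"g{i}" for i in range(1, 8)], {"g3"})
        quiet_corr = _corr_frame({k: (0.1, 0.1) for k in corr.index})
        criteria = qualify_edge(0, 1, degs, quiet_corr, pathways, ppi)
        assert criteria == {"shared_deg"}

    def test_coexpressed_ppi_criterion_for_disjoint_pathways(self, fixture):
        pathways, ppi, corr = fixture
        degs = _deg_frame([f"g{i}" for i in range(1, 8)], set())
        criteria = qualify_edge(0, 2, degs, corr, pathways, ppi)
        assert criteria == {"coexpressed_ppi"}

    def test_no_connection_gives_empty_criteria(self, fixture):
        pathways, ppi, corr = fixture
        degs = _deg_frame([f"g{i}" for i in range(1, 8)], set())
        assert qualify_edge(1, 2, degs, corr, pathways, ppi) == frozenset()

    def test_unknown_pathway_id_rejected(self, fixture):
        pathways, ppi, corr = fixture
        degs = _deg_frame(["g1"], set())
        with pytest.raises(ValueError, match="unknown pathway"):
            qualify_edge(0, 99, degs, corr, pathways, ppi)

    def test_weight_sums_absolute_correlations(self, fixture):
        pathways, ppi, corr = fixture
        # A-B crossing interactions: (g2,g4)=0.90 and (g3,g4)=-0.60
        weight = edge_weight(0, 1, corr, pathways, ppi)
        assert weight == pytest.approx(0.9 + 0.6)

    def test_weight_zero_without_crossing_interactions(self, fixture):
        pathways, ppi, corr = fixture
        assert edge_weight(1, 2, corr, pathways, ppi) == 0.0

    def test_weight_symmetry(self, fixture):
        pathways, ppi, corr = fixture
        assert edge_weight(0, 1, corr, pathways, ppi) == pytest.approx(
            edge_weight(1, 0, corr, pathways, ppi)
        )

    def test_adding_crossing_interaction_never_decreases_weight(self, fixture):
        pathways, ppi, corr = fixture
        before = edge_weight(0, 1, corr, pathways, ppi)
        ppi.add_interaction("g1", "g5", 0.9)
        grown = _corr_frame({
            ("g1", "g6"): (0.95, 0.10),
            ("g2", "g4"): (0.90, 0.20),
            ("g3", "g4"): (-0.60, 0.30),
            ("g1", "g5"): (0.40, 0.10),
        })
        assert edge_weight(0, 1, grown, pathways, ppi) >= before

    def test_shared_gene_interaction_counted_once(self):
        # g1 and g2 both belong to both pathways; their interaction is one
        # crossing edge, not two
        pathways = PathwayCollection({"A": ["g1", "g2", "g3"],
                                      "B": ["g1", "g2", "g4"]})
        ppi = PPINetwork()
        ppi.add_interaction("g1", "g2", 0.9)
        corr = _corr_frame({("g1", "g2"): (0.5, 0.5)})
        assert edge_weight(0, 1, corr, pathways, ppi) == pytest.approx(0.5)


class TestBuildPin:
    def _inputs(self, study, pathways, ppi):
        return TargetedInputs(
            study=standardize_expression(study),
            informative_pathways=pathways,
            targeted_ppi=ppi,
        )

    def test_two_qualified_pathways_give_one_edge(self):
        rng = np.random.default_rng(8)
        values = rng.standard_normal((6, 10))
        values[2, :5] += 5.0  # g2 strongly differential, shared by both
        genes = [f"g{i}" for i in range(6)]
        study = make_study(values, 5, 5, genes=genes)
        pathways = PathwayCollection({"A": ["g0", "g1", "g2"],
                                      "B": ["g2", "g3", "g4"]})
        inputs = self._inputs(study, pathways, PPINetwork())
        degs = differential_expression(inputs.study)
        corr = pairwise_pcc(inputs.study, inputs.targeted_ppi)
        pin = build_pin(inputs, degs, corr)
        assert pin.number_of_edges() == 1
        assert pin[0][1]["criteria"] == {"shared_deg"}

    def test_no_degs_and_weak_correlation_give_empty_network(self):
        rng = np.random.default_rng(9)
        study = make_study(rng.standard_normal((8, 10)), 5, 5)
        pathways = PathwayCollection({"A": ["g0", "g1"], "B": ["g4", "g5"]})
        inputs = self._inputs(study, pathways, PPINetwork())
        degs = differential_expression(inputs.study, alpha=1e-9)
        corr = pairwise_pcc(inputs.study, inputs.targeted_ppi)
        pin = build_pin(inputs, degs, corr, pcc_threshold=1.0)
        assert pin.number_of_edges() == 0
        assert set(pin.nodes) == {0, 1}

    @pytest.mark.parametrize("instance_seed", [0, 1, 2, 3, 4])
    def test_matches_bruteforce_reference(self, instance_seed):
        rng = np.random.default_rng(100 + instance_seed)
        study, pathways, ppi = random_toy_instance(rng)
        inputs = self._inputs(study, pathways, ppi)
        degs = differential_expression(inputs.study)
        corr = pairwise_pcc(inputs.study, inputs.targeted_ppi)
        pin = build_pin(inputs, degs, corr)
        expected = reference_pin(pathways, ppi, degs, corr)
        got = {
            tuple(sorted((a, b))): (data["weight"], data["criteria"])
            for a, b, data in pin.edges(data=True)
        }
        assert set(got) == set(expected)
        for key, (weight, criteria) in expected.items():
            assert got[key][0] == pytest.approx(weight, abs=1e-10)
            assert got[key][1] == criteria


class TestReduceTopFraction:
    def _graph(self, weights):
        g = nx.Graph()
        for (a, b), w in weights.items():
            g.add_edge(a, b, weight=w)
        return g

    def test_fraction_one_is_identity(self):
        g = self._graph({(0, 1): 2.0, (1, 2): 1.0, (0, 3): 3.0})
        out = reduce_top_fraction(g, 1.0)
        assert sorted(out.edges) == sorted(g.edges)

    def test_ties_at_cut_break_on_lexicographic_ids(self):
        g = self._graph({(0, 5): 1.0, (0, 2): 1.0, (1, 3): 1.0})
        out = reduce_top_fraction(g, 2 / 3)
        assert sorted(tuple(sorted(e)) for e in out.edges) == [(0, 2), (0, 5)]

    def test_isolated_nodes_retained(self):
        g = self._graph({(0, 1): 5.0, (2, 3): 1.0})
        g.add_node(9)
        out = reduce_top_fraction(g, 0.5)
        assert set(out.nodes) == {0, 1, 2, 3, 9}
        assert list(out.edges) == [(0, 1)]

    @pytest.mark.parametrize("n_edges,fraction", [(29, 0.29), (100, 0.29),
                                                  (40, 0.05), (7, 0.5)])
    def test_kept_count_is_floor_of_product(self, n_edges, fraction):
        rng = np.random.default_rng(10)
        g = nx.Graph()
        k = 0
        for a in range(200):
            for b in range(a + 1, 200):
                if k >= n_edges:
                    break
                g.add_edge(a, b, weight=float(rng.uniform()))
                k += 1
        out = reduce_top_fraction(g, fraction)
        import math

        assert out.number_of_edges() == math.floor(fraction * n_edges + 1e-9)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            reduce_top_fraction(nx.Graph(), 0.0)
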