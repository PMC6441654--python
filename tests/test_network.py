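import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import degflow as d
import oracles


class TestPearson:
    def test_affine_identity(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert d.pearson_r(x, 2 * x + 1) == pytest.approx(1.0)
        assert d.pearson_r(x, -x) == pytest.approx(-1.0)

    def test_matches_summation_oracle(self):
        x = [1, 2, 3, 4, 5]
        y = [2, 1, 4, 3, 5]
        assert d.pearson_r(x, y) == pytest.approx(oracles.pearson(x, y), abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    def test_symmetry_and_affine_invariance(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.random(5), rng.random(5)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return
        assert d.pearson_r(x, y) == pytest.approx(d.pearson_r(y, x))
        assert d.pearson_r(3 * x + 2, y) == pytest.approx(d.pearson_r(x, y), abs=1e-9)

    def test_constant_profile_rejected(self):
        with pytest.raises(d.DegflowError) as e:
            d.pearson_r([1, 1, 1, 1, 1], [1, 2, 3, 4, 5])
        assert e.value.code == "constant-profile"


def _expr_from_profiles(profiles: dict[str, np.ndarray], condition=d.Condition.LTC):
    """ExpressionMatrix whose per-timepoint replicate means equal the given 5-vectors."""
    tps = (1, 2, 4, 6, 8)
    samples = [
        d.SampleDesign(f"{condition.value}_d{t}_r{r}", condition, t, r) for t in tps for r in (1, 2)
    ]
    genes = list(profiles)
    rpkm = np.array([np.repeat(2.0 ** np.asarray(profiles[g]) - 1.0, 2) for g in genes])
    return d.ExpressionMatrix(genes, samples, np.clip(rpkm, 0, None))


class TestBuildNetwork:
    def test_matches_all_pairs_brute_force(self):
        rng = np.random.default_rng(8)
        tf_ids = [f"tf{i}" for i in range(20)]
        st_ids = [f"st{i}" for i in range(10)]
        profiles = {g: rng.random(5) * 6 for g in tf_ids + st_ids}
        expr = _expr_from_profiles(profiles)
        net = d.build_network(expr, d.Condition.LTC, tf_ids, st_ids, pos=0.7, neg=-0.7)
        log_profiles = d.timepoint_means(expr, d.Condition.LTC, "log2p1")
        expected = set()
        for tf in tf_ids:
            for s in st_ids:
                r = oracles.pearson(list(log_profiles.loc[tf]), list(log_profiles.loc[s]))
                if r >= 0.7 or r <= -0.7:
                    expected.add((tf, s))
        got = set(zip(net.edges["tf_id"], net.edges["structural_id"]))
        assert got == expected
        for row in net.edges.itertuples():
            r = oracles.pearson(
                list(log_profiles.loc[row.tf_id]), list(log_profiles.loc[row.structural_id])
            )
            assert row.r == pytest.approx(r, abs=1e-9)
            assert row.sign == ("pos" if r > 0 else "neg")

    def test_impossible_threshold_gives_empty_network(self):
        rng = np.random.default_rng(1)
        profiles = {g: rng.random(5) for g in ["tf0", "tf1", "st0"]}
        expr = _expr_from_profiles(profiles)
        net = d.build_network(expr, d.Condition.LTC, ["tf0", "tf1"], ["st0"], pos=1.0, neg=-1.0)
        # exact |r| = 1 from continuous noise is a null event
        assert net.edges.empty

    def test_planted_module_recovered(self, planted_sim):
        cfg, cm, meta, _, truth = planted_sim
        expr = d.rpkm(cm, meta)
        tf_ids = [m.gene_id for m in meta if m.tf_family]
        st_ids = [m.gene_id for m in meta if m.is_structural]
        net = d.build_network(expr, d.Condition.LTC, tf_ids, st_ids)
        pos = set(zip(net.edges[net.edges["sign"] == "pos"]["tf_id"],
                      net.edges[net.edges["sign"] == "pos"]["structural_id"]))
        pairs = set()
        for _, grp in truth.module_table.groupby("module"):
            tfs = grp[grp["role"] == "tf"]["gene_id"]
            sts = grp[grp["role"] == "structural"]["gene_id"]
            pairs |= {(a, b) for a in tfs for b in sts}
        assert pairs
        assert len(pairs & pos) / len(pairs) >= 0.9

    def test_empty_node_set_rejected(self, planted_sim):
        _, cm, meta, _, _ = planted_sim
        expr = d.rpkm(cm, meta)
        with pytest.raises(d.DegflowError) as e:
            d.build_network(expr, d.Condition.LTC, [], ["UN00001"])
        assert e.value.code == "empty-node-set"

    def test_null_exceedance_matches_analytic_probability(self):
        """P(|r| >= 0.9) for independent 5-point normal profiles matches the t-based null."""
        rng = np.random.default_rng(42)
        n_pairs = 40_000
        x = rng.standard_normal((n_pairs, 5))
        y = rng.standard_normal((n_pairs, 5))
        xz = (x - x.mean(1, keepdims=True)) / x.std(1, keepdims=True)
        yz = (y - y.mean(1, keepdims=True)) / y.std(1, keepdims=True)
        r = (xz * yz).mean(1)
        empirical = np.mean(np.abs(r) >= 0.9)
        t0 = 0.9 * np.sqrt(3) / np.sqrt(1 - 0.81)
        analytic = 2 * stats.t.sf(t0, df=3)
        se = np.sqrt(analytic * (1 - analytic) / n_pairs)
        assert abs(empirical - analytic) < 4 * se


class TestSharedNeighborFraction:
    def _nets(self, edges_a, edges_b):
        def net(edges):
            return d.CoexpressionNetwork(
                treatment=d.Condition.LTC,
                edges=pd.DataFrame(
                    [(tf, s, 0.95, "pos") for tf, s in edges],
                    columns=["tf_id", "structural_id", "r", "sign"],
                ),
                tf_ids=sorted({e[0] for e in edges}),
                structural_ids=sorted({e[1] for e in edges}),
            )

        return net(edges_a), net(edges_b)

    def test_identical_neighbor_sets(self):
        a, b = self._nets([("A", "s"), ("B", "s")], [("A", "s"), ("B", "s")])
        assert d.shared_neighbor_fraction(a, b, ("s", "s")) == 1.0

    def test_jaccard_count_case(self):
        a, b = self._nets(
            [("A", "s"), ("B", "s"), ("C", "s")], [("B", "s"), ("C", "s"), ("D", "s")]
        )
        assert d.shared_neighbor_fraction(a, b, ("s", "s")) == pytest.approx(2 / 4)

    def test_empty_union_is_zero(self):
        a, b = self._nets([("A", "x")], [("A", "x")])
        assert d.shared_neighbor_fraction(a, b, ("s", "s")) == 0.0

    def test_symmetric_in_networks(self):
        a, b = self._nets([("A", "s"), ("B", "s")], [("B", "s"), ("C", "s")])
        assert d.shared_neighbor_fraction(a, b, ("s", "s")) == d.shared_neighbor_fraction(
            b, a, ("s", "s")
        )


class TestExport:
    def _one_edge_net(self):
        return d.CoexpressionNetwork(
            treatment=d.Condition.HT,
            edges=pd.DataFrame(
                [("tf1", "st1", -0.93, "neg")], columns=["tf_id", "structural_id", "r", "sign"]
            ),
            tf_ids=["tf1", "tf2"],
            structural_ids=["st1"],
        )

    def test_empty_network_header_only(self, tmp_path):
        net = d.CoexpressionNetwork(
            treatment=d.Condition.HT,
            edges=pd.DataFrame(columns=["tf_id", "structural_id", "r", "sign"]),
            tf_ids=["tf1"],
            structural_ids=["st1"],
        )
        p = tmp_path / "net.tsv"
        d.export_network(net, p, "edge_tsv")
        lines = p.read_text().strip().splitlines()
        assert lines == ["tf_id\tstructural_id\tr\tsign\twidth"]

    def test_tsv_round_trip(self, tmp_path):
        from degflow.network import read_network_edges

        p = tmp_path / "net.tsv"
        d.export_network(self._one_edge_net(), p, "edge_tsv")
        back = read_network_edges(p)
        assert back.iloc[0].tolist() == ["tf1", "st1", -0.93, "neg", 0.93]

    def test_gml_parses_with_standard_reader(self, tmp_path):
        p = tmp_path / "net.gml"
        net = self._one_edge_net()
        d.export_network(net, p, "gml")
        g = nx.read_gml(p)
        assert g.number_of_edges() == len(net.edges)
        assert g.nodes["tf1"]["type"] == "tf"
        assert g.edges["tf1", "st1"]["weight"] == pytest.approx(0.93)

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(d.DegflowError) as e:
            d.export_network(self._one_edge_net(), tmp_path / "x", "parquet")
        assert e.value.code == "bad-format"
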