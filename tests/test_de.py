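import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import degflow as d
from degflow.de import DISPERSION_FLOOR
import oracles


def _matrix(counts, conditions, timepoints, replicates):
    samples = [
        d.SampleDesign(f"S{j}", d.Condition(c), t, r)
        for j, (c, t, r) in enumerate(zip(conditions, timepoints, replicates))
    ]
    return d.CountMatrix(
        gene_ids=[f"g{i}" for i in range(np.asarray(counts).shape[0])],
        samples=samples,
        counts=np.asarray(counts),
    )


class TestRpkm:
    def test_formula_identities(self):
        # library sizes engineered via a filler gene so column sums are exact
        cm = _matrix(
            [[1, 0], [0, 50], [999_999, 4_999_950]],
            ["control", "control"],
            [1, 1],
            [1, 2],
        )
        meta = [d.GeneMeta("g0", 1000), d.GeneMeta("g1", 2000), d.GeneMeta("g2", 500)]
        expr = d.rpkm(cm, meta)
        assert expr.rpkm[0, 0] == pytest.approx(1.0)  # 1 read, 1 kb, 1e6 lib
        assert expr.rpkm[1, 1] == pytest.approx(5.0)  # 50 reads, 2 kb, 5e6 lib
        assert expr.rpkm[0, 1] == 0.0  # zero count stays zero

    def test_zero_counts_give_zero_rpkm(self, tiny_counts):
        cm = tiny_counts
        cm.counts[0, :] = 0
        cm.counts[1, 0] += 1  # keep libraries non-empty
        expr = d.rpkm(cm, [d.GeneMeta(g, 500 * (i + 1)) for i, g in enumerate(cm.gene_ids)])
        assert np.all(expr.rpkm[0] == 0)
        assert np.all((expr.rpkm == 0) == (cm.counts == 0))

    def test_scaling_sample_counts_leaves_its_rpkm_unchanged(self, tiny_counts):
        meta = [d.GeneMeta(g, 1000) for g in tiny_counts.gene_ids]
        base = d.rpkm(tiny_counts, meta)
        scaled = d.CountMatrix(
            gene_ids=tiny_counts.gene_ids,
            samples=tiny_counts.samples,
            counts=tiny_counts.counts * np.where(np.arange(len(tiny_counts.samples)) == 2, 3, 1),
        )
        expr = d.rpkm(scaled, meta)
        np.testing.assert_allclose(expr.rpkm[:, 2], base.rpkm[:, 2])

    def test_empty_library_rejected(self):
        cm = _matrix([[0, 5]], ["control", "control"], [1, 1], [1, 2])
        with pytest.raises(d.DegflowError) as e:
            d.rpkm(cm, [d.GeneMeta("g0", 1000)])
        assert e.value.code == "empty-library"


class TestTimepointMeans:
    def test_arithmetic_mean_and_log_transform(self):
        cm = _matrix(
            [[1, 2, 3], [0, 0, 0]],
            ["LTC", "LTC", "LTC"],
            [1, 1, 1],
            [1, 2, 3],
        )
        meta = [d.GeneMeta("g0", 1000), d.GeneMeta("g1", 1000)]
        expr = d.ExpressionMatrix(cm.gene_ids, cm.samples, np.array([[1.0, 2.0, 3.0], [0, 0, 0]]))
        means = d.timepoint_means(expr, d.Condition.LTC, "linear")
        assert means.loc["g0", 1] == pytest.approx(2.0)
        logm = d.timepoint_means(expr, d.Condition.LTC, "log2p1")
        assert logm.loc["g1", 1] == 0.0

    def test_matches_per_cell_recomputation(self, planted_sim):
        _, cm, meta, _, _ = planted_sim
        expr = d.rpkm(cm, meta)
        means = d.timepoint_means(expr, d.Condition.HT, "linear")
        frame = expr.to_frame()
        rng = np.random.default_rng(0)
        for gi in rng.choice(len(cm.gene_ids), 20, replace=False):
            g = cm.gene_ids[gi]
            for t in cm.timepoints():
                cols = [cm.sample_ids[j] for j in cm.columns_for(d.Condition.HT, t)]
                assert means.loc[g, t] == pytest.approx(frame.loc[g, cols].mean())


class TestNBExactTest:
    def test_symmetric_input_gives_null_result(self):
        lfc, p = d.nb_exact_test([5, 5, 5], [5, 5, 5], [1e6] * 3, [1e6] * 3, 0.1)
        assert lfc == 0.0
        assert p == 1.0

    def test_poisson_limit_equals_conditional_binomial(self):
        """At dispersion 0 the conditional split distribution is binomial."""
        from scipy import stats

        a, b = [12, 7], [3, 2, 4]
        lfc, p = d.nb_exact_test(a, b, [1e6] * 2, [1e6] * 3, 0.0)
        total = sum(a) + sum(b)
        probs = stats.binom.pmf(np.arange(total + 1), total, 2 / 5)
        obs = probs[sum(a)]
        expected = probs[probs <= obs * (1 + 1e-10)].sum()
        assert p == pytest.approx(expected, rel=1e-10)

    def test_worked_enumeration_case(self):
        lfc, p = d.nb_exact_test([10, 10], [0, 0], [1e6] * 2, [1e6] * 2, 0.1)
        assert p == pytest.approx(oracles.exact_test_p(20, 0, 2, 2, 0.1), rel=1e-12)
        assert lfc == pytest.approx(np.log2(10.5 / 0.5))

    @given(st.integers(0, 2**31 - 1))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_a, n_b = int(rng.integers(1, 4)), int(rng.integers(1, 4))
        a = rng.integers(0, 200 // max(n_a, 1), size=n_a)
        b = rng.integers(0, 200 // max(n_b, 1), size=n_b)
        phi = float(rng.choice([0.0, 0.01, 0.1, 0.5]))
        lfc, p = d.nb_exact_test(a, b, [1e6] * n_a, [1e6] * n_b, phi)
        expected = oracles.exact_test_p(int(a.sum()), int(b.sum()), n_a, n_b, phi)
        assert p == pytest.approx(expected, rel=1e-9, abs=1e-300)

    @given(st.integers(0, 2**31 - 1))
    def test_swapping_groups_negates_log2fc_and_preserves_p(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 80, size=3)
        b = rng.integers(0, 80, size=3)
        lfc1, p1 = d.nb_exact_test(a, b, [1e6] * 3, [1e6] * 3, 0.1)
        lfc2, p2 = d.nb_exact_test(b, a, [1e6] * 3, [1e6] * 3, 0.1)
        assert lfc1 == pytest.approx(-lfc2)
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_negative_dispersion_rejected(self):
        with pytest.raises(d.DegflowError) as e:
            d.nb_exact_test([1], [2], [1e6], [1e6], -0.1)
        assert e.value.code == "bad-dispersion"


class TestDispersion:
    def _sim(self, phi, n_genes=500, mean=100.0, seed=0):
        rng = np.random.default_rng(seed)
        conds = ["control", "LTC", "HT"]
        samples, cols = [], []
        for c in conds:
            for t in (1, 2, 4, 6, 8):
                for r in (1, 2, 3):
                    samples.append(d.SampleDesign(f"{c}{t}r{r}", d.Condition(c), t, r))
        if phi == 0:
            counts = rng.poisson(mean, size=(n_genes, len(samples)))
        else:
            r_ = 1 / phi
            counts = rng.negative_binomial(r_, r_ / (r_ + mean), size=(n_genes, len(samples)))
        return d.CountMatrix([f"g{i}" for i in range(n_genes)], samples, counts)

    def test_poisson_data_near_floor(self):
        est = d.estimate_dispersion(self._sim(0.0, mean=50.0))
        assert est.median() <= 0.01

    def test_constant_replicates_floor(self):
        cm = _matrix(
            [[10] * 6], ["control"] * 3 + ["LTC"] * 3, [1, 1, 1, 1, 1, 1], [1, 2, 3, 1, 2, 3]
        )
        est = d.estimate_dispersion(cm)
        assert est.iloc[0] == DISPERSION_FLOOR

    def test_nb_parameter_recovery(self):
        est = d.estimate_dispersion(self._sim(0.2, mean=100.0, seed=4))
        assert 0.1 < est.median() < 0.4


class TestBH:
    def test_step_up_hand_case(self):
        np.testing.assert_allclose(d.bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_equal_inputs_unchanged(self):
        np.testing.assert_allclose(d.bh_fdr([0.2] * 7), [0.2] * 7)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_dominates_input_and_matches_hand_procedure(self, ps):
        adj = d.bh_fdr(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-15)
        assert np.all(adj <= 1.0)
        np.testing.assert_allclose(adj, oracles.bh_adjust(ps), atol=1e-12)

    def test_order_invariance(self):
        rng = np.random.default_rng(1)
        ps = rng.random(30)
        perm = rng.permutation(30)
        np.testing.assert_allclose(d.bh_fdr(ps)[perm], d.bh_fdr(ps[perm]))

    def test_out_of_range_rejected(self):
        with pytest.raises(d.DegflowError) as e:
            d.bh_fdr([0.5, 1.5])
        assert e.value.code == "bad-pvalue"


class TestCallDegs:
    def test_fold_change_gate_blocks_significant_small_shift(self):
        """A 1.4-fold shift stays uncalled no matter how significant."""
        conds = ["control"] * 15 + ["LTC"] * 15
        tps = ([1] * 3 + [2] * 3 + [4] * 3 + [6] * 3 + [8] * 3) * 2
        reps = [1, 2, 3] * 10
        row = [10_000] * 15 + [14_000] * 15
        filler = [50_000] * 30
        cm = _matrix([row, filler], conds, tps, reps)
        meta = [d.GeneMeta("g0", 1000), d.GeneMeta("g1", 1000)]
        de = d.call_degs(cm, meta, d.Condition.LTC, dispersion=1e-4)
        g0 = de[de["gene_id"] == "g0"]
        assert (g0["fdr"] < 1e-6).all()
        assert (g0["call"] == "none").all()
        assert (g0["log2fc"].abs() < 1.0).all()

    def test_call_thresholds_enforced(self, planted_de):
        for de in planted_de.values():
            called = de[de["call"] != "none"]
            assert (called["fdr"] <= 0.05).all()
            assert (called["log2fc"].abs() >= 1.0).all()
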