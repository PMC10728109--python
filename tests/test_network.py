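"""Core statistic: ratio computation, shrunken centroid, network building."""

import numpy as np
import pytest

from ewsdda import (
    DynamicNetworkBuilder,
    PairwiseRatios,
    build_networks,
    compute_ratios,
    networks_from_dataset,
    ratio_pairs,
    shrunken_centroid,
)
from ewsdda.dataset import OmicsDataset

from conftest import random_dataset


# ----------------------------------------------------------------------
# independent literal-loop oracle for the statistic
# ----------------------------------------------------------------------
def oracle_d(values, classes, class_order, mk_form="as_printed"):
    """Brute-force d_ijk: every mean/SD/median by explicit loops over samples."""
    import statistics

    m, n = values.shape
    pairs = [(i, j) for i in range(m) for j in range(i + 1, m)]
    ratios = {}
    for (i, j) in pairs:
        ratios[(i, j)] = [values[i][s] / values[j][s] for s in range(n)]
    z = len(class_order)
    d = {}
    s_pooled = {}
    for (i, j), r in ratios.items():
        mu_all = sum(r) / n
        ss = 0.0
        mu_k = {}
        for c in class_order:
            idx = [s for s in range(n) if classes[s] == c]
            mu = sum(r[s] for s in idx) / len(idx)
            mu_k[c] = mu
            ss += sum((r[s] - mu) ** 2 for s in idx)
        s_pooled[(i, j)] = (ss / (n - z)) ** 0.5
        d[(i, j)] = (mu_k, mu_all)
    s0 = statistics.median(s_pooled.values())
    out = {}
    for (i, j), (mu_k, mu_all) in d.items():
        for c in class_order:
            nk = sum(1 for s in range(n) if classes[s] == c)
            if mk_form == "as_printed":
                mk = (1.0 / n + 1.0 / nk) ** 0.5
            else:
                mk = (1.0 / nk - 1.0 / n) ** 0.5
            denom = mk * (s_pooled[(i, j)] + s0)
            out[(i, j, c)] = 0.0 if denom == 0 else (mu_k[c] - mu_all) / denom
    return out


class TestComputeRatios:
    def test_simple_arithmetic(self):
        ds = OmicsDataset(["f1", "f2"], ["a", "b"], np.array([[2.0, 4.0], [1.0, 2.0]]),
                          {"a": "x", "b": "y"}, ["x", "y"])
        r = compute_ratios(ds)
        assert list(r.index) == ["f1/f2"]
        assert np.allclose(r.to_numpy(), [[2.0, 2.0]])

    def test_pair_count_is_m_choose_2(self):
        rng = np.random.default_rng(0)
        ds = random_dataset(rng, 90, [3, 3])
        assert compute_ratios(ds).shape[0] == 90 * 89 // 2

    def test_global_scaling_cancels(self, small_dataset):
        r1 = compute_ratios(small_dataset)
        r2 = compute_ratios(small_dataset.with_values(small_dataset.values * 1e3))
        assert np.allclose(r1.to_numpy(), r2.to_numpy())

    def test_nonpositive_value_rejected(self, small_dataset):
        vals = small_dataset.values.copy()
        vals[1, 2] = 0.0
        with pytest.raises(ValueError, match="fB.*s3"):
            compute_ratios(small_dataset.with_values(vals))


class TestShrunkenCentroid:
    @pytest.mark.parametrize("mk_form", ["as_printed", "classical"])
    @pytest.mark.parametrize("seed", [42, 1, 2])
    def test_matches_literal_loop_oracle(self, seed, mk_form):
        rng = np.random.default_rng(seed)
        ds = random_dataset(rng, 3, [3, 4])
        table = shrunken_centroid(compute_ratios(ds), ds.classes, ds.class_order,
                                  mk_form, ratio_keys=ratio_pairs(ds.feature_ids))
        expected = oracle_d(ds.values, list(ds.classes), ds.class_order, mk_form)
        feat_pos = {f: i for i, f in enumerate(ds.feature_ids)}
        for r, key in enumerate(table.ratio_keys):
            for k, c in enumerate(table.classes):
                i, j = feat_pos[key.numerator], feat_pos[key.denominator]
                assert table.d[r, k] == pytest.approx(expected[(i, j, c)], abs=1e-10)

    def test_constant_ratio_has_zero_d(self):
        rng = np.random.default_rng(3)
        ds = random_dataset(rng, 3, [4, 4])
        vals = ds.values.copy()
        vals[1] = 2.0 * vals[0]  # f1/f0 ratio constant = 2 everywhere
        ds = ds.with_values(vals)
        table = shrunken_centroid(compute_ratios(ds), ds.classes, ds.class_order,
                                  ratio_keys=ratio_pairs(ds.feature_ids))
        r = [k.label() for k in table.ratio_keys].index("f0/f1")
        assert np.allclose(table.d[r], 0.0)

    def test_identical_class_distributions_give_zero_d(self):
        # the same sample values repeated in both classes -> mu_k == mu
        vals = np.array([[1.0, 2, 3, 1, 2, 3], [2.0, 1, 5, 2, 1, 5], [1.0, 1, 2, 1, 1, 2]])
        ids = [f"s{i}" for i in range(6)]
        ds = OmicsDataset(["a", "b", "c"], ids, vals,
                          dict(zip(ids, ["x"] * 3 + ["y"] * 3)), ["x", "y"])
        table = shrunken_centroid(compute_ratios(ds), ds.classes, ds.class_order,
                                  ratio_keys=ratio_pairs(ds.feature_ids))
        assert np.allclose(table.d, 0.0, atol=1e-12)

    def test_weighted_centroid_identity(self):
        rng = np.random.default_rng(11)
        for sizes in ([3, 5], [4, 4, 6], [3, 3, 3, 5]):
            ds = random_dataset(rng, 5, sizes)
            t = shrunken_centroid(compute_ratios(ds), ds.classes, ds.class_order,
                                  ratio_keys=ratio_pairs(ds.feature_ids))
            resid = (t.mu_class - t.mu_overall[:, None]) @ t.class_sizes
            assert np.allclose(resid, 0.0, atol=1e-9 * np.abs(t.mu_overall * sum(sizes)).max())

    def test_s0_is_median_of_pooled_sds(self, staged_null):
        t = shrunken_centroid(compute_ratios(staged_null), staged_null.classes,
                              staged_null.class_order)
        assert t.s0 == pytest.approx(np.median(t.s_pooled))

    def test_sign_of_d_follows_centroid_difference(self, staged_null):
        t = shrunken_centroid(compute_ratios(staged_null), staged_null.classes,
                              staged_null.class_order)
        num = t.mu_class - t.mu_overall[:, None]
        assert np.all(np.sign(t.d) == np.sign(num))

    def test_global_scale_invariance_of_d(self, staged_null):
        base = shrunken_centroid(compute_ratios(staged_null), staged_null.classes,
                                 staged_null.class_order).d
        for c in (1e-3, 1e3):
            scaled = staged_null.with_values(staged_null.values * c)
            d = shrunken_centroid(compute_ratios(scaled), scaled.classes,
                                  scaled.class_order).d
            assert np.allclose(d, base, rtol=1e-9)

    def test_errors(self, small_dataset):
        with pytest.raises(ValueError, match="at least 2 ratios"):
            shrunken_centroid(np.ones((1, 4)), small_dataset.classes, ["N", "I"])
        with pytest.raises(ValueError, match="fewer than 2 samples"):
            shrunken_centroid(np.ones((3, 3)), np.array(["N", "N", "I"]), ["N", "I"])

    def test_all_constant_data_yields_zero_d_not_error(self):
        ids = [f"s{i}" for i in range(8)]
        ds = OmicsDataset(["a", "b", "c"], ids, np.ones((3, 8)),
                          dict(zip(ids, ["x"] * 4 + ["y"] * 4)), ["x", "y"])
        t = shrunken_centroid(compute_ratios(ds), ds.classes, ds.class_order)
        assert np.allclose(t.d, 0.0)


class TestBuildNetworks:
    def _table(self, d_values):
        """Tiny CentroidTable stub via the real constructor path."""
        from ewsdda.network import CentroidTable, RatioKey
        d = np.asarray(d_values, dtype=float)
        nr, z = d.shape
        keys = [RatioKey("a", "b"), RatioKey("a", "c"), RatioKey("b", "c")][:nr]
        return CentroidTable(
            ratio_keys=keys, classes=[f"c{k}" for k in range(z)],
            class_sizes=np.full(z, 5), mu_class=np.zeros_like(d),
            mu_overall=np.zeros(nr), s_pooled=np.ones(nr), s0=1.0,
            m_class=np.ones(z), d=d,
        )

    def test_threshold_is_inclusive_and_signed(self):
        t = self._table([[0.6, -0.59], [-0.6, 0.2]])
        nets = build_networks(t, 0.6)
        assert nets["c0"].has_edge("a", "b")
        assert nets["c0"].edges["a", "b"]["sign"] == "up"
        assert nets["c0"].edges["a", "c"]["sign"] == "down"
        assert not nets["c1"].has_edge("a", "b")  # -0.59 below threshold
        assert nets["c1"].number_of_edges() == 0

    def test_all_zero_d_gives_empty_graphs_with_nodes(self):
        t = self._table(np.zeros((3, 4)))
        nets = build_networks(t, 0.6, feature_ids=["a", "b", "c"])
        assert len(nets) == 4
        for g in nets.values():
            assert g.number_of_edges() == 0
            assert set(g.nodes) == {"a", "b", "c"}

    def test_epsilon_must_be_positive(self):
        with pytest.raises(ValueError):
            build_networks(self._table(np.zeros((2, 2))), 0.0)

    def test_edge_nesting_across_thresholds(self, staged_null):
        nets = {eps: networks_from_dataset(staged_null, eps)[0] for eps in (0.3, 0.6, 0.9)}
        for c in staged_null.class_order:
            e03 = set(map(frozenset, nets[0.3][c].edges))
            e06 = set(map(frozenset, nets[0.6][c].edges))
            e09 = set(map(frozenset, nets[0.9][c].edges))
            assert e09 <= e06 <= e03

    def test_one_graph_per_class(self, staged_null):
        nets, _ = networks_from_dataset(staged_null, 0.6)
        assert list(nets) == staged_null.class_order


class TestEstimators:
    def test_pairwise_ratios_transformer(self):
        X = np.array([[2.0, 1.0, 4.0], [4.0, 2.0, 8.0]])
        tr = PairwiseRatios().fit(X)
        out = tr.transform(X)
        assert out.shape == (2, 3)
        assert np.allclose(out[:, 0], [2.0, 2.0])  # x0/x1
        names = tr.get_feature_names_out(["a", "b", "c"])
        assert list(names) == ["a/b", "a/c", "b/c"]

    def test_builder_matches_function_path(self, staged_null):
        nets_fn, table_fn = networks_from_dataset(staged_null, 0.6)
        est = DynamicNetworkBuilder(epsilon=0.6, class_order=staged_null.class_order)
        est.fit(staged_null.values.T, staged_null.classes,
                feature_names=staged_null.feature_ids)
        assert np.allclose(est.centroid_table_.d, table_fn.d)
        for c in staged_null.class_order:
            assert set(map(frozenset, est.networks_[c].edges)) == set(
                map(frozenset, nets_fn[c].edges))

    def test_get_set_params_roundtrip(self):
        est = DynamicNetworkBuilder(epsilon=1.1, mk_form="classical")
        params = est.get_params()
        assert params["epsilon"] == 1.1
        est2 = DynamicNetworkBuilder().set_params(**params)
        assert est2.mk_form == "classical"
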