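import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from aerlnc.subtype_signature import (
    apply_bins,
    chi2_merit,
    cluster_purity,
    crossval_classify,
    discretize,
    hierarchical_cluster,
    pca,
    select_signature,
    zscore,
)
from tests.conftest import make_panel


class TestZscore:
    def test_sample_sd_convention(self):
        panel = make_panel(np.array([[1.0, 2.0, 3.0]]), ["a", "a", "b"])
        z = zscore(panel)
        np.testing.assert_allclose(z.values.to_numpy()[0], [-1.0, 0.0, 1.0])

    def test_constant_gene_maps_to_zeros_with_warning(self):
        panel = make_panel(np.array([[5.0, 5.0, 5.0], [1.0, 2.0, 4.0]]), ["a", "a", "b"])
        with pytest.warns(UserWarning, match="constant"):
            z = zscore(panel)
        assert np.all(z.values.to_numpy()[0] == 0.0)

    def test_rows_normalized(self):
        rng = np.random.default_rng(0)
        panel = make_panel(rng.normal(5, 2, size=(10, 30)), ["a"] * 15 + ["b"] * 15)
        z = zscore(panel).values.to_numpy()
        np.testing.assert_allclose(z.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=1, ddof=1), 1.0)


class TestDiscretize:
    def test_equal_frequency_on_distinct_values(self):
        bins, _cuts = discretize(np.array([8.0, 1, 5, 3, 7, 2, 6, 4]), n_bins=4)
        assert sorted(np.bincount(bins)) == [2, 2, 2, 2]

    def test_all_ties_collapse_to_single_bin(self):
        values = np.full(8, 3.0)
        bins, _ = discretize(values, n_bins=4)
        assert np.all(bins == 0)

    def test_held_out_value_below_cuts_maps_to_bin_zero(self):
        train = np.array([10.0, 20, 30, 40, 50, 60, 70, 80])
        _bins, cuts = discretize(train, n_bins=4)
        assert apply_bins(cuts, np.array([1.0]))[0] == 0
        assert apply_bins(cuts, np.array([1000.0]))[0] == 3


class TestChi2Merit:
    def test_perfect_binary_feature_merit_equals_train_size(self):
        # 2 classes of 10+10; every 10-fold training split has 18 samples
        values = np.array([[0.0] * 10 + [1.0] * 10])
        panel = make_panel(values, ["a"] * 10 + ["b"] * 10)
        merit = chi2_merit(panel, folds=10, seed=0)
        per_fold = merit.filter(like="fold_").to_numpy()[0]
        np.testing.assert_allclose(per_fold, 18.0)
        assert merit["merit"].iloc[0] == pytest.approx(18.0)

    def test_constant_gene_merit_is_zero(self):
        rng = np.random.default_rng(1)
        values = np.vstack([np.full(20, 7.0), rng.normal(size=20)])
        panel = make_panel(values, ["a"] * 10 + ["b"] * 10)
        merit = chi2_merit(panel, folds=5, seed=0)
        assert merit["merit"].iloc[0] == 0.0

    def test_matches_contingency_oracle(self):
        rng = np.random.default_rng(2)
        labels = ["a"] * 6 + ["b"] * 6 + ["c"] * 6
        values = rng.normal(size=(4, 18))
        panel = make_panel(values, labels)
        folds, seed, n_bins = 3, 5, 4
        merit = chi2_merit(panel, folds=folds, seed=seed, n_bins=n_bins)

        from sklearn.model_selection import StratifiedKFold

        y = np.array(labels)
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        for f, (train, _t) in enumerate(skf.split(values.T, y)):
            for gi in range(4):
                bins, _ = discretize(values[gi, train], n_bins=n_bins)
                table = pd.crosstab(bins, y[train]).to_numpy().astype(float)
                expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
                chi2 = np.sum((table - expected) ** 2 / expected)
                assert merit[f"fold_{f + 1}"].iloc[gi] == pytest.approx(chi2)

    def test_invariant_to_gene_order(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=(6, 20))
        labels = ["a"] * 10 + ["b"] * 10
        m1 = chi2_merit(make_panel(values, labels), folds=5, seed=1)
        perm = [3, 1, 5, 0, 2, 4]
        m2 = chi2_merit(
            make_panel(values[perm], labels, gene_ids=[f"g{i}" for i in perm]),
            folds=5, seed=1,
        )
        for i in perm:
            assert m1.loc[f"g{i}", "merit"] == pytest.approx(m2.loc[f"g{i}", "merit"])

    def test_small_class_suggests_fewer_folds(self):
        panel = make_panel(np.zeros((2, 12)), ["a"] * 9 + ["b"] * 3)
        with pytest.raises(ValueError, match="fewer folds"):
            chi2_merit(panel, folds=10)


class TestSelectSignature:
    def _table(self, merits):
        return pd.DataFrame(
            {"merit": list(merits.values())},
            index=pd.Index(list(merits), name="gene_id"),
        )

    def test_all_below_threshold_gives_empty_list(self):
        assert select_signature(self._table({"a": 10.0, "b": 15.0})) == []

    def test_strict_inequality_and_ordering(self):
        out = select_signature(self._table({"a": 20.0, "b": 15.0, "c": 15.01}))
        assert out == ["a", "c"]

    def test_merit_ties_break_by_gene_id(self):
        out = select_signature(self._table({"z": 16.0, "a": 16.0}))
        assert out == ["a", "z"]

    def test_selection_is_idempotent_in_membership(self):
        table = self._table({"a": 20.0, "b": 17.0, "c": 3.0})
        first = select_signature(table)
        again = select_signature(table.loc[first])
        assert set(first) == set(again)


class TestCrossvalClassify:
    def test_duplicated_samples_with_conflicting_labels_cap_accuracy(self):
        rng = np.random.default_rng(4)
        values = rng.normal(size=(5, 12))
        values[:, 6] = values[:, 0]  # same profile, different class below
        labels = ["a"] * 6 + ["b"] * 6
        panel = make_panel(values, labels)
        acc, _ = crossval_classify(panel, folds=2, seed=0, log_transform=False)
        assert acc < 1.0

    def test_non_finite_feature_raises(self):
        values = np.ones((2, 12))
        values[0, 0] = np.nan
        panel_df = pd.DataFrame(values, index=["g0", "g1"],
                                columns=[f"s{j}" for j in range(12)])
        from aerlnc.models import ExpressionPanel
        with pytest.raises(ValueError, match="missing"):
            ExpressionPanel(panel_df, {f"s{j}": "a" for j in range(12)})

    def test_confusion_matrix_totals(self):
        rng = np.random.default_rng(5)
        centers = {"a": 0.0, "b": 6.0}
        labels = ["a"] * 10 + ["b"] * 10
        values = np.vstack(
            [rng.normal([centers[l] for l in labels], 1.0) for _ in range(5)]
        )
        panel = make_panel(values, labels)
        acc, cm = crossval_classify(panel, folds=5, seed=0, log_transform=False)
        assert cm.to_numpy().sum() == 20
        assert acc == np.trace(cm.to_numpy()) / 20


def ward_oracle(points):
    """Naive Lance-Williams Ward.D2 on raw points; heights on the
    distance scale."""
    n = len(points)
    d2 = squareform(pdist(points)) ** 2
    active = {i: [i] for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    d2 = {(i, j): d2[i, j] for i in range(n) for j in range(i + 1, n)}
    merges = []
    next_id = n
    while len(active) > 1:
        (i, j), val = min(d2.items(), key=lambda kv: (kv[1], kv[0]))
        merges.append(np.sqrt(val))
        ni, nj = sizes[i], sizes[j]
        new = {}
        for k in active:
            if k in (i, j):
                continue
            nk = sizes[k]
            dik = d2[tuple(sorted((i, k)))]
            djk = d2[tuple(sorted((j, k)))]
            dij = d2[(i, j)]
            new[k] = ((ni + nk) * dik + (nj + nk) * djk - nk * dij) / (ni + nj + nk)
        members = active.pop(i) + active.pop(j)
        for key in [k for k in d2 if i in k or j in k]:
            del d2[key]
        active[next_id] = members
        sizes[next_id] = ni + nj
        for k, v in new.items():
            d2[tuple(sorted((k, next_id)))] = v
        next_id += 1
    return np.array(merges)


class TestHierarchicalCluster:
    def test_two_separated_clouds_perfect_purity(self):
        rng = np.random.default_rng(6)
        values = np.hstack([rng.normal(0, 0.1, size=(4, 8)), rng.normal(50, 0.1, size=(4, 8))])
        panel = make_panel(values + 100, ["a"] * 8 + ["b"] * 8)
        _Z, _assign, purity = hierarchical_cluster(panel, k=2)
        assert purity == 1.0

    def test_duplicated_sample_merges_first_at_zero_height(self):
        rng = np.random.default_rng(7)
        values = rng.uniform(1, 10, size=(3, 6))
        values[:, 5] = values[:, 2]
        panel = make_panel(values, ["a"] * 6)
        Z, _a, _p = hierarchical_cluster(panel, k=2)
        assert Z[0, 2] == 0.0
        assert {int(Z[0, 0]), int(Z[0, 1])} == {2, 5}

    def test_six_point_dendrogram_matches_lance_williams_oracle(self):
        rng = np.random.default_rng(8)
        values = rng.uniform(1, 20, size=(2, 6))
        panel = make_panel(values, ["a"] * 6)
        Z, _a, _p = hierarchical_cluster(panel, k=2, log_transform=False)
        expected = ward_oracle(values.T)
        np.testing.assert_allclose(np.sort(Z[:, 2]), np.sort(expected), rtol=1e-10)

    def test_purity_definition(self):
        assert cluster_purity([1, 1, 2, 2], ["a", "a", "a", "b"]) == 0.75


class TestPca:
    def test_collinear_genes_put_all_variance_on_pc1(self):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        panel = make_panel(np.vstack([base, 2 * base]), ["a"] * 4)
        _scores, evr = pca(panel)
        assert evr[0] == pytest.approx(1.0)

    def test_ratios_sum_to_one(self):
        rng = np.random.default_rng(9)
        panel = make_panel(rng.uniform(1, 5, size=(5, 10)), ["a"] * 10)
        _scores, evr = pca(panel)
        assert evr.sum() == pytest.approx(1.0)

    def test_scores_match_covariance_eigendecomposition(self):
        rng = np.random.default_rng(10)
        values = rng.normal(size=(3, 4))  # 3 genes x 4 samples
        panel = make_panel(values, ["a"] * 4)
        scores, evr = pca(panel)
        X = values.T - values.T.mean(axis=0)
        cov = X.T @ X
        w, v = np.linalg.eigh(cov)
        order = np.argsort(w)[::-1]
        w, v = w[order], v[:, order]
        np.testing.assert_allclose(evr[: len(w)], w / w.sum(), atol=1e-10)
        proj = X @ v
        np.testing.assert_allclose(
            np.abs(scores.to_numpy()[:, :3]), np.abs(proj), atol=1e-10
        )
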