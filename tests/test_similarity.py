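import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from gxp.errors import ValidationError
from gxp.similarity import (
    DistanceMatrix,
    correlation_distance,
    euclidean_distance,
    heatmap_result,
    hierarchical_cluster,
    pca_plot_spec,
    render_heatmap_svg,
    render_scatter_svg,
    run_pca,
    z_transform,
)
from gxp.tables_io import parse_sample_name
from oracles import agglomerate_reference, pca_eigh_reference


class TestZTransform:
    def test_simple_row(self):
        z = z_transform(np.array([[1.0, 2.0, 3.0]]))
        assert z.values[0].tolist() == [-1.0, 0.0, 1.0]
        assert not z.constant_rows[0]

    def test_constant_row_zeroed_and_flagged(self):
        z = z_transform(np.array([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]]))
        assert z.values[0].tolist() == [0.0, 0.0, 0.0]
        assert z.constant_rows.tolist() == [True, False]

    def test_random_rows_standardized(self):
        rng = np.random.default_rng(1)
        z = z_transform(rng.normal(size=(50, 10)))
        assert np.allclose(z.values.mean(axis=1), 0.0, atol=1e-9)
        assert np.allclose(z.values.std(axis=1, ddof=1), 1.0, atol=1e-9)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValidationError):
            z_transform(np.empty((0, 0)))


class TestCorrelationDistance:
    def test_self_correlation_zero_distance(self):
        x = np.array([1.0, 2.0, 4.0, 3.0])
        dm = correlation_distance(np.column_stack([x, x]), ["a", "b"])
        assert dm.C[0, 1] == pytest.approx(1.0)
        assert dm.D[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelation_is_maximum_likeness(self):
        x = np.array([1.0, 2.0, 4.0, 3.0])
        dm = correlation_distance(np.column_stack([x, -x]), ["a", "b"])
        assert dm.C[0, 1] == pytest.approx(-1.0)
        assert dm.D[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_pearson(self):
        # c = 0.8 computed by hand from the definition
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 3.0, 2.0, 4.0])
        dm = correlation_distance(np.column_stack([x, y]), ["x", "y"])
        assert dm.C[0, 1] == pytest.approx(0.8, abs=1e-12)
        assert dm.D[0, 1] == pytest.approx(0.2, abs=1e-12)

    def test_constant_vector_error_names_label(self):
        M = np.column_stack([np.ones(4), np.arange(4.0)])
        with pytest.raises(ValidationError, match="flatliner"):
            correlation_distance(M, ["flatliner", "ok"])

    def test_entities_orientation_transposes(self):
        rng = np.random.default_rng(2)
        M = rng.normal(size=(3, 8))
        d1 = correlation_distance(M, ["a", "b", "c"], orientation="entities")
        d2 = correlation_distance(M.T, ["a", "b", "c"], orientation="samples")
        assert np.allclose(d1.D, d2.D)

    def test_spearman_option_rank_based(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 10.0, 100.0, 1000.0])  # monotone, nonlinear
        dm = correlation_distance(np.column_stack([x, y]), ["x", "y"], method="spearman")
        assert dm.C[0, 1] == pytest.approx(1.0)

    @given(
        arrays(
            np.float64,
            (5,),
            elements=st.floats(min_value=-50, max_value=50, allow_nan=False),
        ).filter(lambda v: np.std(v) > 1e-6)
    )
    @settings(max_examples=100, deadline=None)
    def test_distance_properties(self, x):
        M = np.column_stack([x, -x, x * 2 + 1])
        dm = correlation_distance(M, ["a", "b", "c"])
        assert np.all(dm.D >= -1e-12)
        assert np.all(dm.D <= 1 + 1e-12)
        assert dm.D[0, 1] == pytest.approx(0.0, abs=1e-9)
        assert dm.D[0, 2] == pytest.approx(0.0, abs=1e-9)


class TestEuclideanDistance:
    def test_three_four_five(self):
        M = np.column_stack([[0.0, 0.0], [3.0, 4.0]])
        dm = euclidean_distance(M, ["o", "p"])
        assert dm.D[0, 1] == pytest.approx(5.0)
        assert dm.C is None

    def test_identical_vectors(self):
        x = np.arange(4.0)
        dm = euclidean_distance(np.column_stack([x, x]), ["a", "b"])
        assert dm.D[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_matches_naive_loop(self):
        rng = np.random.default_rng(3)
        M = rng.normal(size=(6, 5))
        dm = euclidean_distance(M, [f"s{i}" for i in range(5)])
        for i in range(5):
            for k in range(5):
                naive = np.sqrt(np.sum((M[:, i] - M[:, k]) ** 2))
                assert dm.D[i, k] == pytest.approx(naive, abs=1e-12)


class TestHierarchicalCluster:
    def test_two_leaves(self):
        dm = DistanceMatrix(["a", "b"], "euclidean", np.array([[0.0, 3.0], [3.0, 0.0]]))
        dend = hierarchical_cluster(dm)
        assert len(dend.merges) == 1
        assert dend.merges[0].height == 3.0

    def test_forced_geometry_single_linkage(self):
        pts = np.array([[0.0, 1.0, 10.0]])
        dm = euclidean_distance(pts, ["a", "b", "c"])
        dend = hierarchical_cluster(dm, "single")
        first = dend.merges[0]
        assert {first.left, first.right} == {0, 1}
        assert first.height == pytest.approx(1.0)

    @pytest.mark.parametrize("linkage", ["single", "complete", "average"])
    def test_matches_bruteforce_reference(self, linkage):
        rng = np.random.default_rng(4)
        for _ in range(30):
            n = int(rng.integers(2, 7))
            A = rng.uniform(0.1, 5.0, size=(n, n))
            D = (A + A.T) / 2
            np.fill_diagonal(D, 0.0)
            dm = DistanceMatrix([f"l{i}" for i in range(n)], "euclidean", D)
            dend = hierarchical_cluster(dm, linkage)
            ref = agglomerate_reference(D, linkage)
            got = [(m.left, m.right, m.height) for m in dend.merges]
            for (gl, gr, gh), (rl, rr, rh) in zip(got, ref):
                assert {gl, gr} == {rl, rr}
                assert gh == pytest.approx(rh, abs=1e-9)

    def test_ward_matches_scipy(self):
        scipy_hier = pytest.importorskip("scipy.cluster.hierarchy")
        from scipy.spatial.distance import pdist, squareform

        rng = np.random.default_rng(5)
        X = rng.normal(size=(7, 3))
        D = squareform(pdist(X))
        dm = DistanceMatrix([f"l{i}" for i in range(7)], "euclidean", D)
        dend = hierarchical_cluster(dm, "ward")
        Z = scipy_hier.linkage(pdist(X), method="ward")
        assert np.allclose(sorted(m.height for m in dend.merges), sorted(Z[:, 2]), atol=1e-9)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(6)
        A = rng.uniform(0.1, 5.0, size=(5, 5))
        D = (A + A.T) / 2
        np.fill_diagonal(D, 0.0)
        labels = [f"l{i}" for i in range(5)]
        dend1 = hierarchical_cluster(DistanceMatrix(labels, "euclidean", D), "average")
        perm = [3, 0, 4, 1, 2]
        Dp = D[np.ix_(perm, perm)]
        dend2 = hierarchical_cluster(
            DistanceMatrix([labels[i] for i in perm], "euclidean", Dp), "average"
        )
        h1 = sorted(m.height for m in dend1.merges)
        h2 = sorted(m.height for m in dend2.merges)
        assert np.allclose(h1, h2)
        s1 = {frozenset(x) for x in map(frozenset, map(set, [dend1.root_split()[0], dend1.root_split()[1]]))}
        s2 = {frozenset(x) for x in map(frozenset, map(set, [dend2.root_split()[0], dend2.root_split()[1]]))}
        assert s1 == s2

    def test_single_item_rejected(self):
        dm = DistanceMatrix(["a", "b"], "euclidean", np.zeros((2, 2)))
        with pytest.raises(ValidationError):
            hierarchical_cluster(
                DistanceMatrix(["a"], "euclidean", np.zeros((1, 1)))
            )

    def test_newick_parses_with_dendropy(self):
        dendropy = pytest.importorskip("dendropy")
        rng = np.random.default_rng(7)
        A = rng.uniform(0.1, 5.0, size=(5, 5))
        D = (A + A.T) / 2
        np.fill_diagonal(D, 0.0)
        dm = DistanceMatrix([f"leaf {i}" for i in range(5)], "euclidean", D)
        nwk = hierarchical_cluster(dm).to_newick()
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        assert {t.label for t in tree.taxon_namespace} == set(dm.labels)


class TestHeatmap:
    def _dm(self, n=5, seed=8):
        rng = np.random.default_rng(seed)
        M = rng.normal(size=(10, n))
        return correlation_distance(M, [f"s{i}" for i in range(n)])

    def test_leaf_order_is_permutation(self):
        dm = self._dm()
        hm = heatmap_result(dm, hierarchical_cluster(dm))
        assert sorted(hm.labels) == sorted(dm.labels)

    def test_heatmap_shows_correlation_values(self):
        dm = self._dm()
        dend = hierarchical_cluster(dm)
        hm = heatmap_result(dm, dend)
        order = [dm.labels.index(l) for l in hm.labels]
        assert np.allclose(hm.values, dm.C[np.ix_(order, order)])
        assert hm.value_kind == "correlation"

    def test_symmetry_preserved(self):
        dm = self._dm()
        hm = heatmap_result(dm, hierarchical_cluster(dm))
        assert np.allclose(hm.values, hm.values.T)

    def test_svg_has_scale(self):
        dm = self._dm()
        hm = heatmap_result(dm, hierarchical_cluster(dm))
        svg = render_heatmap_svg(hm)
        assert 'class="scale-cell"' in svg
        assert svg.count('class="heat-cell"') == len(dm.labels) ** 2

    def test_golden_file(self, datadir_golden):
        dm = self._dm(n=4, seed=99)
        hm = heatmap_result(dm, hierarchical_cluster(dm))
        svg = render_heatmap_svg(hm)
        assert svg == datadir_golden("golden_heatmap.svg", svg)


class TestPCA:
    def test_rank_one_data_pc1_is_everything(self):
        t = np.linspace(0, 1, 6)
        X = np.outer(t, np.array([1.0, -2.0, 0.5]))
        res = run_pca(X)
        assert res.explained_fraction[0] == pytest.approx(1.0)

    def test_fractions_sum_to_one_and_decrease(self):
        rng = np.random.default_rng(9)
        res = run_pca(rng.normal(size=(20, 6)))
        assert sum(res.explained_fraction) == pytest.approx(1.0, abs=1e-9)
        assert all(
            a >= b - 1e-12
            for a, b in zip(res.explained_fraction, res.explained_fraction[1:])
        )

    def test_matches_covariance_eigendecomposition(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(20, 6))
        res = run_pca(X)
        w, ref_scores = pca_eigh_reference(X)
        total = w.sum()
        assert np.allclose(res.explained_fraction, w / total, atol=1e-9)
        for k in range(6):
            s = res.scores[:, k]
            r = ref_scores[:, k]
            assert np.allclose(s, r, atol=1e-9) or np.allclose(s, -r, atol=1e-9)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(12, 4))
        r1, r2 = run_pca(X), run_pca(X.copy())
        assert np.allclose(r1.scores, r2.scores)
        for k in range(r1.loadings.shape[0]):
            j = int(np.argmax(np.abs(r1.loadings[k])))
            assert r1.loadings[k, j] > 0

    def test_too_few_observations(self):
        with pytest.raises(ValidationError):
            run_pca(np.ones((1, 3)))


class TestPcaPlot:
    def _keys(self):
        names = [f"a.{x}.{r}" for x in ("ctrl", "cold") for r in (1, 2)]
        return [parse_sample_name(n) for n in names]

    def _res(self):
        rng = np.random.default_rng(12)
        return run_pca(rng.normal(size=(4, 5)))

    def test_replicates_share_color_class(self):
        spec = pca_plot_spec(self._res(), self._keys())
        classes = {}
        for p in spec.points:
            classes.setdefault(p.color_class, set()).add(p.color)
        assert all(len(colors) == 1 for colors in classes.values())
        assert len(spec.color_classes) == 2

    def test_axis_labels_carry_percentages(self):
        res = self._res()
        spec = pca_plot_spec(res, self._keys())
        assert f"{res.explained_fraction[0] * 100:.1f}%" in spec.x_label
        assert f"{res.explained_fraction[1] * 100:.1f}%" in spec.y_label

    def test_scatter_svg_point_count(self):
        spec = pca_plot_spec(self._res(), self._keys())
        svg = render_scatter_svg(spec)
        assert svg.count('class="pca-point"') == 4
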