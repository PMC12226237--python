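import numpy as np
import pytest

from adnapop.pca import (
    PcaModel,
    Projection,
    cline_fraction,
    fit_pca,
    project,
    project_reference,
    site_diversity,
)
from adnapop.synthetic import PopulationTree, draw_frequencies

from conftest import make_table

TREE = PopulationTree.from_edges([("root", "A", 0.08), ("root", "B", 0.08)])


def two_cluster_reference(n_snps=2000, n_per=25, seed=0):
    rng = np.random.default_rng(seed)
    freqs = draw_frequencies(TREE, n_snps, seed)
    cols, groups = [], []
    for pop in ("A", "B"):
        cols.append(rng.binomial(2, freqs[pop][:, None], size=(n_snps, n_per)).astype(np.int8))
        groups += [pop] * n_per
    return make_table(np.hstack(cols), groups=groups), freqs


class TestFitProject:
    def test_pc1_separates_clusters(self):
        ref, _ = two_cluster_reference()
        model = fit_pca(ref, 2, shrinkage="none")
        pc1 = model.reference_scores[:, 0]
        a, b = pc1[:25], pc1[25:]
        gap = abs(a.mean() - b.mean())
        within = max(a.std(), b.std())
        assert gap > 5 * within

    def test_duplicated_individual_identical_coordinates(self):
        ref, _ = two_cluster_reference(n_snps=500, n_per=10)
        dup = make_table(
            np.hstack([ref.calls, ref.calls[:, :1]]),
            groups=list(ref.individuals["group_label"]) + ["A"],
        )
        model = fit_pca(dup, 2, shrinkage="none")
        np.testing.assert_allclose(
            model.reference_scores[0], model.reference_scores[-1], atol=1e-8
        )

    def test_k_above_rank_rejected(self):
        ref, _ = two_cluster_reference(n_snps=300, n_per=3)
        with pytest.raises(ValueError, match="rank"):
            fit_pca(ref, 10, shrinkage="none")

    def test_self_projection_recovers_coordinates(self):
        """A fully covered reference individual projects onto its own
        PCA coordinates when shrinkage is off."""
        ref, _ = two_cluster_reference(n_snps=800, n_per=12)
        model = fit_pca(ref, 2, shrinkage="none")
        proj = project(model, ref, "ind0", min_snps=100)
        np.testing.assert_allclose(proj.coordinates, model.reference_scores[0], atol=1e-8)

    def test_downsampled_copy_stays_in_cluster(self, rng):
        """A pseudo-haploid copy of a reference individual with 30%
        missingness lands within the cluster radius of the original
        (no shrinkage correction: the original is in the panel)."""
        ref, _ = two_cluster_reference()
        model = fit_pca(ref, 2, shrinkage="none")
        # pseudo-haploidize + downsample individual 0
        calls = ref.calls.copy()
        col = calls[:, 0].astype(float)
        het = col == 1
        col[het] = rng.integers(0, 2, het.sum()) * 2
        col[rng.random(len(col)) < 0.3] = -1
        degraded = make_table(
            np.column_stack([calls, col.astype(np.int8)]),
            groups=list(ref.individuals["group_label"]) + ["A"],
        )
        degraded_model_view = project(model, degraded, f"ind{degraded.n_individuals - 1}", min_snps=100)
        cluster = model.reference_scores[:25]
        radius = np.linalg.norm(cluster - cluster.mean(axis=0), axis=1).max()
        dist = np.linalg.norm(degraded_model_view.coordinates - model.reference_scores[0])
        assert dist < radius

    def test_too_few_snps_refused(self):
        ref, _ = two_cluster_reference(n_snps=400, n_per=10)
        model = fit_pca(ref, 2, shrinkage="none")
        sparse = ref.calls.copy()
        sparse[10:, 0] = -1
        tab = make_table(sparse, groups=list(ref.individuals["group_label"]))
        with pytest.raises(ValueError, match="covered SNPs"):
            project(model, tab, "ind0", min_snps=100)

    def test_projection_is_linear(self, rng):
        """Projecting the average of two complete genotype rows gives
        the average of their projections."""
        ref, _ = two_cluster_reference(n_snps=600, n_per=10)
        model = fit_pca(ref, 2, shrinkage="none")
        # two complete pseudo-haploid rows (0/2) average to integral dosages
        c0 = (rng.random(600) < 0.4).astype(np.int8) * 2
        c1 = (rng.random(600) < 0.6).astype(np.int8) * 2
        blend = ((c0 + c1) // 2).astype(np.int8)
        tab = make_table(
            np.column_stack([ref.calls, c0, c1, blend]),
            groups=list(ref.individuals["group_label"]) + ["x", "x", "x"],
        )
        n = tab.n_individuals
        p0 = project(model, tab, f"ind{n - 3}", min_snps=10).coordinates
        p1 = project(model, tab, f"ind{n - 2}", min_snps=10).coordinates
        pm = project(model, tab, f"ind{n - 1}", min_snps=10).coordinates
        np.testing.assert_allclose(pm, (p0 + p1) / 2.0, atol=1e-8)

    def test_save_load_roundtrip(self, tmp_path):
        ref, _ = two_cluster_reference(n_snps=300, n_per=8)
        model = fit_pca(ref, 2, shrinkage="none")
        model.save(tmp_path / "pca")
        back = PcaModel.load(tmp_path / "pca")
        np.testing.assert_allclose(back.loadings, model.loadings, atol=1e-12)
        proj = project(back, ref, "ind0", min_snps=10)
        np.testing.assert_allclose(proj.coordinates, model.reference_scores[0], atol=1e-6)


def proj(x, y, iid="p"):
    return Projection(iid, np.array([x, y], dtype=float))


class TestCline:
    A = [proj(0, 0), proj(0.2, -0.1), proj(-0.2, 0.1)]
    B = [proj(4, 3), proj(3.8, 3.1), proj(4.2, 2.9)]

    def test_endpoints(self):
        assert cline_fraction(proj(0, 0), self.A, self.B).fraction_b == pytest.approx(0.0)
        assert cline_fraction(proj(4, 3), self.A, self.B).fraction_b == pytest.approx(1.0)

    def test_midpoint(self):
        assert cline_fraction(proj(2, 1.5), self.A, self.B).fraction_b == pytest.approx(0.5)

    def test_clamped(self):
        assert cline_fraction(proj(-10, -10), self.A, self.B).fraction_b == 0.0
        assert cline_fraction(proj(40, 30), self.A, self.B).fraction_b == 1.0

    def test_coincident_centroids_rejected(self):
        with pytest.raises(ValueError):
            cline_fraction(proj(1, 1), self.A, self.A)

    def test_small_clusters_rejected(self):
        with pytest.raises(ValueError):
            cline_fraction(proj(1, 1), [proj(0, 0)], self.B)


class TestSiteDiversity:
    def test_identical_points_zero(self):
        pts = [proj(1, 2) for _ in range(10)]
        assert site_diversity(pts) == 0.0

    def test_3_4_5_triangle(self):
        pts = [proj(0, 0), proj(3, 0), proj(0, 4)]
        assert site_diversity(pts, min_individuals=3) == pytest.approx(4.0)

    def test_rotation_invariance_and_scaling(self, rng):
        pts = rng.normal(size=(12, 2))
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        d0 = site_diversity([Projection("x", p) for p in pts])
        d1 = site_diversity([Projection("x", rot @ p) for p in pts])
        d2 = site_diversity([Projection("x", 3.0 * p) for p in pts])
        assert d1 == pytest.approx(d0)
        assert d2 == pytest.approx(3.0 * d0)

    def test_below_gate_skipped_with_warning(self):
        with pytest.warns(UserWarning):
            assert site_diversity([proj(0, 0)] * 4, min_individuals=10) is None

    def test_mixed_site_more_diverse_than_uniform_site(self):
        """Sites mixing two ancestries spread wider in PC space than
        single-source sites of the same size."""
        ref, freqs = two_cluster_reference()
        model = fit_pca(ref, 2, shrinkage="none")
        refs = project_reference(model, ref)
        uniform = refs[:10]
        mixed = refs[20:25] + refs[25:30]
        assert site_diversity(mixed, 10) > site_diversity(uniform, 10)
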