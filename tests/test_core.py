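"""Similarity-test core: taxon matching, projection, component tests, omnibus."""

import numpy as np
import pytest

from starmaps import (
    CompareSettings,
    CountTable,
    compare,
    cos_theta,
    default_ilr_basis,
    fit_projection,
    group_direction,
    match_taxa,
    project,
    pseudo_f,
)
from starmaps.compositions import clr_transform, dirichlet_point_estimate
from starmaps.core import _fit_pca, _taxon_matching_null

from conftest import build_table


class TestMatchTaxa:
    def t(self, names, counts, groups=("g1", "g1")):
        samples = [f"x{i}" for i in range(len(groups))]
        return CountTable(list(names), samples, np.asarray(counts), dict(zip(samples, groups)))

    def test_partial_overlap(self):
        ds1 = self.t(["A", "B", "C"], [[1, 1], [2, 2], [3, 3]])
        ds2 = CountTable(["B", "C", "D"], ["y0", "y1"], np.array([[4, 4], [5, 5], [6, 6]]),
                         {"y0": "g1", "y1": "g1"})
        pair = match_taxa(ds1, ds2)
        assert pair.union_taxa == ["A", "B", "C", "D"]
        assert pair.presence == ["ds1_only", "both", "both", "ds2_only"]
        np.testing.assert_array_equal(pair.ds1.counts[3], 0)
        np.testing.assert_array_equal(pair.ds2.counts[0], 0)
        np.testing.assert_array_equal(pair.ds2.counts[1], [4, 4])

    def test_identical_sets(self):
        ds1 = self.t(["A", "B"], [[1, 2], [3, 4]])
        ds2 = CountTable(["A", "B"], ["y0", "y1"], np.array([[5, 6], [7, 8]]),
                         {"y0": "g1", "y1": "g1"})
        pair = match_taxa(ds1, ds2)
        assert pair.presence == ["both", "both"]
        np.testing.assert_array_equal(pair.ds1.counts, ds1.counts)
        np.testing.assert_array_equal(pair.ds2.counts, ds2.counts)

    def test_disjoint_sets(self):
        ds1 = self.t(["A", "B", "C"], np.ones((3, 2), dtype=int))
        ds2 = CountTable(["D", "E", "F", "G"], ["y0", "y1"], np.ones((4, 2), dtype=int),
                         {"y0": "g1", "y1": "g1"})
        pair = match_taxa(ds1, ds2)
        assert len(pair.union_taxa) == 7
        assert pair.n_shared == 0
        assert np.count_nonzero(pair.ds1.counts.sum(axis=1)) == 3
        assert np.count_nonzero(pair.ds2.counts.sum(axis=1)) == 4


class TestProjection:
    def test_projecting_ds1_reproduces_scores1(self, separated_pair):
        pair = match_taxa(separated_pair.ds1, separated_pair.ds2)
        model, scores1 = fit_projection(pair, seed=3)
        again = project(model, pair, which="ds1", seed=3)
        np.testing.assert_allclose(again, scores1, atol=1e-12)

    def test_self_projection_identical(self, separated_pair):
        pair = match_taxa(separated_pair.ds1, separated_pair.ds1)
        model, scores1 = fit_projection(pair, seed=3)
        scores2 = project(model, pair, which="ds2", seed=3)
        np.testing.assert_array_equal(scores1, scores2)

    def test_score_covariance_is_diagonal_eigenvalues(self, separated_pair):
        pair = match_taxa(separated_pair.ds1, separated_pair.ds2)
        model, scores1 = fit_projection(pair, seed=3)
        cov = scores1.T @ scores1 / (scores1.shape[0] - 1)
        np.testing.assert_allclose(cov, np.diag(model.eigenvalues), atol=1e-8)
        assert np.all(np.diff(model.eigenvalues) <= 1e-12)

    def test_total_variance_preserved(self, separated_pair):
        pair = match_taxa(separated_pair.ds1, separated_pair.ds2)
        comp1 = dirichlet_point_estimate(pair.ds1, seed=3)
        basis = default_ilr_basis(len(pair.union_taxa))
        ilr1 = clr_transform(comp1) @ basis
        model = _fit_pca(ilr1, basis)
        total_ilr = ((ilr1 - ilr1.mean(axis=0)) ** 2).sum()
        total_scores = (model.transform(ilr1) ** 2).sum()
        assert abs(total_scores - total_ilr) < 1e-6 * total_ilr

    def test_rotation_is_orthonormal(self, separated_pair):
        pair = match_taxa(separated_pair.ds1, separated_pair.ds2)
        model, _ = fit_projection(pair, seed=3)
        r = model.rotation
        np.testing.assert_allclose(r.T @ r, np.eye(r.shape[1]), atol=1e-9)
        assert model.n_axes <= min(pair.ds1.n_samples - 1, len(pair.union_taxa) - 1)

    def test_sample_at_center_maps_to_origin(self, separated_pair):
        pair = match_taxa(separated_pair.ds1, separated_pair.ds2)
        model, _ = fit_projection(pair, seed=3)
        np.testing.assert_allclose(model.transform(model.center[None, :]), 0.0, atol=1e-9)


class TestDirections:
    def test_direction_is_centroid_difference(self):
        scores = np.array([[0, 0], [0, 0], [1, 0], [1, 0]], dtype=float)
        d = group_direction(scores, ["A", "A", "B", "B"], ("A", "B"))
        np.testing.assert_allclose(d, [1, 0])
        d_swapped = group_direction(scores, ["A", "A", "B", "B"], ("B", "A"))
        np.testing.assert_allclose(d_swapped, [-1, 0])

    def test_single_sample_groups(self):
        scores = np.array([[1.0, 2.0], [4.0, 6.0]])
        d = group_direction(scores, ["A", "B"], ("A", "B"))
        np.testing.assert_allclose(d, [3, 4])

    def test_unknown_group(self):
        with pytest.raises(ValueError):
            group_direction(np.zeros((2, 2)), ["A", "B"], ("A", "C"))

    def test_cos_theta_values(self):
        v = np.array([1.0, 2.0, 3.0])
        assert cos_theta(v, v) == 1.0
        assert cos_theta(v, -v) == -1.0
        assert abs(cos_theta([1, 0], [0, 1])) < 1e-12
        assert np.isnan(cos_theta([0, 0], [1, 0]))
        assert abs(cos_theta([1, 0], [1, 1]) - 1 / np.sqrt(2)) < 1e-12


def compare_settings(**kw):
    base = dict(n_perm=500, n_boot=500, n_draws=200)
    base.update(kw)
    return CompareSettings(**base)


class TestCompare:
    def test_omnibus_is_max_of_components(self, separated_pair):
        res = compare(separated_pair.ds1, separated_pair.ds2, ("g1", "g2"), ("g1", "g2"),
                      seed=5, settings=compare_settings())
        assert res.omnibus_p == max(res.p1, res.p2, res.p3)
        assert res.p2 == max(res.p2_sample, res.p2_taxon)
        assert -1 <= res.cos_theta <= 1

    def test_similar_pair_detected(self, separated_pair):
        res = compare(separated_pair.ds1, separated_pair.ds2, ("g1", "g2"), ("g1", "g2"),
                      seed=5, settings=compare_settings())
        assert res.omnibus_p < 0.05
        assert res.cos_theta > 0.5

    def test_self_similarity_cosine_is_exactly_one(self, separated_pair):
        res = compare(separated_pair.ds1, separated_pair.ds1, ("g1", "g2"), ("g1", "g2"),
                      seed=5, settings=compare_settings())
        assert res.cos_theta == 1.0
        assert res.p1 <= 0.05 and res.p2_sample <= 0.05 and res.p3 <= 0.05

    def test_swapped_groups_negate_cosine(self, separated_pair):
        res = compare(separated_pair.ds1, separated_pair.ds1, ("g1", "g2"), ("g2", "g1"),
                      seed=5, settings=compare_settings())
        assert res.cos_theta == -1.0

    def test_exhaustive_p_support(self, small_template):
        """n = 2+2 per dataset: exhaustive p values live on the {k/6} lattice
        and, by complementary-assignment ties, k is even."""
        from starmaps import SimulationSpec, simulate_pair

        spec = SimulationSpec(n_per_group=2, log2fc_mean=4.0, template=small_template,
                              seed=31, n_pairs=1)
        pair = simulate_pair(spec, "similar", seed=31)
        res = compare(pair.ds1, pair.ds2, ("g1", "g2"), ("g1", "g2"), seed=5,
                      settings=compare_settings())
        assert res.settings["mode_test1"] == "exhaustive"
        assert res.p1 in {2 / 6, 4 / 6, 1.0}

    def test_sample_order_invariance(self, separated_pair):
        ds2 = separated_pair.ds2
        perm = np.random.default_rng(0).permutation(ds2.n_samples)
        shuffled = CountTable(list(ds2.taxon_ids), [ds2.sample_ids[j] for j in perm],
                              ds2.counts[:, perm], dict(ds2.groups))
        st = compare_settings(n_perm=2000)  # exhaustive for N=6 (924 assignments)
        a = compare(separated_pair.ds1, ds2, ("g1", "g2"), ("g1", "g2"), seed=9, settings=st)
        b = compare(separated_pair.ds1, shuffled, ("g1", "g2"), ("g1", "g2"), seed=9, settings=st)
        assert a.p1 == b.p1 and a.p2_sample == b.p2_sample
        assert a.p2_taxon == b.p2_taxon and a.p3 == b.p3
        assert abs(a.cos_theta - b.cos_theta) < 1e-12

    def test_requires_two_samples_per_group(self, small_template):
        from starmaps import SimulationSpec, simulate_pair

        spec = SimulationSpec(n_per_group=2, log2fc_mean=1.0, template=small_template,
                              seed=41, n_pairs=1)
        pair = simulate_pair(spec, "similar", seed=41)
        ds2 = pair.ds2
        # drop one sample from group g2
        keep = [j for j, s in enumerate(ds2.sample_ids) if s != "bg2_2"]
        crippled = CountTable(list(ds2.taxon_ids), [ds2.sample_ids[j] for j in keep],
                              ds2.counts[:, keep], {s: ds2.groups[s] for s in
                                                    (ds2.sample_ids[j] for j in keep)})
        with pytest.raises(ValueError, match=">= 2 samples"):
            compare(pair.ds1, crippled, ("g1", "g2"), ("g1", "g2"), seed=1,
                    settings=compare_settings())

    def test_n_axes_restriction(self, separated_pair):
        res = compare(separated_pair.ds1, separated_pair.ds2, ("g1", "g2"), ("g1", "g2"),
                      seed=5, settings=compare_settings(n_axes=2))
        assert res.n_axes == 2
        assert res.scores1.shape[1] == 2


class TestBasisInvariance:
    def test_compare_invariant_under_basis_change(self, separated_pair):
        """All P values (exhaustive permutation modes) and cos theta are
        unchanged when the ILR contrast basis is replaced by any other
        orthonormal basis."""
        from scipy.stats import ortho_group

        pair = match_taxa(separated_pair.ds1, separated_pair.ds2)
        d = len(pair.union_taxa)
        q = ortho_group.rvs(d - 1, random_state=7)
        alt_basis = default_ilr_basis(d) @ q
        st1 = compare_settings(n_perm=2000)
        st2 = compare_settings(n_perm=2000, basis=alt_basis)
        a = compare(separated_pair.ds1, separated_pair.ds2, ("g1", "g2"), ("g1", "g2"),
                    seed=13, settings=st1)
        b = compare(separated_pair.ds1, separated_pair.ds2, ("g1", "g2"), ("g1", "g2"),
                    seed=13, settings=st2)
        assert a.settings["mode_test1"] == "exhaustive"
        assert a.p1 == b.p1
        assert a.p2_sample == b.p2_sample
        assert a.p2_taxon == b.p2_taxon
        assert a.p3 == b.p3
        assert abs(a.cos_theta - b.cos_theta) < 1e-9


def inverse_ilr_counts(z, basis, depth, rng):
    """Counts from ILR coordinates: softmax(basis @ z) at a large depth."""
    logp = basis @ z
    p = np.exp(logp - logp.max())
    p /= p.sum()
    return rng.multinomial(depth, p)


class TestTaxonMatchingNull:
    def test_orthogonal_separation_not_called_similar(self, small_template):
        """When ds2's group separation lies entirely outside ds1's PC span,
        the taxon-matching null should usually NOT reject: generic structure
        alone, without the specific matching, must not drive the test."""
        from starmaps import SimulationSpec, simulate_pair

        spec = SimulationSpec(n_per_group=6, log2fc_mean=2.0, template=small_template,
                              seed=51, n_pairs=1)
        rng = np.random.default_rng(51)
        big = 0
        n_rep = 30
        for rep in range(n_rep):
            pair_sim = simulate_pair(spec, "similar", seed=600 + rep)
            mp = match_taxa(pair_sim.ds1, pair_sim.ds1)
            comp1 = dirichlet_point_estimate(mp.ds1, n_draws=200, seed=600 + rep)
            basis = default_ilr_basis(len(mp.union_taxa))
            ilr1 = clr_transform(comp1) @ basis
            model = _fit_pca(ilr1, basis)
            # orthonormal complement of ds1's centered span
            span = np.linalg.svd(ilr1 - ilr1.mean(axis=0), full_matrices=True)[2]
            null_space = span[model.n_axes:]
            sep = null_space[0]
            noise_dirs = null_space[1:6]
            mu = ilr1.mean(axis=0)
            cols, ids, groups = [], [], {}
            for j in range(12):
                sign = -1.0 if j < 6 else 1.0
                eps = noise_dirs.T @ rng.normal(0, 0.3, size=noise_dirs.shape[0])
                z = mu + sign * 3.0 * sep + eps
                cols.append(inverse_ilr_counts(z, basis, 200_000, rng))
                sid = f"o{j}"
                ids.append(sid)
                groups[sid] = "g1" if j < 6 else "g2"
            ds2 = CountTable(list(mp.union_taxa), ids, np.array(cols).T, groups)
            mp2 = match_taxa(pair_sim.ds1, ds2)
            comp2 = dirichlet_point_estimate(mp2.ds2, n_draws=200, seed=700 + rep)
            clr2 = clr_transform(comp2)
            scores2 = model.transform(clr2 @ basis)
            f_obs = pseudo_f(scores2, mp2.ds2.labels())
            p_taxon = _taxon_matching_null(clr2, model, mp2.ds2.labels(), f_obs,
                                           n_perm=199, seed=800 + rep)
            big += p_taxon > 0.05
        assert big >= 0.8 * n_rep
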