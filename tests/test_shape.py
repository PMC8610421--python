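"""Shape PCA, Procrustes ANOVA, allometry, subsetting, distances."""

import numpy as np
import pytest

import lumbarmorph as lm
from lumbarmorph.datatypes import ValidationError
from lumbarmorph.shape import pool_genus


class TestSubset:
    def test_core_subset_has_37_landmarks(self, two_group_sim):
        reduced = lm.subset_landmarks(two_group_sim.landmarks, lm.CORE_LANDMARKS)
        assert reduced.n_landmarks == 37

    def test_keep_all_is_identity(self, two_group_sim):
        full = lm.subset_landmarks(
            two_group_sim.landmarks, two_group_sim.landmarks.landmark_labels
        )
        assert full.landmark_labels == two_group_sim.landmarks.landmark_labels
        assert np.array_equal(
            full.as_array(), two_group_sim.landmarks.as_array()
        )

    def test_order_preserved_regardless_of_keep_order(self, two_group_sim):
        labels = two_group_sim.landmarks.landmark_labels
        shuffled = list(labels[:5])[::-1]
        sub = lm.subset_landmarks(two_group_sim.landmarks, shuffled)
        assert sub.landmark_labels == labels[:5]

    def test_empty_keep_rejected(self, two_group_sim):
        with pytest.raises(ValidationError):
            lm.subset_landmarks(two_group_sim.landmarks, [])

    def test_unknown_label_listed(self, two_group_sim):
        with pytest.raises(ValidationError, match="nope"):
            lm.subset_landmarks(two_group_sim.landmarks, ["nope"])


class TestShapePCA:
    def test_identical_configurations_have_zero_variance(self, template):
        arr = np.stack([template.coordinates] * 5)
        res = lm.shape_pca(arr)
        assert np.all(res.eigenvalues < 1e-20)

    def test_score_distances_equal_coordinate_distances(self, two_group_fit):
        """Orthogonal projection preserves pairwise distances."""
        res = lm.shape_pca(two_group_fit)
        flat = two_group_fit.flattened()
        d_flat = np.linalg.norm(flat[:, None] - flat[None, :], axis=-1)
        d_scores = np.linalg.norm(
            res.scores[:, None] - res.scores[None, :], axis=-1
        )
        assert np.allclose(d_flat, d_scores, atol=1e-8)

    def test_total_variance_conserved(self, two_group_fit):
        res = lm.shape_pca(two_group_fit)
        flat = two_group_fit.flattened()
        cov_trace = np.sum(np.var(flat, axis=0, ddof=1))
        assert res.eigenvalues.sum() == pytest.approx(cov_trace, abs=1e-9)
        assert res.variance_proportions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_rank_bound(self, two_group_fit):
        res = lm.shape_pca(two_group_fit)
        n, k = two_group_fit.n_specimens, two_group_fit.n_landmarks
        nonzero = np.sum(res.eigenvalues > 1e-12 * res.eigenvalues[0])
        assert nonzero <= min(n - 1, 3 * k - 7)

    def test_matches_sklearn(self, two_group_fit):
        sklearn = pytest.importorskip("sklearn.decomposition")
        res = lm.shape_pca(two_group_fit)
        p = sklearn.PCA().fit(two_group_fit.flattened())
        m = len(p.explained_variance_)
        assert np.allclose(
            res.eigenvalues[:m], p.explained_variance_, atol=1e-10
        )
        # components agree up to sign
        dots = np.abs(
            np.sum(res.eigenvectors[: m - 1] * p.components_[: m - 1], axis=1)
        )
        assert np.allclose(dots, 1.0, atol=1e-8)

    def test_sign_convention_fixed(self, two_group_fit):
        res = lm.shape_pca(two_group_fit)
        for row in res.eigenvectors:
            assert row[np.argmax(np.abs(row))] >= 0

    def test_two_cluster_separation(self, two_group_sim, two_group_fit):
        """PC1 separates groups generated with a mean-shape offset."""
        res = lm.shape_pca(two_group_fit)
        g = np.array(two_group_fit.groups)
        pc1 = res.scores[:, 0]
        gap = abs(pc1[g == "A"].mean() - pc1[g == "B"].mean())
        within = max(pc1[g == "A"].std(), pc1[g == "B"].std())
        assert gap > 2 * within

    def test_projection_of_fit_data_reproduces_scores(self, two_group_fit):
        res = lm.shape_pca(two_group_fit)
        assert np.allclose(
            res.project(two_group_fit.flattened()), res.scores, atol=1e-10
        )


class TestDistances:
    def test_two_specimens_single_symmetric_distance(self, template):
        arr = np.stack(
            [template.coordinates, template.coordinates * 1.1 + 2.0]
        )
        rng = np.random.default_rng(3)
        arr[1] += rng.normal(0, 0.5, arr[1].shape)
        fit = lm.GeneralizedProcrustes(arr).fit()
        tables = lm.pairwise_procrustes_distances(fit, groups=["a", "a"])
        assert len(tables.within["a"]) == 1
        assert tables.within["a"][0] == pytest.approx(fit.distance(0, 1))

    def test_duplicated_configurations_give_zero_within(self, template):
        arr = np.stack([template.coordinates] * 4)
        fit = lm.GeneralizedProcrustes(arr).fit()
        tables = lm.pairwise_procrustes_distances(fit, groups=["a"] * 4)
        assert np.all(tables.within["a"] < 1e-8)

    def test_between_exceeds_within_under_group_offset(self, two_group_fit):
        tables = lm.pairwise_procrustes_distances(two_group_fit)
        between = np.median(tables.between[("A", "B")])
        assert between > np.median(tables.within["A"])
        assert between > np.median(tables.within["B"])

    def test_singleton_group_flagged_not_fatal(self, two_group_fit):
        groups = ["solo"] + ["rest"] * (two_group_fit.n_specimens - 1)
        tables = lm.pairwise_procrustes_distances(two_group_fit, groups=groups)
        assert "solo" in tables.flagged_groups

    def test_target_specimen_compared_to_each_group(self, two_group_fit):
        sid = two_group_fit.specimen_ids[0]
        tables = lm.pairwise_procrustes_distances(
            two_group_fit, target_specimens=[sid]
        )
        assert (sid, "A") in tables.to_group
        assert (sid, "B") in tables.to_group
        # target excluded from its own group pool
        assert len(tables.to_group[(sid, "A")]) == 14
        summary = tables.summary_table()
        assert set(summary["comparison"]) == {"within", "between", "to_group"}


class TestProcrustesAnova:
    def test_df_partition_for_128_specimens_4_genera(self):
        """1/3/3/120 with total 127, as in a 128-specimen 4-genus design."""
        rng = np.random.default_rng(41)
        taxa = (
            ["Homo sapiens"] * 60
            + ["Pan troglodytes"] * 20
            + ["Pan paniscus"] * 10
            + ["Gorilla gorilla"] * 15
            + ["Gorilla beringei"] * 8
            + ["Pongo pygmaeus"] * 15
        )
        genera = [pool_genus(t) for t in taxa]
        assert sorted(set(genera)) == ["Gorilla", "Homo", "Pan", "Pongo"]
        y = rng.normal(size=(128, 30))
        size = rng.lognormal(5, 0.1, 128)
        res = lm.ProcrustesAnova(y, size, genera).fit(n_perm=49, seed=1)
        assert res.table.loc["size", "Df"] == 1
        assert res.table.loc["group", "Df"] == 3
        assert res.table.loc["size:group", "Df"] == 3
        assert res.table.loc["Residuals", "Df"] == 120
        assert res.table.loc["Total", "Df"] == 127

    def test_ss_matches_per_coordinate_brute_force(self):
        """Sequential SS equal statsmodels type-I ANOVA summed per coordinate."""
        smf = pytest.importorskip("statsmodels.formula.api")
        import pandas as pd

        rng = np.random.default_rng(5)
        n, p = 10, 6
        y = rng.normal(size=(n, p))
        size = rng.uniform(1, 2, n)
        groups = ["a"] * 5 + ["b"] * 5
        res = lm.ProcrustesAnova(y, size, groups).fit(n_perm=9, seed=0)

        # sequential SS in the stated term order: each term's SS is the
        # drop in residual SS when it enters, summed over coordinates
        formulas = [
            "y ~ 1",
            "y ~ size",
            "y ~ size + group",
            "y ~ size + group + size:group",
        ]
        totals = {"size": 0.0, "group": 0.0, "size:group": 0.0, "resid": 0.0}
        for j in range(p):
            df = pd.DataFrame({"y": y[:, j], "size": size, "group": groups})
            rss = [smf.ols(f, data=df).fit().ssr for f in formulas]
            totals["size"] += rss[0] - rss[1]
            totals["group"] += rss[1] - rss[2]
            totals["size:group"] += rss[2] - rss[3]
            totals["resid"] += rss[3]
        for term in ("size", "group", "size:group"):
            assert res.table.loc[term, "SS"] == pytest.approx(
                totals[term], rel=1e-9
            )
        assert res.table.loc["Residuals", "SS"] == pytest.approx(
            totals["resid"], rel=1e-9
        )

    def test_rsq_partition_sums_to_one(self, two_group_fit):
        res = lm.ProcrustesAnova(two_group_fit).fit(n_perm=49, seed=2)
        terms = res.terms + ["Residuals"]
        assert res.table.loc[terms, "Rsq"].sum() == pytest.approx(1.0, abs=1e-9)
        ss = res.table.loc[terms, "SS"].sum()
        assert ss == pytest.approx(res.table.loc["Total", "SS"], abs=1e-9)

    def test_seeded_p_values_reproducible(self, two_group_fit):
        a = lm.ProcrustesAnova(two_group_fit).fit(n_perm=99, seed=7)
        b = lm.ProcrustesAnova(two_group_fit).fit(n_perm=99, seed=7)
        assert a.table.equals(b.table)
        c = lm.ProcrustesAnova(two_group_fit).fit(n_perm=99, seed=8)
        # across seeds p varies within binomial error of n_perm
        for t in a.terms:
            se = np.sqrt(max(a.p_value(t) * (1 - a.p_value(t)), 0.01) / 100)
            assert abs(a.p_value(t) - c.p_value(t)) < 5 * se + 2 / 100

    def test_group_effect_detected(self, two_group_fit):
        res = lm.ProcrustesAnova(two_group_fit).fit(n_perm=199, seed=3)
        assert res.p_value("group") <= 0.01

    def test_constant_size_drops_term(self, two_group_fit):
        n = two_group_fit.n_specimens
        with pytest.warns(RuntimeWarning, match="size term dropped"):
            res = lm.ProcrustesAnova(
                two_group_fit, size=np.ones(n)
            ).fit(n_perm=9, seed=0)
        assert "size" not in res.terms

    def test_single_group_drops_terms(self, two_group_fit):
        n = two_group_fit.n_specimens
        with pytest.warns(RuntimeWarning, match="single group"):
            res = lm.ProcrustesAnova(
                two_group_fit, groups=["only"] * n
            ).fit(n_perm=9, seed=0)
        assert res.terms == ["size"]

    def test_tiny_group_rejected(self, two_group_fit):
        groups = ["solo"] + ["rest"] * (two_group_fit.n_specimens - 1)
        with pytest.raises(ValueError, match="solo"):
            lm.ProcrustesAnova(two_group_fit, groups=groups)

    def test_summary_contains_table(self, two_group_fit):
        res = lm.ProcrustesAnova(two_group_fit).fit(n_perm=19, seed=0)
        text = res.summary()
        assert "Pr(>F)" in text and "Residuals" in text


class TestAllometry:
    def test_two_specimens_interpolated_exactly(self, template):
        rng = np.random.default_rng(9)
        y = rng.normal(size=(2, 12))
        sizes = np.array([1.0, 2.0])
        res = lm.ShapeAllometry(y, sizes).fit()
        for i in range(2):
            assert np.allclose(res.predict(sizes[i]), y[i], atol=1e-10)

    def test_vector_recovery_with_strong_allometry(self, template):
        spec = lm.LandmarkSimSpec(
            group_offset_magnitudes={"A": 0.0},
            n_per_group=60,
            noise_sd=0.01,
            allometry_slope=0.005,
        )
        sim = lm.gen_landmarks(spec, seed=31)
        fit = lm.GeneralizedProcrustes(sim.landmarks).fit()
        fit = fit.rotate_to(template.coordinates)
        res = lm.ShapeAllometry(fit).fit()
        corr = abs(np.dot(res.direction, sim.allometry_vector.ravel()))
        assert corr > 0.95

    def test_null_allometry_not_significant(self, template):
        """With no generated allometry the size term looks like chance."""
        spec = lm.LandmarkSimSpec(
            group_offset_magnitudes={"A": 0.0}, n_per_group=40, noise_sd=0.01
        )
        sim = lm.gen_landmarks(spec, seed=37)
        fit = lm.GeneralizedProcrustes(sim.landmarks).fit()
        n = fit.n_specimens
        res = lm.ProcrustesAnova(
            fit, groups=["a"] * (n // 2) + ["b"] * (n - n // 2)
        ).fit(n_perm=199, seed=38)
        assert res.p_value("size") > 0.05
        # projection on an independent fixed direction is uncorrelated
        rng = np.random.default_rng(39)
        v = rng.normal(size=fit.n_landmarks * 3)
        v /= np.linalg.norm(v)
        scores = (fit.flattened() - fit.flattened().mean(0)) @ v
        assert abs(np.corrcoef(scores, fit.centroid_sizes)[0, 1]) < 0.2

    def test_scores_are_projection_onto_unit_vector(self, two_group_fit):
        res = lm.ShapeAllometry(two_group_fit).fit()
        flat = two_group_fit.flattened()
        manual = (flat - flat.mean(0)) @ res.direction
        assert np.allclose(manual, res.scores, atol=1e-12)
        assert np.linalg.norm(res.direction) == pytest.approx(1.0, abs=1e-12)

    def test_zero_size_variance_rejected(self, two_group_fit):
        n = two_group_fit.n_specimens
        with pytest.raises(ValueError, match="variance"):
            lm.ShapeAllometry(two_group_fit, size=np.ones(n))


@pytest.mark.parametrize(
    "taxon,genus",
    [
        ("Pan troglodytes", "Pan"),
        ("Pan paniscus", "Pan"),
        ("Gorilla beringei", "Gorilla"),
        ("Homo sapiens", "Homo"),
        ("Pongo abelii", "Pongo"),
        ("Australopithecus sediba", "Australopithecus sediba"),
    ],
)
def test_pool_genus(taxon, genus):
    assert pool_genus(taxon) == genus
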