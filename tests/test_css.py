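"""CSS statistic, stratified permutation null, FDR, outlier PCA, trait fits."""

import numpy as np
import pandas as pd
import pytest

import lakescan as lk
from lakescan.css import n_stratified_assignments


def _design_from(meta, lakes, n_perm=1000, seed=0, min_snps=24):
    g1 = meta.loc[
        (meta["ecomorph"] == "Balchen") & meta["lake"].isin(lakes), "sample"
    ].tolist()
    g2 = meta.loc[
        (meta["ecomorph"] == "Albeli") & meta["lake"].isin(lakes), "sample"
    ].tolist()
    strata = {
        lake: meta.loc[meta["lake"] == lake, "sample"].tolist()
        for lake in lakes
    }
    return lk.ContrastDesign(
        g1, g2, strata, n_permutations=n_perm, min_snps=min_snps, seed=seed
    )


class TestCssWindow:
    def test_identical_individuals_score_zero(self):
        dos = np.ones((8, 5), dtype=np.int8)
        assert lk.css_window(dos, np.arange(4), np.arange(4, 8)) == 0.0

    def test_single_snp_hand_value(self):
        # group1 dosages {0,0}, group2 {2,2}: between mean 2, withins 0
        dos = np.array([[0], [0], [2], [2]], dtype=np.int8)
        assert lk.css_window(dos, [0, 1], [2, 3]) == pytest.approx(2.0)

    def test_unequal_groups_hand_value(self):
        # 1 SNP, group1 {0,0,2}, group2 {2,2}: d = |diff| / 1 SNP
        # between pairs: (0-2)x4, (2-2)x2 -> mean 8/6; within1 mean 8/6... wait
        # within1 pairs: (0,0)=0,(0,2)=2,(0,2)=2 -> mean 4/3; within2: 0
        # CSS = 8/6 - (3*(4/3) + 2*0)/5 = 4/3 - 4/5
        dos = np.array([[0], [0], [2], [2], [2]], dtype=np.int8)
        got = lk.css_window(dos, [0, 1, 4], [2, 3])
        assert got == pytest.approx(4 / 3 - (3 * (4 / 3)) / 5)

    def test_invariant_to_snp_order_and_group_swap(self):
        rng = np.random.default_rng(2)
        dos = rng.integers(0, 3, size=(12, 30)).astype(np.int8)
        g1, g2 = np.arange(6), np.arange(6, 12)
        base = lk.css_window(dos, g1, g2)
        shuffled = dos[:, rng.permutation(30)]
        assert lk.css_window(shuffled, g1, g2) == pytest.approx(base, abs=1e-9)
        assert lk.css_window(dos, g2, g1) == pytest.approx(base, abs=1e-9)

    def test_small_group_rejected(self):
        dos = np.zeros((3, 2), dtype=np.int8)
        with pytest.raises(ValueError):
            lk.css_window(dos, [0], [1, 2])

    def test_label_shuffled_neutral_data_centres_near_zero(self):
        rng = np.random.default_rng(8)
        vals = []
        for _ in range(300):
            dos = rng.binomial(2, 0.4, size=(12, 25)).astype(np.int8)
            rows = rng.permutation(12)
            vals.append(lk.css_window(dos, rows[:6], rows[6:]))
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean()) < 2 * se + 1e-3


class TestStratifiedPermutationTest:
    def test_add_one_rule_minimum_p(self, demo_sim):
        _, g, meta, _ = demo_sim
        design = _design_from(meta, ["Brienz", "Lucerne", "Walen", "Neuchatel"],
                              n_perm=999, seed=4)
        w = lk.make_windows(g, 50_000)
        res = lk.stratified_permutation_test(design, g, w, exact=False)
        assert res["p_perm"].min() >= 1 / 1000
        assert ((res["p_perm"] > 0) & (res["p_perm"] <= 1)).all()

    def test_assignment_counts(self, demo_sim):
        _, _, meta, _ = demo_sim
        four = _design_from(meta, ["Brienz", "Lucerne", "Walen", "Neuchatel"])
        two = _design_from(meta, ["Brienz", "Lucerne"])
        assert n_stratified_assignments(four) == 20**4
        assert n_stratified_assignments(two) == 400

    def test_exact_enumeration_matches_sampled(self, demo_sim):
        # 2 strata of 3+3: 400 distinct assignments; a large sampled run must
        # agree with exact tail probabilities within binomial Monte-Carlo error
        _, g, meta, _ = demo_sim
        sub = g.take_snps(np.arange(0, 600))
        w = lk.make_windows(sub, 50_000)
        exact_des = _design_from(meta, ["Brienz", "Lucerne"], seed=1)
        res_exact = lk.stratified_permutation_test(exact_des, sub, w, exact=True)
        sam_des = _design_from(meta, ["Brienz", "Lucerne"], n_perm=4000, seed=2)
        res_sam = lk.stratified_permutation_test(sam_des, sub, w, exact=False)
        p_e = res_exact["p_perm"].to_numpy()
        p_s = res_sam["p_perm"].to_numpy()
        tol = 3 * np.sqrt(p_e * (1 - p_e) / 4000) + 2 / 4000
        assert np.all(np.abs(p_e - p_s) <= tol)

    def test_min_snps_filter_drops_sparse_windows(self, demo_sim):
        _, g, meta, _ = demo_sim
        design = _design_from(meta, ["Brienz", "Lucerne"], n_perm=50)
        sub = g.take_snps(np.arange(23))  # single window with 23 SNPs
        w = lk.make_windows(sub, 10**9)
        res = lk.stratified_permutation_test(design, sub, w, exact=False)
        assert len(res) == 0

    def test_stratum_with_one_sided_group_rejected(self, demo_sim):
        _, _, meta, _ = demo_sim
        g1 = meta.loc[meta["ecomorph"] == "Balchen", "sample"].tolist()[:3]
        g2 = meta.loc[meta["ecomorph"] == "Albeli", "sample"].tolist()[:3]
        with pytest.raises(ValueError, match="both groups"):
            lk.ContrastDesign(g1, g2, {"only1": g1, "only2": g2})


class TestFdrAdjust:
    def test_bh_hand_computation(self):
        q = lk.fdr_adjust(np.array([0.01, 0.02, 0.03]))
        assert np.allclose(q, [0.03, 0.03, 0.03])

    def test_all_ones(self):
        assert np.allclose(lk.fdr_adjust(np.ones(5)), 1.0)

    def test_storey_with_pi0_one_equals_bh(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.001, 1, size=200)
        assert np.allclose(
            lk.fdr_adjust(p, method="storey", pi0=1.0), lk.fdr_adjust(p)
        )

    def test_monotone_in_p(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.001, 1, size=500)
        q = lk.fdr_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            lk.fdr_adjust(np.array([]))


class TestOutlierPca:
    @pytest.fixture(scope="class")
    def scan(self):
        # construction with strong, widespread parallel shifts so the
        # outlier-window SNPs carry a clear ecomorph axis
        cfg = lk.SimConfig(
            seed=101, n_chromosomes=4, snps_per_chromosome=5_000,
            prop_parallel_loci=0.05, parallel_shift=0.9,
        )
        g, meta, _ = lk.simulate_radiation(cfg)
        design = _design_from(
            meta, ["Brienz", "Lucerne", "Walen", "Neuchatel"], n_perm=3000, seed=3
        )
        w = lk.make_windows(g, 50_000)
        res = lk.stratified_permutation_test(design, g, w, exact=False)
        return g, meta, w, res

    def test_pc1_separates_ecomorph_clusters(self, scan):
        from sklearn.metrics import silhouette_score

        g, meta, w, res = scan
        outl = res[res["outlier"]]
        assert len(outl) > 0
        rad = meta.loc[meta["ecomorph"] != "outgroup", "sample"].tolist()
        scores, var_frac = lk.outlier_pca(g.take_samples(rad), w, outl)
        labels = meta.set_index("sample").loc[rad, "ecomorph"]
        sil = silhouette_score(
            scores[["PC1"]].to_numpy(), (labels == "Balchen").to_numpy()
        )
        assert sil > 0.5
        assert var_frac.sum() <= 1 + 1e-9

    def test_duplicate_samples_get_identical_scores(self, scan):
        g, meta, w, res = scan
        outl = res[res["outlier"]]
        ids = meta["sample"].tolist()[:6]
        dup = g.take_samples(ids)
        dup2 = lk.GenotypeMatrix(
            np.vstack([dup.dosages, dup.dosages[:1]]),
            dup.loci,
            ids + ["copy_of_first"],
        )
        scores, _ = lk.outlier_pca(dup2, w, outl)
        assert np.allclose(
            scores.loc[ids[0]].to_numpy(), scores.loc["copy_of_first"].to_numpy()
        )


class TestTraitRegression:
    def test_exact_linear_relation(self):
        x = np.linspace(-2, 2, 20)
        fits = lk.trait_regression(x, 2 * x)
        assert fits.loc[0, "r_squared"] == pytest.approx(1.0)
        assert fits.loc[0, "slope"] == pytest.approx(2.0)

    def test_zero_variance_predictor_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            lk.trait_regression(np.ones(10), np.arange(10.0))

    def test_null_r2_matches_ols_expectation(self):
        # trait independent of predictor: E[R^2] = 1/(n-1)
        rng = np.random.default_rng(12)
        n, reps = 90, 300
        r2 = [
            lk.trait_regression(rng.normal(size=n), rng.normal(size=n)).loc[
                0, "r_squared"
            ]
            for _ in range(reps)
        ]
        assert np.mean(r2) == pytest.approx(1 / (n - 1), abs=3 / (n - 1) / np.sqrt(reps) * 2 + 0.002)

    def test_stratified_fits_per_lake(self, demo_sim):
        _, _, meta, _ = demo_sim
        rng = np.random.default_rng(5)
        x = rng.normal(size=len(meta))
        fits = lk.trait_regression(x, 2 * x, by=meta["lake"])
        assert set(fits["group"]) == {"all"} | set(meta["lake"])
        assert np.allclose(fits["r_squared"], 1.0)
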