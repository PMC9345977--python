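"""F4 identities, D / f4-ratio arithmetic, f-branch, jackknife machinery."""

import numpy as np
import pandas as pd
import pytest

import lakescan as lk

NWK_4LAKE = (
    "((((Brienz_Balchen,Brienz_Albeli),(Lucerne_Balchen,Lucerne_Albeli)),"
    "((Walen_Balchen,Walen_Albeli),(Neuchatel_Balchen,Neuchatel_Albeli))),"
    "outgroup);"
)


class TestF4Stat:
    def test_equal_ab_gives_zero(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=100)
        c, d = rng.uniform(size=100), rng.uniform(size=100)
        assert lk.f4_stat(p, p, c, d) == 0.0

    def test_two_snp_hand_value(self):
        pa, pb = np.array([1.0, 0.0]), np.array([0.0, 0.0])
        pc, pd_ = np.array([1.0, 1.0]), np.array([0.0, 0.0])
        assert lk.f4_stat(pa, pb, pc, pd_) == pytest.approx(0.5)

    def test_antisymmetry_and_pair_swap(self):
        rng = np.random.default_rng(1)
        a, b, c, d = (rng.uniform(size=50) for _ in range(4))
        base = lk.f4_stat(a, b, c, d)
        assert lk.f4_stat(b, a, c, d) == pytest.approx(-base)
        assert lk.f4_stat(a, b, d, c) == pytest.approx(-base)
        assert lk.f4_stat(c, d, a, b) == pytest.approx(base)

    def test_fisher_identity_of_three_arrangements(self):
        # f4(A,B;C,D) - f4(A,C;B,D) + f4(A,D;B,C) = 0 per SNP set
        rng = np.random.default_rng(2)
        a, b, c, d = (rng.uniform(size=200) for _ in range(4))
        total = (
            lk.f4_stat(a, b, c, d)
            - lk.f4_stat(a, c, b, d)
            + lk.f4_stat(a, d, b, c)
        )
        assert abs(total) < 1e-12

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            lk.f4_stat([], [], [], [])


class TestDAndF4Ratio:
    def test_symmetric_gene_trees_give_zero(self):
        rng = np.random.default_rng(3)
        pa = rng.uniform(size=100)
        pc, po = rng.uniform(size=100), rng.uniform(0, 0.2, size=100)
        d, f = lk.d_and_f4ratio(pa, pa, pc, po)
        assert d == 0.0 and f == 0.0

    def test_single_site_abba(self):
        d, f = lk.d_and_f4ratio([0.0], [1.0], [1.0], [0.0])
        assert d == pytest.approx(1.0)

    def test_d_bounded(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            pa, pb, pc, po = (rng.uniform(size=30) for _ in range(4))
            d, _ = lk.d_and_f4ratio(pa, pb, pc, po)
            assert -1 <= d <= 1

    def test_zero_denominator_reported_nan(self):
        d, f = lk.d_and_f4ratio([0.5], [0.5], [0.0], [0.0])
        assert np.isnan(d) and np.isnan(f)

    def test_recovers_admixture_fraction(self):
        # clean introgression (no selected loci): the 3-seed mean of f lies
        # within 0.05 of the simulated tract fraction (per-seed spread of the
        # ratio estimator at this SNP count is ~0.04, so the mean is the
        # stable quantity)
        fs = []
        for seed in (31, 32, 33):
            cfg = lk.SimConfig(
                seed=seed,
                n_chromosomes=5,
                snps_per_chromosome=10_000,
                prop_parallel_loci=0.0,
                prop_lake_specific_loci=0.0,
                large_effect_locus=None,
                introgression_events=[("Lucerne", "Walen_Albeli", 0.2, 100_000)],
            )
            g, meta, truth = lk.simulate_radiation(cfg)
            groups = {
                sp: meta.loc[meta["species"] == sp, "sample"].tolist()
                for sp in cfg.species
            }
            groups["outgroup"] = meta.loc[
                meta["species"] == "outgroup", "sample"
            ].tolist()
            freqs = lk.allele_freqs(g, groups)
            _, f = lk.d_and_f4ratio(
                freqs["Walen_Balchen"],
                freqs["Walen_Albeli"],
                freqs["Lucerne_Albeli"],
                freqs["outgroup"],
                n_c_alleles=6,
            )
            fs.append(f)
        assert np.mean(fs) == pytest.approx(0.2, abs=0.05)


class TestJackknife:
    def test_constant_blocks_give_infinite_z_with_warning(self):
        with pytest.warns(UserWarning, match="zero jackknife variance"):
            est, se, z = lk.jackknife_z(np.ones(100), np.ones(100), n_blocks=10)
        assert est == 1.0 and se == 0.0 and np.isinf(z)

    def test_doubling_blocks_changes_se_moderately(self):
        rng = np.random.default_rng(5)
        num = rng.normal(0.2, 0.5, size=4000)
        den = np.ones(4000)
        _, se20, _ = lk.jackknife_z(num, den, n_blocks=20)
        _, se40, _ = lk.jackknife_z(num, den, n_blocks=40)
        assert abs(se40 - se20) / se20 < 0.2

    def test_too_few_blocks_rejected(self):
        with pytest.raises(ValueError):
            lk.jackknife_z(np.ones(10), np.ones(10), n_blocks=1)


class TestBonferroniZ:
    @pytest.mark.parametrize(
        "alpha,n,want", [(0.01, 1910, 4.41), (0.05, 1, 1.64)]
    )
    def test_quantiles(self, alpha, n, want):
        assert lk.bonferroni_z_threshold(alpha, n) == want

    def test_median_case(self):
        assert lk.bonferroni_z_threshold(0.5, 1) == 0.0


class TestGroupTree:
    def test_tips_and_outgroup_position(self):
        tree = lk.GroupTree.from_newick(NWK_4LAKE, "outgroup")
        assert len(tree.tips) == 9
        assert "Brienz_Balchen" in tree.tips

    def test_polytomy_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            lk.GroupTree.from_newick("((a,b,c),o);", "o")

    def test_missing_outgroup_rejected(self):
        with pytest.raises(ValueError, match="outgroup"):
            lk.GroupTree.from_newick("((a,b),(c,d));", "o")

    def test_branch_enumeration_excludes_outgroup_side(self):
        tree = lk.GroupTree.from_newick("(((a,b),(c,d)),o);", "o")
        labels = [b[0] for b in tree.branches()]
        assert set(labels) == {"a", "b", "c", "d", "a+b", "c+d"}


class TestTopologyContrast:
    def test_identical_populations_indeterminate(self):
        p = np.full(50, 0.4)
        res = lk.topology_contrast(p, p, p, p)
        assert res["verdict"] == "indeterminate"
        assert res["F4_1"] == res["F4_2"] == 0.0

    @pytest.mark.parametrize(
        "origin,want",
        [
            ("parallel", "parallel within-lake origin"),
            ("single", "single ecomorph origin"),
        ],
    )
    def test_recovers_generating_scenario_across_seeds(self, origin, want):
        hits = 0
        for seed in range(40, 50):
            cfg = lk.SimConfig(
                seed=seed,
                n_chromosomes=2,
                snps_per_chromosome=3_000,
                origin=origin,
                fst_species=0.02 if origin == "single" else 0.0,
            )
            g, meta, _ = lk.simulate_radiation(cfg)
            groups = {
                sp: meta.loc[meta["species"] == sp, "sample"].tolist()
                for sp in cfg.species
            }
            freqs = lk.allele_freqs(g, groups)
            res = lk.topology_contrast(
                freqs["Brienz_Balchen"],
                freqs["Brienz_Albeli"],
                freqs["Lucerne_Balchen"],
                freqs["Lucerne_Albeli"],
            )
            hits += res["verdict"] == want
        assert hits >= 9


class TestFBranch:
    def _freqs_and_sizes(self, cfg, g, meta):
        groups = {
            sp: meta.loc[meta["species"] == sp, "sample"].tolist()
            for sp in cfg.species
        }
        groups["outgroup"] = meta.loc[
            meta["species"] == "outgroup", "sample"
        ].tolist()
        return (
            lk.allele_freqs(g, groups),
            {k: 2 * len(v) for k, v in groups.items()},
        )

    def test_four_tip_tree_reduces_to_single_f_ratio(self):
        rng = np.random.default_rng(6)
        freqs = pd.DataFrame(
            {
                "a": rng.uniform(size=400),
                "b": rng.uniform(size=400),
                "c": rng.uniform(size=400),
                "o": rng.uniform(0, 0.2, size=400),
            }
        )
        tree = lk.GroupTree.from_newick("(((a,b),c),o);", "o")
        res = lk.fbranch(tree, freqs, n_blocks=10)
        _, f = lk.d_and_f4ratio(freqs["a"], freqs["b"], freqs["c"], freqs["o"])
        assert res.fb.at["b", "c"] == pytest.approx(max(f, 0.0))

    def test_topology_violating_cells_untestable(self):
        rng = np.random.default_rng(7)
        freqs = pd.DataFrame(
            {t: rng.uniform(size=300) for t in ["a", "b", "c", "d"]}
            | {"o": rng.uniform(0, 0.2, size=300)}
        )
        tree = lk.GroupTree.from_newick("(((a,b),(c,d)),o);", "o")
        res = lk.fbranch(tree, freqs, n_blocks=10)
        # donor inside the branch's own clade or its sister clade: untestable
        assert np.isnan(res.fb.at["a", "b"])
        assert np.isnan(res.fb.at["a+b", "a"])
        assert not np.isnan(res.fb.at["a", "c"])

    def test_single_event_recovered_as_maximal_significant_cell(self):
        cfg = lk.SimConfig(
            seed=55,
            n_chromosomes=4,
            snps_per_chromosome=5_000,
            introgression_events=[("Lucerne", "Walen_Albeli", 0.2, 100_000)],
        )
        g, meta, _ = lk.simulate_radiation(cfg)
        freqs, sizes = self._freqs_and_sizes(cfg, g, meta)
        tree = lk.GroupTree.from_newick(NWK_4LAKE, "outgroup")
        res = lk.fbranch(tree, freqs, n_blocks=20, n_alleles=sizes)
        lf = res.long_format().dropna(subset=["fb"])
        sig = lf[lf["significant"]]
        assert len(sig) > 0
        top = sig.loc[sig["fb"].idxmax()]
        assert top["branch"] == "Walen_Albeli"
        assert top["donor"].startswith("Lucerne")

    def test_no_gene_flow_yields_no_high_z_cells(self):
        # without introgression, cells above the study-style Z threshold of
        # 4.41 should not exceed the Bonferroni-expected false-positive count
        tree = lk.GroupTree.from_newick(NWK_4LAKE, "outgroup")
        n_high = 0
        for seed in range(60, 65):
            cfg = lk.SimConfig(
                seed=seed, n_chromosomes=2, snps_per_chromosome=3_000
            )
            g, meta, _ = lk.simulate_radiation(cfg)
            freqs, sizes = self._freqs_and_sizes(cfg, g, meta)
            res = lk.fbranch(tree, freqs, n_blocks=20, n_alleles=sizes)
            z = res.z.to_numpy()
            n_high += int(np.nansum((z > 4.41) & (res.fb.to_numpy() > 0)))
        assert n_high <= 1
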