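"""Tests for allele statistics, AMOVA, gene flow, PCoA and variance tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist, squareform

from oracle_helpers import amova_oracle
from ssrscape.popgen import (GenotypeMatrix, allele_stats, allele_summary, amova,
                             category_variance_test, fst_to_2nm, letter_groups,
                             pairwise_distances, pcoa, per_locus_stats)


def make_matrix(alleles, populations, species, categories=None):
    alleles = pd.DataFrame(alleles)
    alleles.index = [f"i{k}" for k in range(len(alleles))]
    categories = categories or {c: "OUT" for c in alleles.columns}
    return GenotypeMatrix(alleles, pd.Series(populations, index=alleles.index),
                          pd.Series(species, index=alleles.index),
                          pd.Series(categories))


def random_matrix(rng, n_per_pop, pops_per_species=(2, 2), n_loci=3, n_alleles=4):
    pops, species = [], []
    for s, k in enumerate(pops_per_species):
        for p in range(k):
            pops += [f"s{s}p{p}"] * n_per_pop
            species += [f"s{s}"] * n_per_pop
    n = len(pops)
    alleles = rng.integers(0, n_alleles, size=(n, n_loci)) * 3 + 100
    return make_matrix({f"L{j}": alleles[:, j] for j in range(n_loci)},
                       pops, species)


class TestGenotypeMatrix:
    def test_population_nested_in_species_enforced(self):
        with pytest.raises(ValueError, match="spanning"):
            make_matrix({"L1": [1, 2, 3, 4]}, ["p1", "p1", "p1", "p1"],
                        ["A", "A", "B", "B"])

    def test_needs_two_populations(self):
        with pytest.raises(ValueError, match="two populations"):
            make_matrix({"L1": [1, 2]}, ["p1", "p1"], ["A", "A"])

    def test_tsv_round_trip(self, toy_genotypes, tmp_path):
        gpath, mpath = tmp_path / "g.tsv", tmp_path / "m.tsv"
        toy_genotypes.to_tsv(gpath, mpath)
        back = GenotypeMatrix.from_tsv(gpath, mpath)
        pd.testing.assert_frame_equal(back.alleles, toy_genotypes.alleles,
                                      check_names=False)
        assert (back.population == toy_genotypes.population).all()
        assert (back.locus_category == toy_genotypes.locus_category).all()

    def test_category_subsetting(self, toy_genotypes):
        assert toy_genotypes.loci_in_category("IN") == ["L2"]
        with pytest.raises(ValueError, match="valid"):
            toy_genotypes.loci_in_category("BOGUS")


class TestAlleleStats:
    def test_effective_alleles_equifrequent(self):
        g = make_matrix({"L1": [180, 180, 183, 183]}, ["p1"] * 2 + ["p2"] * 2,
                        ["A"] * 4)
        stats_ = allele_stats(g, grouping="species")
        assert stats_.loc[("L1", "A"), "ne"] == pytest.approx(2.0)

    def test_na_ne_formula(self):
        g = make_matrix({"L1": [180, 180, 183, 186, 189, 189]},
                        ["p1"] * 4 + ["p2"] * 2, ["A"] * 6)
        row = allele_stats(g).loc[("L1", "p1")]
        assert row["na"] == 3
        assert row["ne"] == pytest.approx(1 / 0.375)

    def test_private_and_shared_partition(self):
        g = make_matrix({"L1": [180, 183, 183, 186]}, ["p1", "p1", "p2", "p2"],
                        ["A", "A", "B", "B"])
        sp = allele_stats(g, grouping="species")
        assert sp.loc[("L1", "A"), "private"] == 1   # {180}
        assert sp.loc[("L1", "B"), "private"] == 1   # {186}
        assert sp.loc[("L1", "A"), "shared"] == 1    # {183}
        # shared + private partitions each species' observed alleles
        assert (sp["private"] + sp["shared"] == sp["na"]).all()

    def test_all_missing_group_is_nan(self):
        g = make_matrix({"L1": [1.0, 2.0, np.nan, np.nan]},
                        ["p1", "p1", "p2", "p2"], ["A"] * 4)
        row = allele_stats(g).loc[("L1", "p2")]
        assert np.isnan(row["na"]) and np.isnan(row["ne"])

    def test_summary_shape(self, sim_pops):
        g, _ = sim_pops
        summary = allele_summary(g)
        assert set(summary.index.get_level_values("category")) == {
            "OUT", "UP", "IN", "DOWN"}
        assert {"na_mean", "ne_mean", "private_mean", "shared_mean"} <= set(
            summary.columns)
        # Ne <= Na holds for every frequency vector
        per = allele_stats(g).dropna()
        assert (per["ne"] <= per["na"] + 1e-12).all()


class TestPairwiseDistances:
    def test_identical_and_counts(self, toy_genotypes):
        d = pairwise_distances(toy_genotypes)
        assert np.all(np.diag(d) == 0)
        assert np.all(d.values == d.values.T)
        assert d.values.max() <= len(toy_genotypes.loci)

    def test_difference_count(self):
        g = make_matrix({"L1": [1, 1], "L2": [2, 5], "L3": [3, 9]},
                        ["p1", "p2"], ["A", "A"])
        assert pairwise_distances(g).iloc[0, 1] == 2

    def test_single_locus_distance_binary(self):
        g = make_matrix({"L1": [1, 2]}, ["p1", "p2"], ["A", "A"])
        assert pairwise_distances(g).iloc[0, 1] == 1

    def test_missing_pairwise_deletion(self):
        g = make_matrix({"L1": [1.0, np.nan], "L2": [2, 2], "L3": [3, 4]},
                        ["p1", "p2"], ["A", "A"])
        assert pairwise_distances(g).iloc[0, 1] == 1

    def test_no_shared_loci_rejected(self):
        g = make_matrix({"L1": [1.0, np.nan], "L2": [np.nan, 2.0]},
                        ["p1", "p2"], ["A", "A"])
        with pytest.raises(ValueError, match="no scored locus"):
            pairwise_distances(g)


class TestAmova:
    def test_fixed_species_difference(self):
        g = make_matrix({"L1": [1, 1, 2, 2]}, ["p1", "p1", "p2", "p2"],
                        ["A", "A", "B", "B"])
        r = amova(g, levels=3)
        assert r.table.loc["Among species", "pct"] == pytest.approx(100.0)
        assert r.phi_st == pytest.approx(1.0)
        assert r.phi_ct == pytest.approx(1.0)

    def test_two_level_negative_component(self):
        # pops {A,B} and {A,B}: sigma_among = -0.25, sigma_within = 0.5
        g = make_matrix({"L1": [1, 2, 1, 2]}, ["p1", "p1", "p2", "p2"],
                        ["A"] * 4)
        r = amova(g, levels=2)
        assert r.table.loc["Among populations", "variance"] == pytest.approx(-0.25)
        assert r.table.loc["Among genotypes within populations",
                           "variance"] == pytest.approx(0.5)
        assert r.phi_st == pytest.approx(-1.0)

    def test_truncate_negative_mode(self):
        g = make_matrix({"L1": [1, 2, 1, 2]}, ["p1", "p1", "p2", "p2"], ["A"] * 4)
        r = amova(g, levels=2, truncate_negative=True)
        assert r.table.loc["Among populations", "variance"] == 0.0
        assert r.phi_st == pytest.approx(0.0)

    def test_all_identical_is_undefined_not_zero(self):
        g = make_matrix({"L1": [5, 5, 5, 5]}, ["p1", "p1", "p2", "p2"],
                        ["A", "A", "B", "B"])
        r = amova(g, levels=3)
        assert np.isnan(r.phi_st) and np.isnan(r.phi_ct)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_matches_exact_rational_oracle(self, seed):
        rng = np.random.default_rng(seed)
        sizes = rng.integers(2, 4, size=4).tolist()  # <= 10 individuals
        pops, species = [], []
        for k, sz in enumerate(sizes):
            pops += [f"p{k}"] * sz
            species += [f"s{k // 2}"] * sz
        n = len(pops)
        alleles = rng.integers(0, 3, size=(n, 2)) * 3 + 100
        g = make_matrix({"L0": alleles[:, 0], "L1": alleles[:, 1]}, pops, species)
        r = amova(g, levels=3)
        d = pairwise_distances(g).to_numpy().tolist()
        df_o, ss_o, var_o = amova_oracle(d, pops, species)
        got_df = r.table["df"].iloc[:3].to_numpy()
        got_ss = r.table["ss"].iloc[:3].to_numpy()
        got_var = r.table["variance"].iloc[:3].to_numpy()
        assert np.allclose(got_df, [float(x) for x in df_o])
        assert np.allclose(got_ss, [float(x) for x in ss_o], atol=1e-10)
        assert np.allclose(got_var, [float(x) for x in var_o], atol=1e-10)

    @pytest.mark.parametrize("seed", range(4))
    def test_conservation_invariants(self, seed):
        rng = np.random.default_rng(seed)
        g = random_matrix(rng, n_per_pop=int(rng.integers(2, 6)),
                          pops_per_species=(2, 3))
        r = amova(g, levels=3)
        assert r.table["pct"].iloc[:3].sum() == pytest.approx(100.0, abs=1e-9)
        assert r.table["df"].iloc[:3].sum() == len(g.individuals) - 1

    def test_balanced_design_expected_mean_squares(self):
        # balanced design: the unbalanced coefficients reduce to n' = n,
        # n'' = nP, so planted components round-trip through the MS relations
        rng = np.random.default_rng(5)
        g = random_matrix(rng, n_per_pop=4, pops_per_species=(3, 3), n_loci=5)
        r = amova(g, levels=3)
        n_ind, n_pop = 4, 3
        df = r.table["df"].iloc[:3]
        ms = (r.table["ss"].iloc[:3] / df).to_numpy()
        var = r.table["variance"].iloc[:3].to_numpy()
        sigma_c = var[2]
        sigma_b = (ms[1] - sigma_c) / n_ind
        sigma_a = (ms[0] - sigma_c - n_ind * sigma_b) / (n_ind * n_pop)
        assert sigma_b == pytest.approx(var[1], abs=1e-10)
        assert sigma_a == pytest.approx(var[0], abs=1e-10)

    def test_permutation_p_values(self, sim_pops):
        g, _ = sim_pops
        r = amova(g, n_perm=199, seed=5)
        # strong species structure: Phi_ST permutation p at its floor
        assert r.p_values["phi_st"] == pytest.approx(1 / 200)
        # whole-population permutation over 2+3 populations cannot go
        # below ~1/10 no matter how strong the signal
        assert r.p_values["phi_ct"] >= 1 / 200
        assert 0 < r.p_values["phi_sc"] <= 1

    def test_seed_required_for_permutations(self, toy_genotypes):
        with pytest.raises(ValueError, match="seed"):
            amova(toy_genotypes, n_perm=10)

    def test_three_level_needs_two_species(self):
        g = make_matrix({"L1": [1, 2, 3, 4]}, ["p1", "p1", "p2", "p2"], ["A"] * 4)
        with pytest.raises(ValueError, match="two species"):
            amova(g, levels=3)


class TestGeneFlow:
    @pytest.mark.parametrize("fst,expected", [(0.2, 2.0), (1.0, 0.0), (0.5, 0.5)])
    def test_examples(self, fst, expected):
        assert fst_to_2nm(fst) == pytest.approx(expected)

    @given(st.floats(1e-6, 1.0))
    @settings(max_examples=100, deadline=None)
    def test_round_trip_identity(self, fst):
        nm2 = fst_to_2nm(fst)
        assert 1.0 / (4 * (nm2 / 2) + 1) == pytest.approx(fst, rel=1e-9)

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5, np.nan])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            fst_to_2nm(bad)


class TestPerLocusStats:
    def test_structure_and_ranges(self, sim_pops):
        g, _ = sim_pops
        table = per_locus_stats(g)
        assert len(table) == len(g.loci)
        assert (table["category"] == g.locus_category).all()
        ok = table["fst"].dropna()
        assert (ok <= 1.0 + 1e-12).all()
        defined = table.dropna(subset=["gene_flow_2nm"])
        assert np.allclose(defined["gene_flow_2nm"],
                           (1 / defined["fst"] - 1) / 2)
        pct = table[["pct_among_species", "pct_among_populations",
                     "pct_within_populations"]].dropna()
        assert np.allclose(pct.sum(axis=1), 100.0)


class TestPCoA:
    def test_identical_points_coincide(self):
        d = np.zeros((3, 3))
        d[0, 2] = d[2, 0] = d[1, 2] = d[2, 1] = 1.0
        res = pcoa(d, n_axes=2)
        assert np.allclose(res.coordinates.iloc[0], res.coordinates.iloc[1])

    def test_equilateral_eigenvalues(self):
        dist = 3.0
        d = np.full((3, 3), dist)
        np.fill_diagonal(d, 0.0)
        res = pcoa(d, n_axes=2)
        assert np.allclose(sorted(res.eigenvalues, reverse=True),
                           [dist**2 / 2, dist**2 / 2])

    @pytest.mark.parametrize("seed", [0, 1])
    def test_euclidean_embedding_reproduces_distances(self, seed):
        rng = np.random.default_rng(seed)
        points = rng.normal(size=(6, 4))
        d = squareform(pdist(points))
        res = pcoa(d, n_axes=6)
        emb = squareform(pdist(res.coordinates.to_numpy()))
        assert np.allclose(emb, d, atol=1e-9)

    def test_matches_reference_implementation(self, sim_pops):
        skbio = pytest.importorskip("skbio")
        g, _ = sim_pops
        d = pairwise_distances(g)
        ours = pcoa(d, n_axes=3)
        theirs = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(d.to_numpy(), ids=list(d.index)))
        n_pos = ours.eigenvalues.size
        assert np.allclose(ours.eigenvalues,
                           theirs.eigvals.to_numpy()[:n_pos], atol=1e-8)
        for axis in range(3):  # eigenvectors defined up to sign
            a = ours.coordinates.iloc[:, axis].to_numpy()
            b = theirs.samples.iloc[:, axis].to_numpy()
            assert np.allclose(a, b, atol=1e-6) or np.allclose(a, -b, atol=1e-6)

    def test_non_euclidean_warns_and_truncates(self):
        d = np.array([[0, 1, 1, 1], [1, 0, 1, 1], [1, 1, 0, 1], [1, 1, 1, 0.05]],
                     dtype=float)
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        with pytest.warns(UserWarning):
            res = pcoa(d, n_axes=4)
        assert res.eigenvalues.size < 4

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            pcoa(np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestCategoryVarianceTest:
    def test_identical_samples(self):
        t = category_variance_test({"A": [1, 2, 3], "B": [1, 2, 3]})
        assert t.loc[0, "f"] == pytest.approx(1.0)
        assert t.loc[0, "p_value"] == pytest.approx(1.0)

    def test_closed_form_f22(self):
        t = category_variance_test({"A": [1, 2, 3], "B": [2, 4, 6]})
        row = t.iloc[0]
        assert row["f"] == pytest.approx(4.0)
        assert (row["df1"], row["df2"]) == (2, 2)
        assert row["p_value"] == pytest.approx(0.4)  # 2 * 1/(1+F) for F(2,2)

    def test_order_invariance(self):
        t1 = category_variance_test({"A": [1, 2, 3], "B": [2, 4, 6]})
        t2 = category_variance_test({"B": [2, 4, 6], "A": [1, 2, 3]})
        assert t1.loc[0, "f"] == t2.loc[0, "f"]
        assert t1.loc[0, "p_value"] == t2.loc[0, "p_value"]

    def test_zero_variance_flagged(self):
        t = category_variance_test({"A": [1, 1, 1], "B": [2, 2, 2]})
        assert np.isnan(t.loc[0, "f"]) and np.isnan(t.loc[0, "p_value"])

    def test_single_locus_category_rejected(self):
        with pytest.raises(ValueError, match="at least two"):
            category_variance_test({"A": [1.0], "B": [1, 2]})

    def test_letter_groups(self):
        t = category_variance_test({
            "A": [1, 2, 3, 2, 1], "B": [1.1, 2.1, 3.2, 2.0, 1.2],
            "C": [0, 50, -50, 80, -80]})
        letters = letter_groups(["A", "B", "C"], t)
        assert letters["A"] == letters["B"]
        assert set(letters["C"]) != set(letters["A"])
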