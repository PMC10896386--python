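"""SNP selection, PCA, neighbour-joining and karyotype clustering."""

import numpy as np
import pandas as pd
import pytest

from mozpopgen import structure
from mozpopgen.datamodel import MISSING, GenotypeDataset


def make_dataset(genotypes: np.ndarray, contig: str = "3L") -> GenotypeDataset:
    """A minimal dataset around a (variants, samples, 2) genotype array."""
    n_var, n_samp, _ = genotypes.shape
    variants = pd.DataFrame({
        "contig": contig,
        "pos": np.arange(1, n_var + 1) * 10,
        "ref": "A",
        "alt": "T",
        "is_pass": True,
    })
    samples = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n_samp)],
        "location": "X", "latitude": 0.0, "longitude": 0.0,
        "year": 2020, "month": 1,
    })
    return GenotypeDataset(genotypes.astype(np.int8), variants, samples,
                           {contig: n_var * 10 + 10})


class TestSelectStructureSnps:
    def test_stride_selection_every_second(self, rng):
        g = (rng.random((10, 6, 2)) < 0.5).astype(np.int8)
        ds = make_dataset(g)
        sel = structure.select_structure_snps(ds, n_target=5, maf_min=0.0)
        qualifying = sel.log["n_maf"]
        if qualifying == 10:
            assert list(sel.indices) == [0, 2, 4, 6, 8]

    def test_missing_call_excludes_variant(self, rng):
        g = (rng.random((10, 6, 2)) < 0.5).astype(np.int8)
        g[3, 0] = MISSING
        ds = make_dataset(g)
        sel = structure.select_structure_snps(ds, n_target=10, maf_min=0.0)
        assert 3 not in sel.indices

    def test_filter_log_matches_recount(self, dataset):
        sel = structure.select_structure_snps(
            dataset, contigs=["3L", "3R"], n_target=500)
        on3 = dataset.variants["contig"].isin(["3L", "3R"])
        assert sel.log["n_considered"] == int(on3.sum())
        # brute-force recount of qualifying SNPs
        count = 0
        for i in np.flatnonzero(on3.to_numpy()):
            g = dataset.genotypes[i]
            if (g == MISSING).any():
                continue
            if len(dataset.alleles(i)) != 2:
                continue
            p = (g == 1).sum() / g.size
            if min(p, 1 - p) > 0.002:
                count += 1
        assert sel.log["n_maf"] == count
        assert sel.log["n_selected"] == min(500, count)

    def test_idempotent_on_own_output(self, dataset):
        sel = structure.select_structure_snps(dataset, contigs=["3L"], n_target=200)
        sub = dataset.take_variants(sel.indices)
        again = structure.select_structure_snps(sub, n_target=200)
        assert again.indices.size == sel.indices.size

    def test_no_qualifying_snps_rejected(self):
        g = np.zeros((5, 4, 2), dtype=np.int8)  # all monomorphic
        with pytest.raises(ValueError, match="no SNPs qualify"):
            structure.select_structure_snps(make_dataset(g), n_target=5)


class TestPca:
    def test_two_planted_clusters_separate_on_pc1(self, dataset, sim):
        """Taxon groups separate with zero overlap on PC1 (fixed AIM blocks)."""
        sel = structure.select_structure_snps(dataset, contigs=["3L", "3R"],
                                              n_target=1000)
        taxon = sim.truth_samples["taxon"].to_numpy()
        keep = np.flatnonzero(taxon != "coluzzii")  # two clean groups
        pca = structure.pca_dosage(dataset, sel, k=2, sample_index=keep)
        pc1 = pca.coords["PC1"].to_numpy()
        arab = pc1[taxon[keep] == "arabiensis"]
        gamb = pc1[taxon[keep] == "gambiae"]
        assert max(arab.min(), gamb.min()) > min(arab.max(), gamb.max()) or \
            max(gamb.min(), arab.min()) > min(gamb.max(), arab.max())
        assert arab.max() < gamb.min() or gamb.max() < arab.min()

    def test_duplicate_sample_identical_coordinates(self, rng):
        g = (rng.random((50, 8, 2)) < 0.4).astype(np.int8)
        g[:, 7, :] = g[:, 0, :]  # sample 7 duplicates sample 0
        ds = make_dataset(g)
        sel = structure.select_structure_snps(ds, n_target=50, maf_min=0.0)
        pca = structure.pca_dosage(ds, sel, k=3)
        c = pca.coords[[f"PC{i}" for i in (1, 2, 3)]].to_numpy()
        assert np.allclose(c[0], c[7])

    def test_rank_one_data_single_component(self):
        # three samples with collinear dosages: PC1 carries ~all variance
        g = np.zeros((40, 3, 2), dtype=np.int8)
        g[:, 1, 0] = 1          # dosage 1
        g[:, 2, :] = 1          # dosage 2
        ds = make_dataset(g)
        sel = structure.select_structure_snps(ds, n_target=40, maf_min=0.0)
        pca = structure.pca_dosage(ds, sel, k=1, scale="none")
        assert pca.explained_variance[0] == pytest.approx(1.0)

    def test_explained_variance_non_increasing(self, dataset):
        sel = structure.select_structure_snps(dataset, contigs=["3L"], n_target=300)
        pca = structure.pca_dosage(dataset, sel, k=5)
        ev = pca.explained_variance
        assert np.all(np.diff(ev) <= 1e-12)
        assert np.all((ev >= 0) & (ev <= 1))

    def test_coords_invariant_to_sample_order(self, dataset):
        import copy
        sel = structure.select_structure_snps(dataset, contigs=["3L"], n_target=200)
        perm = np.random.default_rng(1).permutation(dataset.n_samples)
        shuffled = copy.copy(dataset)
        shuffled.genotypes = dataset.genotypes[:, perm, :]
        shuffled.samples = dataset.samples.iloc[perm].reset_index(drop=True)
        a = structure.pca_dosage(dataset, sel, k=3).coords.set_index("sample_id")
        b = structure.pca_dosage(shuffled, sel, k=3).coords.set_index("sample_id")
        assert np.allclose(a.loc[b.index].to_numpy(), b.to_numpy(), atol=1e-8)


class TestNjTree:
    def test_additive_four_leaf_matrix_recovered_exactly(self):
        """NJ on a tree-additive metric reproduces every path length."""
        ids = list("abcd")
        dm = np.array([
            [0, 5, 9, 9],
            [5, 0, 10, 10],
            [9, 10, 0, 8],
            [9, 10, 8, 0],
        ], dtype=float)
        result = structure.nj_from_distance_matrix(dm, ids)
        dists = result.tree.tip_tip_distances(ids)
        for i, a in enumerate(ids):
            for j, b in enumerate(ids):
                assert dists[a, b] == pytest.approx(dm[i, j])

    def test_three_leaf_closed_form(self):
        d_ab, d_ac, d_bc = 4.0, 6.0, 8.0
        dm = np.array([[0, d_ab, d_ac], [d_ab, 0, d_bc], [d_ac, d_bc, 0]])
        result = structure.nj_from_distance_matrix(dm, list("abc"))
        lengths = {t.name: t.length for t in result.tree.tips()}
        assert lengths["a"] == pytest.approx((d_ab + d_ac - d_bc) / 2)
        assert lengths["b"] == pytest.approx((d_ab + d_bc - d_ac) / 2)
        assert lengths["c"] == pytest.approx((d_ac + d_bc - d_ab) / 2)

    def test_equal_distances_deterministic(self):
        dm = np.ones((4, 4)) - np.eye(4)
        a = structure.nj_from_distance_matrix(dm, list("abcd")).newick
        b = structure.nj_from_distance_matrix(dm, list("abcd")).newick
        assert a == b

    def test_tree_from_dataset_has_all_samples(self, dataset):
        sel = structure.select_structure_snps(dataset, contigs=["3L"], n_target=100)
        result = structure.nj_tree(dataset, sel)
        tips = {t.name for t in result.tree.tips()}
        assert tips == set(dataset.sample_ids)

    def test_cityblock_distances_used(self):
        # three leaves: any 3-point metric is realised exactly by the star tree
        g = np.zeros((20, 3, 2), dtype=np.int8)
        g[:, 1, 0] = 1       # dosage 1 everywhere
        g[:10, 2, :] = 1     # dosage 2 on half the sites
        ds = make_dataset(g)
        sel = structure.SnpSelection(indices=np.arange(20), log={})
        result = structure.nj_tree(ds, sel)
        dists = result.tree.tip_tip_distances(["s0", "s1", "s2"])
        # L1 between s0 (all zero) and s1 (dosage 1 everywhere) is 20
        assert dists["s0", "s1"] == pytest.approx(20.0)
        assert dists["s0", "s2"] == pytest.approx(20.0)
        assert dists["s1", "s2"] == pytest.approx(20.0)


class TestKaryotypePca:
    def _three_group_dataset(self, rng, n_per_group=12, n_inv=80, n_bg=60):
        """0/1/2 copies of a divergent haplotype plus background noise."""
        n = 3 * n_per_group
        copies = np.repeat([0, 1, 2], n_per_group)
        g = np.zeros((n_inv + n_bg, n, 2), dtype=np.int8)
        for s in range(n):
            if copies[s] >= 1:
                g[:n_inv, s, 0] = 1
            if copies[s] == 2:
                g[:n_inv, s, 1] = 1
        g[n_inv:] = (rng.random((n_bg, n, 2)) < 0.3)
        return make_dataset(g, contig="2L"), copies

    def test_three_planted_groups_recovered(self, rng):
        ds, copies = self._three_group_dataset(rng)
        result = structure.karyotype_pca(ds, ("2L", 1, 10_000), min_snps=50)
        assert result.n_clusters == 3
        assert np.array_equal(result.clusters["cluster"].to_numpy(), copies) or \
            np.array_equal(result.clusters["cluster"].to_numpy(), 2 - copies)

    def test_heterozygotes_midway_on_pc1(self, rng):
        ds, copies = self._three_group_dataset(rng)
        result = structure.karyotype_pca(ds, ("2L", 1, 10_000), min_snps=50)
        pc1 = result.pca.coords["PC1"].to_numpy()
        means = [pc1[copies == c].mean() for c in (0, 1, 2)]
        assert means[1] == pytest.approx((means[0] + means[2]) / 2, abs=0.2 * abs(means[2] - means[0]))

    def test_single_group_single_cluster(self, rng):
        n = 30
        g = np.zeros((100, n, 2), dtype=np.int8)
        g[:, :, 0] = 1  # everyone identical (het at every site)
        ds = make_dataset(g, contig="2L")
        result = structure.karyotype_pca(ds, ("2L", 1, 10_000), min_snps=50)
        assert result.n_clusters == 1

    def test_too_few_snps_rejected(self, rng):
        g = (rng.random((10, 8, 2)) < 0.5).astype(np.int8)
        ds = make_dataset(g, contig="2L")
        with pytest.raises(ValueError, match="qualifying SNPs"):
            structure.karyotype_pca(ds, ("2L", 1, 10_000), min_snps=50)
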