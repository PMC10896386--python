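"""Codon-effect annotation and substitution-frequency estimation."""

import numpy as np
import pandas as pd
import pytest

from mozpopgen import resistance
from mozpopgen.datamodel import MISSING
from mozpopgen.resistance import GeneModel
from mozpopgen.simulate import simulate_genotype_dataset
from tests.conftest import small_config


@pytest.fixture(scope="module")
def annotated(bundle, dataset):
    models = resistance.read_gene_models(bundle.gff3)
    return models, resistance.annotate_coding_effects(dataset, models, bundle.fasta)


@pytest.fixture(scope="module")
def truth_cohorts(sim, dataset):
    cohort = sim.truth_samples["cohort"].to_numpy()
    return {key: np.flatnonzero(cohort == key) for key in np.unique(cohort)}


class TestGeneModels:
    def test_gff3_round_trip(self, sim, annotated):
        models, _ = annotated
        by_id = {m.gene_id: m for m in models}
        for gm in sim.gene_models:
            got = by_id[gm.gene_id]
            assert got.strand == gm.strand
            assert got.cds == gm.cds
            assert got.name == gm.name

    def test_cds_not_multiple_of_three_rejected(self, dataset, bundle):
        bad = GeneModel("BAD1", "2L", "+", cds=[(300_001, 300_004)], name="Bad")
        result = resistance.annotate_coding_effects(dataset, [bad], bundle.fasta)
        assert "BAD1" in result.rejected_genes

    def test_overlapping_cds_rejected(self):
        with pytest.raises(ValueError, match="overlapping"):
            GeneModel("X", "2L", "+", cds=[(1, 10), (5, 20)])


class TestAnnotation:
    def test_planted_substitutions_labelled(self, sim, annotated):
        """Every planted locus (including minus-strand Gste2) gets its
        community label, e.g. L995F."""
        _, result = annotated
        nonsyn = result.effects[result.effects["effect"] == "non_synonymous"]
        for _, row in sim.truth_loci.drop_duplicates("substitution").iterrows():
            hit = nonsyn[(nonsyn["gene_name"] == row["gene"])
                         & (nonsyn["label"] == row["substitution"])]
            assert len(hit) == 1, f"missing {row['gene']} {row['substitution']}"
            assert hit["pos"].iloc[0] == row["pos"]

    def test_synonymous_change_detected(self, dataset, bundle, sim):
        """A third-position wobble change coding the same amino acid."""
        # construct a gene whose codon at the planted variant is synonymous:
        # find any background variant inside Vgsc CDS annotated synonymous
        models = resistance.read_gene_models(bundle.gff3)
        result = resistance.annotate_coding_effects(dataset, models, bundle.fasta)
        eff = result.effects
        assert (eff["effect"] == "synonymous").any()
        syn = eff[eff["effect"] == "synonymous"]
        assert (syn["label"] == "").all()

    def test_non_coding_for_intronic_variant(self, annotated, dataset):
        _, result = annotated
        # Vgsc has introns (11_601..11_800, 13_401..13_600); any variant there
        # must be non_coding
        eff = result.effects
        intronic = eff[(eff["contig"] == "2L") & (eff["pos"].between(11_601, 11_800)
                                                  | eff["pos"].between(13_401, 13_600))]
        if len(intronic):
            assert (intronic["effect"] == "non_coding").all()

    def test_strand_consistency(self, tmp_path):
        """The same codon construction on plus and minus strand yields the
        same substitution label."""
        from mozpopgen import io as mio
        from mozpopgen.datamodel import GenotypeDataset

        # gene of 2 codons: ATG GTA (M V); mutate GTA->TTA = V2L
        plus_seq = "ATGGTA"
        comp = str.maketrans("ACGT", "TGCA")
        minus_seq = plus_seq.translate(comp)[::-1]  # TACCAT
        seq = {"c+": "AAAA" + plus_seq + "AAAA", "c-": "AAAA" + minus_seq + "AAAA"}
        fasta = tmp_path / "ref.fa"
        mio.write_fasta(seq, fasta)
        genes = [
            GeneModel("G+", "c+", "+", cds=[(5, 10)], name="G+"),
            GeneModel("G-", "c-", "-", cds=[(5, 10)], name="G-"),
        ]
        # variant at first base of codon 2: plus strand pos 8 (G->T);
        # on minus strand the same codon base is genomic pos 7, C->A
        variants = pd.DataFrame({
            "contig": ["c+", "c-"], "pos": [8, 7],
            "ref": ["G", "C"], "alt": ["T", "A"], "is_pass": True,
        })
        g = np.zeros((2, 2, 2), dtype=np.int8)
        samples = pd.DataFrame({
            "sample_id": ["a", "b"], "location": "X", "latitude": 0.0,
            "longitude": 0.0, "year": 2020, "month": 1,
        })
        ds = GenotypeDataset(g, variants, samples, {"c+": 14, "c-": 14})
        result = resistance.annotate_coding_effects(ds, genes, fasta)
        labels = result.effects.set_index("gene_id")["label"]
        assert labels["G+"] == "V2L"
        assert labels["G-"] == "V2L"

    def test_ref_mismatch_rejected(self, dataset, bundle):
        import copy
        ds = copy.copy(dataset)
        ds.variants = dataset.variants.copy()
        vgsc = (ds.variants["contig"] == "2L") & ds.variants["pos"].between(10_001, 15_200)
        i = int(np.flatnonzero(vgsc)[0])
        wrong = {"A": "C", "C": "A", "G": "T", "T": "G"}[ds.variants.loc[i, "ref"]]
        ds.variants.loc[i, "ref"] = wrong
        models = resistance.read_gene_models(bundle.gff3)
        result = resistance.annotate_coding_effects(ds, models, bundle.fasta)
        assert any(r["pos"] == ds.variants.loc[i, "pos"] for r in result.rejected_variants)


class TestSubstitutionFrequencies:
    def test_planted_frequencies_recovered(self, sim, dataset, annotated, truth_cohorts):
        """Reported frequencies equal the simulator's realized frequencies."""
        _, result = annotated
        table = resistance.substitution_frequencies(
            dataset, result.effects, truth_cohorts, keep_all=True)
        truth = sim.truth_loci.set_index(["gene", "substitution", "cohort"])
        for _, row in table.iterrows():
            key = (row["gene"], row["substitution"], row["cohort"])
            if key in truth.index:
                assert row["frequency"] == pytest.approx(
                    truth.loc[key, "realized_frequency"], abs=1e-12)

    def test_retention_filter(self, dataset, annotated, truth_cohorts):
        _, result = annotated
        full = resistance.substitution_frequencies(
            dataset, result.effects, truth_cohorts, retention=0.05, keep_all=True)
        kept = resistance.substitution_frequencies(
            dataset, result.effects, truth_cohorts, retention=0.05)
        by_sub = full.groupby(["gene", "substitution"])["frequency"].max()
        for (gene, sub), fmax in by_sub.items():
            rows = kept[(kept["gene"] == gene) & (kept["substitution"] == sub)]
            if fmax > 0.05:
                # retained in every cohort row
                assert len(rows) == len(truth_cohorts)
            else:
                assert rows.empty

    def test_frequencies_equal_brute_force_tally(self, dataset, annotated, rng):
        _, result = annotated
        idx = rng.choice(dataset.n_samples, 15, replace=False)
        table = resistance.substitution_frequencies(
            dataset, result.effects, {"c": idx}, keep_all=True)
        nonsyn = result.effects[result.effects["effect"] == "non_synonymous"]
        for _, row in table.iterrows():
            rows = nonsyn[(nonsyn["gene_name"] == row["gene"])
                          & (nonsyn["label"] == row["substitution"])]
            expected = 0.0
            for _, v in rows.iterrows():
                num = den = 0
                for s in idx:
                    g = dataset.genotypes[int(v["variant_index"]), s]
                    if (g == MISSING).any():
                        continue
                    num += int((g == v["alt_index"]).sum())
                    den += 2
                expected += num / den
            assert row["frequency"] == pytest.approx(expected)


class TestDoubleMutant:
    def test_coupled_pair_recovered_within_three_se(self, sim, dataset, annotated,
                                                    truth_cohorts):
        _, result = annotated
        table = resistance.double_mutant_frequency(
            dataset, result.effects, (("Vgsc", "V402L"), ("Vgsc", "I1527T")),
            truth_cohorts)
        for _, row in table.iterrows():
            n_alleles = 2 * row["n_samples"]
            se = np.sqrt(0.38 * 0.62 / n_alleles)
            assert abs(row["joint_frequency"] - 0.38) <= 3 * se
            # complete coupling: joint equals both marginals
            assert row["joint_frequency"] == pytest.approx(row["frequency_1"])
            assert row["joint_frequency"] == pytest.approx(row["frequency_2"])

    def test_marginals_bound_joint(self, dataset, annotated, truth_cohorts):
        _, result = annotated
        table = resistance.double_mutant_frequency(
            dataset, result.effects, (("Vgsc", "L995F"), ("Gste2", "I114T")),
            truth_cohorts)
        for _, row in table.iterrows():
            assert row["joint_frequency"] <= row["frequency_1"] + 1e-12
            assert row["joint_frequency"] <= row["frequency_2"] + 1e-12

    def test_disjoint_carriers_zero_joint(self, dataset, annotated):
        _, result = annotated
        nonsyn = result.effects[result.effects["effect"] == "non_synonymous"]
        v995 = nonsyn[nonsyn["label"] == "L995F"]["variant_index"].iloc[0]
        v114 = nonsyn[nonsyn["label"] == "I114T"]["variant_index"].iloc[0]
        import copy
        ds = copy.copy(dataset)
        ds.genotypes = dataset.genotypes.copy()
        n = ds.n_samples
        ds.genotypes[int(v995)] = 0
        ds.genotypes[int(v114)] = 0
        ds.genotypes[int(v995), : n // 2] = 1      # carriers in first half only
        ds.genotypes[int(v114), n // 2 :] = 1      # carriers in second half only
        table = resistance.double_mutant_frequency(
            ds, result.effects, (("Vgsc", "L995F"), ("Gste2", "I114T")),
            {"all": np.arange(n)})
        assert table["joint_frequency"].iloc[0] == 0.0

    def test_both_fixed_gives_one(self, dataset, annotated):
        _, result = annotated
        nonsyn = result.effects[result.effects["effect"] == "non_synonymous"]
        v995 = int(nonsyn[nonsyn["label"] == "L995F"]["variant_index"].iloc[0])
        v114 = int(nonsyn[nonsyn["label"] == "I114T"]["variant_index"].iloc[0])
        import copy
        ds = copy.copy(dataset)
        ds.genotypes = dataset.genotypes.copy()
        ds.genotypes[v995] = 1
        ds.genotypes[v114] = 1
        table = resistance.double_mutant_frequency(
            ds, result.effects, (("Vgsc", "L995F"), ("Gste2", "I114T")),
            {"all": np.arange(ds.n_samples)})
        assert table["joint_frequency"].iloc[0] == pytest.approx(1.0)

    def test_absent_substitution_zero_with_log(self, dataset, annotated, truth_cohorts):
        _, result = annotated
        table = resistance.double_mutant_frequency(
            dataset, result.effects, (("Vgsc", "L995F"), ("Vgsc", "Q9999Z")),
            truth_cohorts)
        assert (table["joint_frequency"] == 0).all()
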