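"""Simulate the study-scale synthetic dataset and record its ground truth.

Writes the genotype bundle (VCF, metadata, AIM panels, GFF3, FASTA, BED
mask, truth tables) under scratch/bundle/ and a summary of what was
planted under results/.
"""

import pandas as pd

from common import BUNDLE_DIR, RESULTS, SEED, ensure_bundle, study_config
from mozpopgen.simulate import simulate_genotype_dataset, write_fixture_bundle


def main() -> None:
    sim = simulate_genotype_dataset(study_config(SEED))
    bundle = write_fixture_bundle(sim, BUNDLE_DIR)
    RESULTS.mkdir(exist_ok=True)

    truth = sim.truth_samples
    composition = (
        truth.groupby(["location", "year", "month", "taxon"])
        .size().rename("count").reset_index()
    )
    composition.to_csv(RESULTS / "01_planted_composition.tsv", sep="\t", index=False)
    sim.truth_loci.to_csv(RESULTS / "01_planted_loci.tsv", sep="\t", index=False)

    print(f"simulated {sim.dataset.n_variants} variants x {sim.dataset.n_samples} "
          f"samples (seed {SEED}) -> {bundle.vcf}")
    print("\nplanted cohort composition:")
    print(composition.to_string(index=False))
    intro = truth[truth["taxon"] == "coluzzii"]["introgression_state"].value_counts(
        normalize=True).mul(100).round(1)
    print(f"\nplanted introgression zygosity among coluzzii (%):\n{intro.to_string()}")
    loci = sim.truth_loci[sim.truth_loci["cohort"] == "Turkana_2019_01"]
    print("\nplanted resistance alleles (Turkana cohort):")
    print(loci[["gene", "substitution", "target_frequency", "realized_frequency"]]
          .to_string(index=False))


if __name__ == "__main__":
    main()
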