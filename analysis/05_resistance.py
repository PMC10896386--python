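"""Insecticide-resistance substitution frequencies per cohort.

Annotates coding effects in the four target genes (Vgsc, Gste2, Rdl,
Ace1), computes per-cohort amino-acid substitution frequencies with the
>5% retention filter, and the joint frequency of the coupled Vgsc
V402L + I1527T pair.
"""

import numpy as np
import pandas as pd

from common import RESULTS, ensure_bundle, load_dataset
from mozpopgen import cohorts, resistance


def main() -> None:
    bundle = ensure_bundle()
    dataset = load_dataset(bundle)
    truth = pd.read_csv(bundle.truth_samples, sep="\t")
    calls = truth[["sample_id", "taxon"]].rename(columns={"taxon": "taxon_call"})
    groups = cohorts.cohort_sample_indices(
        dataset.samples, calls, min_size=8, taxon="coluzzii")

    models = resistance.read_gene_models(bundle.gff3)
    annotation = resistance.annotate_coding_effects(dataset, models, bundle.fasta)
    n_nonsyn = (annotation.effects["effect"] == "non_synonymous").sum()
    print(f"annotated {len(annotation.effects)} in-gene allele effects "
          f"({n_nonsyn} non-synonymous; {len(annotation.rejected_variants)} REF "
          f"mismatches rejected)")

    table = resistance.substitution_frequencies(dataset, annotation.effects, groups)
    table.to_csv(RESULTS / "05_resistance_frequencies.tsv", sep="\t", index=False)
    print("\nsubstitutions above 5% in at least one coluzzii cohort:")
    print(table.round(4).to_string(index=False))

    pairs = [(("Vgsc", "V402L"), ("Vgsc", "I1527T")),
             (("Rdl", "A296G"), ("Rdl", "T345M"))]
    joint_tables = []
    for pair in pairs:
        jt = resistance.double_mutant_frequency(dataset, annotation.effects, pair, groups)
        jt.insert(0, "pair", f"{pair[0][0]}-{pair[0][1]}+{pair[1][1]}")
        joint_tables.append(jt)
    joint = pd.concat(joint_tables, ignore_index=True)
    joint.to_csv(RESULTS / "05_double_mutants.tsv", sep="\t", index=False)
    print("\nlinked substitution pairs (joint frequency via min-dosage):")
    print(joint.round(4).to_string(index=False))

    planted = pd.read_csv(bundle.truth_loci, sep="\t")
    # planting covers every sample in the geographic cohort; the recovered
    # frequency below is over its coluzzii members only, so the two agree
    # to binomial sampling error rather than exactly
    print("\nplanted (whole cohort) vs recovered (coluzzii members):")
    merged = table[table["cohort"].str.contains("Turkana")].merge(
        planted[planted["cohort"] == "Turkana_2019_01"],
        left_on="substitution", right_on="substitution", how="inner")
    print(merged[["gene_x", "substitution", "target_frequency",
                  "realized_frequency", "frequency"]]
          .rename(columns={"gene_x": "gene", "frequency": "recovered"})
          .round(4).to_string(index=False))


if __name__ == "__main__":
    main()
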