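"""Cohort composition from the published Kenyan sampling table, plus the
consolidated end-to-end report on the synthetic bundle.

Reproduces the headline arithmetic — taxon totals and the per-cohort
coluzzii percentages — and runs the full pipeline (classify -> cohorts ->
diversity -> FST -> structure -> resistance) in one call.
"""

from common import RESULTS, SCRATCH, ensure_bundle
from mozpopgen import report
from mozpopgen.cohorts import load_table_t1, taxon_composition


def main() -> None:
    t1 = load_table_t1()
    totals, comp = taxon_composition(t1)
    comp.to_csv(RESULTS / "06_sampling_composition.tsv", sep="\t", index=False)
    print("taxon totals across all Kenyan cohorts:")
    print(totals.to_string())
    colu = comp[(comp["taxon"] == "coluzzii") & (comp["count"] > 0)]
    print("\ncohorts where An. coluzzii was detected:")
    print(colu[["location", "year", "month", "count", "cohort_total",
                "percentage_display"]].to_string(index=False))

    bundle = ensure_bundle()
    out = report.run_report(
        bundle.vcf, bundle.metadata, bundle.aims, SCRATCH / "report",
        mask=bundle.mask, gff3=bundle.gff3, fasta=bundle.fasta,
        config={"structure": {"n_snps": 2000,
                              "karyotype_regions": {"2L_proximal": ["2L", 1, 80_000]}}},
    )
    print(f"\nfull pipeline report written under {out.out_dir}")
    print("summary taxon totals:", out.summary["taxon_totals"])
    print("introgression state %:", out.summary.get("introgression_state_percentages"))


if __name__ == "__main__":
    main()
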