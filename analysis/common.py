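"""Shared paths and the study-scale synthetic dataset for the analysis scripts.

The genotype bundle is large (multi-MB VCF), so it lives under scratch/
and is regenerated deterministically on demand; the numbered scripts
write only small tables under results/.
"""

from pathlib import Path

from mozpopgen import io
from mozpopgen.simulate import (
    CohortSpec,
    SimulationConfig,
    simulate_genotype_dataset,
    write_fixture_bundle,
)

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"
BUNDLE_DIR = SCRATCH / "bundle"

SEED = 17


def study_config(seed: int = SEED) -> SimulationConfig:
    """The study conditions: a Kenyan cohort with all three taxa plus a
    West African coluzzii reference cohort."""
    return SimulationConfig(
        cohorts=[
            CohortSpec("Turkana", 2019, 1, 3.717, 34.857,
                       {"arabiensis": 60, "gambiae": 40, "coluzzii": 100}),
            CohortSpec("Bamako", 2014, 7, 12.64, -8.0, {"coluzzii": 40}),
        ],
        n_variants=20_000,
        introgression_exact_counts=True,
        seed=seed,
    )


def ensure_bundle(seed: int = SEED):
    """Simulate and write the bundle if absent; return (bundle, sim-or-None)."""
    RESULTS.mkdir(exist_ok=True)
    vcf = BUNDLE_DIR / "genotypes.vcf"
    sim = None
    if not vcf.exists():
        sim = simulate_genotype_dataset(study_config(seed))
        write_fixture_bundle(sim, BUNDLE_DIR)
    from mozpopgen.simulate import FixtureBundle

    return FixtureBundle(
        vcf=vcf,
        metadata=BUNDLE_DIR / "metadata.tsv",
        aims=BUNDLE_DIR / "aim_panels.tsv",
        gff3=BUNDLE_DIR / "genes.gff3",
        fasta=BUNDLE_DIR / "reference.fasta",
        mask=BUNDLE_DIR / "mask.bed",
        truth_samples=BUNDLE_DIR / "truth_samples.tsv",
        truth_loci=BUNDLE_DIR / "truth_loci.tsv",
    )


def load_dataset(bundle):
    return io.read_genotype_dataset(bundle.vcf, bundle.metadata, bundle.mask)
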