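"""Synthetic genotype datasets with known ground truth.

The generator emulates the statistical structure the downstream analyses
assume, on a scaled-down genome:

* multiple taxa of the *An. gambiae* complex separated by fixed
  differences at ancestry-informative marker (AIM) sites;
* background polymorphism differentiated between geographic cohorts
  under the Balding–Nichols model with a single FST dial;
* an introgressed chromosomal block (the 2L centromere-proximal region)
  segregating in the recipient taxon at controllable none/het/hom
  zygosity proportions, planted as whole-region allele replacement;
* non-synonymous resistance alleles at controllable frequencies inside
  small synthetic gene models carrying the community gene ids, with the
  Vgsc V402L/I1527T pair planted on a shared haplotype indicator;
* uniform random missingness.

Every draw comes from one seeded :class:`numpy.random.Generator`, so all
outputs are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import logging
import math
import os
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from mozpopgen import io
from mozpopgen.datamodel import MISSING, AimPanel, GenotypeDataset
from mozpopgen.resistance import GeneModel

logger = logging.getLogger(__name__)

PANEL_GC_VS_ARAB = "gambcolu_vs_arabiensis"
PANEL_GAMB_VS_COLU = "gambiae_vs_coluzzii"

_BASES = np.array(list("ACGT"))
_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]


def _codons_for_aa(aa: str) -> list[str]:
    if aa == "*":
        return sorted(_STANDARD_TABLE.stop_codons)
    return sorted(c for c, a in _STANDARD_TABLE.forward_table.items() if a == aa)


def single_base_path(ref_aa: str, alt_aa: str) -> tuple[str, int, str]:
    """A (ref codon, offset, alt base) whose single-base change is ref_aa→alt_aa.

    Deterministic: codons and bases are scanned in lexicographic order.
    """
    for codon in _codons_for_aa(ref_aa):
        for i in range(3):
            for b in "ACGT":
                if b == codon[i]:
                    continue
                mutated = codon[:i] + b + codon[i + 1 :]
                if mutated in _STANDARD_TABLE.stop_codons:
                    mut_aa = "*"
                else:
                    mut_aa = _STANDARD_TABLE.forward_table.get(mutated)
                if mut_aa == alt_aa:
                    return codon, i, b
    raise ValueError(f"no single-base substitution converts {ref_aa} to {alt_aa}")


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class CohortSpec:
    """One sampling cohort: a place and date with per-taxon sample counts."""

    location: str
    year: int
    month: int
    latitude: float = 0.0
    longitude: float = 0.0
    n_per_taxon: dict[str, int] = field(default_factory=dict)

    @property
    def key(self) -> str:
        return f"{self.location}_{self.year}_{self.month:02d}"


@dataclass(frozen=True)
class ResistanceLocus:
    """A planted amino-acid substitution with a target allele frequency.

    ``frequency`` may be a single float (same target in every cohort) or a
    mapping of cohort key to float. Loci sharing a ``linked_group`` are
    planted on the same simulated haplotype indicator (complete coupling).
    """

    gene_id: str
    codon: int
    ref_aa: str
    alt_aa: str
    frequency: float | dict[str, float] = 0.0
    linked_group: str | None = None

    @property
    def label(self) -> str:
        return f"{self.ref_aa}{self.codon}{self.alt_aa}"

    def target(self, cohort_key: str) -> float:
        if isinstance(self.frequency, dict):
            return float(self.frequency.get(cohort_key, 0.0))
        return float(self.frequency)


def default_gene_models() -> list[GeneModel]:
    """Synthetic scaled-down models of the four resistance target genes.

    CDS extents are sized so the community codon labels (V402L, L995F,
    I1527T, I114T, A296G, T345M, G280S) fall inside the coding sequence
    without any numbering offset. Vgsc sits inside the default 2L
    introgression region, as in the field, and Gste2 is on the minus
    strand to exercise strand handling.
    """
    return [
        GeneModel("AGAP004707", "2L", "+",
                  cds=[(10_001, 11_600), (11_801, 13_400), (13_601, 15_200)],
                  name="Vgsc"),  # 4800 bp = 1600 codons
        GeneModel("AGAP006028", "2L", "+", cds=[(200_001, 201_200)], name="Rdl"),
        GeneModel("AGAP001356", "2R", "+", cds=[(50_001, 50_900)], name="Ace1"),
        GeneModel("AGAP009194", "3R", "-",
                  cds=[(30_301, 30_600), (30_001, 30_150)], name="Gste2"),
    ]


def default_resistance_loci() -> list[ResistanceLocus]:
    """Default planted substitutions, echoing frequencies typical of
    pyrethroid/DDT-resistant *An. coluzzii* populations."""
    return [
        ResistanceLocus("AGAP004707", 995, "L", "F", 0.62),
        ResistanceLocus("AGAP004707", 402, "V", "L", 0.38, linked_group="vgsc_402_1527"),
        ResistanceLocus("AGAP004707", 1527, "I", "T", 0.38, linked_group="vgsc_402_1527"),
        ResistanceLocus("AGAP009194", 114, "I", "T", 0.67),
        ResistanceLocus("AGAP006028", 296, "A", "G", 0.05),
        ResistanceLocus("AGAP006028", 345, "T", "M", 0.05),
        ResistanceLocus("AGAP001356", 280, "G", "S", 0.0),
    ]


def default_cohorts() -> list[CohortSpec]:
    return [
        CohortSpec("Turkana", 2019, 1, 3.717, 34.857,
                   {"arabiensis": 60, "gambiae": 40, "coluzzii": 100}),
        CohortSpec("Bamako", 2014, 7, 12.64, -8.0,
                   {"coluzzii": 40}),
    ]


@dataclass
class SimulationConfig:
    taxa: tuple[str, ...] = ("arabiensis", "gambiae", "coluzzii")
    cohorts: list[CohortSpec] = field(default_factory=default_cohorts)
    contig_lengths: dict[str, int] = field(
        default_factory=lambda: {"2L": 400_000, "2R": 300_000,
                                 "3L": 300_000, "3R": 300_000, "X": 150_000}
    )
    n_variants: int = 20_000
    n_aim_sites: dict[str, int] = field(
        default_factory=lambda: {PANEL_GC_VS_ARAB: 2612, PANEL_GAMB_VS_COLU: 700}
    )
    background_fst: float = 0.006
    ancestral_maf: tuple[float, float] = (0.01, 0.5)
    introgression_region: tuple[str, int, int] = ("2L", 1, 80_000)
    introgression_zygosity_proportions: tuple[float, float, float] = (0.16, 0.46, 0.38)
    introgression_taxon: str = "coluzzii"
    introgression_donor: str = "gambiae"
    introgression_exact_counts: bool = False
    #: fraction of gambiae-vs-coluzzii AIMs placed inside the introgression
    #: region so the region always contains informative sites; kept small so
    #: an introgressed sample's genome-wide AIM fraction stays diagnostic
    region_aim_fraction: float = 0.05
    resistance_loci: list[ResistanceLocus] = field(default_factory=default_resistance_loci)
    gene_models: list[GeneModel] = field(default_factory=default_gene_models)
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        props = self.introgression_zygosity_proportions
        if abs(sum(props) - 1.0) > 1e-9 or any(p < 0 for p in props):
            raise ValueError("zygosity proportions must be non-negative and sum to 1")
        if not 0 <= self.background_fst < 1:
            raise ValueError("background_fst must lie in [0, 1)")
        if not 0 <= self.missing_rate <= 1:
            raise ValueError("missing_rate must lie in [0, 1]")
        lo, hi = self.ancestral_maf
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("ancestral_maf bounds must satisfy 0 < lo <= hi <= 0.5")
        n_special = sum(self.n_aim_sites.values()) + len(self.resistance_loci)
        if self.n_variants < n_special:
            raise ValueError(
                f"n_variants={self.n_variants} smaller than AIM + resistance sites ({n_special})"
            )
        contig, start, end = self.introgression_region
        if contig not in self.contig_lengths or not (
            1 <= start <= end <= self.contig_lengths[contig]
        ):
            raise ValueError("introgression region outside simulated contigs")
        for gm in self.gene_models:
            lo_, hi_ = gm.span
            if gm.contig not in self.contig_lengths or hi_ > self.contig_lengths[gm.contig]:
                raise ValueError(f"gene {gm.gene_id} outside simulated contigs")


# ---------------------------------------------------------------------------
# population-frequency model


def simulate_population_frequencies(
    ancestral_freqs: np.ndarray,
    fst: float,
    n_pops: int,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Per-population allele frequencies under the Balding–Nichols model.

    Each population's frequency at a site with ancestral frequency ``p``
    is drawn from ``Beta(p(1-F)/F, (1-p)(1-F)/F)``, which has mean ``p``
    and variance ``F p (1-p)`` — the classical single-parameter model of
    drift-driven differentiation. ``fst = 0`` returns the ancestral
    frequencies unchanged in every population.

    Returns an array of shape ``(n_pops, n_sites)``.
    """
    p = np.asarray(ancestral_freqs, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("ancestral frequencies must lie strictly in (0, 1)")
    if fst == 0:
        return np.tile(p, (n_pops, 1))
    if not 0 < fst < 1:
        raise ValueError("fst must lie in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    scale = (1.0 - fst) / fst
    freqs = rng.beta(p * scale, (1.0 - p) * scale, size=(n_pops, p.size))
    # beta draws can underflow to exactly 0/1 at tiny F·p; keep frequencies usable
    return np.clip(freqs, 1e-12, 1.0 - 1e-12)


# ---------------------------------------------------------------------------
# dataset simulation


@dataclass
class SimulationResult:
    """Everything one simulation produced, ready to analyse or write out."""

    dataset: GenotypeDataset
    truth_samples: pd.DataFrame
    truth_loci: pd.DataFrame
    panels: dict[str, AimPanel]
    gene_models: list[GeneModel]
    reference: dict[str, str]
    mask: pd.DataFrame
    config: SimulationConfig


def _draw_positions(
    rng: np.random.Generator,
    contig_lengths: dict[str, int],
    n: int,
    used: set[tuple[str, int]],
    region: tuple[str, int, int] | None = None,
    exclude: tuple[str, int, int] | None = None,
) -> list[tuple[str, int]]:
    """``n`` distinct unused (contig, position) pairs, uniform over the genome
    (or over ``region``), optionally avoiding an ``exclude`` interval."""
    if region is None:
        contigs = list(contig_lengths)
        weights = np.array([contig_lengths[c] for c in contigs], dtype=float)
        weights /= weights.sum()
    out: list[tuple[str, int]] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 100 * n + 1000:
            raise RuntimeError("could not place variant positions without collision")
        if region is None:
            c = contigs[rng.choice(len(contigs), p=weights)]
            pos = int(rng.integers(1, contig_lengths[c] + 1))
        else:
            c, lo, hi = region
            pos = int(rng.integers(lo, hi + 1))
        if exclude is not None and c == exclude[0] and exclude[1] <= pos <= exclude[2]:
            continue
        key = (c, pos)
        if key in used:
            continue
        used.add(key)
        out.append(key)
    return out


def _build_reference(rng: np.random.Generator, config: SimulationConfig,
                     planted: list[tuple[GeneModel, ResistanceLocus, str]]) -> dict[str, str]:
    """Random contig sequences with planted reference codons written in."""
    seqs = {
        c: rng.choice(_BASES, size=length)
        for c, length in config.contig_lengths.items()
    }
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for gm, locus, ref_codon in planted:
        positions = gm.codon_genomic_positions(locus.codon)
        for base, pos in zip(ref_codon, positions):
            seqs[gm.contig][pos - 1] = base if gm.strand == "+" else comp[base]
    return {c: "".join(s) for c, s in seqs.items()}


def _zygosity_states(rng: np.random.Generator, n: int,
                     props: tuple[float, float, float], exact: bool) -> np.ndarray:
    """Introgression copy number (0/1/2) for ``n`` recipient samples."""
    if exact:
        counts = [math.floor(p * n) for p in props]
        # largest-remainder rounding so the counts total n
        remainders = [p * n - c for p, c in zip(props, counts)]
        for i in np.argsort(remainders)[::-1][: n - sum(counts)]:
            counts[int(i)] += 1
        states = np.repeat([0, 1, 2], counts)
        return rng.permutation(states)
    return rng.choice([0, 1, 2], size=n, p=list(props))


def simulate_genotype_dataset(config: SimulationConfig) -> SimulationResult:
    """Simulate a genotype dataset plus per-sample and per-locus truth tables."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    # -- samples -----------------------------------------------------------
    sample_rows = []
    for cohort in config.cohorts:
        for taxon in config.taxa:
            for k in range(cohort.n_per_taxon.get(taxon, 0)):
                sample_rows.append({
                    "sample_id": f"{cohort.location[:3].upper()}{cohort.year}"
                                 f"{cohort.month:02d}-{taxon[:4]}-{k:03d}",
                    "location": cohort.location,
                    "latitude": cohort.latitude,
                    "longitude": cohort.longitude,
                    "year": cohort.year,
                    "month": cohort.month,
                    "taxon": taxon,
                    "cohort": cohort.key,
                })
        # unknown taxa in n_per_taxon would silently vanish; refuse
        unknown = set(cohort.n_per_taxon) - set(config.taxa)
        if unknown:
            raise ValueError(f"cohort {cohort.key}: unknown taxa {unknown}")
    samples = pd.DataFrame(sample_rows)
    n_samples = len(samples)
    if n_samples == 0:
        raise ValueError("no samples configured")
    taxon_of = samples["taxon"].to_numpy()
    cohort_of = samples["cohort"].to_numpy()
    cohort_keys = [c.key for c in config.cohorts]

    # -- variant positions -------------------------------------------------
    used: set[tuple[str, int]] = set()

    planted_codons = []
    locus_sites = []  # (gene model, locus, genomic pos of variant, ref base, alt base)
    for locus in config.resistance_loci:
        gm = next((g for g in config.gene_models if g.gene_id == locus.gene_id), None)
        if gm is None:
            raise ValueError(f"resistance locus references unknown gene {locus.gene_id}")
        ref_codon, within, alt_base = single_base_path(locus.ref_aa, locus.alt_aa)
        positions = gm.codon_genomic_positions(locus.codon)
        var_pos = int(positions[within])
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        if gm.strand == "+":
            ref_base, alt = ref_codon[within], alt_base
        else:
            ref_base, alt = comp[ref_codon[within]], comp[alt_base]
        if (gm.contig, var_pos) in used:
            raise ValueError(f"resistance loci collide at {gm.contig}:{var_pos}")
        used.add((gm.contig, var_pos))
        planted_codons.append((gm, locus, ref_codon))
        locus_sites.append((gm, locus, var_pos, ref_base, alt))

    reference = _build_reference(rng, config, planted_codons)

    n_gc = config.n_aim_sites.get(PANEL_GC_VS_ARAB, 0)
    n_gvc = config.n_aim_sites.get(PANEL_GAMB_VS_COLU, 0)
    n_gvc_region = min(n_gvc, int(round(config.region_aim_fraction * n_gvc)))
    aim_gc = _draw_positions(rng, config.contig_lengths, n_gc, used)
    # region_aim_fraction is the total in-region share of the panel, so the
    # genome-wide remainder avoids the region
    aim_gvc = _draw_positions(rng, config.contig_lengths, n_gvc_region, used,
                              region=config.introgression_region)
    aim_gvc += _draw_positions(rng, config.contig_lengths, n_gvc - n_gvc_region, used,
                               exclude=config.introgression_region)

    n_background = config.n_variants - n_gc - n_gvc - len(locus_sites)
    background = _draw_positions(rng, config.contig_lengths, n_background, used)

    # assemble the variant table in (contig, pos) order
    records = []
    for c, p in aim_gc:
        records.append((c, p, "aim_gc"))
    for c, p in aim_gvc:
        records.append((c, p, "aim_gvc"))
    for gm, locus, p, ref_base, alt in locus_sites:
        records.append((gm.contig, p, "resistance"))
    for c, p in background:
        records.append((c, p, "background"))
    contig_order = {c: i for i, c in enumerate(config.contig_lengths)}
    records.sort(key=lambda r: (contig_order[r[0]], r[1]))

    n_variants = len(records)
    contigs = np.array([r[0] for r in records])
    positions = np.array([r[1] for r in records], dtype=np.int64)
    kinds = np.array([r[2] for r in records])

    ref_alleles = np.array(
        [reference[c][p - 1] for c, p in zip(contigs, positions)]
    )
    # ALT: a uniformly chosen different base (resistance sites overridden below)
    alt_alleles = np.empty(n_variants, dtype="<U1")
    for i in range(n_variants):
        others = [b for b in "ACGT" if b != ref_alleles[i]]
        alt_alleles[i] = others[rng.integers(0, 3)]
    locus_variant_index = {}
    for gm, locus, p, ref_base, alt in locus_sites:
        i = int(np.flatnonzero((contigs == gm.contig) & (positions == p))[0])
        assert ref_alleles[i] == ref_base
        alt_alleles[i] = alt
        locus_variant_index[(locus.gene_id, locus.label)] = i

    # -- genotypes ---------------------------------------------------------
    genotypes = np.zeros((n_variants, n_samples, 2), dtype=np.int8)

    is_background = kinds == "background"
    nb = int(is_background.sum())
    lo, hi = config.ancestral_maf
    ancestral = rng.uniform(lo, hi, size=nb)
    pop_freqs = simulate_population_frequencies(
        ancestral, config.background_fst, n_pops=len(cohort_keys), seed=rng
    )
    bg_idx = np.flatnonzero(is_background)
    for ci, ckey in enumerate(cohort_keys):
        members = np.flatnonzero(cohort_of == ckey)
        if members.size == 0:
            continue
        draws = rng.random((nb, members.size, 2)) < pop_freqs[ci][:, None, None]
        genotypes[np.ix_(bg_idx, members)] = draws.astype(np.int8)

    # AIM fixed differences: allele_a (REF) vs allele_b (ALT)
    arab = np.flatnonzero(taxon_of == "arabiensis")
    colu = np.flatnonzero(taxon_of == config.introgression_taxon)
    gc_idx = np.flatnonzero(kinds == "aim_gc")
    gvc_idx = np.flatnonzero(kinds == "aim_gvc")
    genotypes[np.ix_(gc_idx, arab)] = 1   # arabiensis carries allele_b
    genotypes[np.ix_(gvc_idx, colu)] = 1  # coluzzii carries allele_b

    # -- introgression planting -------------------------------------------
    region_contig, r_lo, r_hi = config.introgression_region
    in_region = (
        (kinds == "aim_gvc") & (contigs == region_contig)
        & (positions >= r_lo) & (positions <= r_hi)
    )
    region_sites = np.flatnonzero(in_region)
    recipients = np.flatnonzero(taxon_of == config.introgression_taxon)
    states = _zygosity_states(
        rng, recipients.size, config.introgression_zygosity_proportions,
        config.introgression_exact_counts,
    )
    state_name = np.array(["none", "heterozygous", "homozygous"])
    for s, sample in zip(states, recipients):
        if s >= 1:
            genotypes[region_sites, sample, 0] = 0  # donor (gambiae) allele
        if s == 2:
            genotypes[region_sites, sample, 1] = 0

    introgression_state = np.full(n_samples, "", dtype=object)
    introgression_state[recipients] = state_name[states]

    # -- resistance planting ----------------------------------------------
    group_haplotypes: dict[tuple[str, str], np.ndarray] = {}
    truth_loci_rows = []
    for gm, locus, p, ref_base, alt in locus_sites:
        vi = locus_variant_index[(locus.gene_id, locus.label)]
        for cohort in config.cohorts:
            members = np.flatnonzero(cohort_of == cohort.key)
            if members.size == 0:
                continue
            f = locus.target(cohort.key)
            if not 0 <= f <= 1:
                raise ValueError(f"target frequency {f} for {locus.label} outside [0, 1]")
            achievable = round(f * 2 * members.size) / (2 * members.size)
            if f > 0 and achievable == 0:
                warnings.warn(
                    f"{locus.label}: target {f} unachievable with {members.size} samples "
                    f"in {cohort.key}; rounding to 0", stacklevel=2)
            if locus.linked_group is not None:
                key = (locus.linked_group, cohort.key)
                if key not in group_haplotypes:
                    group_haplotypes[key] = rng.random((members.size, 2)) < f
                carrier = group_haplotypes[key]
            else:
                carrier = rng.random((members.size, 2)) < f
            genotypes[vi, members] = carrier.astype(np.int8)
            realized = carrier.sum() / (2 * members.size)
            truth_loci_rows.append({
                "gene_id": locus.gene_id, "gene": gm.name, "substitution": locus.label,
                "contig": gm.contig, "pos": p, "ref": ref_base, "alt": alt,
                "cohort": cohort.key, "target_frequency": f,
                "realized_frequency": realized,
                "linked_group": locus.linked_group or "",
            })

    # -- missingness -------------------------------------------------------
    if config.missing_rate > 0:
        miss = rng.random((n_variants, n_samples)) < config.missing_rate
        genotypes[miss] = MISSING

    variants = pd.DataFrame({
        "contig": contigs, "pos": positions,
        "ref": ref_alleles, "alt": alt_alleles, "is_pass": True,
    })
    metadata = samples.drop(columns=["cohort"])
    dataset = GenotypeDataset(genotypes, variants, metadata, dict(config.contig_lengths))

    truth_samples = samples.copy()
    truth_samples["introgression_state"] = introgression_state
    truth_loci = pd.DataFrame(truth_loci_rows)

    panels = {}
    if n_gc:
        sites = pd.DataFrame(sorted(aim_gc, key=lambda r: (contig_order[r[0]], r[1])),
                             columns=["contig", "position"])
        sites["allele_a"] = [reference[c][p - 1] for c, p in zip(sites["contig"], sites["position"])]
        idx = {(c, p): i for i, (c, p) in enumerate(zip(contigs, positions))}
        sites["allele_b"] = [alt_alleles[idx[(c, p)]] for c, p in zip(sites["contig"], sites["position"])]
        panels[PANEL_GC_VS_ARAB] = AimPanel(PANEL_GC_VS_ARAB, "gambcolu", "arabiensis", sites)
    if n_gvc:
        sites = pd.DataFrame(sorted(aim_gvc, key=lambda r: (contig_order[r[0]], r[1])),
                             columns=["contig", "position"])
        sites["allele_a"] = [reference[c][p - 1] for c, p in zip(sites["contig"], sites["position"])]
        idx = {(c, p): i for i, (c, p) in enumerate(zip(contigs, positions))}
        sites["allele_b"] = [alt_alleles[idx[(c, p)]] for c, p in zip(sites["contig"], sites["position"])]
        panels[PANEL_GAMB_VS_COLU] = AimPanel(PANEL_GAMB_VS_COLU, "gambiae", "coluzzii", sites)

    mask = pd.DataFrame({
        "contig": list(config.contig_lengths),
        "start": 1,
        "end": list(config.contig_lengths.values()),
    })

    return SimulationResult(
        dataset=dataset, truth_samples=truth_samples, truth_loci=truth_loci,
        panels=panels, gene_models=list(config.gene_models),
        reference=reference, mask=mask, config=config,
    )


# ---------------------------------------------------------------------------
# fixture bundle


@dataclass
class FixtureBundle:
    """Paths of one written simulation bundle."""

    vcf: Path
    metadata: Path
    aims: Path
    gff3: Path
    fasta: Path
    mask: Path
    truth_samples: Path
    truth_loci: Path


def write_fixture_bundle(sim: SimulationResult, out_dir: str | os.PathLike) -> FixtureBundle:
    """Write a simulation as a standards-conformant file bundle.

    Emits VCF (diploid GT), metadata TSV, AIM panel TSV, GFF3 gene models,
    the reference FASTA, the BED accessibility mask, and the two truth
    tables. Refuses to write if any VCF REF allele disagrees with the
    FASTA, so a bundle on disk is always internally consistent.
    """
    out = io.ensure_dir(out_dir)
    ds = sim.dataset
    for i in range(ds.n_variants):
        row = ds.variants.iloc[i]
        if sim.reference[row["contig"]][row["pos"] - 1] != row["ref"]:
            raise ValueError(
                f"REF mismatch at {row['contig']}:{row['pos']}: "
                f"VCF {row['ref']} vs FASTA {sim.reference[row['contig']][row['pos'] - 1]}"
            )
    bundle = FixtureBundle(
        vcf=out / "genotypes.vcf",
        metadata=out / "metadata.tsv",
        aims=out / "aim_panels.tsv",
        gff3=out / "genes.gff3",
        fasta=out / "reference.fasta",
        mask=out / "mask.bed",
        truth_samples=out / "truth_samples.tsv",
        truth_loci=out / "truth_loci.tsv",
    )
    io.write_vcf(ds, bundle.vcf)
    io.write_metadata(ds.samples, bundle.metadata)
    io.write_aim_panels(sim.panels, bundle.aims)
    io.write_gff3(sim.gene_models, bundle.gff3)
    io.write_fasta(sim.reference, bundle.fasta)
    io.write_bed_mask(sim.mask, bundle.mask)
    sim.truth_samples.to_csv(bundle.truth_samples, sep="\t", index=False)
    sim.truth_loci.to_csv(bundle.truth_loci, sep="\t", index=False)
    # drop any stale pyfaidx index so readers re-index the fresh FASTA
    fai = Path(str(bundle.fasta) + ".fai")
    if fai.exists():
        fai.unlink()
    return bundle
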