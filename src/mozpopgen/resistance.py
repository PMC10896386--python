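"""Coding-effect annotation and amino-acid substitution frequencies.

Target-site insecticide resistance in *Anopheles* is tracked through a
small set of genes — the voltage-gated sodium channel (Vgsc, AGAP004707;
pyrethroids/DDT), Gste2 (AGAP009194; metabolic DDT resistance), Rdl
(AGAP006028; dieldrin) and Ace1 (AGAP001356; organophosphates/carbamates).
This module annotates SNPs inside configured gene models with their codon
effect, computes per-cohort substitution frequencies with a retention
filter (substitutions above a frequency threshold in at least one cohort),
and estimates joint frequencies for linked substitution pairs such as
Vgsc V402L + I1527T.

Each SNP is evaluated against the reference codon background
independently; no codon-haplotype (MNV) reconstruction is attempted.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from pyfaidx import Fasta

from mozpopgen.datamodel import MISSING, GenotypeDataset

logger = logging.getLogger(__name__)

#: community gene identifiers for the default resistance targets
DEFAULT_TARGET_GENES = {
    "AGAP004707": "Vgsc",
    "AGAP009194": "Gste2",
    "AGAP006028": "Rdl",
    "AGAP001356": "Ace1",
}

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


@dataclass
class GeneModel:
    """A protein-coding gene: ordered CDS intervals on one contig.

    ``cds`` holds 1-based inclusive ``(start, end)`` intervals in
    transcription order (descending genomic coordinates for minus-strand
    genes). ``codon_offset`` shifts reported codon numbers so community
    substitution labels (e.g. L995F) can be reproduced regardless of the
    transcript used for numbering.
    """

    gene_id: str
    contig: str
    strand: str
    cds: list[tuple[int, int]]
    codon_offset: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        spans = sorted(self.cds)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.gene_id}: overlapping CDS intervals")

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    @property
    def n_codons(self) -> int:
        return self.cds_length // 3

    @property
    def span(self) -> tuple[int, int]:
        return min(s for s, _ in self.cds), max(e for _, e in self.cds)

    def cds_positions(self) -> np.ndarray:
        """Genomic positions of every CDS base, in transcription order."""
        chunks = []
        for s, e in self.cds:
            if self.strand == "+":
                chunks.append(np.arange(s, e + 1))
            else:
                chunks.append(np.arange(e, s - 1, -1))
        return np.concatenate(chunks)

    def codon_genomic_positions(self, codon_number: int) -> np.ndarray:
        """Genomic positions (transcription order) of the codon with this label."""
        idx = codon_number - 1 - self.codon_offset
        if not 0 <= idx < self.n_codons:
            raise ValueError(f"{self.gene_id}: codon {codon_number} outside CDS")
        return self.cds_positions()[3 * idx : 3 * idx + 3]


def read_gene_models(gff3_path: str | os.PathLike) -> list[GeneModel]:
    """Load gene models (gene/mRNA/CDS) from GFF3 via :mod:`gffutils`."""
    import gffutils

    db = gffutils.create_db(
        str(gff3_path), dbfn=":memory:", merge_strategy="create_unique", keep_order=True
    )
    models = []
    for gene in db.features_of_type("gene"):
        cds = list(db.children(gene, featuretype="CDS", order_by="start"))
        if not cds:
            continue
        intervals = [(c.start, c.end) for c in cds]
        if gene.strand == "-":
            intervals = intervals[::-1]
        name = gene.attributes.get("Name", [""])[0]
        models.append(
            GeneModel(
                gene_id=gene.id,
                contig=gene.seqid,
                strand=gene.strand,
                cds=intervals,
                name=name,
            )
        )
    return models


@dataclass
class AnnotationResult:
    """Per-variant coding effects plus the variants/genes that were rejected."""

    effects: pd.DataFrame
    rejected_variants: list[dict] = field(default_factory=list)
    rejected_genes: list[str] = field(default_factory=list)


def _translate(codon: str) -> str:
    return str(Seq(codon).translate())


def annotate_coding_effects(
    dataset: GenotypeDataset,
    gene_models: list[GeneModel],
    reference_fasta: str | os.PathLike,
) -> AnnotationResult:
    """Classify each in-gene SNP as synonymous / non-synonymous / non-coding.

    For every ALT allele of a variant inside a gene model's span, the
    reference codon is looked up from the FASTA (reverse-complemented for
    minus-strand genes), mutated at the variant base and translated with
    the standard genetic code. Non-synonymous changes get the label
    ``<refAA><codon><altAA>`` with ``codon = CDS index // 3 + 1 + offset``.

    Variants whose VCF REF disagrees with the FASTA base are rejected (and
    logged); genes whose CDS length is not a multiple of 3 are rejected.
    """
    fasta = Fasta(str(reference_fasta), as_raw=True, sequence_always_upper=True)
    rows: list[dict] = []
    rejected_variants: list[dict] = []
    rejected_genes: list[str] = []

    contigs = dataset.variants["contig"].to_numpy()
    positions = dataset.variants["pos"].to_numpy()

    for gm in gene_models:
        if gm.cds_length % 3 != 0:
            logger.warning("gene %s: CDS length %d not a multiple of 3; gene rejected",
                           gm.gene_id, gm.cds_length)
            rejected_genes.append(gm.gene_id)
            continue
        span_lo, span_hi = gm.span
        in_span = np.flatnonzero(
            (contigs == gm.contig) & (positions >= span_lo) & (positions <= span_hi)
        )
        if in_span.size == 0:
            continue
        cds_pos = gm.cds_positions()
        pos_to_idx = {int(p): i for i, p in enumerate(cds_pos)}
        for vi in in_span:
            vi = int(vi)
            pos = int(positions[vi])
            alleles = dataset.alleles(vi)
            ref = alleles[0]
            genome_base = str(fasta[gm.contig][pos - 1 : pos])
            if len(ref) == 1 and genome_base != ref:
                logger.warning("variant %s:%d REF %s != FASTA %s; variant rejected",
                               gm.contig, pos, ref, genome_base)
                rejected_variants.append({"contig": gm.contig, "pos": pos,
                                          "ref": ref, "fasta": genome_base})
                continue
            cds_idx = pos_to_idx.get(pos)
            for alt_index, alt in enumerate(alleles[1:], start=1):
                if len(ref) != 1 or len(alt) != 1:
                    continue  # indels / MNVs out of scope
                base = {
                    "variant_index": vi,
                    "gene_id": gm.gene_id,
                    "gene_name": gm.name or gm.gene_id,
                    "contig": gm.contig,
                    "pos": pos,
                    "alt_index": alt_index,
                    "alt_allele": alt,
                }
                if cds_idx is None:
                    rows.append({**base, "effect": "non_coding", "codon_number": -1,
                                 "aa_ref": "", "aa_alt": "", "label": ""})
                    continue
                codon_number = cds_idx // 3 + 1 + gm.codon_offset
                codon_positions = cds_pos[3 * (cds_idx // 3) : 3 * (cds_idx // 3) + 3]
                codon = "".join(str(fasta[gm.contig][int(p) - 1 : int(p)]) for p in codon_positions)
                new_base = alt
                if gm.strand == "-":
                    codon = codon.translate(_COMPLEMENT)
                    new_base = alt.translate(_COMPLEMENT)
                within = cds_idx % 3
                mutated = codon[:within] + new_base + codon[within + 1 :]
                aa_ref = _translate(codon)
                aa_alt = _translate(mutated)
                if aa_ref == aa_alt:
                    rows.append({**base, "effect": "synonymous", "codon_number": codon_number,
                                 "aa_ref": aa_ref, "aa_alt": aa_alt, "label": ""})
                else:
                    rows.append({**base, "effect": "non_synonymous", "codon_number": codon_number,
                                 "aa_ref": aa_ref, "aa_alt": aa_alt,
                                 "label": f"{aa_ref}{codon_number}{aa_alt}"})
    effects = pd.DataFrame(
        rows,
        columns=["variant_index", "gene_id", "gene_name", "contig", "pos", "alt_index",
                 "alt_allele", "effect", "codon_number", "aa_ref", "aa_alt", "label"],
    )
    return AnnotationResult(effects, rejected_variants, rejected_genes)


def _allele_dosage(dataset: GenotypeDataset, variant_index: int, allele_index: int) -> np.ndarray:
    """Per-sample dosage (0/1/2) of one allele; -1 where the call is missing."""
    g = dataset.genotypes[variant_index]
    dosage = (g == allele_index).sum(axis=1).astype(np.int8)
    dosage[(g == MISSING).any(axis=1)] = MISSING
    return dosage


def substitution_frequencies(
    dataset: GenotypeDataset,
    effects: pd.DataFrame,
    cohorts: dict[str, np.ndarray],
    retention: float = 0.05,
    keep_all: bool = False,
) -> pd.DataFrame:
    """Per-cohort allele frequency of every non-synonymous substitution.

    Frequency is the ALT allele count over the called allele count within
    the cohort; several variants that produce the same amino-acid
    substitution have their frequencies summed. Substitutions whose
    frequency does not exceed ``retention`` in any cohort are dropped
    unless ``keep_all`` (the ``retained`` flag is kept either way).
    """
    if not cohorts:
        raise ValueError("at least one cohort required")
    nonsyn = effects[effects["effect"] == "non_synonymous"]
    records = []
    for (gene, label), group in nonsyn.groupby(["gene_name", "label"], sort=True):
        per_cohort_freq: dict[str, float] = {}
        per_cohort_called: dict[str, int] = {}
        for cohort, idx in cohorts.items():
            idx = np.asarray(idx)
            freq_sum, called_min = 0.0, None
            for _, row in group.iterrows():
                dosage = _allele_dosage(dataset, int(row["variant_index"]), int(row["alt_index"]))
                d = dosage[idx]
                called = int(2 * (d != MISSING).sum())
                if called == 0:
                    freq_sum, called_min = np.nan, 0
                    break
                freq_sum += float(d[d != MISSING].sum()) / called
                called_min = called if called_min is None else min(called_min, called)
            per_cohort_freq[cohort] = freq_sum
            per_cohort_called[cohort] = called_min or 0
        retained = any(
            np.isfinite(f) and f > retention for f in per_cohort_freq.values()
        )
        for cohort in cohorts:
            records.append(
                {
                    "gene": gene,
                    "substitution": label,
                    "positions": ",".join(str(p) for p in sorted(group["pos"].unique())),
                    "cohort": cohort,
                    "frequency": per_cohort_freq[cohort],
                    "n_called": per_cohort_called[cohort],
                    "retained": retained,
                }
            )
    table = pd.DataFrame(
        records,
        columns=["gene", "substitution", "positions", "cohort", "frequency",
                 "n_called", "retained"],
    )
    if not keep_all and len(table):
        table = table[table["retained"]].reset_index(drop=True)
    return table


def double_mutant_frequency(
    dataset: GenotypeDataset,
    effects: pd.DataFrame,
    substitution_pair: tuple[tuple[str, str], tuple[str, str]],
    cohorts: dict[str, np.ndarray],
) -> pd.DataFrame:
    """Joint per-cohort frequency of a linked substitution pair.

    Genotypes are unphased, so the joint allele frequency is estimated as
    the cohort mean of ``min(dosage1, dosage2) / 2``. The estimator is
    exact when the pair is in complete coupling, which is the regime the
    pair lists (e.g. Vgsc V402L + I1527T) are meant for. Samples with a
    missing call at either site are excluded.
    """
    nonsyn = effects[effects["effect"] == "non_synonymous"]
    dosages = []
    for gene, label in substitution_pair:
        rows = nonsyn[(nonsyn["gene_name"] == gene) & (nonsyn["label"] == label)]
        if rows.empty:
            logger.warning("substitution %s %s absent from dataset; joint frequency 0", gene, label)
            dosages.append(None)
            continue
        total = np.zeros(dataset.n_samples, dtype=np.int16)
        miss = np.zeros(dataset.n_samples, dtype=bool)
        for _, row in rows.iterrows():
            d = _allele_dosage(dataset, int(row["variant_index"]), int(row["alt_index"]))
            miss |= d == MISSING
            total += np.where(d == MISSING, 0, d)
        total = np.minimum(total, 2).astype(np.int8)
        total[miss] = MISSING
        dosages.append(total)

    records = []
    for cohort, idx in cohorts.items():
        idx = np.asarray(idx)
        if any(d is None for d in dosages):
            records.append({"cohort": cohort, "joint_frequency": 0.0,
                            "frequency_1": 0.0, "frequency_2": 0.0,
                            "n_both_carriers": 0, "n_samples": len(idx)})
            continue
        d1, d2 = dosages[0][idx], dosages[1][idx]
        ok = (d1 != MISSING) & (d2 != MISSING)
        n = int(ok.sum())
        if n == 0:
            joint = f1 = f2 = np.nan
            carriers = 0
        else:
            joint = float(np.minimum(d1[ok], d2[ok]).mean()) / 2.0
            f1 = float(d1[ok].mean()) / 2.0
            f2 = float(d2[ok].mean()) / 2.0
            carriers = int(((d1[ok] > 0) & (d2[ok] > 0)).sum())
        records.append({"cohort": cohort, "joint_frequency": joint,
                        "frequency_1": f1, "frequency_2": f2,
                        "n_both_carriers": carriers, "n_samples": n})
    return pd.DataFrame(records)
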