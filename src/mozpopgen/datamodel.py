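"""Shared in-memory containers for genotype data and AIM panels.

The central object is :class:`GenotypeDataset`: a dense diploid genotype
array (variants x samples x 2 allele indices, ``-1`` = missing call)
together with a variant table, per-sample metadata and contig lengths.
Datasets here are desk-scale (at most a few hundred thousand variants), so
a plain :class:`numpy.ndarray` is the right container; chunked storage
backends are deliberately out of scope.

Coordinates are 1-based inclusive everywhere in memory; BED intervals are
converted at the file boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

#: columns required of a sample metadata table
METADATA_COLUMNS = ["sample_id", "location", "latitude", "longitude", "year", "month"]


@dataclass
class GenotypeDataset:
    """Diploid genotypes plus variant and sample annotations.

    Attributes
    ----------
    genotypes:
        ``int8`` array of shape ``(n_variants, n_samples, 2)`` holding
        allele indices (0 = REF, 1.. = ALT order), ``-1`` for missing.
        Half-calls are stored fully missing.
    variants:
        DataFrame with columns ``contig``, ``pos`` (1-based), ``ref``,
        ``alt`` (comma-joined ALT alleles) and ``is_pass`` (site-filter
        mask flag). Positions are strictly increasing within each contig.
    samples:
        DataFrame with at least :data:`METADATA_COLUMNS`, ordered exactly
        as the genotype columns.
    contig_lengths:
        Mapping of contig name to length in bases.
    """

    genotypes: np.ndarray
    variants: pd.DataFrame
    samples: pd.DataFrame
    contig_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n_var, n_samp, ploidy = self.genotypes.shape
        if ploidy != 2:
            raise ValueError("genotypes must be diploid (last axis of size 2)")
        if len(self.variants) != n_var:
            raise ValueError(
                f"variant table has {len(self.variants)} rows for {n_var} variants"
            )
        if len(self.samples) != n_samp:
            raise ValueError(
                f"sample table has {len(self.samples)} rows for {n_samp} samples"
            )
        for contig, group in self.variants.groupby("contig", sort=False):
            pos = group["pos"].to_numpy()
            if not np.all(np.diff(pos) > 0):
                raise ValueError(f"positions not strictly increasing on {contig}")

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples["sample_id"])

    def n_alleles(self) -> np.ndarray:
        """Number of alleles (REF + ALTs) at each variant."""
        alt = self.variants["alt"].astype(str)
        return (1 + alt.str.count(",") + (alt.str.len() > 0)).to_numpy(dtype=int)

    def is_biallelic(self) -> np.ndarray:
        return self.n_alleles() == 2

    def alleles(self, i: int) -> list[str]:
        """REF followed by the ALT alleles of variant ``i``."""
        row = self.variants.iloc[i]
        alts = [a for a in str(row["alt"]).split(",") if a]
        return [row["ref"], *alts]

    def sample_indices(self, sample_ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples["sample_id"])}
        missing = [s for s in sample_ids if s not in lookup]
        if missing:
            raise KeyError(f"samples not in dataset: {missing}")
        return np.asarray([lookup[s] for s in sample_ids], dtype=int)

    def variant_mask(self, contig: str, start: int | None = None, end: int | None = None) -> np.ndarray:
        """Boolean mask over variants in ``contig[:start-end]`` (1-based inclusive)."""
        m = (self.variants["contig"] == contig).to_numpy()
        pos = self.variants["pos"].to_numpy()
        if start is not None:
            m &= pos >= start
        if end is not None:
            m &= pos <= end
        return m

    def take_variants(self, index: np.ndarray) -> "GenotypeDataset":
        return GenotypeDataset(
            genotypes=self.genotypes[index],
            variants=self.variants.iloc[np.asarray(index)].reset_index(drop=True),
            samples=self.samples,
            contig_lengths=self.contig_lengths,
        )


@dataclass
class AimPanel:
    """A panel of ancestry-informative markers for one taxon pair.

    Each row gives a genomic position with the allele diagnostic for
    ``taxon_a`` and the allele diagnostic for ``taxon_b``. Positions are
    unique within a panel and the two diagnostic alleles always differ.
    """

    name: str
    taxon_a: str
    taxon_b: str
    sites: pd.DataFrame  # columns: contig, position, allele_a, allele_b

    def __post_init__(self) -> None:
        s = self.sites
        if (s["allele_a"] == s["allele_b"]).any():
            raise ValueError(f"panel {self.name}: diagnostic alleles identical at some sites")
        if s.duplicated(["contig", "position"]).any():
            raise ValueError(f"panel {self.name}: duplicate positions")

    def diagnostic_allele(self, taxon: str) -> str:
        if taxon == self.taxon_a:
            return "allele_a"
        if taxon == self.taxon_b:
            return "allele_b"
        raise ValueError(f"taxon {taxon!r} not in panel {self.name} ({self.taxon_a}/{self.taxon_b})")


def allele_counts(
    dataset: GenotypeDataset,
    sample_index: np.ndarray | None = None,
    max_alleles: int | None = None,
) -> np.ndarray:
    """Count each allele per variant over a set of samples.

    Missing calls are excluded. Returns an integer array of shape
    ``(n_variants, max_alleles)`` where column ``a`` holds the number of
    observed copies of allele index ``a``.
    """
    g = dataset.genotypes
    if sample_index is not None:
        sample_index = np.asarray(sample_index)
        if sample_index.size == 0:
            raise ValueError("empty cohort: cannot count alleles over zero samples")
        g = g[:, sample_index, :]
    if max_alleles is None:
        max_alleles = max(2, int(dataset.n_alleles().max(initial=2)))
    flat = g.reshape(g.shape[0], -1)
    counts = np.empty((g.shape[0], max_alleles), dtype=np.int64)
    for a in range(max_alleles):
        counts[:, a] = (flat == a).sum(axis=1)
    return counts


def allele_counts_by_cohort(
    dataset: GenotypeDataset,
    cohorts: dict[str, np.ndarray],
    max_alleles: int | None = None,
) -> dict[str, np.ndarray]:
    """Allele counts for each cohort of a ``{name: sample indices}`` mapping."""
    if max_alleles is None:
        max_alleles = max(2, int(dataset.n_alleles().max(initial=2)))
    return {
        name: allele_counts(dataset, np.asarray(idx), max_alleles=max_alleles)
        for name, idx in cohorts.items()
    }
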