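"""Population-structure analyses: SNP selection, PCA, NJ tree, karyotype PCA.

Structure SNPs follow the standard surveillance recipe: PASS biallelic
sites with minor allele frequency above a floor and no missing calls,
thinned to a target count by equal rank spacing along the chromosome
(chromosome 3 in practice, being free of the large polymorphic
inversions). PCA runs on centered (optionally Patterson-scaled)
alternate-allele dosages; the neighbour-joining tree on cityblock (L1)
distances between raw dosage vectors; and inversion karyotypes (2La,
2Rb) are read off as discrete clusters along PC1 of a region-restricted
PCA, where the 0/1/2 inversion copy numbers appear as three equally
spaced groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.tree import nj

from mozpopgen.datamodel import MISSING, GenotypeDataset, allele_counts

logger = logging.getLogger(__name__)


@dataclass
class SnpSelection:
    """Indices of the chosen variants plus a filter log."""

    indices: np.ndarray
    log: dict = field(default_factory=dict)


def select_structure_snps(
    dataset: GenotypeDataset,
    contigs: list[str] | None = None,
    region: tuple[str, int, int] | None = None,
    n_target: int = 100_000,
    maf_min: float = 0.002,
    sample_index: np.ndarray | None = None,
) -> SnpSelection:
    """Choose up to ``n_target`` equally rank-spaced qualifying SNPs.

    Qualifying: PASS, biallelic, minor allele frequency > ``maf_min`` and
    no missing calls among the considered samples. "Equally distributed"
    is implemented as equal spacing by rank among qualifying SNPs, which
    guarantees the exact target count whenever enough SNPs qualify; if
    fewer qualify, all are returned and the shortfall logged.
    """
    if n_target < 1:
        raise ValueError("n_target must be >= 1")
    keep = dataset.variants["is_pass"].to_numpy().copy()
    if region is not None:
        keep &= dataset.variant_mask(*region)
    elif contigs is not None:
        keep &= dataset.variants["contig"].isin(contigs).to_numpy()
    n_considered = int(keep.sum())

    keep &= dataset.is_biallelic()
    n_biallelic = int(keep.sum())

    idx = sample_index if sample_index is not None else np.arange(dataset.n_samples)
    g = dataset.genotypes[:, np.asarray(idx), :]
    no_missing = ~(g == MISSING).any(axis=(1, 2))
    keep_missing = keep & no_missing
    n_no_missing = int(keep_missing.sum())

    ac = allele_counts(dataset, np.asarray(idx), max_alleles=2)
    totals = ac.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(totals > 0, ac[:, 1] / totals, 0.0)
    maf = np.minimum(p, 1 - p)
    qualified = keep_missing & (maf > maf_min)
    n_maf = int(qualified.sum())

    q_idx = np.flatnonzero(qualified)
    if q_idx.size == 0:
        raise ValueError("no SNPs qualify for structure analysis")
    if q_idx.size <= n_target:
        chosen = q_idx
        if q_idx.size < n_target:
            logger.info("only %d of %d requested SNPs qualify; using all", q_idx.size, n_target)
    else:
        ranks = (np.arange(n_target) * q_idx.size) // n_target
        chosen = q_idx[ranks]
    return SnpSelection(
        indices=chosen,
        log={
            "n_considered": n_considered,
            "n_biallelic": n_biallelic,
            "n_no_missing": n_no_missing,
            "n_maf": n_maf,
            "n_selected": int(chosen.size),
            "n_target": n_target,
        },
    )


def dosage_matrix(
    dataset: GenotypeDataset,
    selection: SnpSelection,
    sample_index: np.ndarray | None = None,
) -> np.ndarray:
    """Samples x variants alternate-allele dosage (0/1/2) for selected SNPs."""
    g = dataset.genotypes[selection.indices]
    if sample_index is not None:
        g = g[:, np.asarray(sample_index), :]
    return (g == 1).sum(axis=2).T.astype(float)


@dataclass
class PcaResult:
    coords: pd.DataFrame           # sample_id + PC1..PCk
    explained_variance: np.ndarray  # fractions, non-increasing
    n_variants_used: int
    n_dropped_constant: int = 0


def pca_dosage(
    dataset: GenotypeDataset,
    selection: SnpSelection,
    k: int = 10,
    scale: str = "patterson",
    sample_index: np.ndarray | None = None,
) -> PcaResult:
    """PCA of the dosage matrix, deterministic up to component sign.

    Variants are centered; with ``scale="patterson"`` each is divided by
    ``sqrt(p (1 - p))`` with ``p`` the alternate-allele frequency, the
    standard normalisation for genotype PCA. Constant variants are
    dropped (and logged). Component signs are fixed so the largest-
    magnitude coordinate on each PC is positive, making results invariant
    to sample order.
    """
    X = dosage_matrix(dataset, selection, sample_index)
    n_samples = X.shape[0]
    if k >= n_samples:
        raise ValueError("k must be smaller than the number of samples")
    mean = X.mean(axis=0)
    keep = ~np.all(X == X[0], axis=0)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropping %d constant variants before PCA", dropped)
    if not keep.any():
        # nothing varies: all samples coincide at the origin
        coords = np.zeros((n_samples, k))
        ids = dataset.sample_ids
        if sample_index is not None:
            ids = [ids[i] for i in np.asarray(sample_index)]
        out = pd.DataFrame(coords, columns=[f"PC{j + 1}" for j in range(k)])
        out.insert(0, "sample_id", ids)
        return PcaResult(out, np.zeros(k), n_variants_used=0, n_dropped_constant=dropped)
    X = X[:, keep] - mean[keep]
    if scale == "patterson":
        p = mean[keep] / 2.0
        X = X / np.sqrt(p * (1 - p))
    elif scale not in (None, "none"):
        raise ValueError(f"unknown scaling {scale!r}")
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    coords = U[:, :k] * s[:k]
    # sign convention: largest |coordinate| positive on each component
    for j in range(coords.shape[1]):
        i = np.argmax(np.abs(coords[:, j]))
        if coords[i, j] < 0:
            coords[:, j] = -coords[:, j]
    explained = (s**2) / (s**2).sum()
    ids = dataset.sample_ids
    if sample_index is not None:
        ids = [ids[i] for i in np.asarray(sample_index)]
    out = pd.DataFrame(coords, columns=[f"PC{j + 1}" for j in range(k)])
    out.insert(0, "sample_id", ids)
    return PcaResult(out, explained[:k], n_variants_used=int(keep.sum()),
                     n_dropped_constant=dropped)


@dataclass
class TreeResult:
    tree: object                   # skbio.TreeNode, unrooted
    newick: str
    n_negative_clamped: int = 0


def nj_tree(
    dataset: GenotypeDataset,
    selection: SnpSelection,
    metric: str = "cityblock",
    sample_index: np.ndarray | None = None,
) -> TreeResult:
    """Unrooted neighbour-joining tree on dosage-vector distances.

    Distances are cityblock (L1) between raw (unscaled) dosage vectors;
    agglomeration is Saitou–Nei NJ with negative branch lengths clamped
    to zero (the clamp count is recorded). Ties resolve deterministically
    by input (sample) order.
    """
    X = dosage_matrix(dataset, selection, sample_index)
    if X.shape[0] < 3:
        raise ValueError("need at least three samples for a tree")
    ids = dataset.sample_ids
    if sample_index is not None:
        ids = [ids[i] for i in np.asarray(sample_index)]
    dm = DistanceMatrix(squareform(pdist(X, metric=metric)), ids=ids)
    raw = nj(dm, neg_as_zero=False)
    clamped = sum(
        1 for node in raw.traverse() if node.length is not None and node.length < 0
    )
    if clamped:
        logger.info("clamped %d negative NJ branch lengths to zero", clamped)
    tree = nj(dm, neg_as_zero=True)
    return TreeResult(tree=tree, newick=str(tree).strip(), n_negative_clamped=clamped)


def nj_from_distance_matrix(dist: np.ndarray, ids: list[str]) -> TreeResult:
    """NJ directly from a precomputed distance matrix (used for validation)."""
    dm = DistanceMatrix(np.asarray(dist, dtype=float), ids=ids)
    tree = nj(dm, neg_as_zero=True)
    return TreeResult(tree=tree, newick=str(tree).strip())


@dataclass
class KaryotypeResult:
    clusters: pd.DataFrame  # sample_id, cluster (0/1/2 ordered by mean PC1)
    pca: PcaResult
    n_clusters: int


def karyotype_pca(
    dataset: GenotypeDataset,
    inversion_region: tuple[str, int, int],
    sample_index: np.ndarray | None = None,
    min_snps: int = 50,
    maf_min: float = 0.0,
    gap_fraction: float = 0.3,
) -> KaryotypeResult:
    """Cluster samples by inversion karyotype from a region-restricted PCA.

    Within the inversion region the three karyotypes (0/1/2 copies of the
    inverted arrangement) form up to three clusters along PC1, the
    heterozygote cluster midway between the homozygotes. The cluster
    count (<= 3) is chosen by gaps in sorted PC1: a gap is split-worthy
    when it exceeds ``gap_fraction`` of the PC1 range. Cluster labels are
    ordered by mean PC1. If all samples are identical in the region a
    single cluster is returned (and logged).
    """
    selection = select_structure_snps(
        dataset, region=inversion_region, n_target=10**9, maf_min=maf_min,
        sample_index=sample_index,
    )
    if selection.indices.size < min_snps:
        raise ValueError(
            f"only {selection.indices.size} qualifying SNPs in region (need {min_snps})"
        )
    n_samples = len(sample_index) if sample_index is not None else dataset.n_samples
    pca = pca_dosage(dataset, selection, k=min(2, n_samples - 1),
                     scale="none", sample_index=sample_index)
    pc1 = pca.coords["PC1"].to_numpy()

    order = np.argsort(pc1, kind="stable")
    x = pc1[order]
    rng_ = x[-1] - x[0]
    labels = np.zeros(len(x), dtype=int)
    if rng_ <= 1e-12:
        logger.info("all samples identical in inversion region; single cluster")
        n_clusters = 1
    else:
        gaps = np.diff(x)
        big = np.flatnonzero(gaps > gap_fraction * rng_)
        # at most two splits -> at most three karyotype clusters
        if big.size > 2:
            big = big[np.argsort(gaps[big])[::-1][:2]]
            big.sort()
        for cut in big:
            labels[cut + 1 :] += 1
        n_clusters = int(labels.max()) + 1
    clusters = np.empty(len(x), dtype=int)
    clusters[order] = labels
    out = pd.DataFrame({"sample_id": pca.coords["sample_id"], "cluster": clusters})
    return KaryotypeResult(clusters=out, pca=pca, n_clusters=n_clusters)
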