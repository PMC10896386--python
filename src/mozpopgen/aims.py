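"""AIM-based taxon assignment and introgression profiling.

Taxa of the *An. gambiae* complex are morphologically indistinguishable;
whole-genome data resolve them through panels of ancestry-informative
markers (AIMs) — sites where the diagnostic allele differs between two
taxa. Each sample gets, per panel, the fraction of its called panel
alleles matching one taxon, and a two-stage decision assigns the taxon:
the arabiensis-vs-gambiae/coluzzii panel is evaluated first and is
decisive; the gambiae-vs-coluzzii panel splits the remainder.

The same machinery, windowed along the genome, profiles adaptive
introgression: the mean donor-diagnostic allele dosage of a recipient
sample over a region (here the 2L centromere-proximal block carrying the
pyrethroid target-site alleles) falls near 0, 0.5 or 1 according to the
number of introgressed haplotypes carried.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from mozpopgen.datamodel import MISSING, AimPanel, GenotypeDataset

TAXA = ("arabiensis", "gambiae", "coluzzii")
UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class TaxonThresholds:
    """Decision thresholds for the two-panel AIM classification.

    Defaults follow the procedure definition: arabiensis AIM fraction
    > 0.6 calls *An. arabiensis*; otherwise a coluzzii AIM fraction > 0.9
    calls *An. coluzzii* and < 0.12 calls *An. gambiae*; anything between
    is left unassigned (putative other taxa or hybrids).
    """

    t_arab: float = 0.6
    t_col_lo: float = 0.12
    t_col_hi: float = 0.9


def compute_aim_fraction(
    dataset: GenotypeDataset,
    panel: AimPanel,
    target_taxon: str,
) -> pd.DataFrame:
    """Per-sample fraction of target-taxon diagnostic alleles over a panel.

    For each sample the fraction is (number of target-diagnostic alleles
    carried at called panel sites) / (2 x number of called panel sites).
    Alleles that match neither diagnostic allele count against the target.
    Samples with zero called panel sites get ``n_sites = 0`` and a NaN
    fraction rather than being dropped.

    Returns a DataFrame indexed like the sample table with columns
    ``sample_id``, ``n_sites``, ``fraction``.
    """
    col = panel.diagnostic_allele(target_taxon)
    lookup = {
        (c, p): i
        for i, (c, p) in enumerate(
            zip(dataset.variants["contig"], dataset.variants["pos"])
        )
    }
    variant_idx, target_allele_idx = [], []
    for _, site in panel.sites.iterrows():
        vi = lookup.get((site["contig"], site["position"]))
        if vi is None:
            continue
        alleles = dataset.alleles(vi)
        if len(alleles) != 2:
            continue  # multiallelic panel sites are discounted
        try:
            target_allele_idx.append(alleles.index(site[col]))
        except ValueError:
            continue  # diagnostic allele not present at this site
        variant_idx.append(vi)
    if not variant_idx:
        raise ValueError(
            f"panel {panel.name} shares no usable sites with the dataset"
        )
    g = dataset.genotypes[variant_idx]  # (n_sites, n_samples, 2)
    target = np.asarray(target_allele_idx, dtype=np.int8)[:, None, None]
    called = (g != MISSING).all(axis=2)
    hits = ((g == target).sum(axis=2)) * called
    n_sites = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        fraction = hits.sum(axis=0) / (2.0 * n_sites)
    return pd.DataFrame({
        "sample_id": dataset.sample_ids,
        "n_sites": n_sites.astype(int),
        "fraction": fraction,
    })


def classify_taxon(
    arab_fraction: float,
    coluzzii_fraction: float,
    thresholds: TaxonThresholds = TaxonThresholds(),
) -> str:
    """Taxon call from the two AIM fractions.

    The arabiensis fraction is decisive; missing fractions (NaN) yield an
    unassigned call, never a silent drop.
    """
    if arab_fraction is not None and np.isfinite(arab_fraction):
        if arab_fraction > thresholds.t_arab:
            return "arabiensis"
    else:
        return UNASSIGNED
    if coluzzii_fraction is None or not np.isfinite(coluzzii_fraction):
        return UNASSIGNED
    if coluzzii_fraction > thresholds.t_col_hi:
        return "coluzzii"
    if coluzzii_fraction < thresholds.t_col_lo:
        return "gambiae"
    return UNASSIGNED


def assign_taxa(
    dataset: GenotypeDataset,
    arab_panel: AimPanel,
    coluzzii_panel: AimPanel,
    thresholds: TaxonThresholds = TaxonThresholds(),
    min_sites: int = 10,
) -> pd.DataFrame:
    """Run the full two-panel assignment for every sample.

    ``min_sites`` is the minimum number of called panel sites for a
    fraction to be trusted; below it the fraction is treated as missing.

    Returns a DataFrame with columns ``sample_id``, ``arab_fraction``,
    ``arab_n_sites``, ``coluzzii_fraction``, ``coluzzii_n_sites``,
    ``taxon_call``.
    """
    arab = compute_aim_fraction(dataset, arab_panel, "arabiensis")
    colu = compute_aim_fraction(dataset, coluzzii_panel, "coluzzii")
    out = pd.DataFrame({
        "sample_id": arab["sample_id"],
        "arab_fraction": arab["fraction"],
        "arab_n_sites": arab["n_sites"],
        "coluzzii_fraction": colu["fraction"],
        "coluzzii_n_sites": colu["n_sites"],
    })
    calls = []
    for _, row in out.iterrows():
        af = row["arab_fraction"] if row["arab_n_sites"] >= min_sites else np.nan
        cf = row["coluzzii_fraction"] if row["coluzzii_n_sites"] >= min_sites else np.nan
        calls.append(classify_taxon(af, cf, thresholds))
    out["taxon_call"] = calls
    return out


def tile_windows(
    contig_lengths: dict[str, int], width: int, contigs: list[str] | None = None
) -> list[tuple[str, int, int]]:
    """Non-overlapping windows of ``width`` bases tiling each contig."""
    windows = []
    for contig in contigs or list(contig_lengths):
        length = contig_lengths[contig]
        for start in range(1, length + 1, width):
            windows.append((contig, start, min(start + width - 1, length)))
    return windows


@dataclass
class IntrogressionProfile:
    """Windowed donor-dosage matrix plus per-sample region calls."""

    windows: list[tuple[str, int, int]]
    dosage: pd.DataFrame      # windows x samples mean donor dosage (NaN = no sites)
    calls: pd.DataFrame       # sample_id, region_dosage, n_sites, state
    state_percentages: pd.Series  # % of samples per state over the profiled samples


def introgression_profile(
    dataset: GenotypeDataset,
    panel: AimPanel,
    windows: list[tuple[str, int, int]],
    region: tuple[str, int, int],
    donor_taxon: str = "gambiae",
    sample_index: np.ndarray | None = None,
    het_range: tuple[float, float] = (0.25, 0.75),
) -> IntrogressionProfile:
    """Mean donor-diagnostic dosage per window and the region zygosity call.

    A sample's mean donor dosage ``d`` over called panel sites in the
    region is thresholded into ``homozygous`` (d >= upper), ``heterozygous``
    (lower <= d < upper) or ``none`` (d < lower); the defaults 0.25/0.75
    are the midpoints between the expected dosages 0, 0.5 and 1.
    """
    col = panel.diagnostic_allele(donor_taxon)
    lookup = {
        (c, p): i
        for i, (c, p) in enumerate(zip(dataset.variants["contig"], dataset.variants["pos"]))
    }
    site_rows = []
    for _, site in panel.sites.iterrows():
        vi = lookup.get((site["contig"], site["position"]))
        if vi is None:
            continue
        alleles = dataset.alleles(vi)
        if len(alleles) != 2 or site[col] not in alleles:
            continue
        site_rows.append((site["contig"], int(site["position"]), vi, alleles.index(site[col])))
    if not site_rows:
        raise ValueError("panel shares no usable sites with the dataset")

    idx = sample_index if sample_index is not None else np.arange(dataset.n_samples)
    idx = np.asarray(idx)
    ids = [dataset.sample_ids[i] for i in idx]

    vis = np.array([r[2] for r in site_rows])
    targets = np.array([r[3] for r in site_rows], dtype=np.int8)[:, None, None]
    g = dataset.genotypes[vis][:, idx, :]
    called = (g != MISSING).all(axis=2)
    dose = ((g == targets).sum(axis=2) / 2.0)  # (n_sites, n_samples)

    site_contig = np.array([r[0] for r in site_rows])
    site_pos = np.array([r[1] for r in site_rows])

    def _mean_dose(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        c = called[mask].sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            m = np.where(c > 0, (dose[mask] * called[mask]).sum(axis=0) / c, np.nan)
        return m, c

    rows = []
    for contig, lo, hi in windows:
        m = (site_contig == contig) & (site_pos >= lo) & (site_pos <= hi)
        mean, _ = _mean_dose(m)
        rows.append(mean)
    dosage = pd.DataFrame(rows, columns=ids)
    dosage.insert(0, "contig", [w[0] for w in windows])
    dosage.insert(1, "start", [w[1] for w in windows])
    dosage.insert(2, "end", [w[2] for w in windows])

    rc, rlo, rhi = region
    rmask = (site_contig == rc) & (site_pos >= rlo) & (site_pos <= rhi)
    if not rmask.any():
        raise ValueError(f"region {region} contains no panel sites")
    region_dose, region_called = _mean_dose(rmask)

    lower, upper = het_range
    state = np.where(
        ~np.isfinite(region_dose), UNASSIGNED,
        np.where(region_dose >= upper, "homozygous",
                 np.where(region_dose >= lower, "heterozygous", "none")),
    )
    calls = pd.DataFrame({
        "sample_id": ids,
        "region_dosage": region_dose,
        "n_sites": region_called.astype(int),
        "state": state,
    })
    pct = calls["state"].value_counts(normalize=True).mul(100.0)
    return IntrogressionProfile(windows, dosage, calls, pct)
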