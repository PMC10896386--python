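"""End-to-end pipeline orchestration.

``run_report`` executes the full surveillance analysis in order —
classify -> cohorts -> diversity -> FST -> structure -> resistance —
from one configuration mapping, writing every table as TSV plus a
machine-readable ``summary.json``. Every stage failure aborts with a
stage-named diagnostic. The pipeline contains no randomness, so a rerun
with the same config is byte-identical.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from mozpopgen import aims, cohorts, diversity, io, resistance, structure
from mozpopgen.datamodel import GenotypeDataset, allele_counts_by_cohort
from mozpopgen.simulate import PANEL_GAMB_VS_COLU, PANEL_GC_VS_ARAB


@dataclass
class ReportBundle:
    out_dir: Path
    taxon_calls: pd.DataFrame
    cohort_table: pd.DataFrame
    composition: pd.DataFrame
    summary: dict
    artifacts: dict[str, Path] = field(default_factory=dict)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def default_config() -> dict:
    return {
        "classify": {"t_arab": 0.6, "t_col_lo": 0.12, "t_col_hi": 0.9, "min_sites": 10},
        "cohorts": {"min_size": 8},
        "introgression": {"region": ["2L", 1, 80_000], "window": 20_000,
                          "donor": "gambiae", "recipient": "coluzzii"},
        "structure": {"contigs": ["3L", "3R"], "n_snps": 2000, "k": 6,
                      "karyotype_regions": {}},
        "diversity": {"per": "mask_bases"},
        "resistance": {"retention": 0.05,
                       "pairs": [[["Vgsc", "V402L"], ["Vgsc", "I1527T"]],
                                 [["Rdl", "A296G"], ["Rdl", "T345M"]]]},
        "seed": 0,
    }


def _merged_config(config: dict | None) -> dict:
    merged = default_config()
    for key, value in (config or {}).items():
        if isinstance(value, dict) and isinstance(merged.get(key), dict):
            merged[key] = {**merged[key], **value}
        else:
            merged[key] = value
    return merged


def run_report(
    vcf: str | os.PathLike,
    metadata: str | os.PathLike,
    aims_path: str | os.PathLike,
    out_dir: str | os.PathLike,
    mask: str | os.PathLike | None = None,
    gff3: str | os.PathLike | None = None,
    fasta: str | os.PathLike | None = None,
    config: dict | None = None,
) -> ReportBundle:
    """Run the full pipeline on a file bundle and write a consolidated report.

    The resistance stage runs only when both ``gff3`` and ``fasta`` are
    supplied; everything else always runs. Returns the in-memory bundle;
    all tables are also written under ``out_dir``.
    """
    cfg = _merged_config(config)
    out = io.ensure_dir(out_dir)
    artifacts: dict[str, Path] = {}
    summary: dict = {"config": cfg, "seed": cfg.get("seed", 0)}

    dataset = _load(vcf, metadata, mask)
    panels = _load_panels(aims_path)

    taxon_calls = _classify(dataset, panels, cfg["classify"])
    _write(taxon_calls, out / "taxon_calls.tsv", artifacts, "taxon_calls")

    cohort_table, composition = _cohort_stage(dataset, taxon_calls, cfg["cohorts"])
    _write(cohort_table, out / "cohort_table.tsv", artifacts, "cohort_table")
    _write(composition, out / "taxon_composition.tsv", artifacts, "taxon_composition")
    summary["taxon_totals"] = (
        cohort_table.groupby("taxon")["count"].sum().sort_index().to_dict()
    )
    summary["n_samples"] = int(cohort_table["count"].sum())

    intro = _introgression(dataset, panels, taxon_calls, cfg["introgression"])
    if intro is not None:
        _write(intro.calls, out / "introgression_calls.tsv", artifacts, "introgression_calls")
        _write(intro.dosage, out / "introgression_windows.tsv", artifacts,
               "introgression_windows")
        summary["introgression_state_percentages"] = {
            k: round(float(v), 6) for k, v in intro.state_percentages.items()
        }

    stats_cohorts = cohorts.cohort_sample_indices(
        dataset.samples, taxon_calls, min_size=cfg["cohorts"]["min_size"]
    )
    div_table, fst_matrix = _diversity_fst(dataset, stats_cohorts, cfg, mask)
    _write(div_table, out / "diversity.tsv", artifacts, "diversity")
    fst_matrix.to_csv(out / "fst_matrix.tsv", sep="\t")
    artifacts["fst_matrix"] = out / "fst_matrix.tsv"
    summary["diversity"] = {
        row["cohort"]: {"theta_pi": row["theta_pi"], "theta_w": row["theta_w"],
                        "tajima_d": row["tajima_d"], "S": int(row["S"])}
        for _, row in div_table.iterrows()
    }

    pca, tree, karyos = _structure(dataset, cfg["structure"])
    _write(pca.coords, out / "pca_coords.tsv", artifacts, "pca_coords",
           header_comment="# explained_variance\t"
           + "\t".join(f"{v:.6f}" for v in pca.explained_variance))
    (out / "njt.nwk").write_text(tree.newick + "\n")
    artifacts["njt"] = out / "njt.nwk"
    for name, result in karyos.items():
        _write(result.clusters, out / f"karyotype_{name}.tsv", artifacts, f"karyotype_{name}")
        summary.setdefault("karyotype_clusters", {})[name] = result.n_clusters

    if gff3 is not None and fasta is not None:
        freq_table, pair_tables = _resistance(dataset, gff3, fasta, stats_cohorts,
                                              cfg["resistance"])
        _write(freq_table, out / "resistance_frequencies.tsv", artifacts,
               "resistance_frequencies")
        if pair_tables is not None:
            _write(pair_tables, out / "double_mutants.tsv", artifacts, "double_mutants")
    else:
        summary["resistance"] = "skipped (no gff3/fasta configured)"

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
    artifacts["summary"] = out / "summary.json"
    return ReportBundle(out, taxon_calls, cohort_table, composition, summary, artifacts)


def _write(df: pd.DataFrame, path: Path, artifacts: dict, name: str,
           header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(header_comment + "\n")
        df.to_csv(fh, sep="\t", index=False)
    artifacts[name] = path


@_stage("load")
def _load(vcf, metadata, mask) -> GenotypeDataset:
    return io.read_genotype_dataset(vcf, metadata, mask)


@_stage("load")
def _load_panels(aims_path):
    return io.read_aim_panels(aims_path)


@_stage("classify")
def _classify(dataset, panels, cfg) -> pd.DataFrame:
    thresholds = aims.TaxonThresholds(cfg["t_arab"], cfg["t_col_lo"], cfg["t_col_hi"])
    return aims.assign_taxa(
        dataset,
        arab_panel=panels[PANEL_GC_VS_ARAB],
        coluzzii_panel=panels[PANEL_GAMB_VS_COLU],
        thresholds=thresholds,
        min_sites=cfg["min_sites"],
    )


@_stage("cohorts")
def _cohort_stage(dataset, taxon_calls, cfg):
    table = cohorts.build_cohorts(dataset.samples, taxon_calls, min_size=cfg["min_size"])
    _, composition = cohorts.taxon_composition(table)
    return table, composition


@_stage("introgression")
def _introgression(dataset, panels, taxon_calls, cfg):
    panel = panels.get(PANEL_GAMB_VS_COLU)
    if panel is None:
        return None
    recipients = taxon_calls.index[
        taxon_calls["taxon_call"] == cfg.get("recipient", "coluzzii")
    ].to_numpy()
    if recipients.size == 0:
        return None
    region = tuple(cfg["region"])
    windows = aims.tile_windows(dataset.contig_lengths, cfg["window"], [region[0]])
    return aims.introgression_profile(
        dataset, panel, windows, region,
        donor_taxon=cfg.get("donor", "gambiae"), sample_index=recipients,
    )


@_stage("diversity/fst")
def _diversity_fst(dataset, stats_cohorts, cfg, mask_path):
    contigs = cfg["structure"]["contigs"]
    keep = (
        dataset.variants["contig"].isin(contigs).to_numpy()
        & dataset.variants["is_pass"].to_numpy()
        & dataset.is_biallelic()
    )
    idx = np.flatnonzero(keep)
    sub = dataset.take_variants(idx)
    counts = allele_counts_by_cohort(sub, stats_cohorts, max_alleles=2)
    per = cfg["diversity"].get("per", "mask_bases")
    if per == "mask_bases":
        if mask_path is not None:
            mask = io.read_bed_mask(mask_path)
            L = sum(
                io.mask_accessible_bases(mask, c, 1, dataset.contig_lengths[c])
                for c in contigs
            )
        else:
            L = sum(dataset.contig_lengths[c] for c in contigs)
    elif per == "segregating_sites":
        L = None  # per-cohort S below
    else:
        raise ValueError(f"unknown diversity denominator {per!r}")

    rows = []
    for name, ac in counts.items():
        Lc = L if L is not None else max(diversity.segregating_sites(ac), 1)
        st = diversity.diversity_stats(ac, Lc, cohort=name, region="+".join(contigs))
        rows.append(vars(st))
    div_table = pd.DataFrame(rows)
    fst_matrix = (
        diversity.pairwise_fst_matrix(counts)
        if len(counts) >= 2
        else pd.DataFrame(index=list(counts), columns=list(counts))
    )
    return div_table, fst_matrix


@_stage("structure")
def _structure(dataset, cfg):
    selection = structure.select_structure_snps(
        dataset, contigs=cfg["contigs"], n_target=cfg["n_snps"]
    )
    k = min(cfg["k"], dataset.n_samples - 1)
    pca = structure.pca_dosage(dataset, selection, k=k)
    tree = structure.nj_tree(dataset, selection)
    karyos = {
        name: structure.karyotype_pca(dataset, tuple(region))
        for name, region in cfg.get("karyotype_regions", {}).items()
    }
    return pca, tree, karyos


@_stage("resistance")
def _resistance(dataset, gff3, fasta, stats_cohorts, cfg):
    models = resistance.read_gene_models(gff3)
    annotation = resistance.annotate_coding_effects(dataset, models, fasta)
    freq = resistance.substitution_frequencies(
        dataset, annotation.effects, stats_cohorts,
        retention=cfg["retention"], keep_all=True,
    )
    pair_rows = []
    for pair in cfg.get("pairs", []):
        (g1, l1), (g2, l2) = pair
        table = resistance.double_mutant_frequency(
            dataset, annotation.effects, ((g1, l1), (g2, l2)), stats_cohorts
        )
        table.insert(0, "pair", f"{g1}-{l1}+{l2}")
        pair_rows.append(table)
    pairs = pd.concat(pair_rows, ignore_index=True) if pair_rows else None
    return freq, pairs
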