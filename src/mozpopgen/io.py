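"""Reading and writing the interchange formats.

Genotypes travel as uncompressed VCF 4.2 with diploid GT calls, sample
metadata as TSV, the accessibility mask as BED (0-based half-open on
disk), AIM panels as TSV and gene models as GFF3 + FASTA. VCF parsing
goes through :mod:`cyvcf2`; writing emits the text formats directly and
is validated by the read/write round-trip tests.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from mozpopgen.datamodel import METADATA_COLUMNS, MISSING, AimPanel, GenotypeDataset

# ---------------------------------------------------------------------------
# reading


def read_metadata(path: str | os.PathLike) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata {path}: missing columns {missing}")
    return meta


def read_bed_mask(path: str | os.PathLike) -> pd.DataFrame:
    """Accessible intervals as a DataFrame (contig, start, end), 1-based inclusive."""
    bed = pd.read_csv(
        path, sep="\t", header=None, names=["contig", "start", "end"], comment="#",
        usecols=[0, 1, 2],
    )
    bed["start"] = bed["start"] + 1  # BED is 0-based half-open
    return bed


def mask_accessible_bases(mask: pd.DataFrame, contig: str, start: int, end: int) -> int:
    """Accessible base count of ``contig:start-end`` (1-based inclusive) under a mask."""
    rows = mask[mask["contig"] == contig]
    lo = np.maximum(rows["start"].to_numpy(), start)
    hi = np.minimum(rows["end"].to_numpy(), end)
    return int(np.maximum(hi - lo + 1, 0).sum())


def _positions_in_mask(mask: pd.DataFrame, contig: np.ndarray, pos: np.ndarray) -> np.ndarray:
    inside = np.zeros(len(pos), dtype=bool)
    for c, rows in mask.groupby("contig"):
        on_contig = contig == c
        if not on_contig.any():
            continue
        p = pos[on_contig]
        hit = np.zeros(p.shape, dtype=bool)
        for s, e in zip(rows["start"], rows["end"]):
            hit |= (p >= s) & (p <= e)
        inside[on_contig] = hit
    return inside


def read_genotype_dataset(
    vcf_path: str | os.PathLike,
    metadata_path: str | os.PathLike,
    mask_path: str | os.PathLike | None = None,
) -> GenotypeDataset:
    """Load a VCF + metadata (+ optional BED mask) into a :class:`GenotypeDataset`.

    Missing and half-calls are stored as ``(-1, -1)``; phase separators are
    accepted but ignored. Samples keep VCF order; every VCF sample must be
    present in the metadata. With no mask every variant is flagged PASS;
    with a mask the flag records whether the position falls inside it.
    """
    vcf = VCF(str(vcf_path), gts012=False)
    samples = list(vcf.samples)

    meta = read_metadata(metadata_path)
    meta_ids = set(meta["sample_id"].astype(str))
    absent = [s for s in samples if s not in meta_ids]
    if absent:
        raise ValueError(f"VCF samples missing from metadata: {absent}")
    meta = (
        meta.set_index("sample_id").loc[samples].reset_index()
    )  # reorder to VCF sample order

    contigs, positions, refs, alts = [], [], [], []
    geno_rows = []
    for rec in vcf:
        contigs.append(rec.CHROM)
        positions.append(rec.POS)
        refs.append(rec.REF)
        alts.append(",".join(rec.ALT))
        gt = np.asarray(rec.genotype.array(), dtype=np.int16)[:, :2]
        # half-calls are conservatively treated as fully missing
        gt[(gt < 0).any(axis=1)] = MISSING
        geno_rows.append(gt.astype(np.int8))
    contig_lengths = dict(zip(vcf.seqnames, vcf.seqlens)) if vcf.seqlens else {}
    vcf.close()

    genotypes = (
        np.stack(geno_rows) if geno_rows else np.empty((0, len(samples), 2), dtype=np.int8)
    )
    variants = pd.DataFrame(
        {
            "contig": contigs,
            "pos": np.asarray(positions, dtype=np.int64),
            "ref": refs,
            "alt": alts,
        }
    )
    if mask_path is None:
        variants["is_pass"] = True
    else:
        mask = read_bed_mask(mask_path)
        variants["is_pass"] = _positions_in_mask(
            mask, variants["contig"].to_numpy(), variants["pos"].to_numpy()
        )
    return GenotypeDataset(genotypes, variants, meta, contig_lengths)


def read_aim_panels(path: str | os.PathLike) -> dict[str, AimPanel]:
    """Read AIM panels from a TSV with columns panel, contig, position, allele_a, allele_b.

    Panel names follow the ``<taxonA>_vs_<taxonB>`` convention, from which
    the two taxon labels are parsed.
    """
    table = pd.read_csv(path, sep="\t", comment="#", dtype={"contig": str})
    required = {"panel", "contig", "position", "allele_a", "allele_b"}
    if not required.issubset(table.columns):
        raise ValueError(f"AIM panel file {path} lacks columns {required - set(table.columns)}")
    panels = {}
    for name, sites in table.groupby("panel"):
        if "_vs_" not in name:
            raise ValueError(f"panel name {name!r} not of the form '<a>_vs_<b>'")
        taxon_a, taxon_b = name.split("_vs_", maxsplit=1)
        panels[name] = AimPanel(
            name=name,
            taxon_a=taxon_a,
            taxon_b=taxon_b,
            sites=sites[["contig", "position", "allele_a", "allele_b"]].reset_index(drop=True),
        )
    return panels


# ---------------------------------------------------------------------------
# writing


def write_metadata(meta: pd.DataFrame, path: str | os.PathLike) -> None:
    meta.to_csv(path, sep="\t", index=False)


def write_bed_mask(mask: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write 1-based inclusive intervals as 0-based half-open BED."""
    out = mask.copy()
    out["start"] = out["start"] - 1
    out[["contig", "start", "end"]].to_csv(path, sep="\t", index=False, header=False)


def write_fasta(sequences: dict[str, str], path: str | os.PathLike, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_vcf(dataset: GenotypeDataset, path: str | os.PathLike) -> None:
    """Write a dataset as minimal VCF 4.2 with GT-only FORMAT."""
    var = dataset.variants
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for contig, length in dataset.contig_lengths.items():
            fh.write(f"##contig=<ID={contig},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(dataset.samples["sample_id"].astype(str))
            + "\n"
        )
        geno = dataset.genotypes
        for i in range(dataset.n_variants):
            row = var.iloc[i]
            alt = row["alt"] if row["alt"] else "."
            calls = "\t".join(
                "./." if g[0] == MISSING else f"{g[0]}/{g[1]}" for g in geno[i]
            )
            fh.write(
                f"{row['contig']}\t{row['pos']}\t.\t{row['ref']}\t{alt}\t.\tPASS\t.\tGT\t{calls}\n"
            )


def write_aim_panels(panels: dict[str, AimPanel], path: str | os.PathLike) -> None:
    rows = []
    for panel in panels.values():
        block = panel.sites.copy()
        block.insert(0, "panel", panel.name)
        rows.append(block)
    pd.concat(rows, ignore_index=True).to_csv(path, sep="\t", index=False)


def write_gff3(gene_models, path: str | os.PathLike) -> None:
    """Write gene/mRNA/CDS features (with phase) for a list of gene models."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gm in gene_models:
            span_lo = min(s for s, _ in gm.cds)
            span_hi = max(e for _, e in gm.cds)
            attrs = f"ID={gm.gene_id};Name={gm.name}" if gm.name else f"ID={gm.gene_id}"
            fh.write(
                f"{gm.contig}\tmozpopgen\tgene\t{span_lo}\t{span_hi}\t.\t{gm.strand}\t.\t{attrs}\n"
            )
            rna_id = f"{gm.gene_id}-RA"
            fh.write(
                f"{gm.contig}\tmozpopgen\tmRNA\t{span_lo}\t{span_hi}\t.\t{gm.strand}\t.\t"
                f"ID={rna_id};Parent={gm.gene_id}\n"
            )
            phase = 0
            for j, (s, e) in enumerate(gm.cds):
                fh.write(
                    f"{gm.contig}\tmozpopgen\tCDS\t{s}\t{e}\t.\t{gm.strand}\t{phase}\t"
                    f"ID={rna_id}-CDS{j + 1};Parent={rna_id}\n"
                )
                phase = (3 - ((e - s + 1) - phase) % 3) % 3


def ensure_dir(path: str | os.PathLike) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
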