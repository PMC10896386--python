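"""Cohort construction and taxon-composition reporting.

A cohort is the unit of all frequency and diversity reporting: the set
of samples sharing a taxon, sampling location, year and month. This
module builds cohort tables from metadata plus taxon calls, computes
per-cohort species composition (e.g. the percentage of *An. coluzzii*
among samples from one site and date), and ships the published Kenyan
sampling table as a packaged fixture.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

COHORT_KEY = ["location", "year", "month"]


def load_table_t1() -> pd.DataFrame:
    """The packaged Kenyan sampling table, in long (cohort x taxon) form.

    Columns: location, latitude, longitude, year, month, taxon, count.
    """
    with resources.files("mozpopgen.data").joinpath("table_t1.tsv").open() as fh:
        wide = pd.read_csv(fh, sep="\t", comment="#")
    long = wide.melt(
        id_vars=["location", "latitude", "longitude", "year", "month"],
        var_name="taxon",
        value_name="count",
    )
    return long.sort_values(COHORT_KEY + ["taxon"]).reset_index(drop=True)


def build_cohorts(
    metadata: pd.DataFrame,
    taxon_calls: pd.DataFrame,
    min_size: int = 8,
) -> pd.DataFrame:
    """Count samples per (location, year, month, taxon).

    ``taxon_calls`` must provide ``sample_id`` and ``taxon_call`` for
    every metadata sample (unassigned included). Cohorts smaller than
    ``min_size`` are flagged ``excluded_from_stats`` but kept, so
    composition tables always cover everything.
    """
    meta_ids = set(metadata["sample_id"])
    call_ids = set(taxon_calls["sample_id"])
    if meta_ids != call_ids:
        raise ValueError(
            f"metadata/taxon-call mismatch: {sorted(meta_ids ^ call_ids)[:5]} ..."
        )
    merged = metadata.merge(
        taxon_calls[["sample_id", "taxon_call"]], on="sample_id", validate="1:1"
    )
    merged["taxon_call"] = merged["taxon_call"].fillna("unassigned").replace("", "unassigned")
    table = (
        merged.groupby(COHORT_KEY + ["taxon_call"], as_index=False)
        .agg(
            latitude=("latitude", "first"),
            longitude=("longitude", "first"),
            count=("sample_id", "size"),
        )
        .rename(columns={"taxon_call": "taxon"})
        .sort_values(COHORT_KEY + ["taxon"])
        .reset_index(drop=True)
    )
    table["excluded_from_stats"] = table["count"] < min_size
    return table


def cohort_sample_indices(
    metadata: pd.DataFrame,
    taxon_calls: pd.DataFrame,
    min_size: int = 8,
    taxon: str | None = None,
) -> dict[str, np.ndarray]:
    """Sample indices per cohort key, for the statistics stages.

    Keys are ``<location>_<year>_<month:02d>[_<taxon>]``; cohorts below
    ``min_size`` are omitted, matching the cohort table's exclusion flag.
    """
    merged = metadata.reset_index(drop=True).merge(
        taxon_calls[["sample_id", "taxon_call"]], on="sample_id", validate="1:1"
    )
    if taxon is not None:
        merged = merged[merged["taxon_call"] == taxon]
    out = {}
    for (loc, year, month, tax), group in merged.groupby(
        COHORT_KEY + ["taxon_call"]
    ):
        if len(group) < min_size:
            continue
        key = f"{loc}_{year}_{month:02d}_{tax}"
        out[key] = group.index.to_numpy()
    return out


def taxon_composition(cohort_table: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Per-taxon totals and per-cohort composition percentages.

    Percentages are kept at full precision in ``percentage`` with a
    one-decimal display column ``percentage_display``; within a cohort
    the full-precision percentages sum to 100.
    """
    if cohort_table.empty:
        raise ValueError("empty cohort table")
    totals = cohort_table.groupby("taxon")["count"].sum().sort_index()
    comp = cohort_table.copy()
    cohort_totals = comp.groupby(COHORT_KEY)["count"].transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        comp["cohort_total"] = cohort_totals
        comp["percentage"] = np.where(
            cohort_totals > 0, 100.0 * comp["count"] / cohort_totals, np.nan
        )
    comp["percentage_display"] = comp["percentage"].round(1)
    return totals, comp
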