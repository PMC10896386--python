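"""Genetic-diversity and differentiation statistics.

Implements the classical summary statistics on cohort allele counts:
nucleotide diversity (theta-pi), Watterson's theta, Tajima's D and
Hudson's pairwise FST as a ratio of averages. All functions take allele
count arrays of shape ``(n_sites, n_alleles)`` as produced by
:func:`mozpopgen.datamodel.allele_counts`; missing genotypes are already
excluded there, so the per-site called allele total can vary across
sites.

With missing data the sample size entering the Watterson/Tajima constants
is not unique; a single per-region value — the median called allele count
— is used so the classical constants remain valid.

The per-base denominator ``L`` is a choice the caller makes: the number
of accessible bases in the region (mask-based, giving per-genome-base
diversity) or the number of segregating/selected sites (giving
per-variant-site magnitudes). Both conventions are supported via the
``accessible_bases`` argument.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def _pairwise_terms(allele_counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site heterozygosity term and called totals.

    The per-site mean pairwise difference is
    ``sum_{a<b} c_a c_b / C(n, 2) = (n^2 - sum_a c_a^2) / (n (n - 1))``.
    Sites with fewer than two called alleles contribute nothing.
    """
    ac = np.asarray(allele_counts, dtype=np.int64)
    n = ac.sum(axis=1)
    valid = n >= 2
    num = n.astype(float) ** 2 - (ac.astype(float) ** 2).sum(axis=1)
    den = n.astype(float) * (n - 1)
    pi = np.zeros(len(ac))
    pi[valid] = num[valid] / den[valid]
    return pi, n


def segregating_sites(allele_counts: np.ndarray) -> int:
    """Number of sites where at least two alleles are observed."""
    ac = np.asarray(allele_counts)
    return int(((ac > 0).sum(axis=1) >= 2).sum())


def harmonic_number(n: int, power: int = 1) -> float:
    """``a1 = sum 1/i`` (or ``a2 = sum 1/i^2``) for ``i = 1 .. n-1``."""
    i = np.arange(1, n)
    return float((1.0 / i**power).sum())


def nucleotide_diversity(allele_counts: np.ndarray, accessible_bases: int) -> float:
    """Theta-pi: mean pairwise differences per accessible base.

    ``sum_sites sum_{a<b} c_a c_b / C(n_s, 2) / L``. Sites with fewer
    than two called alleles are skipped.
    """
    if accessible_bases <= 0:
        raise ValueError("accessible_bases must be positive")
    pi, _ = _pairwise_terms(allele_counts)
    return float(pi.sum()) / accessible_bases


def median_called(allele_counts: np.ndarray) -> int:
    """Median called allele count over polymorphic-capable sites (n >= 2)."""
    n = np.asarray(allele_counts).sum(axis=1)
    n = n[n >= 2]
    if n.size == 0:
        raise ValueError("no sites with at least two called alleles")
    return int(np.median(n))


def watterson_theta(
    allele_counts: np.ndarray,
    accessible_bases: int,
    n: int | None = None,
) -> float:
    """Watterson's theta: segregating sites per accessible base, scaled by a1."""
    if accessible_bases <= 0:
        raise ValueError("accessible_bases must be positive")
    S = segregating_sites(allele_counts)
    if S == 0:
        return 0.0
    if n is None:
        n = median_called(allele_counts)
    if n < 2:
        raise ValueError("need at least two called alleles")
    return S / harmonic_number(n) / accessible_bases


def tajimas_d(allele_counts: np.ndarray, n: int | None = None) -> float:
    """Tajima's D: the normalized difference between theta-pi and theta-w.

    Uses the classical constants (a1, a2, b1, b2, c1, c2, e1, e2) at
    sample size ``n`` (default: the median called allele count). Negative
    values indicate an excess of rare variants. Undefined (raises) when
    there are no segregating sites.
    """
    ac = np.asarray(allele_counts)
    S = segregating_sites(ac)
    if S == 0:
        raise ValueError("Tajima's D undefined with no segregating sites")
    if n is None:
        n = median_called(ac)
    if n < 4:
        raise ValueError("Tajima's D requires n >= 4")
    pi, _ = _pairwise_terms(ac)
    pi_total = float(pi.sum())

    a1 = harmonic_number(n)
    a2 = harmonic_number(n, power=2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    return (pi_total - S / a1) / np.sqrt(var)


@dataclass
class DiversityStats:
    """Summary statistics of one cohort over one region."""

    cohort: str
    region: str
    theta_pi: float
    theta_w: float
    tajima_d: float
    S: int
    L: int
    n: int


def diversity_stats(
    allele_counts: np.ndarray,
    accessible_bases: int,
    cohort: str = "",
    region: str = "",
) -> DiversityStats:
    """Theta-pi, Watterson's theta and Tajima's D for one cohort/region."""
    n = median_called(allele_counts)
    S = segregating_sites(allele_counts)
    return DiversityStats(
        cohort=cohort,
        region=region,
        theta_pi=nucleotide_diversity(allele_counts, accessible_bases),
        theta_w=watterson_theta(allele_counts, accessible_bases, n=n),
        tajima_d=tajimas_d(allele_counts, n=n) if S > 0 else float("nan"),
        S=S,
        L=accessible_bases,
        n=n,
    )


@dataclass
class FstResult:
    """Hudson's FST between two cohorts, as a ratio of averages."""

    fst: float
    numerator_sum: float
    denominator_sum: float
    n_sites: int


def hudson_fst(
    allele_counts_pop1: np.ndarray,
    allele_counts_pop2: np.ndarray,
) -> FstResult:
    """Hudson's pairwise FST from biallelic allele counts.

    Per site, with ``p_i`` the alternate-allele frequency and ``n_i`` the
    called allele count in population ``i``::

        N   = (p1 - p2)^2 - p1 (1 - p1) / (n1 - 1) - p2 (1 - p2) / (n2 - 1)
        Den = p1 (1 - p2) + p2 (1 - p1)

    and the estimate is ``sum(N) / sum(Den)`` over sites — a ratio of
    averages, not an average of per-site ratios. Sites with fewer than two
    called alleles in either population or with a zero denominator (both
    populations monomorphic for the same allele) are excluded from both
    sums. Undefined (raises) when no site remains.
    """
    ac1 = np.asarray(allele_counts_pop1, dtype=float)
    ac2 = np.asarray(allele_counts_pop2, dtype=float)
    if ac1.shape != ac2.shape:
        raise ValueError("allele count arrays must have the same shape")
    if ac1.shape[1] != 2:
        raise ValueError("hudson_fst expects biallelic counts (n_sites x 2)")
    n1 = ac1.sum(axis=1)
    n2 = ac2.sum(axis=1)
    ok = (n1 >= 2) & (n2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.where(n1 > 0, ac1[:, 1] / n1, np.nan)
        p2 = np.where(n2 > 0, ac2[:, 1] / n2, np.nan)
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
    ok &= np.isfinite(den) & (den > 0)
    if not ok.any():
        raise ValueError("FST undefined: all sites monomorphic in both cohorts")
    num_sum = float(num[ok].sum())
    den_sum = float(den[ok].sum())
    return FstResult(
        fst=num_sum / den_sum,
        numerator_sum=num_sum,
        denominator_sum=den_sum,
        n_sites=int(ok.sum()),
    )


def pairwise_fst_matrix(cohort_counts: dict[str, np.ndarray]) -> pd.DataFrame:
    """Symmetric Hudson FST matrix over all cohort pairs."""
    names = list(cohort_counts)
    mat = pd.DataFrame(0.0, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            f = hudson_fst(cohort_counts[a][:, :2], cohort_counts[b][:, :2]).fst
            mat.loc[a, b] = mat.loc[b, a] = f
    return mat


def windowed_diversity(
    allele_counts: np.ndarray,
    positions: np.ndarray,
    contigs: np.ndarray,
    windows: list[tuple[str, int, int]],
    window_accessible_bases: list[int],
    cohort: str = "",
) -> pd.DataFrame:
    """Diversity statistics per genomic window.

    The genome-wide value of each statistic should be recomputed from the
    pooled components (sums of per-site terms over all windows), not
    averaged over windows; :func:`diversity_stats` on the full region does
    exactly that.
    """
    rows = []
    for (contig, lo, hi), L in zip(windows, window_accessible_bases):
        m = (contigs == contig) & (positions >= lo) & (positions <= hi)
        ac = allele_counts[m]
        if L <= 0 or ac.size == 0 or (ac.sum(axis=1) >= 2).sum() == 0:
            rows.append({"cohort": cohort, "contig": contig, "start": lo, "end": hi,
                         "theta_pi": np.nan, "theta_w": np.nan, "tajima_d": np.nan,
                         "S": 0, "L": L, "n": 0})
            continue
        st = diversity_stats(ac, L, cohort=cohort, region=f"{contig}:{lo}-{hi}")
        rows.append({"cohort": cohort, "contig": contig, "start": lo, "end": hi,
                     "theta_pi": st.theta_pi, "theta_w": st.theta_w,
                     "tajima_d": st.tajima_d, "S": st.S, "L": st.L, "n": st.n})
    return pd.DataFrame(rows)
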