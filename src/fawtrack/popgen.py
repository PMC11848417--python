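"""Per-population diversity statistics and Weir & Cockerham F_ST.

Diversity follows the conventions of variant-site exports from RAD/WGS
pipelines: all statistics are means over variant sites with at least
one called diploid in the population. For a locus with n called
diploids and alternate-allele frequency p,

    Hobs      = fraction of heterozygous calls,
    Hexp_raw  = 2 p (1 - p),
    PI        = 2n/(2n - 1) * Hexp_raw      (unbiased mean pairwise
                                             difference among the 2n
                                             sampled alleles),
    FIS_locus = 1 - Hobs / Hexp_raw          (polymorphic loci only).

Differentiation is the Weir & Cockerham (1984) theta with variance
components a (among populations), b (among individuals within
populations) and c (within individuals), combined across loci as a
ratio of averages:  theta = sum(a) / sum(a + b + c).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from fawtrack.core import GenotypeMatrix

log = logging.getLogger(__name__)


@dataclass
class PopDiversitySummary:
    """One row of the per-population diversity table."""

    population: str
    num_indv: float   # mean individuals genotyped per locus
    ohe: float        # observed heterozygosity
    oho: float        # observed homozygosity (1 - ohe, exactly)
    ehe: float        # expected heterozygosity
    eho: float        # expected homozygosity (1 - ehe, exactly)
    pi: float         # nucleotide diversity at variant sites
    fis: float        # inbreeding coefficient

    def as_row(self) -> dict:
        return {
            "Cluster": self.population,
            "Num_Indv": self.num_indv,
            "OHe": self.ohe,
            "OHo": self.oho,
            "EHe": self.ehe,
            "EHo": self.eho,
            "PI": self.pi,
            "FIS": self.fis,
        }


def allele_frequencies(
    matrix: GenotypeMatrix, population: str
) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus alternate-allele frequency and called-diploid count.

    Loci with zero called diploids get frequency NaN; downstream
    statistics exclude them for this population.
    """
    rows = matrix.pop_indices(population)
    dos = matrix.dosages[rows]
    n_called = (~np.isnan(dos)).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.nansum(dos, axis=0) / (2.0 * n_called)
    p[n_called == 0] = np.nan
    return p, n_called


def diversity_summary(matrix: GenotypeMatrix, population: str) -> PopDiversitySummary:
    """Diversity table row for one population (see module docs)."""
    rows = matrix.pop_indices(population)
    dos = matrix.dosages[rows]
    p, n = allele_frequencies(matrix, population)
    use = n > 0
    if not use.any():
        raise ValueError(f"population {population!r} has no called loci")
    p, n = p[use], n[use].astype(float)
    dos = dos[:, use]

    with np.errstate(invalid="ignore"):
        hobs = np.nansum(dos == 1.0, axis=0) / n
    hexp_raw = 2.0 * p * (1.0 - p)
    pi_locus = np.where(n > 0.5, 2.0 * n / (2.0 * n - 1.0), 0.0) * hexp_raw

    poly = hexp_raw > 0.0
    if poly.any():
        fis = float(np.mean(1.0 - hobs[poly] / hexp_raw[poly]))
    else:
        log.warning("population %s monomorphic at every locus; FIS set to 0", population)
        fis = 0.0

    ohe = float(hobs.mean())
    ehe = float(hexp_raw.mean())
    return PopDiversitySummary(
        population=population,
        num_indv=float(n.mean()),
        ohe=ohe,
        oho=1.0 - ohe,
        ehe=ehe,
        eho=1.0 - ehe,
        pi=float(pi_locus.mean()),
        fis=fis,
    )


def diversity_table(matrix: GenotypeMatrix, populations=None) -> pd.DataFrame:
    """Diversity rows for several populations as a DataFrame with
    columns Cluster, Num_Indv, OHe, OHo, EHe, EHo, PI, FIS."""
    populations = populations or matrix.populations()
    rows = [diversity_summary(matrix, pop).as_row() for pop in populations]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Weir & Cockerham (1984) theta
# ---------------------------------------------------------------------------

def _wc84_components(matrix: GenotypeMatrix, populations: list[str]):
    """Per-locus variance components (a, b, c) over r populations.

    Arrays have the matrix locus count; components are NaN where the
    locus is undefined (a population with no calls, or n_bar == 1,
    i.e. a single diploid per population on average).
    """
    freqs, het, counts = [], [], []
    for pop in populations:
        rows = matrix.pop_indices(pop)
        dos = matrix.dosages[rows]
        n_called = (~np.isnan(dos)).sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.nansum(dos, axis=0) / (2.0 * n_called)
            h = np.nansum(dos == 1.0, axis=0) / n_called
        freqs.append(p)
        het.append(h)
        counts.append(n_called)
    p_i = np.stack(freqs)     # (r, L)
    h_i = np.stack(het)
    n_i = np.stack(counts)
    r = float(len(populations))

    with np.errstate(invalid="ignore", divide="ignore"):
        n_bar = n_i.mean(axis=0)
        n_c = (r * n_bar - (n_i**2).sum(axis=0) / (r * n_bar)) / (r - 1.0)
        p_bar = (n_i * p_i).sum(axis=0) / (r * n_bar)
        s2 = (n_i * (p_i - p_bar) ** 2).sum(axis=0) / ((r - 1.0) * n_bar)
        h_bar = (n_i * h_i).sum(axis=0) / (r * n_bar)

        inner = p_bar * (1.0 - p_bar) - (r - 1.0) / r * s2 - h_bar / 4.0
        a = n_bar / n_c * (s2 - inner / (n_bar - 1.0))
        b = n_bar / (n_bar - 1.0) * (
            p_bar * (1.0 - p_bar)
            - (r - 1.0) / r * s2
            - (2.0 * n_bar - 1.0) / (4.0 * n_bar) * h_bar
        )
        c = h_bar / 2.0

    bad = (n_i < 1).any(axis=0) | ~np.isfinite(a) | ~np.isfinite(b) | ~np.isfinite(c)
    a[bad] = b[bad] = c[bad] = np.nan
    return a, b, c


def pairwise_fst(
    matrix: GenotypeMatrix, pop_a: str, pop_b: str, clamp: bool = True
) -> float:
    """WC84 theta between two populations, ratio of averages over loci.

    Slightly negative estimates (sampling noise near zero
    differentiation) are clamped to 0 at reporting time when ``clamp``
    is set; pass ``clamp=False`` for the raw value. Returns NaN when no
    locus is co-called.
    """
    a, b, c = _wc84_components(matrix, [pop_a, pop_b])
    ok = np.isfinite(a)
    denom = (a[ok] + b[ok] + c[ok]).sum()
    if not ok.any() or denom == 0.0:
        log.warning("FST undefined for %s vs %s", pop_a, pop_b)
        return float("nan")
    theta = float(a[ok].sum() / denom)
    if clamp and theta < 0.0:
        return 0.0
    return theta


def per_locus_fst(
    matrix: GenotypeMatrix, populations: list[str]
) -> np.ndarray:
    """Per-locus WC84 theta over the given populations, NaN where
    undefined; length equals the matrix locus count."""
    a, b, c = _wc84_components(matrix, populations)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where((a + b + c) != 0.0, a / (a + b + c), np.nan)


@dataclass
class FstMatrix:
    populations: list[str]
    values: np.ndarray    # symmetric, zero diagonal, NaN where undefined

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.populations, columns=self.populations)


def fst_matrix(matrix: GenotypeMatrix, populations=None, clamp: bool = True) -> FstMatrix:
    """All pairwise WC84 theta values as a symmetric matrix."""
    populations = populations or matrix.populations()
    k = len(populations)
    vals = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            vals[i, j] = vals[j, i] = pairwise_fst(
                matrix, populations[i], populations[j], clamp=clamp
            )
    return FstMatrix(populations=list(populations), values=vals)
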