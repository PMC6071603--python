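"""Weir & Cockerham (1984) F-statistics for multi-population diploid SNP data.

Per-SNP variance components of the hierarchical ANOVA decomposition of allele
frequency variance:

* ``a`` — among populations,
* ``b`` — among individuals within populations,
* ``c`` — between gametes within individuals,

with FST = a / (a + b + c).  The estimator is unbiased and individual
components (and FST itself) may be negative at weakly differentiated sites;
the multi-locus summary by "ratio of averages" (mean numerator over mean
denominator, after Bhatia et al.) is the recommended aggregate because the
per-SNP average of ratios is pulled toward zero by rare variants.

All functions are vectorised over sites.  Genotypes are coded as the count of
the alternate allele in {0, 1, 2}, with -1 for missing; populations with no
non-missing genotype at a site are excluded from that site's estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VarianceComponents",
    "population_allele_stats",
    "wc_variance_components",
    "wc_components_from_genotypes",
    "per_snp_fst",
    "summarize_fst",
    "snp_frequency_summary",
    "per_snp_fst_table",
    "pairwise_fst_table",
]

#: |a+b+c| below this is treated as an undefined FST (floating-point guard).
DENOM_TOL = 1e-12


@dataclass(frozen=True)
class VarianceComponents:
    """Per-SNP WC84 variance components (arrays of equal length)."""

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray

    @property
    def denom(self) -> np.ndarray:
        return self.a + self.b + self.c

    def __len__(self) -> int:
        return len(np.atleast_1d(self.a))


def population_allele_stats(
    genotypes: np.ndarray, pop_codes: np.ndarray, n_pops: int | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site, per-population sample sizes, ALT frequencies and het frequencies.

    Parameters
    ----------
    genotypes
        (n_sites, n_samples) integer array of ALT allele counts, -1 missing.
    pop_codes
        (n_samples,) integer population index per sample.
    n_pops
        Number of populations (defaults to ``pop_codes.max() + 1``).

    Returns
    -------
    n, p, h
        Each of shape (n_sites, n_pops): number of non-missing diploids,
        ALT allele frequency, and observed heterozygote frequency.  ``p`` and
        ``h`` are 0 where ``n`` is 0.
    """
    genotypes = np.asarray(genotypes)
    if genotypes.ndim != 2:
        raise ValueError("genotypes must be a 2-D (sites x samples) array")
    pop_codes = np.asarray(pop_codes)
    if pop_codes.shape[0] != genotypes.shape[1]:
        raise ValueError("pop_codes length must equal the sample dimension")
    r = int(n_pops if n_pops is not None else pop_codes.max() + 1)

    missing = genotypes < 0
    gt = np.where(missing, 0, genotypes)
    het = (genotypes == 1)

    # one-hot population membership: (n_samples, r)
    onehot = np.zeros((pop_codes.shape[0], r))
    onehot[np.arange(pop_codes.shape[0]), pop_codes] = 1.0

    n = (~missing).astype(float) @ onehot
    alt = gt.astype(float) @ onehot
    nhet = het.astype(float) @ onehot
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / (2.0 * n), 0.0)
        h = np.where(n > 0, nhet / np.maximum(n, 1.0), 0.0)
    return n, p, h


def wc_variance_components(
    n: np.ndarray, p: np.ndarray, h: np.ndarray
) -> VarianceComponents:
    """WC84 per-locus components from per-population summaries.

    ``n``, ``p`` and ``h`` are (n_sites, n_pops) arrays of non-missing diploid
    counts, ALT allele frequencies and observed heterozygote frequencies.
    Populations with ``n == 0`` at a site are dropped from that site; sites
    with fewer than two populated populations get NaN components.

    Raises
    ------
    ValueError
        If fewer than two populations are supplied overall.
    """
    n = np.atleast_2d(np.asarray(n, dtype=float))
    p = np.atleast_2d(np.asarray(p, dtype=float))
    h = np.atleast_2d(np.asarray(h, dtype=float))
    if n.shape[1] < 2:
        raise ValueError("need at least 2 populations")

    present = n > 0
    r = present.sum(axis=1).astype(float)  # populations with data, per site
    nsum = n.sum(axis=1)

    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = nsum / r
        # n_c = (r*nbar - sum(n_i^2)/(r*nbar)) / (r - 1)
        n_c = (nsum - (n**2).sum(axis=1) / nsum) / (r - 1.0)
        pbar = (n * p).sum(axis=1) / nsum
        s2 = (n * (p - pbar[:, None]) ** 2 * present).sum(axis=1) / (
            (r - 1.0) * nbar
        )
        hbar = (n * h).sum(axis=1) / nsum

        pq = pbar * (1.0 - pbar)
        frac = (r - 1.0) / r
        a = (nbar / n_c) * (
            s2 - (pq - frac * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pq - frac * s2 - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0

    bad = (r < 2) | (nbar <= 1) | (n_c <= 0)
    for arr in (a, b):
        arr[bad] = np.nan
    c = np.where(bad, np.nan, c)
    return VarianceComponents(a=a, b=b, c=c)


def wc_components_from_genotypes(
    genotypes: np.ndarray, pop_codes: np.ndarray, n_pops: int | None = None
) -> VarianceComponents:
    """Convenience wrapper: genotype matrix -> WC84 components per site."""
    n, p, h = population_allele_stats(genotypes, pop_codes, n_pops)
    return wc_variance_components(n, p, h)


def per_snp_fst(vc: VarianceComponents, tol: float = DENOM_TOL) -> np.ndarray:
    """FST = a/(a+b+c) per SNP; NaN where the denominator is (near-)zero."""
    denom = vc.denom
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(np.abs(denom) > tol, vc.a / denom, np.nan)
    return fst


def summarize_fst(
    vc: VarianceComponents, mode: str = "ratio_of_averages", tol: float = DENOM_TOL
) -> float:
    """Multi-locus FST summary.

    ``ratio_of_averages``: mean(a) / mean(a+b+c) over SNPs with finite
    components — the least biased aggregate, which downweights rare variants.
    ``average_of_ratios``: mean of the defined per-SNP FST values.
    """
    a = np.atleast_1d(vc.a)
    denom = np.atleast_1d(vc.denom)
    if a.size == 0:
        raise ValueError("empty component list")
    if mode == "ratio_of_averages":
        ok = np.isfinite(a) & np.isfinite(denom)
        if not ok.any():
            raise ValueError("no SNP with finite components")
        md = denom[ok].mean()
        if md <= tol:
            raise ValueError("mean denominator is not positive")
        return float(a[ok].mean() / md)
    if mode == "average_of_ratios":
        fst = per_snp_fst(vc, tol)
        fst = fst[np.isfinite(fst)]
        if fst.size == 0:
            raise ValueError("no SNP with defined FST")
        return float(fst.mean())
    raise ValueError(f"unknown mode: {mode!r}")


def snp_frequency_summary(
    genotypes: np.ndarray, pop_codes: np.ndarray, n_pops: int | None = None
) -> dict[str, np.ndarray]:
    """Per-population AF/MAF/het and pooled global MAF for every site.

    The global MAF is the frequency of the rarer allele in the pooled sample
    (all retained individuals together), not an average of per-population
    MAFs.
    """
    n, p, h = population_allele_stats(genotypes, pop_codes, n_pops)
    pooled_alt = (2.0 * n * p).sum(axis=1)
    pooled_n = n.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        global_af = np.where(pooled_n > 0, pooled_alt / (2.0 * pooled_n), np.nan)
    return {
        "n": n,
        "af": p,
        "maf": np.minimum(p, 1.0 - p),
        "het": h,
        "global_af": global_af,
        "global_maf": np.minimum(global_af, 1.0 - global_af),
    }


def per_snp_fst_table(
    genotypes: np.ndarray,
    pop_codes: np.ndarray,
    sites: pd.DataFrame | None = None,
    n_pops: int | None = None,
) -> pd.DataFrame:
    """Per-SNP table of global MAF, variance components and FST.

    If ``sites`` is given, its columns (chrom, pos, gene, region_class, ...)
    are carried through positionally.
    """
    stats = snp_frequency_summary(genotypes, pop_codes, n_pops)
    vc = wc_components_from_genotypes(genotypes, pop_codes, n_pops)
    out = pd.DataFrame(
        {
            "global_maf": stats["global_maf"],
            "a": vc.a,
            "denom": vc.denom,
            "fst": per_snp_fst(vc),
        }
    )
    if sites is not None:
        out = pd.concat(
            [sites.reset_index(drop=True), out.reset_index(drop=True)], axis=1
        )
    return out


def _pair_polymorphic_mask(n: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Sites variable in at least one of the two populations of ``n``/``p``."""
    alt = 2.0 * n * p
    tot = 2.0 * n
    seg = (alt > 0) & (alt < tot)
    return seg.any(axis=1)


def pairwise_fst_table(
    genotypes: np.ndarray,
    pop_codes: np.ndarray,
    pop_names: Sequence[str],
    groups: Sequence[str] | None = None,
    mode: str = "ratio_of_averages",
) -> pd.DataFrame:
    """Multi-locus FST for every unordered pair of populations.

    For each pair, sites are re-filtered to those variable in at least one of
    the two populations before summarising.  A pair with no variable site
    gets NaN.  ``groups`` (e.g. continental labels, aligned with
    ``pop_names``) populate a ``same_group`` flag per pair.
    """
    n_pops = len(pop_names)
    n, p, h = population_allele_stats(genotypes, pop_codes, n_pops)
    rows = []
    for i, j in combinations(range(n_pops), 2):
        n2, p2, h2 = n[:, [i, j]], p[:, [i, j]], h[:, [i, j]]
        keep = _pair_polymorphic_mask(n2, p2)
        if keep.any():
            vc = wc_variance_components(n2[keep], p2[keep], h2[keep])
            try:
                fst = summarize_fst(vc, mode)
            except ValueError:
                fst = np.nan
        else:
            fst = np.nan
        row = {
            "pop_a": pop_names[i],
            "pop_b": pop_names[j],
            "n_sites": int(keep.sum()),
            "fst": fst,
        }
        if groups is not None:
            row["same_group"] = groups[i] == groups[j]
        rows.append(row)
    return pd.DataFrame(rows)
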