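"""Haplotype-level differentiation: two-field HLA alleles as biallelic loci.

Classical HLA alleles (intragenic haplotypes, named ``GENE*FF:FF[:..]``) are
normalised to two fields (protein-level resolution), ambiguous calls are
resolved to the most common candidate in the pooled sample, and each gene's
multiallelic calls are recoded one-vs-rest: every distinct two-field allele
becomes a pseudo-biallelic locus whose per-sample genotype is the count of
that allele (0/1/2).  These loci feed the same Weir-Cockerham machinery as
SNPs, so haplotype-level FST is directly comparable to SNP FST within MAF
bins.  Because no haplotype reaches high frequency, the comparison uses a
finer bin scheme confined to the haplotype MAF range (default edges up to
0.2).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import fst as fst_mod
from .difftest import _mw_pvalue, assign_maf_bin, _edges
from .genotype_io import PopulationPanel

__all__ = [
    "HAPLOTYPE_BIN_EDGES",
    "PseudoBiallelicLocus",
    "normalize_two_field",
    "resolve_ambiguous_call",
    "load_hla_calls",
    "disambiguate_calls",
    "recode_one_vs_rest",
    "haplotype_fst_table",
    "haplotype_fst_by_maf_bin",
]

HAPLOTYPE_BIN_EDGES: tuple[float, ...] = (0.0, 0.02, 0.04, 0.08, 0.12, 0.16, 0.2)

_ALLELE_RE = re.compile(r"^([A-Za-z0-9-]+)\*(\d+):(\d+)(?::.*)?$")


def normalize_two_field(allele_name: str) -> str:
    """Truncate an HLA allele name to two fields (``A*01:01:01:02`` -> ``A*01:01``).

    Idempotent; raises ValueError on names with fewer than two fields.
    """
    m = _ALLELE_RE.match(allele_name.strip())
    if not m:
        raise ValueError(f"malformed HLA allele name: {allele_name!r}")
    gene, f1, f2 = m.groups()
    return f"{gene}*{f1}:{f2}"


def resolve_ambiguous_call(candidates, freq_table) -> str:
    """Pick the most common candidate (pooled frequency); ties break
    lexicographically."""
    cands = sorted(set(candidates))
    if not cands:
        raise ValueError("empty candidate set")
    # min over (-frequency, name): ties go to the lexicographically smaller
    return min(cands, key=lambda a: (-freq_table.get(a, 0.0), a))


def load_hla_calls(path, genes=None, sample_col: str = "sample_id") -> pd.DataFrame:
    """Read an HLA call table (dbMHC diversity-file shape).

    Expects one row per sample with two columns per gene named ``GENE.1`` and
    ``GENE.2``; ambiguous calls are ``/``-separated candidate lists.  Returns
    a long-format frame (sample_id, gene, chromosome in {1, 2}, candidates as
    a tuple of raw names).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if genes is None:
        genes = sorted(
            {c[:-2] for c in df.columns if c.endswith(".1") and f"{c[:-2]}.2" in df.columns}
        )
    rows = []
    for rec in df.to_dict("records"):
        for gene in genes:
            for copy in (1, 2):
                raw = rec.get(f"{gene}.{copy}")
                if raw is None or pd.isna(raw) or not str(raw).strip():
                    continue
                rows.append(
                    {
                        "sample_id": rec[sample_col],
                        "gene": gene,
                        "copy": copy,
                        "candidates": tuple(str(raw).split("/")),
                    }
                )
    return pd.DataFrame(rows)


def disambiguate_calls(calls: pd.DataFrame, max_iter: int = 10) -> pd.DataFrame:
    """Normalise candidates to two fields and resolve ambiguities.

    Pooled allele frequencies are computed from the current assignment
    (unambiguous calls seed the first pass) and ambiguous calls are re-pointed
    at their most frequent candidate, iterating until the assignment is
    stable.  Adds an ``allele`` column.
    """
    calls = calls.copy()
    norm_cands = [
        tuple(sorted({normalize_two_field(c) for c in cands}))
        for cands in calls["candidates"]
    ]
    calls["norm_candidates"] = norm_cands
    assigned = [c[0] if len(c) == 1 else None for c in norm_cands]

    for _ in range(max_iter):
        freq = pd.Series([a for a in assigned if a is not None]).value_counts(
            normalize=True
        ).to_dict()
        new = [
            c[0] if len(c) == 1 else resolve_ambiguous_call(c, freq)
            for c in norm_cands
        ]
        if new == assigned:
            break
        assigned = new
    calls["allele"] = assigned
    return calls.drop(columns=["norm_candidates"])


@dataclass
class PseudoBiallelicLocus:
    """One-vs-rest recoding of a single two-field allele at one gene."""

    gene: str
    allele: str
    sample_ids: list[str]
    genotypes: np.ndarray  # count of the focal allele per typed sample, {0,1,2}


def recode_one_vs_rest(
    calls: pd.DataFrame, panel: PopulationPanel
) -> list[PseudoBiallelicLocus]:
    """Recode each gene's calls as one biallelic locus per distinct allele.

    ``calls`` must carry an ``allele`` column (see :func:`disambiguate_calls`)
    with two rows per typed sample per gene.  Panel samples untyped at a gene
    are dropped for that gene.  Within a gene, each sample's focal-allele
    counts across loci sum to 2 by construction.
    """
    if "allele" not in calls.columns:
        raise ValueError("calls must be disambiguated first (no 'allele' column)")
    panel_samples = set(panel.sample_ids)
    loci: list[PseudoBiallelicLocus] = []
    for gene, sub in calls.groupby("gene", sort=True):
        sub = sub[sub["sample_id"].isin(panel_samples)]
        counts = sub.groupby("sample_id")["allele"].apply(list)
        typed = counts[counts.apply(len) == 2]
        if typed.empty:
            continue
        samples = sorted(typed.index)
        pairs = typed[samples]
        for allele in sorted({a for pair in pairs for a in pair}):
            g = np.array([pair.count(allele) for pair in pairs], dtype=np.int8)
            loci.append(
                PseudoBiallelicLocus(
                    gene=str(gene), allele=allele, sample_ids=samples, genotypes=g
                )
            )
    return loci


def haplotype_fst_table(
    loci: list[PseudoBiallelicLocus], panel: PopulationPanel
) -> pd.DataFrame:
    """WC84 FST per pseudo-biallelic locus, plus pooled global MAF."""
    pop_of = dict(zip(panel.table["sample_id"], panel.pop_codes))
    n_pops = len(panel.populations)
    rows = []
    for locus in loci:
        codes = np.array([pop_of[s] for s in locus.sample_ids])
        gt = locus.genotypes[None, :]
        vc = fst_mod.wc_components_from_genotypes(gt, codes, n_pops)
        stats = fst_mod.snp_frequency_summary(gt, codes, n_pops)
        rows.append(
            {
                "gene": locus.gene,
                "allele": locus.allele,
                "global_maf": float(stats["global_maf"][0]),
                "a": float(vc.a[0]),
                "denom": float(vc.denom[0]),
                "fst": float(fst_mod.per_snp_fst(vc)[0]),
            }
        )
    return pd.DataFrame(rows)


def haplotype_fst_by_maf_bin(
    hap_table: pd.DataFrame,
    hla_snps: pd.DataFrame,
    control_snps: pd.DataFrame,
    scheme=HAPLOTYPE_BIN_EDGES,
    maf_col: str = "global_maf",
    fst_col: str = "fst",
) -> pd.DataFrame:
    """Per-bin comparison of haplotype loci against focal and control SNPs.

    SNP sets are restricted to the haplotype bin range; each bin reports
    medians and two-sided Mann-Whitney p-values for haplotypes vs focal SNPs
    and haplotypes vs control SNPs (NaN where a side is empty).
    """
    edges = _edges(scheme)
    frames = {"hap": hap_table, "hla": hla_snps, "control": control_snps}
    binned = {}
    for key, df in frames.items():
        maf = df[maf_col].to_numpy(dtype=float)
        keep = np.isfinite(maf) & (maf >= edges[0]) & (maf <= edges[-1])
        d = df.loc[keep]
        binned[key] = (np.atleast_1d(assign_maf_bin(d[maf_col].to_numpy(), edges)),
                       d[fst_col].to_numpy(dtype=float))
    rows = []
    for b in range(edges.size - 1):
        vals = {k: fstv[binsv == b] for k, (binsv, fstv) in binned.items()}
        hap = vals["hap"][np.isfinite(vals["hap"])]
        row = {
            "maf_lo": edges[b],
            "maf_hi": edges[b + 1],
            "n_hap": hap.size,
            "hap_median": float(np.median(hap)) if hap.size else np.nan,
        }
        for key in ("hla", "control"):
            other = vals[key][np.isfinite(vals[key])]
            row[f"n_{key}"] = other.size
            row[f"{key}_median"] = float(np.median(other)) if other.size else np.nan
            row[f"p_vs_{key}"] = (
                _mw_pvalue(hap, other) if hap.size and other.size else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)
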