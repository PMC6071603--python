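"""Input handling: population panel, region map, annotations and VCF genotypes.

The loader applies the study's sample and site filters:

* samples from populations flagged admixed are dropped;
* only biallelic SNVs are kept (multi-allelic records are dropped, never
  decomposed — the estimator's theory is biallelic);
* sites on the exclusion list (e.g. known genotyping-error sites) are
  dropped;
* only sites of the requested functional class (from a consumed annotation
  table, e.g. ANNOVAR output) are kept, so focal/control comparisons are
  made within the same functional category;
* a retained site must be polymorphic in at least one retained population
  (ALT count strictly between 0 and twice the non-missing sample count).

Region intervals are 1-based, fully closed, matching the VCF POS convention.
Drop counts per filter are recorded in a provenance log; each dropped site is
attributed to the first filter it fails in the order multiallelic, excluded,
functional class, monomorphic (the retained set itself is order-independent).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PopulationPanel",
    "RegionMap",
    "GenotypeMatrix",
    "load_panel",
    "load_region_map",
    "load_annotations",
    "classify_snp_region",
    "apply_site_filters",
]


@dataclass
class PopulationPanel:
    """Retained (non-admixed) samples with population and continental group."""

    table: pd.DataFrame  # sample_id, population, group
    n_excluded_populations: int = 0

    def __post_init__(self):
        if self.table["sample_id"].duplicated().any():
            dup = self.table.loc[self.table["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValueError(f"duplicate sample id: {dup}")
        if self.table["population"].nunique() < 2:
            raise ValueError("fewer than 2 populations remain after exclusion")

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    @property
    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.table["population"]))

    @property
    def groups(self) -> list[str]:
        first = self.table.drop_duplicates("population").set_index("population")
        return [str(first.loc[p, "group"]) for p in self.populations]

    @property
    def pop_codes(self) -> np.ndarray:
        index = {p: i for i, p in enumerate(self.populations)}
        return np.array([index[p] for p in self.table["population"]])

    def counts(self) -> pd.Series:
        return self.table["population"].value_counts()[self.populations]


def load_panel(path) -> PopulationPanel:
    """Read a sample panel TSV (sample_id, population, group, admixed yes/no).

    Admixed populations are excluded from all analysis sets.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "population", "group", "admixed"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"panel is missing columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample id: {dup}")
    admixed = df["admixed"].str.lower().isin({"yes", "true", "1"})
    n_excl = df.loc[admixed, "population"].nunique()
    kept = df.loc[~admixed, ["sample_id", "population", "group"]].reset_index(drop=True)
    return PopulationPanel(table=kept, n_excluded_populations=int(n_excl))


@dataclass
class RegionMap:
    """Focal/peri-focal gene intervals (1-based, closed) plus excluded sites."""

    hla_intervals: list[tuple[str, int, int, str]] = field(default_factory=list)
    peri_intervals: list[tuple[str, int, int, str]] = field(default_factory=list)
    excluded_sites: set[tuple[str, int]] = field(default_factory=set)

    def __post_init__(self):
        for chrom, start, end, name in self.hla_intervals + self.peri_intervals:
            if start > end:
                raise ValueError(f"degenerate interval for {name}: {start} > {end}")
        for h in self.hla_intervals:
            for p in self.peri_intervals:
                if h[0] == p[0] and h[1] <= p[2] and p[1] <= h[2]:
                    raise ValueError(
                        f"HLA interval {h[3]} overlaps peri-HLA interval {p[3]}"
                    )

    def classify(self, chrom: str, pos: int) -> str:
        for c, s, e, _ in self.hla_intervals:
            if c == chrom and s <= pos <= e:
                return "HLA"
        for c, s, e, _ in self.peri_intervals:
            if c == chrom and s <= pos <= e:
                return "periHLA"
        return "control"

    def gene_at(self, chrom: str, pos: int) -> str | None:
        for c, s, e, name in self.hla_intervals + self.peri_intervals:
            if c == chrom and s <= pos <= e:
                return name
        return None


def classify_snp_region(chrom: str, pos: int, region_map: RegionMap) -> str:
    """Region class of a site: HLA, periHLA, or control (the default)."""
    return region_map.classify(chrom, pos)


def load_region_map(regions_path, exclude_path=None) -> RegionMap:
    """Read interval TSV (chrom, start, end, gene, label) and exclusion TSV."""
    df = pd.read_csv(regions_path, sep="\t")
    hla, peri = [], []
    for row in df.itertuples(index=False):
        tup = (str(row.chrom), int(row.start), int(row.end), str(row.gene))
        if str(row.label) == "HLA":
            hla.append(tup)
        elif str(row.label) == "periHLA":
            peri.append(tup)
        else:
            raise ValueError(f"unknown region label: {row.label!r}")
    excluded: set[tuple[str, int]] = set()
    if exclude_path is not None:
        ex = pd.read_csv(exclude_path, sep="\t")
        excluded = {(str(c), int(p)) for c, p in zip(ex["chrom"], ex["pos"])}
    return RegionMap(hla_intervals=hla, peri_intervals=peri, excluded_sites=excluded)


def load_annotations(path) -> pd.DataFrame:
    """Read the functional annotation table (chrom, pos, functional_class[, gene])."""
    df = pd.read_csv(path, sep="\t")
    df["chrom"] = df["chrom"].astype(str)
    df["pos"] = df["pos"].astype(int)
    return df


@dataclass
class GenotypeMatrix:
    """Filtered diploid genotypes for the retained samples.

    ``genotypes`` holds ALT allele counts (-1 missing), one row per retained
    site, columns aligned with ``panel.sample_ids``.
    """

    sites: pd.DataFrame  # chrom, pos, ref, alt, gene, functional_class, region_class
    genotypes: np.ndarray
    panel: PopulationPanel
    provenance: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.genotypes.shape != (len(self.sites), len(self.panel.sample_ids)):
            raise ValueError("genotype matrix dimensions inconsistent with panel/sites")

    @property
    def pop_codes(self) -> np.ndarray:
        return self.panel.pop_codes


def _is_biallelic_snv(variant) -> bool:
    return (
        len(variant.ALT) == 1
        and len(variant.REF) == 1
        and len(variant.ALT[0]) == 1
        and variant.REF != variant.ALT[0]
        and variant.REF in "ACGT"
        and variant.ALT[0] in "ACGT"
    )


def apply_site_filters(
    vcf_path,
    panel: PopulationPanel,
    annotations: pd.DataFrame,
    region_map: RegionMap,
    functional_class: str = "exonic",
) -> GenotypeMatrix:
    """Stream a VCF and return the filtered genotype matrix.

    Raises if panel samples are missing from the VCF or if no site survives.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=True)
    vcf_samples = set(vcf.samples)
    missing = [s for s in panel.sample_ids if s not in vcf_samples]
    if missing:
        raise ValueError(f"panel samples absent from VCF: {missing[:5]}")
    vcf.close()
    vcf = VCF(str(vcf_path), gts012=True, samples=panel.sample_ids)
    # cyvcf2 returns subset samples in file order; map back to panel order
    col_of = {s: i for i, s in enumerate(vcf.samples)}
    reorder = np.array([col_of[s] for s in panel.sample_ids])

    ann = annotations.set_index(["chrom", "pos"])
    has_gene = "gene" in annotations.columns
    pop_codes = panel.pop_codes
    n_pops = len(panel.populations)

    drops = {"multiallelic": 0, "excluded": 0, "functional_class": 0,
             "monomorphic": 0}
    site_rows, geno_rows = [], []
    for variant in vcf:
        chrom, pos = str(variant.CHROM), int(variant.POS)
        if not _is_biallelic_snv(variant):
            drops["multiallelic"] += 1
            continue
        if (chrom, pos) in region_map.excluded_sites:
            drops["excluded"] += 1
            continue
        try:
            rec = ann.loc[(chrom, pos)]
        except KeyError:
            raise ValueError(f"no functional annotation for {chrom}:{pos}") from None
        if isinstance(rec, pd.DataFrame):
            rec = rec.iloc[0]
        if str(rec["functional_class"]) != functional_class:
            drops["functional_class"] += 1
            continue
        gt = np.asarray(variant.gt_types)[reorder]
        gt = np.where(gt == 3, -1, gt).astype(np.int8)
        ok = gt >= 0
        poly = False
        for k in range(n_pops):
            sel = pop_codes == k
            alt = int(gt[sel & ok].sum())
            tot = 2 * int((sel & ok).sum())
            if 0 < alt < tot:
                poly = True
                break
        if not poly:
            drops["monomorphic"] += 1
            continue
        site_rows.append(
            {
                "chrom": chrom,
                "pos": pos,
                "ref": variant.REF,
                "alt": variant.ALT[0],
                "gene": str(rec["gene"]) if has_gene else None,
                "functional_class": functional_class,
                "region_class": region_map.classify(chrom, pos),
            }
        )
        geno_rows.append(gt)
    vcf.close()

    if not site_rows:
        raise ValueError("zero sites survived the filters")
    return GenotypeMatrix(
        sites=pd.DataFrame(site_rows),
        genotypes=np.vstack(geno_rows),
        panel=panel,
        provenance=drops,
    )
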