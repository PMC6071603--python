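"""Synthetic multi-population genotype fixtures with HLA-like structure.

Generates the full input bundle the pipeline consumes (VCF, population panel,
region map, functional annotation, exclusion list, HLA-style haplotype call
table) with the statistical structure the analysis assumes:

* control genes carry a rare-variant-rich folded site frequency spectrum
  (density proportional to 1/x) and stronger differentiation (Balding-Nichols
  concentration ``f_control``);
* focal ("HLA-like") and peri-focal genes carry an intermediate-frequency SFS
  (shifted symmetric Beta) and weaker differentiation (``f_focal``), so that
  the *unconditional* FST distribution of focal SNPs sits above the control
  distribution while the MAF-conditional comparison reverses — the signature
  of balancing selection the pipeline is built to expose;
* SNPs within a gene share part of their population-level frequency
  deviation (a Gaussian copula on the Balding-Nichols quantiles), inducing
  intra-gene LD so that gene-block resampling is meaningfully different from
  i.i.d. SNP sampling.

The Balding-Nichols model draws each population's allele frequency from
Beta(p(1-F)/F, (1-p)(1-F)/F) around the ancestral frequency p; F plays the
role of the parametric FST among populations.  This is test scaffolding: it
makes no claim about human demography (no migration, no recombination maps,
exchangeable populations).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SynthConfig",
    "SyntheticDataset",
    "draw_site_frequencies",
    "generate_dataset",
    "emit_fixture",
    "tree_split_frequencies",
]

_GROUPS = ("AFR", "EUR", "EAS", "SAS")
_FOCAL_GENE_NAMES = ("A", "B", "C", "DRB1", "DQB1", "DRA", "DQA1")


@dataclass(frozen=True)
class SynthConfig:
    """Generator parameters; defaults mirror the study conditions.

    20 populations of 100 diploids in 4 continental groups; focal
    differentiation 0.04 vs control 0.09 (the two multi-locus
    ratio-of-averages levels the real-data analysis reports); 7 focal genes;
    focal SFS concentrated at intermediate frequency vs a control SFS whose
    dominant component sits at or below ~2 expected copies in the pooled
    sample, so that — as in exome resequencing data — most realized control
    variants are few-copy and carry near-zero estimated FST.
    """

    n_pops: int = 20
    samples_per_pop: int = 100
    n_control_genes: int = 3000
    control_snps_per_gene: int = 10
    n_focal_genes: int = 7
    focal_snps_per_gene: int = 30
    n_peri_genes: int = 2
    peri_snps_per_gene: int = 20
    f_control: float = 0.09
    f_focal: float = 0.04
    ld_strength: float = 0.8
    control_rare_weight: float = 0.92
    control_maf_min: float = 5e-5
    control_rare_maf_max: float = 5e-4
    exclusion_frac: float = 0.02
    intronic_frac: float = 0.1
    n_hla_alleles: int = 12
    f_hla: float = 0.04
    ambiguous_frac: float = 0.05
    n_admixed_pops: int = 0
    rng_seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.f_control < 1.0 and 0.0 < self.f_focal < 1.0):
            raise ValueError("F parameters must lie in (0, 1)")
        if not 0.0 <= self.ld_strength <= 1.0:
            raise ValueError("ld_strength must lie in [0, 1]")
        if self.n_pops < 2:
            raise ValueError("need at least 2 populations")


@dataclass
class SyntheticDataset:
    """In-memory fixture: genotypes plus every table the pipeline reads."""

    config: SynthConfig
    panel: pd.DataFrame          # sample_id, population, group, admixed
    sites: pd.DataFrame          # chrom, pos, ref, alt, gene, functional_class,
                                 # region_class, excluded
    genotypes: np.ndarray        # (n_sites, n_samples) int8 ALT counts
    pop_freqs: np.ndarray        # (n_sites, n_pops) true per-population freqs
    ancestral_freq: np.ndarray   # (n_sites,)
    hla_calls: pd.DataFrame
    regions: pd.DataFrame        # chrom, start, end, gene, label

    @property
    def pop_codes(self) -> np.ndarray:
        pops = list(dict.fromkeys(self.panel["population"]))
        index = {p: i for i, p in enumerate(pops)}
        return np.array([index[p] for p in self.panel["population"]])

    @property
    def pop_names(self) -> list[str]:
        return list(dict.fromkeys(self.panel["population"]))


def _sample_ancestral_maf(n: int, gene_class: str, cfg: SynthConfig, rng) -> np.ndarray:
    if gene_class == "control":
        # two-component folded SFS, each ~ 1/x: a heavy ultra-rare component
        # (below ~2 pooled copies, so post-ascertainment the realized control
        # spectrum is dominated by few-copy variants, as in exome data) and a
        # common tail keeping every MAF bin populated
        rare = rng.random(n) < cfg.control_rare_weight
        lo = np.where(rare, np.log(cfg.control_maf_min),
                      np.log(cfg.control_rare_maf_max))
        hi = np.where(rare, np.log(cfg.control_rare_maf_max), np.log(0.5))
        return np.exp(rng.uniform(lo, hi, size=n))
    # focal / peri: symmetric Beta shifted into (0.1, 0.5)
    return 0.1 + 0.4 * rng.beta(2.0, 2.0, size=n)


def draw_site_frequencies(
    config: SynthConfig,
    gene_class: str,
    n_genes: int,
    snps_per_gene: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Ancestral and per-population frequencies for a block of genes.

    Returns ``(ancestral, pop_freqs, gene_index)`` with shapes (S,), (S, P)
    and (S,).  Per-population frequencies are Balding-Nichols draws with the
    class F; a Gaussian copula shares a per-gene, per-population deviation
    across the gene's SNPs with weight ``ld_strength`` (0 = independent SNPs,
    1 = identical within-gene quantiles), leaving each SNP's marginal
    Balding-Nichols distribution intact.
    """
    f = config.f_control if gene_class == "control" else config.f_focal
    n_snps = n_genes * snps_per_gene
    p_total = config.n_pops + config.n_admixed_pops

    maf = _sample_ancestral_maf(n_snps, gene_class, config, rng)
    flip = rng.random(n_snps) < 0.5
    p0 = np.where(flip, 1.0 - maf, maf)

    lam = config.ld_strength
    z_gene = rng.standard_normal((n_genes, config.n_pops))
    z_snp = rng.standard_normal((n_snps, config.n_pops))
    gene_index = np.repeat(np.arange(n_genes), snps_per_gene)
    z = np.sqrt(lam) * z_gene[gene_index] + np.sqrt(1.0 - lam) * z_snp
    u = stats.norm.cdf(z)

    ratio = (1.0 - f) / f
    alpha = p0[:, None] * ratio
    beta = (1.0 - p0)[:, None] * ratio
    freqs = stats.beta.ppf(u, alpha, beta)
    freqs = np.clip(freqs, 0.0, 1.0)

    if config.n_admixed_pops:
        # admixed populations are even mixtures of two random source pops
        mix = np.empty((n_snps, config.n_admixed_pops))
        for k in range(config.n_admixed_pops):
            i, j = rng.choice(config.n_pops, size=2, replace=False)
            mix[:, k] = 0.5 * (freqs[:, i] + freqs[:, j])
        freqs = np.hstack([freqs, mix])
        assert freqs.shape[1] == p_total
    return p0, freqs, gene_index


def _polymorphic_in_a_pop(genotypes: np.ndarray, pop_codes: np.ndarray,
                          n_pops: int) -> np.ndarray:
    keep = np.zeros(genotypes.shape[0], dtype=bool)
    for k in range(n_pops):
        g = genotypes[:, pop_codes == k]
        ok = g >= 0
        alt = np.where(ok, g, 0).sum(axis=1)
        tot = 2 * ok.sum(axis=1)
        keep |= (alt > 0) & (alt < tot)
    return keep


def _make_hla_calls(cfg: SynthConfig, panel: pd.DataFrame, gene_names, rng) -> pd.DataFrame:
    ratio = (1.0 - cfg.f_hla) / cfg.f_hla
    pops = list(dict.fromkeys(panel["population"]))
    rows = {"sample_id": panel["sample_id"].tolist(),
            "population": panel["population"].tolist()}
    for gene in gene_names:
        names = [f"{gene}*{i + 1:02d}:01" for i in range(cfg.n_hla_alleles)]
        global_w = rng.dirichlet(np.full(cfg.n_hla_alleles, 2.0))
        pop_w = {p: rng.dirichlet(global_w * ratio) for p in pops}
        col1, col2 = [], []
        for pop in panel["population"]:
            for col in (col1, col2):
                idx = rng.choice(cfg.n_hla_alleles, p=pop_w[pop])
                call = names[idx]
                # occasionally report extra nomenclature fields
                if rng.random() < 0.3:
                    call = call + f":{rng.integers(1, 4):02d}"
                if rng.random() < cfg.ambiguous_frac:
                    other = names[int(rng.choice(cfg.n_hla_alleles))]
                    if other != names[idx]:
                        call = call + "/" + other
                col.append(call)
        rows[f"{gene}.1"] = col1
        rows[f"{gene}.2"] = col2
    return pd.DataFrame(rows)


def generate_dataset(config: SynthConfig) -> SyntheticDataset:
    """Draw the complete fixture for ``config`` (deterministic in the seed).

    Sites that come out monomorphic in every non-admixed population are
    dropped, mimicking variant-call ascertainment, so a loaded fixture
    round-trips with no filter losses beyond those deliberately planted
    (exclusion-list sites, off-class annotations).
    """
    rng = np.random.default_rng(config.rng_seed)

    pops = [f"POP{i + 1:02d}" for i in range(config.n_pops)]
    groups = [_GROUPS[i % len(_GROUPS)] for i in range(config.n_pops)]
    admixed_pops = [f"ADM{i + 1:02d}" for i in range(config.n_admixed_pops)]
    panel_rows = []
    for pop, grp in zip(pops + admixed_pops,
                        groups + ["ADMIXED"] * config.n_admixed_pops):
        for j in range(config.samples_per_pop):
            panel_rows.append(
                {
                    "sample_id": f"{pop}_S{j + 1:03d}",
                    "population": pop,
                    "group": grp,
                    "admixed": "yes" if pop.startswith("ADM") else "no",
                }
            )
    panel = pd.DataFrame(panel_rows)

    blocks = []  # (class, chrom, base_pos, gene prefix, p0, freqs, gene_idx)
    p0_c, fr_c, gi_c = draw_site_frequencies(
        config, "control", config.n_control_genes, config.control_snps_per_gene, rng
    )
    blocks.append(("control", gi_c, p0_c, fr_c))
    p0_f, fr_f, gi_f = draw_site_frequencies(
        config, "focal", config.n_focal_genes, config.focal_snps_per_gene, rng
    )
    blocks.append(("HLA", gi_f, p0_f, fr_f))
    p0_p, fr_p, gi_p = draw_site_frequencies(
        config, "peri", config.n_peri_genes, config.peri_snps_per_gene, rng
    )
    blocks.append(("periHLA", gi_p, p0_p, fr_p))

    focal_gene_names = [
        _FOCAL_GENE_NAMES[i] if i < len(_FOCAL_GENE_NAMES) else f"FG{i + 1}"
        for i in range(config.n_focal_genes)
    ]

    site_rows, freq_rows, anc = [], [], []
    region_rows = []
    bases = "ACGT"
    for cls, gene_idx, p0, freqs in blocks:
        for s in range(len(p0)):
            g = int(gene_idx[s])
            if cls == "control":
                chrom = f"chr{g % 5 + 1}"
                gene = f"CTRL{g + 1:04d}"
                pos = 1_000_000 + (g // 5) * 100_000 + (s % config.control_snps_per_gene) * 100 + 1
            elif cls == "HLA":
                chrom = "chr6"
                gene = f"HLA_{focal_gene_names[g]}"
                pos = 29_000_000 + g * 100_000 + (s % config.focal_snps_per_gene) * 100 + 1
            else:
                chrom = "chr6"
                gene = f"PERI{g + 1}"
                pos = 31_000_000 + g * 100_000 + (s % config.peri_snps_per_gene) * 100 + 1
            ref = bases[int(rng.integers(4))]
            alt = bases[(bases.index(ref) + 1 + int(rng.integers(3))) % 4]
            if cls == "control":
                func = "intronic" if rng.random() < config.intronic_frac else "exonic"
            else:
                func = "exonic"
            site_rows.append(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "ref": ref,
                    "alt": alt,
                    "gene": gene,
                    "functional_class": func,
                    "region_class": cls,
                    "excluded": cls == "HLA" and rng.random() < config.exclusion_frac,
                }
            )
            freq_rows.append(freqs[s])
            anc.append(p0[s])

    sites = pd.DataFrame(site_rows)
    pop_freqs = np.asarray(freq_rows)
    ancestral = np.asarray(anc)

    # genotypes: HWE binomial draws from the population frequencies
    n_per = config.samples_per_pop
    cols = []
    for k in range(config.n_pops + config.n_admixed_pops):
        cols.append(rng.binomial(2, pop_freqs[:, [k]], size=(len(sites), n_per)))
    genotypes = np.hstack(cols).astype(np.int8)

    pop_codes = np.repeat(np.arange(config.n_pops + config.n_admixed_pops), n_per)
    retained = pop_codes < config.n_pops
    keep = _polymorphic_in_a_pop(genotypes[:, retained], pop_codes[retained],
                                 config.n_pops)
    sites = sites.loc[keep].reset_index(drop=True)
    genotypes = genotypes[keep]
    pop_freqs = pop_freqs[keep]
    ancestral = ancestral[keep]

    # sort by chrom (contig order) then pos for a valid VCF
    chrom_order = {f"chr{i}": i for i in range(1, 7)}
    order = sites.assign(_c=sites["chrom"].map(chrom_order)).sort_values(
        ["_c", "pos"], kind="mergesort"
    ).index.to_numpy()
    sites = sites.loc[order].reset_index(drop=True)
    genotypes = genotypes[order]
    pop_freqs = pop_freqs[order]
    ancestral = ancestral[order]

    for g, gene in enumerate(focal_gene_names):
        start = 29_000_000 + g * 100_000 + 1
        region_rows.append(
            {"chrom": "chr6", "start": start,
             "end": start + config.focal_snps_per_gene * 100,
             "gene": f"HLA_{gene}", "label": "HLA"}
        )
    for g in range(config.n_peri_genes):
        start = 31_000_000 + g * 100_000 + 1
        region_rows.append(
            {"chrom": "chr6", "start": start,
             "end": start + config.peri_snps_per_gene * 100,
             "gene": f"PERI{g + 1}", "label": "periHLA"}
        )
    regions = pd.DataFrame(region_rows)

    retained_panel = panel.loc[panel["admixed"] == "no"]
    hla_calls = _make_hla_calls(config, retained_panel, focal_gene_names, rng)

    return SyntheticDataset(
        config=config,
        panel=panel,
        sites=sites,
        genotypes=genotypes,
        pop_freqs=pop_freqs,
        ancestral_freq=ancestral,
        hla_calls=hla_calls,
        regions=regions,
    )


def emit_fixture(dataset: SyntheticDataset, outdir) -> dict[str, str]:
    """Write the fixture bundle to ``outdir``; returns the file paths.

    Files: genotypes.vcf, panel.tsv, regions.tsv, exclude.tsv,
    annotations.tsv, hla_calls.tsv.  Output is byte-identical for a fixed
    generator seed.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    vcf_path = outdir / "genotypes.vcf"
    samples = dataset.panel["sample_id"].tolist()
    gt_strings = np.array(["0/0", "0/1", "1/1", "./."])
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##source=balsel-diff synthetic fixture\n')
        for c in range(1, 7):
            fh.write(f"##contig=<ID=chr{c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        codes = np.where(dataset.genotypes < 0, 3, dataset.genotypes)
        for i, site in enumerate(dataset.sites.itertuples(index=False)):
            gts = "\t".join(gt_strings[codes[i]])
            fh.write(
                f"{site.chrom}\t{site.pos}\t.\t{site.ref}\t{site.alt}\t.\tPASS\t.\tGT\t{gts}\n"
            )
    paths["vcf"] = str(vcf_path)

    panel_path = outdir / "panel.tsv"
    dataset.panel.to_csv(panel_path, sep="\t", index=False)
    paths["panel"] = str(panel_path)

    regions_path = outdir / "regions.tsv"
    dataset.regions.to_csv(regions_path, sep="\t", index=False)
    paths["regions"] = str(regions_path)

    excl_path = outdir / "exclude.tsv"
    dataset.sites.loc[dataset.sites["excluded"], ["chrom", "pos"]].to_csv(
        excl_path, sep="\t", index=False
    )
    paths["exclude"] = str(excl_path)

    annot_path = outdir / "annotations.tsv"
    dataset.sites[["chrom", "pos", "functional_class", "gene"]].to_csv(
        annot_path, sep="\t", index=False
    )
    paths["annotations"] = str(annot_path)

    hla_path = outdir / "hla_calls.tsv"
    dataset.hla_calls.to_csv(hla_path, sep="\t", index=False)
    paths["hla_calls"] = str(hla_path)
    return paths


def tree_split_frequencies(
    depth: int,
    n_snps: int,
    f_branch: float = 0.02,
    maf_min: float = 0.05,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Serial-divergence frequencies along a balanced binary tree.

    Each branch applies a Balding-Nichols perturbation with concentration
    ``f_branch`` to the parent frequency; the 2**depth leaves are the
    populations.  Returns ``(freqs, split_time)`` where ``split_time[i, j]``
    is the tree distance (number of branches) separating leaves i and j —
    pairwise FST is expected to increase with it.
    """
    rng = np.random.default_rng() if rng is None else rng
    ratio = (1.0 - f_branch) / f_branch
    freqs = rng.uniform(maf_min, 1.0 - maf_min, size=(n_snps, 1))
    for _ in range(depth):
        children = []
        for k in range(freqs.shape[1]):
            parent = np.clip(freqs[:, k], 1e-6, 1 - 1e-6)
            for _ in range(2):
                children.append(rng.beta(parent * ratio, (1 - parent) * ratio))
        freqs = np.column_stack(children)
    n_leaves = 2**depth
    split = np.zeros((n_leaves, n_leaves))
    for i in range(n_leaves):
        for j in range(n_leaves):
            if i != j:
                lca_depth = depth - (i ^ j).bit_length()
                split[i, j] = 2 * (depth - lca_depth)
    return freqs, split
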