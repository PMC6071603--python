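import numpy as np
import pytest

from balseldiff import SynthConfig, generate_dataset, per_snp_fst_table

# Small configuration for I/O round trips: 4 populations, modest SNP counts,
# deliberate intronic and excluded sites to exercise the filters.
SMALL_CONFIG = SynthConfig(
    n_pops=4,
    samples_per_pop=12,
    n_control_genes=12,
    control_snps_per_gene=5,
    control_rare_weight=0.3,
    control_maf_min=0.01,
    control_rare_maf_max=0.05,
    n_focal_genes=2,
    focal_snps_per_gene=6,
    n_peri_genes=1,
    peri_snps_per_gene=4,
    intronic_frac=0.2,
    exclusion_frac=0.15,
    n_hla_alleles=6,
    rng_seed=11,
)


@pytest.fixture(scope="session")
def default_dataset():
    """The generator's default study conditions (20 pops x 100 diploids)."""
    return generate_dataset(SynthConfig(rng_seed=7))


@pytest.fixture(scope="session")
def default_fst_table(default_dataset):
    ds = default_dataset
    return per_snp_fst_table(
        ds.genotypes, ds.pop_codes, ds.sites, ds.config.n_pops
    )


@pytest.fixture(scope="session")
def small_dataset():
    return generate_dataset(SMALL_CONFIG)


def random_instance(rng, n_pops=None, min_n=2, max_n=50, allow_missing=False):
    """Random per-population genotype lists for oracle comparisons."""
    r = int(n_pops if n_pops is not None else rng.integers(2, 9))
    pops = []
    for _ in range(r):
        n = int(rng.integers(min_n, max_n + 1))
        p = rng.uniform(0.02, 0.98)
        g = rng.binomial(2, p, size=n)
        if allow_missing and n > 1:
            g = g.astype(int)
            k = int(rng.integers(0, n // 2 + 1))
            g[:k] = -1
            rng.shuffle(g)
        pops.append(g.tolist())
    return pops


def to_matrix(pops):
    """Per-population genotype lists -> (1, N) matrix plus population codes."""
    gt = np.concatenate([np.asarray(g) for g in pops])[None, :]
    codes = np.concatenate(
        [np.full(len(g), k) for k, g in enumerate(pops)]
    )
    return gt.astype(np.int64), codes
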