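"""Wright-Fisher split simulations under shared and divergent overdominance.

An ancestral population at the deterministic equilibrium of heterozygote
advantage splits into two daughters.  Under *shared* overdominance both
daughters keep the ancestral fitness scheme; under *divergent* overdominance
one daughter's homozygote fitnesses shift so that its equilibrium frequency
moves by ``delta``.  A matched neutral locus starts at the same frequency in
both daughters and evolves by pure drift.  Tracking parametric FST between
the daughters for the selected and the neutral locus over time yields
``dFST = FST_neutral - FST_selection``: shared overdominance keeps dFST >= 0
at all times (selection suppresses differentiation), while divergent
overdominance with a large enough equilibrium shift and selection strength
makes dFST < 0 shortly after the split (selection transiently *drives*
differentiation) before the usual positive regime takes over as drift
accumulates at the neutral locus.

Fitnesses are parametrised by the equilibrium frequency ``feq`` and a total
selection strength ``s``: genotype fitnesses (1 - s1, 1, 1 - t1) with
s1 = s * (1 - feq) and t1 = s * feq, so that the interior equilibrium
t1/(s1 + t1) equals ``feq`` and the summed homozygote load s1 + t1 equals
``s``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "OverdominantFitness",
    "SimulationConfig",
    "FstTrajectory",
    "overdominant_fitnesses",
    "deterministic_freq_update",
    "wright_fisher_generation",
    "parametric_fst_two_pops",
    "simulate_divergence_experiment",
]


@dataclass(frozen=True)
class OverdominantFitness:
    """Genotype fitnesses (w_AA, w_Aa, w_aa) with the heterozygote fittest."""

    w_AA: float
    w_Aa: float
    w_aa: float

    @property
    def equilibrium(self) -> float:
        s1 = self.w_Aa - self.w_AA
        t1 = self.w_Aa - self.w_aa
        return t1 / (s1 + t1)


def overdominant_fitnesses(feq: float, s: float) -> OverdominantFitness:
    """Fitness scheme with interior equilibrium ``feq`` and homozygote load ``s``."""
    if not 0.0 < feq < 1.0:
        raise ValueError("feq must lie strictly in (0, 1)")
    if not 0.0 < s < 1.0:
        raise ValueError("s must lie strictly in (0, 1)")
    s1 = s * (1.0 - feq)
    t1 = s * feq
    return OverdominantFitness(w_AA=1.0 - s1, w_Aa=1.0, w_aa=1.0 - t1)


def deterministic_freq_update(p, w: OverdominantFitness):
    """One generation of viability selection (infinite population)."""
    p = np.asarray(p, dtype=float)
    q = 1.0 - p
    wbar = p**2 * w.w_AA + 2.0 * p * q * w.w_Aa + q**2 * w.w_aa
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(wbar > 0, (p**2 * w.w_AA + p * q * w.w_Aa) / np.where(wbar > 0, wbar, 1.0), p)
    return float(out) if out.ndim == 0 else out


def wright_fisher_generation(p, N: int, w: OverdominantFitness | None, rng):
    """Binomial resampling of 2N gametes after (optional) viability selection."""
    if N < 1:
        raise ValueError("N must be >= 1")
    p_sel = deterministic_freq_update(p, w) if w is not None else np.asarray(p, dtype=float)
    draws = rng.binomial(2 * N, p_sel) / (2.0 * N)
    return draws


def parametric_fst_two_pops(p1, p2):
    """Two-deme parametric FST (p1-p2)^2 / (4 pbar qbar); NaN if monomorphic."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    num = (p1 - p2) ** 2
    pbar = (p1 + p2) / 2.0
    den = 4.0 * pbar * (1.0 - pbar)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the split experiment.

    ``delta = 0`` is shared overdominance; ``delta != 0`` shifts daughter 2's
    equilibrium to ``feq + delta`` (divergent overdominance).  Both daughters
    have size ``size_fold * N0`` from the split onward.
    """

    N0: int = 1000
    size_fold: float = 1.0
    s: float = 0.05
    feq: float = 0.5
    delta: float = 0.0
    t_max: int = 2000
    n_replicates: int = 2000
    rng_seed: int = 0
    record_times: tuple[int, ...] | None = None

    def __post_init__(self):
        if self.N0 < 2:
            raise ValueError("N0 must be >= 2")
        if not 0.0 < self.feq < 1.0:
            raise ValueError("feq must lie in (0, 1)")
        if not 0.0 < self.feq + self.delta < 1.0:
            raise ValueError("feq + delta must lie in (0, 1)")
        if not 0.0 <= self.s < 1.0:
            raise ValueError("s must lie in [0, 1)")
        if self.size_fold <= 0:
            raise ValueError("size_fold must be positive")

    @property
    def nt(self) -> int:
        return max(1, int(round(self.size_fold * self.N0)))


@dataclass
class FstTrajectory:
    """Per-generation FST (selected and neutral loci) aggregated over replicates.

    ``table`` columns: t; ratio-of-averages FST (fst_sel, fst_neu) with
    Monte-Carlo standard errors; mean-of-ratios variants (fst_sel_mor,
    fst_neu_mor); dfst = fst_neu - fst_sel and dfst_mor.
    """

    table: pd.DataFrame
    config: SimulationConfig = field(repr=False)

    def dfst_at(self, t: int, kind: str = "ratio") -> float:
        col = "dfst" if kind == "ratio" else "dfst_mor"
        row = self.table.loc[self.table["t"] == t]
        if row.empty:
            raise KeyError(f"time {t} was not recorded")
        return float(row[col].iloc[0])


def _ratio_of_averages(num: np.ndarray, den: np.ndarray) -> tuple[float, float]:
    """mean(num)/mean(den) with a delta-method standard error."""
    n = num.size
    mnum, mden = num.mean(), den.mean()
    if mden <= 0:
        return np.nan, np.nan
    ratio = mnum / mden
    resid = num - ratio * den
    se = np.sqrt(np.sum(resid**2) / (n - 1) / n) / mden if n > 1 else np.nan
    return float(ratio), float(se)


def simulate_divergence_experiment(config: SimulationConfig) -> FstTrajectory:
    """Run the split experiment and return FST/dFST trajectories.

    Replicates are simulated in lock-step as vectors; each replicate carries
    four loci: the selected locus in daughters 1 and 2 and an unlinked
    neutral locus in daughters 1 and 2, all starting at ``feq``.  Replicate
    aggregation is the ratio of averages of the two-deme parametric FST's
    numerator and denominator (replicates monomorphic in both daughters
    contribute nothing); the per-replicate mean of ratios is reported
    alongside.
    """
    rng = np.random.default_rng(config.rng_seed)
    R = config.n_replicates
    N = config.nt
    w1 = overdominant_fitnesses(config.feq, config.s) if config.s > 0 else None
    w2 = (
        overdominant_fitnesses(config.feq + config.delta, config.s)
        if config.s > 0
        else None
    )

    sel1 = np.full(R, config.feq)
    sel2 = np.full(R, config.feq)
    neu1 = np.full(R, config.feq)
    neu2 = np.full(R, config.feq)

    times = (
        sorted(set(config.record_times))
        if config.record_times is not None
        else list(range(1, config.t_max + 1))
    )
    if times and times[-1] > config.t_max:
        raise ValueError("record_times beyond t_max")
    record = set(times)

    rows = []
    for t in range(1, config.t_max + 1):
        sel1 = wright_fisher_generation(sel1, N, w1, rng)
        sel2 = wright_fisher_generation(sel2, N, w2, rng)
        neu1 = wright_fisher_generation(neu1, N, None, rng)
        neu2 = wright_fisher_generation(neu2, N, None, rng)
        if t not in record:
            continue
        row = {"t": t}
        for tag, (pa, pb) in {"sel": (sel1, sel2), "neu": (neu1, neu2)}.items():
            num = (pa - pb) ** 2
            pbar = (pa + pb) / 2.0
            den = 4.0 * pbar * (1.0 - pbar)
            roa, se = _ratio_of_averages(num, den)
            row[f"fst_{tag}"] = roa
            row[f"fst_{tag}_se"] = se
            ratios = parametric_fst_two_pops(pa, pb)
            ratios = ratios[np.isfinite(ratios)]
            row[f"fst_{tag}_mor"] = float(ratios.mean()) if ratios.size else np.nan
        row["dfst"] = row["fst_neu"] - row["fst_sel"]
        row["dfst_se"] = float(
            np.hypot(row["fst_neu_se"], row["fst_sel_se"])
        )
        row["dfst_mor"] = row["fst_neu_mor"] - row["fst_sel_mor"]
        rows.append(row)

    return FstTrajectory(table=pd.DataFrame(rows), config=config)
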