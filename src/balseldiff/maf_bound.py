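"""Analytic constraint of minor allele frequency on parametric FST.

For K demes with weights w summing to 1 and per-deme allele frequencies p_i,
parametric FST is the weighted among-deme variance scaled by the pooled
heterozygosity:

    FST = Var_w(p) / (pbar * (1 - pbar)),   pbar = sum(w_i * p_i).

Holding the pooled minor allele frequency m = min(pbar, 1 - pbar) fixed, FST
is a convex function of the frequency vector, so its maximum over the
constrained box [0,1]^K is attained at an extreme point: a configuration with
every deme fixed at 0 or 1 except at most one.  For equal weights this gives
the closed form implemented here; rare variants are therefore bounded to low
FST (for K = 2 the bound is m/(1-m)), which is why FST comparisons between
SNP sets with different site frequency spectra are misleading unless MAF is
controlled for.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from scipy.optimize import minimize

__all__ = [
    "parametric_fst",
    "max_parametric_fst",
    "maf_fst_envelope",
]


def parametric_fst(freqs, weights=None) -> float:
    """Parametric FST of a deme frequency configuration.

    NaN when the pooled frequency is 0 or 1 (monomorphic overall).
    """
    p = np.asarray(freqs, dtype=float)
    if weights is None:
        w = np.full(p.shape[-1], 1.0 / p.shape[-1])
    else:
        w = np.asarray(weights, dtype=float)
        w = w / w.sum()
    pbar = p @ w
    denom = pbar * (1.0 - pbar)
    var = ((p - np.expand_dims(pbar, -1)) ** 2) @ w
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, var / np.where(denom > 0, denom, 1.0), np.nan)
    return float(out) if np.ndim(out) == 0 else out


def _max_fst_equal_weights(maf: float, k: int) -> float:
    # extreme point: j demes fixed at 1, one at the fractional remainder,
    # the rest at 0; maximise over the (unique feasible) j = floor(K*pbar).
    pbar = 1.0 - maf
    kp = k * pbar
    j = int(np.floor(kp + 1e-9))
    frac = kp - j
    if frac < 1e-9:  # exact fixed-deme decomposition
        frac = 0.0
    # variance via deviations from the mean (stable for maf near 0)
    var = (j * (1.0 - pbar) ** 2 + (frac - pbar) ** 2
           + (k - j - 1) * pbar**2) / k
    return float(min(1.0, var / (pbar * maf)))


def _max_fst_weighted(maf: float, weights: np.ndarray, n_restarts: int = 64,
                      seed: int = 0) -> float:
    # numerical maximisation (convex objective, linear constraint): SLSQP
    # from random feasible starts; used only for unequal deme weights.
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    k = w.size
    pbar = 1.0 - maf
    rng = np.random.default_rng(seed)

    def neg_fst(p):
        return -parametric_fst(p, w)

    cons = {"type": "eq", "fun": lambda p: p @ w - pbar}
    best = 0.0
    for _ in range(n_restarts):
        x0 = rng.dirichlet(np.ones(k)) * 0.0 + rng.uniform(0, 1, k)
        # project the start onto the constraint
        shift = (pbar - x0 @ w) / (w @ w)
        x0 = np.clip(x0 + shift * w, 0.0, 1.0)
        res = minimize(neg_fst, x0, method="SLSQP", bounds=[(0.0, 1.0)] * k,
                       constraints=[cons])
        if res.success and -res.fun > best:
            best = -res.fun
    return float(min(1.0, best))


def max_parametric_fst(maf, k: int = 2, weights=None) -> float | np.ndarray:
    """Maximum parametric FST attainable at pooled minor allele frequency ``maf``.

    Parameters
    ----------
    maf
        Pooled minor allele frequency, in (0, 0.5]; may be an array for
        equal weights.
    k
        Number of demes (>= 2).
    weights
        Optional deme weights; equal weights (the closed form) by default.

    Returns
    -------
    The bound in (0, 1]; 1 exactly when ``k * (1 - maf)`` admits a
    decomposition into fixed demes.
    """
    if k < 2:
        raise ValueError("need at least 2 demes")
    maf_arr = np.atleast_1d(np.asarray(maf, dtype=float))
    if np.any((maf_arr <= 0) | (maf_arr > 0.5)):
        raise ValueError("maf must lie in (0, 0.5]")
    if weights is not None:
        if np.ndim(maf) != 0:
            raise ValueError("array maf only supported with equal weights")
        if len(weights) != k:
            raise ValueError("weights length must equal k")
        return _max_fst_weighted(float(maf), np.asarray(weights))
    out = np.array([_max_fst_equal_weights(m, k) for m in maf_arr])
    return float(out[0]) if np.ndim(maf) == 0 else out


def maf_fst_envelope(
    snp_table: pd.DataFrame,
    k: int,
    bin_width: float = 0.01,
    maf_col: str = "global_maf",
    fst_col: str = "fst",
) -> pd.DataFrame:
    """Observed maximum FST per MAF bin against the analytic bound.

    Estimator noise can push sample FST above the parametric bound; such
    exceedances are counted and reported as diagnostics, never clipped.
    """
    if len(snp_table) == 0:
        raise ValueError("empty SNP table")
    maf = snp_table[maf_col].to_numpy(dtype=float)
    fst = snp_table[fst_col].to_numpy(dtype=float)
    ok = np.isfinite(maf) & np.isfinite(fst) & (maf > 0)
    maf, fst = maf[ok], fst[ok]
    edges = np.arange(0.0, 0.5 + bin_width / 2, bin_width)
    idx = np.clip(np.searchsorted(edges, maf, side="right") - 1,
                  0, len(edges) - 2)
    rows = []
    for b in np.unique(idx):
        sel = idx == b
        mid = (edges[b] + edges[b + 1]) / 2
        bound = max_parametric_fst(min(mid, 0.5), k)
        rows.append(
            {
                "maf_lo": edges[b],
                "maf_hi": edges[b + 1],
                "n_snps": int(sel.sum()),
                "max_fst": float(fst[sel].max()),
                "bound": bound,
                "n_exceed": int((fst[sel] > bound + 1e-12).sum()),
            }
        )
    return pd.DataFrame(rows)
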