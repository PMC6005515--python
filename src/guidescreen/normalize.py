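"""Count normalization: trimmed mean of M-values (TMM) and log2-CPM."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .counts import CountMatrix


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    logratio_trim: float,
    abs_trim: float,
) -> float:
    """Weighted trimmed mean of M-values of one sample against the reference.

    Guides with a zero in either sample are excluded pairwise. M-values
    are doubly trimmed — the most extreme ``logratio_trim`` fraction on
    each side by log-ratio and ``abs_trim`` by absolute expression — and
    the surviving M-values are averaged with inverse (delta-method)
    variance weights. Returns the log2 scaling factor.
    """
    keep = (obs > 0) & (ref > 0)
    obs, ref = obs[keep].astype(float), ref[keep].astype(float)
    if obs.size == 0:
        return 0.0
    p_obs, p_ref = obs / n_obs, ref / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)

    # degenerate: samples are scalar multiples of each other
    if np.max(np.abs(m)) < 1e-6:
        return 0.0

    n = m.size
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * abs_trim) + 1
    hi_a = n + 1 - lo_a
    rm, ra = rankdata(m), rankdata(a)
    keep2 = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep2.any() or not np.isfinite(v[keep2]).all():
        return 0.0
    w = 1.0 / v[keep2]
    return float(np.sum(m[keep2] * w) / np.sum(w))


def tmm_factors(
    counts: CountMatrix | pd.DataFrame,
    logratio_trim: float = 0.30,
    abs_trim: float = 0.05,
) -> pd.Series:
    """Per-sample TMM normalization factors, geometric mean 1.

    The reference sample is the one whose 75th-percentile count fraction
    is closest to the mean 75th percentile across samples. A factor
    below 1 means the sample's counts are inflated by a few dominant
    guides and are scaled down relative to sequencing depth.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    lib = mat.sum(axis=0).astype(float)
    if (lib <= 0).any():
        bad = lib.index[lib <= 0][0]
        raise ValueError(f"sample '{bad}' has all-zero counts")

    frac75 = mat.quantile(0.75, axis=0) / lib
    ref_name = (frac75 - frac75.mean()).abs().idxmin()
    ref = mat[ref_name].to_numpy()
    n_ref = lib[ref_name]

    logf = pd.Series(
        {
            s: _tmm_pair(
                mat[s].to_numpy(), ref, lib[s], n_ref, logratio_trim, abs_trim
            )
            for s in mat.columns
        }
    )
    factors = np.exp2(logf)
    factors /= np.exp(np.log(factors).mean())  # geometric mean 1
    return factors


def log_cpm(
    counts: CountMatrix | pd.DataFrame,
    factors: pd.Series | None = None,
    prior_count: float = 0.5,
) -> pd.DataFrame:
    """log2 counts-per-million with effective (TMM-scaled) library sizes.

    value = log2((count + prior) / (factor * libsize + 2 * prior) * 1e6)
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    lib = mat.sum(axis=0).astype(float)
    if factors is None:
        factors = pd.Series(1.0, index=mat.columns)
    eff = lib * factors.loc[mat.columns]
    return np.log2(
        (mat + prior_count).div(eff + 2 * prior_count, axis=1) * 1e6
    )
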