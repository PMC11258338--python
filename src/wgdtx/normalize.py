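"""Between-sample normalization of raw count libraries.

Count matrices are plain pandas DataFrames (genes x samples, non-negative
integers); library sizes are column sums.  `tmm_factors` implements the
trimmed mean of M-values (TMM) scaling procedure; `log_cpm` turns raw counts
plus factors into log2 counts-per-million with a 0.5 prior count.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = ["drop_unexpressed", "choose_reference", "tmm_factors", "log_cpm"]


def drop_unexpressed(counts: pd.DataFrame) -> pd.DataFrame:
    """Drop genes with zero counts in every sample.

    The post-filter gene set is the universe used downstream.
    """
    return counts.loc[counts.sum(axis=1) > 0]


def choose_reference(counts: pd.DataFrame) -> str:
    """Default TMM reference: sample whose upper-quartile of scaled counts
    is closest to the mean upper-quartile across samples."""
    scaled = counts / counts.sum(axis=0)
    f75 = scaled.quantile(0.75, axis=0)
    return (f75 - f75.mean()).abs().idxmin()


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    *,
    logratio_trim: float = 0.30,
    sum_trim: float = 0.05,
) -> float:
    """TMM factor of one library against the reference.

    M-values (log2 expression ratios) are trimmed two-sided by
    ``logratio_trim`` per tail, A-values (average log2 abundances) by
    ``sum_trim`` per tail; the factor is 2 to the inverse-asymptotic-variance
    weighted mean of the surviving M-values.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        p_obs = obs / lib_obs
        p_ref = ref / lib_ref
        m = np.log2(p_obs / p_ref)
        a = 0.5 * np.log2(p_obs * p_ref)
    # binomial asymptotic variance of M
    with np.errstate(divide="ignore"):
        w = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    fin = np.isfinite(m) & np.isfinite(a)
    m, a, w = m[fin], a[fin], w[fin]
    if m.size == 0:
        raise ValueError("no genes expressed in both the sample and the reference")
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * sum_trim) + 1
    hi_a = n + 1 - lo_a
    rm = rankdata(m)
    ra = rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    return float(2.0**f)


def tmm_factors(counts: pd.DataFrame, ref: str | None = None) -> pd.Series:
    """Per-sample TMM normalization factors, rescaled to geometric mean 1.

    Parameters
    ----------
    counts : DataFrame, genes x samples
        Raw non-negative counts; at least two samples.
    ref : sample name, optional
        Reference library; defaults to :func:`choose_reference`.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        bad = lib.index[lib <= 0].tolist()
        raise ValueError(f"zero library size for samples: {bad}")
    if ref is None:
        ref = choose_reference(counts)
    ref_col = counts[ref].to_numpy(dtype=float)
    factors = {}
    for sample in counts.columns:
        try:
            factors[sample] = _tmm_pair(
                counts[sample].to_numpy(dtype=float),
                ref_col,
                float(lib[sample]),
                float(lib[ref]),
            )
        except ValueError as exc:
            raise ValueError(f"sample {sample!r}: {exc}") from None
    f = pd.Series(factors, name="tmm_factor")
    f /= np.exp(np.log(f).mean())  # geometric mean 1
    return f


def log_cpm(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    """log2 counts-per-million on TMM-effective library sizes.

    value = log2((count + 0.5) / (lib_size * factor + 1) * 1e6); finite for
    every non-negative count.
    """
    lib = counts.sum(axis=0).astype(float)
    if factors is None:
        factors = pd.Series(1.0, index=counts.columns)
    eff = lib * factors.reindex(counts.columns)
    return np.log2((counts + 0.5).div(eff + 1.0, axis=1) * 1e6)
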