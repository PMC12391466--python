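"""Median-of-ratios size factors.

The estimator shared by the spike-in ChIP stage (over spike-in peaks
within one replicate batch) and RNA-seq normalization (over all genes):
each sample's factor is the median, over features whose counts are
positive in every sample, of that sample's count divided by the
feature's geometric mean across samples. Even-length medians are the
arithmetic mean of the two central values (numpy convention).
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def size_factors_median_of_ratios(counts: pd.DataFrame) -> pd.Series:
    """Per-sample size factors from a features × samples count matrix.

    Rows containing any zero are dropped before forming ratios. Raises
    if no all-positive row remains (for spike-in use: add more spike-in
    peaks or depth).
    """
    mat = np.asarray(counts, dtype=float)
    if mat.ndim != 2 or mat.shape[1] < 1:
        raise ValueError("counts must be a 2-D features x samples matrix")
    keep = (mat > 0).all(axis=1)
    if not keep.any():
        raise ValueError(
            "no feature has positive counts in every sample; size factors are "
            "undefined (for spike-in scaling, provide more spike-in peaks)"
        )
    sub = mat[keep]
    log_geomean = np.log(sub).mean(axis=1)
    ratios = sub / np.exp(log_geomean)[:, None]
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def apply_size_factors(counts: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    """Divide each sample column by its size factor."""
    missing = [c for c in counts.columns if c not in factors.index]
    if missing:
        raise ValueError(f"no size factor for sample(s): {missing}")
    if (factors.loc[counts.columns] <= 0).any():
        raise ValueError("size factors must be strictly positive")
    return counts / factors.loc[counts.columns]
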