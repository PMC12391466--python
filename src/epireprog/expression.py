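"""Simplified negative-binomial Wald differential expression.

Counts are normalized by median-of-ratios size factors over all genes.
Each gene's variance is modeled as var = μ + α μ² (NB parameterization);
the dispersion α is estimated by method of moments from the pooled
within-arm variances and, by default, shared across genes as the median
of the per-gene moment estimates — with only a few replicates per arm
the gene-wise estimate is far too noisy to plug into a Wald statistic,
while the common estimate keeps the test calibrated when dispersions
are comparable across genes. The Wald statistic for the log2 fold
change uses the delta-method standard error

    SE = (1 / ln 2) * sqrt(1/(n1 μ1) + α/n1 + 1/(n2 μ2) + α/n2)

with p-values from the standard normal and BH FDR across genes. This is
an intentionally simplified model (no shrinkage, no trended dispersion);
its guarantees are calibration-based, not identity with heavier
workflows.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffchip import bh_adjust
from .normalization import apply_size_factors, size_factors_median_of_ratios

_LN2 = np.log(2.0)
_ALPHA_FLOOR = 1e-8


def normalize_counts(counts: pd.DataFrame) -> tuple:
    """Median-of-ratios normalization over all genes.

    Returns ``(normalized, size_factors)``.
    """
    factors = size_factors_median_of_ratios(counts)
    return apply_size_factors(counts, factors), factors


def _moment_dispersion(y1: np.ndarray, y2: np.ndarray) -> np.ndarray:
    """Per-gene method-of-moments dispersion from pooled within-arm
    variance: alpha = (var_w - mu) / mu^2, floored."""
    n1, n2 = y1.shape[1], y2.shape[1]
    var_w = ((n1 - 1) * y1.var(axis=1, ddof=1) + (n2 - 1) * y2.var(axis=1, ddof=1)) / (
        n1 + n2 - 2
    )
    mu = np.concatenate([y1, y2], axis=1).mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (var_w - mu) / mu**2
    return np.where(np.isfinite(alpha), np.maximum(alpha, _ALPHA_FLOOR), _ALPHA_FLOOR)


def nb_wald_test(
    counts: pd.DataFrame,
    arm1_samples: Sequence[str],
    arm2_samples: Sequence[str],
    pseudocount: float = 1.0,
    dispersion: str = "common",
) -> pd.DataFrame:
    """Wald test of arm2 vs arm1 on a genes × samples count matrix.

    ``dispersion="common"`` (default) shares the median moment estimate
    across genes; ``"per-gene"`` uses each gene's own estimate (noisy at
    typical replicate numbers, provided for diagnostics). Genes with
    zero mean in both arms are reported untested (NaN statistics).
    """
    if len(arm1_samples) < 2 or len(arm2_samples) < 2:
        raise ValueError("need >= 2 replicates per arm")
    normalized, factors = normalize_counts(counts[list(arm1_samples) + list(arm2_samples)])
    y1 = normalized[list(arm1_samples)].values
    y2 = normalized[list(arm2_samples)].values
    n1, n2 = y1.shape[1], y2.shape[1]
    mu1, mu2 = y1.mean(axis=1), y2.mean(axis=1)

    alpha_gene = _moment_dispersion(y1, y2)
    if dispersion == "common":
        # mean over expressed genes: the median of per-gene moment
        # estimates is biased low at few replicates
        expressed = (mu1 + mu2) > 0
        alpha = np.full(len(alpha_gene), float(np.mean(alpha_gene[expressed])))
    elif dispersion == "per-gene":
        alpha = alpha_gene
    else:
        raise ValueError(f"unknown dispersion mode {dispersion!r}")

    log2fc = np.log2((mu2 + pseudocount) / (mu1 + pseudocount))
    tested = (mu1 > 0) & (mu2 > 0)
    se = np.full(len(mu1), np.nan)
    se[tested] = (1.0 / _LN2) * np.sqrt(
        1.0 / (n1 * mu1[tested])
        + alpha[tested] / n1
        + 1.0 / (n2 * mu2[tested])
        + alpha[tested] / n2
    )
    w = np.full(len(mu1), np.nan)
    p = np.full(len(mu1), np.nan)
    w[tested] = log2fc[tested] / se[tested]
    p[tested] = 2.0 * stats.norm.sf(np.abs(w[tested]))
    q = np.full(len(mu1), np.nan)
    if tested.any():
        q[tested] = bh_adjust(p[tested])

    out = pd.DataFrame(
        {
            "mu1": mu1,
            "mu2": mu2,
            "dispersion": alpha,
            "log2fc": log2fc,
            "wald": w,
            "p": p,
            "q": q,
            "tested": tested,
        },
        index=counts.index,
    )
    return out


def de_classify(
    result: pd.DataFrame,
    p_threshold: float = 0.05,
    lfc_threshold: float = 0.5,
    use_adjusted: bool = True,
) -> pd.Series:
    """up / down / none per gene at p (or q) and |log2 FC| thresholds."""
    pcol = result["q"] if use_adjusted else result["p"]
    status = pd.Series("none", index=result.index, dtype=object)
    sig = (pcol < p_threshold) & result["tested"]
    status[sig & (result["log2fc"] > lfc_threshold)] = "up"
    status[sig & (result["log2fc"] < -lfc_threshold)] = "down"
    return status


def differential_expression(
    counts: pd.DataFrame,
    arm1_samples: Sequence[str],
    arm2_samples: Sequence[str],
    p_threshold: float = 0.05,
    lfc_threshold: float = 0.5,
    use_adjusted: bool = True,
) -> pd.DataFrame:
    """NB Wald test + classification in one step (arm2 vs arm1)."""
    out = nb_wald_test(counts, arm1_samples, arm2_samples)
    out["status"] = de_classify(out, p_threshold, lfc_threshold, use_adjusted)
    return out
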