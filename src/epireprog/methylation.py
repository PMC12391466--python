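"""Region-level β aggregation and per-probe differential methylation.

Array β values (methylated fraction per CpG probe, in [0, 1]) are
compared between sample groups probe-by-probe with a Welch
unequal-variance t-test (Satterthwaite degrees of freedom) directly on
the β scale, followed by Benjamini-Hochberg FDR. A probe is called
hypo-/hypermethylated when both the q-value and the effect size |Δβ|
clear their thresholds. This is a transparent, formula-level stand-in
for the limma-moderated array pipelines commonly used on such data;
see docs/methods.md for what the substitution does and does not affect.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import GenomicInterval
from .diffchip import bh_adjust


@dataclass
class BetaMatrix:
    """Probes × samples β values with probe coordinates and sample groups.

    probes
        DataFrame indexed by probe_id with columns chrom, pos (0-based
        base position; the probe occupies [pos, pos+1)).
    beta
        DataFrame (same index) of β in [0, 1].
    groups
        sample_id -> group/treatment label.
    """

    probes: pd.DataFrame
    beta: pd.DataFrame
    groups: Dict[str, str]

    def __post_init__(self) -> None:
        if not self.probes.index.equals(self.beta.index):
            raise ValueError("probes and beta must share an index")
        if self.probes.index.duplicated().any():
            raise ValueError("probe ids must be unique")
        vals = np.asarray(self.beta, dtype=float)
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError("beta values must lie in [0, 1]")
        missing = set(self.beta.columns) - set(self.groups)
        if missing:
            raise ValueError(f"samples without a group label: {sorted(missing)}")
        pos_key = self.probes["chrom"].astype(str) + ":" + self.probes["pos"].astype(str)
        if pos_key.duplicated().any():
            raise ValueError("probe positions must be unique")

    def samples_in(self, group: str) -> List[str]:
        return [s for s in self.beta.columns if self.groups[s] == group]

    def probe_intervals(self) -> List[GenomicInterval]:
        return [
            GenomicInterval(r.chrom, int(r.pos), int(r.pos) + 1)
            for r in self.probes.itertuples()
        ]


def harmonize_probes(a: BetaMatrix, b: BetaMatrix) -> tuple:
    """Restrict two arrays to their shared probe ids (e.g. 450k ∩ EPIC)."""
    shared = a.probes.index.intersection(b.probes.index)
    return (
        BetaMatrix(a.probes.loc[shared], a.beta.loc[shared], a.groups),
        BetaMatrix(b.probes.loc[shared], b.beta.loc[shared], b.groups),
    )


def region_mean_beta(
    betas: BetaMatrix, regions: Sequence[GenomicInterval], group: Optional[str] = None
) -> pd.Series:
    """Mean β over (probes within region × samples in group) per region.

    Regions containing no probe are NaN (reported missing, not 0).
    """
    cols = betas.samples_in(group) if group is not None else list(betas.beta.columns)
    chroms = betas.probes["chrom"].values
    pos = betas.probes["pos"].values.astype(int)
    vals = betas.beta[cols].values
    out = np.full(len(regions), np.nan)
    for i, region in enumerate(regions):
        mask = (chroms == region.chrom) & (pos >= region.start) & (pos < region.end)
        if mask.any():
            out[i] = float(vals[mask].mean())
    return pd.Series(out, name="mean_beta")


def welch_t(a: np.ndarray, b: np.ndarray) -> tuple:
    """Row-wise Welch t-test (b vs a): returns (delta, t, df, p).

    Zero variance in both groups: p = 1 when the means agree, else p = 0
    (degenerate, t = ±inf).
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    n1, n2 = a.shape[1], b.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 samples per group")
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    v1 = a.var(axis=1, ddof=1) / n1
    v2 = b.var(axis=1, ddof=1) / n2
    delta = m2 - m1
    se2 = v1 + v2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = delta / np.sqrt(se2)
        df = se2**2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = np.empty_like(delta)
    ok = se2 > 0
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df[ok])
    zero = ~ok
    t[zero & (delta == 0)] = 0.0
    p[zero & (delta == 0)] = 1.0
    deg = zero & (delta != 0)
    t[deg] = np.sign(delta[deg]) * np.inf
    p[deg] = 0.0
    df[zero] = np.nan
    return delta, t, df, p


def diff_meth_welch(betas: BetaMatrix, group1: str, group2: str) -> pd.DataFrame:
    """Per-probe differential methylation, group2 vs group1.

    Returns a table with Δβ (group2 − group1), Welch t, Satterthwaite
    df, two-sided p, BH q, plus probe coordinates.
    """
    c1, c2 = betas.samples_in(group1), betas.samples_in(group2)
    if len(c1) < 2 or len(c2) < 2:
        raise ValueError("need >= 2 samples per group")
    delta, t, df, p = welch_t(betas.beta[c1].values, betas.beta[c2].values)
    out = betas.probes[["chrom", "pos"]].copy()
    out["delta_beta"] = delta
    out["t"] = t
    out["df"] = df
    out["p"] = p
    out["q"] = bh_adjust(p)
    return out


def classify_probe_changes(
    result: pd.DataFrame,
    fdr_threshold: float = 0.05,
    delta_beta_threshold: float = 0.1,
) -> pd.Series:
    """hypo / hyper / none per probe: requires both q below the FDR
    threshold and |Δβ| beyond the effect threshold."""
    call = pd.Series("none", index=result.index, dtype=object)
    sig = result["q"] < fdr_threshold
    call[sig & (result["delta_beta"] < -delta_beta_threshold)] = "hypo"
    call[sig & (result["delta_beta"] > delta_beta_threshold)] = "hyper"
    return call


def differential_methylation(
    betas: BetaMatrix,
    group1: str,
    group2: str,
    fdr_threshold: float = 0.05,
    delta_beta_threshold: float = 0.1,
) -> pd.DataFrame:
    """Welch test + BH + calls in one step (group2 vs group1)."""
    out = diff_meth_welch(betas, group1, group2)
    out["call"] = classify_probe_changes(out, fdr_threshold, delta_beta_threshold)
    return out
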