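"""Spike-in-anchored differential ChIP enrichment.

A constant amount of foreign-species (spike-in) chromatin added to every
sample anchors cross-sample scaling: because the spike-in signal is
biologically invariant, per-sample size factors estimated from spike-in
peaks alone calibrate out both depth differences and genome-wide shifts
of the target mark. The workflow per mark and contrast is:

1. within each replicate batch, median-of-ratios size factors from the
   spike-in peak counts only;
2. divide all peak counts by those factors;
3. per batch, log2 fold change of treatment vs vehicle arm means (with a
   pseudocount);
4. one-sample two-sided t-test across the batch fold changes against a
   zero mean, Benjamini-Hochberg FDR over peaks;
5. direction calls (gain/loss/none) at a q-value threshold.

Peaks whose pooled normalized mean is below a minimum count are excluded
from testing to avoid unstable fold changes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import GenomicInterval, SampleSheet
from .normalization import apply_size_factors, size_factors_median_of_ratios

SPECIES_TARGET = "target"
SPECIES_SPIKEIN = "spikein"


@dataclass
class PeakCountMatrix:
    """Consensus peaks × samples counts with species/batch/treatment metadata.

    peaks
        DataFrame indexed by peak id with columns chrom/start/end/strand/
        species (``target`` or ``spikein``).
    counts
        DataFrame (same index) of non-negative counts, one column per
        sample.
    samples
        SampleSheet restricted to the count columns.
    """

    peaks: pd.DataFrame
    counts: pd.DataFrame
    samples: SampleSheet

    def __post_init__(self) -> None:
        if not self.peaks.index.equals(self.counts.index):
            raise ValueError("peaks and counts must share an index")
        sheet_ids = set(self.samples.sample_ids)
        if sheet_ids != set(self.counts.columns):
            raise ValueError("sample sheet does not match count columns")
        if (np.asarray(self.counts) < 0).any():
            raise ValueError("counts must be non-negative")
        bad = set(self.peaks["species"]) - {SPECIES_TARGET, SPECIES_SPIKEIN}
        if bad:
            raise ValueError(f"unknown species tags: {sorted(bad)}")

    @property
    def spikein_counts(self) -> pd.DataFrame:
        return self.counts.loc[self.peaks["species"] == SPECIES_SPIKEIN]

    @property
    def target_counts(self) -> pd.DataFrame:
        return self.counts.loc[self.peaks["species"] == SPECIES_TARGET]

    def target_intervals(self) -> List[GenomicInterval]:
        sub = self.peaks[self.peaks["species"] == SPECIES_TARGET]
        return [
            GenomicInterval(r.chrom, int(r.start), int(r.end), getattr(r, "strand", "."))
            for r in sub.itertuples()
        ]

    def subset_samples(self, **criteria) -> "PeakCountMatrix":
        sheet = self.samples.subset(**criteria)
        return PeakCountMatrix(self.peaks, self.counts[sheet.sample_ids], sheet)


def spikein_size_factors(pcm: PeakCountMatrix) -> pd.Series:
    """Per-sample size factors estimated within each replicate batch,
    from spike-in peak counts only."""
    spike = pcm.spikein_counts
    factors = {}
    batches = sorted({r["batch"] for r in pcm.samples})
    for batch in batches:
        ids = pcm.samples.subset(batch=batch).sample_ids
        f = size_factors_median_of_ratios(spike[ids])
        factors.update(f.to_dict())
    return pd.Series(factors, name="size_factor").loc[pcm.counts.columns]


def normalize_by_spikein(pcm: PeakCountMatrix) -> PeakCountMatrix:
    factors = spikein_size_factors(pcm)
    return PeakCountMatrix(pcm.peaks, apply_size_factors(pcm.counts, factors), pcm.samples)


def per_batch_log2fc(
    pcm: PeakCountMatrix,
    treatment: str,
    vehicle: str = "vehicle",
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Peak × batch log2 fold changes of treatment vs vehicle arm means.

    Replicates within an arm/batch are averaged before the ratio;
    ``pseudocount`` (in normalized-count units) stabilizes low counts.
    """
    batches = sorted({r["batch"] for r in pcm.samples})
    out = {}
    for batch in batches:
        t_ids = pcm.samples.subset(batch=batch, treatment=treatment).sample_ids
        v_ids = pcm.samples.subset(batch=batch, treatment=vehicle).sample_ids
        if not t_ids or not v_ids:
            raise ValueError(
                f"batch {batch!r} lacks a {treatment!r} or {vehicle!r} arm"
            )
        mean_t = pcm.counts[t_ids].mean(axis=1)
        mean_v = pcm.counts[v_ids].mean(axis=1)
        out[batch] = np.log2((mean_t + pseudocount) / (mean_v + pseudocount))
    return pd.DataFrame(out, index=pcm.counts.index)


def one_sample_t(values: Sequence[float]) -> tuple:
    """Two-sided one-sample t-test of a fold-change vector against 0.

    Returns ``(t, df, p)``. Degenerate zero-variance vectors: t = 0 and
    p = 1 when the mean is also zero, else p = 0 (flagged by t = ±inf).
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    n = x.size
    if n < 2:
        raise ValueError("need >= 2 finite fold changes")
    mean = x.mean()
    sd = x.std(ddof=1)
    df = n - 1
    if sd == 0.0:
        if mean == 0.0:
            return 0.0, df, 1.0
        return float(np.sign(mean)) * np.inf, df, 0.0
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), df, float(p)


def _one_sample_t_rows(fc: np.ndarray) -> tuple:
    """Vectorized row-wise one-sample t against zero (no NaNs)."""
    n = fc.shape[1]
    mean = fc.mean(axis=1)
    sd = fc.std(axis=1, ddof=1)
    t = np.full(fc.shape[0], 0.0)
    p = np.ones(fc.shape[0])
    ok = sd > 0
    t[ok] = mean[ok] / (sd[ok] / np.sqrt(n))
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), n - 1)
    deg = (~ok) & (mean != 0)
    t[deg] = np.sign(mean[deg]) * np.inf
    p[deg] = 0.0
    return t, p


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_differential_regions(result: pd.DataFrame, fdr_threshold: float = 0.05) -> pd.Series:
    """gain / loss / none per peak from q-values and mean fold change."""
    call = pd.Series("none", index=result.index, dtype=object)
    sig = result["q"] < fdr_threshold
    call[sig & (result["mean_log2fc"] > 0)] = "gain"
    call[sig & (result["mean_log2fc"] < 0)] = "loss"
    return call


def differential_enrichment(
    pcm: PeakCountMatrix,
    treatment: str,
    vehicle: str = "vehicle",
    pseudocount: float = 1.0,
    min_mean_count: float = 5.0,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Full spike-in differential-enrichment stage for one contrast.

    Returns a per-target-peak table: chrom/start/end, per-batch and mean
    log2 FC, t, df, p, q and the direction call. Peaks failing the
    minimum normalized mean count across the two arms are reported with
    ``tested = False`` and no call.
    """
    keep_treat = [
        r["sample_id"] for r in pcm.samples if r["treatment"] in (treatment, vehicle)
    ]
    sheet = SampleSheet([r for r in pcm.samples if r["sample_id"] in set(keep_treat)])
    sub = PeakCountMatrix(pcm.peaks, pcm.counts[sheet.sample_ids], sheet)
    norm = normalize_by_spikein(sub)

    fc = per_batch_log2fc(norm, treatment, vehicle, pseudocount)
    targets = norm.peaks["species"] == SPECIES_TARGET
    fc = fc.loc[targets]
    mean_count = norm.counts.loc[targets].mean(axis=1)
    tested = mean_count >= min_mean_count

    n_batches = fc.shape[1]
    t = np.full(len(fc), np.nan)
    p = np.full(len(fc), np.nan)
    t[tested.values], p[tested.values] = _one_sample_t_rows(fc.values[tested.values])
    q = np.full(len(fc), np.nan)
    if tested.any():
        q[tested.values] = bh_adjust(p[tested.values])

    out = norm.peaks.loc[targets, ["chrom", "start", "end"]].copy()
    for b in fc.columns:
        out[f"log2fc_{b}"] = fc[b]
    out["mean_log2fc"] = fc.mean(axis=1)
    out["mean_count"] = mean_count
    out["tested"] = tested
    out["t"] = t
    out["df"] = n_batches - 1
    out["p"] = p
    out["q"] = q
    out["call"] = "none"
    sub_res = out.loc[tested, ["q", "mean_log2fc"]]
    out.loc[tested, "call"] = call_differential_regions(sub_res, fdr_threshold)
    return out
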