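"""Chromatin-state segmentation support: binning, track binarization,
state labeling, annotation enrichment and metaprofiles.

Genomes are tiled into fixed-width bins (default 200 bp). Each mark is
binarized per bin either from called peaks (any-overlap) or from per-bin
read counts via an upper-tail Poisson threshold against the genome-wide
mean. The binarized matrix feeds :func:`epireprog.hmm.learn_hmm`; fitted
states are labeled into functional families by deterministic rules on
their emission probabilities, codifying the conventional manual
assignment (promoter = H3K4me3-high, Polycomb = H3K27me3-only, etc.).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import GenomicInterval


@dataclass
class BinGrid:
    """Fixed-width bins exhaustively tiling each chromosome.

    Bins are ordered by the given chromosome order then position; the
    terminal bin of a chromosome may be narrower than ``bin_size``.
    """

    chrom_sizes: Dict[str, int]
    bin_size: int = 200

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        for chrom, size in self.chrom_sizes.items():
            if size <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive size")
        self._chroms = list(self.chrom_sizes)
        self._n_bins = {
            c: -(-self.chrom_sizes[c] // self.bin_size) for c in self._chroms
        }
        offsets = np.cumsum([0] + [self._n_bins[c] for c in self._chroms])
        self._offset = dict(zip(self._chroms, offsets[:-1]))
        self.n_bins = int(offsets[-1])

    def bin_index(self, chrom: str, pos: int) -> int:
        """Global index of the bin containing base ``pos``."""
        self._check(chrom)
        if not 0 <= pos < self.chrom_sizes[chrom]:
            raise ValueError(f"position {pos} outside {chrom}")
        return self._offset[chrom] + pos // self.bin_size

    def bin_interval(self, index: int) -> GenomicInterval:
        for chrom in self._chroms:
            off, n = self._offset[chrom], self._n_bins[chrom]
            if off <= index < off + n:
                start = (index - off) * self.bin_size
                end = min(start + self.bin_size, self.chrom_sizes[chrom])
                return GenomicInterval(chrom, start, end)
        raise IndexError(index)

    def bin_range(self, iv: GenomicInterval) -> range:
        """Global indices of all bins overlapping ``iv`` (>= 1 bp)."""
        self._check(iv.chrom)
        size = self.chrom_sizes[iv.chrom]
        start = max(iv.start, 0)
        end = min(iv.end, size)
        if start >= size or end <= 0 or end <= start:
            return range(0)
        off = self._offset[iv.chrom]
        return range(off + start // self.bin_size, off + (end - 1) // self.bin_size + 1)

    def _check(self, chrom: str) -> None:
        if chrom not in self.chrom_sizes:
            raise ValueError(
                f"unknown chromosome {chrom!r}; grid covers {self._chroms}"
            )

    def intervals(self) -> List[GenomicInterval]:
        return [self.bin_interval(i) for i in range(self.n_bins)]


def make_bins(chrom_sizes: Dict[str, int], bin_size: int = 200) -> BinGrid:
    return BinGrid(dict(chrom_sizes), bin_size)


def binarize_peaks(
    grid: BinGrid, peaks_by_mark: Dict[str, Sequence[GenomicInterval]]
) -> pd.DataFrame:
    """Binary bins × marks matrix: 1 iff the bin overlaps >= 1 bp of any
    peak of that mark."""
    marks = list(peaks_by_mark)
    x = np.zeros((grid.n_bins, len(marks)), dtype=np.int8)
    for m, mark in enumerate(marks):
        for peak in peaks_by_mark[mark]:
            rng = grid.bin_range(peak)
            x[rng.start : rng.stop, m] = 1
    return pd.DataFrame(x, columns=marks)


def poisson_threshold_count(lam: float, pvalue_threshold: float = 1e-4) -> int:
    """Smallest count whose upper-tail Poisson probability
    P(X >= count | lam) falls at or below the threshold."""
    if lam <= 0:
        raise ValueError("lam must be positive")
    # sf(k-1) = P(X >= k); ppf-based start then walk to be exact
    k = int(stats.poisson.ppf(1 - pvalue_threshold, lam))
    while stats.poisson.sf(k - 1, lam) > pvalue_threshold:
        k += 1
    while k > 1 and stats.poisson.sf(k - 2, lam) <= pvalue_threshold:
        k -= 1
    return k


def binarize_counts_poisson(
    grid: BinGrid,
    counts_by_mark: Dict[str, np.ndarray],
    pvalue_threshold: float = 1e-4,
) -> pd.DataFrame:
    """Binarize per-bin counts: 1 iff P(X >= count) <= threshold under a
    Poisson with the mark's genome-wide mean rate.

    A mark with zero mean yields an all-zero column (with a warning via
    ``warnings``).
    """
    import warnings

    marks = list(counts_by_mark)
    x = np.zeros((grid.n_bins, len(marks)), dtype=np.int8)
    for m, mark in enumerate(marks):
        counts = np.asarray(counts_by_mark[mark])
        if counts.shape[0] != grid.n_bins:
            raise ValueError(f"mark {mark!r}: counts do not match grid bins")
        if (counts < 0).any():
            raise ValueError(f"mark {mark!r}: counts must be non-negative")
        lam = counts.mean()
        if lam == 0:
            warnings.warn(f"mark {mark!r} has zero mean; all-zero column")
            continue
        threshold = poisson_threshold_count(lam, pvalue_threshold)
        x[:, m] = (counts >= threshold).astype(np.int8)
    return pd.DataFrame(x, columns=marks)


# ---------------------------------------------------------------------------
# state labeling

FAMILIES_PRIMARY = (
    "TSS/promoter",
    "poised TSS",
    "enhancer",
    "transcribed",
    "Polycomb",
    "heterochromatin",
    "undefined",
    "low signal",
)
FAMILIES_CELL_LINE = (
    "Polycomb",
    "active TSS",
    "active enhancer",
    "bivalent TSS/enhancer",
    "low signal",
)

# fine family -> 5-family cell-line class
_CELL_LINE_MAP = {
    "TSS/promoter": "active TSS",
    "poised TSS": "bivalent TSS/enhancer",
    "enhancer": "active enhancer",
    "active enhancer": "active enhancer",
    "transcribed": "active TSS",
    "Polycomb": "Polycomb",
    "heterochromatin": "low signal",
    "undefined": "low signal",
    "low signal": "low signal",
}


def _label_one(e: Dict[str, float], high: float, low: float) -> str:
    def g(mark):
        return e.get(mark, 0.0)

    if all(v < low for v in e.values()):
        return "low signal"
    k4me3_high = g("H3K4me3") >= high
    k27me3_high = g("H3K27me3") >= high
    if k4me3_high and k27me3_high:
        return "poised TSS"
    if k4me3_high:
        return "TSS/promoter"
    if g("H3K4me1") >= high:
        return "active enhancer" if g("H3K27ac") >= high else "enhancer"
    if g("H3K36me3") >= high:
        return "transcribed"
    others = [m for m in e if m not in ("H3K27me3",)]
    if k27me3_high and all(g(m) < high for m in others):
        return "Polycomb"
    others9 = [m for m in e if m != "H3K9me3"]
    if g("H3K9me3") >= high and all(g(m) < high for m in others9):
        return "heterochromatin"
    return "undefined"


def label_states(
    model,
    high: float = 0.5,
    low: float = 0.1,
    mode: str = "primary",
) -> Dict[int, str]:
    """Assign each HMM state a functional family from its emissions.

    Deterministic rules on the Bernoulli emission probabilities
    (``high``/``low`` thresholds are tunable): H3K4me3-high promoters
    (poised when H3K27me3 is also high), H3K4me1 enhancers (active with
    H3K27ac), H3K36me3 transcription, H3K27me3-only Polycomb,
    H3K9me3-only heterochromatin, everything weak = low signal, the rest
    undefined. ``mode="cell_line"`` collapses the families to the
    5-class panel (Polycomb / active TSS / active enhancer / bivalent
    TSS-enhancer / low signal).
    """
    labels = {}
    for k in range(model.n_states):
        e = dict(zip(model.marks, model.emissions[k]))
        fam = _label_one(e, high, low)
        if mode == "cell_line":
            fam = _CELL_LINE_MAP[fam]
        elif mode != "primary":
            raise ValueError(f"unknown labeling mode {mode!r}")
        labels[k] = fam
    model.labels = labels
    return labels


# ---------------------------------------------------------------------------
# segmentation export, enrichment, profiles


def segmentation_to_intervals(
    grid: BinGrid, states: np.ndarray, labels: Optional[Dict[int, str]] = None
) -> pd.DataFrame:
    """Collapse per-bin states to contiguous same-state runs per
    chromosome, as a BED-like table."""
    if len(states) != grid.n_bins:
        raise ValueError("states do not match grid bins")
    rows = []
    prev = None
    for i, s in enumerate(states):
        iv = grid.bin_interval(i)
        if prev is not None and prev["chrom"] == iv.chrom and prev["state"] == s:
            prev["end"] = iv.end
        else:
            if prev is not None:
                rows.append(prev)
            prev = {"chrom": iv.chrom, "start": iv.start, "end": iv.end, "state": int(s)}
    if prev is not None:
        rows.append(prev)
    out = pd.DataFrame(rows)
    if labels is not None:
        out["family"] = out["state"].map(labels)
    return out


def annotation_enrichment(
    grid: BinGrid, states: np.ndarray, annotation: Iterable[GenomicInterval]
) -> pd.Series:
    """Per-state fold enrichment of an annotation.

    fold(k) = (fraction of state-k bins overlapping the annotation) /
    (fraction of all bins overlapping it). States with zero bins, or an
    annotation overlapping zero bins, yield NaN rather than 0.
    """
    hit = np.zeros(grid.n_bins, dtype=bool)
    for iv in annotation:
        rng = grid.bin_range(iv)
        hit[rng.start : rng.stop] = True
    overall = hit.mean()
    out = {}
    for k in sorted(set(int(s) for s in states)):
        mask = states == k
        if overall == 0 or mask.sum() == 0:
            out[k] = np.nan
        else:
            out[k] = float(hit[mask].mean() / overall)
    return pd.Series(out, name="fold_enrichment")


def metaprofile(
    grid: BinGrid,
    signal: np.ndarray,
    regions: Sequence[GenomicInterval],
    flank: int = 2000,
    n_points: int = 41,
) -> pd.DataFrame:
    """Mean ± SD signal profile around region centers.

    Each region's per-bin signal is resampled (linear interpolation on
    bin centers) onto a common axis of ``n_points`` positions spanning
    ±``flank`` bp about its center. Regions whose flank would leave the
    chromosome are dropped; the returned frame's ``.attrs['n_dropped']``
    reports how many.
    """
    if len(regions) == 0:
        raise ValueError("regions must be non-empty")
    signal = np.asarray(signal, dtype=float)
    if signal.shape[0] != grid.n_bins:
        raise ValueError("signal does not match grid bins")
    axis = np.linspace(-flank, flank, n_points)
    rows = []
    dropped = 0
    for region in regions:
        center = region.center
        size = grid.chrom_sizes.get(region.chrom)
        if size is None:
            raise ValueError(f"region on unknown chromosome {region.chrom!r}")
        if center - flank < 0 or center + flank >= size:
            dropped += 1
            continue
        lo = grid.bin_index(region.chrom, center - flank)
        hi = grid.bin_index(region.chrom, min(center + flank, size - 1))
        idx = np.arange(lo, hi + 1)
        centers = np.array(
            [(grid.bin_interval(i).start + grid.bin_interval(i).end) / 2 for i in idx]
        ) - center
        rows.append(np.interp(axis, centers, signal[idx]))
    if not rows:
        raise ValueError("all regions dropped (too close to chromosome edges)")
    mat = np.vstack(rows)
    out = pd.DataFrame(
        {"position": axis, "mean": mat.mean(axis=0), "sd": mat.std(axis=0, ddof=0)}
    )
    out.attrs["n_regions"] = len(rows)
    out.attrs["n_dropped"] = dropped
    return out
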