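"""Shared coordinate data model and run configuration.

All genomic coordinates in this package are 0-based, half-open (BED
convention). Inputs declared 1-based (e.g. methylation array probe
positions) are converted once at ingest; nothing downstream re-parses
coordinates. Chromosome names are taken verbatim — a mismatch between
files is an error, never silently repaired.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Iterable

import yaml

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """A chromosome/strand-aware half-open span [start, end).

    Parameters
    ----------
    chrom : str
        Chromosome name, taken verbatim.
    start : int
        0-based inclusive start (bp), ``>= 0``.
    end : int
        0-based exclusive end (bp), ``> start``.
    strand : str
        One of ``+``, ``-`` or ``.`` (unstranded).
    attrs : tuple
        Optional extra attributes (e.g. narrowPeak summit) as
        ``(key, value)`` pairs, kept hashable.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    attrs: tuple = ()

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {VALID_STRANDS}, got {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def attr(self, key, default=None):
        for k, v in self.attrs:
            if k == key:
                return v
        return default


@dataclass(frozen=True)
class GeneModel:
    """A gene with an oriented interval.

    The TSS is the first transcribed base: ``interval.start`` on the +
    strand, ``interval.end - 1`` on the − strand. ``three_prime_end`` is
    the opposite terminus.
    """

    gene_id: str
    symbol: str
    interval: GenomicInterval

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(
                f"gene {self.gene_id}: strand must be + or -, got "
                f"{self.interval.strand!r} (windows require orientation)"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        if self.strand == "+":
            return self.interval.start
        return self.interval.end - 1

    @property
    def three_prime_end(self) -> int:
        if self.strand == "+":
            return self.interval.end - 1
        return self.interval.start


ASSAYS = ("chip", "meth", "rna")
TREATMENTS = ("vehicle", "unc1999", "aza", "combination")


@dataclass
class SampleSheet:
    """Experiment design: one row per sample.

    Each row carries ``(sample_id, assay, mark, treatment, batch)``.
    ChIP rows must name a histone mark, and within each mark the
    replicate batches must form complete treatment blocks so that
    per-batch fold changes are defined.
    """

    rows: list  # list of dicts with the five keys

    def __post_init__(self) -> None:
        ids = [r["sample_id"] for r in self.rows]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sample_ids: {dupes}")
        for r in self.rows:
            if r["assay"] not in ASSAYS:
                raise ValueError(f"unknown assay {r['assay']!r} for {r['sample_id']}")
            if r["assay"] == "chip" and not r.get("mark"):
                raise ValueError(f"ChIP sample {r['sample_id']} lacks a mark")

    def subset(self, **criteria) -> "SampleSheet":
        rows = [
            r for r in self.rows if all(r.get(k) == v for k, v in criteria.items())
        ]
        return SampleSheet(rows)

    @property
    def sample_ids(self) -> list:
        return [r["sample_id"] for r in self.rows]

    def __iter__(self):
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class RunConfig:
    """Pipeline-wide tunables.

    bin_size
        Chromatin-state bin width in bp.
    window_up / window_down
        Promoter window extent upstream/downstream of the TSS in
        transcription direction (bp); the promoter window is
        ``window_up + window_down`` wide.
    de_p_threshold / de_lfc_threshold
        Differential-expression calling thresholds (p or q, |log2 FC|).
    fdr_threshold
        BH q-value cutoff shared by the ChIP and methylation callers.
    delta_beta_threshold
        Minimum |Δβ| for a methylation call.
    seed
        Root seed for every stochastic step.
    """

    bin_size: int = 200
    window_up: int = 2500
    window_down: int = 1000
    de_p_threshold: float = 0.05
    de_lfc_threshold: float = 0.5
    fdr_threshold: float = 0.05
    delta_beta_threshold: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        for name in (
            "window_up",
            "window_down",
            "de_p_threshold",
            "de_lfc_threshold",
            "fdr_threshold",
            "delta_beta_threshold",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {f.name: getattr(self, f.name) for f in fields(self)}, fh
            )


def check_single_chromosome_set(intervals: Iterable[GenomicInterval], known: set) -> None:
    """Fail loud when interval files mix chromosome naming schemes."""
    seen = {iv.chrom for iv in intervals}
    extra = seen - set(known)
    if extra:
        raise ValueError(
            f"unknown chromosomes {sorted(extra)}; known: {sorted(known)} "
            "(chromosome names are compared verbatim)"
        )
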