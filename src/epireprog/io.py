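"""Readers and writers for the tabular formats the pipeline touches.

BED/narrowPeak intervals, TSV count/β matrices, gene-model tables and a
JSON manifest for result directories. Everything returns or accepts the
shared :class:`~epireprog.core.GenomicInterval` /
:class:`~epireprog.core.GeneModel` data model; no later stage re-parses
files.
"""

from __future__ import annotations

import hashlib
import json
import os
from typing import Dict, List

import pandas as pd

from .core import GeneModel, GenomicInterval, SampleSheet

# narrowPeak columns 7-10; broadPeak lacks the summit column.
_NARROWPEAK_EXTRA = ("signal_value", "p_value", "q_value", "summit")
_BROADPEAK_EXTRA = ("signal_value", "p_value", "q_value")


class ParseError(ValueError):
    """Malformed line in an input file; message names the line number."""


def _parse_bed_line(line: str, lineno: int, fmt: str) -> GenomicInterval:
    parts = line.split("\t") if "\t" in line else line.split()
    min_cols = {"bed": 3, "narrowPeak": 10, "broadPeak": 9}[fmt]
    if len(parts) < min_cols:
        raise ParseError(
            f"line {lineno}: expected >= {min_cols} columns for {fmt}, got {len(parts)}"
        )
    chrom = parts[0]
    try:
        start, end = int(parts[1]), int(parts[2])
    except ValueError as exc:
        raise ParseError(f"line {lineno}: non-integer coordinates") from exc
    strand = "."
    attrs = []
    if len(parts) >= 6 and parts[5] in ("+", "-", "."):
        strand = parts[5]
    if len(parts) >= 4 and parts[3] not in ("", "."):
        attrs.append(("name", parts[3]))
    if len(parts) >= 5:
        attrs.append(("score", parts[4]))
    if fmt == "narrowPeak":
        for key, raw in zip(_NARROWPEAK_EXTRA, parts[6:10]):
            attrs.append((key, int(raw) if key == "summit" else float(raw)))
    elif fmt == "broadPeak":
        for key, raw in zip(_BROADPEAK_EXTRA, parts[6:9]):
            attrs.append((key, float(raw)))
    try:
        return GenomicInterval(chrom, start, end, strand, tuple(attrs))
    except ValueError as exc:
        raise ParseError(f"line {lineno}: {exc}") from exc


def read_intervals(path, format: str = "bed") -> List[GenomicInterval]:
    """Read a BED3/BED6, narrowPeak or broadPeak file, preserving order.

    Coordinates are kept verbatim (0-based half-open). narrowPeak /
    broadPeak extra columns are carried as interval attributes (e.g.
    ``iv.attr("summit")``).
    """
    if format not in ("bed", "narrowPeak", "broadPeak"):
        raise ValueError(f"unknown interval format {format!r}")
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            out.append(_parse_bed_line(line, lineno, format))
    return out


def write_intervals(intervals, path) -> None:
    """Write intervals as BED6 (name/score drawn from attrs when present)."""
    with open(path, "w") as fh:
        for iv in intervals:
            name = iv.attr("name", ".")
            score = iv.attr("score", "0")
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")


def read_matrix(path, kind: str = "counts") -> pd.DataFrame:
    """Read a features × samples TSV matrix.

    ``kind="counts"`` enforces non-negative values; ``kind="beta"``
    enforces values in [0, 1]. Validation errors name the offending
    row/column labels.
    """
    if kind not in ("counts", "beta"):
        raise ValueError(f"unknown matrix kind {kind!r}")
    try:
        mat = pd.read_csv(path, sep="\t", index_col=0)
        mat = mat.astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric cell ({exc})") from exc
    if mat.isna().any().any():
        rows = mat.index[mat.isna().any(axis=1)].tolist()
        raise ParseError(f"{path}: missing/non-numeric values in rows {rows[:5]}")
    if kind == "counts":
        bad = mat < 0
    else:
        bad = (mat < 0) | (mat > 1)
    if bad.any().any():
        i, j = next(zip(*bad.values.nonzero()))
        raise ValueError(
            f"{path}: {kind} value {mat.iat[i, j]} out of range at "
            f"row {mat.index[i]!r}, column {mat.columns[j]!r}"
        )
    return mat


def write_matrix(mat: pd.DataFrame, path) -> None:
    mat.to_csv(path, sep="\t", index_label="feature")


def read_gene_models(path) -> List[GeneModel]:
    """Read a gene-model TSV (chrom, start, end, strand, gene_id, symbol).

    TSS and 3′ end follow from the strand; duplicate gene_ids and
    unstranded rows are rejected.
    """
    tab = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "strand", "gene_id", "symbol"}
    missing = required - set(tab.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    dupes = tab["gene_id"][tab["gene_id"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"{path}: duplicated gene_id(s): {sorted(set(dupes))}")
    genes = []
    for row in tab.itertuples(index=False):
        genes.append(
            GeneModel(
                gene_id=str(row.gene_id),
                symbol=str(row.symbol),
                interval=GenomicInterval(
                    str(row.chrom), int(row.start), int(row.end), str(row.strand)
                ),
            )
        )
    return genes


def write_gene_models(genes, path) -> None:
    pd.DataFrame(
        {
            "chrom": [g.chrom for g in genes],
            "start": [g.interval.start for g in genes],
            "end": [g.interval.end for g in genes],
            "strand": [g.strand for g in genes],
            "gene_id": [g.gene_id for g in genes],
            "symbol": [g.symbol for g in genes],
        }
    ).to_csv(path, sep="\t", index=False)


def read_sample_sheet(path) -> SampleSheet:
    tab = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"sample_id", "assay", "mark", "treatment", "batch"}
    missing = required - set(tab.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return SampleSheet(tab.to_dict("records"))


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    pd.DataFrame(sheet.rows).to_csv(path, sep="\t", index=False)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_results(tables: Dict[str, pd.DataFrame], out_dir, overwrite: bool = False) -> dict:
    """Write one TSV per named table plus a JSON manifest.

    Column order is preserved as given (deterministic); the manifest
    records file name, row count and sha256 so identical inputs yield
    identical checksums.
    """
    os.makedirs(out_dir, exist_ok=True)
    entries = []
    for name in sorted(tables):
        fname = f"{name}.tsv"
        path = os.path.join(out_dir, fname)
        if os.path.exists(path) and not overwrite:
            raise FileExistsError(f"{path} exists; pass overwrite=True")
        tables[name].to_csv(path, sep="\t", index=True)
        entries.append(
            {"table": name, "file": fname, "n_rows": int(len(tables[name])), "sha256": _sha256(path)}
        )
    manifest = {"tables": entries}
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
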