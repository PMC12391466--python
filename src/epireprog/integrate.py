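"""Multi-omic target integration.

The core integrative step: per gene, strand-aware promoter and
gene-body windows collect evidence from the differential ChIP, DNA
methylation and expression stages, yielding boolean flags — lost
H3K27me3, lost DNA methylation, gained H3K4me3, upregulated. The
combination-target "epigenetic map" is the set of genes with any of the
three epigenetic losses/gains; reactivated genes are targets that are
also transcriptionally upregulated; the patient-cohort intersection and
a tumour-suppressor list then narrow these to final candidates.

Windows (transcription direction): promoter = TSS−2.5 kb → TSS+1 kb,
gene body = TSS−2.5 kb → 3′ end. Evidence links to windows by any
overlap (>= 1 bp): H3K27me3 losses against the gene body, H3K4me3 gains
and hypomethylated probes against the promoter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .core import GeneModel, GenomicInterval


@dataclass(frozen=True)
class GeneWindows:
    """Promoter and gene-body windows of one gene."""

    gene_id: str
    promoter: GenomicInterval
    body: GenomicInterval


def gene_windows(gene: GeneModel, up: int = 2500, down_promoter: int = 1000) -> GeneWindows:
    """Strand-aware promoter/body windows, truncated at position 0.

    + strand: promoter [tss−up, tss+down), body [tss−up, 3′end].
    − strand: promoter [tss−down, tss+up), body [3′end, tss+up) — the
    genomic mirror of the + rule.
    """
    tss = gene.tss
    if gene.strand == "+":
        prom = GenomicInterval(gene.chrom, max(tss - up, 0), tss + down_promoter)
        body = GenomicInterval(gene.chrom, max(tss - up, 0), gene.three_prime_end + 1)
    else:
        prom = GenomicInterval(gene.chrom, max(tss - down_promoter, 0), tss + up)
        body = GenomicInterval(gene.chrom, gene.three_prime_end, tss + up)
    return GeneWindows(gene.gene_id, prom, body)


def _interval_tree(table: pd.DataFrame, mask: pd.Series) -> Dict[str, IntervalTree]:
    trees: Dict[str, IntervalTree] = {}
    sub = table.loc[mask]
    for chrom, grp in sub.groupby("chrom"):
        trees[str(chrom)] = IntervalTree.from_tuples(
            zip(grp["start"].astype(int), grp["end"].astype(int), grp.index)
        )
    return trees


def _overlapping_ids(trees: Dict[str, IntervalTree], window: GenomicInterval) -> list:
    tree = trees.get(window.chrom)
    if tree is None:
        return []
    return sorted(iv.data for iv in tree.overlap(window.start, window.end))


def assign_gene_flags(
    windows: Sequence[GeneWindows],
    k27_result: Optional[pd.DataFrame] = None,
    k4_result: Optional[pd.DataFrame] = None,
    meth_result: Optional[pd.DataFrame] = None,
    de_status: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Per-gene epigenetic profile from the stage result tables.

    k27_result / k4_result
        Differential-enrichment tables (chrom/start/end/call) for
        H3K27me3 and H3K4me3; losses are matched to the body window,
        gains to the promoter window.
    meth_result
        Differential-methylation table (chrom/pos/call); hypo calls are
        matched to the promoter window.
    de_status
        up/down/none per gene_id; genes absent from it are treated as
        not upregulated.

    Returns a gene_id-indexed frame with the four boolean flags and the
    supporting evidence ids per flag.
    """
    k27_trees = (
        _interval_tree(k27_result, k27_result["call"] == "loss")
        if k27_result is not None
        else {}
    )
    k4_trees = (
        _interval_tree(k4_result, k4_result["call"] == "gain")
        if k4_result is not None
        else {}
    )
    meth_trees = {}
    if meth_result is not None:
        probes = meth_result.assign(
            start=meth_result["pos"].astype(int), end=meth_result["pos"].astype(int) + 1
        )
        meth_trees = _interval_tree(probes, probes["call"] == "hypo")

    rows = []
    for w in windows:
        k27_ev = _overlapping_ids(k27_trees, w.body)
        k4_ev = _overlapping_ids(k4_trees, w.promoter)
        meth_ev = _overlapping_ids(meth_trees, w.promoter)
        up = bool(de_status is not None and de_status.get(w.gene_id) == "up")
        rows.append(
            {
                "gene_id": w.gene_id,
                "lost_k27me3": bool(k27_ev),
                "lost_dname": bool(meth_ev),
                "gained_k4me3": bool(k4_ev),
                "upregulated": up,
                "k27_evidence": ",".join(map(str, k27_ev)),
                "k4_evidence": ",".join(map(str, k4_ev)),
                "meth_evidence": ",".join(map(str, meth_ev)),
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def define_combination_targets(profiles: pd.DataFrame) -> Set[str]:
    """The epigenetic map: genes that lose H3K27me3 and/or lose DNAme
    and/or gain H3K4me3. Expression alone is insufficient."""
    mask = profiles["lost_k27me3"] | profiles["lost_dname"] | profiles["gained_k4me3"]
    return set(profiles.index[mask])


def normalize_gene_ids(ids: Iterable[str]) -> Set[str]:
    """Strip version suffixes (ENSG…​.N → ENSG…) before set algebra."""
    return {str(i).split(".")[0] for i in ids}


def overlap_sets(sets: Dict[str, Set[str]]) -> pd.DataFrame:
    """Venn region counts and memberships for 2 or 3 named sets.

    Each exclusive region (e.g. ``A&B~C``) is one row with its count and
    sorted member list; counts sum to the union size.
    """
    names = list(sets)
    if len(names) not in (2, 3):
        raise ValueError("overlap_sets handles 2 or 3 sets")
    norm = {n: normalize_gene_ids(sets[n]) for n in names}
    universe = set().union(*norm.values())
    rows = []
    for pattern in range(1, 2 ** len(names)):
        inside = [n for i, n in enumerate(names) if pattern >> i & 1]
        outside = [n for n in names if n not in inside]
        region = set(universe)
        for n in inside:
            region &= norm[n]
        for n in outside:
            region -= norm[n]
        label = "&".join(inside) + ("" if not outside else "~" + "~".join(outside))
        rows.append(
            {"region": label, "count": len(region), "members": ",".join(sorted(region))}
        )
    out = pd.DataFrame(rows).set_index("region")
    assert int(out["count"].sum()) == len(universe)
    return out


def patient_marked_genes(
    windows: Sequence[GeneWindows],
    patient_k27_result: Optional[pd.DataFrame],
    patient_meth_result: Optional[pd.DataFrame],
    patient_de_status: pd.Series,
) -> Set[str]:
    """Genes marked by H3K27me3 gain (body window) and/or promoter
    hypermethylation in patients vs normal plasma cells, and
    downregulated in patients."""
    k27_trees = (
        _interval_tree(patient_k27_result, patient_k27_result["call"] == "gain")
        if patient_k27_result is not None
        else {}
    )
    meth_trees = {}
    if patient_meth_result is not None:
        probes = patient_meth_result.assign(
            start=patient_meth_result["pos"].astype(int),
            end=patient_meth_result["pos"].astype(int) + 1,
        )
        meth_trees = _interval_tree(probes, probes["call"] == "hyper")
    marked = set()
    for w in windows:
        has_mark = bool(
            _overlapping_ids(k27_trees, w.body) or _overlapping_ids(meth_trees, w.promoter)
        )
        if has_mark and patient_de_status.get(w.gene_id) == "down":
            marked.add(w.gene_id)
    return marked


def build_target_sets(
    profiles: pd.DataFrame,
    up_combination: Set[str],
    up_mono_unc: Set[str],
    up_mono_aza: Set[str],
    patient_marked: Set[str],
    tsg_list: Iterable[str],
) -> Dict[str, Set[str]]:
    """Assemble the named gene sets and assert their set identities."""
    targets = define_combination_targets(profiles)
    reactivated = targets & up_combination
    tsg = normalize_gene_ids(tsg_list)
    sets = {
        "epigenetic_map": targets,
        "upregulated_combination": up_combination,
        "upregulated_mono_unc": up_mono_unc,
        "upregulated_mono_aza": up_mono_aza,
        "reactivated": reactivated,
        "tsg_reactivated": reactivated & tsg,
        "patient_marked": patient_marked,
        "final_candidates": reactivated & patient_marked,
    }
    assert sets["reactivated"] <= sets["epigenetic_map"]
    assert sets["final_candidates"] <= sets["patient_marked"]
    assert sets["final_candidates"] <= sets["reactivated"]
    return sets


def final_candidates(
    sets: Dict[str, Set[str]],
    tsg_list: Iterable[str],
    survival_p: Optional[Dict[str, float]] = None,
) -> pd.DataFrame:
    """Ranked candidate table: reactivated ∩ patient-marked genes,
    annotated with TSG membership and survival p, ordered by (TSG
    first, then ascending survival p, then gene id)."""
    tsg = normalize_gene_ids(tsg_list)
    survival_p = survival_p or {}
    rows = []
    for gene in sorted(sets["reactivated"] & sets["patient_marked"]):
        rows.append(
            {
                "gene_id": gene,
                "is_tsg": gene in tsg,
                "survival_p": survival_p.get(gene, np.nan),
            }
        )
    out = pd.DataFrame(rows, columns=["gene_id", "is_tsg", "survival_p"])
    if len(out):
        out = out.sort_values(
            ["is_tsg", "survival_p", "gene_id"],
            ascending=[False, True, True],
            na_position="last",
        ).reset_index(drop=True)
    return out
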