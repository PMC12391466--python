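"""Synthetic multi-omic experiment generator with planted ground truth.

Emulates the structure of a combined EZH2 + DNMT inhibition study in a
myeloma cell line plus a patient cohort, at desk scale:

* one synthetic target chromosome carrying non-overlapping genes on
  random strands, plus a separate spike-in chromosome whose peaks are
  biologically invariant across treatments;
* ChIP peak count matrices for four histone marks × four treatment arms
  (vehicle / EZH2 inhibitor / 5-azacytidine / combination) × four
  replicate batches, negative-binomial counts with per-sample depth
  factors that the spike-in stage must recover;
* EPIC-like methylation β values (promoter probes plus background) for
  the cell-line arms and for a patient-vs-normal-plasma-cell cohort;
* RNA-seq counts for the cell-line arms and the patient cohort;
* survival tables for flagship tumour-suppressor-like genes and a
  viability dose grid with a planted Bliss excess.

A subset of genes is planted with epigenetic reactivation effects —
loss of H3K27me3 (gene body + promoter) and/or promoter DNA
hypomethylation and/or H3K4me3 gain, with transcriptional upregulation
in the combination arm. Two "flagship" genes additionally carry the
patient-cohort signature (H3K27me3/DNAme marking and downregulation in
patients) with an adverse-survival association, emulating the
DOK2/PHLPP1-like candidates such a screen is meant to surface. Every
generator is a deterministic function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .chromstates import BinGrid, make_bins
from .core import GeneModel, GenomicInterval, SampleSheet
from .diffchip import PeakCountMatrix
from .integrate import gene_windows
from .methylation import BetaMatrix

TARGET_CHROM = "chrSim"
SPIKE_CHROM = "chrSpike"
MARKS = ("H3K27me3", "H3K4me3", "H3K27ac", "H3K4me1")
ARMS = ("vehicle", "unc1999", "aza", "combination")


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic experiment.

    The defaults mirror the emulated design: 4 treatment arms × 4
    replicate batches of spike-in ChIP per mark, triplicate RNA-seq and
    methylation arrays, a patient cohort compared against normal plasma
    cells, and planted effect sizes (ChIP |log2 FC| 1.5, |Δβ| 0.3,
    expression log2 FC 1.0) chosen to be comfortably detectable at
    these replicate numbers.
    """

    n_genes: int = 1000
    n_peaks_per_mark: int = 1500  # gene promoter peaks + intergenic background
    n_spikein_peaks: int = 500
    n_batches: int = 4
    n_probes: int = 6000  # 5 per promoter + intergenic background
    genome_length: int = 20_000_000
    fraction_planted: float = 0.05
    nb_dispersion: float = 0.1  # RNA-seq NB dispersion
    beta_noise_sd: float = 0.12  # logit-scale jitter of beta values
    seed: int = 0

    # ChIP counts: high batch reproducibility so the planted |log2 FC|
    # sits well above the detection floor of a df=3 t-test under BH
    chip_dispersion: float = 0.003
    chip_mean: float = 500.0
    spikein_mean: float = 100.0
    # effect sizes
    chip_lfc: float = 1.5  # magnitude; losses are negative
    delta_beta: float = 0.3  # magnitude; losses are negative
    expr_lfc: float = 1.0
    flagship_expr_lfc: float = 2.0
    upregulated_fraction: float = 0.85
    # cohort / design sizes
    n_replicates_rna: int = 3
    n_replicates_meth: int = 3
    n_mm_patients: int = 20
    n_npc: int = 8
    n_mono_up: int = 30  # genes upregulated by each monotherapy
    n_patient_marked_extra: int = 15  # patient-marked planted genes beyond flagships
    n_tsg_extra: int = 20  # TSG-list entries beyond flagships
    rna_mean: float = 300.0
    # survival / synergy
    n_subjects: int = 200
    hazard_ratio: float = 2.0
    synergy_excess: float = 0.15
    viability_noise_sd: float = 0.0
    probes_per_promoter: int = 5

    def __post_init__(self) -> None:
        for name in (
            "n_genes",
            "n_peaks_per_mark",
            "n_spikein_peaks",
            "n_batches",
            "n_probes",
            "genome_length",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 < self.fraction_planted < 1:
            raise ValueError("fraction_planted must lie in (0, 1)")
        if self.n_peaks_per_mark < self.n_genes:
            raise ValueError("n_peaks_per_mark must be >= n_genes")
        if self.n_probes < self.probes_per_promoter * self.n_genes:
            raise ValueError("n_probes must cover probes_per_promoter per gene")

    @property
    def n_planted(self) -> int:
        return max(int(round(self.fraction_planted * self.n_genes)), 2)


@dataclass
class SyntheticGenome:
    genes: List[GeneModel]
    grid: BinGrid
    peaks: Dict[str, pd.DataFrame]  # per mark: chrom/start/end/species/gene_id/role
    chrom_sizes: Dict[str, int]
    slot: int


@dataclass
class GroundTruth:
    """Planted per-gene effects and nuisance parameters.

    genes
        gene_id-indexed frame of flags (planted, lost_k27me3,
        lost_dname, gained_k4me3, upregulated, mono_unc_up,
        mono_aza_up, patient_marked, is_tsg, is_flagship) and signed
        effect sizes (k27_lfc, k4_lfc, delta_beta, expr_lfc,
        patient_k27_lfc, patient_delta_beta, patient_expr_lfc).
    chip_scaling
        sample_id -> true per-sample depth factor for every ChIP sample
        (cell line and patient cohort).
    """

    genes: pd.DataFrame
    chip_scaling: pd.Series
    tsg_list: List[str]
    hazard_ratio: float
    synergy_excess: pd.DataFrame
    drug_a: tuple = (1.3, 0.8)  # median-effect (m, Dm)
    drug_b: tuple = (1.0, 1.0)

    @property
    def planted_targets(self) -> List[str]:
        g = self.genes
        return sorted(g.index[g["planted"]])

    @property
    def flagships(self) -> List[str]:
        g = self.genes
        return sorted(g.index[g["is_flagship"]])


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# genome


def simulate_genome(cfg: SimulationConfig, seed=None) -> SyntheticGenome:
    """Non-overlapping genes in fixed slots on one target chromosome,
    consensus peaks per mark (promoter peak per gene, a gene-body peak
    for H3K27me3, intergenic background peaks), and spike-in peaks on a
    separate chromosome."""
    rng = _rng(cfg.seed if seed is None else seed)
    slot = cfg.genome_length // cfg.n_genes
    min_len, max_len = 3000, 8000
    margin = 3000
    if slot < margin + max_len + 2700:
        raise ValueError(
            f"genome too small: slot {slot} bp per gene, need >= {margin + max_len + 2700}"
        )
    genes = []
    for i in range(cfg.n_genes):
        length = int(rng.integers(min_len, max_len + 1))
        # keep the promoter/body windows (±2.5 kb around the TSS span)
        # inside the gene's slot so windows of neighbours never touch
        jitter = int(rng.integers(0, slot - margin - length - 2600))
        start = i * slot + margin + jitter
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneModel(
                gene_id=f"G{i:04d}",
                symbol=f"SYM{i:04d}",
                interval=GenomicInterval(TARGET_CHROM, start, start + length, strand),
            )
        )

    spike_len = cfg.n_spikein_peaks * 2000
    chrom_sizes = {TARGET_CHROM: cfg.genome_length, SPIKE_CHROM: spike_len}
    grid = make_bins(chrom_sizes, 200)

    n_background = cfg.n_peaks_per_mark - cfg.n_genes
    spike_rows = [
        {
            "chrom": SPIKE_CHROM,
            "start": i * 2000 + 500,
            "end": i * 2000 + 1500,
            "species": "spikein",
            "gene_id": "",
            "role": "spikein",
        }
        for i in range(cfg.n_spikein_peaks)
    ]
    peaks: Dict[str, pd.DataFrame] = {}
    for mark in MARKS:
        rows = []
        for g in genes:
            tss = g.tss
            rows.append(
                {
                    "chrom": TARGET_CHROM,
                    "start": max(tss - 500, 0),
                    "end": tss + 500,
                    "species": "target",
                    "gene_id": g.gene_id,
                    "role": "promoter",
                }
            )
            if mark == "H3K27me3":
                mid = (g.interval.start + g.interval.end) // 2
                rows.append(
                    {
                        "chrom": TARGET_CHROM,
                        "start": mid - 500,
                        "end": mid + 500,
                        "species": "target",
                        "gene_id": g.gene_id,
                        "role": "body",
                    }
                )
        bg_slots = rng.choice(cfg.n_genes, size=n_background, replace=False)
        for s in sorted(bg_slots):
            rows.append(
                {
                    "chrom": TARGET_CHROM,
                    "start": s * slot,
                    "end": s * slot + 400,
                    "species": "target",
                    "gene_id": "",
                    "role": "background",
                }
            )
        tab = pd.DataFrame(rows + spike_rows)
        tab.index = [f"{mark}_pk{i:05d}" for i in range(len(tab))]
        peaks[mark] = tab
    return SyntheticGenome(genes, grid, peaks, chrom_sizes, slot)


# ---------------------------------------------------------------------------
# ground truth


def make_ground_truth(genome: SyntheticGenome, cfg: SimulationConfig, seed=None) -> GroundTruth:
    """Plant per-gene effects.

    Each planted gene receives a random non-empty subset of the three
    epigenetic reactivation modes (H3K27me3 loss, promoter DNAme loss,
    H3K4me3 gain) and is upregulated in the combination arm with
    probability ``upregulated_fraction``. The first two planted genes
    are flagships: all three modes, strong upregulation, the
    patient-cohort signature, TSG membership and an adverse survival
    hazard for low expression.
    """
    rng = _rng(cfg.seed + 1 if seed is None else seed)
    gene_ids = [g.gene_id for g in genome.genes]
    n = len(gene_ids)
    tab = pd.DataFrame(index=pd.Index(gene_ids, name="gene_id"))
    tab["symbol"] = [g.symbol for g in genome.genes]
    for col in (
        "planted",
        "lost_k27me3",
        "lost_dname",
        "gained_k4me3",
        "upregulated",
        "mono_unc_up",
        "mono_aza_up",
        "patient_marked",
        "is_tsg",
        "is_flagship",
    ):
        tab[col] = False
    for col in (
        "k27_lfc",
        "k4_lfc",
        "delta_beta",
        "expr_lfc",
        "patient_k27_lfc",
        "patient_delta_beta",
        "patient_expr_lfc",
    ):
        tab[col] = 0.0

    planted_idx = np.sort(rng.choice(n, size=cfg.n_planted, replace=False))
    planted = [gene_ids[i] for i in planted_idx]
    flagships = planted[:2]
    tab.loc[planted, "planted"] = True

    for gid in planted:
        if gid in flagships:
            modes = (True, True, True)
        else:
            bits = int(rng.integers(1, 8))  # non-empty subset of 3 modes
            modes = (bool(bits & 1), bool(bits & 2), bool(bits & 4))
        k27, dname, k4 = modes
        if k27:
            tab.loc[gid, ["lost_k27me3", "k27_lfc"]] = True, -cfg.chip_lfc
        if dname:
            tab.loc[gid, ["lost_dname", "delta_beta"]] = True, -cfg.delta_beta
        if k4:
            tab.loc[gid, ["gained_k4me3", "k4_lfc"]] = True, cfg.chip_lfc
        up = gid in flagships or rng.random() < cfg.upregulated_fraction
        if up:
            lfc = cfg.flagship_expr_lfc if gid in flagships else cfg.expr_lfc
            tab.loc[gid, ["upregulated", "expr_lfc"]] = True, lfc

    # monotherapy-only upregulated genes (shared with the combination arm)
    null_pool = [g for g in gene_ids if g not in set(planted)]
    n_mono = min(cfg.n_mono_up, len(null_pool) // 4)
    mono = rng.choice(len(null_pool), size=2 * n_mono, replace=False)
    unc_up = [null_pool[i] for i in mono[:n_mono]]
    aza_up = [null_pool[i] for i in mono[n_mono:]]
    tab.loc[unc_up, "mono_unc_up"] = True
    tab.loc[aza_up, "mono_aza_up"] = True
    tab.loc[unc_up + aza_up, "expr_lfc"] = cfg.expr_lfc

    # patient cohort signature: flagships + a subset of other planted genes
    others = [g for g in planted if g not in flagships]
    extra = rng.choice(len(others), size=min(cfg.n_patient_marked_extra, len(others)), replace=False)
    marked = flagships + [others[i] for i in extra]
    tab.loc[marked, "patient_marked"] = True
    tab.loc[marked, "patient_k27_lfc"] = cfg.chip_lfc
    tab.loc[marked, "patient_delta_beta"] = cfg.delta_beta
    tab.loc[marked, "patient_expr_lfc"] = -cfg.chip_lfc

    tsg_pool = [g for g in gene_ids if g not in flagships]
    n_tsg = min(cfg.n_tsg_extra, len(tsg_pool) // 2)
    tsg_extra = [tsg_pool[i] for i in rng.choice(len(tsg_pool), size=n_tsg, replace=False)]
    tsg_list = sorted(flagships + tsg_extra)
    tab.loc[tsg_list, "is_tsg"] = True
    tab.loc[flagships, "is_flagship"] = True

    # true per-sample ChIP depth factors (cell line + patient cohort)
    sample_ids = []
    for mark in MARKS:
        for arm in ARMS:
            for b in range(1, cfg.n_batches + 1):
                sample_ids.append(f"chip_{mark}_{arm}_b{b}")
    for grp in ("npc", "mm"):
        for b in range(1, cfg.n_batches + 1):
            sample_ids.append(f"pchip_H3K27me3_{grp}_b{b}")
    scaling = pd.Series(rng.uniform(0.5, 2.0, size=len(sample_ids)), index=sample_ids)

    doses = _default_doses()
    excess = pd.DataFrame(0.0, index=doses, columns=doses)
    # mid-dose block: leaves headroom so viability stays positive
    excess.iloc[2:4, 2:4] = cfg.synergy_excess

    return GroundTruth(
        genes=tab,
        chip_scaling=scaling,
        tsg_list=tsg_list,
        hazard_ratio=cfg.hazard_ratio,
        synergy_excess=excess,
    )


def _default_doses() -> List[float]:
    return [0.0, 0.25, 0.5, 1.0, 2.0]


def _nb(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean).astype(float)
    size_param = 1.0 / dispersion
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p).astype(float)


# ---------------------------------------------------------------------------
# ChIP counts


def simulate_chip_counts(
    truth: GroundTruth, genome: SyntheticGenome, cfg: SimulationConfig, seed=None
) -> Dict[str, PeakCountMatrix]:
    """Negative-binomial peak counts per mark for the cell-line arms.

    Expected count of peak i in sample j is base_i × depth_j ×
    2^{lfc_i} with the planted log2 FC applied only in affected
    treatments (H3K27me3 loss and H3K4me3 gain act in the EZH2-inhibitor
    and combination arms). Spike-in peak expectations carry only the
    depth factor, so they are treatment-invariant up to depth.
    """
    rng = _rng(cfg.seed + 2 if seed is None else seed)
    out: Dict[str, PeakCountMatrix] = {}
    affected_arms = ("unc1999", "combination")
    for mark in MARKS:
        peaks = genome.peaks[mark]
        base = np.where(
            peaks["species"] == "spikein",
            np.exp(rng.normal(np.log(cfg.spikein_mean), 0.3, size=len(peaks))),
            np.exp(rng.normal(np.log(cfg.chip_mean), 0.5, size=len(peaks))),
        )
        lfc = np.zeros(len(peaks))
        if mark == "H3K27me3":
            effect = truth.genes["k27_lfc"]
        elif mark == "H3K4me3":
            effect = truth.genes["k4_lfc"]
        else:
            effect = None
        if effect is not None:
            gene_of_peak = peaks["gene_id"].values
            has_gene = gene_of_peak != ""
            lfc[has_gene] = effect.reindex(gene_of_peak[has_gene]).values
        rows = []
        counts = {}
        for arm in ARMS:
            arm_lfc = lfc if arm in affected_arms else np.zeros_like(lfc)
            for b in range(1, cfg.n_batches + 1):
                sid = f"chip_{mark}_{arm}_b{b}"
                depth = truth.chip_scaling[sid]
                mean = base * depth * 2.0**arm_lfc
                counts[sid] = _nb(rng, mean, cfg.chip_dispersion)
                rows.append(
                    {
                        "sample_id": sid,
                        "assay": "chip",
                        "mark": mark,
                        "treatment": arm,
                        "batch": f"b{b}",
                    }
                )
        cmat = pd.DataFrame(counts, index=peaks.index)
        out[mark] = PeakCountMatrix(peaks, cmat, SampleSheet(rows))
    return out


def simulate_patient_chip(
    truth: GroundTruth, genome: SyntheticGenome, cfg: SimulationConfig, seed=None
) -> PeakCountMatrix:
    """Patient-cohort H3K27me3 counts: matched NPC/MM pseudo-batches
    with spike-in peaks retained for schema parity. Patient-marked genes
    gain H3K27me3 (promoter + body peaks) in the MM group."""
    rng = _rng(cfg.seed + 3 if seed is None else seed)
    peaks = genome.peaks["H3K27me3"]
    base = np.where(
        peaks["species"] == "spikein",
        np.exp(rng.normal(np.log(cfg.spikein_mean), 0.3, size=len(peaks))),
        np.exp(rng.normal(np.log(cfg.chip_mean), 0.5, size=len(peaks))),
    )
    lfc = np.zeros(len(peaks))
    gene_of_peak = peaks["gene_id"].values
    has_gene = gene_of_peak != ""
    lfc[has_gene] = truth.genes["patient_k27_lfc"].reindex(gene_of_peak[has_gene]).values
    rows = []
    counts = {}
    for grp in ("npc", "mm"):
        grp_lfc = lfc if grp == "mm" else np.zeros_like(lfc)
        for b in range(1, cfg.n_batches + 1):
            sid = f"pchip_H3K27me3_{grp}_b{b}"
            mean = base * truth.chip_scaling[sid] * 2.0**grp_lfc
            counts[sid] = _nb(rng, mean, cfg.chip_dispersion)
            rows.append(
                {
                    "sample_id": sid,
                    "assay": "chip",
                    "mark": "H3K27me3",
                    "treatment": grp,
                    "batch": f"b{b}",
                }
            )
    return PeakCountMatrix(peaks, pd.DataFrame(counts, index=peaks.index), SampleSheet(rows))


# ---------------------------------------------------------------------------
# methylation


def _jitter_beta(rng: np.random.Generator, mean: np.ndarray, sd: float) -> np.ndarray:
    mean = np.clip(mean, 0.02, 0.98)
    return expit(logit(mean) + rng.normal(0.0, sd, size=mean.shape))


def simulate_methylation(
    truth: GroundTruth, genome: SyntheticGenome, cfg: SimulationConfig, seed=None
) -> tuple:
    """(cell-line BetaMatrix, patient BetaMatrix) over shared probes.

    Promoter probes sit inside each gene's promoter window; background
    probes sit between gene slots. β is a logit-normal jitter around
    the group mean; planted DNAme-loss genes shift promoter probes by
    −Δβ in the 5-azacytidine-containing arms, and patient-marked genes
    are hypermethylated in the patient group relative to NPCs.
    """
    rng = _rng(cfg.seed + 4 if seed is None else seed)
    probe_rows = []
    base = []
    for g in genome.genes:
        w = gene_windows(g)
        step = w.promoter.width // (cfg.probes_per_promoter + 1)
        gene_base = float(rng.uniform(0.55, 0.85))
        for k in range(cfg.probes_per_promoter):
            probe_rows.append(
                {
                    "probe_id": f"cg_{g.gene_id}_{k}",
                    "chrom": w.promoter.chrom,
                    "pos": w.promoter.start + (k + 1) * step,
                    "gene_id": g.gene_id,
                }
            )
            base.append(gene_base)
    n_background = cfg.n_probes - len(probe_rows)
    bg_slots = rng.choice(cfg.n_genes, size=n_background, replace=True)
    offsets = rng.integers(0, 450, size=n_background)
    seen = {r["pos"] for r in probe_rows}
    for i, (s, off) in enumerate(zip(bg_slots, offsets)):
        pos = int(s) * genome.slot + int(off)
        while pos in seen:
            pos += 1
        seen.add(pos)
        probe_rows.append(
            {"probe_id": f"cg_bg{i:05d}", "chrom": TARGET_CHROM, "pos": pos, "gene_id": ""}
        )
        base.append(float(rng.uniform(0.1, 0.9)))
    probes = pd.DataFrame(probe_rows).set_index("probe_id")
    base = np.asarray(base)

    gene_of_probe = probes["gene_id"].values
    has_gene = gene_of_probe != ""
    cell_delta = np.zeros(len(probes))
    cell_delta[has_gene] = truth.genes["delta_beta"].reindex(gene_of_probe[has_gene]).values
    pat_delta = np.zeros(len(probes))
    pat_delta[has_gene] = truth.genes["patient_delta_beta"].reindex(
        gene_of_probe[has_gene]
    ).values

    cell_cols = {}
    groups_cell = {}
    for arm in ARMS:
        mean = base + (cell_delta if arm in ("aza", "combination") else 0.0)
        for r in range(1, cfg.n_replicates_meth + 1):
            sid = f"meth_{arm}_r{r}"
            cell_cols[sid] = _jitter_beta(rng, mean, cfg.beta_noise_sd)
            groups_cell[sid] = arm
    cell = BetaMatrix(
        probes[["chrom", "pos"]], pd.DataFrame(cell_cols, index=probes.index), groups_cell
    )

    pat_cols = {}
    groups_pat = {}
    npc_mean = np.where(pat_delta != 0, 0.25, base)
    for j in range(1, cfg.n_npc + 1):
        sid = f"meth_npc_{j:02d}"
        pat_cols[sid] = _jitter_beta(rng, npc_mean, cfg.beta_noise_sd)
        groups_pat[sid] = "npc"
    mm_mean = npc_mean + pat_delta
    for j in range(1, cfg.n_mm_patients + 1):
        sid = f"meth_mm_{j:02d}"
        pat_cols[sid] = _jitter_beta(rng, mm_mean, cfg.beta_noise_sd)
        groups_pat[sid] = "mm"
    patient = BetaMatrix(
        probes[["chrom", "pos"]], pd.DataFrame(pat_cols, index=probes.index), groups_pat
    )
    return cell, patient


# ---------------------------------------------------------------------------
# expression


def simulate_expression(
    truth: GroundTruth, genome: SyntheticGenome, cfg: SimulationConfig, seed=None
) -> tuple:
    """(cell-line counts, cell-line arm map, patient counts, patient
    group map): genes × samples NB counts.

    Upregulated planted genes act in the combination arm only;
    monotherapy-up genes act in their monotherapy and the combination;
    patient-marked genes are downregulated in the patient group.
    """
    rng = _rng(cfg.seed + 5 if seed is None else seed)
    gene_ids = truth.genes.index
    base = np.exp(rng.normal(np.log(cfg.rna_mean), 1.0, size=len(gene_ids)))
    base = np.maximum(base, 5.0)
    g = truth.genes

    arm_lfc = {arm: np.zeros(len(gene_ids)) for arm in ARMS}
    arm_lfc["combination"] += np.where(g["upregulated"], g["expr_lfc"], 0.0)
    arm_lfc["combination"] += np.where(g["mono_unc_up"] | g["mono_aza_up"], g["expr_lfc"], 0.0)
    arm_lfc["unc1999"] += np.where(g["mono_unc_up"], g["expr_lfc"], 0.0)
    arm_lfc["aza"] += np.where(g["mono_aza_up"], g["expr_lfc"], 0.0)

    cell_cols = {}
    cell_arms = {}
    for arm in ARMS:
        for r in range(1, cfg.n_replicates_rna + 1):
            sid = f"rna_{arm}_r{r}"
            lib = rng.uniform(0.7, 1.3)
            mean = base * lib * 2.0 ** arm_lfc[arm]
            cell_cols[sid] = _nb(rng, mean, cfg.nb_dispersion)
            cell_arms[sid] = arm
    cell = pd.DataFrame(cell_cols, index=gene_ids)

    pat_cols = {}
    pat_groups = {}
    pat_lfc = np.where(g["patient_marked"], g["patient_expr_lfc"], 0.0)
    for j in range(1, cfg.n_npc + 1):
        sid = f"rna_npc_{j:02d}"
        lib = rng.uniform(0.7, 1.3)
        pat_cols[sid] = _nb(rng, base * lib, cfg.nb_dispersion)
        pat_groups[sid] = "npc"
    for j in range(1, cfg.n_mm_patients + 1):
        sid = f"rna_mm_{j:02d}"
        lib = rng.uniform(0.7, 1.3)
        pat_cols[sid] = _nb(rng, base * lib * 2.0**pat_lfc, cfg.nb_dispersion)
        pat_groups[sid] = "mm"
    patient = pd.DataFrame(pat_cols, index=gene_ids)
    return cell, cell_arms, patient, pat_groups


# ---------------------------------------------------------------------------
# survival and viability


def simulate_survival(
    truth: GroundTruth, cfg: SimulationConfig, gene_id: str, seed=None
) -> pd.DataFrame:
    """Survival table for one stratifying gene: exponential event times
    with the planted hazard ratio for the low-expression half, uniform
    censoring."""
    rng = _rng(cfg.seed + 6 if seed is None else seed)
    n = cfg.n_subjects
    expression = np.exp(rng.normal(0.0, 0.5, size=n))
    low = expression < np.median(expression)
    hr = truth.hazard_ratio if truth.genes.loc[gene_id, "is_flagship"] else 1.0
    base_rate = 1.0 / 1000.0
    rate = np.where(low, base_rate * hr, base_rate)
    event_time = rng.exponential(1.0 / rate)
    censor_time = rng.uniform(200.0, 3000.0, size=n)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    return pd.DataFrame({"time": time, "event": event, "expression": expression})


def simulate_viability_grid(truth: GroundTruth, cfg: SimulationConfig, seed=None) -> pd.DataFrame:
    """Dose-grid viability fractions: monotherapy effects follow each
    drug's median-effect curve; combination cells follow Bliss
    independence minus the planted excess (plus optional noise)."""
    rng = _rng(cfg.seed + 7 if seed is None else seed)
    doses = list(truth.synergy_excess.index)
    ma, dma = truth.drug_a
    mb, dmb = truth.drug_b

    def fa(d, m, dm):
        if d == 0:
            return 0.0
        r = (d / dm) ** m
        return r / (1 + r)

    grid = np.empty((len(doses), len(doses)))
    for i, da in enumerate(doses):
        for j, db in enumerate(doses):
            ea, eb = fa(da, ma, dma), fa(db, mb, dmb)
            v = (1 - ea) * (1 - eb) - truth.synergy_excess.iloc[i, j]
            if cfg.viability_noise_sd > 0:
                v += rng.normal(0.0, cfg.viability_noise_sd)
            grid[i, j] = min(max(v, 0.0), 1.0)
    return pd.DataFrame(grid, index=pd.Index(doses, name="dose_a"), columns=pd.Index(doses, name="dose_b"))


def dose_response_curves(truth: GroundTruth) -> dict:
    """Noiseless single-agent affected fractions on the grid doses, for
    median-effect fitting."""
    out = {}
    for name, (m, dm) in (("a", truth.drug_a), ("b", truth.drug_b)):
        doses = np.array([d for d in _default_doses() if d > 0])
        r = (doses / dm) ** m
        out[name] = (doses, r / (1 + r))
    return out


# ---------------------------------------------------------------------------
# whole experiment


@dataclass
class SyntheticExperiment:
    cfg: SimulationConfig
    genome: SyntheticGenome
    truth: GroundTruth
    chip: Dict[str, PeakCountMatrix]
    patient_chip: PeakCountMatrix
    meth_cell: BetaMatrix
    meth_patient: BetaMatrix
    expr_cell: pd.DataFrame
    expr_cell_arms: Dict[str, str]
    expr_patient: pd.DataFrame
    expr_patient_groups: Dict[str, str]
    survival: Dict[str, pd.DataFrame]
    viability: pd.DataFrame

    def rna_samples(self, arm: str) -> List[str]:
        return [s for s, a in self.expr_cell_arms.items() if a == arm]

    def patient_rna_samples(self, group: str) -> List[str]:
        return [s for s, g in self.expr_patient_groups.items() if g == group]


def simulate_experiment(cfg: Optional[SimulationConfig] = None) -> SyntheticExperiment:
    """Generate the full synthetic multi-omic experiment from cfg.seed."""
    cfg = cfg or SimulationConfig()
    genome = simulate_genome(cfg)
    truth = make_ground_truth(genome, cfg)
    chip = simulate_chip_counts(truth, genome, cfg)
    patient_chip = simulate_patient_chip(truth, genome, cfg)
    meth_cell, meth_patient = simulate_methylation(truth, genome, cfg)
    expr_cell, cell_arms, expr_patient, pat_groups = simulate_expression(truth, genome, cfg)
    survival = {
        gid: simulate_survival(truth, cfg, gid, seed=cfg.seed + 6 + k)
        for k, gid in enumerate(truth.flagships)
    }
    viability = simulate_viability_grid(truth, cfg)
    return SyntheticExperiment(
        cfg=cfg,
        genome=genome,
        truth=truth,
        chip=chip,
        patient_chip=patient_chip,
        meth_cell=meth_cell,
        meth_patient=meth_patient,
        expr_cell=expr_cell,
        expr_cell_arms=cell_arms,
        expr_patient=expr_patient,
        expr_patient_groups=pat_groups,
        survival=survival,
        viability=viability,
    )
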