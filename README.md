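# epireprog

Multi-omic identification of genes epigenetically reactivated by
combined EZH2 + DNMT inhibition.

In multiple myeloma, the Polycomb methyltransferase EZH2 (depositing
H3K27me3) and DNA methyltransferases cooperate to silence tumour
suppressor genes. Dual pharmacological inhibition (an EZH2 inhibitor
plus low-dose 5-azacytidine) can reactivate them. `epireprog`
implements the full analysis chain such a study needs, as a Python
library for computational epigenomics:

- **Spike-in differential ChIP** — per-batch size factors estimated by
  median-of-ratios over foreign-species spike-in peaks only, so that
  genome-wide mark loss is not normalized away; per-batch log2 fold
  changes; a two-sided one-sample t-test across replicate batches
  (H₀: mean log2 FC = 0); Benjamini–Hochberg FDR and gain/loss calls.
- **Chromatin states** — 200-bp binarization of mark tracks (peak
  overlap or upper-tail Poisson threshold), a multivariate
  Bernoulli-emission HMM fit by Baum–Welch with restarts, posterior
  decoding, rule-based labeling into functional families (promoter,
  bivalent TSS, enhancer, Polycomb, …), annotation enrichment and
  metaprofiles.
- **Differential methylation** — per-probe Welch t on array β values
  with BH FDR and joint q/|Δβ| calling.
- **Differential expression** — simplified negative-binomial Wald test
  (median-of-ratios normalization, common moment dispersion,
  delta-method SE), classified at p < 0.05 and |log2 FC| > 0.5.
- **Target integration** — strand-aware promoter (TSS−2.5 kb → TSS+1 kb)
  and gene-body (TSS−2.5 kb → 3′ end) windows; per-gene flags (lost
  H3K27me3, lost DNAme, gained H3K4me3, upregulated); the *epigenetic
  map* = genes with any of the three epigenetic changes; reactivated =
  map ∩ upregulated; intersection with a patient cohort (marked by
  H3K27me3/DNAme and downregulated vs normal plasma cells) and a
  TSG list into a ranked candidate table.
- **Survival & synergy** — Kaplan–Meier curves, log-rank (Mantel–Cox)
  test with median-expression stratification; Bliss-independence
  excess (E_A + E_B − E_A·E_B reference) and the Chou–Talalay
  combination index from the median-effect model.
- **Synthetic data** — a first-class generator
  (`epireprog.simulate`) that emulates the whole study design — 4
  marks × 4 treatment arms × 4 replicate batches of spike-in ChIP
  counts, EPIC-like β values, NB expression counts, a patient cohort,
  survival tables and viability dose grids — with planted,
  recoverable ground truth.

## Worked example

```bash
python examples/simulate_and_recover.py
```

```
Planted combination targets: 50
  target_sensitivity           0.980
  target_precision             0.980
  n_epigenetic_map             50.000
  n_reactivated                27.000
  n_patient_marked             17.000
  patient_marked_sensitivity   1.000
  n_final_candidates           9.000
  flagships_recovered          2.000

Final candidate table (reactivated ∩ patient-marked):
gene_id  is_tsg   survival_p
  G0039    True 2.146034e-07
  G0053    True 1.460881e-06
  G0887    True          NaN
  ...
```

Of 1,000 synthetic genes, 50 were planted as combination targets
(losing H3K27me3 and/or promoter DNA methylation and/or gaining
H3K4me3 under the combined treatment). The pipeline's epigenetic map
recovers them with 98% sensitivity and precision; the two flagship
TSG-like genes (planted with the patient-cohort signature and an
adverse survival hazard) head the final candidate table with log-rank
p < 10⁻⁵ — the synthetic analogue of recovering DOK2/PHLPP1-style
candidates. The other `examples/` scripts walk through each stage
(spike-in ChIP, chromatin states, target integration,
survival/synergy) individually.

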