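# radiometab

Tools for linking metabolic-pathway state to tumor radiosensitivity, built
around the analysis design used in glioblastoma (GBM) cell-line panels:

* **Radiosensitivity quantification** from clonogenic survival assays —
  plating-efficiency-normalized surviving fractions, linear-quadratic (LQ)
  fits SF(d) = exp(−(αd + βd²)), and the mean inactivating dose
  **Dmid = ∫ SF(d) dd** (area under the survival curve on a linear SF axis;
  larger Dmid = more radioresistant). Radiosensitizers and radioprotectors
  are quantified by the **enhancement ratio** ER = Dmid(control)/Dmid(treated)
  (ER > 1: sensitization), or by GI50 ratios for viability-based assays on
  neurosphere lines.
* **Pathway regulation scoring** of targeted LC-MS/MS metabolite panels —
  QC filtering (detection threshold, replicate CV), per-metabolite
  z-transform across cell lines, up/down regulation calls at z = ±1,
  per-pathway regulation scores (fraction of measured metabolites called),
  Pearson correlation of pathway scores with the radiosensitivity score
  (−Dmid), and Benjamini–Hochberg FDR control. A post-irradiation variant
  operates on log2 fold changes of matched irradiated/unirradiated samples.
* **Time-to-event endpoints** — caliper volumes (π/6·L·W²), day-1
  normalization, LOCF imputation of bioluminescence flux, tumor tripling
  time (earliest measured day ≥ 3× the day-1 value), Kaplan–Meier curves,
  the Mantel–Cox log-rank test, univariate Cox regression, and
  median-split survival analysis of expression cohorts.
* **Synthetic data generators** for every input, with recorded ground
  truth (coupled pathway, coupling strength, LQ parameters, growth rates,
  hazard ratios), so the whole pipeline is testable without external data.

The statistical procedures (Pearson r with the t-distribution p-value,
pooled/Welch t-tests, Holm–Šidák, BH, KM, log-rank, Cox with Breslow
ties) are implemented from their defining formulas and cross-checked in
the test suite against independent oracles and reference libraries
(scipy, statsmodels, lifelines).

## Worked example

Simulate a 23-line panel whose guanylate pathway is coupled to
radioresistance (per-metabolite coupling r = 0.8), then run the scoring
pipeline:

```sh
radiometab simulate --scenario panel --seed 1 --out-dir demo
radiometab run --panel demo/metabolite_panel.tsv \
    --pathway-map demo/pathway_map.tsv \
    --resistance demo/resistance.tsv \
    --out-dir demo/results
```

`demo/results/pathway_correlations.tsv` (down-regulation direction):

```
         pathway direction  n         r        p        q  significant
      adenylates      down 23 -0.429884 0.040625 0.066686         True
        cytidine      down 23  0.296417 0.169631 0.169631        False
     glutathione      down 23 -0.460671 0.026954 0.066686         True
      guanylates      down 23  0.607307 0.002117 0.012703         True
      inosinates      down 23 -0.332487 0.121115 0.145338        False
nucleotide_sugar      down 23 -0.422754 0.044458 0.066686         True
```

The coupled pathway (guanylates) is recovered as the strongest hit:
largest |r| (0.61) and smallest q (0.013). The positive r means its
down-regulation score rises with radiosensitivity (−Dmid) — depleted
guanylates mark radiosensitive lines. At n = 23 some null pathways reach
nominal p < 0.05 by chance (this seed shows three); the q column is the
multiplicity-corrected quantity to read. A `manifest.json` in the output
directory records the full configuration, input checksums and package
version needed to re-run the analysis.

Other entry points: `radiometab qc` (panel filtering only),
`radiometab fit-survival` (LQ fits + Dmid from colony counts),
`radiometab endpoints` (tripling time / KM / log-rank / median-split),
`radiometab simulate --scenario {panel,clonogenic,growth,survival,end2end}`.
Everything is also importable: `radiometab.pathway_corr`,
`radiometab.radioresponse`, `radiometab.stats_core`,
`radiometab.invivo_endpoints`, `radiometab.msprep`,
`radiometab.synthetic_data`, `radiometab.tables_io`.

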