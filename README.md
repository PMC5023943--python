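# nmrfib

A tested, reusable Python implementation of the ¹H NMR tissue-metabolomics
analysis used to characterise renal interstitial fibrosis in the rat
unilateral-ureteral-obstruction (UUO) model — for metabolomics researchers
who want the full workflow (spectral bucketing through biomarker screening
and endpoint correlation) as an importable library rather than a GUI
chemometrics package.

## The problem and the method

Ligating one ureter induces fibrosis in the obstructed kidney; the open
question the analysis addresses is how far the *contralateral* kidney has
moved along the same metabolic trajectory. Four kidney groups are compared:
**A** (UUO left, obstructed), **B** (UUO right, contralateral), **C** (sham
left) and **D** (sham right).

The pipeline is:

1. **Preprocessing** — each spectrum is integrated into 0.01 ppm buckets
   over δ 0.78–9.66 with the residual-water region δ 4.68–5.23 excluded
   (888 raw buckets, 55 removed, 833 analysed), then normalised to tissue
   weight. Metabolite relative contents are integrals over each
   metabolite's least-overlapping signal.
2. **Chemometrics** — mean-centered PCA for overview; two-class PLS-DA and
   OPLS-DA (NIPALS, from scratch) with class-stratified k-fold Q², a
   200-permutation validation test, CV-ANOVA on cross-validated residuals,
   S-plot (cov/corr of each bucket with the predictive score) and VIP.
3. **Screening** — a metabolite is differential when VIP ≥ 1, |p(corr)| ≥
   0.5 and Welch p < 0.05 (A vs C) all hold.
4. **Fibrosis index** — per metabolite *i* with group-mean contents
   X<sub>Ai</sub>, X<sub>Bi</sub>, X<sub>Ci</sub>,

   α<sub>i</sub> = (X<sub>Bi</sub> − X<sub>Ci</sub>) / (X<sub>Ai</sub> − X<sub>Ci</sub>),
   &nbsp;&nbsp; %ADF = 100 × mean<sub>i</sub> |α<sub>i</sub>|

   — the contralateral kidney's shift as a fraction of the obstructed
   kidney's shift, averaged over the 14-metabolite panel.
5. **Correlation report** — Pearson r (exact t-transform p, significance
   stars) between each metabolite and the clinical/histology endpoints
   Scr, BUN, ALB, TIS, ICD, plus PLS biplot coordinates.

Because the original spectra are not deposited, the package ships a
calibrated synthetic-data generator: a per-animal latent fibrosis severity
drives both kidneys' metabolite levels (group means from the packaged
reference table) and the endpoints, producing Lorentzian-peak spectra with
configurable dispersion and noise. Every downstream stage is testable
end-to-end without downloads.

## Worked example

```sh
python examples/03_screen_and_fibrosis_index.py
```

prints

```
selected 14/14 metabolites (top by VIP):
  Methionine    VIP=2.54 pcorr=+0.97 p(AvsC)=1.7e-09 up
  Allantoin     VIP=2.51 pcorr=+0.96 p(AvsC)=1.2e-08 up
  Adenosine     VIP=2.51 pcorr=-0.96 p(AvsC)=2.3e-10 down
  Leucine       VIP=2.43 pcorr=-0.93 p(AvsC)=5.8e-07 down
  Valine        VIP=2.43 pcorr=-0.92 p(AvsC)=1.3e-08 down
simulated-study ADF: 23.1% over 14 metabolites
published-means ADF: 26.1% (alpha lactate = 0.198)
```

All 14 panel metabolites pass the three-criterion screen on the default
synthetic study (11 UUO / 9 sham animals, 15% coefficient of variation,
seed 17), with the expected directions (lactate up, TMAO down, …). The
simulated-study ADF (23.1%) is the fibrosis index recomputed from noisy
samples; the published-means ADF (26.1%) is the same statistic evaluated
directly on the packaged reference group means. The other examples cover
simulation/preprocessing, model validation (R²Y = 0.998, Q² = 0.860,
permutation intercept −0.17, CV-ANOVA p ≈ 6e-08) and the correlation
report (sign concordance 0.929 against the reference pattern).

The same workflow is available from the shell:

```sh
nmrfib run --out run_dir --seed 17         # full pipeline, JSON report
nmrfib simulate|preprocess|model|screen|adf|correlate --help
```

## Layout

- `src/nmrfib/` — library (`io`, `reference`, `assignments`, `simulate`,
  `preprocess`, `chemometrics`, `screening`, `fibrosis`, `correlation`,
  `pipeline`, `cli`)
- `examples/` — one narrative script per capability
- `tests/` — pytest suite (unit, property and acceptance tests)
- `docs/methods.md` — modelling assumptions, parameter choices, numerical
  conventions and limitations
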