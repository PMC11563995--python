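# perfterr

Quantitative contrast-enhanced MRI estimation of the **relative arterial
contributions of the medial vs. lateral femoral circumflex arteries (MFCA /
LFCA)** to the trochanteric region of the proximal femur — for researchers in
orthopaedic vascular anatomy and quantitative imaging who need a tested,
reproducible implementation of the paired-hip perfusion-territory design.

## The method

The experimental design uses each donor as their own control. One hip (the
*experimental* hip) receives gadolinium contrast into a single artery (MFCA
or LFCA, randomized); the contralateral *control* hip is infused in **both**
arteries with equal doses, so its enhancement represents the total
MFCA + LFCA supply. Pre- and post-contrast volumes are acquired for both
hips; four bone regions of interest — greater trochanter (GT),
intertrochanteric (IT), lesser trochanter (LT), subtrochanteric (ST) — are
delineated on coronal slices, each split into anterior/posterior halves.

For each scan, intensities are normalized by the mean signal **m** of a
non-enhancing muscle reference region (division, so scanner gain cancels).
The enhancement of ROI *R* is

&nbsp;&nbsp;&nbsp;&nbsp;E(R) = ⟨I_post / m_post⟩_R − ⟨I_pre / m_pre⟩_R,

where ⟨·⟩_R is the count-weighted mean of per-coronal-slice ROI means
(identically the plain voxel mean). The infused artery's relative
contribution in region *R* is the experimental/control ratio, clipped to the
unit interval:

&nbsp;&nbsp;&nbsp;&nbsp;contribution% = 100 · clip( E_exp(R) / E_ctrl(R), 0, 1 ),

and the other artery's share is the complement (the pair sums to 100
exactly). Cohort cells are summarized as mean, SD, median and IQR, and MFCA%
is compared with LFCA% per cell by a **Mann–Whitney U test whose two-sided
p-value is exact for small samples**: all C(n_a+n_b, n_a) group assignments
of the observed pooled values are enumerated, which handles the tie-heavy,
0/100-clipped data without approximation.

Because the original cadaveric images are not publicly available, the
package ships a first-class **phantom generator** that emulates the full
design — paired hips, dual- vs. single-artery infusion, fat-suppressed
baseline, muscle reference, 2 mm coronal slices, per-region ground-truth
MFCA fractions with between-specimen variation — so every stage of the
pipeline is verifiable by parameter recovery.

## Worked example

```python
from perfterr import ArterialContributionModel, CohortConfig

model = ArterialContributionModel.from_simulation(CohortConfig(), seed=42)
results = model.fit()
print(results.summary())
print(f"cohort-mean recovery MAE: {results.recovery().mae:.2f} percentage points")
```

```
Relative arterial contributions (MFCA vs LFCA), n = 10 specimens
Region of perfusion            MFCA mean (SD)       MFCA median [IQR]   LFCA mean (SD)        p
-----------------------------------------------------------------------------------------------
Full trochanteric region        63.4% (11.5%)      61.2% [53.2-68.8%]    36.6% (11.5%)   <0.001
Subtrochanteric (ST)            71.7% (14.2%)      71.7% [63.4-79.7%]    28.3% (14.2%)   <0.001
Lesser trochanter (LT)          55.0% (18.1%)      56.5% [45.9-66.0%]    45.0% (18.1%)    0.280
Intertrochanteric (IT)          64.4% (20.0%)      64.2% [48.3-74.7%]    35.6% (20.0%)    0.004
Greater trochanter (GT)         54.8% (24.4%)      58.9% [44.6-65.6%]    45.2% (24.4%)    0.353
...
cohort-mean recovery MAE: 0.03 percentage points
```

Each row is one report cell: the cohort mean ± SD and median [IQR] of the
MFCA share, the complementary LFCA share, and the Mann–Whitney p-value for
the MFCA-vs-LFCA contrast. In this simulated cohort the MFCA dominates the
full trochanteric, ST and IT regions (p < 0.05) while the GT is balanced —
the qualitative pattern the estimator is designed to resolve. The recovery
MAE line compares the cohort-mean estimates against the simulation's known
ground truth.

The same analysis is scriptable from the shell:

```bash
perfterr simulate --seed 42 --out runs/demo          # phantom cohort + full report
perfterr analyze runs/demo/data/S*_manifest.json --out runs/reanalysis
perfterr report runs/demo/contributions.csv --out runs/tables
```

`simulate` writes NIfTI volumes, manifests, the truth table, per-specimen
enhancement and contribution CSVs, the 15-row summary table (CSV + text) and
a truth-vs-estimate recovery report; `analyze` runs the identical pipeline
on existing specimen manifests.

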