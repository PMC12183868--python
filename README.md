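# acidmri

Quantitative MRI analysis of tumor acidosis: from raw CEST and DCE
acquisitions to extracellular-pH maps, spatial heterogeneity metrics,
vascular pharmacokinetic maps, and cohort-level biomarker statistics.

## The problem

Aggressive, metastasis-prone tumors acidify their extracellular space
(pH_e well below the ~7.4 of normal tissue) through glycolytic metabolism
and poor vascular clearance. Two MRI methods measure this noninvasively in
the same session:

* **CEST-MRI with iopamidol.** Saturating the agent's amide protons at two
  pH-sensitive resonances (4.2 and 5.5 ppm from water) transfers signal
  loss to water. The saturation-transfer contrast at offset Δω is
  ST(Δω) = 1 − Z(Δω), where Z is the water signal normalized to the
  unsaturated reference. The post-minus-pre-injection difference
  ΔST cancels endogenous contributions, and the ratio of the two agent
  offsets cancels agent concentration, leaving a pure pH readout:

      pH_e = p0 + p1 · log10( ΔST(4.2 ppm) / ΔST(5.5 ppm) )

* **DCE-MRI with gadoteridol.** Serial T1-weighted imaging during contrast
  passage, converted to concentration via a variable-flip-angle T1 map, is
  fit with the extended Tofts model

      Ct(t) = v_p · Cp(t) + K^trans ∫₀ᵗ Cp(τ) e^{−(K^trans/v_e)(t−τ)} dτ

  yielding vessel permeability (K^trans), interstitial fraction (v_e) and
  plasma fraction (v_p) per voxel.

On top of the maps, the package computes spatial acidosis summaries — the
**acidity score** (voxel fractions in three pH bins, 7.0–7.4 / 6.7–7.0 /
6.0–6.7, weighted 1/2/3, so 1 = uniformly mild and 3 = uniformly highly
acidic), rim/core decompositions by morphological erosion, tumor growth
rates — and cohort statistics: t-tests, signed correlations, and ROC/AUC
with bootstrap confidence intervals and Youden-optimal operating points for
separating metastatic from non-metastatic tumor groups.

Because raw animal imaging data are not redistributable, a first-class
synthetic-data module generates digital tumor phantoms and two-group
cohorts with the statistical structure of a metastatic (4T1-like) vs
non-metastatic (67NR-like) murine breast-tumor study, giving every pipeline
stage a known ground truth.

## Worked example

```python
from acidmri.synthetic import simulate_cohort
from acidmri.stats import cohort_report

cohort = simulate_cohort(n_per_group=14, seed=1)   # 2 x 14 tumors
report = cohort_report(cohort, n_boot=2000, seed=1)

for metric in ("ph_e", "acidity_score"):
    s, r = report["summaries"][metric], report["roc"][metric]
    print(f"{metric}: metastatic {s['metastatic']['mean']:.2f} +/- {s['metastatic']['sd']:.2f}, "
          f"non-metastatic {s['non-metastatic']['mean']:.2f} +/- {s['non-metastatic']['sd']:.2f}")
    print(f"  AUC {r['auc']:.3f} (95% CI {r['ci_low']:.3f}-{r['ci_high']:.3f}), "
          f"sens {r['sensitivity']:.3f}, spec {r['specificity']:.3f}, J {r['youden']:.3f}")
```

prints

```
ph_e: metastatic 6.71 +/- 0.06, non-metastatic 6.81 +/- 0.05
  AUC 0.918 (95% CI 0.801-1.000), sens 1.000, spec 0.786, J 0.786
acidity_score: metastatic 2.11 +/- 0.07, non-metastatic 1.88 +/- 0.12
  AUC 0.954 (95% CI 0.862-1.000), sens 0.857, spec 0.929, J 0.786
```

i.e. the simulated metastatic group is more acidic (lower mean pH_e, higher
acidity score), and either metric separates the groups well; with only 14
tumors per group the AUC of any single draw scatters around its population
value, which the bootstrap CI makes explicit.

The full imaging chain is available from the shell:

```sh
acidmri simulate --out study/ --seed 1          # phantom + raw stacks
acidmri cest-ph  --pre study/cest_pre.nii.gz --post study/cest_post.nii.gz \
                 --s0-pre study/s0_pre.nii.gz --s0-post study/s0_post.nii.gz \
                 --mask study/mask.nii.gz --out study/cest/
acidmri dce-fit  --vfa study/vfa.nii.gz --dyn study/dce_dynamic.nii.gz \
                 --mask study/mask.nii.gz --config study/config.json --out study/dce/
acidmri heterogeneity --ph study/cest/ph.nii.gz --mask study/mask.nii.gz \
                 --depth 2 --out study/het/
acidmri run-study --seed 0 --out study/full/    # end-to-end 2x14-tumor demo
```

Exit codes: 0 success, 2 configuration error, 3 data error.

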