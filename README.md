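# strokefate

Quantitative MRI analysis of post-recanalization cerebral hemodynamics in
experimental (rodent) ischemia-reperfusion stroke.

Transient middle cerebral artery occlusion (tMCAO) followed by
recanalization does not always salvage tissue: outcome depends on how the
post-ischemic perfusion landscape evolves.  This package re-implements, as
a tested and fully synthetic-data-verifiable pipeline, the quantitative
chain that links multiparametric MRI at occlusion, 0.5 h and four days
after recanalization to tissue fate and functional outcome:

1. **Parametric maps** — mean ADC from two-point monoexponential fits
   (b = 0 / 1454 s/mm², three gradient directions) and T2 from
   variance-stabilized log-linear fits of multi-echo data
   (TE = 30/50/80/190 ms).
2. **DSC perfusion** — tissue concentration C(t) = −ln(S/S₀)/TE from a
   bolus-tracking series (TR/TE = 164/13 ms, bolus at the 180th image), an
   arterial reference curve extracted from the contralateral hemisphere,
   and CBF/CBV/MTT maps by block-circulant (oSVD) deconvolution with the
   truncation threshold chosen per voxel so the residue function's
   oscillation index stays below 0.17.  CBV integrates the concentration
   curve through the 400th image; MTT = CBV/CBF (central volume theorem).
3. **Lesion segmentation & tissue fate** — reference statistics (x̄, sd)
   from the contralateral MCA territory (S1FL, S2, CPu; CSF excluded);
   acute lesion = ADC < x̄ − 2sd, subacute infarct = T2 > x̄ + 2sd, with
   deterministic cluster/closing cleanup.  Fate algebra:
   core = acute ∩ subacute, salvageable = acute \ subacute,
   delayed injury = subacute \ acute; contralateral homologues by exact
   midline mirroring; lesion volume change =
   100 × (T2_volume − ADC_volume)/ADC_volume; subjects with acute lesions
   under 30 µL are flagged excluded.
4. **Perfusion profiles** — relative regional indices
   (rrCBF/rrCBV/rrMTT = ROI mean as % of the mirrored homologue) and
   voxel-class fractions after repercentaging to the contralateral median:
   hypo < 85%, normo 85–115%, hyper > 115% (reversed for MTT).
5. **Outcome models** — mixed models of the rr indices over session,
   occlusion duration (45/90 min) and sex; beta-family regression of the
   voxel-class fractions; and AICc-ranked multi-model inference of lesion
   volume change (Gaussian) and the sensorimotor deficit score
   (SDS 0–22, Poisson log-link), where rrMTT is never combined with
   rrCBF/rrCBV.

A synthetic module generates two-hemisphere phantoms with planted lesions
and full ground-truth ADC/T2/CBF/CBV/MTT, raw acquisitions (DWI,
multi-echo T2, gamma-variate-bolus DSC), and cohort tables with known
effect structure — so every stage is validated by parameter recovery
without the animal data.

## Worked example

Simulate and analyze a 40-subject cohort end to end (about a minute):

```bash
strokefate run-all --n-per-group 10 --seed 1 --out results/cohort
```

```
cohort of 40 subjects analyzed -> results/cohort
mean volume change by sex:
sex
F   -27.5
M     0.2
```

Female cells show the larger acute-to-subacute lesion volume reduction, the
effect structure planted in the generator (females salvage a larger share
of the acutely ischemic shell).  The written tables contain, per subject
and session, the rr perfusion indices and the hypo/normo/hyper fractions
per fate parcel; at day 4 the ipsilateral parcels are dominated by
hyperperfused voxels (mean fraction ≈ 0.44 vs ≈ 0.01 contralaterally).

The numbered scripts under `analysis/` run the same stages as narrative
steps: `01_simulate_and_run_cohort.py` (imaging pipeline),
`02_perfusion_recovery.py` (deconvolution bias/RMSE over planted CBF–MTT
grids at SNR ∞/100/50), `03_outcome_inference.py` (mixed models, fraction
model, AICc ranking).  The ranking on a default synthetic cohort:

```
        model  k    aicc  delta_aicc_vs_base  r2_adj   rmse  p_vs_base
rrCBF & rrCBV 10 383.888              -3.453   0.564 23.624      0.018
        rrCBF  9 386.337              -1.004   0.509 25.074      0.064
         base  8 387.340               0.000   0.469 26.074        NaN
        rrCBV  9 389.551               2.211   0.467 26.102      0.342
        rrMTT  9 390.245               2.905   0.458 26.330      0.552
         NULL  2 402.987              15.647  -0.000 35.766      NaN
```

The configuration carrying the generating coefficients (positive on rrCBF,
negative on rrCBV, none on rrMTT) ranks first.

Every stage is also available as a library call
(`strokefate.fit_adc`, `strokefate.osvd_deconvolve`,
`strokefate.classify_fate`, `strokefate.multimodel_inference`, ...) and as
individual CLI commands (`strokefate simulate|maps|perfusion|segment|fate|
profile|infer|run-all`).

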