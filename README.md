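# psmaquant

Quantitative response assessment for whole-body PSMA-PET in metastatic
castration-resistant prostate cancer (mCRPC). The package implements the
full pipeline used to monitor PSMA-targeted radioligand therapy with
[⁶⁸Ga]Ga-PSMA-11 PET/CT:

1. **SUV quantification** — activity maps (Bq/mL) are normalised to
   body-weight SUV: `SUV = C · w / A(t)`, with `C` the activity
   concentration, `w` the body weight in g and `A(t)` the injected
   activity decay-corrected to scan start (⁶⁸Ga half-life 67.71 min).
2. **Lesion segmentation** — voxels with SUV ≥ 3.0 outside caller-supplied
   physiological-organ masks are grouped into connected components; liver
   lesions are segmented at `1.5 × SUV_mean` of healthy liver tissue.
3. **Tumour burden** — molecular tumour volume `MTV = Σᵢ Vᵢ` (mL) and
   total lesion PSMA `TLP = Σᵢ Vᵢ · SUV_mean,ᵢ` (mL × SUV), the PSMA
   analogue of total lesion glycolysis.
4. **Response classification** — modified PERCIST on ΔTLP/ΔMTV
   (PR: decrease > 30 %; PD: increase > 30 % *or* new metastases;
   SD: otherwise) and PCWG3 on ΔPSA (PR: decrease > 50 %;
   PD: increase > 25 %; SD: otherwise).
5. **Statistics** — response concordance, tie-corrected Spearman
   correlation screens, Kaplan–Meier estimation with Brookmeyer–Crowley
   median CIs, and the two-group log-rank test.
6. **Synthetic data** — ellipsoid phantoms with known analytic volumes and
   statistically realistic response cohorts, so every stage is testable
   without any image download, plus a packaged 17-patient reference
   cohort with published response calls for regression testing.

Intended for nuclear-medicine and imaging-biomarker researchers who need
a reproducible, scriptable implementation of whole-body PSMA burden
response criteria.

## Worked example

Classify the packaged 17-patient reference cohort:

```python
from psmaquant import assess_cohort, concordance, reference_cohort

records, _ = reference_cohort()
result = assess_cohort(records)
print(result.frequencies)
call = next(c for c in result.calls if c.patient_id == "8")
print(f"patient 8: dTLP {call.delta_tlp_pct:+.1f}% -> {call.tlp_response}, "
      f"dPSA {call.delta_psa_pct:+.1f}% -> {call.psa_response}")
tlp = [c.tlp_response for c in result.calls]
psa = [c.psa_response for c in result.calls]
conc = concordance(tlp, psa)
print(f"imaging vs PSA concordance: {conc.n_agree}/{conc.n_total} = {100*conc.fraction:.1f}%")
```

prints

```
          tlp_n  tlp_pct  mtv_n  mtv_pct  psa_n  psa_pct
response
PR            5     29.4      5     29.4      5     29.4
SD            7     41.2      7     41.2      8     47.1
PD            5     29.4      5     29.4      4     23.5
patient 8: dTLP -83.0% -> PR, dPSA -94.3% -> PR
imaging vs PSA concordance: 12/17 = 70.6%
```

Reading: by imaging criteria 5/17 patients (29.4 %) reached partial
remission, 7 (41.2 %) were stable and 5 (29.4 %) progressed; the TLP and
MTV verdicts agree for every patient, while imaging and PSA agree for
12/17 (70.6 %). Patient 8's tumour burden fell by 83 % and PSA by 94 % —
a concordant partial remission.

The same pipeline runs from the shell. A synthetic two-arm survival
analysis (partial remission vs. stable/progressive disease, exponential
hazards 0.03 vs 0.10 per month):

```sh
psmaquant simulate --seed 7 --n-patients 200 --out sim
psmaquant survival --survival sim/survival.csv --out surv
```

```
"PR":       { "n": 53,  "events": 24,  "median_months": 24.136, "median_ci": [15.838, "undefined"] }
"SD_or_PD": { "n": 147, "events": 121, "median_months": 6.059,  "median_ci": [4.978, 9.038] }
```

The non-remission arm's Kaplan–Meier median of about 6.1 months sits near
the theoretical ln 2 / 0.10 ≈ 6.9 months; the remission arm survives far
longer, as expected from its three-fold lower hazard.

Subcommands: `simulate`, `segment` (NIfTI SUV volume + organ masks →
per-lesion CSV, burden CSV, label map), `assess` (cohort CSV →
change/response table and concordance summary), `survival` (survival CSV
→ per-group KM curves, medians with CIs, log-rank p).

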