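# Methods

## SUV model

Images are body-weight SUV (SUVbw); lean-body-mass variants are out of
scope because SUVbw is the standard reporting convention for
[⁶⁸Ga]Ga-PSMA-11. The conversion from an activity-concentration map is

    SUV(x) = C(x) [Bq/mL] · w [g] / A_dc [Bq],
    A_dc   = A_inj · 2^(−Δt / T½),

with the injected activity decay-corrected from injection to **scan
start** (Δt in minutes, default T½ = 67.71 min for ⁶⁸Ga, overridable per
acquisition). Grids are index-ordered (x, y, z), 0-based, voxel-centre
convention: physical position = origin + index · spacing. Masks must
share the exact grid of their image; any mismatch in shape or frame is an
error, never a silent resample.

## Segmentation

Tumour voxels are those with SUV ≥ 3.0 (inclusive — the threshold
convention is a design choice; common vendor tools include the boundary
value) lying outside all physiological exclusion masks and outside the
liver. Connected components are labelled with 26-neighbourhood
connectivity by default (6/18 configurable) and components below
`min_voxels` (default 1, i.e. nothing dropped) are discarded. Liver
lesions are segmented separately at `liver_factor × SUV_mean(healthy
liver)` with `liver_factor = 1.5`, over a caller-supplied healthy-liver
reference mask; no iterative lesion-free re-estimation of the reference
is attempted, mirroring the manual clinical workflow. Supplying a liver
mask without a healthy-liver reference is rejected rather than guessed.

Physiological exclusion is mask-based and caller-supplied. The package
performs no automatic organ detection: in clinical use these regions are
drawn by a reader, and the synthetic phantoms provide them as ground
truth.

SUV_peak is the mean SUV inside a 1 mL sphere (radius 6.204 mm) centred
at the lesion's hottest voxel, voxelised by centre-inclusion and clipped
to the grid — a PERCIST-style convention adopted here as the definition.

### Longitudinal matching

New-metastasis detection in practice is a reader decision. The automatic
surrogate pairs pre/post lesions greedily by ascending centroid distance
with a 15 mm acceptance radius on co-registered frames; unmatched
post-therapy lesions are *candidate* new metastases. The per-patient
`new_metastases` flag on a record always takes precedence in
classification, so a manual adjudication overrides the matcher.

## Burden metrics

MTV is voxel count × voxel volume; TLP is Σᵢ MTVᵢ · SUV_mean,ᵢ, which is
algebraically identical to the voxelwise sum of SUV × voxel volume over
all lesion voxels — the test suite asserts this identity exactly, since
it pins down both the statistics and the bookkeeping. All internal
arithmetic is double precision; TLP/MTV are rounded to one decimal only
in CSV exports.

## Response classification

Modified PERCIST on whole-body burden: PR iff Δ < −30 %, PD iff
Δ > +30 % or new metastases, SD otherwise. Band edges are strict
inequalities (exactly −30 % → SD), reading "decrease of > 30 %"
literally. The new-lesion override dominates: any Δ with new metastases
is PD. The headline imaging call is the TLP verdict; the MTV verdict is
computed and reported alongside, and a disagreement is logged as a
warning, not resolved.

PCWG3 on PSA: PR iff Δ < −50 %, PD iff Δ > +25 %, SD otherwise — on a
single post-therapy measurement, a documented deviation from full PCWG3,
which asks for confirmation by a second value.

Percent changes are undefined for a non-positive baseline; such records
are rejected individually (logged, run continues). Classification uses
unrounded deltas; the 1-d.p. values in outputs are display only.

## Statistics

- **Concordance**: elementwise agreement fraction plus the full 3×3
  PR/SD/PD cross-table; the table's marginals equal the per-method
  frequency tables.
- **Spearman correlation**: Pearson on average ranks (tie-corrected).
  Two-sided p by exhaustive permutation of one ranking for n ≤ 10 and by
  the t-approximation for larger n. A constant vector yields an
  undefined (NaN) coefficient rather than an error. Where a literature
  coefficient's flavour is ambiguous, `pearson` is provided so both can
  be reported side by side. The correlation screen is pairwise-complete
  per cell (a cell with < 3 complete pairs is undefined) and applies no
  multiplicity adjustment: each cell carries its raw p.
- **Survival**: death is the event; treatment switch and last study
  visit are right-censoring — the standard reading when an interval end
  is not labelled. Kaplan–Meier fitting delegates to lifelines; the
  median is the earliest t with S(t) ≤ 0.5 ("not reached" when the curve
  stays above 0.5). The 95 % CI for the median is Brookmeyer–Crowley on
  the log scale: the set of event times where
  |log S(t) − log 0.5| ≤ 1.96 · se(log S(t)), with the Greenwood
  variance of log S; a CI side is undefined when the region reaches the
  end of follow-up. The log-rank test (lifelines) is the standard
  (O−E)²/V chi-square(1) two-group test; with zero events it is reported
  undefined rather than raised.
- **Cohort summaries**: standard sample medians and min–max ranges of
  TLP/MTV/PSA pre and post.

## Synthetic data

The phantom generator emulates whole-body PET geometry only as far as
the quantification pipeline needs: uniform-uptake ellipsoids (lesions
and hot organs) rasterised by voxel-centre inclusion on a configurable
grid, optional isotropic Gaussian blur as a crude partial-volume
surrogate, and additive Gaussian noise in SUV space clipped at zero.
Ground truth carries the analytic ellipsoid volume 4/3·π·abc. It does
*not* model Poisson emission statistics, reconstruction artefacts,
scanner resolution anisotropy or realistic anatomy — passing phantom
tests therefore demonstrates correctness of thresholding, labelling and
burden arithmetic under idealised uptake, not robustness to real
reconstruction noise.

The cohort generator draws baseline TLP log-normally (median 3685
mL × SUV, log-sd 0.75, spanning roughly 7×10² to 1.4×10⁴ — the magnitude
range of real whole-body PSMA burden measurements, so synthetic-scale
and fixture-scale tests exercise the same numbers), derives MTV from TLP
through a patient-level mean uptake (SUV ≈ 8), and draws PSA
log-normally (median 152 ng/mL, log-sd 1.5) coupled to log TLP only
through an explicit Gaussian-copula correlation whose default is 0 —
baseline imaging burden and PSA are treated as independent axes, which
is what the reference cohort's near-zero baseline correlation suggests.
Response classes come from a mixture (defaults 5/17 PR, 7/17 SD, 4/17
PD, 1/17 PD-by-new-lesion); class-conditional percent changes are
uniform on bands chosen strictly inside the classification bands
(PR: −90 to −35 %, SD: ±28 %, PD: +35 to +300 %) so the label is
recoverable from the generated record; a scenario whose Δ support
contradicts its class label is rejected at construction. By default the
uptake change is zero, so ΔTLP = ΔMTV and the two imaging verdicts are
concordant by construction. Survival is exponential per response group
(defaults: hazard 0.03/month for PR, 0.10/month otherwise), with
independent exponential censoring (default 0.02/month) and an
administrative cut-off (default 30 months). One integer seed fixes every
volume and cohort bit-for-bit.

### Packaged reference cohort

A 17-patient mCRPC cohort with published per-patient pre/post TLP, MTV
and PSA values, new-metastasis flags, and reference deltas and response
calls is embedded for regression testing (`reference_cohort`). The
published absolute values above 15 are display-rounded to whole numbers
while the published change column was computed from unrounded source
data, so a change recomputed from the embedded values can differ from
the published one by a small, bounded propagation of that rounding
(≤ ~0.3 percentage points); `reference_cohort_precision` exposes the printed
half-widths so tests can bound the discrepancy by exact interval
arithmetic. All 51 response calls are reproduced exactly regardless,
because no patient's delta lies near a band edge.

## Problem sizes used in the validation suite

Phantom recovery runs on (2 mm)³ grids of 64³–129³ voxels with a
refinement check at 1 mm; Monte-Carlo checks use 1000 null replicates
and 200 alternative replicates (n = 50–100 per arm) for the log-rank
operating characteristics, n = 500 for Kaplan–Meier median recovery
against ln 2/λ, and n = 1000 cohorts for mixture-frequency and copula
recovery. These sizes keep each property estimate's Monte-Carlo error
well inside the asserted tolerances.

## Known limitations

- Fixed-threshold segmentation underestimates lesions with uptake near
  the threshold and is sensitive to background spill-in at coarse voxel
  sizes; percentage-of-max isocontours (41 %/50 %) are deliberately not
  implemented.
- The centroid matcher is a surrogate for reader-based new-lesion
  adjudication and will mislabel large displacements or merging lesions;
  the manual flag exists precisely for those cases.
- PCWG3 confirmation by a second PSA measurement is omitted (single
  follow-up design).
- No image registration is performed; longitudinal comparisons assume
  co-registered frames.
- Survival tooling covers KM, median CIs and the two-group log-rank
  only; no Cox regression or competing risks.
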