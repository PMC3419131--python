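# Methods

`rhcmr` implements the right-heart cardiac MR (CMR) measurement chain used to
screen for pulmonary hypertension (PH) — defined throughout as a mean
pulmonary artery pressure (mPAP) ≥ 25 mmHg at right heart catheterisation —
together with the diagnostic-accuracy statistics that evaluate each
measurement against that invasive reference, and synthetic generators that
make the whole chain testable without patient data.

## Volumetry and mass (Simpson slice summation)

Cavity volume at a cine phase is

    V = Σ_slices A_slice × Δz

where `A_slice` is the shoelace area of the endocardial polygon (mm²,
computed via `shapely`, which also rejects self-intersecting outlines) and
`Δz` is the effective inter-slice distance: slice thickness plus gap (the
default acquisition is 8 mm + 2 mm → 10 mm; the contour format carries
`slice_spacing_mm` explicitly so other protocols work unchanged). Slices
without a contour contribute zero — no basal or apical extrapolation,
matching manual workstation practice.

End-diastole (ED) is cine phase 0 (first phase after the R-wave trigger).
End-systole (ES) is the phase minimising the *summed* endocardial volume,
ties broken to the earliest phase; per-slice minima would compose a
non-physical phase. ES is selected on the RV endocardium for RV metrics;
`select_ed_es_phases` is public and takes a structure argument, so a caller
who wants an independently selected LV ES phase can do so (both conventions
are defensible; the default work-up only needs LV contours at ED, for mass).

Derived quantities: SV = EDV − ESV, EF = 100·SV/EDV; myocardial volume per
slice is (epicardial − endocardial area)·Δz, and mass is that volume times
the density of myocardium, 1.05 g/cm³. The inter-ventricular septum belongs
to the LV: the RV epicardial contour must trace only the free wall. The
ventricular mass index VMI = RV mass / LV mass is therefore a free-wall /
(septum + LV free wall) ratio. BSA-indexed variants divide by body surface
area; when height/weight are supplied instead of BSA, the Du Bois formula
0.007184·h^0.725·w^0.425 is used (cohort files may carry BSA directly and
bypass it).

## Functional indices

All from manual landmarks. TAPSE is the ED−ES change of the tricuspid
annulus–apex distance (cm); fractional TAAD divides it by the ED distance.
Transverse function uses the septum–free-wall distance (SFD) at the
mid-ventricular level; the "mid-point between apex and base" is realised as
the annotator's septal/free-wall mid-points (the generator places them at
50% of the apex–annulus axis). RVRAC = 100·(ED area − ES area)/ED area on
the 4-chamber view. LV eccentricity is D2/D1 on the mid-chamber short-axis
slice, D2 parallel and D1 perpendicular to the septum, same formula at ES
(sEI) and ED (dEI); values > 1.2 indicate septal flattening. Excursions are
signed: paradoxical motion yields negative values and is never clamped,
since screening thresholds operate on the signed value.

## Phase-contrast PA flow

Frames are uniform bins of the cardiac cycle (retrospective gating), so each
frame lasts RR/n and per-beat volumes are plain sums — bin averages, not
samples, hence no trapezoidal weighting. Instantaneous flow is Σ velocity ×
pixel area over the PA mask (cm³/s ≡ mL/s, antegrade positive). Retrograde
volume per beat sums the magnitude of negative-velocity pixel flow; the
retrograde flow index converts to L/min (60/RR beats per minute) and divides
by BSA. Percent retrograde flow uses the antegrade volume per beat as
denominator (a convention choice; the denominator is not dictated by the
index's definition) and is returned as NaN when no antegrade flow exists.
PA areas are mask pixel counts × pixel area; the PA relative area change is
100·(max − min)/min over the cycle — note the *minimum*-area denominator,
unlike RVRAC. Velocity aliasing is out of scope; inputs are assumed
unwrapped (venc 150 cm/s covers the PA in practice).

## Echo pressure chain

TG = 4·TRJV² (modified Bernoulli; TRJV in m/s — cohort tables sometimes
label the column cm/s, but the magnitudes only make sense in m/s, and the
package treats them so), PASP = TG + estimated RA pressure, and
mPAP ≈ 0.61·PASP + 2 mmHg (published regression). All three steps are
exposed individually plus the composed `echo_mpap`.

## Diagnostic statistics

Threshold rules carry an explicit direction (`GE_POSITIVE` / `LE_POSITIVE`)
with inclusive cutpoints; directions are declared per metric, never inferred
from data. Records missing a metric are dropped from that metric's analysis
only, reproducing per-analysis denominators when sub-studies (phase
contrast, LGE, echo) cover subsets. Fisher's exact test is two-sided by the
minimum-likelihood convention (sum of tables with probability ≤ observed;
`scipy.stats.fisher_exact`), cross-checked in the tests against an
exhaustive hypergeometric enumeration for all small tables. ROC AUC is the
rank-based (Mann–Whitney) estimator with midrank ties — our own
implementation, cross-checked against scikit-learn; for a binary marker it
reduces exactly to (sensitivity + specificity)/2, which is also the
`binary_test_auc` used for LGE. Group comparisons: Student t (pooled
variance; Welch by flag), chi-square for categorical data, one-way ANOVA
with Bonferroni-adjusted pairwise t-tests (factor = number of pairs) beyond
two groups. Bland–Altman: differences obs1 − obs2, bias = mean, SD with
ddof = 1, limits of agreement bias ± 1.96·SD. Everything upstream keeps full
precision; table-style rounding (integer percents rounded half-up, AUC and r
to 2 dp) happens only in the reporting layer.

`ppv_from_sens_spec` reconstructs predictive values from published
sensitivity/specificity at a given prevalence via Bayes:
PPV = s·p/(s·p + (1−c)(1−p)).

## Synthetic phantoms

Ventricle phantoms are stacks of polygonized circles: concentric
endo/epicardial rings per ventricle, cavity area scaled through the cycle by
a piecewise-sin² curve with its single minimum at a declared ES phase.
Ground truth is closed-form (cylinder πr²h; half-ellipsoid slice radii
a·√(1−z²/c²); shell mass = ring area × height × 1.05). The only systematic
extraction error is the regular-n-gon area deficit, (n/2π)·sin(2π/n)
(≈0.16% at the default 64 vertices), so cylinder and half-ellipsoid volumes
converge well inside 1% of the analytic values at 64 vertices and 1 mm
spacing.

Velocity phantoms place a parabolic antegrade jet over the systolic half of
the cycle and a uniform retrograde patch over diastole, then rescale both
patterns so the *discrete* per-beat volumes equal the request exactly — the
generator's truth and the flow module's extraction must then agree to float
precision. A requested cycle-mean velocity sets the mask size
(A = net volume / (RR × v̄), corrected for area modulation); requested area
pulsatility modulates the mask sinusoidally while velocities stay inside the
minimal mask, leaving flows untouched.

## Synthetic cohorts

The default cohort emulates a suspected-PH referral population: 39 no-PH /
194 PH, with per-group mean ± SD for 21 haemodynamic, echo and CMR metrics,
per-group LGE rates (2/31 and 108/128), PH aetiology mix
(28 IPAH / 39 PAH-CTD / 16 other PAH / 21 left-heart / 29 respiratory /
59 CTEPH, apportioned by largest remainder — the published subgroup counts
are internally inconsistent by two patients, so proportional apportionment
is used), and sub-study coverage (LGE 31 + 128 = 159; phase contrast 106 and
echo 195 split proportionally between groups, since the source splits are
not published).

Sampling is a one-factor Gaussian copula: a latent standard normal drives
mPAP; each metric's latent is correlated with it and metrics are
conditionally independent given mPAP. Marginals are truncated normals —
mean ± SD is all the source tables give, and physiologic floors (VMI > 0,
EF ∈ [0, 100], areas > 0, …) require truncation. Two numerical devices keep
the targets honest:

* **moment matching** — the parent (μ, σ) is solved (scipy root-finding on
  `truncnorm` moments) so the *truncated* mean/SD equal the specified
  values; a lower-truncated normal cannot reach (mean − lower)/SD ≤ 1, which
  is why PVR (149 ± 167 in the no-PH group) is left unbounded rather than
  floored at zero;
* **NORTA correlation calibration** — the latent correlation is solved
  (Gauss–Hermite quadrature + Brent) so the achieved *Pearson* correlation
  after the nonlinear marginal transforms equals the target, compensating
  the attenuation the truncation would otherwise cause.

The no-PH mPAP marginal is truncated above 25 mmHg and the PH marginal below
at 25, so group labels derived from drawn mPAP satisfy the PH definition by
construction. TRJV–mPAP (0.70) and PVR–mPAP (0.80) correlations are not
published for this population; the defaults are field-realistic values fixed
once in the recipe YAML. Table-3-style subgroup marginals are not modelled —
subgroups are labels only (one published subgroup SD, CTEPH VMI ± 3.1, is an
evident misprint, a further reason not to build on those rows).

What the generator does **not** emulate: non-normal skew of real
haemodynamic variables, metric–metric dependence beyond the shared mPAP
factor, missingness that is informative rather than random within group, and
measurement error correlated across metrics from a single scan. Passing
recovery tests therefore validates the arithmetic of the measurement and
statistics modules, not clinical performance on real patients; simulated
sensitivities/specificities of the screening rules will track the published
ones only approximately (they depend on distributional shape, not just
moments).

## Problem sizes and numerical choices

Recovery checks run at n = 10 000 per group, where the Monte-Carlo standard
error of a metric mean is SD/100 — small enough to resolve the 0.01
tolerances used for the VMI marginal — and correlation checks at ±0.02
(≈5 SE). Phantom convergence uses 64-vertex polygons at 1 mm spacing. The
reporting layer rounds half-up (clinical convention) via `decimal`, not
banker's rounding. The pipeline is deterministic: identical seeds produce
byte-identical cohorts and reports.

## Known limitations

Volumetry has no papillary-muscle or trabeculation rules and no long-axis
(biplane) mode. Phase-contrast processing assumes a supplied PA mask per
frame (no segmentation, no background-phase correction). The echo chain
takes TRJV and RAP as inputs (no IVC-based RAP rules). AUC confidence
intervals and multivariable modelling are out of scope.
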