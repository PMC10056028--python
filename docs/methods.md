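# Methods

## Problem and quantities

¹⁸F-DOPA concentrates in cells expressing the LAT transporter and the AADC
enzyme. In nigrostriatal dysfunction (NSD) striatal uptake falls — typically
asymmetrically and in the posterior (distal) putamen first — while pineal-body
uptake is often elevated. The package implements the uptake statistics used to
turn these observations into scan-level calls:

* **POR** = pineal SUVmax / mean(right, left occipital SUVmean). Occipital
  cortex serves as a nonspecific reference region, so the ratio cancels
  global-uptake variability (injected dose, body habitus, scanner scaling).
  Positive at POR ≥ 1.57.
* **Pineal SUVmax** thresholded directly at ≥ 0.72.
* **SBR** = (striatal region counts − background counts) / background counts,
  computed per atlas region from VOI SUVmeans (any common scale cancels).
  A patient's SBR is compared with a normal reference as a Z-score; the
  automated basal-ganglia call (AM-BG) is positive when any region's z < −2.
  The rule is one-sided low because the disease signature is uptake
  *reduction*; the boundary is strict (z exactly −2 is negative). A config
  option restricts triggering to chosen regions (e.g. posterior putamina).
* **Two-stage interpretation rule**: a positive expert visual read (VA-BG) is
  final; a negative or equivocal visual read falls back to POR ≥ 1.57.
  Equivocal reads are routed exactly like negative ones, so in a cohort with
  no equivocal reads the rule is identically OR(VA-BG, POR ≥ 1.57) — asserted
  as a structural property in the tests.

All binary criteria use the inclusive convention: value ≥ cutoff is positive.

Performance metrics (sensitivity, specificity, accuracy, PPV, NPV) are kept
as exact integer fractions; percentages are rendered by half-up rounding to
one decimal. Published tables contain three cells where the printed value is
a truncation rather than a half-up rounding of the exact fraction
(68/69 → printed 98.5 vs 98.6; 29/30 → 96.6 vs 96.7; 29/51 → 56.8 vs 56.9),
and one same-fraction inconsistency (44/69 printed 63.8 in one table and 63.7
in another). The exact fractions are authoritative throughout; table
verification therefore compares integer counts, never printed decimals.

Association between group and call uses Pearson's χ² without continuity
correction, falling back to Fisher's exact test when any expected cell count
is below 5; p-values are two-sided. Published significance statements are
bounds (p < 0.01) and are asserted as bounds.

## Reconstructed cohort

The clinical dataset behind the published analysis is not deposited, but its
binary structure is fully determined by the printed per-group counts. For
each diagnosis group the pairwise joint of (VA-BG, AM-BG) and of (VA-BG,
POR ≥ 1.57) is recovered by inclusion–exclusion from the marginal, AND and OR
counts (`reconstruct_joint_counts`, validated against all printed OR cells).
Indicators the tables do not jointly constrain — which particular records
carry the SUVmax ≥ 0.72 and visual-pineal flags, and the cross-assignment of
AM-BG vs POR within visual-read strata — are assigned independently at
random. The binary joint structure used by every table is therefore
seed-independent; the seed only shuffles records and draws continuous values.

Continuous values are sampled consistently with each record's indicators:
pineal SUVmax from the group's log-normal truncated on the correct side of
0.72, POR from the group's log-normal truncated at 1.57, and occipital means
derived as SUVmax/POR with a small random right–left asymmetry (≤ 5%),
so the stored fields always reproduce the record's POR exactly.

**Cutoff-recovery construction.** Within each side of the 1.57 boundary the
pooled sampled POR values are sorted and the two classes are interleaved by
rank (evenly spread, validated by an explicit prefix/suffix dominance check
with a guaranteed-valid fallback ordering). The check enforces that for every
candidate threshold above the boundary the lost sensitivity exceeds the
gained specificity, and conversely below it; with the published group sizes
(69/43) exact ties are impossible, so the empirical Youden-optimal threshold
is unique at the boundary on every seed and dichotomizing there reproduces
the published 44/69 vs 11/43 split. The reconstructed cohort's within-side
orderings are thus a construction, not an estimate: its empirical POR AUC
(≈ 0.69) is a by-product, and distributional fidelity is the parametric
generator's job, not this mode's.

## Parametric generator and calibration

Parametric cohorts model, per diagnosis group, pineal SUVmax and occipital
SUVmean as log-normals sharing a per-patient global-uptake factor:

    suvmax = exp(mu_g) * G * eps_p,   occ = exp(mu_occ) * G * eps_o,
    G ~ LN(0, 0.30),  eps_p ~ LN(0, 0.30),  eps_o ~ LN(0, 0.15)

POR = suvmax/occ cancels G, so its marginal log-SD (√(0.30² + 0.15²) = 0.335)
is smaller than SUVmax's (√(0.30² + 0.30²) = 0.424). For two log-normals
with common σ the AUC is Φ(Δμ/(σ√2)); with the shipped group separation
Δμ = 0.2625 this gives AUC ≈ 0.71 for POR and ≈ 0.67 for SUVmax — the
clinically observed ordering in which the normalized ratio discriminates
better than the raw SUV. The location parameters place the group medians at
POR ≈ 1.77 (NSD) / 1.32 (non-NSD) and occipital SUVmean ≈ 0.51, plausible
for this tracer. With Δμ pinned by the two AUCs, the implied exceedance
rates at the fixed cutoffs land near but not exactly on the published
positivity rates; the calibration targets are the AUCs only. All defaults
are recorded in `src/dopapet/data/cohort_spec_default.json`.

Visual-read calls are drawn per group from configurable
sensitivity/specificity (defaults 61/69 and 40/43) with an optional
equivocal rate (default 0) to exercise the fallback branch of the two-stage
rule.

## Phantoms and the measurement layer

Phantoms are piecewise-constant SUV volumes on a 2 mm isotropic 96×112×96
grid centred on the world origin: ellipsoidal striatal nuclei, occipital
cortices, a small pineal sphere (r = 4 mm, volume ≪ 1 cm³) and a uniform
background, plus optional Gaussian noise truncated at zero. Healthy levels:
striatum 2.2–2.4, occipital 0.5, pineal 0.45, background 0.35 SUV; the NSD
pattern reduces the posterior putamina asymmetrically (0.9 / 1.3) and raises
the pineal to 1.3, giving noiseless POR values of 0.9 (healthy) and 2.6
(NSD) on either side of the 1.57 cutoff. A phantom pair shares its noise
realisation, so unmodified regions are voxel-identical.

VOI extraction uses center-in-sphere voxel membership with an inclusive
boundary (≤ r), r = (3V/4π)^(1/3) (1.5 cm³ → r ≈ 7.10 mm); voxel centers sit
at origin + index·spacing with a diagonal affine. The same 1.5 cm³ default
applies to every VOI (overridable per VOI). Striatal "counts" for the SBR
are VOI SUVmeans — any common summarization scale cancels in the ratio.
The shipped normal reference model is *synthetic*: fitted (sample SD, n−1)
from simulated healthy phantoms, standing in for a scanner normative
database that is not publicly available for this tracer.

Phantoms deliberately omit scanner physics (PSF, attenuation,
partial-volume, Poisson counting), anatomy and inter-subject geometric
variability, and the volumes are born aligned to the VOI atlas — no
registration is modelled. Passing phantom tests therefore validate the
geometry and arithmetic of the measurement layer, not robustness to real
acquisition effects or template-registration error.

## ROC and cutoff selection

ROC points are computed at every distinct observed score plus a +inf
sentinel (via scikit-learn, `drop_intermediate=False`); AUC is the
trapezoidal area, which the tests verify equals pairwise Mann–Whitney
concordance with ties counted ½ against a brute-force oracle. Cutoff
selection maximizes sensitivity + specificity with deterministic tie-breaks
(higher specificity, then lower cutoff); for all-tied scores the sentinel is
selected with Youden sum 1.0 (chance). Using observed values rather than
midpoints makes selected cutoffs attainable data values, matching how the
clinical cutoffs 0.72 and 1.57 were reported.

## Problem sizes and determinism

Default problem sizes — 112-subject reconstructed cohorts, 2000-per-group
parametric cohorts for AUC checks, 16³ grids for brute-force VOI oracles and
the default grid for end-to-end phantom runs — keep the full suite and the
acceptance script to a few seconds while leaving Monte-Carlo standard errors
well inside the asserted tolerances (e.g. AUC SE ≈ 0.008 at n = 2000/group
against a ±0.05 band). Every stochastic step takes a single integer seed
through `numpy.random.default_rng`; property tests are derandomized.

## Known limitations

* The reconstructed cohort reproduces binary joint structure and
  cutoff-splits exactly, but its continuous values are draws from calibrated
  families — per-patient SUVs of the original study are not recoverable.
* Joints the published tables never print (e.g. AM-BG × POR, any three-way
  joint) are unconstrained and vary with the assignment seed.
* AM-BG on real scans depends on template registration and a proprietary
  normative database; here it is either input data (cohorts) or a synthetic
  reference (phantoms).
* The visual reads (basal ganglia and pineal) are human judgements and are
  always modelled as input data, never computed from images.
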