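# Methods

## Scope and intent

`podosim` is a ground-truthed virtual laboratory for podometrics in a
progressive glomerular disease setting modeled on the obese Zucker (fa/fa)
rat. The package has two halves that meet at a tidy-table interface:

1. a **generator** that simulates longitudinal cohorts whose truth has the
   statistical structure the analysis assumes (growing glomeruli, linear
   podocyte loss, density-driven albuminuria, detachment-driven urinary
   mRNA excretion), and
2. an **estimation layer** that re-implements the measurement chain used
   on real tissue: profile stereology, thickness-corrected nuclear
   counting, area-fraction volumetry, standard-curve qPCR, budget
   accounting and nonparametric statistics.

Because the estimators only ever see what a microscope or thermocycler
would report (profile radii, slab counts, Cq values), recovery of the
configured truth is a genuine end-to-end test of the methodology.

## Cohort generator

**Arms and trajectories.** An `ArmConfig` fixes, per week of age, the true
mean tuft volume, GLEPP1⁺ volume fraction, phospho-S6-positive podocyte
fraction, hormone means and mRNA excretion. Weekly lookups interpolate
linearly between configured weeks and clamp at the ends. Podocyte number
follows `N(w) = N₀ + s·(w − w_ref)` with slope `s ≤ 0`, floored at zero.

**Hierarchy of variation.** Animals carry multiplicative lognormal effects
(CV 15% by default) on the volume trajectory and on the starting count;
the loss slope is common to all animals, so arm means track the configured
slope and a pooled OLS of per-animal estimates is an unbiased slope
recovery. Within an animal-week, glomerular volumes are lognormal
(CV 20%) and per-glomerulus density is lognormal (CV 15%) around the
animal mean, with realized counts Poisson. All CVs are config fields; the
defaults are field-plausible choices, not published values.

**Albuminuria.** 24-h albumin is a piecewise-linear function of the true
animal podocyte density through anchor points
(density per 10⁶ µm³ → mg/day): fa/fa (100 → 10), (82 → 20), (65 → 100),
extended with (45 → 300), (150 → 2), (250 → 0.5); the lean arm stays below
1 mg/day at density 100. Multiplicative lognormal noise (σ = 0.25)
preserves positivity and produces a realistic scatter. The R² of albumin
against estimated density is an emergent property of this link plus the
measurement noise; it is reported, not calibrated.

**Urinary mRNA truth.** When `podocin_linked_to_detachment` is set, the
true podocin excretion is `|s|·G/7 · c_p · f` copies/24 h (`G` glomeruli
per animal over two kidneys, default 60,000; `c_p` copies per podocyte,
default 50; recovery fraction `f`, default 0.75). This makes the podocyte
budget close by construction: with `f = 1` and no noise, the urinary
pellet accounts for exactly 100% of the morphometric loss, and the
packaged `f = 0.75` yields the ≈75% closure the budget reports. Arms
without a declining count (lean control, calorie-restricted) configure
podocin explicitly; the control level is set 88-fold below the fa/fa
plateau relative to the shared aquaporin2 reference. Collections are
overnight timed samples (mean 17 h, SD 1.5 h, clipped to 8–24 h); copies
collected scale with duration, and between-collection biological noise is
lognormal (σ = 0.30).

**qPCR instrument model.** Cq = m·log₁₀(copies) + b with m = −3.3219
(100% amplification efficiency) and b = 35 (Cq of one copy), additive
Gaussian Cq noise (σ = 0.15), a detection cutoff at Cq 40 (censored to
zero copies), and a 10⁶→10¹ serial dilution series with two replicates
per point for curve fitting. Fluorescence-level amplification curves are
out of scope; Cq is the primitive.

**Sclerosis labels.** Each glomerulus is flagged sclerotic with
probability `clip((50 − D_g)/13, 0, 1)` where `D_g` is its realized
density per 10⁶ µm³ — zero risk above the density threshold of 50, rising
linearly below it. The span of 13 was fixed by a design-time expectation
calculation so that the packaged 46-week fa/fa density distribution
(mean 45/10⁶ µm³) yields a ≈47% profile-level sclerosis index; it was not
adjusted afterwards.

**Packaged scenarios.** `fafa-vs-control` runs weeks 6/15/30/46 with n = 6
per arm; the fa/fa volume trajectory {1.467, 2.066, 2.834, 3.564}×10⁶ µm³
is derived from the count trajectory and the target densities
150 → 100 → 65 → 45, and the lean control is 1.6-fold smaller at week 6.
`calorie-restriction` switches diet at week 15: the CR arm's volume growth
nearly stops (density stabilizes at 82/10⁶ µm³ by week 30, phospho-S6
positivity falls 78% → 28%) while the ad-libitum comparator continues to
density 65. Hormone truths encode 6.4-fold insulin, 3.2-fold IGF1 and
2.1-fold IGF2 elevations with lognormal σ = 0.10.

## Sectioning and measurement

Tufts are spheres of radius `R`; the section plane offset is uniform on
[−R, R] (conditioned on hitting the tuft) and the profile radius is the
equivalent-circle radius `r_p = √(R² − z²)` — the operational definition
chosen because the protocol's radius definition is not otherwise pinned
down. Nuclei are spheres of caliper diameter `d` (default 6.5 µm) with
centers uniform in the tuft ball; a nucleus is counted when it intersects
the slab `[z, z + T]` (profile counting; disector/guard-zone schemes are a
non-goal). Phospho-S6 positivity of counted nuclei is a hypergeometric
draw from the tuft's labeled pool, so label scoring inherits the correct
finite-population variance. "Consecutive profiles" are modeled as simple
random sampling of an animal's glomeruli; cortical-depth gradients are not
modeled.

The raster path renders a profile as a 16-bit label TIFF (tuft = 1,
GLEPP1 = 2 as a peripheral annulus with the profile's exact area fraction,
nuclei ≥ 10 one label each) plus a JSON sidecar (pixel size, legend,
per-nucleus flags); `measure_mask` recovers the profile record from the
raster, and the two paths agree within discretization error. Nuclei are
drawn in the annulus interior so the GLEPP1 fraction stays exact; when a
profile is too small to hold its nuclei there, placement falls back to the
whole tuft and the sidecar marks the layout approximate.

## Stereological estimators

**Volume.** `V̂ = (4/3)π((4/π)·r̄)³`. For monodisperse spheres this is
unbiased (E[r_p] = (π/4)R); with a within-animal size distribution it
estimates the volume of the mean-radius sphere, a ~1–2% underestimate of
the mean volume at the packaged CVs. The bias cancels in between-arm
ratios.

**Density.** The first-order (Abercrombie) density `y = Q/(T + d)`
over-/under-counts by a small geometry-dependent amount (slab sampling
near the poles, finite tuft radius). `calibrate_correction` simulates
sections at a grid of true densities (50–325 per 10⁶ µm³, spanning the
packaged studies), nuclear diameters 4–8 µm and tuft radii 55–95 µm, and
least-squares fits the quadratic `D = q₀ + q₁y + q₂y²`. The calibration
uses the closed-form slab-intersection expectation with Poisson sampling;
the test suite checks it against an independent brute-force simulation
with explicit nucleus positions (agreement within 3%), and against the
closed form itself (the quadratic is a ≤3% perturbation of `y`). The
published correction's coefficients are not available, so the module ships
this self-calibration; users needing bit-compatibility with a specific
published quadratic can construct a `CorrectionModel` directly.

**Summary identities.** `N̂ = V̂·D̂`, total podocyte volume `V̂·AA`,
average podocyte volume `V̂·AA/N̂`, non-podocyte volume `V̂(1 − AA)`;
`total + non-podocyte = V̂` holds exactly and `N̂ = 0` yields missing
per-cell volumes. Estimates are computed per animal from pooled profiles
(mean-of-profiles), matching the 30–50-profile averaging protocol;
per-glomerulus estimation is possible by grouping the profile table
differently.

## Statistics

Two-sided throughout, α = 0.05. Mann–Whitney U is exact for combined
n ≤ 16 (scipy's exact distribution for tie-free data; full enumeration of
labelings when ties are present) and a tie-corrected normal approximation
otherwise. Kruskal–Wallis uses scipy's tie-corrected H; Dunn's post-hoc z
tests are computed from pooled ranks with tie correction and
Holm-adjusted by default (the adjustment is configurable — the original
reports name the Dunn test without one). Spearman's ρ uses an exact
permutation p for tie-free n ≤ 9 and the t approximation otherwise. OLS
fits come from `scipy.stats.linregress`, with constant-y handled as the
degenerate slope-0/R² = 0 case.

## Recovery experiments and problem sizes

`podosim.recovery` re-runs each packaged condition exactly as specified
(n = 6 animals/arm, 40 profiles/animal — 12 for the phospho-S6 count —
1.5 µm sections, Cq σ 0.15, hormone σ 0.10) and reports the replicate mean
over independent cohorts: 24 replicates for the 6-week volume fold, 160
for the loss slope (a single n = 6 study estimates the slope with SD
≈ 0.4 podocytes/week), 32 for the mRNA fold and the phospho-S6 percent,
48 for the insulin fold and 64 for the sclerosis index. Replicate counts
were sized so the standard error of the reported mean is a small fraction
of each quantity's recovery tolerance; replication averages the estimator
without changing any study condition. A full run takes ~30 s on one CPU.

## What the simulation does and does not show

Passing recovery demonstrates that the estimation chain is consistent and
nearly unbiased **under the generator's assumptions**: spherical tufts and
nuclei, uniform nuclear placement, lognormal biological variation,
Gaussian Cq noise, linear density–albumin links. Real tissue violates all
of these to some degree (aspherical and lobulated tufts, peripheral
nuclear crowding, fixation shrinkage, RNA degradation, assay inhibitors),
so recovery here bounds estimator error from below, not from above. Known
limitations: no disector counting, no non-spherical shape correction, no
mRNA degradation kinetics beyond the single recovery fraction `f`, no
mechanistic mTORC1 or glucose dynamics (phospho-S6 is a labeled fraction
only), and nephron number is a configured constant (default 60,000 per
animal), not a measured quantity.
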