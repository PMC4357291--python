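# Methods

This note documents the models and procedures implemented in `endotrack`,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic benchmarks do and do not demonstrate.

## Coordinate and unit conventions

All positions are in nanometres, times in seconds; file dialects declare
their units and are converted on read.  The invagination axis is the +X
axis of the aligned frame, pointing into the cell; plots that draw inward
movement vertically are a presentation transform only.  Membrane profiles
measure axial depth `z` from the flat membrane (0) toward the tip.

## Single-channel alignment and averaging

Assumption: every endocytic event of a given protein follows the same
trajectory up to a planar isometry (random position and orientation on the
cell surface), a time shift (random start), and isotropic Gaussian
centroid noise.  The pairwise alignment minimises the
fluorescence-product-weighted mean squared residual over rotation,
translation and integer lag; weighting by `q^f p^f` both concentrates the
spatial fit on the bright, well-localised frames and acts as a temporal
cross-correlation that locks the lag.

Numerical notes:

* The per-lag rigid fit is the closed-form weighted 2D Procrustes
  solution.  All lag-indexed moment sums factorise into cross-correlations
  of per-channel products, so a full lag sweep costs a handful of O(N²)
  correlations rather than a fit per lag.
* Lags are admissible when at least 5 frames overlap (below that the
  3-parameter rigid fit is unstable); ties in cost prefer the smallest
  |τ|, then the smaller τ.
* A single overlapping point degenerates to a translation-only fit with
  θ = 0.
* The n(n−1) pairwise transforms are combined per trajectory by averaging,
  over all references, the reference's own frame transform composed with
  the pairwise transform; rotations are averaged on the circle (mean of
  sin/cos), lags by the median.  The common frame is anchored at the first
  trajectory and, by default, re-centred to the cohort's
  fluorescence-weighted centre of mass.  Because the translation and
  rotation components are averaged separately, the procedure is exactly
  equivariant under a global isometry only for a noiseless cohort; with
  noise the equivariance holds to second order in the rotation scatter
  (and re-centring deliberately removes the global translation).
* Per-point SEMs use the sample standard deviation over contributors
  (ddof 1); indices with a single contributor report NaN SEMs and are
  excluded from downstream weights.  `trim_average` drops edge indices
  with fewer than a chosen number of contributors (the benchmarks use half
  the cohort), since those are dominated by a few randomly-lagged events.
* Smoothing (Savitzky–Golay, default window 11, order 3; or moving
  average, window 5) is presentational and applied per coordinate with the
  window shrunk symmetrically at the boundaries, so constants and local
  polynomials up to the order are preserved everywhere and time stamps
  never change.  The polynomial order is a package default; order 3 is
  common practice and satisfies order < window.

For abundant cytoskeletal reference proteins whose disassembly phase is
not stereotyped (Abp1-like cohorts), the `invagination_only` flag restricts
alignment costs to frames up to each trajectory's fluorescence peak.

## Two-color registration

Average trajectories of different proteins are registered through pairs of
simultaneously acquired tracks.  Per pair: the lag τ_p maximises the
fluorescence cross-correlation Σ p^f_{i+τ} P^f_i (ties toward the smallest
|τ|, at least 5 overlapping samples); the spatial fit weights are
`P^f_i p^f_{i+τ} / (δ^x_i δ^y_i)`, so precisely determined portions of the
average dominate.  Pairs are smoothed with a short moving average (default
3 frames) and cubic-spline resampled onto the average's time grid before
fitting.  Where the SEM product underflows, weights are capped at the 99th
percentile of the remaining weights so no single frame dominates.

The per-pair estimate of the target→reference transform is the exact
composition T_r (T_p)⁻¹; its translation components are accumulated with
the small-angle form (valid because both averages are first rotated to
their symmetry axis and the target average is centred on its weighted
centre of mass, making the two per-pair rotations nearly cancel).  A
warning is raised when the median rotation exceeds 0.1 rad, where the
small-angle composition degrades; no correction is applied beyond the
warning.  Components are aggregated by medians with standard errors
1.4826·MAD/√M, and confidence bands are reported at 1.96 standard errors.

The symmetry axis is estimated as the principal direction of the
fluorescence-weighted spread of the average positions, signed so the
late-minus-early displacement points along +X.  This is robust for motile
proteins; for non-motile proteins the two-color *averaging* variant is used
instead: each pair's reference track is aligned to the reference average
and the resulting rotation, translation and lag are applied to the paired
target track before per-timepoint averaging.

Chromatic registration between channels is estimated from multicolour
beads, either as an affine fit or as a local weighted mean warp (per-bead
second-order polynomial fits over the 12 nearest beads, blended with a
cubic radial weight); leave-one-out residuals quantify the registration
error.  The warp is applied to raw coordinates before any alignment.

## Copy numbers

`n_p = c (f/g) n_r` from the medians of per-spot intensities of the target
(f) and of a co-imaged reference protein of known abundance (g).  The
shipped constants Nuf2 = 280.6 ± 16.1 molecules per spot (calibrated
against 5 Cse4 per kinetochore) are documented inputs, not hidden
defaults.  The target-channel spread enters through the MAD-based standard
error of the median of log intensities (the distributions are skewed), the
brighter reference channel through the MAD of raw intensities — an
asymmetry kept deliberately.  The tag-brightness correction `c` (e.g.
myEGFP ≈ 68% ± 14% of EGFP) adds a fourth error term; at c = 1, δc = 0 the
four-term formula reduces exactly to the three-term one.  Fluorescence
curves are rescaled so that the baseline-subtracted time average equals
n_p; consequently the curve is zero at the fluorescence minimum and its
peak exceeds n_p whenever the curve spends time near baseline.  The
baseline error term uses the SEM at the index of the fluorescence minimum.

All propagation formulas are first-order; the tests verify them against
Monte-Carlo sampling (transform and curve propagation) and nonparametric
bootstrap (median ratios) at 5–20% tolerances.

## Geometry

* Projection: an event at axial offset z in a spherical cell of radius R
  has its membrane-normal movement foreshortened by 1 − √(1 − (z/R)²);
  with R = 2.5 µm and a 500 nm depth of field the maximum is 0.5%.
* Track-to-membrane angles use the fluorescence-weighted total
  least-squares direction of the track against the tangent at the nearest
  contour point, folded into [0°, 90°]; tracks without measurable net
  displacement are rejected explicitly.
* Photobleaching tracks are projected on the membrane-normal axis; the lag
  comes from the *normalised* fluorescence cross-correlation of the
  pre-bleach segment (the raw product sum is biased for a truncated rising
  curve) and the spatial offset from a weighted least-squares match of the
  pre-bleach inward movement.  The reported jump is the first post-bleach
  position minus the average trajectory at the matched time (negative =
  toward the membrane).
* Membrane profiles are registered in time by computing, for each profile,
  the surface centre of mass of a coat band at the tip (default arclength
  35 nm, the midpoint of the 30–40 nm coat extent) and assigning the time
  at which the coat-protein centroid first crosses that position; the
  position origin is the initial coat centroid (= flat membrane level,
  configurable offset, default 0), and the time origin is the peak of the
  Rvs molecule-number curve (scission).  Surface integrals on the
  piecewise-linear (z, ρ) polylines are exact per segment (trapezoid for
  area, Simpson for the z-moment, which is quadratic).

## BAR-dimer coverage

Dimers are modelled as a rectangular tiling of 13 nm × 5 nm (dimer length
× spiral spacing), i.e. 65 nm² of membrane per dimer; only the two lengths
are physically constrained, not the lattice geometry.  By default two
tagged molecules count as one dimer (`molecules_per_dimer = 2`, so 130
molecules → 65 dimers → 4225 nm²); the mapping is exposed because one
could equally count one tagged Rvs167 per heterodimer.  The covered region
is a single contiguous arclength band whose area matches the dimer count;
among all such bands the one whose surface centre of mass is closest to
the tracked centroid is selected by a dense scan (0.05 nm steps) over
cumulative-area inverses.  If the required area exceeds the profile the
band clips to the whole profile and is flagged.  Profile morphing between
time points reparameterises to a common vertex count by arclength fraction
and interpolates vertexwise linearly in time; extrapolation beyond the
covered span is limited to one inter-profile interval.

## Separation distances

The measured 2D distance between two fluorophores at true separation d,
each localised with isotropic spread σ, follows
p(s|d,σ) = (s/σ²)·exp(−(s²+d²)/2σ²)·I₀(sd/σ²).  The fit maximises the
likelihood with L-BFGS-B from moment-based starts (E[s²] = d² + 2σ²),
with a coarse-grid rescue, after normalising the samples by their median
(which makes the fit exactly scale-equivariant).  Standard errors come
from the inverse observed Fisher information (central-difference Hessian);
at the d → 0 boundary the information matrix is singular and the d error
falls back to the profile-likelihood half-unit scale, which should be read
as a magnitude rather than a symmetric interval.  σ can be frozen at an
independently calibrated value (`fix_sigma`).

## Synthetic data and benchmarks

The generator emulates the stereotyped endocytic event: a non-motile phase
(default 5 s of a 15 s event at dt = 0.25 s) followed by a linear 100 nm
inward ramp, a smooth rise-and-fall fluorescence curve, and a
deterministic nm-scale meander of the path (fixed sine modes, amplitude
2 nm, wavelengths ≈ 2–3 s, vanishing at the endpoints).  The meander
represents the fine tortuosity real average trajectories show; it matters
because the documented smoothing bias of averaging — the average of many
imperfectly registered copies slightly underestimates the path length of
the truth — acts on exactly this structure and is invisible on an idealised
straight path.  Measured tracks add isotropic Gaussian centroid noise
(reference channel 19 nm, the experimentally encountered value; target
channels 10–24 nm, 16 nm as the representative default) and multiplicative
intensity noise of 20%, a realistic fluctuation level for patch
intensities and the reason temporal alignment is imperfect in practice.
Pairs sample event windows at random start offsets (up to 3 frames) and
uniformly random orientations on [0, 2π); benchmarks search lags over ±8
frames, comfortably covering the generated offsets.

The alignment benchmark builds 100 pairs per repeat and 30 repeats,
runs the full two-color pipeline, and reports per repeat the recovered
transform components, the fluorescence-weighted mean pointwise distance of
the aligned trajectory from its ground truth, and the weighted mean error
vector.  Two summary metrics serve different claims: the *mean
displacement* (average over repeats of the per-repeat mean distance)
quantifies single-alignment accuracy, while the *mean-position
displacement* (norm of the repeat-averaged error vector) quantifies the
systematic part, the relevant quantity for the color-shift robustness
test — a lab-frame shift of the reference channel enters each pair's
estimate at full magnitude but random orientation, so it cancels from the
mean while inflating the per-repeat scatter and the reported MAD-based
uncertainties.  The separation benchmark places the target ground truth
30 nm from the reference along the invagination axis and reports the
signed error component toward the reference; small alignment errors
preferentially shrink the apparent separation, so the bias points toward
the reference and grows with the true separation.

The averaging benchmark generates 65 noisy trajectories, runs the
all-pairs averaging, trims edge indices with fewer than half the cohort
contributing, aligns the result to a virtual reference through the
two-color procedure (pair noise fixed at σ_p = 10 nm, σ_r = 19 nm), and
reports the weighted mean deviation from ground truth and a path-length
ratio.  The ratio is computed from the noise-orthogonal attenuation of the
template's meander in the average — the weighted regression of the
average's residual (relative to the smooth backbone) onto the meander —
converted to a length ratio as (L_backbone + c²(L_truth −
L_backbone))/L_truth over the matched window.  A naive polyline length of
the noisy average would be inflated by point noise in proportion to σ² and
mask the underestimate; the attenuation estimator is insensitive to
isotropic noise because noise is uncorrelated with the deterministic
meander.

What passing benchmarks do *not* show about real data: the generator has a
single template per cohort (no event-to-event shape or lifetime
variability), exact frame synchrony within pairs, Gaussian noise with no
tracking outliers or localisation bias, no photobleaching trend, and no
residual chromatic distortion beyond the optional uniform shift.  Accuracy
on real cohorts is bounded below by these idealisations.

## Known limitations

* The rotation composition in the two-color aggregation assumes the
  per-pair rotations nearly cancel; beyond ~0.1 rad the translation
  medians degrade and the package warns rather than corrects.
* Cohort averaging is a single pass (no re-alignment to the average); an
  optional refinement iteration was considered and left out because the
  benchmarks meet their accuracy targets without it.
* Coverage bands are contiguous; fragmented BAR coverage is out of scope.
* The registration of membrane profiles assumes the coat centroid
  position crosses each tip position once; non-monotone trajectories would
  need explicit segment selection.
* `patch_lifetimes` reports observed trajectory durations of complete,
  early-starting events; with stringent detection thresholds upstream this
  systematically underestimates true patch lifetimes, a bias inherited
  from the detection step, not corrected here.
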