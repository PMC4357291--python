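# endotrack

Trajectory alignment, averaging and calibration for centroid tracking of
endocytic sites in budding yeast.

Clathrin-mediated endocytosis reshapes a patch of plasma membrane into a
vesicle in about ten seconds, driven by dozens of proteins whose positions
differ by only tens of nanometres — far below the diffraction limit.  The
positions can nevertheless be resolved by tracking the *centroid* of each
fluorescent patch with nm precision, exploiting the fact that the process
is highly stereotyped: many individual event trajectories can be aligned in
space and time, averaged, registered across color channels to a common
reference protein (Abp1), and calibrated to absolute molecule numbers.
`endotrack` implements that machinery, the geometric models built on top of
it (projection effects, membrane-profile registration, BAR-domain coverage,
two-fluorophore separation distances), and the synthetic-data benchmarks
that quantify its accuracy.

## The core algorithms

**Single-channel averaging.** A trajectory is a time series
p_i = {p_i^x, p_i^y, p_i^f} (centroid in nm, fluorescence).  Two
trajectories are aligned by the planar isometry T = {T^x, T^y, T^θ} and
integer lag τ minimising the fluorescence-weighted squared residual

    cost(T, τ) = Σ_i w_i ‖q_{i+τ} − T(p_i)‖² / Σ_i w_i ,   w_i = q_{i+τ}^f p_i^f ,

with the optimal T per lag in closed form (weighted 2D Procrustes).  Each
of n trajectories serves as reference for all others (n(n−1) alignments);
per-trajectory transforms into a common frame are averaged, and the aligned
cohort is averaged per time point into P_i = {P^x, P^y, P^f, δ^x, δ^y, δ^f}
with standard errors.

**Two-color registration.** Pairs of simultaneously acquired tracks
(target protein + Abp1) each yield transforms T_p (pair target → target
average) and T_r (pair reference → reference average); T_r (T_p)⁻¹
estimates the transform aligning the target average to the reference
frame.  Over M pairs the components are combined by medians with robust
standard errors 1.4826·MAD/√M, and the positional uncertainty is
propagated as ζ_i^x = √((δ_i^x)² + (P_i^y δT^θ)² + (δT^x)²).  Because the
pairs are oriented randomly on the cell surface, a systematic chromatic
shift between the channels averages out of the median and only inflates
the reported uncertainty.

**Copy-number calibration.** Patch intensities are converted to molecule
counts via the median intensity ratio against Nuf2 (280.6 ± 16.1 molecules
per spot): n_p = c·(f/g)·n_r, with MAD-based error propagation (target
intensities on a log scale, as their distributions are skewed) and
fluorescence curves rescaled so the baseline-subtracted time average
equals n_p.

**Separation distances.** Measured 2D distances s between two fluorophore
populations at true separation d with localization spread σ follow the
non-Gaussian displacement density
p(s|d,σ) = (s/σ²) exp(−(s²+d²)/2σ²) I₀(sd/σ²); `fit_separation` is the
maximum-likelihood fit with standard errors from the observed Fisher
information.

Further modules model the membrane area covered by BAR (Rvs161/167) dimers
on axisymmetric invagination profiles, register electron-microscopy
membrane shapes to the trajectory frame, align photobleaching experiments,
and measure trajectory-to-membrane angles.

## Worked example

```python
import numpy as np
from endotrack import (SyntheticConfig, run_alignment_benchmark,
                       IntensitySample, copy_number, calibrate_curve)

# accuracy of the full two-color alignment at experimental noise levels
res = run_alignment_benchmark(SyntheticConfig(sigma_p=16.0, sigma_r=19.0,
                                              n_pairs=100, n_repeats=30, seed=1))
print(f"aligned trajectory within {res.mean_displacement:.2f} nm of ground truth")
print(f"recovered translation ({res.tx.mean():+.2f}, {res.ty.mean():+.2f}) nm,"
      f" scatter ({res.tx.std():.2f}, {res.ty.std():.2f}) nm")

# molecule-number calibration against a reference of known abundance
rng = np.random.default_rng(1)
f = rng.lognormal(np.log(95.0), 0.6, 400)   # target patch intensities
g = rng.lognormal(np.log(180.0), 0.3, 250)  # Nuf2 reference spots
cal = copy_number(IntensitySample(f, g), n_r=280.6, dn_r=16.1)
print(f"copies per patch: {cal.n_p:.1f} +/- {cal.dn_p:.1f}")
```

prints

```
aligned trajectory within 0.93 nm of ground truth
recovered translation (+0.05, +0.03) nm, scatter (0.56, 0.68) nm
copies per patch: 140.5 +/- 9.4
```

i.e. with 16 nm / 19 nm centroid noise and 100 trajectory pairs the
two-step alignment recovers the ground-truth frame to well under a pixel
(100 nm), and the median intensity ratio converts patch brightness into
absolute copy numbers with its propagated standard error.

A command-line interface mirrors the library:

```bash
endotrack average  --in cohort.tsv --out average.tsv
endotrack align2c  --pairs pairs.tsv --target-avg P.tsv --ref-avg R.tsv --out aligned.tsv
endotrack simulate accuracy --config sim.yaml --seed 3 --out results.tsv
```

Every subcommand accepts `--seed`, `--config` and `--out` and writes a JSON
run manifest next to its output.

## Layout

| module | contents |
|---|---|
| `endotrack.trajectory` | trajectory containers, TSV/CSV I/O, smoothing, lifetimes |
| `endotrack.align_single` | weighted rigid+lag fits, all-pairs cohort averaging |
| `endotrack.twocolor` | chromatic warps, pair fits, median/MAD aggregation, error propagation |
| `endotrack.calibration` | copy numbers, molecule curves, tagged fraction |
| `endotrack.geometry` | projection effects, membrane angles, photobleach alignment, profile registration |
| `endotrack.profiles`, `endotrack.coverage` | invagination profiles, BAR-dimer coverage bands |
| `endotrack.distances` | separation-distance MLE, termini orientation |
| `endotrack.simulate` | ground-truth templates, noisy cohorts/pairs, benchmarks |
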