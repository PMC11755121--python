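# Methods

## The subject-level QC statistic

For each pair of region-averaged BOLD series the package computes the
sliding-window Pearson correlation (window width w TR, stride s; defaults
w = 46, s = 1, i.e. 138 s at TR = 3 s) and the window mean of the framewise
displacement (FD) over the identical windows, then the Pearson correlation
r between the two resulting length-L series (L = ⌊(T − w)/s⌋ + 1; T = 96
volumes gives L = 51). A large |r| means connectivity strength rises and
falls with head motion — the signature of residual motion artefact rather
than neural dynamics.

Two null models are implemented for r:

* **Parametric**: t = r√(L−2)/√(1−r²) against Student's t with L−2 degrees
  of freedom. This is exact when the L windowed samples are independent, and
  the package's calibration test confirms the 5% level on independent
  inputs. With overlapping windows, consecutive cc and fd samples share
  w−1 of w points; the effective degrees of freedom collapse and the test
  rejects true nulls far above its level (measured ≈ 20–70% at α = .05
  depending on the FD autocorrelation). It is retained for independent-
  sample settings and for demonstrating exactly this failure.
* **Surrogate (default)**: phase randomisation of the FD series. Surrogates
  keep the amplitude spectrum of the measured FD exactly (Hermitian-
  symmetric uniform phases; DC and Nyquist bins kept real) and therefore its
  autocorrelation, while destroying the temporal alignment with FC. The
  entire window-average-and-correlate procedure is rerun per surrogate, and
  the two-sided add-one empirical p is (1 + #{|r_null| ≥ |r|})/(n_surr + 1),
  with n_surr = 1000 by default (achieved level 0.04995 at α = .05).
  Randomising the FD series only (conditioning on the observed FC course) is
  the default; a mode that additionally randomises the windowed-FC series
  exists but measures anticonservative (~20% at the null), because phase
  randomisation Gaussianises the bounded, non-Gaussian windowed-correlation
  series — it is therefore not the default.

Within one subject all edges share the FD series, so a single surrogate
batch serves every edge; per-edge null correlations are one standardised
matrix product, making the default 1000-surrogate analysis of a 98-region
parcellation (4753 edges) a sub-minute computation.

Edge significance at α (default .05, uncorrected, matching the usual
reporting; Benjamini–Hochberg FDR available) defines the *corrupted* set.
Subject summaries: corrupted fraction, median |r|, per-region counts of
incident corrupted edges, and the Spearman correlation between r and
inter-centroid Euclidean distance (mm, computed per subject because fetal
brain size varies with gestational age).

Degenerate inputs: zero-variance regions are excluded and listed;
zero-variance windows yield NaN windowed FC, are excluded from r with a
count; a constant FD series marks the whole subject's test undefined rather
than silently returning p-values.

## The generative simulator

The simulator produces pairs of observed signals whose neural truth and
motion contamination are known, for validating the statistic.

*Neural stage.* Latent events are a binary first-order Markov chain at
nu_g = 20 Hz with stationary activity probability 0.05 and active-state
self-transition 0.5 (short bursts; both exposed). Convolution with a
canonical double-gamma HRF (peak 6 s, undershoot 16 s, dispersions 1 s,
undershoot ratio 1/6, 32 s support; gamma shapes chosen so the density mode
sits exactly at the stated delays) gives the noiseless BOLD signal at the
latent rate. Neural correlation between the two signals of a pair is imposed
by mixing standardized signals with the lower Cholesky factor of the target
correlation matrix.

*Observation stage*, in order: (1) each active latent bin is deleted with
probability 0.1 in the observed branch only (event pruning); (2) a
physiological/motion noise course shared by both signals is added, scaled so
the signal-to-noise RMS (amplitude) ratio equals SNRphys; (3) the series is
block-averaged over d = nu_g/nu_o = 60 consecutive samples down to
n_obs = 96 points at TR = 3 s (block averaging mimics volume-integrating
acquisition; pure decimation is a flag); (4) independent white thermal noise
is added at RMS ratio SNRscan relative to the downsampled noiseless signal;
(5) each series is z-scored. The ground-truth FD proxy is the magnitude of
the shared noise downsampled at rate d; FD is a magnitude, hence the
absolute value.

*Noise process.* The shared noise is a low-pass Gaussian carrier
(< 0.3 Hz) multiplied by a slow nonnegative envelope — the square of a
low-pass Gaussian process (0.055 Hz default), normalised to unit RMS. The
envelope makes the noise episodic: quiescent stretches interrupted by
movement bursts of tens of seconds, which is the defining feature of fetal
motion. This non-stationarity is essential, not cosmetic: with stationary
noise the windowed FD is nearly constant across a scan, there is no
time-varying coupling for the statistic to detect, and the method could not
be validated at all. The envelope bandwidth and exponent control burst
length and sharpness and are exposed on `SimParams`.

What the simulator does **not** model: image-space acquisition (it works at
the signal level), distinct cardiac/respiratory spectral lines, spin-history
effects, or partial sharing of physiological noise between regions (the
shared/unshared choice is a boolean; fully shared is the default because
shared noise is what produces motion-inflated FC). Passing tests therefore
demonstrate the statistic's behaviour under a plausible contamination
mechanism, not under every artefact of real acquisitions.

*Simulation-study scale.* The validation runs 5000 pairs per contamination
level — low (SNRphys, SNRscan) = (12, 18) and high (2, 3) — at 96 volumes,
the 46-TR window and 1000 surrogates; this completes in roughly two minutes
on one CPU. At the high level the shared-noise variance fraction is ≈ 0.06
of the total under the amplitude-ratio SNR definition, which inflates the
mean observed FC of truly uncorrelated pairs to ≈ 0.14 and the median FC–FD
correlation to ≈ 0.36, with ≈ 13% of pairs flagged; at the low level the
flag rate sits at the test's level (≈ 5%) and both centres near zero.

## Framewise displacement

Rigid motion is six parameters per volume (mm translations, degree
rotations; extrinsic x-y-z convention about a configurable centre — the
convention must be fixed for reproducibility and only matters at large
angles). The brain is represented either by explicit voxel coordinates or by
a sphere fitted to surface points with the algebraic least-squares method
(expanding |p − c|² = r² into a linear system; exact on noiseless spheres).
FD at volume t is the RMS displacement of the representative points under
the relative transform M_t M_{t−1}^{-1} (surface points of the fitted
sphere by default, 1000 deterministic Fibonacci-lattice points), with a
leading zero to align with volumes. The sum-of-absolute-parameters FD
(|Δt|₁ + R·|Δθ|₁) is provided for comparison with scrubbing literature.

Censoring combines two flags by logical OR: volumes whose in-mask voxel
intensities contain more than 5% outliers (|v − median| > 3 × 1.4826·MAD,
robust statistics so that the outliers cannot mask themselves), and volumes
with FD above a threshold (default 0.5 mm; not prescribed by any analysis
here and always reported in outputs, since appropriate thresholds are
dataset-specific).

## Nuisance regression

Strategies are atomic builders in a registry, composed by ``+`` (e.g.
``aCompCor+6HMP``); ``+censor`` marks censored-frame exclusion at regression
time. Definitions: 24HMP = [p, Δp, p², Δp²] of the six parameters
(backward differences, first element 0); 2Phys/8Phys = WM and CSF means and
their expansion; GSR expansions likewise; aCompCor = top-5 principal
components of the standardized WM+CSF voxel series (component count
exposed); tCompCor = top-5 PCs of the 2% highest-temporal-SD in-brain
voxels; localWM = per-region mean of eroded-WM voxels within 25 mm of the
region centroid (ANATICOR-style; the definition is conventional, the
radius exposed, and the regressor is applied per matching region).
Constant-zero columns (e.g. motionless axes) are dropped with a warning
rather than carried as degenerate regressors.

Regression is OLS with an implicit intercept (series and regressors demeaned
over retained frames), so residuals are exactly uncorrelated with every
design column on those frames; rank-deficient designs fall back to the
pseudoinverse with a warning; designs with at least as many columns as
retained frames are rejected. Filtering order follows the benchmarked
pipeline: regression first, then demean/detrend and discrete-cosine
high-pass at 0.008 Hz. Sequential projection can reintroduce small
correlations with the design — this is a property of the pipeline order,
not a defect of the regression step.

## Group-level benchmark

QC–FC: per edge, the Pearson correlation (Spearman optional) across subjects
between FC and mean FD, with the t-test at n−2 degrees of freedom and the
significant-edge count at α = .05 uncorrected. Edges whose FC is constant
across subjects are undefined, not zero. The package's ceiling-effect test
constructs a cohort in which every subject's FC is saturated by motion and
verifies the diagnostic dissociation: QC–FC stays near its chance level
while the median subject-level corrupted fraction stays high.

Cohort summaries report median and IQR of per-subject corrupted fractions
per strategy, flagging subjects whose connections are all corrupted (the
signature of a series left too short by censoring) and reporting summaries
with and without them. Pooled distance dependence is the Spearman rank
correlation over all subjects' (distance, r) pairs, with subject-specific
distances.

## The synthetic fixture subject

``make_fixture_subject`` builds a complete miniature subject — 4-D BOLD
NIfTI on a 20×10×6 grid (2 mm voxels) holding ten block regions, WM and CSF
slabs, tissue masks, a motion-parameter file, and a ground-truth corrupted
edge set — entirely from the simulator. Half of the regions (configurable)
share the episodic motion noise; the WM slab carries the same noise course
so CompCor-style regressors can recover it; the motion file is a pure
x-translation random walk with step sizes equal to the true FD, so the FD
machinery reproduces the planted series exactly. The default profile is a
severely corrupted acquisition (SNRphys = 0.5, 300 volumes, movement
episodes of a few minutes): at milder contamination and 96 volumes the
statistic's per-edge sensitivity is intrinsically modest, and a recovery
fixture must plant effects strong enough to be recoverable. Everything is
deterministic under the seed.

## Numerical choices and limitations

* Windowed statistics are computed from sliding views with per-window means;
  equality with brute-force per-window computation to 1e−12 is a test.
* Empirical p-values use the add-one convention, so the smallest attainable
  p is 1/(n_surr + 1) and the test is never exactly zero.
* The batch simulator draws in fixed chunks of 500 pairs from one master
  generator; datasets are bit-reproducible for a given (seed, n_pairs,
  parameters).
* ICA-based denoising is out of scope (no fetal-trained component
  classifiers); image registration/motion estimation is out of scope (the
  package consumes realignment parameters, it does not estimate them).
* The parametric and surrogate tests answer slightly different questions:
  the surrogate null conditions on the realised FD spectrum. With very short
  series (few windows) its power is limited — heavy contamination can carry
  |r| ≈ 0.8 and still sit inside the surrogate null if the FD is smooth
  enough; this is honest uncertainty, not a defect.
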