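# Methods

This note documents the models, the numerical choices, and what the
synthetic experiments do and do not establish.

## Directed connectivity

**MVAR estimation.** Each subject's 82-region (configurable) scalar
source series, epoched into 1-s windows at 125 Hz, is fit by ordinary
least squares on lagged regressors with order p = 5 (a 40 ms lag span).
Channel means are removed per epoch and lagged rows never cross an
epoch boundary. The default estimator pools the lagged regressions of
all epochs into one regression per subject (the standard multi-trial
MVAR estimator): an order-5 model over n regions has 5n coefficients
per channel, which one 125-sample epoch cannot identify once n is more
than ~24, and which at smaller n yields estimates so noisy that planted
network structure is buried (in our 20-region hub benchmark, per-epoch
fitting recovers the hub in 0/10 runs on noiseless source series, the
pooled fit in 100/100 through the full sensor pipeline). A
`per_epoch=True` path fits each epoch separately and averages the
per-epoch PDC tensors elementwise, for small n and for comparison with
the averaging formulation. Rank-deficient designs raise; nothing is
silently pseudo-inverted. The innovation covariance is the residual
covariance with the regression degrees of freedom in the denominator.

**PDC.** Column-normalised plain-magnitude PDC (the canonical
normalisation; the literature also contains row- and squared-variants).
Convention, fixed throughout: element (i, j, f) is the influence *from
column j to row i*, so senders are columns and summed outflow is a
column sum. The frequency grid is the integers 1–40 Hz, matching the
1 Hz resolution of 1-s epochs. PDC is a function of the coefficients
only; the stability check can be waived for finite-sample fits that
land marginally outside the stationarity region (`require_stable`).

**Spectral-power weighting.** Source spectral power is computed by the
FFT-through-the-inverse route: per epoch, the real and imaginary parts
of each electrode's FFT are separately passed through the (linear)
inverse, centroid reduction and orientation projection, then squared
and summed — algebraically the power spectrum of the projected source
series, while avoiding frequency doubling. PDC (subject-level) and
power are each min-max scaled to 0–1 globally across regions and the
1–40 Hz grid; the PDC diagonal (self-influence) is excluded from the
scaling pool — self-loops are not connectivity and would otherwise
anchor the maximum (a flag restores them for sensitivity analysis).
wPDC(i←j, f) = scaledSP(j, f) · scaledPDC(i←j, f): weighting is by the
*sender's* power. Band values are arithmetic means over in-band bins
(theta 4,5,6,7; alpha 8–12; beta 13–30); summed outflow excludes the
diagonal, so it lies in [0, n−1]. Beta is computed and stored but the
headline analyses use theta and alpha, where driving concentrates.

Because each subject's tensors are 0–1 scaled *within subject*, pure
amplitude differences between groups cancel; detectable group effects
are structural (e.g. how many regions a hub drives). The synthetic
two-group study plants exactly such a difference.

## Source imaging

The inverse is a weighted minimum-norm (LORETA-type) kernel
K = W⁻¹Lᵀ(LW⁻¹Lᵀ + λI)⁻¹ = (LᵀL + λW)⁻¹Lᵀ with W = BᵀB, B the block
graph Laplacian over solution points (k-nearest-neighbour graph, k = 6)
applied per dipole component. The Laplacian is singular on its constant
mode, so W carries a small ridge (1e-6 of its mean diagonal). Because
W = kron(Lap² + εI, I₃), the solve factorises over the three dipole
components and scales to thousands of points. λ defaults to
trace(LWL)-normalised 1/SNR² with SNR 3, overridable; an optional
gain-norm depth weighting (off by default) counters the superficial
bias of minimum-norm solutions. The kernel is checked against its
normal equations to 1e-8 relative residual. Regions are reduced to the
solution point nearest their centroid (ties to the lowest index), and
the 3-D dipole series is projected onto the first left singular vector
of the 3 × (samples·epochs) matrix — one orientation per subject across
epochs, since per-epoch orientations would break cross-epoch
comparability — with the sign fixed so the largest-magnitude component
is positive (bit-identical reruns).

## Synthetic forward model

The forward model is the analytic dipole-in-a-homogeneous-sphere
solution (insulated boundary), evaluated as a Legendre series derived
from first principles: V = (1/4πσ) Σ_n ((2n+1)/n) p·∇[bⁿPₙ(cos γ)] on
the unit sphere, truncated when bⁿ(2n+1) < 1e-13. The n = 1 term
reproduces the textbook central-dipole law 3(p·r̂)/4πσ, and the series
is verified in tests against an independent finite-difference
evaluation. Electrodes form a golden-angle lattice (full sphere, 111 by
default); solution points sit on five concentric Fibonacci shells
spanning 0.45–0.75 of the scalp radius — a grey-matter compartment with
no sources near the centre, its conservative outer radius standing in
for the smearing of the unmodelled skull. ROI placements use
farthest-point sampling restricted to cortical depth with radial
(surface-normal) orientations, the pyramidal-generator convention,
which also gives regions comparable sensor visibility; sensor noise is
white Gaussian calibrated so signal power / noise power equals the
requested SNR.

**Planted dynamics.** Each region's diagonal dynamics are an AR(2)
resonance (a₁ = 2ρcos(2πf₀/fs), a₂ = −ρ²). In the hub benchmark the
hub is a *dominant theta driver*: sharp 6 Hz resonance (ρ = 0.9) with
boosted innovation variance, driving damped broadband receivers
(ρ = 0.3). This matters: if receivers resonated at the drive frequency
they would amplify the hub's input beyond the hub's own power
(measured: receiver variance 17× the hub's), and the sender-power
weighting that defines "driving" would no longer point at the source.
If a draft model is unstable, lag-r matrices are scaled by γʳ, which
scales companion eigenvalues by exactly γ, until the spectral radius is
0.95.

## Preprocessing

Zero-phase windowed-sinc FIR filters applied forward-backward (1–40 Hz
band-pass, 49–51 Hz band-stop notch; transition width min(low, 2) Hz,
Hamming window, so quoted attenuations double in dB). Polyphase
anti-aliased resampling to 125 Hz. Spherical-spline interpolation of
listed bad channels (order-4 Legendre weights, 7 terms, ridge 1e-5,
with the constant-reproducing constraint); bad channels are an explicit
input, with an optional variance screen (5× MAD) off by default.
Average reference is a projection (idempotent, checked). Non-
overlapping 1-s epochs are tiled within artefact-free spans and never
straddle a mask edge; fewer than 120 epochs raises an explicit
exclusion error, mirroring a subject-exclusion rule. The applied
operation order is recorded in each container's history. ICA artifact
removal is expert-in-the-loop and out of scope; a hook accepts an
external unmixing matrix and rejection list.

## Gaze Proximity Index

Per frame, a Gaussian product-kernel density over the valid reference
gaze points, on a 64×64 cell-centre lattice over the unit screen,
bandwidth per axis by Scott's rule (σ·n^(−1/6)) floored at 0.01 screen
units, renormalised to unit mass on screen. A frame needs ≥ 3 valid
reference points to be usable (a property of the frame, for all
subjects). The frame score is the bilinearly interpolated density at
the subject's gaze point divided by the frame's maximum density — a
similarity in [0, 1], max-normalised so tight and diffuse reference
clouds contribute comparably. PI is the mean over used frames, which
equals the frame-weighted mean of the reported per-film values.
Invalid or off-screen samples skip the frame rather than scoring zero;
a subject with valid gaze in fewer than 10% of usable frames raises an
error carrying the frame counts. The simulator moves a smooth
two-component attention locus and displaces test subjects by δ
attention-SDs in a random direction; PI falls monotonically in δ, and
δ = 0 subjects are exchangeable with reference draws.

## Statistics

Mann-Whitney-Wilcoxon reports the first sample's rank sum Ws (a flag
reports U), a tie-corrected normal deviate z *without* continuity
correction — the convention under which published (Ws, z, r) triples in
this literature are internally consistent (Ws = 267 at 18 vs 18 gives
z = −66/√999 = −2.088, r = z/6 = −0.348) — and a two-tailed p that
switches to exact enumeration of rank assignments when n₁+n₂ ≤ 16. The
plain approximation deviates from enumeration by up to 0.25 at the
smallest shapes, is within 0.02 once both groups reach ~5, and is
excellent at the study scale (n = 36); the exact branch makes the
returned p correct everywhere. Effect size r = z/√N in all regimes.
Type-I error of the full path at α = 0.05, 18 vs 18 Gaussian nulls,
measures 0.050 over 2000 replicates. BH-FDR is the step-up procedure
(statsmodels backend, verified against the brute-force definition),
applied within explicit families (per band, per score battery) — never
pooled implicitly. Spearman is tie-aware with exact permutation p below
n = 10; Pearson and the D'Agostino-Pearson K2 omnibus test follow their
standard forms; t tests are pooled-variance (paired where stated), and
`t_from_summary` recomputes published rows from printed mean/SD/N
(with equal group sizes the pooled and unequal-variance statistics
coincide; the published unequal-n developmental-profile rows are
internally inconsistent between the two conventions and are not
asserted).

Phenotype scores are simulated by a Gaussian copula: latent score
ρ_P·z(x) + √(1−ρ_P²)·ε with ρ_P = 2sin(πρ_S/6), giving a target
Spearman ρ_S exactly in expectation (recovered to 0.744 at ρ_S = 0.75,
n = 18, 200 seeds).

## Problem sizes and determinism

The recovery experiments run at the pipeline's reference conditions —
120 × 1-s epochs at 125 Hz, 111 electrodes, SNR 10 — with 20 regions on
a 300-point grid for hub detection, 6 concurrent sources for
source-series recovery, a 200-point grid for localization, and 100 /
50 / 20 / 2000 repetitions for hub detection, PI monotonicity,
localization and type-I calibration respectively. Dipole localization
is summarised by the median distance-rank over 20 random
configurations, the usual point-spread summary; single trials scatter
between 0 and ~10 ranks on a 200-point grid. All generators take
explicit seeds and are bit-reproducible; repeated pipeline runs with
one config produce byte-identical tables.

## What the synthetic experiments do not show

The sphere is not a head: no skull/CSF conductivity profile, no
anatomy, electrodes cover the full sphere rather than the scalp, and
region "centroids" are synthetic placements, not atlas geometry.
Planted dynamics are stationary Gaussian MVAR — no artifacts, no
nonstationarity, no volume-conducted muscle or eye activity; the gaze
simulator has no saccade/fixation microstructure, blinks or
calibration drift. Passing recovery tests therefore demonstrates the
*correctness of the computations* and the pipeline's behaviour under
its own model assumptions, not performance on real infant EEG. Known
limitations: deep or weakly visible sources are not recoverable by the
minimum-norm inverse (with ten equal-power concurrent sources the
weakest region's recovery correlation can fall to ~0.3 — a resolution
limit, which is why the recovery benchmark uses six); per-epoch PDC
estimates carry an irreducible |noise| floor ≈ 0.8/√T on null edges
that epoch-averaging cannot remove; and group effects expressed purely
in amplitude are invisible after within-subject 0–1 scaling.
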