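# Methods

## IVIM model and fitting

Each voxel's diffusion-weighted signal is modeled as a two-pool
biexponential, S(b)/S0 = f·e^(−b·D*) + (1−f)·e^(−b·D), with S0 the signal
at b = 0. In CSF spaces the "fast" pool (fraction f, pseudo-diffusion
coefficient D*) reflects incoherent pulsatile fluid motion; the slow pool is
true diffusion D. The model assumes a single compartment pair per voxel, no
exchange, and magnitude signal well above the noise floor.

Fitting minimizes Σ_b (S_b/S0 − model)² under box constraints
f ∈ [10⁻⁴, 1−10⁻⁴], D ∈ [10⁻⁵, 10⁻²] mm²/s, D* ∈ [D, 1] mm²/s. The ordering
constraint is imposed exactly by parameterizing δ = D* − D ≥ 0, and the
bounded problem is solved with scipy's trust-region-reflective least-squares
solver (the contract is "constrained least squares within these boxes", not
a specific optimizer). Initialization is segmented, the standard two-step
IVIM practice that stabilizes the ill-conditioned D*: D₀ and the intercept
come from log-linear OLS on b ≥ 250 s/mm² (where the fast pool has decayed),
f₀ = 1 − exp(intercept) clamped to [0.01, 0.99], D*₀ = 10·D₀. Tolerances are
xtol = ftol = gtol = 10⁻¹², max 400 function evaluations; non-convergence
returns the best iterate flagged `converged=False` rather than raising.
Noiseless signals in the physiological range (f ∈ [0.05, 0.95],
D ∈ [3·10⁻⁴, 3·10⁻³] mm²/s, D* ≥ 5·D) are recovered to better than 0.1%
relative.

The upper box for D* (1 mm²/s) is a declared choice: it is far above any
physiological pseudo-diffusion and serves only to keep the solver bounded.
When the fitted f falls below 1%, the biexponential degenerates to a
monoexponential and D* carries no information; the voxel is flagged
`dstar_reliable=False`.

ADC is the slope of ordinary least squares on (b, −ln(S/S0)) over all
b-values with positive signal — the common "all-b ADC" convention (an
intercept is estimated so b=0 noise does not bias the slope). For a
biexponential signal the ADC lies between D and D*.

f is a fraction internally and percent in maps, reports and the FOI
formulas; the single ×100 conversion happens when parameter maps are
assembled. Degenerate voxels (nonpositive S0, non-finite signal) are flagged
`failed` and excluded from ROI statistics, which report n_voxels alongside
mean/max/min f.

### Magnitude (Rician) noise and the noise-floor correction

Magnitude MRI noise is Rician: the observed signal is |S + ε₁ + i·ε₂| with
Gaussian channel noise of level σ. This floor is material for CSF IVIM: at
b = 1000 s/mm² a CSF-like voxel (f = 0.75, D = 3·10⁻³, D* = 3·10⁻²,
S0 = 1000) has true signal ≈ 12 a.u., below σ = 25 at SNR 40, so a plain
least-squares fit sees a flattened tail and is asymptotically biased
(fitting the exact Rician-mean curve gives f = 0.786 instead of 0.750).
`FitOptions.noise_sigma` therefore enables the standard magnitude-bias
correction M ← √(max(M² − 2σ², 0)) before fitting, which removes the floor
in expectation; with it, the Monte-Carlo mean bias of f at SNR 40 over 500
CSF-like voxels is −0.014 (within ±0.02). The correction requires knowing
σ — available by construction in simulations and estimable from background
air in real acquisitions — and is off by default.

## 4D-flow metrics

All metrics are defined on a signed through-plane velocity waveform sampled
at the cardiac phases of one heartbeat (8 or 12 phases in the emulated
acquisitions). Velocity amplitude VA = max − min of the series; it is
computed on the per-phase spatial-extremum ("peak") channel by default, with
the spatial-mean channel selectable, and is invariant under sign flips of
the through-plane axis convention.

Volumes integrate the instantaneous flow rate Q = v̄ · area, using the unit
identity 1 cm/s × 1 mm² = 10 μL/s applied exactly once. Integration is
trapezoidal with periodic closure (phase 0 is appended at one full period),
which is unbiased for periodic signals and makes the volumes invariant under
cyclic rotation of the phase order. With forward volume F = ∫max(Q,0)dt and
backward volume B = ∫max(−Q,0)dt per cycle:

- stroke volume = (F + B)/2 — half the total oscillatory volume;
- net flow = F − B;
- reverse flow rate = 100·min(F,B)/(F+B), defined 0 when nothing moves.

These forms are the standard ones in aqueductal CSF 4D-flow work; a pure
zero-mean oscillation gives reverse = 50% and net = 0. Published
stroke-volume tables are treated as context only, since the exact
workstation definition is not recoverable.

Phase-offset correction fits a least-squares polynomial of total degree
0–3 in normalized voxel coordinates to the velocities of static-tissue
voxels and subtracts it from the whole field, removing phase offsets and
eddy-current background. It requires at least as many static voxels as
polynomial coefficients; an order-1 fit reproduces a linear ramp exactly.

## The f→VA calibration and the FOI

The calibration VA_est(f) = exp(a·(f − b)) + c with a = 0.2 /%, b = 85 %,
c = 0.25 cm/s is strictly increasing and bounded below by c. When refitting
it to (f, VA) pairs, b is held fixed (default 85): exp(a·(f−b)) confounds b
with an overall scale exp(−a·b), so only (a, c) are identifiable; the shift
is exposed for sensitivity analysis. Noiseless self-generated pairs are
recovered to 10⁻⁶.

FOI = VA × 10 + f × 0.02 with f the ROI mean in percent. The weighting
constants are adopted verbatim from the index's definition; the index is
exactly linear in each argument. Measured VA is preferred wherever one of
the 7 flow regions maps onto an IVIM region; the packaged ROI vocabulary
(45 IVIM regions, 7 flow regions) encodes the mapping, including the
equivalence of the lower cerebral aqueduct (4D flow) with the upper part of
the fourth ventricle (IVIM). Reports round VA to 2 decimals and FOI to 1;
full precision is kept in memory.

## Cohort statistics

Morphometric indices are simple ratios of manually measured lengths (Evans,
Z-Evans, BVR) or the interior angle at the ventricular-roof apex from three
landmark coordinates (collinear landmarks are rejected with a 10⁻⁴-degree
tolerance absorbing arccos round-off).

Group comparisons are two-sided at α = 0.05: Kruskal–Wallis (tie-corrected)
across the three healthy age bands, Mann–Whitney–Wilcoxon for Hakim vs.
elderly (exact enumeration when both groups have ≤ 8 untied observations,
tie-corrected normal approximation otherwise), chi-square for proportions
and Fisher's exact test (two-sided by summing tables no more probable than
the observed one) for sex ratios. These delegate to scipy.stats; the test
suite verifies them against independent brute-force enumeration oracles.

Pearson correlations report the Fisher-z 95% interval
tanh(atanh(r) ± 1.96/√(n−3)) and a t-distribution p with n−2 df. The
index × ROI correlation matrix uses pairwise-complete deletion (missing
values affect only their own cell) and reports per-cell n; cells with fewer
than 4 complete pairs or zero variance are flagged missing. No
multiple-testing correction is applied by default, matching the source
analysis; a Benjamini–Hochberg helper is available.

## Synthetic data: what it emulates and what it does not

The DWI generator evaluates the biexponential forward model on axis-aligned
region blocks (trivially verifiable ROI statistics) at the six-point b
scheme, with Gaussian or Rician noise at a configured SNR (σ = largest
region S0 / SNR). Default regions are a CSF-like block (f = 0.75,
D = 3·10⁻³, D* = 3·10⁻², S0 = 1000) and a tissue-like block (f = 0.15,
D = 8·10⁻⁴, D* = 10⁻², S0 = 800) at SNR 40.

The flow generator produces sinusoidal near-zero-mean waveforms
v_k = offset + A·sin(2πk/n) at the left-endpoint phases k/n of one cycle
(retrospective gating convention; for n divisible by 4 the extrema are
sampled exactly), clipped at ±venc = 5 cm/s — clipping, not wrapping,
because aliasing reconstruction is out of scope and the clip documents the
encoding ceiling. The synthetic peak channel scales the oscillation by 1.5
(between plug flow's 1 and parabolic flow's 2); default per-ROI amplitudes
are chosen so the peak-channel VA equals the published per-ROI VA means,
and ROI areas are order-of-magnitude anatomical values. Ground-truth
metrics use the closed-form integrals of the clipped-free, noise-free
waveform: F = (T/2π)[C(π + 2·asin(r)) + 2A√(1−r²)] with C, A the offset and
amplitude of Q and r = C/A.

The cohort generator draws Gaussian per-group values with the published
group means and SDs (three healthy age bands n = 45/46/36 and a Hakim-like
group n = 44, with the published sex splits), optionally imposing
cross-measurement correlations through a Cholesky factor of the correlation
matrix (so SD = 0 reproduces the mean exactly).

None of the generators model anatomy, k-space, partial volume, spatially
correlated noise, motion, heteroscedastic f across a region, or non-Gaussian
cohort tails. Passing tests therefore demonstrate the correctness of the
estimators and statistics under the stated forward models — not robustness
to real-scanner artifacts, segmentation error, or distributional
misspecification in patient data.

## Problem sizes and numerical choices

The test suite exercises voxel fitting on 27 noiseless parameter
combinations plus a 500-voxel Rician Monte Carlo, flow integrals at 8–256
phases, and cohort statistics at n = 500 per group — sizes at which the
sampling-error bounds asserted by the tests (3·SE for means, ±0.08 for a
ρ = 0.5 correlation at n = 500) are comfortably diagnostic. Seeds are fixed
throughout; the pipeline CLI logs every seed and stamps outputs with a
config digest, so fixed-seed reruns are byte-identical.

Known limitations: the low-f (tissue-like) IVIM regime remains noticeably
biased at SNR 40 even with the floor correction (f is hard to separate from
D* when the fast pool is small) — ROI means there should be read with the
reported voxel counts in mind; the Mann–Whitney exact path declines to
enumerate tied samples; and the FOI's weighting constants are adopted, not
derived, so the index's scale has no physical unit.
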