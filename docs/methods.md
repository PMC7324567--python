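# Methods

`cardioqsm` implements quantitative susceptibility mapping (QSM) of the
myocardium: from multi-echo gradient-echo complex data to a voxelwise map of
the magnetic susceptibility difference Δχ (ppm relative to water), plus the
analyses built on it — T2*/R2* relaxometry, region statistics of the infarct
paramagnetic shift, FWHM infarct sizing and ROC classification. Because no
public cardiac multi-echo dataset accompanies the problem, a synthetic
cardiac phantom generator is a first-class component: it defines the study
conditions under which every property of the pipeline is tested.

## Forward model

Tissue magnetized by the main field B₀ perturbs it by the convolution of Δχ
with the unit dipole response. In the Fourier domain,

    Φ = F⁻¹ D F Δχ,    D(k) = 1/3 − kz²/|k|²,

with kz the projection of the spatial frequency vector onto the B₀
direction and Φ the field perturbation in the same ppm units as Δχ. D is
sampled on the DFT lattice in physical units (cycles/mm), so anisotropic
voxels and oblique B₀ are handled; D(0) := 0, i.e. a uniform susceptibility
offset is unobservable and maps are referenced to a tissue region after
inversion. Convolution is circular; the phantom keeps all sources at least
25% of the grid extent away from the boundary so wrap-around is negligible.
The operator is a real, even Fourier multiplier and therefore self-adjoint,
which the conjugate-gradient solvers rely on.

Validation: for a uniformly susceptible sphere the kernel above gives
exactly zero field shift inside and the point-dipole field
χ·(a³/3r³)(3cos²θ−1) outside; the FFT field of a radius-8-voxel sphere on a
128³ grid matches this closed form to well under 2% RMS of the peak outside
a 2-voxel boundary shell.

## Synthetic cardiac phantom

Geometry is an ellipsoidal shell (LV myocardium) around a blood pool, with
an infarct as an angular wedge of the shell: voxels within a stated azimuth
sector whose transmural depth from the endocardium does not exceed the
transmurality fraction. Voxels take the label of their center (no
partial-volume mixing) so label-wise ground truth is exact. Defaults mirror
the ex vivo imaging conditions: 5 echoes at TE 3.3–16.1 ms (ΔTE 3.2 ms),
3 T, isotropic ~1 mm voxels on 48–128³ grids, a susceptibility-matched
zero-signal bath (a heart explant in Fomblin), infarct Δχ = +0.07 ppm over
remote myocardium at 0 ppm, and amplitude SNR 40. An optional air inclusion
(χ ≈ 9.4 ppm, no signal) emulates the in vivo lung-interface background
field. Values the source protocol does not pin down are package choices,
made once: remote T2* 25 ms, infarct (hemorrhagic core) T2* 8 ms, blood
20 ms, S0 100 (myocardium) / 110 (blood), receiver phase 0.1 rad, infarct
wedge 90° at 0.8 transmurality (≈20% of the LV, matching the intended
infarct size of the occlusion model).

Signals are synthesized per voxel as S(TE) = S₀·e^(−TE/T2*)·e^(i(φ₀+2πfTE))
with f = Φ·10⁻⁶·γ̄·B₀ (γ̄ = 42.576 MHz/T) and independent complex Gaussian
noise of SD S₀,myo/SNR per echo; phase wrapping arises naturally from the
complex representation. What the generator does *not* model: cardiac or
respiratory motion, flow, coil sensitivities, chemical shift (water-only
tissue), partial-volume mixing, or contrast agents. Passing tests therefore
demonstrate correctness of the reconstruction chain under its stated noise
model, not robustness to those confounds.

## Field preparation

Phase is unwrapped temporally: echo-to-echo increments come from
angle(S_j·S̄_{j−1}), wrap-free while the true increment stays below π
(ΔTE 3.2 ms allows local fields up to ±156 Hz ≈ ±1.2 ppm at 3 T), and echo 1
is unwrapped spatially by a quality-guided algorithm to handle larger
accumulated phase. Every output is congruent to the wrapped input modulo 2π
— the testable contract, independent of algorithm choice.

The total field is a per-voxel weighted linear least-squares fit of
φ(TE) = φ₀ + 2πf·TE with magnitude-squared weights (maximum-likelihood for
complex Gaussian noise), converted to ppm. The tissue mask thresholds the
echo-1 magnitude at rel_threshold × (99th percentile), default 0.15, keeps
the largest connected component and erodes by one voxel. The SNR weight W
is the root-sum-of-squares echo magnitude, zeroed outside the mask and
normalized to mean 1 over it.

## Background field removal (PDF)

Fields from sources outside the tissue (air, anatomy beyond the FOV) are
estimated by fitting an exterior-supported susceptibility distribution
minimizing ‖W(F⁻¹DFχ_ext − Φ_total)‖₂², solved by conjugate gradient on the
normal equations (defaults: relative tolerance 1e−6, 100 iterations,
exterior = complement of the 1-voxel-eroded mask). The local field is the
masked residual.

Two properties of this projection deserve emphasis, both established by
direct experiment in this package and reflected in its tests:

- **Extended interior sources are partially removed.** Any component of the
  in-mask field that is harmonic inside the mask can be represented by
  exterior sources. A compact ("point-dipole") source deep in the mask
  keeps ≳90% of its field RMS — the regime of the orthogonality argument
  that motivates the method — but a source of extent comparable to the mask
  loses ~40–50% of its field, because the smooth dipolar tail *is*
  harmonic away from the source. Susceptibility maps reconstructed after
  the projection therefore underestimate broad contrasts.
- **The projection is regularized by CG truncation, not by the model.** The
  exterior holds more unknowns than the mask holds data samples, so the
  fully converged least-squares fit would interpolate the in-mask field
  exactly and null it. The default truncation is what leaves tissue field
  behind; re-running the projection on its own output removes a further
  few percent rather than being exactly idempotent.

Consequently, for the default ex vivo phantom — a susceptibility-matched
bath with no exterior sources, where the true local field equals the masked
total field — the pipeline exposes `apply_pdf=False`, and the headline
parameter-recovery analyses use that setting. The projection remains the
default for data with genuine background sources (in vivo profile), where
it suppresses an exterior source's field to <1% RMS inside the mask.

## Dipole inversion (MEDI)

Δχ minimizes

    λ‖M G Δχ‖₁ + ‖W (F⁻¹ D F Δχ − Φ)‖₂²,

with G the per-axis forward-difference gradient (per mm; zero at the far
boundary), M a per-axis binary edge mask that lifts the penalty on the top
`edge_fraction` (default 0.3) of in-mask magnitude-gradient voxels so
susceptibility edges may coincide with anatomy, and anisotropic
(L1-of-components) total variation. The solver is iteratively reweighted
least squares: the L1 term is majorized by a weighted L2 term with weights
1/√(|MGΔχ|²+ε²) (ε = 1e−6 ppm/mm), and each outer iteration solves the
resulting SPD system by conjugate gradient (tolerance 1e−6, ≤100
iterations), warm-started from the current iterate. This majorizes the
ε-smoothed objective, so a monotone safeguard rejects any outer step that
would raise the exact L1 objective (possible at the O(λ·ε) level near
convergence) and stops. χ is constrained to zero outside the mask;
initialization is χ₀ = 0 and the solver contains no randomness. Outer
iterations stop at a relative objective decrease below 1e−4 or after 10
iterations.

λ defaults to 3e−4 under this package's unit convention (fields in ppm,
gradients per mm), chosen once by an L-curve sweep on the default phantom
at SNR 40: the maximum-curvature corner of (log fidelity, log TV) over
λ ∈ 1e−5…3e−3 sits at 3e−4. Larger values visibly over-smooth the wedge
contrast. λ, ε, the edge fraction and all iteration controls are exposed
configuration, not constants.

On the default 96³ phantom at SNR 40 the full chain (mask → unwrap → field
fit → inversion → referencing to remote myocardium) recovers the
infarct−remote contrast of 0.07 ppm within a few percent, with a voxelwise
infarct-vs-remote ROC AUC above 0.95.

## Relaxometry

Voxelwise two-parameter fit of S = A·e^(−TE/T2*) on magnitude data:
weighted log-linear initialization (weights S²) refined by damped
Gauss–Newton with per-voxel backtracking, iterated to parameter
convergence. T2* is clamped to [1, 200] ms with clamped voxels flagged;
R2* = 1/T2* (ms⁻¹); the error map is the RMS residual divided by fitted A.
No Rician-bias correction is applied (fits use magnitudes as acquired), so
at SNR ≲ 5 the noise floor biases T2* upward — asserted as a sign check in
the tests. Zero-signal voxels yield flagged NaNs rather than exceptions.

## ROI analysis

Region classification replaces interactive contouring with a deterministic
rule: with μ, σ (sample SD) from a known-remote seed region on the
last-echo T2*-weighted image, voxels below μ−kσ are hypointense, above
μ+kσ hyperintense, the rest isointense (k = 2 by default; externally drawn
masks are accepted unchanged). Susceptibility is referenced by subtracting
the mean over the remote region — only Δχ contrasts are observable.

FWHM infarct sizing anchors the half-maximum to the remote mean
(threshold = remote_mean + ½(max − remote_mean)), making the rule invariant
to affine intensity scaling; the plain ½·max variant is available. ROC
analysis sweeps thresholds over the unique predictor values with
"greater is positive" polarity; AUC is the trapezoidal integral and equals
the pairwise concordance probability with ties counted ½ (asserted exactly
against a brute-force count); Youden's J = max(sens+spec−1) defines the
optimal operating point, reporting the lower threshold at ties. Group
statistics are exported as tidy tables (sample SD throughout); hypothesis
testing is left to standard statistics environments.

## Numerical choices and degenerate inputs

- All fields in ppm after the field fit; one unit convention end to end.
- Grids of fewer than 2 voxels per axis, empty masks, non-finite inputs,
  single-echo field fits, zero-variance reference regions and non-increasing
  echo times are rejected with specific errors; zero-signal voxels and
  no-enhancement FWHM inputs degrade gracefully (flags/warnings).
- Determinism: identical phantom specs (including seed) give bit-identical
  data; the reconstruction contains no randomness; pipeline reruns with the
  same config are bit-exact.
- Problem sizes in the shipped tests and the acceptance script are desk
  scale: 48–64³ for unit properties, 96³ for the background-removal and
  parameter-recovery checks, 128³ for the sphere oracle.

## Known limitations

- PDF over-removal of extended interior fields (above) — the central
  caveat when interpreting reconstructed amplitudes after background
  removal on data where lesions are large relative to the mask.
- The temporal unwrapping regime requires |Δφ| < π between echoes
  (≈ ±1.2 ppm at 3 T with ΔTE 3.2 ms); stronger fields rely on the spatial
  unwrap of echo 1.
- Monoexponential T2* only; no fat–water separation, no motion or flow
  modeling, no multi-orientation acquisition support.
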