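# Methods

## The reconstruction problem

Ptychography scans a localized coherent illumination (the *probe*
P(r)) across a sample (the *object transmissivity* O(r)) and records,
for each scan position r_j, the far-field diffraction intensity of the
exit wave Ψ_j(r) = P(r − r_j) O(r).  Because neighbouring positions
overlap, the redundant intensity-only measurements determine both P
and O up to well-understood ambiguities.  The forward model used
throughout is

    I_j(q) = Σ_m | F[ P_m(r − r_j) O(r) ] |²,

where F is a centered, unitary 2-D discrete Fourier transform and the
sum runs over mutually incoherent probe modes P_m.  Incoherent modes
model partial transverse coherence and slow vibrations: mode
intensities, not amplitudes, add at the detector.  Object modes and
multiple layers are stored in the data model but not solved; the
engines operate on object mode 1, layer 1.

The effective real-space pixel of the reconstruction is
Δr = λz/(NΔd) (wavelength λ, detector distance z, frame size N,
detector pixel Δd).  Scan positions are kept in object-plane pixels;
metre-valued inputs are converted at ingest.  Positions are rounded to
the nearest pixel (ties to even) for view extraction; sub-pixel
interpolation is out of scope.

Several scans can be reconstructed jointly while pointing to shared
probe and/or object storage slices through two per-scan index vectors
(`probe_share_ID`, `object_share_ID`), renumbered to dense 1..K at
construction so arbitrary labels such as (2,7,2) behave like (1,2,1).

## Difference-map engine

The exit-wave stack is iterated as

    Ψ ← Ψ + P_O(2·P_F(Ψ) − Ψ) − P_F(Ψ),

with the Fourier projection applied first and the overlap projection
second; with a good starting guess this ordering avoids a redundant
initial overlap projection.  P_F propagates every mode to the
detector, rescales all modes at valid pixels by
sqrt(I_meas / Σ_m |ψ̂_m|²) (0/0 → 0; invalid pixels untouched), and
propagates back.  P_O computes the least-squares-consistent pair

    O(r) = Σ_j Σ_m P_m*(r−r_j) Ψ_jm(r) / Σ_j Σ_m |P_m(r−r_j)|²,
    P_m(r) = Σ_j O*(r+r_j) Ψ_jm(r) / Σ_j |O(r+r_j)|²,

accumulated over every scan sharing the slice, and returns refreshed
views P·O.

**Regularization.**  Each quotient's denominator is floored at
ε = 1e-4 × its maximum rather than incremented by ε.  The floor form
leaves well-illuminated pixels *exactly* at their least-squares value
(the additive form biases every pixel by ~ε), while still damping
unilluminated pixels to zero.  This is why a consistent (P, O) pair is
a fixed point of the overlap projection to near machine precision.

**Error metric.**  The reported error is
Σ_k Σ_{l∈M} (√I_model − √I_meas)² over valid pixels l and positions
k, both raw and normalized by the measured flux Σ I_meas.  An
absolute-difference variant (|√I_model − √I_meas| summed) is available
via `error_metric="abs"`; the squared form is the default because it
coincides with the ML objective, so the two engines share one error
surface and `error_target` values are interchangeable.

**Defaults.**  Probe updates are frozen for the first 3 iterations so
the object can settle against the initial probe; no object-amplitude
clipping; no randomness anywhere in the engine.

## Maximum-likelihood engine

ML refinement minimizes the same amplitude objective
L = Σ (√I_model − √I_meas)² by nonlinear conjugate gradient over the
concatenated probe-and-object space (one joint line search per
iteration).  The amplitude-Gaussian objective was chosen over a
Poisson likelihood so DM and ML optimize the identical surface.

Gradients are Wirtinger-style and returned as the *real* gradient
g = 2 ∂L/∂z̄, so the directional derivative along a step z + αd is the
plain real inner product ⟨g, d⟩ — the convention every finite-
difference check in the tests uses.  With
A = Σ_m |ψ̂_m|² and the per-pixel residual factor
c = 1 − √I_meas/√A on valid pixels (0 elsewhere, A floored at
1e-30 × max A against division by zero),

    ∂L/∂O* ∝ Σ_j,m P_m* · F⁻¹[c · ψ̂_m],   ∂L/∂P_m* ∝ Σ_j O* · F⁻¹[c · ψ̂_m].

**Search directions.**  Polak–Ribière *plus*,
β = max(0, ⟨g_new, g_new − g_old⟩/⟨g_old, g_old⟩), with the Powell
restart |⟨g_new, g_old⟩| ≥ ν ⟨g_new, g_new⟩ (ν = 0.2 by default).
The absolute-value form of the restart is used deliberately: it makes
ν = 0 mean "restart every iteration", which reduces the method exactly
to steepest descent — a property the tests verify step-for-step
against an independent gradient-descent loop.

**Line search.**  Bracket by geometric expansion (factor 2), probe the
bracket with a quadratic fit through (0, f(0), f'(0)) and the first
trial, then a cubic fit through the two best points, then geometric
bisection toward zero; accept under the Armijo criterion
f(α) ≤ f(0) + c₁ α f'(0) with c₁ = 1e-4, budget 20 evaluations,
returning the best Armijo-satisfying point seen.  Because slopes are
negative and c₁ < 1, the geometric-shrink fallback always terminates
on smooth objectives; a genuine failure (twice in a row) stops the
engine with a status flag rather than looping.

**Grouped summation.**  Objective values are reduced with a
magnitude-grouped summation: values are bucketed by binary exponent,
each bucket is summed pairwise in its native precision, and the bucket
totals are combined exactly (ascending by magnitude).  The result is
within 64·eps·Σ|values| of the exact sum for any input ordering, which
keeps Armijo comparisons meaningful when residuals span many orders of
magnitude.

## Compression codec

Counts N are variance-stabilized as M = √N (Poisson noise then has
σ ≈ 0.5 independent of the mean) and uniformly quantized:
code = clip(round(M/QS), 0, 2^b − 1), round half to even, with the
saturated-pixel count surfaced to the caller.  Defaults: QS = 0.5
(equal to the Poisson σ, adding quantization variance QS²/12 ≤ σ²/3),
b = 8 with automatic promotion to 16 bits when the input maximum
exceeds the nominal 8-bit capacity.  Capacity is reported both as the
nominal bound (2^b·QS)² — 16 384 counts at b=8, QS=0.5; ≥ 1e9 at
b=16 — and the exact saturation value ((2^b−1)·QS)² = 16 256.25 at
b=8.  Memory saving versus 32-bit float moduli is 100·(1 − b/32)%.
Decompression is N̂ = (code·QS)², bounding the square-root-domain
round-trip error by QS/2 for non-saturated values.

The quality sweep reconstructs the same measured stack after
compression at each QS and scores the recovered object against ground
truth by SNR = −10 log₁₀(mean|O_rec − O_true|²/mean|O_true|²) and by
the Fourier ring correlation (ring width one frequency bin, half-bit
threshold; ring 0 is excluded from the crossing search because its
single-pixel threshold is identically 1).

## Synthetic data

The generator emulates a far-field scanning experiment at desk scale.
Defaults, chosen once as a representative small instance of the
scanning geometries the engines target:

* geometry: λ = 0.1 nm, z = 7.2 m, Δd = 112.5 µm, N = 64
  → Δr = 100 nm;
* probe: binary circular aperture of 3.2 µm (32 px), propagated
  2.4×10⁻⁴ m out of focus by the angular spectrum method, unit energy;
  extra incoherent modes are phase-ramped apertures, Gram–Schmidt
  orthonormalized, with energies ∝ 4⁻ᵏ (0.8/0.2 for two modes);
* object: overlapping-Gaussian-disc phantom, amplitude in [0.7, 1],
  phase in ±1 rad, deterministic per seed;
* scan: 7×7 raster, step 12.8 px (60% linear overlap with the 32 px
  aperture), uniform jitter up to 0.1·step to break the raster
  pathology; a Fermat-spiral pattern is available (its
  nearest-neighbour spacing is more uniform than a strongly jittered
  raster, CV ≈ 0.08 vs ≈ 0.13 at 0.2 jitter);
* flux: 10⁶ counts per frame on average (the probe is rescaled so the
  ground truth reproduces the stored intensities exactly), Poisson
  noise optional, optional dead-pixel mask (default all valid).

What the generator does *not* emulate: detector point-spread and
readout noise, background, position errors, continuous (non-modal)
partial coherence.  Passing tests therefore demonstrate algorithmic
correctness on an idealized instrument, not robustness to those
systematics.

**Scoring conventions.**  Probe/object factorizations leave a global
complex scale and an affine phase (offset + linear ramp) undetermined.
Before scoring, the reconstruction is aligned to ground truth over the
well-illuminated region (accumulated |P|² footprint above 10% of its
peak — a fixed constant): a coarse ramp estimate from the spectral
peak of the weighted ratio O_true·conj(O_rec), two wrap-free weighted
plane fits, then a least-squares complex scale.  Phase RMSE and SNR
are computed on the aligned object inside the mask.

## Problem sizes and observed behaviour

The shipped tests and the acceptance script run, per seed, a noiseless
64×64-probe 7×7-position reconstruction (200 DM + ≤80 ML iterations),
a two-mode/one-mode comparison (150 DM iterations each), and a
Poisson-limited QS sweep over {0, 0.25, 0.5, 1, 2, 4} (100 DM
iterations each) — sizes at which the whole suite completes in about a
minute on one core while still exercising every code path.  At these
conditions the DM error drops by more than two orders of magnitude,
ML reaches < 1e-6 normalized error, phase RMSE lands well below
0.01 rad, the two-mode model beats the one-mode model by far more
than 10×, and QS = 0.5 costs under 0.1 dB of SNR.

## Known limitations

* Only far-field engines; the angular-spectrum propagator exists (with
  a hard evanescent cutoff and an optional paraxial transfer function)
  but no near-field reconstruction path is validated.
* Single object mode / single layer solved; no position, geometry or
  wavelength refinement; no relaxed-DM/RAAR variants; no Poisson ML.
* The HDF5 group and dataset names are this package's documented
  dialect; the layout (per-scan groups, single-copy probe/object
  storage with soft links, external data link) is the stable contract.
* Fractional scan positions are rounded to whole pixels; datasets whose
  information lives at deep sub-pixel scales need refinement methods
  out of scope here.
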