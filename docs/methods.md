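# Methods

This document defines the signal model, the numerical phantom, the analysis
arms, the default parameters (with rationale), and the known limitations of
`cestll`.

## 1. Signal model

### 1.1 Sequence

One repetition of the dynamic acquisition consists of, per frequency
offset Δω:

1. an off-resonant saturation block of duration T<sub>prep</sub> at
   amplitude ω<sub>1</sub> = γB<sub>1</sub>,
2. an adiabatic inversion (modelled as ideal, crushed, efficiency 1), and
3. a continuous spoiled-FLASH readout of N<sub>TR</sub> low-flip pulses
   (the Look-Locker train).

Offsets are acquired back to back; there is no steady-state wait between
them.  The recovery between the end of one readout and the next saturation
is part of the readout train itself.

### 1.2 Saturation

Exchange-dependent relaxation of a dilute solute pool s with relative
fraction f<sub>s</sub>, exchange rate k<sub>s</sub> and transverse rate
R<sub>2s</sub> is modelled as a Lorentzian line in the rotating frame,

R<sub>ex</sub>(Δω) = a · (Γ/2)² / ((Γ/2)² + (Δω − δ<sub>s</sub>)²),

with amplitude and full width

a = f<sub>s</sub> k<sub>s</sub> ω<sub>1</sub>² /
(k<sub>s</sub>(k<sub>s</sub> + R<sub>2s</sub>) + ω<sub>1</sub>²),   
Γ = 2 √( (R<sub>2s</sub> + k<sub>s</sub>)² +
(R<sub>2s</sub> + k<sub>s</sub>)/k<sub>s</sub> · ω<sub>1</sub>² ).

The amplitude relation is algebraically invertible, so a fitted line
amplitude maps back to f<sub>s</sub> exactly
(`signal_model.fraction_from_amplitude`).

The water rotating-frame rate is

R<sub>1ρ</sub>(Δω) = R<sub>1</sub> cos²θ + R<sub>2</sub> sin²θ +
Σ<sub>pools</sub> R<sub>ex</sub>,  with cos²θ = Δω²/(Δω² + ω<sub>1</sub>²),

and the driven steady-state Z-value is
f<sub>ss</sub> = cos²θ · R<sub>1</sub>/R<sub>1ρ</sub>.  After a finite
saturation time the transient Z-value is

Z<sub>trans</sub> = (f<sub>rec</sub> − f<sub>ss</sub>)
e^(−T<sub>prep</sub> R<sub>1ρ</sub>) + f<sub>ss</sub>,

where f<sub>rec</sub> is the Z-fraction at the start of the block.

### 1.3 Readout and chaining

During the FLASH train the longitudinal magnetization relaxes with the
apparent rate R<sub>1</sub>* = R<sub>1</sub> + R<sub>1</sub>′ towards the
Look-Locker steady state f<sub>ss,LL</sub> =
R<sub>1</sub>/(R<sub>1</sub> + R<sub>1</sub>′).  R<sub>1</sub>′ collects
the readout-induced saturation; for the default train (TR 4.2 ms, flip 6°)
R<sub>1</sub>′ = −ln(cos α)/TR = 1.308 s⁻¹.  After the inversion the signal
along the train is

M(t) = M<sub>0</sub> [ f<sub>ss,LL</sub> −
(Z<sub>trans</sub> + f<sub>ss,LL</sub>) e^(−t R<sub>1</sub>*) ].

Because offsets are chained, the starting fraction of every block except
the first is f<sub>ss,LL</sub> (the train is long enough to reach its
steady state); the very first block starts from thermal equilibrium,
f<sub>rec</sub> = 1.  `signal_model.combined_signal_arrays` evaluates the
full (offset × time × voxel) model in vectorized form; it is the forward
model shared by the voxel fit and the model-based reconstruction.

### 1.4 Assumptions

* Dilute pools: back-transfer to each solute is linear in
  f<sub>s</sub> k<sub>s</sub>; pool–pool cross exchange is neglected.
* Ideal spoiling: transverse magnetization is discarded between pulses.
* Ideal inversion (efficiency 1, crushed).
* Continuous-wave saturation at the stated B<sub>1</sub>; shaped or pulsed
  trains are represented by their average amplitude.
* A single B<sub>0</sub> shift per voxel (fitted as a global spectrum
  shift ω<sub>0</sub>).

## 2. Bloch–McConnell oracle

`cestll.bmc_sim` integrates the full coupled Bloch–McConnell equations
(3 components per pool plus a constant) with matrix exponentials; nothing
from Section 1 enters it.  It supplies:

* `evolve` — exact constant-RF propagation, used for steady-state checks;
* `simulate_scheme` — the full chained sequence: exact saturation
  propagators per offset, ideal inversion, and the FLASH train propagated
  with a longitudinal-only homogenized generator between pulses, with
  cos α applied at each excitation and the transverse signal sampled as
  sin α · M<sub>z</sub>.

The phantom ground-truth signals come from this simulator, so agreement of
the fitted parameters with the ground truth is an end-to-end test of the
analytic model, not a tautology.

What the oracle does *not* emulate: shaped RF pulses (CW stand-in),
B<sub>0</sub>/B<sub>1</sub> field inhomogeneity, imperfect spoiling,
diffusion, magnetization-transfer pools with super-Lorentzian lineshapes.

## 3. Numerical phantom and data synthesis

* 64×64 grid; a ring of 10 tubes plus one centre tube (11 regions) on a
  uniform background disc.  Tube T<sub>1</sub> values span 450–1600 ms and
  solute fractions 0–0.9% in 0.1 %-pt steps (one tube has zero solute),
  k<sub>s</sub> = 200 s⁻¹, T<sub>2</sub> = 110 ms for water and solute,
  solute at +4.2 ppm.
* Coil sensitivities: 20 smooth complex maps (low-order random polynomials
  over the FOV), representing a realistic receive array.  For the
  model-based reconstruction they are compressed to 8 virtual coils by SVD,
  which preserves > 99.9% of the signal energy at a 2.5× cost reduction.
* k-space: stack-of-spokes golden-angle radial, 3 spokes per frame
  (angle increment 111.246°, continuous across frames), one frame per
  (offset, time) pair — a nominal undersampling factor of ~33 relative to
  a fully sampled Cartesian frame.  A Cartesian path exists for reference.
* Noise: complex Gaussian noise added per k-space sample with
  σ = 0.05 · max|image| per real/imaginary component
  (`noise_interpretation="image-amplitude"`), i.e. 5% of the peak image
  magnitude.  The noise-free and noisy analysis arms use the same seed
  machinery, so arms differ only by the noise realization.

## 4. Analysis arms

1. **Image-space fit (noise free / noisy)** — coil-combined image series
   (inverse FFT of fully sampled Cartesian data) fitted voxel-wise with the
   combined model; parameters per voxel: M<sub>0</sub>, R<sub>1</sub>,
   R<sub>1</sub>′, R<sub>2</sub>, ω<sub>0</sub>, plus (a, Γ) per pool.
   Magnitude data first pass through polarity restoration (sign flip before
   the magnitude minimum of each inversion-recovery block, with the pivot
   sign chosen by local linear prediction).
2. **Model-based reconstruction (MBR)** — the same parameter maps estimated
   directly from undersampled radial multi-coil k-space by Gauss–Newton:
   each outer step linearizes the forward operator (model Jacobian ×
   coil-projection × NUFFT) and solves the TGV-regularized linear subproblem
   with a primal–dual (Chambolle–Pock) iteration.  Regularization weight γ
   is reduced geometrically over the outer steps and floored once the data
   fidelity reaches the noise floor (discrepancy principle); the remaining
   outer steps iterate at the floored γ so the maps converge without
   fitting noise.  Steps that increase the data fidelity by more than 10%
   are rejected and revert the iterate.  Initialization is a
   density-compensated gridding reconstruction fitted voxel-wise (with the
   same channel pins as the outer loop), with a global least-squares scale
   on M<sub>0</sub>.  Channels that the acquisition does not modulate are
   pinned to their nominal values: R<sub>1</sub>′ (a sequence constant),
   the Lorentzian width (determined by the same k<sub>s</sub>/R<sub>2s</sub>
   assumed by the fraction inversion), ω<sub>0</sub> = 0 and water
   R<sub>2</sub> (the phantom has no B<sub>0</sub> inhomogeneity or
   R<sub>2</sub> contrast).  Freeing them only opens noise-driven drift
   directions: a free ω<sub>0</sub> rectifies one-sidedly into a positive
   amplitude bias, and a free R<sub>2</sub> or width entangles with
   M<sub>0</sub> and the amplitude under heavy undersampling.
3. **Conventional arm (QUASS + Lorentzian, noise free / noisy)** — the last
   readout sample per offset forms a transient Z-spectrum; QUASS
   extrapolates it to steady state by solving the transient equation for
   R<sub>1ρ</sub> per offset (bracketed root finding), using the fitted
   T<sub>1</sub> and the chained recovery fraction; a two-pool Lorentzian
   fit of the corrected spectrum yields label/reference values at
   ±4.2 ppm; MTR<sub>AREX</sub> = (1/Z<sub>lab</sub> − 1/Z<sub>ref</sub>) ·
   R<sub>1</sub> equals R<sub>ex</sub>/cos²θ at steady state, so the line
   amplitude passed to the fraction inversion is
   MTR<sub>AREX</sub> · cos²θ.

ROI statistics are Bland–Altman style: per-tube means of fitted minus
ground-truth maps after a 1-pixel erosion, reported as the ROI-mean absolute
T<sub>1</sub> deviation (ms) and the mean signed fraction deviation
(percentage points), plus the maximum relative concentration error over the
non-zero tubes.

## 5. Default parameters

| Parameter | Default | Rationale |
|---|---|---|
| B<sub>0</sub> | 3 T | clinical field; γ·3T = 127.7 MHz |
| B<sub>1</sub>, T<sub>prep</sub> | 1 µT, 1.5 s | selective for slow–intermediate exchange; transient regime that QUASS must correct |
| T<sub>rec</sub> | 3.5 s | recovery entering the QUASS chaining |
| Offsets | 26, −5…+6 ppm | asymmetric span so the +4.2 ppm line and its reference are both sampled; 0.44 ppm spacing resolves the line width |
| Readout | TR 4.2 ms, flip 6°, 960 TRs | ≈4 s train covering the full Look-Locker recovery; R<sub>1</sub>′ = 1.308 s⁻¹ |
| Time bins | 20, log-spaced | early samples carry the inversion transient; logarithmic spacing concentrates them there |
| Coils | 20 physical, 4 virtual for MBR | array-sized coil count; SVD compression bounds the per-iteration NUFFT cost (linear in channels) while retaining the dominant sensitivity energy |
| Spokes/frame | 3, golden angle | extreme per-frame undersampling that MBR is designed to handle |
| Noise | 5% of max image amplitude | visible in single frames, representative SNR |
| k<sub>s</sub>, T<sub>2</sub> | 200 s⁻¹, 110 ms | amide-proton-like slow exchange at physiological relaxation |
| TGV | γ ratio 0.5, geometric reduction 0.5, 9 outer steps with γ floored at 3×10⁻² of γ_start, 50 inner iterations | standard second-order TGV weighting; the floor stops the continuation at the measured noise floor and the remaining steps converge there |

## 6. Numerical choices

* **NUFFT**: Kaiser–Bessel interpolation (width 8, oversampling 2, Beatty
  β), deapodization by the inverse DFT of the sampled kernel so that
  on-grid transforms are exact; forward/adjoint pass a dot-product test to
  < 10⁻⁶ relative in double precision.  Float32 is used inside the MBR for
  speed.
* **Step sizes**: the primal–dual operator norm is estimated by power
  iteration each outer step.
* **Channel equalization**: parameter channels are rescaled each outer step
  so the Jacobian columns have comparable norms (bounded below at 10⁻³ of
  the maximum), which conditions the linear subproblem.
* **QUASS root finding**: Brent's method on a bracket
  [10⁻³·R<sub>1</sub>, 10³] s⁻¹; offsets without a sign change are flagged
  `uncorrectable` and left at their input value.
* **Look-Locker initialization**: the voxel fit seeds from a 3-parameter
  Look-Locker fit of the farthest offset block, which is nearly
  CEST-free.

## 7. Limitations

* **Lorentzian R<sub>ex</sub> validity**: the amplitude/width expressions
  are a large-shift, dilute-pool approximation.  Against the
  Bloch–McConnell oracle the steady-state Z-spectrum agrees to well under
  1% for fractions ≲ 0.1% but deviates by up to ~15% locally for
  fractions approaching 1% at 1 µT, mostly between the water and solute
  lines.  The *fitted* parameters remain accurate because the deviation is
  largely absorbed by the fitted width and the parameter inversion uses
  the amplitude only, but spectrum-level agreement beyond a few percent
  should not be expected at high fractions.  Near water resonance
  (|Δω| < 1 ppm) the single-eigenvalue R<sub>1ρ</sub> picture itself
  breaks down.
* The fitted fraction deviations of the conventional arm depend on the
  Lorentzian approximation twice (once in the data, once in the metric),
  so its bias differs in sign and size from the joint-model arms.
* Ideal inversion and spoiling; no B<sub>0</sub>/B<sub>1</sub> maps; no
  motion; single-slice 2D.
* The MBR runtime is dominated by the NUFFT; with default settings a full
  study takes on the order of 15–20 minutes on one CPU core.
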