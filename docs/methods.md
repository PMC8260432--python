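# Methods

`echosos` implements pulse-echo speed-of-sound (SoS) tomography with a
conventional linear array, comparing plane-wave (PW) and diverging-wave
(DW) transmit schemes. This note documents the model, the choices behind
every tunable parameter, what the synthetic data generator does and does
not emulate, and the numerical details of the solver.

## Imaging model

Local sound speed `c(x, z)` (m/s) — equivalently slowness
`sigma = 1/c` (s/m) — is reconstructed from *apparent displacements*
between images of the same medium formed from different transmit events.
Beamforming assumes a constant `c0`; wherever the true slowness deviates
from `sigma0 = 1/c0`, echoes arrive early or late relative to the
assumption, and the beamformed speckle shifts axially. For straight rays
the echo-time error of event *i* at image point *p* is the line integral
of `sigma - sigma0` along the transmit leg (source-to-p) plus the receive
leg (p-to-array); when two events are beamformed with the same receive
geometry the receive legs coincide, so the *relative* delay of a tracked
pair carries the transmit-leg difference.

Stacking all tracked pairs and image points gives the linear model
`dtau = L (sigma - sigma0)`, with L the sparse differential path matrix:
each row holds signed Siddon intersection lengths (positive for the path
of event *i*, negative for event *j*) over the reconstruction grid.
The slowness map is recovered as

    sigma_hat = argmin_sigma  || L (sigma - sigma0) - dtau ||_1
                              + lambda || D sigma ||_1

where D stacks Sobel horizontal/vertical and Roberts diagonal gradient
filters with anisotropic weights (axial Sobel weighted `kappa = 0.9`,
lateral `2 - kappa`, diagonals 1) to suppress the streaking artifacts of
limited-angle geometry. Both norms use the smooth surrogate
`phi(r) = sqrt(r^2 + eps^2) - eps` and the problem is solved with L-BFGS.

This is straight-ray travel-time tomography: refraction, diffraction and
full-wave aberration are outside the model.

## Transmit schemes and displacement tracking

A *multistatic* (full-matrix) capture — each element transmitting alone,
all receiving — is the common source from which both schemes are
recomposed by linearity:

- **PW**: every element fires with delay `x_e sin(theta) / c0`, forming an
  angled plane wave. The default fan is −20°..20°. Tracking runs between
  small angle increments `delta_theta` (2° by default; 0.5° supported) to
  limit speckle decorrelation, and increments are chained (summed) into
  the target disparity `delta_phi` (8° default).
- **DW**: a transmit event is a single element (circular wavefront inside
  a directivity cone); frames of transmits `delta_channel` elements apart
  are tracked directly.

In both schemes a fixed number `M = 9` of pair combinations feeds the
inversion. The exact pair placement is a convention of this package:
first elements (DW) or lower angles (PW) are placed uniformly across the
available range, snapped to the transmit grid; `M = 1` sits at the
center.

Displacements are estimated per pixel by zero-mean windowed normalized
cross-correlation (NCC) along the axial axis. The RF correlation
oscillates at the carrier, so the integer lag is chosen as follows: the
raw RF score argmax is accepted when it lies within half a carrier period
of the *envelope* cross-correlation peak, otherwise the lobe under the
envelope peak is used (this suppresses one-period "hops" between
partially decorrelated frames). The sub-sample refinement is a cosine fit
matched to the carrier (3-point parabola as fallback), and a peak on the
search boundary is marked invalid rather than reported. Measured
precision on synthetic band-limited speckle at 4 samples/carrier-period:
median error ~0.01 samples, 99th percentile ~0.03–0.05; integer shifts
are recovered with the integer part exact.

Delays convert from axial samples to seconds via the two-way rule
`dtau = 2 dz lag / c0` and are projected onto the axial direction by
`cos(psi_psf)` when the adapted (PSF-aligned) aperture is used.

## Beamforming

Delay-and-sum on a fixed Cartesian grid, dynamic receive aperture of
width `z / f_number` (F-number 1), Tukey(0.25) receive taper, linear
interpolation in fast time after 4x FFT upsampling. Two receive modes:
*full* (aperture centered above the pixel) and *adapted* (centered at
`x + z tan(psi_psf)`, aligning the receive axis at `psi_psf`; run at 0°
and ±15°). A pixel is invalid when its required aperture extends beyond
the physical array, fewer than 4 elements contribute, or (DW) it lies
outside the transmit cone `|x - x_src| <= z tan(opening)` (35° default,
matching the element-directivity cutoff of the simulator).

Two numerical choices matter and were set after explicit diagnosis:

- **Axial grid spacing is lambda/8 (37.5 um)**. The beamformed RF carries
  a `2 fc / c0` axial oscillation — 6.67 cycles/mm at 5 MHz — so a 0.15 mm
  axial grid aliases it and NCC on RF is impossible; 75 um samples it at
  Nyquist, making the envelope unreliable. lambda/8 gives 4 samples per
  carrier period.
- **Sub-sample delays are applied spectrally** in PW recomposition, and
  fast time is FFT-upsampled before beamformer interpolation. Linear
  interpolation has a small sub-sample phase bias; because it is coherent
  per transmit event, the ill-conditioned inversion amplifies it into a
  global SoS offset of several m/s.

## Synthetic data generator

The study set is 28 phantoms on a 38 mm x 50 mm field: cases 1–6 and 28
are geometric (layers, circles, ellipses, two circles) at ±2% contrast on
a 1500 m/s substrate; cases 7–27 carry a randomly shaped inclusion
(1450–1550 m/s) on a substrate with mean in 1485–1515 m/s plus a smooth
local ±3 m/s field. Random inclusions are the largest connected component
of thresholded Gaussian-smoothed noise (target area fraction drawn from
2–8% of the field of view); neither the size distribution nor the
background correlation length is prescribed by the study design, so both
are exposed as parameters (`blob_smooth_px`, `background_corr_px`).

RF channel data is synthesized by a **ray-based surrogate**: scatterers
are a random 10% of medium pixels given a density perturbation
(amplitude 0.05); each (tx element, scatterer, rx element) echo is a
band-limited pulse (3 half cycles at 5 MHz under a Hann taper,
mean-subtracted) placed at the two-leg slowness line-integral arrival
time with `1/sqrt(r_tx r_rx)` spreading and a cosine directivity window
cut at 35°. Scatterers live on a 75 um simulation grid — roughly ten per
resolution cell, enough for developed speckle; generating them on the
0.3 mm phantom-definition grid leaves ~0.05 per cell and tracking
decorrelates. A 60% fractional-bandwidth zero-phase band-pass is applied
after recomposition. Slowness line integrals use midpoint sampling at
0.15 mm steps (sub-nanosecond error for tissue-scale contrast).

What the surrogate reproduces: exact first-order travel times, hence the
delay signal that drives the tomography, plus realistic speckle
decorrelation between transmits. What it does not: diffraction, edge
waves, multiple scattering, attenuation and the full aberration physics
of a wave solver. Passing end-to-end tests therefore demonstrates the
correctness and internal consistency of the processing chain, not
performance on measured or full-wave-simulated data.

## Problem sizes

Module-level defaults are the full study conditions: 128 elements,
300 um pitch, 5 MHz, multistatic capture, 81 PW angles, `delta_channel`
17, `kappa` 0.9, 10^4 measurement subsampling. The end-to-end demo
pipeline (`RunConfig`) runs a scaled instance chosen so a full chain
completes in ~2.5 minutes on one CPU: 96 elements, 28.8 mm x 26 mm field
of view, `delta_channel` 13 (preserving the 17/128 disparity-to-aperture
ratio), 40 MHz sampling. A shallower 64-element scale was tried first and
rejected: the global-offset mode of the PW inversion — constrained only
by path-length differences that grow with depth — was too weakly pinned,
giving seed-dependent ±5 m/s offsets.

The NCC gate of the demo pipeline is 0.5 (not a hard 0.8): diverging-wave
pairs decorrelate by design at useful channel separations, and the robust
L1 data term is the intended consumer of partially decorrelated
readings; `ncc_axial` itself applies no gate unless asked.

## Solver numerics

The optimization variable is the dimensionless `u = sigma / sigma0` and
delays are expressed in microseconds, so `lambda` is a dimensionless
weight of order 1–10 (values are not commensurate with any other
package's units). Smoothing constants: 1 ns on the data term, 1e-4
(relative slowness) on the regularizer. Stopping: relative objective
change < 1e-8 or 500 iterations. The objective history is recorded per
accepted iterate and is monotone non-increasing; an increase beyond
tolerance raises a divergence flag in the diagnostics rather than an
exception. `lambda -> 0` with exact data recovers the truth (inverse
crime, RMSE < 1 m/s); `lambda -> inf` drives `||D sigma||_1` to zero.

## Known limitations

- Straight-ray physics only; no refraction or bent-ray updates.
- Desk-scale inclusion imaging from ray-simulated RF is qualitative: at
  the scaled aperture the differential delay signal of a ±2% inclusion
  (tens of ns) is comparable to tracking noise through decorrelated
  speckle, so recovered contrast is well below truth. Quantitative solver
  validation uses the inverse-crime route instead, where recovery is
  sub-m/s (noiseless) and < 1 m/s at 5% delay noise.
- The Walsh-Hadamard codec requires power-of-two channel counts (no
  padding).
- CNR is reported only for cases with >= 1% ground-truth contrast;
  evaluation masks exclude a 10% lateral margin on both sides (PW edge
  artifacts; the same mask is applied to DW for fairness).
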