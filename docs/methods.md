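# Methods

## Scattering model

`fastecho` simulates pulse-echo ultrasound in soft tissue with the
standard linear model: an isotropic, homogeneous, non-dissipative medium
(sound speed `c`, density `rho0`) containing `N` independent point
scatterers, each an instantaneous fractional density perturbation with
amplitude `a_s = d(rho)/rho0`. The signal received by element `j` after
element `i` transmits and scatterer `n` reflects is

    p_r(t) = d/dt [ (1 / (2 rho0 c^2)) * (p_T * p_R)(t) ] * a_s ,

where `*` is temporal convolution and `p_T`, `p_R` are the *intermediate
fields* — the transient pressures that the transmitting and receiving
elements would radiate at the scatterer position for face normal
velocities `w1(t)` and `w2(t)`:

    p_T(r, t) = rho0 * dw1/dt (t) * h_T(r, t) ,    (and likewise p_R)

with `h` the element's spatial impulse response. Transmit delays
`tau_i` and receive delays `tau_j` shift the intermediates in time.
Imaging modes differ only in how the pairwise terms are summed:

* **Synthetic aperture**: every element transmits individually; all
  M x M transmit/receive pairs are recorded.
* **B-mode**: a Hanning-apodized sub-aperture (64 elements by default)
  transmits focused at one depth per A-line; the transmit intermediates
  are delayed, weighted, and summed *before* the convolution, which is
  what makes an A-line cost one convolution per (scatterer, channel).
* **Plane wave**: all elements transmit with linear steering delays
  (offset to be non-negative; the offset is carried into beamforming);
  again the transmit sum precedes the convolution, and receive is
  element-wise.

Assumptions worth stating: no absorption or attenuation, no multiple
scattering, no high-impedance structures (bone), scatterers do not
interact, and elements are ideal rectangular pistons with uniform
normal velocity. Element directivity arises only from the aperture
integral itself.

## Transient-field evaluation

The intermediates are Rayleigh integrals of `dw/dt` at the retarded
time over the element face. For the rectangular-envelope sinusoidal
bursts used throughout (`w(t) = sin(2 pi f0 t)` on `[0, n_cyc/f0)`),
`dw/dt` jumps at the burst edges, so *point-sampled* spatial quadrature
of any kind converges only at first order in the node count — a 550-cell
lambda/8 discretization still carries ~1e-2 error. Both evaluation
schemes here therefore integrate the time dimension analytically and
spend numerical quadrature only on smooth spatial remainders:

* **Gauss–Legendre sets** (`element_quadrature`, default 1 lateral x 6
  elevation abscissas; 2 x 25 for nearfield work): for each lateral
  abscissa, the elevation integral is *clipped exactly* to the
  excitation support — the integration limits in the elevation
  coordinate are solved from `tau(u) in (t - T, t]` per time sample —
  leaving a smooth integrand that 6 Gauss–Legendre nodes per smooth
  piece integrate essentially exactly. Each node additionally folds the
  lateral strip's retarded-time spread in closed form (an exact boxcar
  average of `dw/dt` across the strip, plus the second-order lateral
  mean-delay from wavefront curvature, absorbed into an effective strip
  distance).
* **Uniform sets** (`uniform_quadrature`): dense sub-element
  discretization in which each cell contributes the exact time-average
  of `dw/dt` over its own retarded-time span, computed from the exact
  nearest/farthest cell distances. This is the brute-force oracle; the
  exact per-cell time integration makes it second-order convergent, so
  at lambda/8 spacing it is itself converged to ~1e-4 (verified against
  lambda/16 and lambda/32 refinements and adaptive 2-D integration).

With the defaults, the 6-abscissa field at 60 mm on axis agrees with
the lambda/8 oracle to NRMSE ~3e-4. Accuracy is anisotropic: with a
single lateral abscissa, points at large lateral angles see a few
percent error from the boxcar model of the lateral spread; `order_x=2`
reduces this by roughly two orders of magnitude where it matters.

Discretization of the pulse-echo assembly: convolutions are discrete
linear convolutions scaled by `1/fs` (rectangle rule); the outer time
derivative is the centered finite difference at `fs`. All waveforms
live on the shared lattice `t_k = k/fs` (k integer, possibly negative),
so delayed, convolved, and accumulated signals keep sample phase, and
event traces are *exactly* the superposition of single-scatterer
pulse-echo traces (the test suite relies on reciprocity and
superposition holding to machine precision). The dominant
sampling-frequency error is the centered difference acting on the
band-limited echo (amplitude factor `sin(w dt)/(w dt)`), which is what
the convergence study measures.

## Delay handling (three paths)

1. **analytic** — delays folded into the retarded times and the field
   re-evaluated exactly; the accuracy baseline.
2. **cached_linear** — undelayed intermediates are evaluated once on the
   grid, and each event's delays are applied by discrete-time shifting
   with linear interpolation.
3. **cached_upsampled** — the undelayed bank is evaluated *directly* at
   4x fs, shifted with linear interpolation on the fine lattice, and
   decimated back (every 4th sample, lattice-aligned; a pure delay
   creates no new frequency content, so no anti-alias filter is
   applied).

The convergence harness (`metrics.convergence_study`) compares all
three at fs = 12, 24, 48, 96 MHz against the analytic path at 16x the
largest test fs with the lambda/8 uniform oracle aperture — the same
role the conventional very-high-fs impulse-response reference plays.
Observed behavior (16 elements, 50 scatterers, 3 angles): every path's
NRMSE falls monotonically with fs; linear-interpolation shifting is
consistently elevated; the upsampled path tracks the baseline within
~1 %. Wall time is reported but never asserted.

## Beamforming

Delay-and-sum with a constant f-number: at focal point (x, z), channels
inside `|x_j - x| <= z / (2 f#)` are sampled (linear interpolation) at
`t_tx(x, z) + |r_f - r_j|/c` and summed un-apodized. Transmit times:
element time-of-flight (synthetic aperture), `(z cos(th) + x sin(th))/c`
plus the event's stored delay offset (plane wave), sub-aperture-center
time-of-flight (B-mode). Receive focusing is dynamic per depth by
default; a fixed-foci mode freezes the focal law per axial segment
(nearest-focus assignment) to reproduce conventional multi-zone B-mode
receive. Two deliberate choices:

* **Pulse-center compensation**: the two-way pulse envelope peaks half
  the combined burst length after the geometric arrival; sampling at
  `t + (T_tx + T_rx)/2` puts point targets at their true depth (within
  one pixel in the tests).
* **Analytic beamforming for Doppler/coarse grids**: the beamformed
  A-line carrier has an axial period of lambda/2, so demodulating by a
  Hilbert transform along *depth* requires axial pixel steps below
  lambda/4 — practical grids (0.5–1 mm) alias it, flipping Doppler
  signs. `das_beamform(..., analytic=True)` instead Hilbert-transforms
  the channel data along the well-sampled *time* axis before
  delay-and-sum, giving complex frames whose per-pixel phase is valid
  at any pixel spacing. Envelope images on coarse grids use the same
  route (`|complex frame|`); `envelope_logcompress` falls back to
  depth-axis Hilbert for real frames on fine grids.

Compounding is a coherent (pre-envelope) sum over events; images are
normalized to their global peak, log-compressed, and clipped at the
display dynamic range (default 60 dB).

## Color Doppler

Ensembles are acquired per steering angle (`frames_per_angle`
acquisitions at `fPRF`, phantom advancing by `v/fPRF` between pulses;
acquisition order is angle-major). The chain per angle: analytic
beamforming -> slow-time mean subtraction (wall filter; exact for the
frame-invariant static background) -> lag-one Kasai autocorrelation
`R = mean(conj(s_k) s_{k+1})`. The per-angle `R` maps are averaged as
complex numbers *before* the phase is taken, which keeps inter-angle
phase offsets out of the slow-time statistics. Velocity:

    v = c * fPRF / (4 pi f0 cos(theta)) * atan2(Im R, Re R) ,

positive toward the transducer; `theta` is the beam-to-flow angle
(beam along +z; for the 45-degree vessel the alternative
"tangent-to-array" reading coincides). Estimates are unambiguous up to
the Nyquist speed `c fPRF / (4 f0 cos th)` (1.089 m/s at the default
parameters — the 1.0 m/s parabolic peak sits 92 % of the way there, so
occasional wrap outliers near the vessel center are expected and are
handled by the complex averaging). Pixels whose slow-time mean
magnitude falls more than 4 dB below the post-wall-filter peak are
gated out; the 1.54 x 1.57 mm Hamming moving average (normalized over
the valid mask) then interpolates across gated pixels, producing the
filled-in color-flow map. The gate is aggressive on sparse speckle —
at 10k movers only the brightest few percent of in-vessel pixels pass
pre-smoothing — but gated pixels are magnitude-selected, not
velocity-selected, so the surviving estimates are unbiased.

### Profile extraction over a tilted vessel

For a cylinder tilted 45 degrees in the imaging plane, a vertical
A-line through lateral position x has radial distance
`rho(s) = |x - s| / sqrt(2)` (s the depth offset from the vessel-center
depth), so *every* full-depth chord samples the complete radial range:
depth-averaging the velocity over the whole vessel interior returns the
cross-sectional mean — `2/3 v_peak` for Poiseuille flow — at every x,
i.e. a flat profile (the simulations reproduce this: the full-interior
mean for the 1.0 m/s parabolic phantom is 0.70). To resolve the radial
profile, the lateral profile is averaged over a thin axial slab through
the vessel-center depth (`vessel_slab_mask`, half-height 1.5 mm by
default): within the slab, lateral position maps to radial distance
(`rho ~ |x|/sqrt(2)`), and the slab average at x = 0 is
`v_peak (1 - h^2 / (6 R^2))` = 0.985 `v_peak` for h = 1.5 mm, R = 5 mm.
The profile is parabolic in x with apparent radius `sqrt(2) R`.

## Phantoms

* **Cyst phantom**: uniform positions, N(0,1) amplitudes; amplitude set
  to 0 inside anechoic spheres, multiplied by 10 inside hyperechoic
  spheres; point targets appended with amplitude 20. The default
  feature layout (five of each in three depth columns) is this
  package's own arrangement.
* **Image-template phantom**: grayscale pixels divided by 100,
  exponentiated, global minimum subtracted, rescaled to [0, max_weight]
  (default 1e6 — immaterial after image normalization); each
  scatterer's amplitude is its nearest pixel's weight times an
  independent N(0,1) draw; scatterers outside the image bounds are
  dropped.
* **Vessel flow phantom**: movers uniform in a tilted cylinder (axial
  uniform, radial by the area-uniform sqrt rule), N(0,1) amplitudes;
  static background uniform in a box with the cylinder carved out by
  rejection, N(0, 625) amplitudes. Laminar flow moves every scatterer
  at the peak speed; parabolic uses the Poiseuille form
  `v(rho) = v_peak (1 - (rho/R)^2)`. Scatterers leaving the cylinder's
  axial extent re-enter at the opposite end with the same radial offset
  (wrap-around keeps the density uniform through long ensembles).

One `numpy.random.default_rng(seed)` stream per phantom with a fixed
draw order makes fields bit-reproducible.

### What the synthetic data does and does not emulate

The phantoms produce fully developed speckle only above ~10 scatterers
per resolution cell; the reduced-scale test configurations (10–12k
scatterers) sit near that threshold, so their speckle statistics are
slightly heavy-tailed relative to tissue. Real data additionally has
frequency-dependent attenuation, reverberation, element noise, and
tissue motion — none of which are modeled — so passing tests certify
the simulation/estimation chain, not robustness to those effects.

## Problem sizes used in the shipped studies

The flow-recovery studies run at 64 elements, 10k moving + 10k static
scatterers, three steering angles with 10 acquisitions each (a few
minutes per study on one core); the convergence study uses 16 elements
and 50 scatterers against a 1.536 GHz reference (~2 minutes); imaging
property checks use 64 elements and ~12k scatterers. The full
reference-scenario configurations (256 elements, 50k + 50k scatterers,
five angles) are shipped as example configs with a `--scale` flag.

## Known limitations

* The excitation is restricted to rectangular-envelope sinusoids (the
  closed-form time integrals the evaluation kernels rely on).
* Single lateral abscissa accuracy degrades to a few percent at large
  lateral steering/viewing angles (use `order_x >= 2` when that
  matters).
* Delays are exact only in the 'analytic' path; the cached paths carry
  the documented interpolation error.
* No attenuation, nonlinearity, or multiple scattering; 1-D linear
  arrays of rectangular pistons only.
* Doppler velocities wrap at the Nyquist speed; no unwrapping is
  attempted.
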