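# Methods

## The measurement and the model

A two-electrode impedance sweep of a suspension in the 10–1000 Hz band is
shaped almost entirely by electrical double layers: the electrode/electrolyte
interface (electrode polarization) and the many double layers formed around
suspended particles or cells (α dispersion). Both are imperfect capacitors —
rough, porous, heterogeneous interfaces disperse the relaxation — so both are
modelled with constant phase elements (CPE),

    Z_CPE(ω) = 1 / (T (jω)^P),   |Z| = 1/(T ω^P),   phase = −P·90°,

with `T` in F·s^(P−1) and `P ∈ [0, 1]` interpolating between an ideal
resistor (P = 0) and an ideal capacitor (P = 1).

The full circuit is a bulk-suspension CPE in series with the electrode
capacitance shunting the dispersed-medium branch:

    Z(ω) = Z_CPEs(ω) + [ Z_Ce(ω) ∥ (Rd + Z_CPEd(ω)) ],   Z_Ce = 1/(jωCe).

The source material never prints the total-impedance equation, so the
topology is an inference. Two candidates are algebraically compatible with
the effective-capacitance formula below (the Brug form for R in series with
a CPE and the Hsu–Mansfeld form for R in parallel with it coincide):
`Ce ∥ (Rd + CPEd)` and the all-parallel `Ce ∥ Rd ∥ CPEd`. The series-Rd
variant is used because it alone reproduces the described phenomenology of
the simulated spectra: an interior phase "crest" whose maximum rises as Pd
increases (−82.8° → −76.6° across the Pd = 0.7/0.8/0.9 cases) and falls as
Ce increases (−76.6° → −85.8°), and a low-frequency inclined spike in the
Nyquist plane. The topology lives in one composable function so the
alternative can be swapped in if an instrument says otherwise. One
consequence worth knowing: the Pd-ordered magnitude curves converge near the
top of the 10–100 Hz decade and cross with inversions below 1% — on a
log-scale Bode plot they appear ordered throughout.

### Effective capacitance

The dispersed branch is summarised by the Cole–Cole-style effective
capacitance, and the electrode capacitance adds in parallel:

    Cd  = (Td · Rd^(1−Pd))^(1/Pd),        Cef = Ce + Cd.

`Cef` is the scalar used for calibration. It is evaluated in log space
because the 1/Pd exponent overflows float64 for small Pd; Pd = 0 is rejected
outright (the formula is singular there, and fitted dispersed-medium
exponents in practice sit around 0.71–0.81).

### Dispersed-medium index

The fit-free alternative normalizes the suspension magnitude spectrum by its
liquid medium, pointwise: `DMi(f) = (|Z|_S − |Z|_LM)/|Z|_LM`. The medium
itself is 0 by construction and any common scale factor (cell constant,
electrode area) cancels. Replicate aliquots are averaged in |Z| per
frequency before normalization, and the per-frequency relative standard
deviation (percent) is reported alongside. The scalar read-out defaults to
the nearest grid point at 50 Hz — the frequency where concentration
separation is largest — with log-linear interpolation as an explicit option;
nearest-point is the default because instrument sweeps are nominally
identical across samples and an on-grid 50 Hz point is the common case.

### Gouy–Chapman–Stern capacitance

For interpreting fitted capacitances, `edl` evaluates the GCS double layer:
Stern and diffuse layers in series,

    1/C_DL = x_OHP/(ε ε0) + 1 / [ √(2 ε ε0 z² e² n0 / (k_B T)) · cosh(z e ψ / (2 k_B T)) ],

per unit area (F·m⁻²), with CODATA 2018 constants via scipy. The
permittivity is treated as constant across both layers, which overstates the
Stern term when the field saturates the solvent dipoles. (The diffuse-layer
prefactor must divide by k_B T for the dimensions to close; the package uses
that standard form.)

## Units and conventions

SI throughout the library (F, Ω, Hz, radians); microfarads and degrees only
in reports, CSV exports, and the CLI. ω = 2πf is computed once at grid
construction. Spectrum CSVs carry unit-bearing headers in rectangular
(`frequency_hz,re_z_ohm,im_z_ohm`) or polar (`frequency_hz,mag_z_ohm,phase_deg`)
dialects, auto-detected. The default simulation grid is 50 log-spaced points
over 10–1000 Hz: the band is the measured one, and 50 points resolves the
one visible relaxation without inflating fit cost.

## Fitting

`fit_circuit` minimises interleaved real/imaginary residuals with scipy's
trust-region reflective least squares — Levenberg–Marquardt in spirit, with
the box bounds LM lacks, needed to keep both CPE exponents in [0, 1].
Choices that matter:

* **Weighting.** Modulus weighting (residuals divided by |Z_obs| per point)
  is the default; |Z| spans about a decade over the band and relative
  weighting is also the Gaussian likelihood under the proportional noise
  model below. Unit weighting is available for comparison; a zero-residual
  minimum is a minimum under either.
* **Parameterisation.** Ts, Ce, Rd, Td are optimised as log10 (they are
  positive scale parameters spanning decades); Ps, Pd stay linear.
* **Multistart.** CPE circuits have well-known local minima. Start 0 is a
  heuristic guess (Rd from the Nyquist real-axis extent, Ce from Im Z at the
  top of the band, the bulk exponent from the lowest-frequency phase, Td and
  Pd at typical dispersed-EDL values of 1 µF·s^(P−1)-scale and 0.75);
  subsequent starts jitter it by ±0.5 decade (log-uniform) on scale
  parameters and ±0.1 on exponents, seeded. Default 8 starts; lowest final
  cost wins, ties broken by start index. Hitting the iteration cap returns
  `converged=False` rather than raising.
* **Tolerances.** xtol = ftol = gtol = 1e−14 by default so that noiseless
  round trips recover generating parameters to numerical precision; default
  bounds are generous envelopes around values seen for saline suspensions
  (T-type 1e−8–10, Ce 1e−9–1e−3 F, Rd 1–1e7 Ω, exponents 0.01–1).

### Identifiability

The band covers only two decades, so the bulk CPE and the electrode
capacitance trade off at the band edges and the dispersed branch is only
partially resolved: at a few percent measurement noise the likelihood is
nearly flat along directions that move Ts, Ps and Rd by tens of percent.
`Cef` inherits an uncertainty of several percent per fitted spectrum at 1%
proportional noise — of the same order as, and often larger than, the
concentration-induced change between adjacent half-fold dilutions. The
package therefore reports the final cost and leaves formal uncertainty
quantification (bootstrap, profile likelihood) out of scope; averaging
replicate spectra before fitting is the practical lever, as it is in the
bench protocol.

## Synthetic data

`synthetic` emulates the acquisition campaign: spectra from the forward
circuit with multiplicative complex Gaussian noise,
`Z_obs = Z(1 + ε_re + j·ε_im)`, ε i.i.d. N(0, σ) per frequency and part.
Proportional noise was chosen over additive because potentiostat error is
relative across the ~1-decade |Z| range; σ defaults to 1%, the quiet end of
the 1–36% replicate spread observed across aliquots. The 15 fitted parameter
sets for PMMA suspensions (5 half-fold concentrations × 3 diameters of 6, 15
and 48 µm) are embedded as the single source of realistic generator values;
concentration series interpolate Ce linearly between the lowest- and
highest-concentration fitted values of a diameter (making Cef exactly linear
in concentration, since Cd stays fixed at the per-diameter medians) and
spawn an independent child seed per concentration.

What the generator does **not** emulate: drift and electrode fouling,
temperature dependence, pipetting error (concentration jitter between
aliquots), frequency-correlated instrument error, and polydispersity.
Passing tests therefore demonstrate correctness of the algorithms under the
stated noise model, not robustness to every bench artefact; in particular,
real replicate scatter mixes pipetting with instrument noise in a way the
single σ knob does not separate.

## Suspensions and calibration

Particles are perfect spheres (only diameters are specified), so the volume
fraction is `V_f = c · (π/6)d³/1e9` with d in µm and c per µL, linear in
concentration and cubic in diameter; chamber counts are concentration ×
fill volume, rounded to the nearest integer. Serial dilutions are descending
geometric series beginning at the stock concentration.

Calibration is unweighted ordinary least squares of a scalar response
(DMi at the reporting frequency, or Cef in F) on concentration:
`response = slope·c + intercept`, slope reported as the sensitivity and
`R² = 1 − SS_res/SS_tot` as goodness of fit. Linear-in-concentration is the
minimal model consistent with the observed linear behaviour and keeps the
sensitivity interpretable; a log10-concentration option exists but is off by
default. No per-point uncertainties are available for the response scalars,
hence no weighting. Inversion is algebraic; estimates outside the calibrated
range carry an extrapolation warning rather than an error. Degenerate inputs
(fewer than three points, duplicate concentrations, zero response variance)
are rejected.

## Problem sizes in the test suite

The acceptance-level checks run on the study-sized problems: the 50-point
grid, all 15 embedded parameter rows for noiseless recovery, 20 seeds for
the noisy recovery and end-to-end loops, and 100 random draws for oracle
equivalence of the forward model. The complete suite finishes in about two
minutes on one CPU.

## Known limitations

* The circuit topology is inferred, not documented by the source; the
  forward model isolates it in one function for that reason.
* No confidence intervals on fitted parameters; cost and convergence flags
  only.
* No Kramers–Kronig validity screening of measured spectra, no model
  selection among alternative circuits, and no β/γ-dispersion (cell
  membrane) modelling — the band ends at 1 kHz.
* DMi is magnitude-only by definition; phase information is used only
  through the complex fit.
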