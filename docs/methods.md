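# Methods

## Forward model

The generator is a 1-D ballistic Beer–Lambert model, not a polarized Monte
Carlo. A chiral absorber slab occupies optical depths $z \in [0, d]$
(default $d = 2$ mm, the path length of interest). The initial pressure is

$$p(z) = \tau\, \mu_a\, \phi_0\, e^{-\mu_\mathrm{eff} z} \cos^2(\kappa z),$$

with Grüneisen parameter $\tau$ (held constant — the standard PA
assumption for a single solvent at fixed temperature), chromophore
absorption $\mu_a$, surface fluence $\phi_0$, fluence attenuation
$\mu_\mathrm{eff}$ and rotation rate $\kappa$ (rad/m), proportional to
concentration. Separating $\mu_\mathrm{eff}$ from $\mu_a$ matters for one
limiting case: an optically thin absorber ($\mu_\mathrm{eff}=0$,
$\mu_a>0$) emits pressure without measurable attenuation, which isolates
the Malus $\cos^2$ factor and makes rotation recovery testable without the
attenuation confound. By default $\mu_\mathrm{eff} = \mu_a$.

A source at depth $z$ is mapped to arrival time $t = (L + z)/v$, where
$L = 40$ mm is the known illumination-to-transducer distance and $v$ the
speed of sound, so recorded time increases with optical depth and the
entry face arrives at the acoustic path length used for calibration. For
a mirrored physical geometry a trace can simply be time-reversed; the
estimator uses only the monotone time–depth correspondence. The profile
is convolved with a Gaussian-modulated sinusoid (7.5 MHz center, 60%
fractional −6 dB bandwidth, unit L2 norm — `scipy.signal.gausspulse`),
scaled by a multiplicative pulse-energy jitter (truncated normal, CV
configurable; the jittered energy is stored in the trace metadata exactly
as a real-time energy meter would record it), and corrupted with i.i.d.
Gaussian noise. `snr_db` sets the noise level from the clean trace RMS via
SNR $= 20\log_{10}(\mathrm{rms_{signal}}/\mathrm{rms_{noise}})$. A single
master seed fans out to per-record seeds through `numpy.random.SeedSequence`.

### What the generator emulates, and what it does not

It reproduces the structure the estimator assumes: exponential fluence
decay, $\cos^2$ rotation modulation, band-limited detection, energy
jitter, white acquisition noise, and a finite absorber layer with sharp
entry/exit faces (a solution chamber between holder walls or tissue
slices). It does **not** model polarized photon transport, scattering
phase functions, depolarization, acoustic attenuation or heterogeneous
speed of sound. Passing tests therefore demonstrate correctness of the
signal-processing and calibration chain under the model's assumptions,
not robustness to depolarizing or strongly scattering tissue.

### Default study conditions

10 concentrations spanning 90–400 mg/dl (the clinically relevant range),
3 replicates, 20 dB trace SNR, 2% energy-jitter CV, 1420 m/s (solution
phantom) or 1490 m/s (ex vivo) true speed of sound. The rotation scale is
1.75 rad m⁻¹ per mg/dl, chosen once so the strongest sample stays below
the $\pi/2$ ambiguity of the $\cos^2$ law at 2 mm (400 mg/dl → 1.4 rad)
while keeping magnitudes in the tenths-of-a-radian to ~1 rad range the
piecewise calibration expects. Simulated windows are 4096 samples at
1 GS/s, which covers a 0.5 mm pre-roll, the 2 mm slab and both boundary
responses at 1420 m/s; file-format examples use the 1400-sample window of
a typical oscilloscope record.

## Processing pipeline

Fixed order: band-pass filter → energy normalization → deconvolution →
envelope → SOS calibration → depth mapping → amplitude extraction →
Malus inversion → calibration fit → prediction → CEGA. Deconvolution can
be disabled only by an explicit ablation flag.

**Band-pass.** Chebyshev type I, order 4, 0.5 dB passband ripple,
1–9 MHz, applied forward–backward (`sosfiltfilt`). Zero-phase filtering
preserves arrival times, on which the depth mapping depends; a
single-pass option exists behind a flag. The zero-phase magnitude
response is the squared single-pass response, so worst-case passband loss
is 1 dB.

**Wiener deconvolution.** Frequency-domain, with regularizer
$\lambda(f) = \max_f |H|^2 \,(\mathrm{nsr}\cdot s(f) + 10^{-12})$. The
$10^{-12}$ floor keeps bins where the band-limited kernel underflows from
amplifying rounding noise even at `nsr=0`. Two spectral shapes $s(f)$ are
provided:

- `smooth` (default): $s(f) = (f/f_c)^2$ with $f_c$ the transducer center
  frequency — the Wiener solution for a signal whose power falls as
  $1/f^2$ (a profile with step boundaries) in white noise. Use this to
  reconstruct the full fluence profile, including its slowly varying
  interior.
- `flat`: frequency-independent penalty. Use this after band-pass
  prefiltering when the analysis reads band-limited boundary responses:
  re-amplifying out-of-band bins the prefilter has emptied would inject
  pure noise. The end-to-end pipeline uses `flat`.

The kernel's group delay (envelope-peak position) is compensated so the
output stays aligned with the input.

**Envelope.** Magnitude of the analytic signal (`scipy.signal.hilbert`).
The deconvolved trace is bipolar; the envelope makes it nonnegative so
the amplitude ratio is guaranteed in $[0, 1]$ up to noise.

**SOS calibration.** Candidate speeds are swept over 1400–1550 m/s in
5 m/s steps; the candidate minimizing $|v\,t_\mathrm{landmark} - L|$ is
chosen, ties toward the lower speed. The landmark defaults to the
envelope peak (the illumination-face response, which is the strongest
feature for any non-increasing fluence profile); an onset landmark (first
crossing of 10% of the peak) is available.

**Extraction and inversion.** Depths are anchored at the envelope-peak
landmark; $P_0$ is the mean of a 5-sample window at 0.018 mm past the
anchor and $P$ at the path length of interest (the slab exit face, where
the boundary-step amplitude equals the interior fluence at that depth).
$\theta = \arccos\sqrt{P/P_0}$; noisy ratios above 1 are clamped with a
warning (erroring by default would make real noisy data unusable), and
clamping can be disabled. This faithful estimator deliberately conflates
Beer–Lambert decay with rotation, as the amplitude-ratio method does; the
attenuation-free simulator mode quantifies exactly that confound.

## Calibration models

The piecewise quadratic consists of two *independently* fitted OLS
quadratics — no continuity constraint at $\theta_T$, matching the model
as published. The threshold may be fixed (per-polarization serum values
0.88/0.98/0.822 rad for V/P/R are provided as constants) or chosen by
`"auto"`: a grid search over the unique observed rotations minimizing the
total residual sum of squares, requiring at least 3 points per segment,
ties toward the smaller threshold. The lower branch is inclusive
($\theta \le \theta_T$). Negative predictions are floored at zero with a
warning. `PiecewiseQuadraticRegressor` exposes the scikit-learn estimator
interface (`fit`/`predict`/`get_params`, fitted attributes with trailing
underscores) so it composes with sklearn model selection; the module
functions wrap it.

Outlier screening before fitting is deterministic: iteratively fit a
provisional quadratic, remove the point with the largest internally
studentized residual if it exceeds 2.5, at most 3 times (both
configurable). Statsmodels' OLS influence provides the residuals. The
naproxen-style model is a single `scipy.stats.linregress` line with
$R^2$; a constant response is reported as slope 0 with $R^2 = 0$.

## Clarke error grid and LOD

Zones follow the published Clarke (1987) region boundaries. Each zone is
encoded as a closed region and zones are evaluated in order A→E, so a
point exactly on a shared boundary is assigned to the alphabetically
earlier (clinically better) zone — e.g. (100, 120) on the 20% line is A,
(240, 100) on the D border is B. Published implementations differ on
boundary ties; this rule is explicit and tested against an independently
coded oracle on a dense grid.

The limit of detection is Zone-A based: the smallest reference
concentration $c^*$ such that every tested concentration $\ge c^*$ keeps
all replicate predictions in Zone A (replicate-wise by default — stricter
than mean-wise, which is also available), reported as absent when no
level qualifies. A classic calibration-curve LOD
($3.3\,\sigma_\mathrm{resid}/\mathrm{slope}$) is available for
comparison.

## Numerical choices and degenerate inputs

- Angles are radians internally; degrees appear only in reports.
- Samples round-trip exactly: JSON containers use full `repr` floats and
  delimited text uses `%.17g`.
- The Wiener floor ($10^{-12}$ of the kernel's peak power) bounds
  amplification at $\sim 5\times 10^5$, keeping `nsr=0` usable on
  noiseless data while suppressing underflow bins.
- Envelope outputs may undershoot zero by machine epsilon; profile
  validation clips magnitudes below $10^{-9}$ of the peak.
- Empty traces, zero-energy shots, all-zero impulse responses,
  out-of-band filter edges, flat traces at calibration, out-of-range
  extraction depths and non-finite rotations all raise `ValueError` with
  the offending field named.
- Sample SD over a single replicate is reported as missing, not zero.

## Problem sizes

The test suite and the acceptance script use 4096-sample traces, 30-trace
studies, 20 random profiles for deconvolution checks and a 500×500
Clarke-grid comparison; the whole suite runs in a few seconds on one
core. These sizes give stable statistics for every check while keeping
runs quick to iterate on.

## Known limitations

- The faithful rotation estimator is biased when $\mu_\mathrm{eff} > 0$
  unless attenuation is corrected with a user-supplied coefficient; the
  default end-to-end study isolates the rotation effect instead.
- Rotations beyond $\pi/2$ alias under the $\cos^2$ law; the generator's
  default scale avoids the region, and real deployments must choose path
  lengths accordingly.
- Homogeneous speed of sound is assumed; layered media would need
  per-layer calibration.
- The synthetic noise is white and Gaussian; structured interference
  (e.g. water-absorption background drift) is not modeled.
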