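# Methods

This note documents the models, numerical choices and limitations behind
`neuroei`. Everything quantitative stated here is recomputed by the test
suite or `scripts/acceptance.py`; nothing is quoted from stored results.

## Synthetic EEG

**Aperiodic background.** A recording with one-sided PSD
`S(f) = c · f^(−χ)` is synthesized by frequency-domain amplitude shaping:
rFFT amplitudes are set deterministically to `√(S(f)·fs·N/2)` and only the
phases are random (uniform, per channel). The full-length periodogram of
each channel therefore equals the target density bin-exactly, which makes
the generator its own spectral oracle. The law is clamped flat below
0.5 Hz so slow drift stays bounded; the analysis band (≥ 1 Hz) is
unaffected, and the 1–45 Hz high-pass removes the clamped region anyway.
Defaults: χ = 1.2, c = 20 μV²/Hz at 1 Hz, 180 s at 1000 Hz — values typical
of occipital resting EEG and of a 3-minute resting run. Recordings are
generated directly at 1000 Hz, the rate at which all spectral analysis
operates; a higher acquisition rate followed by decimation would be
indistinguishable after the 45 Hz low-pass.

**Alpha oscillation.** A band-limited stochastic component whose PSD is a
Hann-shaped bump supported exactly on `[center − bw/2, center + bw/2]`
(default 8–12 Hz) and integrating to the requested power (defaults:
30 μV² eyes-closed, 12 μV² eyes-open, 8 μV² during luminance stimulation —
the eyes-closed dominance every resting EEG shows). Exact band confinement
is what lets the alpha-exclusion property be tested to machine precision.

**Artifacts.** Transient Hann pulses (200 ms, configurable peak amplitude)
on one random channel at the center of randomly chosen 1 s epochs; the pulse
sign matches the underlying sample so the contaminated epoch is guaranteed
to exceed any rejection threshold below the pulse amplitude. The generator
returns the exact per-epoch truth mask. Ocular and muscle artifact
*morphology* is not modeled — only the amplitude-threshold phenomenology the
rejection stage operates on.

## EEG preprocessing

**Filter.** Zero-phase Hamming-windowed sinc FIR band-pass, kernel length
from the 3.3/(N·Δt) transition heuristic at a 1 Hz design transition,
applied once with group-delay compensation and edge-value padding; the taps
are re-centered to exactly zero DC gain. The high-pass 6-dB point is placed
at 0.4 × the low edge (0.4 Hz for the 1 Hz edge) rather than at the edge
itself: the aperiodic fit's lowest bin (1 Hz) integrates the PSD over
roughly 0–3 Hz through the 1 s Welch window's mainlobe, and calibration on
synthetic 1/f recordings showed this placement balances transition-band loss
against sub-edge leakage, keeping slope and intercept biases within ±0.05
for χ up to 2.5 (a 6-dB point at 0.5 Hz left a −0.17 log10 deficit at the
1 Hz bin). The low-pass 6-dB point sits half a transition width above
45 Hz, giving ≥ 50 dB at 50 Hz; no separate line-noise handling is needed
below the 20 Hz fit ceiling.

**Epoching and rejection.** Consecutive non-overlapping epochs (1 s resting,
6.25 s luminance), trailing partials discarded; per-epoch per-channel mean
subtraction; an epoch is rejected in toto when any sample on any channel
strictly exceeds ±120 μV ("exceeding" is read literally, so boundary
equality keeps the epoch; the threshold is configurable). Rejection is
monotone in the threshold by construction. For resting data the order is
filter → epoch → baseline → reject; for luminance data filter → downsample
(polyphase, anti-aliasing low-pass at 0.9× the new Nyquist) → epoch →
baseline → reject.

## Aperiodic parameterization

Welch PSD with periodic Hamming taper, window 1000 samples / overlap 0 at
1000 Hz (resting) and window 60 / overlap 0 at 60 Hz (luminance), averaged
over segments and retained epochs; per-trial densities are averaged before
the log transform. Each channel's density is normalized by its mean over
1–20 Hz (the constant is retained), and an ordinary least-squares line is
fit to (log10 f, log10 P) over bins with 1 ≤ f ≤ 20 Hz excluding
8 ≤ f ≤ 14 Hz, band edges inclusive on both intervals. Outputs per channel:
slope, intercept at 1 Hz re-referenced to the un-normalized spectrum (the
stored constant is re-applied, so normalization shifts nothing but the
bookkeeping), RMS log10 residual as the fit error, and R². Occipital values
are the arithmetic means of the O1 and O2 parameters — fit first, then
average, which differs from fitting the averaged spectrum and is pinned by a
regression test. Log base 10 is used on both axes; the slope is
base-invariant.

## Synthetic MEGA-PRESS and quantification

The generator emulates the averaged spectra a scanner exports, not pulse
physics: editing is a single efficiency scalar (default 0.5), and sequence
timing (TR 2000 ms, TE 68 ms, editing pulse at 1.9 ppm) is carried as
metadata only. On a 4096-point 0–5 ppm axis (ascending), the edit-OFF
spectrum carries pseudo-Voigt creatine (3.0 ppm) and NAA (2.0 ppm)
singlets; the edit-ON spectrum adds the edited signals: a GABA Gaussian at
3.0 ppm with area ∝ concentration × efficiency, a co-edited macromolecular
Gaussian at the same position scaled by the MM-contamination fraction
(default 0.45 — the "+" in GABA+), and a symmetric Glx double Gaussian at
3.75 ppm (separation 0.06 ppm; a single-Gaussian mode exists). The water
reference is a pseudo-Voigt at 4.68 ppm. White noise is added per spectrum
at `noise_sd/√n_averages` (256 metabolite, 8 water averages); the default
`noise_sd = 5` puts the DIFF-spectrum GABA+ SNR near 20, the visual-cortex
regime. Default concentrations (GABA 2, Glx 10, NAA 12, Cr 8 mM) are
standard physiological values.

Quantification fits the DIFF spectrum with lmfit: Glx first (double
Gaussian + linear baseline over 3.45–4.10 ppm), whose fitted peak model is
subtracted before the GABA+ fit (Gaussian + linear baseline over
2.79–3.55 ppm) because the windows overlap; NAA and Cr are pseudo-Voigt
fits on the OFF spectrum (1.8–2.2 / 2.8–3.2 ppm) with one mutual-subtraction
refinement pass, since Lorentzian tails reach across windows. Initial
values: center at the nominal shift, width from the window's second moment,
height from the window maximum; up to three restarts from perturbed
parameters on non-convergence, after which the quantification is flagged,
never silently dropped. Noise-free recovery of all areas is exact to better
than 1e-6 relative, which is the point of matching generator and fitter
lineshapes.

**Normalization.** Water-referenced concentrations use
`C = (A_m/A_w) · W · (f_gm·k_gm + f_wm·k_wm + f_csf·k_csf) / (f_gm + α·f_wm)`
with α = 0.5 (GM:WM metabolite ratio), per-compartment water visibility
constants (0.78/0.65/0.97) and W = 55.5 M; CSF is metabolite-free, so the
correction grows strictly with the CSF fraction and a pure-CSF voxel is an
error. The absolute scale is institutional — only ratios and group
contrasts are meaningful. Cr-referenced ratios are provided as the
alternative normalization. Glx/GABA+ is computed from the normalized
concentrations and is invariant under any global spectral scaling.

**Quality metrics.** SNR = |fitted peak height| / noise SD from a
signal-free window (default 0.2–0.8 ppm on this axis — the conventional
far-downfield noise region lies outside a 0–5 ppm axis — linear-detrended);
FWHM in Hz = fitted ppm width × proton frequency (127.7 MHz at 3 T);
fit error = SD of the fit residual as % of peak height; CRLB = relative
standard error of the area from the fit covariance, reported for NAA in the
pipeline's quality table.

## Cohort simulation and statistics

Two groups ("CC" affected, "SC" control) of n age-matched pairs (default
10, ages 11–44 y with ≤ ~1 y within-pair jitter). Between-subject SDs —
χ 0.15, log10 scale 0.10, GABA 0.2 mM, generative Glx/GABA+ ratio 0.3 —
are set to plausible inter-individual variability; group effects offset the
CC group's recovered slope, log-intercept and generative ratio. Effects that
would push χ or concentrations negative raise immediately.

The ANOVA treats (subject, condition) observations as independent with
Type-II sums of squares (identical to I/III on balanced data) and reports
partial η² = SS_effect/(SS_effect + SS_error); a repeated-measures variant
(condition within subject, group on subject means) is available because the
independence assumption is a design choice, not a law. Pearson r carries a
t-transform p and a Fisher-z 95% CI (degenerate [r, r] at |r| = 1);
Bonferroni adjustment is min(1, m·p) with m = 6 for the exploratory
EEG×MRS family (intercept and slope × {GABA+, Glx, Glx/GABA+}). Shapiro-Wilk
and Levene checks are exposed as a helper. Demographic summaries use the
n−1 SD and one-decimal, half-away-from-zero rounding.

Calibration (recomputed by the acceptance script): type-I error of every
ANOVA effect, the t-test and the Pearson p stays within 0.05 ± 0.02 over
2500 null replicates, and Fisher-z CI coverage within 95 ± 2% at n = 10 for
ρ ∈ {0, 0.5}. 2500 replicates rather than the minimal 1000 are used so the
Monte-Carlo noise of the rate estimate (binomial SD ≈ 0.004) is small
against the ±0.02 band.

## Problem sizes

The validation experiments use 20 seeds × 4 exponents of 180 s recordings
for aperiodic recovery, 50 simulations for noisy MRS recovery, 40 paired
simulations for the 0.02 mM discrimination experiment at phantom-like SNR
(250), and 2500/2000 replicates for statistical calibration — sizes chosen
so every experiment's Monte-Carlo error is well inside the tolerance it is
checked against while a full run stays around a minute.

## What the synthetic data do and do not show

The generators reproduce the *statistical structure* the analysis consumes:
exact 1/f spectra, band-limited alpha, threshold-crossing artifacts,
lineshape-exact edited spectra with known areas, and group designs with
known effects. They do not contain ocular/muscle artifact morphology,
volume conduction, non-Gaussian EEG moments, baseline distortions,
frequency/phase drift across transients (the rigid Cr-region alignment is a
simplified surrogate, off by default), macromolecule spectra beyond a
single co-edited Gaussian, or scanner-specific water lineshapes. Passing
tests therefore demonstrate correctness of the estimators under the stated
models and calibrated behaviour of the statistics — not robustness to every
artifact a clinical recording can contain. Real-data group results require
the corresponding deposited datasets and are out of scope.

## Known limitations

- The aperiodic recovery bias (≤ ~0.05 in slope and intercept) is inherent
  to 1 s Welch windows against a steep 1/f spectrum with a 1 Hz high-pass;
  it is calibrated, not zero.
- The luminance-condition spectrum shares the resting fit machinery; its
  13 integer-Hz fit bins make per-bin noise larger than in the resting
  conditions.
- Quantification is a single peak-fitting path; linear-combination basis-set
  modelling and vendor raw formats are not implemented.
- `independent_t` on the bundled cohort ages reproduces the group match
  qualitatively (|t| ≈ 0.11, p ≈ 0.91 unpaired); the pairing convention
  behind any particular printed df cannot be recovered from the table
  alone.
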