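# neuroei

EEG and edited-MRS markers of the cortical excitation/inhibition (E/I)
ratio, implemented as a fully testable pipeline driven by synthetic data
with known ground truth.

## The scientific problem

Whether the E/I balance of human visual cortex depends on early visual
experience can be probed non-invasively with two complementary markers:

- **EEG aperiodic activity.** The resting EEG power spectrum has a 1/f-like
  background, `P(f) ≈ c · f^(−χ)`. On log-log axes this is a line whose
  *slope* (−χ) indexes the E/I ratio (flatter = more excitation) and whose
  *intercept* indexes broadband neuronal firing. The fit is performed on the
  normalized spectrum over 1–20 Hz with the alpha band (8–14 Hz) excluded,
  and averaged over the occipital electrodes O1/O2.
- **Edited MR spectroscopy.** The MEGA-PRESS sequence alternates edit-ON and
  edit-OFF acquisitions; the ON−OFF difference (DIFF) spectrum isolates
  GABA+ (3.0 ppm, inhibition) and Glx (3.75 ppm, excitation) from the much
  larger creatine and NAA resonances, which cancel. Peak areas referenced to
  unsuppressed water, with a tissue alpha-correction for the voxel's
  GM/WM/CSF composition, give concentrations; `Glx/GABA+` is the
  neurochemical E/I proxy.

The package implements every stage — synthetic generators for EEG,
MEGA-PRESS and two-group cohorts; deterministic EEG conditioning (1–45 Hz
zero-phase FIR, epoching, ±120 μV rejection, 60 Hz resampling for the
luminance-stimulation condition); Welch PSD and the masked log-log aperiodic
fit; DIFF construction, peak fitting and normalization with SNR/FWHM/fit
error/CRLB quality metrics; and the group×condition ANOVA / Pearson /
Bonferroni statistics layer — plus a pipeline runner and CLI.

## Worked example

```python
import numpy as np
from neuroei import EEGSimSpec, MRSSimSpec, generate_eeg, \
    generate_mega_press_acquisition
from neuroei.preprocess import preprocess_resting
from neuroei.spectral import spectrum_to_aperiodic, average_occipital
from neuroei.mrs import quantify_acquisition

# --- EEG: generate a 3-min recording with chi = 1.5 and alpha, recover it
spec = EEGSimSpec(aperiodic_exponent=1.5, aperiodic_scale=20.0,
                  alpha_power=20.0, duration=180.0, seed=42)
ts, _ = generate_eeg(spec)
epochs = preprocess_resting(ts)            # filter, epoch, baseline, reject
_, fits = spectrum_to_aperiodic(epochs)    # Welch + masked log-log fit
slope, intercept = average_occipital(fits)
print(f"slope={slope:.3f}  intercept={intercept:.3f}")
# slope=-1.454  intercept=1.261

# --- MRS: quantify a synthetic MEGA-PRESS acquisition
acq = generate_mega_press_acquisition(MRSSimSpec(seed=42))
q = quantify_acquisition(acq)
print(f"Glx/GABA+ = {q.glx_gaba_ratio:.3f}   GABA+ SNR = "
      f"{q.quality['GABA+'].snr:.1f}")
# Glx/GABA+ = 3.466   GABA+ SNR = 19.5
```

The recovered slope −1.454 sits within the pipeline's calibrated bias of the
generative −1.5 (the 1 Hz high-pass and 1 s Welch windows cost a few
hundredths; see `docs/methods.md`), and the intercept 1.261 tracks
log10(20) = 1.301. The quantified Glx/GABA+ of 3.466 matches the generative
concentration ratio 10 / (2 × 1.45) = 3.448 to half a percent at the
default visual-cortex-like SNR of ≈ 20.

A full simulated study (two groups of 10, EEG conditions EC/EO/LU, MRS
conditions EO/EC, ANOVAs and the exploratory EEG×MRS correlation family):

```bash
neuroei all --seed 1 --out results/run1     # writes CSVs + report.txt
```

## Layout

| Module | Contents |
| --- | --- |
| `neuroei.synthetic_eeg` | 1/f EEG generator (exact spectral shaping), alpha injection, artifact injection with truth masks |
| `neuroei.synthetic_mrs` | MEGA-PRESS ON/OFF/water generator with editing model |
| `neuroei.cohort_sim` | two-group age-matched cohort designs with configurable effects |
| `neuroei.preprocess` | FIR filtering, epoching, baseline removal, amplitude rejection, resampling |
| `neuroei.spectral` | Welch PSD, spectrum normalization, masked aperiodic fit, occipital averaging |
| `neuroei.mrs` | DIFF construction, lmfit peak models, water/Cr normalization, quality metrics |
| `neuroei.stats` | ANOVA with partial η², t-tests, Pearson + Fisher-z CI, Bonferroni, Shapiro/Levene, cohort summaries |
| `neuroei.pipeline` / `neuroei.cli` | end-to-end runner, report bundle, `neuroei` command |
| `neuroei.validation` | the recovery/calibration experiments used by tests and the reproduction script |
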