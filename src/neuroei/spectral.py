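"""Welch power spectral density and aperiodic (1/f) parameterization.

The aperiodic component is estimated exactly as in the pwelch-based workflow
this package mirrors: the spectrum is normalized by its mean density over the
1–20 Hz fit range, converted to log-log scale, and an ordinary least-squares
line is fit over 1–20 Hz with the alpha band (8–14 Hz) masked out to avoid
contamination by oscillatory alpha power.  The fit yields a slope (decay
exponent in log10 power per log10 Hz), an intercept at 1 Hz re-referenced to
the un-normalized spectrum, an RMS fit error and R².
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .types import AperiodicFit, EpochedData, PowerSpectrum

DEFAULT_FIT_RANGE = (1.0, 20.0)
DEFAULT_EXCLUDED_BAND = (8.0, 14.0)
OCCIPITAL_ELECTRODES = ("O1", "O2")


def welch_psd(e: EpochedData, window: int | None = None,
              overlap: int = 0) -> PowerSpectrum:
    """One-sided Welch PSD averaged over segments and retained epochs.

    Per-segment periodograms use a periodic Hamming taper, matching the
    pwelch defaults of the workflow this reproduces (resting: fs = 1000,
    window = 1000 samples, overlap = 0; luminance: fs = 60, window = 60).
    """
    if e.n_retained < 1:
        raise ValueError("all epochs rejected; no data for PSD")
    fs = e.sampling_rate
    epoch_samples = e.epochs.shape[2]
    if window is None:
        window = min(int(round(fs)), epoch_samples)
    if window > epoch_samples:
        raise ValueError("window longer than epoch")
    if not 0 <= overlap < window:
        raise ValueError("overlap must lie in [0, window)")
    data = e.retained()  # (n_epochs, n_channels, n_times)
    freqs, pxx = signal.welch(
        data, fs=fs, window=signal.get_window("hamming", window, fftbins=True),
        nperseg=window, noverlap=overlap, detrend=False, axis=2,
        scaling="density", return_onesided=True)
    power = pxx.mean(axis=0)
    return PowerSpectrum(frequencies=freqs, power=power,
                         channel_labels=list(e.channel_labels),
                         n_epochs_used=e.n_retained,
                         welch_params={"window": int(window),
                                       "overlap": int(overlap),
                                       "sampling_rate": float(fs)})


def normalize_spectrum(ps: PowerSpectrum,
                       fit_range: tuple[float, float] = DEFAULT_FIT_RANGE,
                       ) -> PowerSpectrum:
    """Divide each channel by its mean density over the fit range.

    The divided-out constant is retained on the returned spectrum so the
    aperiodic intercept can be reported on the un-normalized scale.  In log
    space normalization is a vertical shift only; the fitted slope is
    unchanged by it.
    """
    lo, hi = fit_range
    band = (ps.frequencies >= lo) & (ps.frequencies <= hi)
    if not band.any():
        raise ValueError("fit range contains no frequency bins")
    const = ps.power[:, band].mean(axis=1)
    if np.any(const <= 0):
        raise ValueError("zero spectrum in the fit range")
    prior = ps.normalization if ps.normalization is not None else 1.0
    return PowerSpectrum(frequencies=ps.frequencies.copy(),
                         power=ps.power / const[:, None],
                         channel_labels=list(ps.channel_labels),
                         n_epochs_used=ps.n_epochs_used,
                         welch_params=dict(ps.welch_params),
                         normalization=const * prior)


def _masked_bins(freqs: np.ndarray, fit_range: tuple[float, float],
                 excluded: tuple[float, float]) -> np.ndarray:
    """Boolean mask of fit bins: inside the closed fit range, outside the
    closed exclusion interval (bins at exactly 8 or 14 Hz are excluded)."""
    lo, hi = fit_range
    ex_lo, ex_hi = excluded
    mask = (freqs >= lo) & (freqs <= hi)
    mask &= ~((freqs >= ex_lo) & (freqs <= ex_hi))
    return mask


def fit_aperiodic(ps: PowerSpectrum,
                  fit_range: tuple[float, float] = DEFAULT_FIT_RANGE,
                  excluded: tuple[float, float] = DEFAULT_EXCLUDED_BAND,
                  ) -> list[AperiodicFit]:
    """Masked log-log OLS fit of the aperiodic component, per channel.

    Fits ``log10 P = intercept + slope · log10 f`` over bins with
    1 ≤ f ≤ 20 Hz and not 8 ≤ f ≤ 14 Hz.  The reported intercept refers to
    the un-normalized spectrum: any constant stored by
    :func:`normalize_spectrum` is re-applied as ``+ log10(constant)``.
    """
    mask = _masked_bins(ps.frequencies, fit_range, excluded)
    if mask.sum() < 3:
        raise ValueError("fewer than 3 usable frequency bins after masking")
    logf = np.log10(ps.frequencies[mask])
    fits = []
    for ci, label in enumerate(ps.channel_labels):
        p = ps.power[ci, mask]
        if np.any(p <= 0):
            raise ValueError(f"non-positive power in fit range on {label}")
        logp = np.log10(p)
        slope, intercept = np.polyfit(logf, logp, 1)
        resid = logp - (intercept + slope * logf)
        fit_error = float(np.sqrt(np.mean(resid ** 2)))
        ss_tot = float(np.sum((logp - logp.mean()) ** 2))
        r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid ** 2)) / ss_tot
        if ps.normalization is not None:
            intercept = intercept + np.log10(ps.normalization[ci])
        fits.append(AperiodicFit(slope=float(slope),
                                 intercept=float(intercept),
                                 fit_error=fit_error,
                                 r_squared=float(min(max(r2, 0.0), 1.0)),
                                 fit_range=fit_range, excluded_band=excluded,
                                 channel=label, n_bins=int(mask.sum())))
    return fits


def average_occipital(fits: list[AperiodicFit],
                      electrodes: tuple[str, ...] = OCCIPITAL_ELECTRODES,
                      ) -> tuple[float, float]:
    """Mean slope and intercept over the pre-selected occipital electrodes.

    Fitting happens per electrode first; parameters are averaged after
    (fit-then-average, not fit-of-average).
    """
    by_channel = {f.channel: f for f in fits}
    missing = [e for e in electrodes if e not in by_channel]
    if missing:
        raise KeyError(f"no aperiodic fit for electrode(s): {missing}")
    slope = float(np.mean([by_channel[e].slope for e in electrodes]))
    intercept = float(np.mean([by_channel[e].intercept for e in electrodes]))
    return slope, intercept


def spectrum_to_aperiodic(e: EpochedData, window: int | None = None,
                          fit_range: tuple[float, float] = DEFAULT_FIT_RANGE,
                          excluded: tuple[float, float] = DEFAULT_EXCLUDED_BAND,
                          ) -> tuple[PowerSpectrum, list[AperiodicFit]]:
    """Convenience: Welch PSD → normalization → masked aperiodic fit."""
    ps = welch_psd(e, window=window)
    fits = fit_aperiodic(normalize_spectrum(ps, fit_range), fit_range, excluded)
    return ps, fits
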