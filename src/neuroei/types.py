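"""Core data containers shared across the pipeline.

Units follow the conventions of clinical EEG/MRS work: EEG samples in
microvolts (μV), power spectral densities in μV²/Hz, MR spectra in arbitrary
units on a parts-per-million (ppm) chemical-shift axis, and concentrations in
institutional units (water-normalized) or as dimensionless ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

#: Standard 10/20 channel names used by the synthetic generator, in the order
#: channels are laid out when no explicit labels are given.
TEN_TWENTY_LABELS = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6", "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP1", "CP2", "CP6", "P7", "P3", "Pz", "P4", "P8",
    "PO9", "O1", "Oz", "O2", "PO10", "TP9", "TP10",
]


@dataclass
class TimeSeriesRecording:
    """Multichannel EEG recording.

    Attributes
    ----------
    samples : ndarray, shape (n_channels, n_times)
        Signal in μV.
    sampling_rate : float
        Sampling frequency in Hz.
    channel_labels : list of str
        10/20 electrode names, unique.
    condition : str or None
        One of ``{"EC", "EO", "LU"}`` when known.
    """

    samples: np.ndarray
    sampling_rate: float
    channel_labels: list[str]
    condition: Optional[str] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a (channels, time) array")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError("channel_labels length must match channel count")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_times / self.sampling_rate

    def copy(self) -> "TimeSeriesRecording":
        return replace(self, samples=self.samples.copy(),
                       channel_labels=list(self.channel_labels))

    def pick(self, labels: list[str]) -> "TimeSeriesRecording":
        """Return a channel subset in the requested order."""
        missing = [l for l in labels if l not in self.channel_labels]
        if missing:
            raise KeyError(f"channels not present: {missing}")
        idx = [self.channel_labels.index(l) for l in labels]
        return replace(self, samples=self.samples[idx].copy(),
                       channel_labels=list(labels))


@dataclass
class EpochedData:
    """Fixed-length consecutive epochs cut from a recording.

    ``rejected`` marks epochs excluded from further analysis; ``reasons``
    carries a short code (e.g. ``"amplitude"``) per rejected epoch.
    """

    epochs: np.ndarray  # (n_epochs, n_channels, n_times)
    sampling_rate: float
    channel_labels: list[str]
    epoch_length: float  # seconds
    rejected: np.ndarray = field(default=None)  # type: ignore[assignment]
    reasons: list[str] = field(default_factory=list)
    baseline_removed: bool = False
    condition: Optional[str] = None

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be (epochs, channels, time)")
        if self.rejected is None:
            self.rejected = np.zeros(self.epochs.shape[0], dtype=bool)
        self.rejected = np.asarray(self.rejected, dtype=bool)
        if self.rejected.shape[0] != self.epochs.shape[0]:
            raise ValueError("rejected flags must cover every epoch")
        if not self.reasons:
            self.reasons = [""] * self.epochs.shape[0]

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_retained(self) -> int:
        return int((~self.rejected).sum())

    @property
    def rejection_fraction(self) -> float:
        return float(self.rejected.mean()) if self.n_epochs else 0.0

    def retained(self) -> np.ndarray:
        """Epoch array restricted to retained epochs."""
        return self.epochs[~self.rejected]

    def copy(self) -> "EpochedData":
        return replace(self, epochs=self.epochs.copy(),
                       rejected=self.rejected.copy(),
                       reasons=list(self.reasons),
                       channel_labels=list(self.channel_labels))


@dataclass
class PowerSpectrum:
    """One-sided Welch power spectral density per channel."""

    frequencies: np.ndarray  # Hz, strictly increasing
    power: np.ndarray  # (n_channels, n_freqs), μV²/Hz
    channel_labels: list[str]
    n_epochs_used: int
    welch_params: dict = field(default_factory=dict)
    #: per-channel constant divided out by normalize_spectrum (None before)
    normalization: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power = np.atleast_2d(np.asarray(self.power, dtype=float))
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if np.any(self.frequencies < 0):
            raise ValueError("frequencies must be non-negative")
        if self.power.shape != (len(self.channel_labels), self.frequencies.size):
            raise ValueError("power must be (n_channels, n_freqs)")

    def channel(self, label: str) -> np.ndarray:
        return self.power[self.channel_labels.index(label)]


@dataclass
class AperiodicFit:
    """Parameters of the aperiodic (1/f) component of one channel's spectrum.

    ``slope`` and ``intercept`` describe the least-squares line through
    (log10 f, log10 P) over the fit range with the exclusion band masked out.
    ``intercept`` refers to the *un-normalized* spectrum at 1 Hz (log10 f = 0);
    the constant divided out during spectrum normalization is re-applied.
    """

    slope: float
    intercept: float
    fit_error: float  # RMS residual, log10 power units
    r_squared: float
    fit_range: tuple[float, float] = (1.0, 20.0)
    excluded_band: tuple[float, float] = (8.0, 14.0)
    channel: str = ""
    n_bins: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("r_squared must lie in [0, 1]")
        if self.fit_error < 0:
            raise ValueError("fit_error must be non-negative")


@dataclass
class MRSAcquisition:
    """Averaged MEGA-PRESS sub-spectra on a shared ppm axis.

    ``on`` / ``off`` are the edit-ON and edit-OFF averages; ``water`` is the
    unsuppressed water reference. ``field_mhz`` is the proton frequency used
    for ppm→Hz conversion (127.7 MHz at 3 T).
    """

    ppm: np.ndarray
    on: np.ndarray
    off: np.ndarray
    water: np.ndarray
    field_mhz: float = 127.7
    region: str = "visual"
    condition: Optional[str] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        for name in ("on", "off", "water"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != self.ppm.shape:
                raise ValueError(f"{name} spectrum must share the ppm axis")
        if np.any(np.diff(self.ppm) <= 0):
            raise ValueError("ppm axis must be strictly increasing")
        if self.field_mhz <= 0:
            raise ValueError("field_mhz must be positive")


@dataclass
class TissueFractions:
    """Grey-matter / white-matter / CSF volume fractions of the MRS voxel."""

    f_gm: float
    f_wm: float
    f_csf: float

    def __post_init__(self) -> None:
        for f in (self.f_gm, self.f_wm, self.f_csf):
            if not 0.0 <= f <= 1.0:
                raise ValueError("tissue fractions must lie in [0, 1]")
        if abs(self.f_gm + self.f_wm + self.f_csf - 1.0) > 1e-6:
            raise ValueError("tissue fractions must sum to 1")


@dataclass
class PeakQuality:
    """Quality metrics for one fitted peak."""

    snr: float
    fwhm_hz: float
    fit_error_pct: float
    crlb: float  # relative standard error of the fitted area


@dataclass
class MRSQuantification:
    """Quantified metabolite outcomes for one acquisition."""

    gaba_plus: float  # water-normalized, institutional units
    glx: float
    naa: float
    gaba_plus_cr: float
    glx_cr: float
    glx_gaba_ratio: float
    quality: dict[str, PeakQuality] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("gaba_plus", "glx", "naa"):
            v = getattr(self, name)
            if np.isfinite(v) and v < 0:
                # Negative fitted areas can occur at very low SNR; they are
                # clipped upstream, so a negative here signals a logic error.
                raise ValueError(f"{name} concentration must be >= 0")


@dataclass
class StatsResult:
    """One ANOVA effect: F statistic, degrees of freedom, p, partial η²."""

    effect: str
    F: float
    df_num: float
    df_den: float
    p: float
    partial_eta_sq: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.degenerate:
            return
        if self.F < 0:
            raise ValueError("F must be non-negative")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")
        if not 0.0 <= self.partial_eta_sq <= 1.0:
            raise ValueError("partial eta squared must lie in [0, 1]")


@dataclass
class CorrelationResult:
    """Pearson correlation with Fisher-z confidence interval."""

    r: float
    p: float
    ci95: tuple[float, float]
    n: int
    p_adjusted: Optional[float] = None
    m: Optional[int] = None

    def __post_init__(self) -> None:
        if not -1.0 <= self.r <= 1.0:
            raise ValueError("r must lie in [-1, 1]")
        lo, hi = self.ci95
        if not (lo - 1e-12 <= self.r <= hi + 1e-12):
            raise ValueError("ci95 must contain r")
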