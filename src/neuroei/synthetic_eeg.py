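"""Synthetic resting-state / stimulation EEG with known ground truth.

The generator produces multichannel recordings whose one-sided power spectral
density follows a 1/f aperiodic law ``S(f) = scale · f^(−χ)`` by construction:
spectral amplitudes are shaped deterministically in the frequency domain and
only the phases are random.  An alpha-band oscillation and transient
high-amplitude artifacts can be layered on top, each with an exactly known
contribution, so downstream estimators (Welch PSD, masked log-log fit,
±threshold epoch rejection) can be validated against generative truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import TimeSeriesRecording

#: Simulation channel order: occipital analysis electrodes first so that small
#: channel counts still carry the O1/O2 analysis set.
DEFAULT_SIM_LABELS = [
    "O1", "O2", "Oz", "Fp1", "Fp2", "F3", "Fz", "F4", "F7", "F8",
    "C3", "Cz", "C4", "T7", "T8", "P3", "Pz", "P4", "P7", "P8",
    "FC1", "FC2", "FC5", "FC6", "CP1", "CP2", "CP5", "CP6",
    "PO9", "PO10", "TP9", "TP10",
]

#: Below this frequency the synthesized 1/f law is clamped flat so that
#: slow drift (removed anyway by the 1 Hz high-pass) stays bounded.
_LOW_FREQ_CLAMP_HZ = 0.5

#: Frequency ceiling of the modeled band; the Nyquist guard checks against it.
_MODEL_BAND_TOP_HZ = 45.0


@dataclass
class EEGSimSpec:
    """Ground-truth parameters of one synthetic EEG recording.

    Parameters
    ----------
    aperiodic_exponent : float
        Decay exponent χ ≥ 0 of the aperiodic PSD, ``S(f) ∝ f^(−χ)``.
    aperiodic_scale : float
        Power density at 1 Hz in μV²/Hz.
    alpha_center, alpha_bandwidth : float
        Center (Hz) and full bandwidth (Hz) of the alpha oscillation.
    alpha_power : float
        Total alpha band power in μV²; 0 disables the oscillation.
    artifact_rate : float
        Transient artifact events per minute; 0 disables artifacts.
    artifact_amplitude : float
        Peak deflection of each artifact in μV.
    duration : float
        Recording length in s; ``duration × sampling_rate`` must be integer.
    sampling_rate : float
        Hz; must exceed twice the highest modeled frequency.
    n_channels : int
        Number of channels, labelled from :data:`DEFAULT_SIM_LABELS`.
    seed : int
        Fixes the output bit-exactly.
    """

    aperiodic_exponent: float = 1.2
    aperiodic_scale: float = 20.0
    alpha_center: float = 10.0
    alpha_bandwidth: float = 4.0
    alpha_power: float = 20.0
    artifact_rate: float = 0.0
    artifact_amplitude: float = 200.0
    duration: float = 180.0
    sampling_rate: float = 1000.0
    n_channels: int = 2
    channel_labels: list[str] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("aperiodic_exponent", "aperiodic_scale", "alpha_center",
                     "alpha_bandwidth", "alpha_power", "artifact_rate",
                     "artifact_amplitude", "duration", "sampling_rate"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.aperiodic_exponent < 0:
            raise ValueError("aperiodic_exponent must be >= 0")
        if self.aperiodic_scale < 0:
            raise ValueError("aperiodic_scale must be >= 0")
        if self.duration <= 0 or self.sampling_rate <= 0:
            raise ValueError("duration and sampling_rate must be positive")
        n = self.duration * self.sampling_rate
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration x sampling_rate must be an integer "
                             "sample count")
        highest = _MODEL_BAND_TOP_HZ
        if self.alpha_power > 0:
            highest = max(highest, self.alpha_center + self.alpha_bandwidth / 2)
        if self.sampling_rate <= 2 * highest:
            raise ValueError("sampling_rate must exceed twice the highest "
                             "modeled frequency")
        if self.duration < 1.0 / max(self.sampling_rate / 2, 1.0) * 3:
            raise ValueError("duration too short for the requested band")
        if not self.channel_labels:
            self.channel_labels = DEFAULT_SIM_LABELS[: self.n_channels]
        if len(self.channel_labels) != self.n_channels:
            raise ValueError("channel_labels must match n_channels")


def _synthesize_from_psd(psd: np.ndarray, n_times: int, fs: float,
                         rng: np.random.Generator,
                         n_channels: int) -> np.ndarray:
    """Realize time series whose one-sided PSD equals ``psd`` bin-exactly.

    Amplitudes are fixed by the target density; only phases are random, so the
    full-length periodogram of each channel reproduces ``psd`` exactly.
    """
    n_freqs = psd.size
    amp = np.sqrt(psd * fs * n_times / 2.0)
    amp[0] = 0.0  # no DC
    if n_times % 2 == 0:
        amp[-1] = 0.0  # drop the Nyquist bin (cannot carry a random phase)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(n_channels, n_freqs))
    spectrum = amp[None, :] * np.exp(1j * phases)
    spectrum[:, 0] = 0.0
    if n_times % 2 == 0:
        spectrum[:, -1] = 0.0
    return np.fft.irfft(spectrum, n=n_times, axis=1)


def generate_aperiodic_timeseries(spec: EEGSimSpec) -> TimeSeriesRecording:
    """Generate a recording with PSD ``aperiodic_scale · f^(−χ)`` over 1–45 Hz.

    Channels are independent phase realizations of the same target density.
    The law is clamped flat below 0.5 Hz to bound slow drift; the analysis
    band (≥1 Hz) is unaffected.
    """
    rng = np.random.default_rng(spec.seed)
    n_times = int(round(spec.duration * spec.sampling_rate))
    freqs = np.fft.rfftfreq(n_times, d=1.0 / spec.sampling_rate)
    f_eff = np.maximum(freqs, _LOW_FREQ_CLAMP_HZ)
    psd = spec.aperiodic_scale * f_eff ** (-spec.aperiodic_exponent)
    psd[0] = 0.0
    samples = _synthesize_from_psd(psd, n_times, spec.sampling_rate, rng,
                                   spec.n_channels)
    return TimeSeriesRecording(samples=samples,
                               sampling_rate=spec.sampling_rate,
                               channel_labels=list(spec.channel_labels))


def add_alpha_oscillation(ts: TimeSeriesRecording, center: float,
                          bandwidth: float, power: float,
                          seed: int = 0) -> TimeSeriesRecording:
    """Add a band-limited stochastic alpha oscillation.

    The added component's PSD is a Hann-shaped bump supported exactly on
    ``[center − bandwidth/2, center + bandwidth/2]`` and integrating to
    ``power`` μV², so band-integrated Welch power increases by ≈``power`` and
    bins outside the band are untouched.  ``power = 0`` returns the input
    unchanged.
    """
    if power < 0:
        raise ValueError("power must be >= 0")
    if power == 0:
        return ts.copy()
    lo, hi = center - bandwidth / 2.0, center + bandwidth / 2.0
    if lo < 0 or hi >= ts.sampling_rate / 2.0:
        raise ValueError("alpha band must lie within [0, Nyquist)")
    rng = np.random.default_rng(seed)
    n_times = ts.n_times
    freqs = np.fft.rfftfreq(n_times, d=1.0 / ts.sampling_rate)
    in_band = (freqs > lo) & (freqs < hi)
    shape = np.zeros_like(freqs)
    shape[in_band] = 0.5 * (1.0 + np.cos(2.0 * np.pi
                                         * (freqs[in_band] - center)
                                         / bandwidth))
    df = freqs[1] - freqs[0]
    total = shape.sum() * df
    if total <= 0:
        raise ValueError("alpha band contains no frequency bins; "
                         "recording too short for the requested bandwidth")
    psd = shape * (power / total)
    alpha = _synthesize_from_psd(psd, n_times, ts.sampling_rate, rng,
                                 ts.n_channels)
    out = ts.copy()
    out.samples = out.samples + alpha
    return out


def inject_artifacts(ts: TimeSeriesRecording, rate: float, amplitude: float,
                     seed: int = 0,
                     pulse_width: float = 0.2) -> tuple[TimeSeriesRecording,
                                                        np.ndarray]:
    """Insert transient deflections and return the contaminated-epoch mask.

    Each event is a Hann pulse of peak ``amplitude`` μV and ``pulse_width`` s,
    placed at the center of a randomly chosen 1 s epoch on one random channel.
    The pulse sign matches the underlying sample so the peak magnitude is at
    least ``amplitude`` above zero — an event epoch always exceeds a rejection
    threshold below ``amplitude``.  ``truth_mask[i]`` is True iff epoch *i*
    received an event.
    """
    if amplitude <= 0:
        raise ValueError("amplitude must be positive")
    if rate < 0:
        raise ValueError("rate must be >= 0")
    n_epochs = int(ts.duration)  # 1 s epochs
    truth_mask = np.zeros(n_epochs, dtype=bool)
    out = ts.copy()
    if rate == 0:
        return out, truth_mask
    n_events = int(round(rate * ts.duration / 60.0))
    if n_events >= n_epochs:
        raise ValueError("artifact rate would contaminate every epoch")
    rng = np.random.default_rng(seed)
    event_epochs = rng.choice(n_epochs, size=n_events, replace=False)
    fs = ts.sampling_rate
    half = int(round(pulse_width * fs / 2.0))
    t = np.arange(-half, half + 1)
    pulse = amplitude * 0.5 * (1.0 + np.cos(np.pi * t / half))
    for ep in event_epochs:
        center = int((ep + 0.5) * fs)
        ch = rng.integers(ts.n_channels)
        sign = 1.0 if out.samples[ch, center] >= 0 else -1.0
        sl = slice(center - half, center + half + 1)
        out.samples[ch, sl] += sign * pulse
        truth_mask[ep] = True
    return out, truth_mask


def generate_eeg(spec: EEGSimSpec) -> tuple[TimeSeriesRecording, np.ndarray]:
    """Full generator: aperiodic background + alpha + artifacts.

    Sub-stages draw from independent streams spawned from ``spec.seed`` so the
    whole recording is reproducible bit-exactly.  Returns the recording and
    the per-1 s-epoch artifact truth mask (all False when artifact_rate = 0).
    """
    ss = np.random.SeedSequence(spec.seed)
    s_ap, s_alpha, s_art = ss.spawn(3)
    ap_spec = EEGSimSpec(**{**spec.__dict__,
                            "seed": int(s_ap.generate_state(1)[0])})
    ts = generate_aperiodic_timeseries(ap_spec)
    if spec.alpha_power > 0:
        ts = add_alpha_oscillation(ts, spec.alpha_center,
                                   spec.alpha_bandwidth, spec.alpha_power,
                                   seed=int(s_alpha.generate_state(1)[0]))
    if spec.artifact_rate > 0:
        ts, mask = inject_artifacts(ts, spec.artifact_rate,
                                    spec.artifact_amplitude,
                                    seed=int(s_art.generate_state(1)[0]))
    else:
        mask = np.zeros(int(ts.duration), dtype=bool)
    return ts, mask
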