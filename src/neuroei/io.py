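"""Readers and writers for the package's on-disk formats.

EEG: BrainVision triplet (.vhdr/.eeg/.vmrk, IEEE float32 multiplexed) and
plain CSV (time × channels).  MRS: an HDF5 container and a commented CSV,
both carrying the ppm axis, ON/OFF/water sub-spectra and acquisition
metadata.  Spectra and fit tables are tidy CSVs via pandas.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .types import MRSAcquisition, PowerSpectrum, TimeSeriesRecording


# ---------------------------------------------------------------- BrainVision

def write_brainvision(ts: TimeSeriesRecording, basename: str | Path) -> Path:
    """Write a BrainVision triplet; returns the .vhdr path.

    Data are stored as multiplexed IEEE float32 in μV with unit resolution,
    readable by any BrainVision-aware tool.
    """
    base = Path(basename)
    base.parent.mkdir(parents=True, exist_ok=True)
    stem = base.name
    vhdr, vmrk, eeg = (base.with_suffix(s) for s in (".vhdr", ".vmrk", ".eeg"))

    interval_us = 1e6 / ts.sampling_rate
    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "; Written by neuroei",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={stem}.eeg",
        f"MarkerFile={stem}.vmrk",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={ts.n_channels}",
        f"SamplingInterval={interval_us:.6f}",
        "",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "",
        "[Channel Infos]",
    ]
    for i, label in enumerate(ts.channel_labels, start=1):
        lines.append(f"Ch{i}={label},,1,µV")
    vhdr.write_text("\n".join(lines) + "\n", encoding="utf-8")

    vmrk.write_text("\n".join([
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={stem}.eeg",
        "",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,0",
    ]) + "\n", encoding="utf-8")

    data = ts.samples.T.astype("<f4")  # multiplexed: time-major
    data.tofile(eeg)
    return vhdr


def read_brainvision(vhdr_path: str | Path,
                     condition: str | None = None) -> TimeSeriesRecording:
    """Read a BrainVision triplet via MNE (imported lazily)."""
    import mne

    raw = mne.io.read_raw_brainvision(str(vhdr_path), preload=True,
                                      verbose="error")
    samples = raw.get_data() * 1e6  # MNE loads volts; convert back to μV
    return TimeSeriesRecording(samples=samples,
                               sampling_rate=float(raw.info["sfreq"]),
                               channel_labels=list(raw.ch_names),
                               condition=condition)


# ------------------------------------------------------------------- EEG CSV

def write_eeg_csv(ts: TimeSeriesRecording, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(ts.samples.T, columns=ts.channel_labels)
    df.insert(0, "time_s", np.arange(ts.n_times) / ts.sampling_rate)
    df.to_csv(path, index=False)
    return path


def read_eeg_csv(path: str | Path,
                 condition: str | None = None) -> TimeSeriesRecording:
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError("EEG CSV must contain a time_s column")
    t = df.pop("time_s").to_numpy()
    fs = 1.0 / np.median(np.diff(t))
    return TimeSeriesRecording(samples=df.to_numpy().T,
                               sampling_rate=float(round(fs, 6)),
                               channel_labels=list(df.columns),
                               condition=condition)


# ------------------------------------------------------------- MRS container

def write_mrs_hdf5(acq: MRSAcquisition, path: str | Path) -> Path:
    """HDF5 schema: datasets ppm/on/off/water; attrs field_mhz, region,
    condition, metadata (JSON)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        for name in ("ppm", "on", "off", "water"):
            f.create_dataset(name, data=getattr(acq, name))
        f.attrs["field_mhz"] = acq.field_mhz
        f.attrs["region"] = acq.region
        f.attrs["condition"] = acq.condition or ""
        f.attrs["metadata"] = json.dumps(acq.metadata, default=str)
    return path


def read_mrs_hdf5(path: str | Path) -> MRSAcquisition:
    with h5py.File(path, "r") as f:
        kwargs = {name: f[name][()] for name in ("ppm", "on", "off", "water")}
        meta = json.loads(f.attrs.get("metadata", "{}"))
        condition = str(f.attrs.get("condition", "")) or None
        return MRSAcquisition(field_mhz=float(f.attrs["field_mhz"]),
                              region=str(f.attrs["region"]),
                              condition=condition, metadata=meta, **kwargs)


def write_mrs_csv(acq: MRSAcquisition, path: str | Path) -> Path:
    """Commented-header CSV: `# key=value` lines then ppm,on,off,water."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# field_mhz={acq.field_mhz}\n")
        fh.write(f"# region={acq.region}\n")
        fh.write(f"# condition={acq.condition or ''}\n")
        pd.DataFrame({"ppm": acq.ppm, "on": acq.on, "off": acq.off,
                      "water": acq.water}).to_csv(fh, index=False)
    return path


def read_mrs_csv(path: str | Path) -> MRSAcquisition:
    attrs: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            attrs[key.strip()] = val.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    return MRSAcquisition(ppm=df["ppm"].to_numpy(), on=df["on"].to_numpy(),
                          off=df["off"].to_numpy(),
                          water=df["water"].to_numpy(),
                          field_mhz=float(attrs.get("field_mhz", 127.7)),
                          region=attrs.get("region", "visual"),
                          condition=attrs.get("condition") or None)


# ---------------------------------------------------------------- spectra CSV

def write_spectrum_csv(ps: PowerSpectrum, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(ps.power.T, columns=ps.channel_labels)
    df.insert(0, "frequency_hz", ps.frequencies)
    df.to_csv(path, index=False)
    return path


def read_spectrum_csv(path: str | Path) -> PowerSpectrum:
    df = pd.read_csv(path)
    freqs = df.pop("frequency_hz").to_numpy()
    return PowerSpectrum(frequencies=freqs, power=df.to_numpy().T,
                         channel_labels=list(df.columns), n_epochs_used=0)
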