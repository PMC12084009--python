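"""Two-group cohort simulation with configurable group effects.

Emulates the study design this package targets: two age-matched groups of 10
(a congenital cataract-reversal group "CC" and sighted controls "SC"), three
EEG conditions (eyes closed EC, eyes open EO, luminance stimulation LU:
3-minute resting recordings and 100 × 6.25 s stimulation trials), and one
MEGA-PRESS acquisition per MRS condition (EO, EC).  Group effects are applied
to the CC group's generative parameters: an offset on the aperiodic slope,
an offset on the log10 aperiodic intercept, and an offset on the generative
Glx/GABA+ concentration ratio.  The ground-truth parameter table is returned
alongside the data so recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic_eeg import EEGSimSpec, generate_eeg
from .synthetic_mrs import MRSSimSpec, generate_mega_press_acquisition
from .types import MRSAcquisition, TissueFractions

#: Between-subject SDs of the generative parameters (biological variability).
SUBJECT_SD = {
    "chi": 0.15,          # aperiodic exponent
    "log_scale": 0.10,    # log10 of the 1 Hz power density
    "gaba": 0.20,         # mM
    "ratio": 0.30,        # generative Glx/GABA+ ratio
    "age_match": 1.0,     # years of age-matching jitter within a pair
}

#: Condition-dependent alpha power (μV²): strongest with eyes closed.
ALPHA_POWER_BY_CONDITION = {"EC": 30.0, "EO": 12.0, "LU": 8.0}

MRS_CONDITIONS = ("EO", "EC")


@dataclass
class CohortSimSpec:
    """Design of a simulated two-group cohort.

    ``group_effect_slope`` is the CC−SC difference in mean *recovered* slope
    (negative = steeper CC spectra); ``group_effect_intercept`` the CC−SC
    difference in log10 1 Hz power; ``group_effect_glx_gaba`` the CC−SC
    difference in the generative Glx/GABA+ concentration ratio.
    """

    n_per_group: int = 10
    age_range: tuple[float, float] = (11.0, 44.0)
    group_effect_slope: float = 0.0
    group_effect_intercept: float = 0.0
    group_effect_glx_gaba: float = 0.0
    conditions: tuple[str, ...] = ("EC", "EO", "LU")
    eeg_duration: float = 180.0
    lu_duration: float = 625.0
    sampling_rate: float = 1000.0
    n_channels: int = 2
    base_chi: float = 1.2
    base_scale: float = 20.0
    base_gaba: float = 2.0
    base_ratio: float = 3.45  # generative Glx/(GABA·(1+mm)) ratio
    mm_contamination: float = 0.45
    editing_efficiency: float = 0.5
    mrs_noise_sd: float = 5.0
    artifact_rate: float = 0.0
    artifact_amplitude: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if not self.conditions:
            raise ValueError("conditions must be non-empty")
        bad = set(self.conditions) - {"EC", "EO", "LU"}
        if bad:
            raise ValueError(f"unknown conditions: {sorted(bad)}")
        if self.base_chi < 0:
            raise ValueError("base_chi must be >= 0")


def cohort_truth(spec: CohortSimSpec) -> pd.DataFrame:
    """Per-subject generative parameters (the ground-truth table).

    Subjects are age-matched in pairs across groups; the CC group's
    parameters carry the configured effects.  Draws are reproducible from
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for pair in range(spec.n_per_group):
        age_sc = rng.uniform(*spec.age_range)
        age_cc = float(np.clip(age_sc + SUBJECT_SD["age_match"]
                               * rng.standard_normal(),
                               spec.age_range[0], spec.age_range[1]))
        for group, age in (("SC", age_sc), ("CC", age_cc)):
            eff = group == "CC"
            chi = (spec.base_chi
                   - (spec.group_effect_slope if eff else 0.0)
                   + SUBJECT_SD["chi"] * rng.standard_normal())
            if chi < 0:
                raise ValueError("group effect drives aperiodic exponent "
                                 "below zero")
            log_scale = (np.log10(spec.base_scale)
                         + (spec.group_effect_intercept if eff else 0.0)
                         + SUBJECT_SD["log_scale"] * rng.standard_normal())
            gaba = spec.base_gaba + SUBJECT_SD["gaba"] * rng.standard_normal()
            gaba = float(np.clip(gaba, 0.3, None))
            ratio = (spec.base_ratio
                     + (spec.group_effect_glx_gaba if eff else 0.0)
                     + SUBJECT_SD["ratio"] * rng.standard_normal())
            if ratio <= 0:
                raise ValueError("group effect drives Glx/GABA+ ratio "
                                 "non-positive")
            glx = ratio * gaba * (1.0 + spec.mm_contamination)
            f_gm = float(np.clip(0.55 + 0.03 * rng.standard_normal(),
                                 0.3, 0.8))
            f_csf = float(np.clip(0.10 + 0.02 * rng.standard_normal(),
                                  0.01, 0.3))
            rows.append({
                "subject": f"{group}{pair + 1:02d}", "group": group,
                "pair": pair, "age": age,
                "true_chi": float(chi), "true_slope": float(-chi),
                "true_log_scale": float(log_scale),
                "true_gaba": gaba, "true_glx": float(glx),
                "true_ratio": float(ratio),
                "f_gm": f_gm, "f_wm": float(1.0 - f_gm - f_csf),
                "f_csf": f_csf,
                "eeg_seed": int(rng.integers(2 ** 31)),
                "mrs_seed": int(rng.integers(2 ** 31)),
            })
    return pd.DataFrame(rows)


def simulate_subject_eeg(spec: CohortSimSpec, row: pd.Series,
                         condition: str):
    """One subject's recording for one condition (with artifact truth mask)."""
    duration = spec.lu_duration if condition == "LU" else spec.eeg_duration
    cond_index = {"EC": 0, "EO": 1, "LU": 2}[condition]
    eeg_spec = EEGSimSpec(
        aperiodic_exponent=row["true_chi"],
        aperiodic_scale=10.0 ** row["true_log_scale"],
        alpha_power=ALPHA_POWER_BY_CONDITION[condition],
        artifact_rate=spec.artifact_rate,
        artifact_amplitude=spec.artifact_amplitude,
        duration=duration, sampling_rate=spec.sampling_rate,
        n_channels=spec.n_channels,
        seed=int(row["eeg_seed"]) + cond_index)
    ts, mask = generate_eeg(eeg_spec)
    ts.condition = condition
    return ts, mask


def simulate_subject_mrs(spec: CohortSimSpec, row: pd.Series,
                         condition: str) -> MRSAcquisition:
    """One subject's MEGA-PRESS acquisition for one MRS condition."""
    cond_index = {"EO": 0, "EC": 1}[condition]
    mrs_spec = MRSSimSpec(
        concentrations={"GABA": row["true_gaba"], "Glx": row["true_glx"],
                        "NAA": 12.0, "Cr": 8.0},
        editing_efficiency=spec.editing_efficiency,
        mm_contamination=spec.mm_contamination,
        noise_sd=spec.mrs_noise_sd, condition=condition,
        seed=int(row["mrs_seed"]) + cond_index)
    return generate_mega_press_acquisition(mrs_spec)


def subject_tissue(row: pd.Series) -> TissueFractions:
    return TissueFractions(f_gm=row["f_gm"], f_wm=row["f_wm"],
                           f_csf=row["f_csf"])


def simulate_cohort(spec: CohortSimSpec):
    """Materialize the full cohort.

    Returns ``(truth, subjects)`` where ``truth`` is the ground-truth
    parameter table and ``subjects`` maps subject id to a dict with
    ``recordings`` (condition → (recording, artifact mask)),
    ``acquisitions`` (condition → MRSAcquisition) and ``tissue``.
    For long recordings prefer iterating with :func:`simulate_subject_eeg`
    / :func:`simulate_subject_mrs` to keep memory flat.
    """
    truth = cohort_truth(spec)
    subjects = {}
    for _, row in truth.iterrows():
        recordings = {c: simulate_subject_eeg(spec, row, c)
                      for c in spec.conditions}
        acquisitions = {c: simulate_subject_mrs(spec, row, c)
                        for c in MRS_CONDITIONS}
        subjects[row["subject"]] = {
            "recordings": recordings,
            "acquisitions": acquisitions,
            "tissue": subject_tissue(row),
        }
    return truth, subjects
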