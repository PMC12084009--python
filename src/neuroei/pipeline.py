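"""End-to-end pipeline: simulate → preprocess → fit → quantify → statistics.

Produces, per run: a per-subject outcome table (aperiodic slope/intercept per
EEG condition, metabolite concentrations per MRS condition), group×condition
ANOVA tables, an MRS quality-metric summary, a per-condition rejection-rate
table, an exploratory EEG–MRS correlation family (Bonferroni m = 6), and a
human-readable report.  Stage outputs are checkpointed as CSVs so any stage
can be inspected or re-run in isolation; everything is deterministic given
the seeds in the config.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import mrs, spectral, stats
from .cohort_sim import (MRS_CONDITIONS, CohortSimSpec, cohort_truth,
                         simulate_subject_eeg, simulate_subject_mrs,
                         subject_tissue)
from .preprocess import preprocess_luminance, preprocess_resting

log = logging.getLogger("neuroei.pipeline")

#: The fixed exploratory correlation family: EEG aperiodic parameter ×
#: MRS outcome, six comparisons per family.
CORRELATION_FAMILY = [("intercept", "gaba_plus"), ("intercept", "glx"),
                      ("intercept", "glx_gaba_ratio"),
                      ("slope", "gaba_plus"), ("slope", "glx"),
                      ("slope", "glx_gaba_ratio")]


@dataclass
class PipelineConfig:
    """Resolved parameters of one pipeline run (YAML-serializable)."""

    cohort: CohortSimSpec = field(default_factory=CohortSimSpec)
    rejection_threshold: float = 120.0
    fit_range: tuple[float, float] = (1.0, 20.0)
    excluded_band: tuple[float, float] = (8.0, 14.0)
    electrodes: tuple[str, ...] = ("O1", "O2")
    normalization: str = "water"  # or "cr"
    anova_repeated: bool = False
    correlation_m: int = 6
    align_spectra: bool = False
    seed: int | None = None  # overrides cohort.seed when set

    def __post_init__(self) -> None:
        if isinstance(self.cohort, dict):
            self.cohort = CohortSimSpec(**self.cohort)
        if self.normalization not in ("water", "cr"):
            raise ValueError("normalization must be 'water' or 'cr'")
        if self.seed is not None:
            self.cohort = dataclasses.replace(self.cohort, seed=int(self.seed))

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        blob = dataclasses.asdict(self)
        path.write_text(yaml.safe_dump(blob, sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        blob = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**blob)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def process_subject_eeg(config: PipelineConfig, row: pd.Series,
                        condition: str) -> dict:
    """Simulate and analyze one subject-condition EEG recording."""
    ts, _mask = simulate_subject_eeg(config.cohort, row, condition)
    if condition == "LU":
        epochs = preprocess_luminance(ts, config.rejection_threshold)
    else:
        epochs = preprocess_resting(ts, config.rejection_threshold)
    ps, fits = spectral.spectrum_to_aperiodic(
        epochs, fit_range=config.fit_range, excluded=config.excluded_band)
    slope, intercept = spectral.average_occipital(fits, config.electrodes)
    r2 = float(np.mean([f.r_squared for f in fits
                        if f.channel in config.electrodes]))
    return {"subject": row["subject"], "group": row["group"],
            "condition": condition, "slope": slope, "intercept": intercept,
            "r_squared": r2,
            "rejection_pct": 100.0 * epochs.rejection_fraction,
            "n_epochs": epochs.n_epochs, "n_retained": epochs.n_retained}


def process_subject_mrs(config: PipelineConfig, row: pd.Series,
                        condition: str) -> dict:
    """Simulate and quantify one subject-condition MRS acquisition."""
    acq = simulate_subject_mrs(config.cohort, row, condition)
    q = mrs.quantify_acquisition(acq, tissue=subject_tissue(row),
                                 align=config.align_spectra)
    if config.normalization == "cr":
        gaba, glx = q.gaba_plus_cr, q.glx_cr
        ratio = glx / gaba if gaba > 0 else np.nan
    else:
        gaba, glx, ratio = q.gaba_plus, q.glx, q.glx_gaba_ratio
    rec = {"subject": row["subject"], "group": row["group"],
           "condition": condition, "gaba_plus": gaba, "glx": glx,
           "glx_gaba_ratio": ratio, "naa": q.naa,
           "flags": ";".join(q.flags)}
    for met, qual in q.quality.items():
        key = met.lower().replace("+", "_plus")
        rec[f"snr_{key}"] = qual.snr
        rec[f"fwhm_{key}"] = qual.fwhm_hz
        rec[f"fit_error_{key}"] = qual.fit_error_pct
        rec[f"crlb_{key}"] = qual.crlb
    return rec


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage and write the report bundle into ``outdir``.

    Returns a dict with the outcome tables and the report text.  Any stage
    failure raises with the stage name and subject id in the message.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")

    truth = cohort_truth(config.cohort)
    _write_csv(truth, outdir / "ground_truth.csv")

    eeg_rows, mrs_rows = [], []
    for _, row in truth.iterrows():
        for condition in config.cohort.conditions:
            try:
                eeg_rows.append(process_subject_eeg(config, row, condition))
            except Exception as exc:  # noqa: BLE001 - annotate and re-raise
                raise RuntimeError(
                    f"stage=eeg subject={row['subject']} "
                    f"condition={condition}: {exc}") from exc
        for condition in MRS_CONDITIONS:
            try:
                mrs_rows.append(process_subject_mrs(config, row, condition))
            except Exception as exc:  # noqa: BLE001
                raise RuntimeError(
                    f"stage=mrs subject={row['subject']} "
                    f"condition={condition}: {exc}") from exc

    eeg_outcomes = pd.DataFrame(eeg_rows)
    mrs_outcomes = pd.DataFrame(mrs_rows)
    _write_csv(eeg_outcomes, outdir / "eeg_outcomes.csv")
    _write_csv(mrs_outcomes, outdir / "mrs_outcomes.csv")

    anova_rows = []
    for outcome, table in (("slope", eeg_outcomes),
                           ("intercept", eeg_outcomes),
                           ("gaba_plus", mrs_outcomes),
                           ("glx", mrs_outcomes),
                           ("glx_gaba_ratio", mrs_outcomes),
                           ("naa", mrs_outcomes)):
        try:
            effects = stats.anova_group_condition(
                table, outcome, repeated=config.anova_repeated)
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"stage=stats outcome={outcome}: {exc}") from exc
        for e in effects:
            anova_rows.append({"outcome": outcome, "effect": e.effect,
                               "F": e.F, "df_num": e.df_num,
                               "df_den": e.df_den, "p": e.p,
                               "partial_eta_sq": e.partial_eta_sq,
                               "degenerate": e.degenerate})
    anova_table = pd.DataFrame(anova_rows)
    _write_csv(anova_table, outdir / "anova.csv")

    correlations = _correlation_family(config, eeg_outcomes, mrs_outcomes)
    _write_csv(correlations, outdir / "correlations.csv")

    quality = _quality_summary(mrs_outcomes)
    _write_csv(quality, outdir / "quality_metrics.csv")

    rejection = (eeg_outcomes.groupby(["group", "condition"], as_index=False)
                 ["rejection_pct"].mean())
    _write_csv(rejection, outdir / "rejection_rates.csv")

    results = {"truth": truth, "eeg_outcomes": eeg_outcomes,
               "mrs_outcomes": mrs_outcomes, "anova": anova_table,
               "correlations": correlations, "quality": quality,
               "rejection": rejection}
    report = make_report(results)
    (outdir / "report.txt").write_text(report)
    results["report"] = report
    return results


def _correlation_family(config, eeg_outcomes, mrs_outcomes) -> pd.DataFrame:
    """CC-group EEG×MRS Pearson family, Bonferroni-adjusted (m = 6).

    EEG EO/EC pair with the matching MRS condition; the LU EEG condition
    pairs with the eyes-open MRS scan.
    """
    rows = []
    for eeg_cond in config.cohort.conditions:
        mrs_cond = "EO" if eeg_cond == "LU" else eeg_cond
        e = eeg_outcomes.query("group == 'CC' and condition == @eeg_cond")
        m = mrs_outcomes.query("group == 'CC' and condition == @mrs_cond")
        merged = e.merge(m, on=["subject", "group"],
                         suffixes=("_eeg", "_mrs"))
        family = []
        for eeg_var, mrs_var in CORRELATION_FAMILY:
            try:
                res = stats.pearson_ci(merged[eeg_var], merged[mrs_var])
            except ValueError:
                continue
            family.append((eeg_var, mrs_var, res))
        stats.adjust_correlations([r for *_, r in family],
                                  m=config.correlation_m)
        for eeg_var, mrs_var, res in family:
            rows.append({"eeg_condition": eeg_cond, "mrs_condition": mrs_cond,
                         "eeg_var": eeg_var, "mrs_var": mrs_var, "r": res.r,
                         "p": res.p, "ci_low": res.ci95[0],
                         "ci_high": res.ci95[1], "p_adjusted": res.p_adjusted,
                         "n": res.n})
    return pd.DataFrame(rows)


def _quality_summary(mrs_outcomes: pd.DataFrame) -> pd.DataFrame:
    """Group-mean (SD) table of SNR/FWHM/fit error/CRLB per metabolite."""
    rows = []
    metrics = [c for c in mrs_outcomes.columns
               if c.startswith(("snr_", "fwhm_", "fit_error_", "crlb_"))]
    for (group,), sub in mrs_outcomes.groupby(["group"]):
        for col in metrics:
            vals = sub[col].dropna()
            rows.append({"group": group, "metric": col,
                         "mean": float(vals.mean()),
                         "sd": float(vals.std(ddof=1))})
    return pd.DataFrame(rows)


def make_report(results: dict) -> str:
    """Render the outcome tables as a human-readable summary."""
    if not results or "anova" not in results or results["anova"].empty:
        raise ValueError("no results to report")
    lines = ["neuroei pipeline report", "=" * 23, ""]
    eeg = results["eeg_outcomes"]
    lines.append(f"Subjects: {eeg['subject'].nunique()}  "
                 f"(EEG conditions: {sorted(eeg['condition'].unique())})")
    lines.append("")
    lines.append("Group x condition ANOVA")
    lines.append("-" * 23)
    for _, r in results["anova"].iterrows():
        if r["degenerate"]:
            lines.append(f"{r['outcome']:>16s} {r['effect']:<16s} degenerate")
        else:
            lines.append(
                f"{r['outcome']:>16s} {r['effect']:<16s} "
                f"F({r['df_num']:.0f},{r['df_den']:.0f}) = {r['F']:.10g}, "
                f"p = {r['p']:.10g}, eta_p^2 = {r['partial_eta_sq']:.10g}")
    lines.append("")
    lines.append("Exploratory EEG-MRS correlations (CC group, Bonferroni)")
    lines.append("-" * 55)
    for _, r in results["correlations"].iterrows():
        lines.append(
            f"{r['eeg_condition']:>3s} {r['eeg_var']:>9s} x "
            f"{r['mrs_var']:<15s} r = {r['r']:.10g} "
            f"[{r['ci_low']:.10g}, {r['ci_high']:.10g}], "
            f"p_adj = {r['p_adjusted']:.10g}")
    lines.append("")
    lines.append("Mean rejection percentage by group and condition")
    for _, r in results["rejection"].iterrows():
        lines.append(f"  {r['group']} {r['condition']}: "
                     f"{r['rejection_pct']:.10g}%")
    return "\n".join(lines) + "\n"
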