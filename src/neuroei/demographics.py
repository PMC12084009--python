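"""Bundled cohort demographics of the congenital cataract-reversal study.

Ten congenital cataract-reversal (CC) participants and ten age-matched
normally sighted controls (SC), with age (years), binocular logMAR acuity at
testing, duration of visual deprivation (age at first-eye surgery, years) and
time since surgery (years).  Surgery-related fields are CC-only and empty for
SC rows.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_RESOURCE = "cohort_demographics.csv"


def load_study_cohort() -> pd.DataFrame:
    """Load the bundled demographic table as a DataFrame."""
    with resources.files("neuroei.data").joinpath(_RESOURCE).open() as fh:
        df = pd.read_csv(fh)
    cc_only = df.loc[df.group == "SC",
                     ["deprivation_duration", "time_since_surgery"]]
    if cc_only.notna().any().any():
        raise ValueError("surgery fields must be absent for SC rows")
    return df
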