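"""Packaged reference datasets.

The cohort table ships the per-subject Fahn-Tolosa-Marin Tremor Rating Scale
summaries of the 24-person MS tremor cohort (two visits, five subjects
without a second dominant-arm assessment), transcribed from the published
cohort summary and verified against its printed column means, minima and
maxima.  A second file carries the summary statistics of the 15-subject
sub-cohort for which the scale2 metric could be computed.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .evaluation import CohortScores

__all__ = ["ftmtrs_cohort", "scale2_subcohort_summary"]


def _read(name: str) -> pd.DataFrame:
    with resources.files("tremorprofile.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, dtype={"subject_id": str})


def ftmtrs_cohort() -> CohortScores:
    """FTMTRS A/B/C per subject per visit for the 24-person cohort.

    Part A is the dominant-limb intention tremor item (0-4); Part B the sum
    of dominant-hand task scores; Part C the summed self-assessed impact on
    daily living (excluding speaking).  ``days_since_visit1`` is 0 on visit
    1 and the between-visit interval on visit 2.
    """
    return CohortScores(table=_read("ftmtrs_cohort.csv"))


def scale2_subcohort_summary() -> pd.DataFrame:
    """Summary statistics of the 15-subject sub-cohort with scale2 data."""
    return _read("scale2_subcohort_summary.csv")
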