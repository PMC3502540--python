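"""Packaged experimental fixtures and file helpers.

The package ships two small CSV fixtures transcribed from the in-vitro
AtT-20 experiments: a 22-h CRH/cortisol dose-response of supernatant
ACTH, and the FCS (with ELISA control) percent-change time courses for
the basal, 10 nM CRH, and 10 nM CRH + 100 nM cortisol arms. These are
measurements, not recomputable quantities; they serve as fitting data
for the feedback models and as reference points in tests.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = [
    "DoseResponseRecord",
    "TimeCourseRecord",
    "load_table1",
    "load_table2",
    "table2_fcs_frame",
]

_ARMS = ("basal", "crh", "crh_cortisol")


@dataclass(frozen=True)
class DoseResponseRecord:
    """One 22-h dose-response condition (doses, cell density, ACTH)."""

    crh_nM: float
    cortisol_nM: float
    cells_per_ml: float
    cells_per_ml_dev: float
    acth_nM: float
    acth_dev_nM: float

    def __post_init__(self) -> None:
        if self.crh_nM < 0 or self.cortisol_nM < 0:
            raise ValueError("doses must be >= 0")
        if self.acth_nM <= 0:
            raise ValueError("ACTH concentration must be > 0")


@dataclass(frozen=True)
class TimeCourseRecord:
    """One time point of the percent-change validation time course."""

    arm: str
    time_min: float
    fcs_pct: float
    fcs_dev: float
    elisa_pct_to_fcs: float
    elisa_dev: float

    def __post_init__(self) -> None:
        if self.arm not in _ARMS:
            raise ValueError(f"unknown arm {self.arm!r}")
        if self.time_min < 0:
            raise ValueError("time must be >= 0")
        if self.fcs_dev <= 0 or self.elisa_dev <= 0:
            raise ValueError("deviations must be > 0")


def _read_fixture(name: str) -> pd.DataFrame:
    with resources.files("fcshpa.data").joinpath(name).open("r", encoding="utf-8") as fh:
        text = fh.read()
    # normalize typographic minus signs that sneak into transcriptions
    text = unicodedata.normalize("NFKC", text).replace("−", "-")
    from io import StringIO

    return pd.read_csv(StringIO(text))


def load_table1() -> list[DoseResponseRecord]:
    """The seven 22-h dose-response records (ACTH in nM, mean +- t-deviation)."""
    df = _read_fixture("table1_dose_response.csv")
    return [DoseResponseRecord(**row) for row in df.to_dict("records")]


def load_table2() -> list[TimeCourseRecord]:
    """The sixteen percent-change time-course records across the three arms."""
    df = _read_fixture("table2_time_course.csv")
    return [TimeCourseRecord(**row) for row in df.to_dict("records")]


def table2_fcs_frame() -> pd.DataFrame:
    """FCS columns of the time course as a DataFrame (arm, time, pct, dev)."""
    df = _read_fixture("table2_time_course.csv")
    return df[["arm", "time_min", "fcs_pct", "fcs_dev"]].copy()
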