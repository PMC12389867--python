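"""Cohort table: per-subject, per-measure index values with group labels.

The long (tidy) shape mirrors the reference study's results table: one row
per (subject, measure) with a group label in {SZ, CNT}.  Measure keys are
flat strings: ``co_<r1>_<r2>`` (colocality at target/gaze ball radii in mm),
``dtheta_sample``, ``dtheta_regr``, and ``area_<ms>`` (polygon area in
normalized units at the window length in milliseconds).
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

__all__ = ["CohortTable", "load_table1_fixture", "load_printed_means"]

GROUPS = ("SZ", "CNT")

_COLUMNS = ["subject", "group", "measure", "value"]


class CohortTable:
    """Validated long-format table of per-subject index values."""

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"cohort table missing columns {missing}")
        df = df[_COLUMNS].copy()
        bad_groups = set(df["group"]) - set(GROUPS)
        if bad_groups:
            raise ValueError(f"unknown group labels {sorted(bad_groups)}")
        dup = df.duplicated(subset=["subject", "measure"])
        if dup.any():
            first = df[dup].iloc[0]
            raise ValueError(
                f"duplicate entry for subject {first['subject']!r}, "
                f"measure {first['measure']!r}"
            )
        if not np.all(np.isfinite(df["value"].to_numpy(float))):
            raise ValueError("values must be finite")
        self.df = df.reset_index(drop=True)

    @classmethod
    def from_wide(cls, wide: pd.DataFrame) -> "CohortTable":
        """Build from one row per subject with one column per measure."""
        long = wide.melt(
            id_vars=["subject", "group"], var_name="measure", value_name="value"
        )
        return cls(long)

    def to_wide(self) -> pd.DataFrame:
        wide = self.df.pivot(index=["subject", "group"], columns="measure", values="value")
        return wide.reset_index()

    @property
    def measures(self) -> list[str]:
        return sorted(self.df["measure"].unique())

    @property
    def subjects(self) -> list[str]:
        return list(dict.fromkeys(self.df["subject"]))

    def group_values(self, measure: str) -> tuple[np.ndarray, np.ndarray]:
        """Values of one measure as ``(sz, cnt)`` arrays, subject order kept."""
        sub = self.df[self.df["measure"] == measure]
        if sub.empty:
            raise KeyError(f"measure {measure!r} not in table")
        sz = sub[sub["group"] == "SZ"]["value"].to_numpy(float)
        cnt = sub[sub["group"] == "CNT"]["value"].to_numpy(float)
        if sz.size == 0 or cnt.size == 0:
            raise ValueError(f"measure {measure!r} missing one group")
        return sz, cnt

    def __len__(self) -> int:
        return len(self.df)

    def save_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def load_csv(cls, path) -> "CohortTable":
        return cls(pd.read_csv(path, comment="#"))


def load_table1_fixture() -> CohortTable:
    """The packaged reference cohort: per-subject values for 9 SZ + 9 CNT."""
    ref = resources.files("spemlab").joinpath("data/table1_fixture.csv")
    with ref.open("r") as fh:
        wide = pd.read_csv(fh, comment="#")
    return CohortTable.from_wide(wide)


def load_printed_means() -> pd.DataFrame:
    """Printed group-mean rows and significance flags of the reference table.

    Columns: measure, sz_mean, cnt_mean, significant (0/1), and
    known_discrepancy naming the group (SZ/CNT, else NaN) whose printed mean
    is a rounding artifact relative to the printed per-subject values.
    """
    ref = resources.files("spemlab").joinpath("data/table1_printed_means.csv")
    with ref.open("r") as fh:
        return pd.read_csv(fh, comment="#")
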