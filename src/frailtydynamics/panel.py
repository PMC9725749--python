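"""The universal input container: a longitudinal panel of binary health deficits.

A :class:`DeficitPanel` holds, in long format, the observed state of ``N``
binarized health deficits per subject per visit, subject-level covariates
(sex, treatment/intervention group, baseline age, optionally household
wealth), and optional death/censoring times. The Frailty Index (FI) at a
visit is the fraction of deficits present, ``f = n / N``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["DeficitPanel", "PanelError"]

OBS_COLUMNS = ["subject_id", "time", "deficit_id", "value"]


class PanelError(ValueError):
    pass


@dataclass
class DeficitPanel:
    """Long-format deficit observations plus subject covariates.

    Parameters
    ----------
    observations : DataFrame
        Columns ``subject_id, time, deficit_id, value``. Values are binary
        {0, 1}, fractional on the quarter grid before binary expansion, or
        NaN for missing.
    covariates : DataFrame
        Indexed by ``subject_id``; typically columns ``sex`` (0/1),
        ``treatment`` (0/1), ``baseline_age`` and optionally ``wealth``.
    survival : DataFrame, optional
        Indexed by ``subject_id`` with columns ``death_time`` and
        ``censored`` (1 = right-censored at ``death_time``).
    time_unit : str
        "months" (mice) or "years" (humans); rates are per this unit.
    """

    observations: pd.DataFrame
    covariates: pd.DataFrame
    survival: Optional[pd.DataFrame] = None
    time_unit: str = "months"

    def __post_init__(self):
        missing = [c for c in OBS_COLUMNS if c not in self.observations.columns]
        if missing:
            raise PanelError(f"observations missing columns {missing}")
        self.observations = self.observations.sort_values(
            ["subject_id", "time", "deficit_id"], kind="stable"
        ).reset_index(drop=True)
        if not self.covariates.index.name == "subject_id":
            if "subject_id" in self.covariates.columns:
                self.covariates = self.covariates.set_index("subject_id")
        if self.survival is not None and self.survival.index.name != "subject_id":
            if "subject_id" in self.survival.columns:
                self.survival = self.survival.set_index("subject_id")

    # ------------------------------------------------------------------ views

    @property
    def n_items(self) -> int:
        """Number N of deficits in the index (fixed within a dataset)."""
        return self.observations["deficit_id"].nunique()

    @property
    def subjects(self) -> np.ndarray:
        return self.observations["subject_id"].unique()

    def is_binary(self) -> bool:
        v = self.observations["value"].dropna()
        return bool(v.isin([0.0, 1.0]).all())

    def wide(self) -> pd.DataFrame:
        """(subject, time) x deficit matrix of states."""
        return self.observations.pivot(
            index=["subject_id", "time"], columns="deficit_id", values="value"
        )

    def visit_times(self) -> pd.Series:
        """Sorted unique visit times per subject (groupby subject)."""
        return (
            self.observations.groupby("subject_id")["time"]
            .unique()
            .apply(np.sort)
        )

    def fi(self) -> pd.DataFrame:
        """Frailty index per subject-visit: columns subject_id, time, n, fi."""
        g = self.observations.groupby(["subject_id", "time"])["value"]
        out = g.agg(n="sum", items="count").reset_index()
        out["fi"] = out["n"] / out["items"]
        return out

    def validate(self) -> None:
        """Raise on invariant violations (non-increasing times, bad values)."""
        for sid, times in self.visit_times().items():
            if np.any(np.diff(times) <= 0):
                raise PanelError(f"subject {sid}: visit times not strictly increasing")
        v = self.observations["value"].dropna()
        if ((v < 0) | (v > 1)).any():
            raise PanelError("deficit values outside [0, 1]")

    # ------------------------------------------------------------------- I/O

    def write_csv(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.observations.to_csv(directory / "observations.csv", index=False)
        self.covariates.to_csv(directory / "covariates.csv")
        if self.survival is not None:
            self.survival.to_csv(directory / "survival.csv")

    @classmethod
    def read_csv(cls, directory, time_unit: str = "months") -> "DeficitPanel":
        directory = Path(directory)
        obs = pd.read_csv(directory / "observations.csv")
        cov = pd.read_csv(directory / "covariates.csv", index_col="subject_id")
        surv_path = directory / "survival.csv"
        surv = (
            pd.read_csv(surv_path, index_col="subject_id")
            if surv_path.exists()
            else None
        )
        return cls(obs, cov, surv, time_unit=time_unit)

    def copy(self) -> "DeficitPanel":
        return DeficitPanel(
            self.observations.copy(),
            self.covariates.copy(),
            None if self.survival is None else self.survival.copy(),
            time_unit=self.time_unit,
        )
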