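"""Covariate designs for the damage/repair rate models.

The mouse longitudinal design is
``x_i(t) = (1, t, sex, treatment, f, a0, sex*treatment, sex*t, treatment*t,
sex*treatment*t)`` and the survival design
``u_i = (1, sex, treatment, sex*treatment, f, a0)``; the human design is
``x_i(t) = (1, t, sex, w, f, a0, sex*t, w*t, a0*t, sex*f, w*f, a0*f)``.
All covariates are standardized to mean 0, SD 1 over the fitting data
before interactions are formed, so the shared N(0,1) coefficient priors act
on a common scale. The raw (unstandardized) builders are used by the
synthetic-cohort generator; :func:`map_coefficients` converts coefficient
vectors between the two bases (they span the same column space), which is
how recovery tests compare fitted and generating effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "mouse_raw_design",
    "mouse_raw_survival_design",
    "human_raw_design",
    "Standardizer",
    "MouseDesign",
    "map_coefficients",
    "MOUSE_X_NAMES",
    "MOUSE_U_NAMES",
    "HUMAN_X_NAMES",
]

MOUSE_X_NAMES = [
    "intercept", "time", "sex", "treatment", "fi", "baseline_age",
    "sex:treatment", "sex:time", "treatment:time", "sex:treatment:time",
]
MOUSE_U_NAMES = ["intercept", "sex", "treatment", "sex:treatment", "fi", "baseline_age"]
HUMAN_X_NAMES = [
    "intercept", "time", "sex", "wealth", "fi", "baseline_age",
    "sex:time", "wealth:time", "baseline_age:time",
    "sex:fi", "wealth:fi", "baseline_age:fi",
]


def mouse_raw_design(t, sex, treatment, f, a0) -> np.ndarray:
    """Raw-covariate mouse longitudinal design matrix (columns MOUSE_X_NAMES)."""
    t, sex, treatment, f, a0 = np.broadcast_arrays(
        *[np.asarray(v, dtype=float) for v in (t, sex, treatment, f, a0)]
    )
    one = np.ones_like(t)
    return np.column_stack([
        one, t, sex, treatment, f, a0,
        sex * treatment, sex * t, treatment * t, sex * treatment * t,
    ])


def mouse_raw_survival_design(sex, treatment, f, a0) -> np.ndarray:
    sex, treatment, f, a0 = np.broadcast_arrays(
        *[np.asarray(v, dtype=float) for v in (sex, treatment, f, a0)]
    )
    one = np.ones_like(sex)
    return np.column_stack([one, sex, treatment, sex * treatment, f, a0])


def human_raw_design(t, sex, w, f, a0) -> np.ndarray:
    t, sex, w, f, a0 = np.broadcast_arrays(
        *[np.asarray(v, dtype=float) for v in (t, sex, w, f, a0)]
    )
    one = np.ones_like(t)
    return np.column_stack([
        one, t, sex, w, f, a0,
        sex * t, w * t, a0 * t, sex * f, w * f, a0 * f,
    ])


@dataclass
class Standardizer:
    """Per-covariate centering/scaling constants (zero-SD columns get scale 1)."""

    means: dict
    sds: dict

    @classmethod
    def fit(cls, frame: pd.DataFrame, columns) -> "Standardizer":
        means, sds = {}, {}
        for c in columns:
            v = frame[c].to_numpy(dtype=float)
            means[c] = float(v.mean())
            s = float(v.std(ddof=0))
            sds[c] = s if s > 0 else 1.0
        return cls(means, sds)

    def transform(self, frame: pd.DataFrame, column: str) -> np.ndarray:
        v = frame[column].to_numpy(dtype=float)
        return (v - self.means[column]) / self.sds[column]


def _standardized_design(frame, base_cols, builder, std: Standardizer) -> np.ndarray:
    z = {c: std.transform(frame, c) for c in base_cols}
    return builder(z)


@dataclass
class MouseDesign:
    """Standardized mouse designs built from transition-count rows.

    ``X``: longitudinal design (rows = subject-intervals); ``U``: survival
    covariate design at the same rows (hazard covariates held at interval
    start); ``t_raw``: unstandardized time-from-baseline for the subject
    random slopes; ``subject_index``: integer subject per row.
    """

    X: np.ndarray
    U: np.ndarray
    t_raw: np.ndarray
    subject_index: np.ndarray
    subject_ids: np.ndarray
    standardizer: Standardizer
    x_names: list = field(default_factory=lambda: list(MOUSE_X_NAMES))
    u_names: list = field(default_factory=lambda: list(MOUSE_U_NAMES))

    @classmethod
    def from_counts(cls, counts_data: pd.DataFrame, n_items: int) -> "MouseDesign":
        d = counts_data.copy()
        d["fi"] = d["n"] / n_items
        base = ["time", "sex", "treatment", "fi", "baseline_age"]
        std = Standardizer.fit(d, base)
        z = {c: std.transform(d, c) for c in base}
        one = np.ones(len(d))
        X = np.column_stack([
            one, z["time"], z["sex"], z["treatment"], z["fi"], z["baseline_age"],
            z["sex"] * z["treatment"], z["sex"] * z["time"],
            z["treatment"] * z["time"], z["sex"] * z["treatment"] * z["time"],
        ])
        U = np.column_stack([
            one, z["sex"], z["treatment"], z["sex"] * z["treatment"],
            z["fi"], z["baseline_age"],
        ])
        ids, sidx = np.unique(d["subject_id"].to_numpy(), return_inverse=True)
        return cls(
            X=X, U=U,
            t_raw=d["time"].to_numpy(dtype=float),
            subject_index=sidx, subject_ids=ids, standardizer=std,
        )

    def standardized_x_row(self, t, sex, treatment, f, a0) -> np.ndarray:
        """Design row(s) for arbitrary covariate values on the fitted scale."""
        frame = pd.DataFrame({
            "time": np.atleast_1d(t).astype(float),
            "sex": sex, "treatment": treatment, "fi": f, "baseline_age": a0,
        })
        std = self.standardizer
        z = {c: std.transform(frame, c) for c in ["time", "sex", "treatment", "fi", "baseline_age"]}
        one = np.ones(len(frame))
        return np.column_stack([
            one, z["time"], z["sex"], z["treatment"], z["fi"], z["baseline_age"],
            z["sex"] * z["treatment"], z["sex"] * z["time"],
            z["treatment"] * z["time"], z["sex"] * z["treatment"] * z["time"],
        ])


def map_coefficients(beta_from: np.ndarray, X_from: np.ndarray, X_to: np.ndarray) -> np.ndarray:
    """Re-express a coefficient vector in another design basis.

    Solves ``X_to b = X_from beta_from`` by least squares; exact whenever
    the two designs span the same column space (raw vs standardized bases
    of the same covariates).
    """
    eta = X_from @ beta_from
    b, *_ = np.linalg.lstsq(X_to, eta, rcond=None)
    return b
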