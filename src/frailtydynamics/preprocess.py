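"""Data-cleaning rules for mouse and human deficit panels.

Mice: last-observation-carried-forward imputation, expansion of fractional
deficit scores into ordered binary items, removal of abnormally short/long
inter-visit gaps, and removal of subjects with fewer than two visits.
Humans (ELSA-style): baseline-age window, follow-up count and gap filters,
and the log transform of net household wealth. A sensitivity-analysis
pruning flattens isolated single-visit state excursions that are likely
measurement errors.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .panel import DeficitPanel, PanelError

__all__ = [
    "impute_locf",
    "encode_fractional",
    "expand_fractional_panel",
    "filter_visits",
    "elsa_select",
    "prune_isolated_transitions",
]

QUARTER_GRID = np.array([0.0, 0.25, 0.5, 0.75, 1.0])


class ImputationError(ValueError):
    pass


class EncodingError(ValueError):
    pass


def impute_locf(panel: DeficitPanel) -> DeficitPanel:
    """Fill missing deficit values forward, then leading gaps backward.

    Every subject-deficit series must contain at least one observed value;
    otherwise an :class:`ImputationError` names the offending series.
    """
    out = panel.copy()
    obs = out.observations
    fully_missing = (
        obs.groupby(["subject_id", "deficit_id"])["value"]
        .apply(lambda s: s.isna().all())
    )
    if fully_missing.any():
        sid, did = fully_missing[fully_missing].index[0]
        raise ImputationError(
            f"subject {sid}, deficit {did}: series fully missing, cannot impute"
        )
    obs["value"] = (
        obs.groupby(["subject_id", "deficit_id"], group_keys=False)["value"]
        .apply(lambda s: s.ffill().bfill())
    )
    return out


def encode_fractional(value: float) -> np.ndarray:
    """Expand one fractional deficit score into 4 ordered binary deficits.

    A score ``d`` on the quarter grid {0, 0.25, 0.5, 0.75, 1} becomes a
    4-vector with the first ``4 d`` bits set: e.g. 0.75 -> [1, 1, 1, 0].
    """
    if not np.isclose(value, QUARTER_GRID, atol=1e-9).any():
        raise EncodingError(f"value {value!r} not on the quarter grid")
    k = int(round(4 * value))
    bits = np.zeros(4, dtype=float)
    bits[:k] = 1.0
    return bits


def expand_fractional_panel(panel: DeficitPanel) -> DeficitPanel:
    """Apply :func:`encode_fractional` panel-wide.

    An N-item fractional panel becomes a 4N-item binary panel; every FI
    value is preserved exactly since mean(bits) == fractional score.
    """
    out = panel.copy()
    obs = out.observations
    vals = obs["value"].to_numpy(dtype=float)
    offgrid = ~np.isclose(vals[:, None], QUARTER_GRID[None, :], atol=1e-9).any(axis=1)
    if offgrid.any():
        raise EncodingError(
            f"{offgrid.sum()} values not on the quarter grid (first: "
            f"{vals[offgrid][0]!r})"
        )
    k = np.rint(4 * vals).astype(int)
    rows = obs.loc[obs.index.repeat(4)].reset_index(drop=True)
    bit_pos = np.tile(np.arange(1, 5), len(obs))
    rows["deficit_id"] = rows["deficit_id"].astype(str) + "_b" + bit_pos.astype(str)
    rows["value"] = (bit_pos <= np.repeat(k, 4)).astype(float)
    out.observations = rows
    return out


def filter_visits(
    panel: DeficitPanel,
    min_gap: float | None = None,
    max_gap: float | None = None,
    min_visits: int = 2,
) -> DeficitPanel:
    """Remove visits with abnormal gaps, then under-observed subjects.

    A visit is dropped when its gap to the previous *retained* visit is
    below ``min_gap`` or above ``max_gap`` (either threshold may be None).
    Subjects left with fewer than ``min_visits`` visits are removed.
    """
    out = panel.copy()
    keep_frames = []
    for sid, times in out.visit_times().items():
        kept = [times[0]]
        for t in times[1:]:
            gap = t - kept[-1]
            if min_gap is not None and gap < min_gap:
                continue
            if max_gap is not None and gap > max_gap:
                continue
            kept.append(t)
        if len(kept) >= min_visits:
            keep_frames.append(
                pd.DataFrame({"subject_id": sid, "time": kept})
            )
    if not keep_frames:
        warnings.warn("all subjects removed by visit filtering", stacklevel=2)
        out.observations = out.observations.iloc[0:0]
        return out
    keep = pd.concat(keep_frames, ignore_index=True)
    out.observations = out.observations.merge(keep, on=["subject_id", "time"])
    kept_subjects = keep["subject_id"].unique()
    out.covariates = out.covariates.loc[
        out.covariates.index.intersection(kept_subjects)
    ]
    if out.survival is not None:
        out.survival = out.survival.loc[
            out.survival.index.intersection(kept_subjects)
        ]
    return out


def elsa_select(
    panel: DeficitPanel,
    age_range: tuple[float, float] = (50.0, 89.0),
    max_gap: float = 4.0,
    min_followups: int = 6,
) -> DeficitPanel:
    """Cohort selection and wealth transform for ELSA-style human panels.

    Drops subjects with baseline age outside ``age_range``, any inter-visit
    gap above ``max_gap`` years, fewer than ``min_followups`` observation
    waves, or imputed wealth (``wealth_imputed`` flag truthy). Wealth is
    then transformed as ``w = log(w_raw + mean(w_raw))`` with the mean over
    retained subjects.
    """
    if "wealth" not in panel.covariates.columns:
        raise PanelError("elsa_select requires a 'wealth' covariate column")
    out = panel.copy()
    cov = out.covariates
    keep = cov["baseline_age"].between(age_range[0], age_range[1])
    if "wealth_imputed" in cov.columns:
        keep &= ~cov["wealth_imputed"].astype(bool)
    vt = out.visit_times()
    enough = vt.apply(len) >= min_followups
    gaps_ok = vt.apply(lambda t: len(t) < 2 or np.max(np.diff(t)) <= max_gap)
    keep &= keep.index.map(enough.reindex(keep.index, fill_value=False))
    keep &= keep.index.map(gaps_ok.reindex(keep.index, fill_value=False))
    kept_ids = keep[keep].index
    out.covariates = cov.loc[kept_ids].copy()
    out.observations = out.observations[
        out.observations["subject_id"].isin(kept_ids)
    ].reset_index(drop=True)
    if out.survival is not None:
        out.survival = out.survival.loc[out.survival.index.intersection(kept_ids)]
    w_raw = out.covariates["wealth"].to_numpy(dtype=float)
    if len(w_raw):
        out.covariates["wealth"] = np.log(w_raw + w_raw.mean())
    return out


def prune_isolated_transitions(panel: DeficitPanel) -> DeficitPanel:
    """Flatten single-visit excursions flanked by >= 2 opposite-state visits.

    Exactly the patterns ``x,x,!x,x,x -> x,x,x,x,x`` (putative measurement
    errors); excursions with fewer than two flanking visits on either side
    are untouched. Idempotent, and never increases the transition count.
    """
    if not panel.is_binary():
        raise PanelError("pruning requires a binary panel")
    out = panel.copy()

    def _prune(series: pd.Series) -> pd.Series:
        v = series.to_numpy(dtype=float).copy()
        for i in range(2, len(v) - 2):
            window = v[i - 2 : i + 3]
            x = window[0]
            if (
                window[1] == x
                and window[2] == 1 - x
                and window[3] == x
                and window[4] == x
            ):
                v[i] = x
        return pd.Series(v, index=series.index)

    out.observations["value"] = (
        out.observations.groupby(["subject_id", "deficit_id"], group_keys=False)[
            "value"
        ].apply(_prune)
    )
    return out
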