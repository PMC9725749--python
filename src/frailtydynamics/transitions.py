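"""Damage/repair transition counts and nonparametric binned rate estimates.

Per subject-interval ``[t_j, t_{j+1})`` we count deficits damaged
(``0 -> 1`` transitions, ``n_d``) and repaired (``1 -> 0``, ``n_r``); the
deficit count obeys the conservation identity
``n(t_{j+1}) = n(t_j) + n_d(t_j) - n_r(t_j)`` exactly. Counts are
attributed to the interval start. Binned averages of the normalized
per-interval rates (with standard errors) are the model-free view of how
repair and damage rates change with age.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import DeficitPanel, PanelError

__all__ = ["TransitionCounts", "count_transitions", "binned_rates"]


@dataclass
class TransitionCounts:
    """Tidy per-subject-interval transition counts.

    ``data`` columns: subject_id, time (interval start t_j), dt, n (deficits
    present at t_j), n_damage, n_repair, n_next, plus subject covariates.
    ``n_items`` is the panel-wide item count N.
    """

    data: pd.DataFrame
    n_items: int
    time_unit: str = "months"

    def validate(self) -> None:
        d = self.data
        if (d["dt"] <= 0).any():
            raise PanelError("non-positive interval length")
        if ((d["n_repair"] > d["n"]) | (d["n_damage"] > self.n_items - d["n"])).any():
            raise PanelError("transition count exceeds available items")
        if not np.array_equal(
            d["n_next"].to_numpy(), (d["n"] + d["n_damage"] - d["n_repair"]).to_numpy()
        ):
            raise PanelError("conservation identity violated")

    def write_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def count_transitions(panel: DeficitPanel) -> TransitionCounts:
    """Extract per-interval damage/repair counts from a binary panel."""
    if not panel.is_binary():
        raise PanelError("count_transitions requires a binary panel")
    wide = panel.wide()
    n_items = wide.shape[1]
    rows = []
    for sid, block in wide.groupby(level="subject_id", sort=False):
        mat = block.to_numpy(dtype=float)
        times = block.index.get_level_values("time").to_numpy(dtype=float)
        if len(times) < 2:
            continue
        cur, nxt = mat[:-1], mat[1:]
        n_damage = ((cur == 0) & (nxt == 1)).sum(axis=1)
        n_repair = ((cur == 1) & (nxt == 0)).sum(axis=1)
        n = cur.sum(axis=1).astype(int)
        rows.append(
            pd.DataFrame(
                {
                    "subject_id": sid,
                    "time": times[:-1],
                    "dt": np.diff(times),
                    "n": n,
                    "n_damage": n_damage.astype(int),
                    "n_repair": n_repair.astype(int),
                    "n_next": nxt.sum(axis=1).astype(int),
                }
            )
        )
    data = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(
            columns=["subject_id", "time", "dt", "n", "n_damage", "n_repair", "n_next"]
        )
    )
    data = data.join(panel.covariates, on="subject_id")
    counts = TransitionCounts(data, n_items=n_items, time_unit=panel.time_unit)
    counts.validate()
    return counts


def binned_rates(
    counts: TransitionCounts,
    bin_edges,
    age_column: str = "age",
) -> pd.DataFrame:
    """Binned mean normalized rates with standard errors (left-closed bins).

    The per-interval repair rate is ``n_r / (n dt)`` (intervals with no
    damaged items excluded), the damage rate ``n_d / ((N - n) dt)``
    (intervals with all items damaged excluded). Rates are averaged
    unweighted within each age bin; the standard error is sample SD /
    sqrt(m). Empty bins are omitted with a warning.

    ``age_column``: column of ``counts.data`` giving the age at interval
    start ("time" for time-from-baseline binning; add baseline age upstream
    for chronological-age binning).
    """
    d = counts.data
    if age_column not in d.columns:
        if age_column == "age" and "baseline_age" in d.columns:
            d = d.assign(age=d["time"] + d["baseline_age"])
        else:
            raise PanelError(f"no column {age_column!r} for binning")
    edges = np.asarray(bin_edges, dtype=float)
    N = counts.n_items
    out = []
    ages = d[age_column].to_numpy(dtype=float)
    idx = np.digitize(ages, edges, right=False) - 1
    for b in range(len(edges) - 1):
        sel = d[idx == b]
        if sel.empty:
            warnings.warn(f"empty age bin [{edges[b]}, {edges[b+1]})", stacklevel=2)
            continue
        row = {"bin_left": edges[b], "bin_right": edges[b + 1]}
        rep = sel[sel["n"] > 0]
        if len(rep):
            r = rep["n_repair"] / (rep["n"] * rep["dt"])
            row.update(
                repair_rate=r.mean(),
                repair_se=r.std(ddof=1) / np.sqrt(len(r)) if len(r) > 1 else np.nan,
                repair_m=len(r),
            )
        dam = sel[sel["n"] < N]
        if len(dam):
            dr = dam["n_damage"] / ((N - dam["n"]) * dam["dt"])
            row.update(
                damage_rate=dr.mean(),
                damage_se=dr.std(ddof=1) / np.sqrt(len(dr)) if len(dr) > 1 else np.nan,
                damage_m=len(dr),
            )
        out.append(row)
    return pd.DataFrame(out)
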