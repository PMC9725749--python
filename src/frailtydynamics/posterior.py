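"""Labeled posterior draws shared by all model Results objects."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PosteriorDraws"]


def _diag(arr2d):
    """R-hat and bulk ESS for one (chain, draw) array."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import arviz as az

        return float(az.rhat(arr2d)), float(az.ess(arr2d))


@dataclass
class PosteriorDraws:
    """Posterior samples keyed by parameter name.

    Each value has shape ``(n_chains, n_draws, *param_shape)``. Scalar and
    vector parameters get per-component rows in :meth:`summary`.
    """

    draws: dict
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    def flat(self, name: str) -> np.ndarray:
        """Draws pooled over chains, shape (n_chains * n_draws, *shape)."""
        a = self.draws[name]
        return a.reshape(a.shape[0] * a.shape[1], *a.shape[2:])

    def component_names(self, names=None):
        names = list(self.draws) if names is None else names
        out = []
        for name in names:
            shape = self.draws[name].shape[2:]
            if shape == ():
                out.append((name, ()))
            else:
                for idx in np.ndindex(*shape):
                    out.append((name, idx))
        return out

    def summary(self, names=None, diagnostics: bool = True) -> pd.DataFrame:
        """Mean/SD/quantiles (and R-hat, ESS) per scalar component."""
        rows = []
        for name, idx in self.component_names(names):
            a = self.draws[name]
            comp = a[(slice(None), slice(None)) + idx]
            flat = comp.reshape(-1)
            label = name if idx == () else f"{name}[{','.join(map(str, idx))}]"
            row = {
                "parameter": label,
                "mean": flat.mean(),
                "sd": flat.std(ddof=1),
                "q2.5": np.quantile(flat, 0.025),
                "median": np.quantile(flat, 0.5),
                "q97.5": np.quantile(flat, 0.975),
            }
            if diagnostics:
                row["rhat"], row["ess"] = _diag(comp)
            rows.append(row)
        return pd.DataFrame(rows)

    def max_rhat(self, names) -> float:
        worst = 0.0
        for name, idx in self.component_names(names):
            a = self.draws[name]
            comp = a[(slice(None), slice(None)) + idx]
            r, _ = _diag(comp)
            if np.isfinite(r):
                worst = max(worst, r)
        return worst

    def to_tidy(self, names=None) -> pd.DataFrame:
        """Long format (chain, draw, parameter, value) for CSV export."""
        rows = []
        for name, idx in self.component_names(names):
            a = self.draws[name]
            comp = a[(slice(None), slice(None)) + idx]
            label = name if idx == () else f"{name}[{','.join(map(str, idx))}]"
            nc, nd = comp.shape
            rows.append(pd.DataFrame({
                "chain": np.repeat(np.arange(nc), nd),
                "draw": np.tile(np.arange(nd), nc),
                "parameter": label,
                "value": comp.reshape(-1),
            }))
        return pd.concat(rows, ignore_index=True)
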