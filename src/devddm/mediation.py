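"""Moderated mediation in which every path is moderated ("model 59").

Two OLS equations on standardized variables:

    M ~ a1*X + a2*W + a3*X*W
    Y ~ c1'*X + c2'*W + c3'*X*W + b1*M + b2*M*W

The conditional indirect effect of X on Y through M at moderator value w is
``omega(w) = (a1 + a3*w) * (b1 + b2*w)`` and the conditional direct effect is
``c1' + c3'*w``.  Significance is judged from case-bootstrap percentile CIs
of omega at w = mean and +/-1 SD (90% intervals by convention here): an
effect is called significant when its interval excludes zero.  Percentile
(not bias-corrected) intervals are used deliberately — they are exactly
reproducible without acceleration constants, at the cost of a small
divergence from macro implementations that default to BCa.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "MediationPaths",
    "Model59Mediation",
    "fit_model59",
    "conditional_indirect",
    "mediation_bootstrap",
]


@dataclass(frozen=True)
class MediationPaths:
    """Path coefficients of the two model-59 equations."""

    a1: float  # X -> M
    a2: float  # W -> M
    a3: float  # X*W -> M
    b1: float  # M -> Y
    b2: float  # M*W -> Y
    c1p: float  # X -> Y (direct)
    c2p: float  # W -> Y
    c3p: float  # X*W -> Y
    i_m: float = 0.0
    i_y: float = 0.0
    sigma_m: float = np.nan
    sigma_y: float = np.nan

    def indirect(self, w: float) -> float:
        return (self.a1 + self.a3 * w) * (self.b1 + self.b2 * w)

    def direct(self, w: float) -> float:
        return self.c1p + self.c3p * w


def conditional_indirect(paths: MediationPaths, w: float) -> float:
    """``(a1 + a3*w) * (b1 + b2*w)`` at moderator value ``w`` (z scale)."""
    return paths.indirect(w)


def _solve_paths(x, w, m, y) -> MediationPaths:
    n = x.size
    Xm = np.column_stack([np.ones(n), x, w, x * w])
    bm = np.linalg.solve(Xm.T @ Xm, Xm.T @ m)
    Xy = np.column_stack([np.ones(n), x, w, x * w, m, m * w])
    by = np.linalg.solve(Xy.T @ Xy, Xy.T @ y)
    rm = m - Xm @ bm
    ry = y - Xy @ by
    return MediationPaths(
        a1=bm[1], a2=bm[2], a3=bm[3],
        b1=by[4], b2=by[5], c1p=by[1], c2p=by[2], c3p=by[3],
        i_m=bm[0], i_y=by[0],
        sigma_m=float(rm.std(ddof=1)), sigma_y=float(ry.std(ddof=1)),
    )


class Model59Mediation(BaseEstimator):
    """Moderated mediation estimator (all three paths moderated).

    Parameters
    ----------
    x, m, y, w : str
        Column names of the independent variable, mediator, outcome and
        moderator.
    standardize : bool
        z-score all four variables on the listwise-complete analysis sample
        before fitting (default); products are formed after z-scoring, so the
        +/-1 SD moderator levels are simply w = +/-1.

    Attributes
    ----------
    paths_ : MediationPaths
    n_used_ : int
    used_index_ : pd.Index
    """

    def __init__(self, x: str, m: str, y: str, w: str, standardize: bool = True):
        self.x = x
        self.m = m
        self.y = y
        self.w = w
        self.standardize = standardize

    def _prepare(self, table: pd.DataFrame) -> pd.DataFrame:
        cols = [self.x, self.w, self.m, self.y]
        missing = [c for c in cols if c not in table.columns]
        if missing:
            raise ValueError(f"missing column(s): {missing}")
        return table[cols].dropna()

    @staticmethod
    def _zscore(arr: np.ndarray) -> np.ndarray:
        sd = arr.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("zero variance in a mediation variable")
        return (arr - arr.mean(axis=0)) / sd

    def fit(self, table: pd.DataFrame, y=None):
        data = self._prepare(table)
        arr = data.to_numpy(dtype=float)
        if self.standardize:
            arr = self._zscore(arr)
        self.paths_ = _solve_paths(arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3])
        self.n_used_ = len(data)
        self.used_index_ = data.index
        return self

    def conditional_indirect(self, w: float) -> float:
        return self.paths_.indirect(w)

    def conditional_direct(self, w: float) -> float:
        return self.paths_.direct(w)

    def bootstrap(
        self,
        table: pd.DataFrame,
        B: int = 5000,
        level: float = 90.0,
        seed: int | np.random.Generator | None = None,
        w_levels: tuple[float, ...] = (-1.0, 0.0, 1.0),
    ) -> pd.DataFrame:
        """Case-bootstrap percentile CIs of the conditional indirect effects.

        Both equations are refitted per resample (with re-standardization);
        omega(w) is computed per resample and percentiled at ``level`` %.
        Returns one row per moderator level with the point estimate, CI,
        conditional direct effect and a ``significant`` flag (CI excludes 0).
        """
        if B < 100:
            warnings.warn(f"B={B} is very small for percentile intervals",
                          stacklevel=2)
        rng = (seed if isinstance(seed, np.random.Generator)
               else np.random.default_rng(seed))
        if not hasattr(self, "paths_"):
            self.fit(table)
        raw = self._prepare(table).to_numpy(dtype=float)
        n = raw.shape[0]
        levels_arr = np.asarray(w_levels, dtype=float)
        omegas = np.empty((B, levels_arr.size))
        for b in range(B):
            for _attempt in range(100):
                idx = rng.integers(0, n, n)
                sub = raw[idx]
                if np.all(sub.std(axis=0, ddof=1) > 0):
                    break
            else:
                raise RuntimeError("could not draw a non-degenerate resample")
            if self.standardize:
                sub = self._zscore(sub)
            p = _solve_paths(sub[:, 0], sub[:, 1], sub[:, 2], sub[:, 3])
            omegas[b] = (p.a1 + p.a3 * levels_arr) * (p.b1 + p.b2 * levels_arr)
        alpha = (100.0 - level) / 2.0
        lo = np.percentile(omegas, alpha, axis=0)
        hi = np.percentile(omegas, 100.0 - alpha, axis=0)
        rows = []
        for j, wl in enumerate(levels_arr):
            rows.append(
                {
                    "w_level": wl,
                    "indirect": self.paths_.indirect(wl),
                    "ci_low": lo[j],
                    "ci_high": hi[j],
                    "direct": self.paths_.direct(wl),
                    "significant": (lo[j] > 0) or (hi[j] < 0),
                    "n_used": self.n_used_,
                    "B": B,
                    "level": level,
                }
            )
        return pd.DataFrame(rows)


def fit_model59(
    table: pd.DataFrame, x: str, m: str, y: str, w: str, standardize: bool = True
) -> Model59Mediation:
    """Fit model 59 and return the estimator (paths in ``paths_``)."""
    return Model59Mediation(x=x, m=m, y=y, w=w, standardize=standardize).fit(table)


def mediation_bootstrap(
    table: pd.DataFrame,
    x: str,
    m: str,
    y: str,
    w: str,
    B: int = 5000,
    level: float = 90.0,
    seed: int | np.random.Generator | None = None,
    w_levels: tuple[float, ...] = (-1.0, 0.0, 1.0),
) -> pd.DataFrame:
    """Fit model 59 and bootstrap its conditional indirect effects."""
    est = fit_model59(table, x=x, m=m, y=y, w=w)
    return est.bootstrap(table, B=B, level=level, seed=seed, w_levels=w_levels)
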