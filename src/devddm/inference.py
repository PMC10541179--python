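"""Moderated multiple regression with case-bootstrap inference and BH-FDR.

The analysis convention throughout: continuous dependent and predictor
variables are z-scored on the model's analysis sample (after listwise
deletion and any exclusions), interaction terms are products of the z-scored
components (not z-scored products), coefficients are therefore standardized
betas.  Inference is by case bootstrap (resampling participant rows with
replacement, re-standardizing and refitting per draw) with percentile
confidence intervals and a two-sided sign-crossing bootstrap p-value; the
enumerated hypothesis families are corrected with Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AGE_BANDS",
    "age_band",
    "screen_outliers",
    "standardize",
    "ModeratedRegression",
    "BootstrapResult",
    "bootstrap_inference",
    "exclude_by_residuals",
    "build_family",
    "main_family_factors",
    "supplementary_family_factors",
    "fdr_adjust",
    "probe_interaction",
    "plot_interaction",
]

#: The five developmental bands, used only for the 3-SD outlier screen;
#: age itself enters every model as a continuous variable.
AGE_BANDS = ("6-7", "10-11", "14-15", "16-17", "18+")


def age_band(age: float) -> str:
    """Assign an age in years to its developmental band."""
    if age < 9:
        return "6-7"
    if age < 13:
        return "10-11"
    if age < 16:
        return "14-15"
    if age < 18:
        return "16-17"
    return "18+"


def screen_outliers(
    table: pd.DataFrame,
    variables: list[str],
    group_col: str = "age_band",
    sd_mult: float = 3.0,
    min_group: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-variable, per-age-group 3-SD screen.

    Values with |z| > ``sd_mult`` within their group are set to NaN (the
    participant's other variables survive).  Groups smaller than ``min_group``
    are skipped with a warning.  Returns the screened table and a log of
    removals.
    """
    out = table.copy()
    log_rows = []
    for group, grp in table.groupby(group_col):
        if len(grp) < min_group:
            warnings.warn(
                f"group {group!r} has {len(grp)} members (< {min_group}); "
                "outlier screening skipped",
                stacklevel=2,
            )
            continue
        for var in variables:
            col = grp[var].dropna()
            if len(col) < min_group:
                continue
            sd = col.std(ddof=1)
            if sd == 0 or not np.isfinite(sd):
                continue
            z = (col - col.mean()) / sd
            bad = z.index[z.abs() > sd_mult]
            for idx in bad:
                log_rows.append(
                    {"index": idx, "group": group, "variable": var,
                     "value": table.at[idx, var]}
                )
                out.at[idx, var] = np.nan
    log = pd.DataFrame(log_rows, columns=["index", "group", "variable", "value"])
    return out, log


def standardize(
    table: pd.DataFrame, variables: list[str], ddof: int = 1
) -> pd.DataFrame:
    """z-score the named columns (mean 0, sample SD 1); idempotent."""
    out = table.copy()
    for var in variables:
        col = out[var].astype(float)
        sd = col.std(ddof=ddof)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"zero variance in variable {var!r}")
        out[var] = (col - col.mean()) / sd
    return out


def _parse_terms(terms: list[str]) -> tuple[list[str], list[tuple[str, ...]]]:
    """Split terms into the atom variables and per-term atom tuples."""
    parsed = [tuple(t.split(":")) for t in terms]
    atoms: list[str] = []
    for tup in parsed:
        for atom in tup:
            if atom not in atoms:
                atoms.append(atom)
    for tup in parsed:
        if len(tup) > 1:
            for atom in tup:
                if (atom,) not in parsed:
                    raise ValueError(
                        f"product term {':'.join(tup)!r} requires main effect {atom!r}"
                    )
    return atoms, parsed


class ModeratedRegression(BaseEstimator):
    """OLS on standardized variables with product (moderation) terms.

    Parameters
    ----------
    dependent : str
        Column name of the outcome.
    terms : list of str
        Predictor terms; products are written ``"x:age"`` and require both
        main effects.  Polynomial age trends can be added as extra columns
        (e.g. ``age2``) by the caller.
    standardize : bool
        z-score the outcome and the atom predictors on the analysis sample
        before fitting (default).  Products are formed after z-scoring.

    Attributes
    ----------
    coef_ : pd.Series
        Standardized coefficient per term.
    se_, tvalues_, pvalues_ : pd.Series
        Classical OLS standard errors / t / p per term (the study-level
        inference uses :func:`bootstrap_inference` instead).
    resid_ : pd.Series
        Residuals indexed like the analysis rows.
    n_used_ : int
    used_index_ : pd.Index
        Rows retained after listwise deletion.
    """

    def __init__(
        self, dependent: str, terms: list[str], standardize: bool = True
    ):
        self.dependent = dependent
        self.terms = terms
        self.standardize = standardize

    # -- design helpers shared with the bootstrap fast path ---------------

    def _columns(self) -> list[str]:
        atoms, _ = _parse_terms(self.terms)
        return [self.dependent] + atoms

    def _design(self, arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map a raw (n, 1+n_atoms) array to (X with intercept, y)."""
        atoms, parsed = _parse_terms(self.terms)
        if self.standardize:
            mu = arr.mean(axis=0)
            sd = arr.std(axis=0, ddof=1)
            if np.any(sd == 0):
                raise ValueError("zero variance in a model variable")
            arr = (arr - mu) / sd
        y = arr[:, 0]
        atom_ix = {a: i + 1 for i, a in enumerate(atoms)}
        cols = [np.ones(arr.shape[0])]
        for tup in parsed:
            col = arr[:, atom_ix[tup[0]]].copy()
            for atom in tup[1:]:
                col = col * arr[:, atom_ix[atom]]
            cols.append(col)
        return np.column_stack(cols), y

    def fit(self, table: pd.DataFrame, y=None):
        cols = self._columns()
        missing = [c for c in cols if c not in table.columns]
        if missing:
            raise ValueError(f"missing column(s): {missing}")
        data = table[cols].dropna()
        X, yv = self._design(data.to_numpy(dtype=float))
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(
                f"rank-deficient design for terms {self.terms}; "
                "check for collinear predictors"
            )
        res = sm.OLS(yv, X).fit()
        names = ["Intercept"] + list(self.terms)
        self.result_ = res
        self.intercept_ = float(res.params[0])
        self.coef_ = pd.Series(res.params[1:], index=self.terms)
        self.se_ = pd.Series(res.bse[1:], index=self.terms)
        self.tvalues_ = pd.Series(res.tvalues[1:], index=self.terms)
        self.pvalues_ = pd.Series(res.pvalues[1:], index=self.terms)
        self.params_ = pd.Series(res.params, index=names)
        self.resid_ = pd.Series(res.resid, index=data.index)
        self.n_used_ = len(data)
        self.used_index_ = data.index
        self.df_resid_ = int(res.df_resid)
        return self


@dataclass
class BootstrapResult:
    """Percentile bootstrap CIs and sign-crossing p-values per term."""

    table: pd.DataFrame  # columns: beta, ci_low, ci_high, p_bo
    B: int
    level: float
    n_redrawn: int = 0
    draws: np.ndarray | None = field(default=None, repr=False)


def bootstrap_inference(
    model: ModeratedRegression,
    table: pd.DataFrame,
    B: int = 5000,
    level: float = 95.0,
    seed: int | np.random.Generator | None = None,
    keep_draws: bool = False,
) -> BootstrapResult:
    """Case bootstrap of a moderated regression.

    Rows are resampled with replacement; each resample is re-standardized and
    refitted, reproducing the full estimation procedure per draw.  Percentile
    CIs at ``level`` %; ``p_bo = 2 * min(#{b* <= 0}, #{b* >= 0}) / B`` floored
    at ``2/B``.  Resamples in which a model variable collapses to zero
    variance are redrawn (counted in ``n_redrawn``).
    """
    if B < 100:
        warnings.warn(f"B={B} is very small for percentile intervals", stacklevel=2)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if not hasattr(model, "coef_"):
        model = model.fit(table)
    data = table[model._columns()].dropna().to_numpy(dtype=float)
    n = data.shape[0]
    k = len(model.terms)
    draws = np.empty((B, k))
    n_redrawn = 0
    for b in range(B):
        for _attempt in range(100):
            idx = rng.integers(0, n, n)
            sub = data[idx]
            if np.all(sub.std(axis=0, ddof=1) > 0):
                break
            n_redrawn += 1
        else:
            raise RuntimeError("could not draw a non-degenerate bootstrap resample")
        X, yv = model._design(sub)
        beta = np.linalg.solve(X.T @ X, X.T @ yv)
        draws[b] = beta[1:]
    alpha = (100.0 - level) / 2.0
    lo = np.percentile(draws, alpha, axis=0)
    hi = np.percentile(draws, 100.0 - alpha, axis=0)
    n_le = (draws <= 0).sum(axis=0)
    n_ge = (draws >= 0).sum(axis=0)
    p_bo = np.maximum(2.0 * np.minimum(n_le, n_ge) / B, 2.0 / B)
    out = pd.DataFrame(
        {
            "beta": model.coef_.to_numpy(),
            "ci_low": lo,
            "ci_high": hi,
            "p_bo": np.minimum(p_bo, 1.0),
        },
        index=model.terms,
    )
    return BootstrapResult(
        table=out, B=B, level=level, n_redrawn=n_redrawn,
        draws=draws if keep_draws else None,
    )


def exclude_by_residuals(
    model: ModeratedRegression, table: pd.DataFrame, sd_mult: float = 3.0
) -> tuple[ModeratedRegression, list]:
    """Remove cases with |standardized residual| > 3 and refit once.

    Standardized residuals are residual / sample SD of residuals from the
    initial fit; the refit re-standardizes on the reduced sample.  Single
    pass — the rule is not iterated.
    """
    if not hasattr(model, "resid_"):
        model = model.fit(table)
    sd = model.resid_.std(ddof=1)
    if sd == 0:
        return model, []
    z = model.resid_ / sd
    excluded = list(z.index[z.abs() > sd_mult])
    if not excluded:
        return model, []
    refit = ModeratedRegression(
        dependent=model.dependent, terms=list(model.terms),
        standardize=model.standardize,
    ).fit(table.drop(index=excluded))
    return refit, excluded


def main_family_factors() -> dict[str, list[str]]:
    """The 36-hypothesis main-assessment family: 3 x 3 x 2 x 2."""
    return {
        "diffusion_parameter": ["drift_rate", "boundary_separation", "ndt"],
        "neurochemical": ["gaba", "glutamate", "naa"],
        "region": ["ips", "mfg"],
        "effect_type": ["interaction", "main_effect"],
    }


def supplementary_family_factors() -> dict[str, list[str]]:
    """The 180-hypothesis supplementary family (adds 5 cognitive functions)."""
    return {
        **main_family_factors(),
        "cognitive_function": [
            "alerting", "orienting", "executive", "distance", "snarc",
        ],
    }


def build_family(factors: dict[str, list[str]]) -> list[dict[str, str]]:
    """Cartesian product of factor levels, one hypothesis per cell."""
    for name, levels in factors.items():
        if len(levels) == 0:
            raise ValueError(f"factor {name!r} has no levels")
    names = list(factors)
    return [
        dict(zip(names, combo))
        for combo in itertools.product(*(factors[n] for n in names))
    ]


def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def probe_interaction(
    model: ModeratedRegression,
    focal: str,
    moderator: str,
    levels: tuple[float, ...] = (-1.0, 0.0, 1.0),
) -> pd.DataFrame:
    """Simple slopes of ``focal`` at moderator = mean + k*SD.

    On the standardized scale the slope at level ``k`` is
    ``beta_focal + k * beta_interaction`` and the intercept is
    ``intercept + k * beta_moderator``; the returned table is directly
    plottable (one regression line per moderator level).
    """
    product = f"{focal}:{moderator}"
    if product not in model.coef_.index:
        product_rev = f"{moderator}:{focal}"
        if product_rev not in model.coef_.index:
            raise ValueError(f"model has no product term for {focal} x {moderator}")
        product = product_rev
    b_focal = model.coef_[focal]
    b_int = model.coef_[product]
    b_mod = model.coef_[moderator]
    rows = [
        {
            "level_sd": k,
            "slope": b_focal + k * b_int,
            "intercept": model.intercept_ + k * b_mod,
        }
        for k in levels
    ]
    return pd.DataFrame(rows)


def plot_interaction(probe_table: pd.DataFrame, focal: str, dependent: str, path=None):
    """Basic +/-1 SD simple-slopes plot from a :func:`probe_interaction` table."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    x = np.linspace(-2, 2, 50)
    colors = {-1.0: "tab:red", 0.0: "tab:blue", 1.0: "tab:green"}
    for _, row in probe_table.iterrows():
        k = row["level_sd"]
        label = {-1.0: "-1 SD (younger)", 0.0: "mean", 1.0: "+1 SD (older)"}.get(
            k, f"{k:+.1f} SD"
        )
        ax.plot(x, row["intercept"] + row["slope"] * x,
                color=colors.get(k), label=label)
    ax.set_xlabel(f"{focal} (z)")
    ax.set_ylabel(f"{dependent} (z)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
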