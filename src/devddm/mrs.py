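"""MRS concentration corrections, water-T2 fitting and quality exclusions.

Operates downstream of spectral quantification: inputs are metabolite-to-water
amplitude ratios together with their Cramer-Rao lower bounds (CRLB), SNR and
the voxel's gray-matter / white-matter / CSF fractions.

The partial-volume ("tissue") correction rescales a raw ratio for the water
visibility of the voxel compartments using literature water concentrations
(GM 43300, WM 35880, CSF 55556 mmol/L) and the assumption that CSF carries no
metabolites; the additional T2 correction applies the multiplicative
``exp(-TE/T2)`` attenuation term exactly as used by the quantification
pipeline this package mirrors.  Note the conventional relaxation correction
*divides* by the attenuation factor; the multiplicative form is kept
deliberately for fidelity with that pipeline and is flagged in the docs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

__all__ = [
    "GM_WATER",
    "WM_WATER",
    "CSF_WATER",
    "T2_CSF_MS",
    "WATER_TE_GRID_MS",
    "tissue_correct",
    "t2_correct",
    "WaterT2Model",
    "fit_water_t2",
    "water_biexponential",
    "apply_mrs_exclusions",
]

GM_WATER = 43300.0  # mmol/L water, gray matter
WM_WATER = 35880.0  # mmol/L water, white matter
CSF_WATER = 55556.0  # mmol/L water, CSF (reference)
T2_CSF_MS = 740.0  # fixed CSF water T2 used in the biexponential fit

#: Echo times (ms) of the unsuppressed water series.
WATER_TE_GRID_MS = (
    32.0, 42.0, 52.0, 85.0, 100.0, 115.0, 150.0, 250.0, 450.0, 850.0,
    1650.0, 3250.0, 4040.0,
)


def tissue_correct(raw_conc, f_gm, f_wm, f_csf):
    """Partial-volume corrected concentration.

    ``((43300/55556*fGM + 35880/55556*fWM + 1*fCSF) / (1 - fCSF)) * raw``.
    Accepts scalars or aligned arrays; linear in ``raw_conc`` and strictly
    increasing in ``f_csf`` for fixed positive raw concentration.
    """
    f_csf = np.asarray(f_csf, dtype=float)
    if np.any(f_csf >= 1.0):
        raise ValueError("pure-CSF voxel: f_csf must be < 1")
    num = (GM_WATER / CSF_WATER) * np.asarray(f_gm, dtype=float) + (
        WM_WATER / CSF_WATER
    ) * np.asarray(f_wm, dtype=float) + 1.0 * f_csf
    out = num / (1.0 - f_csf) * np.asarray(raw_conc, dtype=float)
    return float(out) if out.ndim == 0 else out


def t2_correct(conc, te: float, t2_tissue: float):
    """Apply the multiplicative T2 attenuation term ``conc * exp(-TE/T2)``.

    ``te`` and ``t2_tissue`` must share units (seconds throughout this
    package).
    """
    if t2_tissue <= 0:
        raise ValueError("t2_tissue must be positive")
    out = np.asarray(conc, dtype=float) * np.exp(-te / t2_tissue)
    return float(out) if out.ndim == 0 else out


def water_biexponential(te_ms, t2_tissue_ms: float, amp_tissue: float, amp_csf: float):
    """Signal model of the unsuppressed water series.

    ``S(TE) = A_t * exp(-TE/T2_t) + A_c * exp(-TE/740)`` with the CSF T2
    fixed.
    """
    te_ms = np.asarray(te_ms, dtype=float)
    return amp_tissue * np.exp(-te_ms / t2_tissue_ms) + amp_csf * np.exp(
        -te_ms / T2_CSF_MS
    )


class WaterT2Model(BaseEstimator):
    """Biexponential water-T2 fit with the CSF component's T2 fixed at 740 ms.

    Three free parameters — tissue-water T2, tissue-water amplitude and
    CSF-water amplitude — fitted by bounded trust-region least squares.
    Initialisation: the CSF amplitude from the longest echo (where tissue
    water has fully decayed), the tissue T2 and amplitude from a log-linear
    fit of the first six echoes after removing the CSF contribution.

    Parameters
    ----------
    t2_bounds : (low, high)
        Bounds on the tissue-water T2 in ms; default (10, 300).

    Attributes
    ----------
    t2_tissue_ : float
        Fitted tissue-water T2 (ms).
    amp_tissue_, amp_csf_ : float
        Fitted amplitudes (arbitrary units, non-negative).
    csf_fraction_ : float
        ``A_c / (A_t + A_c)``, the percent-CSF contribution as a fraction.
    """

    def __init__(self, t2_bounds: tuple[float, float] = (10.0, 300.0)):
        self.t2_bounds = t2_bounds

    def fit(self, te_ms, integrals):
        te = np.asarray(te_ms, dtype=float)
        y = np.asarray(integrals, dtype=float)
        if te.shape != y.shape or te.ndim != 1:
            raise ValueError("te_ms and integrals must be 1-D and aligned")
        if te.size < 4:
            raise ValueError("need at least 4 echo points for a 3-parameter fit")
        if np.any(y <= 0):
            raise ValueError("water integrals must be positive")
        order = np.argsort(te)
        te, y = te[order], y[order]

        a_csf0 = max(y[-1] / np.exp(-te[-1] / T2_CSF_MS), 1e-12)
        resid0 = np.clip(y[:6] - a_csf0 * np.exp(-te[:6] / T2_CSF_MS), 1e-12, None)
        slope, intercept = np.polyfit(te[:6], np.log(resid0), 1)
        t2_0 = float(np.clip(-1.0 / slope if slope < 0 else 60.0, *self.t2_bounds))
        a_t0 = max(float(np.exp(intercept)), 1e-12)

        def residuals(theta):
            return water_biexponential(te, *theta) - y

        lo = (self.t2_bounds[0], 0.0, 0.0)
        hi = (self.t2_bounds[1], np.inf, np.inf)
        x0 = np.clip([t2_0, a_t0, a_csf0], lo, hi)
        sol = least_squares(
            residuals, x0, bounds=(lo, hi), method="trf",
            xtol=1e-15, ftol=1e-15, gtol=1e-15,
        )
        if not sol.success:
            raise RuntimeError(f"water T2 fit did not converge: {sol.message}")
        self.t2_tissue_, self.amp_tissue_, self.amp_csf_ = map(float, sol.x)
        total = self.amp_tissue_ + self.amp_csf_
        self.csf_fraction_ = self.amp_csf_ / total if total > 0 else np.nan
        self.te_grid_ = te
        self.n_iter_ = sol.nfev
        return self

    def predict(self, te_ms):
        return water_biexponential(
            te_ms, self.t2_tissue_, self.amp_tissue_, self.amp_csf_
        )


def fit_water_t2(te_ms, integrals) -> WaterT2Model:
    """Convenience wrapper: fit and return a :class:`WaterT2Model`."""
    return WaterT2Model().fit(te_ms, integrals)


def apply_mrs_exclusions(
    records: pd.DataFrame,
    crlb_max: float = 50.0,
    snr_sd_mult: float = 3.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag non-detectable metabolites and remove SNR outliers.

    Metabolite records with ``crlb > crlb_max`` (%) are classified as not
    detectable and dropped (that metabolite only).  Then, per region (and per
    assessment wave when a ``wave`` column is present), participant-level SNR
    values lying more than ``snr_sd_mult`` sample SDs from the region mean are
    excluded — removing all of that participant's metabolites in the region.

    Returns the surviving records and a log with one row per removal
    (participant_id, region, metabolite, reason).
    """
    df = records.copy()
    log_rows = []

    nd = df["crlb"] > crlb_max
    for _, row in df.loc[nd].iterrows():
        log_rows.append(
            {
                "participant_id": row["participant_id"],
                "region": row["region"],
                "metabolite": row["metabolite"],
                "reason": "crlb_not_detectable",
            }
        )
    df = df.loc[~nd]

    group_cols = ["region"] + (["wave"] if "wave" in df.columns else [])
    drop_mask = pd.Series(False, index=df.index)
    for _, grp in df.groupby(group_cols):
        # one SNR per participant-region acquisition, repeated across metabolites
        per_part = grp.drop_duplicates("participant_id")[["participant_id", "snr"]]
        if len(per_part) < 2:
            continue
        mu = per_part["snr"].mean()
        sd = per_part["snr"].std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            continue
        bad = per_part.loc[(per_part["snr"] - mu).abs() > snr_sd_mult * sd]
        if len(bad):
            mask = grp["participant_id"].isin(bad["participant_id"])
            drop_mask.loc[grp.index[mask]] = True
    for _, row in df.loc[drop_mask].iterrows():
        log_rows.append(
            {
                "participant_id": row["participant_id"],
                "region": row["region"],
                "metabolite": row["metabolite"],
                "reason": "snr_outlier",
            }
        )
    survivors = df.loc[~drop_mask]
    log = pd.DataFrame(
        log_rows, columns=["participant_id", "region", "metabolite", "reason"]
    )
    return survivors, log
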