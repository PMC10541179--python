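"""Synthetic developmental-cohort generator.

Two layers:

* **Regression-structure generators** (:func:`generate_moderation_sample`,
  :func:`generate_model59_sample`) draw samples whose *population*
  standardized coefficients equal a requested coefficient set exactly:
  predictors are iid standard normal and the residual SD is solved
  analytically so every generated variable has population variance 1.  These
  drive the parameter-recovery studies.

* **The full cohort generator** (:func:`generate_cohort`) emulates all four
  observable streams of the study — trial-level behavior in three two-choice
  tasks, MRS records per region/metabolite, resting-state ROI time series,
  and a 30-item fluid-intelligence score — on top of latent standardized
  variables that carry the developmental trends (glutamate decreasing and
  GABA increasing with age; drift rate rising while boundary separation and
  non-decision time fall) and the neurochemical-by-age moderation structure.
  Observables are built by *inverting* the analysis-side transformations
  (partial-volume correction, the EZ forward equations, the Fisher-z map),
  so with noise switched off every pipeline stage recovers its generating
  quantity exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .behavior import (
    DiffusionParams,
    TASK_CONDITIONS,
    TASKS,
    digit_distance_bin,
    ez_forward,
    simulate_wiener_trials,
)
from .connectivity import N_VOLUMES, VISUOMOTOR_ROIS
from .mrs import WATER_TE_GRID_MS, tissue_correct, water_biexponential

__all__ = [
    "TER_IPS_GLUTAMATE_COEFFS",
    "TER_IPS_GABA_COEFFS",
    "M59_GABA_INTELLIGENCE",
    "M59_GLUTAMATE_INTELLIGENCE",
    "M59_GABA_CONNECTIVITY",
    "generate_moderation_sample",
    "generate_model59_sample",
    "CohortConfig",
    "SyntheticCohort",
    "generate_cohort",
    "generate_mrs_observables",
    "generate_intelligence",
]

# ---------------------------------------------------------------------------
# Study-calibrated generating coefficient sets (standardized scale).
# The interaction coefficients are the first-assessment Task 1 IPS estimates;
# mediation path sets are solved so the conditional indirect effects at the
# reported moderator level equal the reported values while the opposite level
# is null, with the shared mediator->outcome path split evenly (b1 = b2).
# ---------------------------------------------------------------------------

#: first-assessment-shaped generator for non-decision time ~ IPS glutamate x age.
TER_IPS_GLUTAMATE_COEFFS: dict[str, float] = {
    "nt": -0.155, "age": -0.5, "nt:age": -0.22, "c1": 0.2, "c2": -0.1,
}

#: first-assessment-shaped generator for non-decision time ~ IPS GABA x age.
TER_IPS_GABA_COEFFS: dict[str, float] = {
    "nt": 0.02, "age": -0.5, "nt:age": 0.23, "c1": 0.2, "c2": -0.1,
}

#: X = IPS GABA, M = composite visuomotor, Y = intelligence, W = age:
#: omega(+1) = (a1+a3)(b1+b2) = 0.25 * 0.16 = 0.04; omega(-1) = 0.
M59_GABA_INTELLIGENCE: dict[str, float] = {
    "a1": 0.02, "a2": -0.5, "a3": 0.23,
    "b1": 0.08, "b2": 0.08,
    "c1p": 0.0, "c2p": 0.3, "c3p": -0.05,
}

#: X = IPS glutamate: omega(+1) = (-0.375) * 0.16 = -0.06; omega(-1) = 0.
M59_GLUTAMATE_INTELLIGENCE: dict[str, float] = {
    "a1": -0.155, "a2": -0.5, "a3": -0.22,
    "b1": 0.08, "b2": 0.08,
    "c1p": 0.0, "c2p": 0.3, "c3p": 0.16,
}

#: X = IPS GABA, M = visuomotor connectivity, Y = composite visuomotor:
#: omega(-1) = (a1-a3)(b1-b2) = (-0.15) * 0.20 = -0.03.
M59_GABA_CONNECTIVITY: dict[str, float] = {
    "a1": 0.0, "a2": 0.2, "a3": 0.15,
    "b1": 0.04, "b2": -0.16,
    "c1p": 0.02, "c2p": -0.5, "c3p": 0.23,
}


def generate_moderation_sample(
    n: int,
    coeffs: dict[str, float],
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw one first-assessment-shaped sample with unit-variance population moments.

    ``y = b_nt*nt + b_age*age + b_int*nt*age + b_c1*c1 + b_c2*c2 + e`` with
    nt, age, c1, c2 iid standard normal; the product nt*age then has unit
    variance and zero correlation with the main effects, and
    ``Var(e) = 1 - sum(b^2)`` makes Var(y) = 1 so the population standardized
    coefficients equal ``coeffs`` exactly.
    """
    required = {"nt", "age", "nt:age", "c1", "c2"}
    if set(coeffs) != required:
        raise ValueError(f"coeffs must have keys {sorted(required)}")
    ss = sum(b * b for b in coeffs.values())
    if ss >= 1.0:
        raise ValueError("sum of squared coefficients must be < 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nt, age, c1, c2 = rng.standard_normal((4, n))
    sigma = np.sqrt(1.0 - ss)
    y = (
        coeffs["nt"] * nt
        + coeffs["age"] * age
        + coeffs["nt:age"] * nt * age
        + coeffs["c1"] * c1
        + coeffs["c2"] * c2
        + sigma * rng.standard_normal(n)
    )
    return pd.DataFrame({"y": y, "nt": nt, "age": age, "c1": c1, "c2": c2})


def _model59_sigmas(p: dict[str, float]) -> tuple[float, float]:
    """Residual SDs giving both M and Y unit population variance.

    With X, W iid standard normal the mediator systematic variance is
    ``a1^2 + a2^2 + a3^2``.  Substituting M into the outcome equation gives
    ``Y = alpha*X + beta*W + gamma*XW + b1*e_M + delta*W^2 + eps*XW^2
    + b2*e_M*W + e_Y`` whose variance follows from normal moments
    (Var(W^2) = 2, Var(XW^2) = 3, Cov(X, XW^2) = 1; all other cross terms
    vanish).
    """
    a_ss = p["a1"] ** 2 + p["a2"] ** 2 + p["a3"] ** 2
    if a_ss >= 1.0:
        raise ValueError("mediator systematic variance must be < 1")
    sigma_m2 = 1.0 - a_ss

    alpha = p["c1p"] + p["b1"] * p["a1"]
    beta = p["c2p"] + p["b1"] * p["a2"]
    gamma = p["c3p"] + p["b1"] * p["a3"] + p["b2"] * p["a1"]
    delta = p["b2"] * p["a2"]
    eps = p["b2"] * p["a3"]
    var_s = (
        alpha**2
        + beta**2
        + gamma**2
        + p["b1"] ** 2 * sigma_m2
        + 2.0 * delta**2
        + 3.0 * eps**2
        + p["b2"] ** 2 * sigma_m2
        + 2.0 * alpha * eps
    )
    if var_s >= 1.0:
        raise ValueError("outcome systematic variance must be < 1")
    return float(np.sqrt(sigma_m2)), float(np.sqrt(1.0 - var_s))


def generate_model59_sample(
    n: int,
    paths: dict[str, float],
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw one model-59-shaped sample (columns x, w, m, y).

    X and W are iid standard normal; M and Y follow the two moderated
    equations with residual SDs solved by :func:`_model59_sigmas` so both
    have unit population variance — the population conditional indirect
    effect at moderator value w is exactly ``(a1+a3*w)*(b1+b2*w)``.
    """
    required = {"a1", "a2", "a3", "b1", "b2", "c1p", "c2p", "c3p"}
    if set(paths) != required:
        raise ValueError(f"paths must have keys {sorted(required)}")
    sigma_m, sigma_y = _model59_sigmas(paths)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x, w = rng.standard_normal((2, n))
    m = (
        paths["a1"] * x + paths["a2"] * w + paths["a3"] * x * w
        + sigma_m * rng.standard_normal(n)
    )
    y = (
        paths["c1p"] * x + paths["c2p"] * w + paths["c3p"] * x * w
        + paths["b1"] * m + paths["b2"] * m * w
        + sigma_y * rng.standard_normal(n)
    )
    return pd.DataFrame({"x": x, "w": w, "m": m, "y": y})


# ---------------------------------------------------------------------------
# Full cohort
# ---------------------------------------------------------------------------


def _default_band_sizes() -> dict[str, int]:
    return {"6-7": 52, "10-11": 52, "14-15": 52, "16-17": 51, "18+": 51}


@dataclass
class CohortConfig:
    """Generating conditions of the synthetic study.

    All structural coefficients are on the standardized (z) scale; residual
    SDs of the latent equations are solved so each latent has population
    variance 1, then multiplied by ``noise_scale`` (0 switches the structural
    noise off entirely for exactness tests).
    """

    band_sizes: dict[str, int] = field(default_factory=_default_band_sizes)
    retention_a2: float = 0.7  # fraction of participants with a second wave
    years_between_waves: float = 1.75  # ~21 months
    years_between_waves_sd: float = 0.2  # per-participant interval variation

    # latent structural models (standardized coefficients)
    neurochem_age_trend: dict[str, float] = field(
        default_factory=lambda: {"glutamate": -0.4, "gaba": 0.4, "naa": 0.2}
    )
    neurochem_stability: float = 0.7  # wave-to-wave latent autocorrelation
    ter_model: dict[str, float] = field(
        default_factory=lambda: {
            "age": -0.5,
            "glutamate": -0.155, "gaba": 0.02,
            "glutamate:age": -0.22, "gaba:age": 0.23,
            "connectivity": 0.04, "connectivity:age": -0.16,
        }
    )
    v_model: dict[str, float] = field(default_factory=lambda: {"age": 0.5})
    a_model: dict[str, float] = field(default_factory=lambda: {"age": -0.5})
    connectivity_model: dict[str, float] = field(
        default_factory=lambda: {
            "age": 0.2, "glutamate:age": -0.18, "gaba:age": 0.15,
        }
    )
    iq_model: dict[str, float] = field(
        default_factory=lambda: {
            "age": 0.3,
            "glutamate": 0.0, "gaba": 0.0,
            "glutamate:age": 0.16, "gaba:age": -0.05,
            "ter": 0.08, "ter:age": 0.08,
        }
    )
    noise_scale: float = 1.0
    #: per-equation overrides of the residual multiplier, e.g. {"ter": 0.0}
    #: switches off only the non-decision-time residual so the full chain
    #: can be checked for exact recovery while the predictors keep
    #: independent variation (a global zero would collapse every latent onto
    #: age and destroy identifiability)
    equation_noise: dict[str, float] = field(default_factory=dict)

    # observable scales
    ter_base_s: dict[str, float] = field(
        default_factory=lambda: {"attention": 0.35, "digit": 0.40, "rotation": 0.45}
    )
    ter_sd_s: float = 0.05
    ter_floor_s: float = 0.1
    v_base: dict[str, float] = field(
        default_factory=lambda: {"attention": 0.22, "digit": 0.30, "rotation": 0.18}
    )
    v_sd: float = 0.05
    v_floor: float = 0.05
    a_base: float = 0.12
    a_sd: float = 0.02
    a_floor: float = 0.06
    task_dev_sd: float = 0.3  # task-specific deviation of the shared ndt latent
    s: float = 0.1
    trial_mode: str = "simulate"  # "simulate" (Wiener trials) or "analytic" (moments)
    dt: float = 0.001

    # attention condition offsets (cue -> Ter seconds, flanker -> drift)
    cue_ter_offsets: dict[str, float] = field(
        default_factory=lambda: {
            "no": 0.010, "central": 0.004, "double": 0.0, "spatial": -0.004,
        }
    )
    flanker_v_offsets: dict[str, float] = field(
        default_factory=lambda: {"congruent": 0.02, "incongruent": -0.02, "neutral": 0.0}
    )
    distance_v_offset: float = 0.03  # far/near and r45/r135 drift split

    # MRS observables
    metabolite_mean: dict[str, float] = field(
        default_factory=lambda: {"glutamate": 10.0, "gaba": 2.0, "naa": 12.0}
    )
    metabolite_cv: float = 0.10
    crlb_dist: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "glutamate": (6.0, 2.0), "gaba": (20.0, 8.0), "naa": (3.0, 1.0)
        }
    )
    snr_mean: float = 40.0
    snr_sd: float = 8.0
    linewidth_ppm: dict[str, float] = field(
        default_factory=lambda: {"ips": 0.022, "mfg": 0.027}
    )
    te_s: float = 0.032
    tissue_fracs: tuple[float, float, float] = (0.55, 0.37, 0.08)
    tissue_frac_sd: float = 0.03  # 0 in noiseless runs
    water_t2_ms: tuple[float, float] = (70.0, 8.0)  # tissue-water T2 mean, SD
    water_noise_cv: float = 0.0  # multiplicative noise on water integrals

    # connectivity observables
    conn_base_z: float = 0.3
    conn_sd_z: float = 0.1
    n_volumes: int = N_VOLUMES
    roi_mode: str = "simulate"  # "simulate" (factor model) or "exact"
    fd_scale_mm: float = 0.15
    high_motion_rate: float = 0.1  # fraction of participants failing the 5% rule

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SyntheticCohort:
    participants: pd.DataFrame
    trials: dict[str, pd.DataFrame]  # wave -> trial table
    moments: dict[str, pd.DataFrame]  # wave -> analytic moment table
    mrs: pd.DataFrame
    water: pd.DataFrame
    roi: dict[str, pd.DataFrame]  # participant -> (fd + 7 ROI columns)
    truth: dict
    config: CohortConfig


def _linear_latent(
    coeffs: dict[str, float], parts: dict[str, np.ndarray],
    rng: np.random.Generator, noise_scale: float,
) -> np.ndarray:
    """Latent = sum of coeff * component (+ product terms "a:b") + residual.

    The residual SD is 1 - sum(b^2) (clipped at 0) scaled by ``noise_scale``;
    with independent standardized components the latent then has unit
    population variance at ``noise_scale`` = 1.
    """
    n = len(next(iter(parts.values())))
    out = np.zeros(n)
    ss = 0.0
    for term, b in coeffs.items():
        atoms = term.split(":")
        col = parts[atoms[0]].copy()
        for atom in atoms[1:]:
            col = col * parts[atom]
        out += b * col
        ss += b * b
    sigma = np.sqrt(max(1.0 - ss, 0.0)) * noise_scale
    if sigma > 0:
        out += sigma * rng.standard_normal(n)
    return out


def _draw_ages(config: CohortConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    bounds = {"6-7": (6.0, 8.0), "10-11": (10.0, 12.0), "14-15": (14.0, 16.0),
              "16-17": (16.0, 18.0), "18+": (18.0, 22.0)}
    ages, bands = [], []
    for band, size in config.band_sizes.items():
        if size < 1:
            raise ValueError(f"band {band!r} must have at least 1 participant")
        lo, hi = bounds[band]
        ages.append(rng.uniform(lo, hi, size))
        bands.extend([band] * size)
    return np.concatenate(ages), np.asarray(bands)


def _participant_params(
    config: CohortConfig, task: str,
    v_z: np.ndarray, a_z: np.ndarray, ter_z: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Map latent z-scores to per-task diffusion parameters in natural units."""
    n = v_z.size
    dev = config.task_dev_sd * config.noise_scale
    ter_task = ter_z + (dev * rng.standard_normal(n) if dev > 0 else 0.0)
    v_task = v_z + (dev * rng.standard_normal(n) if dev > 0 else 0.0)
    a_task = a_z + (dev * rng.standard_normal(n) if dev > 0 else 0.0)
    ter = np.maximum(config.ter_base_s[task] + config.ter_sd_s * ter_task,
                     config.ter_floor_s)
    v = np.maximum(config.v_base[task] + config.v_sd * v_task, config.v_floor)
    a = np.maximum(config.a_base + config.a_sd * a_task, config.a_floor)
    return pd.DataFrame({"v": v, "a": a, "ter": ter})


def _condition_params(
    config: CohortConfig, task: str, condition: str, base: DiffusionParams
) -> DiffusionParams:
    """Small fixed condition offsets so the contrast scores are non-degenerate."""
    v, a, ter = base.v, base.a, base.ter
    if task == "attention":
        cue, flanker = condition.split(":")
        ter = ter + config.cue_ter_offsets[cue]
        v = v + config.flanker_v_offsets[flanker]
    elif task == "digit":
        v = v + (config.distance_v_offset
                 if digit_distance_bin(condition) == "far"
                 else -config.distance_v_offset)
    elif task == "rotation":
        v = v + {"r45": config.distance_v_offset, "r90": 0.0,
                 "r135": -config.distance_v_offset}[condition]
    return DiffusionParams(v=max(v, 0.02), a=a, ter=max(ter, 0.05), s=base.s)


def _trial_plan(task: str) -> list[tuple[str, int]]:
    """(condition, n_trials) cells matching the printed task designs."""
    if task == "attention":
        return [(c, 8) for c in TASK_CONDITIONS["attention"]]  # 96 trials
    if task == "digit":
        return [(c, 2) for c in TASK_CONDITIONS["digit"]]  # 72 trials
    if task == "rotation":
        return [(c, 24) for c in TASK_CONDITIONS["rotation"]]  # 72 trials
    raise ValueError(task)


def _generate_trials(
    config: CohortConfig, pid: str, task: str, base: DiffusionParams,
    rng: np.random.Generator, wave: str,
) -> pd.DataFrame:
    frames = []
    plan = _trial_plan(task)
    # group cells sharing identical parameters into one simulator call
    by_params: dict[DiffusionParams, list[tuple[str, int]]] = {}
    for cond, n_tr in plan:
        p = _condition_params(config, task, cond, base)
        by_params.setdefault(p, []).append((cond, n_tr))
    for p, cells in by_params.items():
        total = sum(n for _, n in cells)
        block = simulate_wiener_trials(
            p, total, dt=config.dt, seed=rng,
            participant_id=pid, task=task, condition="",
        )
        block["condition"] = np.repeat([c for c, _ in cells], [n for _, n in cells])
        frames.append(block)
    out = pd.concat(frames, ignore_index=True)
    out["wave"] = wave
    return out


def generate_mrs_observables(
    truth: pd.DataFrame,
    config: CohortConfig,
    rng: np.random.Generator,
    plant_crlb: int = 0,
    plant_snr: int = 0,
) -> pd.DataFrame:
    """Build raw MRS records by inverting the partial-volume correction.

    ``truth`` needs columns participant_id, wave, region, metabolite,
    truth_conc.  Tissue fractions are sampled around the configured voxel
    composition; the raw metabolite-to-water ratio is
    ``truth_conc / correction_factor`` so :func:`devddm.mrs.tissue_correct`
    recovers the truth exactly.  ``plant_crlb`` / ``plant_snr`` insert that
    many deliberate quality violators (CRLB 60%; SNR at mean + 6 SD).
    """
    n = len(truth)
    f_gm0, f_wm0, f_csf0 = config.tissue_fracs
    jitter = config.tissue_frac_sd
    f_csf = np.clip(f_csf0 + (jitter * rng.standard_normal(n) if jitter else 0.0),
                    0.01, 0.4)
    gm_share = f_gm0 / (f_gm0 + f_wm0)
    share = np.clip(gm_share + (jitter * rng.standard_normal(n) if jitter else 0.0),
                    0.2, 0.8)
    f_gm = (1.0 - f_csf) * share
    f_wm = (1.0 - f_csf) * (1.0 - share)

    factor = tissue_correct(np.ones(n), f_gm, f_wm, f_csf)
    raw = truth["truth_conc"].to_numpy() / factor

    met = truth["metabolite"].to_numpy()
    crlb = np.empty(n)
    for m, (mu, sd) in config.crlb_dist.items():
        mask = met == m
        crlb[mask] = np.clip(mu + sd * rng.standard_normal(mask.sum()), 0.5, None)

    # one SNR per participant-region-wave acquisition
    key = (truth["participant_id"].astype(str) + "|" + truth["region"].astype(str)
           + "|" + truth["wave"].astype(str))
    uniq, inv = np.unique(key.to_numpy(), return_inverse=True)
    snr_u = np.clip(config.snr_mean + config.snr_sd * rng.standard_normal(uniq.size),
                    5.0, None)
    snr = snr_u[inv]

    out = truth[["participant_id", "wave", "region", "metabolite"]].copy()
    out["raw_conc"] = raw
    out["crlb"] = crlb
    out["snr"] = snr
    out["linewidth_ppm"] = out["region"].map(config.linewidth_ppm)
    out["f_gm"] = f_gm
    out["f_wm"] = f_wm
    out["f_csf"] = f_csf
    out["te_s"] = config.te_s
    out["truth_conc"] = truth["truth_conc"].to_numpy()

    if plant_crlb:
        idx = rng.choice(out.index, size=plant_crlb, replace=False)
        out.loc[idx, "crlb"] = 60.0
    if plant_snr:
        parts = rng.choice(uniq, size=plant_snr, replace=False)
        for u in parts:
            out.loc[key.to_numpy() == u, "snr"] = (
                config.snr_mean + 6.0 * config.snr_sd
            )
    return out


def generate_intelligence(
    latent: np.ndarray, rng: np.random.Generator, n_items: int = 30
) -> np.ndarray:
    """Map a standardized latent ability to an integer 0..n_items score.

    Monotone probit link: ``score = round(n_items * Phi(latent))``.  The
    test's discontinue rule is emulated only through the bounded support.
    """
    score = np.rint(n_items * norm.cdf(np.asarray(latent, dtype=float)))
    return np.clip(score, 0, n_items).astype(int)


def _roi_timeseries(
    z_target: float, T: int, rng: np.random.Generator, mode: str
) -> pd.DataFrame:
    """7-ROI series whose population (or exact sample) mean pair-z is z_target."""
    r = float(np.clip(np.tanh(z_target), 0.02, 0.95))
    k = len(VISUOMOTOR_ROIS)
    if mode == "exact":
        # whiten empirical draws, recolor with the equicorrelation target:
        # the sample correlation of every pair is then exactly r.
        u = rng.standard_normal((T, k))
        u = u - u.mean(axis=0)
        cov = u.T @ u / (T - 1)
        u_white = u @ np.linalg.inv(np.linalg.cholesky(cov)).T
        target = (1.0 - r) * np.eye(k) + r * np.ones((k, k))
        data = u_white @ np.linalg.cholesky(target).T
    else:
        f = rng.standard_normal(T)
        data = (np.sqrt(r) * f[:, None]
                + np.sqrt(1.0 - r) * rng.standard_normal((T, k)))
    return pd.DataFrame(data, columns=list(VISUOMOTOR_ROIS))


def generate_cohort(
    config: CohortConfig | None = None,
    seed: int | np.random.Generator | None = None,
) -> SyntheticCohort:
    """Generate the full synthetic study for both assessment waves.

    Deterministic given (config, seed).  The participant table keeps the
    latent truth columns (suffix ``_z``) alongside the observables.
    """
    config = config or CohortConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ns = config.noise_scale

    def eq_ns(name: str) -> float:
        return config.equation_noise.get(name, config.noise_scale)

    age, band = _draw_ages(config, rng)
    n = age.size
    pids = np.array([f"P{i:04d}" for i in range(n)])
    age_z = (age - age.mean()) / age.std(ddof=1)

    def nz(size):
        return rng.standard_normal(size)

    # latent neurochemistry per region (standardized); only IPS carries the
    # behavioral moderation structure, MFG shares the age trends
    chem: dict[str, dict[str, np.ndarray]] = {"ips": {}, "mfg": {}}
    for region in ("ips", "mfg"):
        for met, b_age in config.neurochem_age_trend.items():
            resid = np.sqrt(max(1.0 - b_age**2, 0.0)) * eq_ns("neurochem")
            chem[region][met] = b_age * age_z + resid * nz(n)

    conn_z = _linear_latent(
        config.connectivity_model,
        {"age": age_z, "glutamate": chem["ips"]["glutamate"],
         "gaba": chem["ips"]["gaba"]},
        rng, eq_ns("connectivity"),
    )
    ter_z = _linear_latent(
        config.ter_model,
        {"age": age_z, "glutamate": chem["ips"]["glutamate"],
         "gaba": chem["ips"]["gaba"], "connectivity": conn_z},
        rng, eq_ns("ter"),
    )
    v_z = _linear_latent(config.v_model, {"age": age_z}, rng, eq_ns("v"))
    a_z = _linear_latent(config.a_model, {"age": age_z}, rng, eq_ns("a"))
    iq_z = _linear_latent(
        config.iq_model,
        {"age": age_z, "glutamate": chem["ips"]["glutamate"],
         "gaba": chem["ips"]["gaba"], "ter": ter_z},
        rng, eq_ns("iq"),
    )
    iq_score = generate_intelligence(iq_z, rng)

    # second wave: retained subset, aged forward, latents partially stable
    retained = rng.random(n) < config.retention_a2
    age2 = age + np.maximum(
        config.years_between_waves
        + config.years_between_waves_sd * rng.standard_normal(n),
        0.5,
    )
    age2_z = (age2 - age2.mean()) / age2.std(ddof=1)
    rho = config.neurochem_stability
    chem2: dict[str, dict[str, np.ndarray]] = {"ips": {}, "mfg": {}}
    for region in ("ips", "mfg"):
        for met, b_age in config.neurochem_age_trend.items():
            innov = np.sqrt(max(1.0 - rho**2, 0.0)) * eq_ns("neurochem")
            chem2[region][met] = rho * chem[region][met] + innov * nz(n)
    ter2_z = _linear_latent(
        config.ter_model,
        {"age": age2_z, "glutamate": chem2["ips"]["glutamate"],
         "gaba": chem2["ips"]["gaba"], "connectivity": conn_z},
        rng, eq_ns("ter"),
    )
    v2_z = _linear_latent(config.v_model, {"age": age2_z}, rng, eq_ns("v"))
    a2_z = _linear_latent(config.a_model, {"age": age2_z}, rng, eq_ns("a"))
    iq2_z = _linear_latent(
        config.iq_model,
        {"age": age2_z, "glutamate": chem2["ips"]["glutamate"],
         "gaba": chem2["ips"]["gaba"], "ter": ter2_z},
        rng, eq_ns("iq"),
    )
    iq2_score = generate_intelligence(iq2_z, rng)

    participants = pd.DataFrame(
        {
            "participant_id": pids,
            "age_a1": age,
            "age_band": band,
            "iq_a1": iq_score,
            "retained_a2": retained,
            "age_a2": np.where(retained, age2, np.nan),
            "iq_a2": np.where(retained, iq2_score, np.nan),
            # latent truth (z scale)
            "ter_z_a1": ter_z, "v_z_a1": v_z, "a_z_a1": a_z,
            "conn_z_a1": conn_z, "iq_z_a1": iq_z,
            "ter_z_a2": ter2_z, "v_z_a2": v2_z, "a_z_a2": a2_z,
        }
    )
    for region in ("ips", "mfg"):
        for met in config.neurochem_age_trend:
            participants[f"{met}_{region}_z_a1"] = chem[region][met]
            participants[f"{met}_{region}_z_a2"] = chem2[region][met]

    # behavioral streams
    trials: dict[str, list[pd.DataFrame]] = {"A1": [], "A2": []}
    moments: dict[str, list[dict]] = {"A1": [], "A2": []}
    wave_latents = {
        "A1": (v_z, a_z, ter_z, np.ones(n, dtype=bool)),
        "A2": (v2_z, a2_z, ter2_z, retained),
    }
    for wave, (vz, az, tz, include) in wave_latents.items():
        for task in TASKS:
            params = _participant_params(config, task, vz, az, tz, rng)
            for i in np.flatnonzero(include):
                base = DiffusionParams(
                    v=params.at[i, "v"], a=params.at[i, "a"],
                    ter=params.at[i, "ter"], s=config.s,
                )
                if config.trial_mode == "simulate":
                    trials[wave].append(
                        _generate_trials(config, pids[i], task, base, rng, wave)
                    )
                mom = ez_forward(base)
                moments[wave].append(
                    {
                        "participant_id": pids[i], "wave": wave, "task": task,
                        "pc": mom.pc, "mrt": mom.mrt, "vrt": mom.vrt,
                        "n": sum(c for _, c in _trial_plan(task)),
                    }
                )
    trial_tables = {
        w: (pd.concat(t, ignore_index=True) if t else pd.DataFrame())
        for w, t in trials.items()
    }
    moment_tables = {w: pd.DataFrame(m) for w, m in moments.items()}

    # MRS streams (both waves)
    truth_rows = []
    for wave, chems, include in (("A1", chem, np.ones(n, dtype=bool)),
                                 ("A2", chem2, retained)):
        for region in ("ips", "mfg"):
            for met in config.neurochem_age_trend:
                mean = config.metabolite_mean[met]
                conc = mean * (1.0 + config.metabolite_cv * chems[region][met])
                for i in np.flatnonzero(include):
                    truth_rows.append(
                        {
                            "participant_id": pids[i], "wave": wave,
                            "region": region, "metabolite": met,
                            "truth_conc": conc[i],
                        }
                    )
    mrs = generate_mrs_observables(pd.DataFrame(truth_rows), config, rng)

    # water-reference series (A1, per participant-region)
    water_rows = []
    t2_mu, t2_sd = config.water_t2_ms
    te_grid = np.asarray(WATER_TE_GRID_MS)
    for pid in pids:
        for region in ("ips", "mfg"):
            t2 = float(np.clip(t2_mu + t2_sd * nz(1)[0] * ns, 30.0, 150.0))
            a_c = float(np.clip(0.10 + 0.03 * nz(1)[0] * ns, 0.0, 0.4))
            ints = water_biexponential(te_grid, t2, 1.0, a_c)
            if config.water_noise_cv > 0:
                ints = ints * (1.0 + config.water_noise_cv * nz(te_grid.size))
            for te, integral in zip(te_grid, ints):
                water_rows.append(
                    {"participant_id": pid, "region": region,
                     "te_ms": te, "integral": integral, "truth_t2": t2}
                )
    water = pd.DataFrame(water_rows)

    # resting-state streams (A1)
    roi: dict[str, pd.DataFrame] = {}
    z_targets = config.conn_base_z + config.conn_sd_z * conn_z
    high_motion = rng.random(n) < config.high_motion_rate
    for i, pid in enumerate(pids):
        ts = _roi_timeseries(z_targets[i], config.n_volumes, rng, config.roi_mode)
        fd = rng.exponential(config.fd_scale_mm, config.n_volumes)
        if high_motion[i]:
            bad = rng.choice(config.n_volumes, size=30, replace=False)
            fd[bad] = 3.0
        ts.insert(0, "fd", fd)
        roi[pid] = ts
    participants["conn_target_z"] = np.arctanh(
        np.clip(np.tanh(z_targets), 0.02, 0.95)
    )
    participants["high_motion"] = high_motion

    truth_info = {
        "config": config.to_dict(),
        "n_participants": int(n),
        "latent_models": {
            "ter": config.ter_model, "v": config.v_model, "a": config.a_model,
            "connectivity": config.connectivity_model, "iq": config.iq_model,
        },
    }
    return SyntheticCohort(
        participants=participants,
        trials=trial_tables,
        moments=moment_tables,
        mrs=mrs,
        water=water,
        roi=roi,
        truth=truth_info,
        config=config,
    )
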