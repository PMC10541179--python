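"""Trial-level QC, EZ-diffusion estimation, and the Wiener simulator.

The EZ-diffusion model maps the three observed moments of a two-choice task —
accuracy ``Pc``, mean correct RT ``MRT`` and variance of correct RTs ``VRT`` —
onto three latent process parameters: drift rate ``v`` (quality of evidence
accumulation, "cognitive processing"), boundary separation ``a`` (response
caution, "decision processing") and non-decision time ``Ter`` (perceptual
encoding plus motor execution, "visuomotor processing").  The closed form is
exactly invertible: :func:`ez_forward` is the algebraic inverse of
:func:`ez_estimate` and serves as the package's internal oracle, while
:func:`simulate_wiener_trials` provides an independent stochastic oracle by
simulating the underlying diffusion process trial by trial.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "MomentSummary",
    "DiffusionParams",
    "TrialQC",
    "TASK_CONDITIONS",
    "TASKS",
    "CONTRAST_CELLS",
    "filter_trials",
    "summarize_trials",
    "ez_estimate",
    "ez_forward",
    "simulate_wiener_trials",
    "condition_contrast",
    "composite_visuomotor",
    "attention_conditions",
    "digit_conditions",
    "rotation_conditions",
    "digit_distance_bin",
]

TRIAL_COLUMNS = ["participant_id", "task", "condition", "correct", "rt"]

TASKS = ("attention", "digit", "rotation")

ATTENTION_CUES = ("no", "central", "double", "spatial")
ATTENTION_FLANKERS = ("congruent", "incongruent", "neutral")


def attention_conditions() -> list[str]:
    """The 12 cue-by-flanker cells of the attention network task."""
    return [f"{c}:{f}" for c in ATTENTION_CUES for f in ATTENTION_FLANKERS]


def digit_conditions() -> list[str]:
    """The 36 unordered pairs of distinct digits 1-9, labelled ``d{i}{j}``."""
    return [f"d{i}{j}" for i, j in itertools.combinations(range(1, 10), 2)]


def digit_distance_bin(condition: str) -> str:
    """Map a digit-pair condition to its distance bin.

    Numerical distance |i - j| <= 3 is "near" (21 pairs), >= 4 is "far"
    (15 pairs); the near/far contrast is the digit task's distance effect.
    """
    i, j = int(condition[1]), int(condition[2])
    return "near" if abs(i - j) <= 3 else "far"


def rotation_conditions() -> list[str]:
    """Rotation angles of the mental rotation task (animal figures)."""
    return ["r45", "r90", "r135"]


TASK_CONDITIONS: dict[str, list[str]] = {
    "attention": attention_conditions(),
    "digit": digit_conditions(),
    "rotation": rotation_conditions(),
}

#: (minuend, subtrahend) condition cells for each contrast, applied to each of
#: v, a and Ter.  Attention cells are cue levels (collapsed over flankers) for
#: alerting/orienting and flanker levels for executive.
CONTRAST_CELLS: dict[str, tuple[str, str]] = {
    "alerting": ("no", "double"),
    "orienting": ("central", "spatial"),
    "executive": ("incongruent", "congruent"),
    "distance": ("far", "near"),
}


@dataclass(frozen=True)
class MomentSummary:
    """Observed moments of one participant-task (or condition) cell."""

    pc: float
    mrt: float
    vrt: float
    n: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.pc <= 1.0:
            raise ValueError(f"Pc must lie in [0, 1], got {self.pc}")
        if self.vrt < 0:
            raise ValueError(f"VRT must be non-negative, got {self.vrt}")


@dataclass(frozen=True)
class DiffusionParams:
    """EZ-diffusion parameters with the diffusion scaling constant ``s``."""

    v: float
    a: float
    ter: float
    s: float = 0.1

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError(f"boundary separation must be positive, got {self.a}")
        if self.s <= 0:
            raise ValueError(f"scaling constant must be positive, got {self.s}")


@dataclass(frozen=True)
class TrialQC:
    """Counts of trials removed by each QC rule."""

    n_removed_fast: int
    n_removed_sd: int


def filter_trials(
    trials: pd.DataFrame, min_rt: float = 0.200, sd_mult: float = 3.0
) -> tuple[pd.DataFrame, TrialQC]:
    """Apply the RT floor and the per-participant 3-SD trial exclusion.

    Trials faster than ``min_rt`` seconds are removed first; then trials whose
    RT lies more than ``sd_mult`` sample SDs from the participant's mean RT
    across *all* conditions (computed on the floor-filtered set) are removed in
    a single pass.  ``trials`` must belong to one participant-task.
    """
    if len(trials) == 0:
        raise ValueError("no trials")
    if sd_mult <= 0:
        raise ValueError("sd_mult must be positive")
    rt = trials["rt"].to_numpy(dtype=float)
    if not np.all(np.isfinite(rt)) or np.any(rt <= 0):
        raise ValueError("reaction times must be finite and positive")

    keep_fast = rt >= min_rt
    n_fast = int((~keep_fast).sum())
    kept = trials.loc[keep_fast]
    if len(kept) == 0:
        raise ValueError("participant unusable")

    rt_kept = kept["rt"].to_numpy(dtype=float)
    if len(rt_kept) > 1:
        mu, sd = rt_kept.mean(), rt_kept.std(ddof=1)
    else:
        mu, sd = rt_kept.mean(), 0.0
    keep_sd = np.abs(rt_kept - mu) <= sd_mult * sd
    n_sd = int((~keep_sd).sum())
    out = kept.loc[keep_sd]
    if len(out) == 0:
        raise ValueError("participant unusable")
    return out, TrialQC(n_removed_fast=n_fast, n_removed_sd=n_sd)


def summarize_trials(trials: pd.DataFrame) -> MomentSummary:
    """Collapse filtered trials to (Pc, MRT, VRT, n).

    Accuracy is computed over all trials; the RT mean and the unbiased
    (n-1 denominator) RT variance over correct trials only.
    """
    if len(trials) == 0:
        raise ValueError("no trials")
    correct = trials["correct"].to_numpy(dtype=bool)
    n = len(trials)
    pc = float(correct.sum()) / n
    rts = trials.loc[correct, "rt"].to_numpy(dtype=float)
    if rts.size == 0:
        raise ValueError("no correct RTs")
    if rts.size == 1:
        raise ValueError("single correct trial: RT variance undefined")
    return MomentSummary(pc=pc, mrt=float(rts.mean()), vrt=float(rts.var(ddof=1)), n=n)


def _edge_correct(pc: float, n: int | None) -> float:
    if pc in (0.0, 0.5, 1.0):
        if n is None or n < 1:
            raise ValueError("edge-corrected Pc requires the trial count n")
        half = 1.0 / (2.0 * n)
        pc = {0.0: half, 1.0: 1.0 - half, 0.5: 0.5 + half}[pc]
    if pc == 0.5:
        raise ValueError("chance-level participant")
    return pc


def ez_estimate(summary: MomentSummary, s: float = 0.1) -> DiffusionParams:
    """Closed-form EZ estimates (v, a, Ter) from one moment summary.

    Edge cases of accuracy (0, 0.5, 1) are shifted by the half-count rule
    ``1/(2n)`` before taking the logit.
    """
    if summary.vrt <= 0:
        raise ValueError("VRT must be positive for EZ estimation")
    pc = _edge_correct(summary.pc, summary.n)
    L = np.log(pc / (1.0 - pc))
    x = L * (L * pc**2 - L * pc + pc - 0.5) / summary.vrt
    v = float(np.sign(pc - 0.5) * s * x**0.25)
    a = float(s**2 * L / v)
    y = -v * a / s**2
    mdt = (a / (2.0 * v)) * (1.0 - np.exp(y)) / (1.0 + np.exp(y))
    ter = float(summary.mrt - mdt)
    return DiffusionParams(v=v, a=a, ter=ter, s=s)


def ez_forward(params: DiffusionParams) -> MomentSummary:
    """Exact algebraic inverse of :func:`ez_estimate`.

    Maps (v, a, Ter) to the moments (Pc, MRT, VRT) the EZ equations would
    reproduce; ``ez_estimate(ez_forward(p)) == p`` to machine precision.
    """
    v, a, s = params.v, params.a, params.s
    if v == 0:
        raise ValueError("forward moments undefined at v = 0")
    y = np.exp(-v * a / s**2)
    pc = 1.0 / (1.0 + y)
    mrt = params.ter + (a / (2.0 * v)) * (1.0 - y) / (1.0 + y)
    L = np.log(pc / (1.0 - pc))
    vrt = L * (L * pc**2 - L * pc + pc - 0.5) / (v / s) ** 4
    return MomentSummary(pc=float(pc), mrt=float(mrt), vrt=float(vrt))


def simulate_wiener_trials(
    params: DiffusionParams,
    n_trials: int,
    dt: float = 0.001,
    seed: int | np.random.Generator | None = None,
    participant_id: str = "sim",
    task: str = "attention",
    condition: str = "sim",
    max_time: float = 20.0,
) -> pd.DataFrame:
    """Simulate first-passage trials of the Wiener process between 0 and ``a``.

    Euler-Maruyama with step ``dt``: the accumulator starts unbiased at
    ``a/2`` and gains Normal(v*dt, s^2*dt) increments until it is absorbed at
    ``a`` (correct) or 0 (error); the trial RT is the first-passage time plus
    ``Ter``.  Interior boundary crossings between grid points are recovered
    with the Brownian-bridge correction (crossing probability
    ``exp(-2*d0*d1/(s^2*dt))`` for endpoint distances d0, d1 from the
    boundary), which removes the leading discretization bias of plain Euler
    absorption checks.  Reproducible given ``seed``.
    """
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    if dt <= 0:
        raise ValueError("dt must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    v, a, s = params.v, params.a, params.s
    pos = np.full(n_trials, a / 2.0)
    active = np.arange(n_trials)
    rt = np.empty(n_trials)
    correct = np.empty(n_trials, dtype=bool)
    sqrt_dt = np.sqrt(dt)
    two_over_s2dt = 2.0 / (s * s * dt)
    max_steps = int(np.ceil(max_time / dt))
    for step in range(1, max_steps + 1):
        prev = pos.copy()
        pos = pos + rng.normal(v * dt, s * sqrt_dt, size=pos.shape)
        hi = pos >= a
        lo = pos <= 0.0
        inside = ~(hi | lo)
        if inside.any():
            # bridge crossing probabilities for paths inside at both ends
            p_up = np.exp(-two_over_s2dt * (a - prev[inside]) * (a - pos[inside]))
            p_dn = np.exp(-two_over_s2dt * prev[inside] * pos[inside])
            u = rng.random((2, p_up.size))
            bridge_hi = u[0] < p_up
            bridge_lo = u[1] < p_dn
            both = bridge_hi & bridge_lo
            if both.any():
                up_wins = p_up >= p_dn
                bridge_hi &= ~both | up_wins
                bridge_lo &= ~both | ~up_wins
            hi[inside] |= bridge_hi
            lo[inside] |= bridge_lo & ~bridge_hi
        done = hi | lo
        if done.any():
            idx = active[done]
            rt[idx] = step * dt + params.ter
            correct[idx] = hi[done]
            active = active[~done]
            pos = pos[~done]
        if active.size == 0:
            break
    else:
        raise RuntimeError(
            f"{active.size} trials unabsorbed after {max_time} s; "
            "increase max_time or check parameters"
        )
    return pd.DataFrame(
        {
            "participant_id": participant_id,
            "task": task,
            "condition": condition,
            "correct": correct,
            "rt": rt,
        }
    )


def condition_contrast(
    by_condition: dict[str, DiffusionParams], contrast: str
) -> dict[str, float]:
    """Difference of diffusion parameters between two condition cells.

    ``alerting = no-cue - double-cue``, ``orienting = central - spatial``,
    ``executive = incongruent - congruent``, ``distance = far - near`` (the
    rotation task's distance contrast uses 135 vs 45 degrees; pass those cells
    under the "far"/"near" keys or use explicit cells).  Returns the contrast
    on each of v, a and Ter.
    """
    if contrast not in CONTRAST_CELLS:
        raise ValueError(f"unknown contrast {contrast!r}")
    minuend, subtrahend = CONTRAST_CELLS[contrast]
    for cell in (minuend, subtrahend):
        if cell not in by_condition:
            raise ValueError(f"missing condition cell {cell!r} for contrast {contrast!r}")
    p1, p0 = by_condition[minuend], by_condition[subtrahend]
    return {"v": p1.v - p0.v, "a": p1.a - p0.a, "ter": p1.ter - p0.ter}


def composite_visuomotor(ter_by_task: pd.DataFrame) -> pd.Series:
    """Mean of per-task z-scored non-decision times.

    ``ter_by_task`` is participants x tasks (columns attention, digit,
    rotation).  Each task's Ter is z-scored across the analysis sample
    (sample SD, n-1 denominator) and the three z-scores averaged; participants
    missing any task are dropped (listwise).
    """
    missing = [t for t in TASKS if t not in ter_by_task.columns]
    if missing:
        raise ValueError(f"missing task column(s): {missing}")
    complete = ter_by_task.loc[:, list(TASKS)].dropna()
    z = pd.DataFrame(index=complete.index)
    for task in TASKS:
        col = complete[task]
        sd = col.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"zero cohort SD for task {task!r}")
        z[task] = (col - col.mean()) / sd
    return z.mean(axis=1).rename("composite_ter")
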