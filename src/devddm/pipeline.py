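"""End-to-end orchestration: QC -> estimation -> corrections -> models.

Stage order is fixed: trial QC, EZ estimation, contrasts and the composite
visuomotor score, MRS corrections and exclusions, connectivity scoring, the
per-age-band 3-SD screens, the enumerated regression families (first
assessment with 36-hypothesis FDR, second-assessment replication
uncorrected, longitudinal prediction with its own 36-hypothesis FDR), ±1 SD
interaction probing, and the two moderated mediations (connectivity mediating
neurochemistry -> visuomotor processing; visuomotor processing mediating
neurochemistry -> intelligence).  All randomness flows from the run seed and
every exclusion is tallied in the run manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .behavior import (
    composite_visuomotor,
    condition_contrast,
    ez_estimate,
    filter_trials,
    summarize_trials,
    MomentSummary,
    TASKS,
)
from .cohort import CohortConfig, SyntheticCohort, generate_cohort
from .connectivity import connectivity_score
from .inference import (
    ModeratedRegression,
    bootstrap_inference,
    exclude_by_residuals,
    fdr_adjust,
    probe_interaction,
    screen_outliers,
)
from .mediation import Model59Mediation
from .mrs import apply_mrs_exclusions, fit_water_t2, t2_correct, tissue_correct

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "estimate_parameters",
    "estimate_from_moments",
    "compute_contrasts",
    "mrs_stage",
    "connectivity_stage",
    "assemble_table",
    "run_pipeline",
    "read_trials_csv",
    "write_trials_csv",
    "read_mrs_csv",
    "read_roi_csv",
]

NEUROCHEMICALS = ("gaba", "glutamate", "naa")
REGIONS = ("ips", "mfg")
PARAM_LABELS = {"v": "drift_rate", "a": "boundary_separation", "ter": "ndt"}


@dataclass
class PipelineConfig:
    """Tunable analysis settings (defaults follow the study conventions)."""

    min_rt_s: float = 0.200
    trial_sd_mult: float = 3.0
    ez_scaling: float = 0.1
    apply_t2_correction: bool = False
    highpass_hz: float | None = 0.01
    fd_threshold_mm: float = 2.0
    max_censored_frac: float = 0.05
    screen_sd: float = 3.0
    n_boot: int = 5000
    ci_level: float = 95.0
    mediation_ci_level: float = 90.0
    run_a2: bool = True
    run_longitudinal: bool = True

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    seed: int | None
    config_hash: str
    software_version: str
    inputs: dict = field(default_factory=dict)
    exclusions: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)
    stages: list = field(default_factory=list)

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str))


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------


def read_trials_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df = df.rename(columns={"rt_s": "rt"})
    df["correct"] = df["correct"].astype(bool)
    return df


def write_trials_csv(trials: pd.DataFrame, path) -> None:
    out = trials.rename(columns={"rt": "rt_s"}).copy()
    out["correct"] = out["correct"].astype(int)
    out.to_csv(path, index=False)


def read_mrs_csv(path) -> pd.DataFrame:
    return pd.read_csv(path).rename(columns={"crlb_pct": "crlb"})


def read_roi_csv(path) -> dict[str, pd.DataFrame]:
    df = pd.read_csv(path)
    out = {}
    for pid, grp in df.groupby("participant_id"):
        grp = grp.sort_values("frame")
        ts = grp.drop(columns=["participant_id", "frame"]).rename(
            columns={"fd_mm": "fd"}
        )
        out[str(pid)] = ts.reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def estimate_parameters(
    trials: pd.DataFrame,
    min_rt: float = 0.200,
    sd_mult: float = 3.0,
    s: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per participant-task trial QC, moments and EZ parameters.

    Trials are collapsed across conditions (the study's main-text
    convention).  Returns the parameter table and a log of participant-tasks
    that could not be estimated.
    """
    rows, failures = [], []
    group_cols = ["participant_id", "task"] + (
        ["wave"] if "wave" in trials.columns else []
    )
    for key, grp in trials.groupby(group_cols):
        key = dict(zip(group_cols, key if isinstance(key, tuple) else (key,)))
        try:
            kept, qc = filter_trials(grp, min_rt=min_rt, sd_mult=sd_mult)
            summ = summarize_trials(kept)
            params = ez_estimate(summ, s=s)
        except (ValueError, FloatingPointError) as err:
            failures.append({**key, "reason": str(err)})
            continue
        rows.append(
            {
                **key,
                "v": params.v, "a": params.a, "ter": params.ter,
                "pc": summ.pc, "mrt": summ.mrt, "vrt": summ.vrt,
                "n_trials": summ.n,
                "n_removed_fast": qc.n_removed_fast,
                "n_removed_sd": qc.n_removed_sd,
            }
        )
    return pd.DataFrame(rows), pd.DataFrame(failures)


def estimate_from_moments(moments: pd.DataFrame, s: float = 0.1) -> pd.DataFrame:
    """EZ parameters straight from a (pc, mrt, vrt, n) moment table."""
    rows = []
    for _, row in moments.iterrows():
        params = ez_estimate(
            MomentSummary(pc=row["pc"], mrt=row["mrt"], vrt=row["vrt"],
                          n=int(row["n"])),
            s=s,
        )
        rows.append({**row.to_dict(), "v": params.v, "a": params.a,
                     "ter": params.ter})
    return pd.DataFrame(rows)


def _attention_cell_params(grp, min_rt, sd_mult, s, by):
    """EZ parameters per cue or flanker cell of one participant's trials."""
    out = {}
    labels = grp["condition"].str.split(":", expand=True)
    cells = labels[0] if by == "cue" else labels[1]
    for cell, sub in grp.groupby(cells):
        try:
            kept, _ = filter_trials(sub, min_rt=min_rt, sd_mult=sd_mult)
            out[cell] = ez_estimate(summarize_trials(kept), s=s)
        except ValueError:
            continue
    return out


def compute_contrasts(
    trials: pd.DataFrame,
    min_rt: float = 0.200,
    sd_mult: float = 3.0,
    s: float = 0.1,
) -> pd.DataFrame:
    """Attention-network and distance contrast scores per participant.

    Alerting/orienting use cue-level cells, executive uses flanker-level
    cells, the digit distance effect contrasts far vs near pairs and the
    rotation distance effect 135 vs 45 degrees.
    """
    from .behavior import digit_distance_bin

    rows = []
    for (pid, task), grp in trials.groupby(["participant_id", "task"]):
        cell_sets: list[tuple[str, dict]] = []
        if task == "attention":
            cue_cells = _attention_cell_params(grp, min_rt, sd_mult, s, "cue")
            fl_cells = _attention_cell_params(grp, min_rt, sd_mult, s, "flanker")
            cell_sets = [("alerting", cue_cells), ("orienting", cue_cells),
                         ("executive", fl_cells)]
        elif task == "digit":
            cells = {}
            bins = grp["condition"].map(digit_distance_bin)
            for cell, sub in grp.groupby(bins):
                try:
                    kept, _ = filter_trials(sub, min_rt=min_rt, sd_mult=sd_mult)
                    cells[cell] = ez_estimate(summarize_trials(kept), s=s)
                except ValueError:
                    continue
            cell_sets = [("distance", cells)]
        elif task == "rotation":
            cells = {}
            for cell, sub in grp.groupby(grp["condition"]):
                try:
                    kept, _ = filter_trials(sub, min_rt=min_rt, sd_mult=sd_mult)
                    cells[cell] = ez_estimate(summarize_trials(kept), s=s)
                except ValueError:
                    continue
            # 135 - 45 degrees is the rotation distance contrast
            cells = {"far": cells.get("r135"), "near": cells.get("r45")}
            cells = {k: p for k, p in cells.items() if p is not None}
            cell_sets = [("distance", cells)]
        for contrast, cells in cell_sets:
            try:
                diff = condition_contrast(cells, contrast)
            except ValueError:
                continue
            for param, value in diff.items():
                rows.append(
                    {"participant_id": pid, "task": task, "contrast": contrast,
                     "parameter": param, "value": value}
                )
    return pd.DataFrame(rows)


def mrs_stage(
    mrs: pd.DataFrame,
    water: pd.DataFrame | None = None,
    apply_t2: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Corrections and exclusions; returns a wide per-participant table.

    Tissue (partial-volume) correction always; the T2 correction additionally
    when ``apply_t2`` and a water-reference table is supplied (the tissue
    water T2 is fitted per participant-region from the 13-echo series).
    Output columns are ``{metabolite}_{region}`` per participant-wave.
    """
    df = mrs.copy()
    df["conc"] = tissue_correct(
        df["raw_conc"], df["f_gm"], df["f_wm"], df["f_csf"]
    )
    if apply_t2 and water is not None:
        t2_by_key = {}
        for (pid, region), grp in water.groupby(["participant_id", "region"]):
            fit = fit_water_t2(grp["te_ms"], grp["integral"])
            t2_by_key[(pid, region)] = fit.t2_tissue_ / 1000.0  # ms -> s
        t2 = df.set_index(["participant_id", "region"]).index.map(t2_by_key.get)
        df["conc"] = [
            t2_correct(c, te, t) if t is not None else np.nan
            for c, te, t in zip(df["conc"], df["te_s"], t2)
        ]
    survivors, log = apply_mrs_exclusions(df)
    wide = survivors.pivot_table(
        index=["participant_id", "wave"],
        columns=["metabolite", "region"],
        values="conc",
        aggfunc="first",
    )
    wide.columns = [f"{met}_{reg}" for met, reg in wide.columns]
    return wide.reset_index(), log


def connectivity_stage(
    roi: dict[str, pd.DataFrame],
    highpass_hz: float | None = 0.01,
    fd_threshold: float = 2.0,
    max_frac: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Visuomotor connectivity score per participant plus an exclusion log."""
    rows, excl = [], []
    for pid, ts in roi.items():
        fd = ts["fd"].to_numpy() if "fd" in ts.columns else None
        series = ts.drop(columns=["fd"], errors="ignore")
        try:
            score = connectivity_score(
                series, fd=fd, highpass_hz=highpass_hz,
                fd_threshold=fd_threshold, max_frac=max_frac,
                participant_id=pid,
            )
        except ValueError as err:
            excl.append({"participant_id": pid, "reason": str(err)})
            continue
        rows.append(
            {"participant_id": pid, "conn": score.z,
             "frac_censored": score.frac_censored}
        )
    return pd.DataFrame(rows), pd.DataFrame(excl)


def assemble_table(
    params: pd.DataFrame,
    neurochem: pd.DataFrame,
    connectivity: pd.DataFrame,
    participants: pd.DataFrame,
) -> pd.DataFrame:
    """Merge all streams into one row per participant analysis table.

    Behavioral parameters become ``{v,a,ter}_{task}_{wave}`` columns,
    neurochemistry ``{metabolite}_{region}_{wave}``, and the composite
    visuomotor score is added per wave when all three tasks are present.
    """
    wide = participants.copy()
    has_wave = "wave" in params.columns
    for wave in ("A1", "A2"):
        sub = params[params["wave"] == wave] if has_wave else (
            params if wave == "A1" else params.iloc[0:0]
        )
        if len(sub) == 0:
            continue
        suffix = wave.lower()
        piv = sub.pivot_table(index="participant_id", columns="task",
                              values=["v", "a", "ter"], aggfunc="first")
        piv.columns = [f"{p}_{t}_{suffix}" for p, t in piv.columns]
        wide = wide.merge(piv.reset_index(), on="participant_id", how="left")
        ter_cols = {t: f"ter_{t}_{suffix}" for t in TASKS}
        if all(c in wide.columns for c in ter_cols.values()):
            ter_by_task = wide.set_index("participant_id")[
                list(ter_cols.values())
            ].rename(columns={v: k for k, v in ter_cols.items()})
            comp = composite_visuomotor(ter_by_task)
            wide = wide.merge(
                comp.rename(f"composite_ter_{suffix}").reset_index(),
                on="participant_id", how="left",
            )
    for wave in ("A1", "A2"):
        sub = neurochem[neurochem["wave"] == wave]
        if len(sub) == 0:
            continue
        sub = sub.drop(columns=["wave"])
        sub.columns = ["participant_id"] + [
            f"{c}_{wave.lower()}" for c in sub.columns[1:]
        ]
        wide = wide.merge(sub, on="participant_id", how="left")
    conn = connectivity.rename(columns={"conn": "conn_a1"})
    wide = wide.merge(conn[["participant_id", "conn_a1"]],
                      on="participant_id", how="left")
    return wide


def _family_models(wave: str) -> list[dict]:
    """The 18 single-assessment models (36 hypotheses) of one family."""
    w = wave.lower()
    controls = {"v": ("a", "ter"), "a": ("v", "ter"), "ter": ("v", "a")}
    models = []
    for param, (c1, c2) in controls.items():
        for region in REGIONS:
            for chem in NEUROCHEMICALS:
                nt = f"{chem}_{region}_{w}"
                models.append(
                    {
                        "spec_id": f"{wave}:{PARAM_LABELS[param]}:{chem}:{region}",
                        "dependent": f"{param}_attention_{w}",
                        "terms": [nt, f"age_{w}", f"{nt}:age_{w}",
                                  f"{c1}_attention_{w}", f"{c2}_attention_{w}"],
                        "hypotheses": {"interaction": f"{nt}:age_{w}",
                                       "main_effect": nt},
                    }
                )
    return models


def _longitudinal_models() -> list[dict]:
    """Longitudinal models: first-assessment predictors of later scores."""
    controls = {"v": ("a", "ter"), "a": ("v", "ter"), "ter": ("v", "a")}
    models = []
    for param, (c1, c2) in controls.items():
        for region in REGIONS:
            for chem in NEUROCHEMICALS:
                nt = f"{chem}_{region}_a1"
                models.append(
                    {
                        "spec_id": f"long:{PARAM_LABELS[param]}:{chem}:{region}",
                        "dependent": f"{param}_attention_a2",
                        "terms": [
                            nt, "age_a1", f"{nt}:age_a1",
                            f"{c1}_attention_a1", f"{c2}_attention_a1",
                            f"{c1}_attention_a2", f"{c2}_attention_a2",
                            "age_a2",
                        ],
                        "hypotheses": {"interaction": f"{nt}:age_a1",
                                       "main_effect": nt},
                    }
                )
    return models


def _run_family(
    family_id: str,
    models: list[dict],
    table: pd.DataFrame,
    cfg: PipelineConfig,
    rng: np.random.Generator,
    apply_fdr: bool,
) -> pd.DataFrame:
    rows = []
    for spec in models:
        model = ModeratedRegression(spec["dependent"], spec["terms"])
        try:
            model = model.fit(table)
            model, _excluded = exclude_by_residuals(model, table, cfg.screen_sd)
            boot = bootstrap_inference(
                model, table.loc[model.used_index_],
                B=cfg.n_boot, level=cfg.ci_level, seed=rng,
            )
        except (ValueError, np.linalg.LinAlgError) as err:
            rows.append({"family_id": family_id, "spec_id": spec["spec_id"],
                         "term": None, "error": str(err)})
            continue
        for effect, term in spec["hypotheses"].items():
            rec = boot.table.loc[term]
            rows.append(
                {
                    "family_id": family_id,
                    "spec_id": spec["spec_id"],
                    "effect_type": effect,
                    "term": term,
                    "beta": rec["beta"],
                    "ci_low": rec["ci_low"],
                    "ci_high": rec["ci_high"],
                    "p_bo": rec["p_bo"],
                    "n_used": model.n_used_,
                }
            )
    out = pd.DataFrame(rows)
    if apply_fdr and "p_bo" in out.columns:
        ok = out["p_bo"].notna()
        out.loc[ok, "q"] = fdr_adjust(out.loc[ok, "p_bo"].to_numpy())
    return out


def run_pipeline(
    out_dir,
    cohort: SyntheticCohort | None = None,
    inputs: dict | None = None,
    pipeline_config: PipelineConfig | None = None,
    cohort_config: CohortConfig | None = None,
    seed: int | None = 0,
) -> RunManifest:
    """Execute the full analysis chain and write result tables.

    ``cohort`` (a generated synthetic study) or ``inputs`` (a dict with
    'trials', 'mrs', optional 'water', 'roi', 'participants' frames) supplies
    the data; with neither, a cohort is generated from ``cohort_config`` and
    ``seed``.  Writes CSV result tables plus a JSON manifest to ``out_dir``.
    """
    cfg = pipeline_config or PipelineConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    manifest = RunManifest(
        seed=seed,
        config_hash=hashlib.sha256(
            json.dumps(cfg.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16],
        software_version=__version__,
    )

    if cohort is None and inputs is None:
        cohort = generate_cohort(cohort_config, seed=rng)
    if cohort is not None:
        trials = pd.concat(
            [t for t in cohort.trials.values() if len(t)], ignore_index=True
        )
        mrs, water, roi = cohort.mrs, cohort.water, cohort.roi
        participants = cohort.participants[
            ["participant_id", "age_a1", "age_a2", "age_band", "iq_a1", "iq_a2"]
        ].copy()
    else:
        trials = inputs["trials"]
        mrs = inputs["mrs"]
        water = inputs.get("water")
        roi = inputs.get("roi", {})
        participants = inputs["participants"]
    manifest.inputs = {"n_trials": int(len(trials)), "n_mrs_records": int(len(mrs)),
                       "n_roi_participants": len(roi),
                       "n_participants": int(len(participants))}

    # --- behavior ---------------------------------------------------------
    manifest.stages.append("trial_qc_ez")
    params, failures = estimate_parameters(
        trials, min_rt=cfg.min_rt_s, sd_mult=cfg.trial_sd_mult, s=cfg.ez_scaling
    )
    missing_tasks = [t for t in TASKS if t not in set(params["task"])]
    if missing_tasks:
        manifest.write(out_dir / "manifest.json")
        raise ValueError(
            f"task(s) {missing_tasks} missing from the trial stream; the "
            "composite visuomotor score needs all three tasks"
        )
    params.to_csv(out_dir / "diffusion_parameters.csv", index=False)
    manifest.exclusions["behavior_unusable"] = int(len(failures))

    manifest.stages.append("contrasts")
    a1_trials = trials[trials["wave"] == "A1"] if "wave" in trials.columns else trials
    contrasts = compute_contrasts(
        a1_trials, min_rt=cfg.min_rt_s, sd_mult=cfg.trial_sd_mult, s=cfg.ez_scaling
    )
    contrasts.to_csv(out_dir / "contrast_scores.csv", index=False)

    # --- MRS --------------------------------------------------------------
    manifest.stages.append("mrs_corrections")
    neurochem, mrs_log = mrs_stage(mrs, water, apply_t2=cfg.apply_t2_correction)
    manifest.exclusions["mrs_records"] = int(len(mrs_log))

    # --- connectivity -----------------------------------------------------
    manifest.stages.append("connectivity")
    conn, conn_log = connectivity_stage(
        roi, highpass_hz=cfg.highpass_hz,
        fd_threshold=cfg.fd_threshold_mm, max_frac=cfg.max_censored_frac,
    )
    manifest.exclusions["connectivity_participants"] = int(len(conn_log))

    # --- assemble + screen ------------------------------------------------
    manifest.stages.append("assemble_screen")
    table = assemble_table(params, neurochem, conn, participants)
    if "age_band" not in table.columns:
        from .inference import age_band
        table["age_band"] = table["age_a1"].map(age_band)
    screen_vars = [
        c for c in table.columns
        if c.startswith(("v_", "a_", "ter_", "composite_ter", "conn",
                         "gaba_", "glutamate_", "naa_")) or c in ("iq_a1", "iq_a2")
    ]
    table, screen_log = screen_outliers(
        table, screen_vars, group_col="age_band", sd_mult=cfg.screen_sd
    )
    manifest.exclusions["screened_values"] = int(len(screen_log))
    table.to_csv(out_dir / "analysis_table.csv", index=False)

    # --- regression families ---------------------------------------------
    manifest.stages.append("families")
    family_frames = [
        _run_family("A1", _family_models("A1"), table, cfg, rng, apply_fdr=True)
    ]
    if cfg.run_a2 and "ter_attention_a2" in table.columns:
        family_frames.append(
            _run_family("A2", _family_models("A2"), table, cfg, rng,
                        apply_fdr=False)
        )
    if cfg.run_longitudinal and "ter_attention_a2" in table.columns:
        family_frames.append(
            _run_family("longitudinal", _longitudinal_models(), table, cfg,
                        rng, apply_fdr=True)
        )
    families = pd.concat(family_frames, ignore_index=True)
    families.to_csv(out_dir / "family_results.csv", index=False)

    # --- connectivity models --------------------------------------------- 
    manifest.stages.append("connectivity_models")
    conn_rows = []
    conn_to_vm = ModeratedRegression(
        "composite_ter_a1", ["conn_a1", "age_a1", "conn_a1:age_a1"]
    )
    specs = [("conn_to_vm", conn_to_vm)]
    for chem in ("glutamate", "gaba"):
        specs.append(
            (f"nt_to_conn:{chem}",
             ModeratedRegression(
                 "conn_a1",
                 [f"{chem}_ips_a1", "age_a1", f"{chem}_ips_a1:age_a1"],
             ))
        )
    for spec_id, model in specs:
        model = model.fit(table)
        model, _ = exclude_by_residuals(model, table, cfg.screen_sd)
        boot = bootstrap_inference(
            model, table.loc[model.used_index_], B=cfg.n_boot,
            level=cfg.ci_level, seed=rng,
        )
        for term, rec in boot.table.iterrows():
            conn_rows.append({"spec_id": spec_id, "term": term,
                              "n_used": model.n_used_, **rec.to_dict()})
    pd.DataFrame(conn_rows).to_csv(out_dir / "connectivity_models.csv", index=False)

    # probe + plot the connectivity-by-age interaction as the example figure
    probe = probe_interaction(conn_to_vm.fit(table), "conn_a1", "age_a1")
    probe.to_csv(out_dir / "probe_conn_to_vm.csv", index=False)
    from .inference import plot_interaction
    plot_interaction(probe, "conn_a1", "composite_ter_a1",
                     path=out_dir / "probe_conn_to_vm.png")

    # --- mediations ------------------------------------------------------ 
    manifest.stages.append("mediations")
    med_rows = []
    mediations = [
        ("mediation_conn", "conn_a1", "composite_ter_a1"),
        ("mediation_iq", "composite_ter_a1", "iq_a1"),
    ]
    for label, m_col, y_col in mediations:
        for chem in ("gaba", "glutamate"):
            est = Model59Mediation(
                x=f"{chem}_ips_a1", m=m_col, y=y_col, w="age_a1"
            ).fit(table)
            res = est.bootstrap(
                table, B=cfg.n_boot, level=cfg.mediation_ci_level, seed=rng
            )
            res.insert(0, "spec_id", f"{label}:{chem}")
            med_rows.append(res)
    pd.concat(med_rows, ignore_index=True).to_csv(
        out_dir / "mediation_results.csv", index=False
    )

    manifest.outputs = sorted(
        str(p.name) for p in out_dir.iterdir() if p.suffix == ".csv"
    )
    manifest.write(out_dir / "manifest.json")
    return manifest
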