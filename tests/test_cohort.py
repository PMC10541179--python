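"""The synthetic study: designs, determinism, inversion round trips."""

import numpy as np
import pandas as pd
import pytest

from devddm.behavior import TASK_CONDITIONS
from devddm.cohort import (
    CohortConfig,
    TER_IPS_GABA_COEFFS,
    M59_GABA_INTELLIGENCE,
    generate_cohort,
    generate_moderation_sample,
    generate_intelligence,
    generate_model59_sample,
    generate_mrs_observables,
)
from devddm.mrs import WATER_TE_GRID_MS, apply_mrs_exclusions, fit_water_t2, tissue_correct


def tiny_config(**overrides):
    base = dict(
        band_sizes={b: 1 for b in ("6-7", "10-11", "14-15", "16-17", "18+")},
        retention_a2=1.0,
        high_motion_rate=0.0,
    )
    base.update(overrides)
    return CohortConfig(**base)


@pytest.fixture(scope="module")
def tiny_cohort():
    return generate_cohort(tiny_config(), seed=11)


class TestTrialDesigns:
    def test_attention_block_matches_printed_design(self, tiny_cohort):
        att = tiny_cohort.trials["A1"].query("task == 'attention'")
        per_part = att.groupby("participant_id")
        assert (per_part.size() == 96).all()
        counts = att.groupby(["participant_id", "condition"]).size()
        assert (counts == 8).all()
        assert set(att["condition"]) == set(TASK_CONDITIONS["attention"])
        assert len(TASK_CONDITIONS["attention"]) == 12

    def test_digit_task_covers_all_pairs_twice(self, tiny_cohort):
        dig = tiny_cohort.trials["A1"].query("task == 'digit'")
        assert (dig.groupby("participant_id").size() == 72).all()
        counts = dig.groupby(["participant_id", "condition"]).size()
        assert (counts == 2).all()
        assert len(TASK_CONDITIONS["digit"]) == 36

    def test_rotation_task_design(self, tiny_cohort):
        rot = tiny_cohort.trials["A1"].query("task == 'rotation'")
        assert (rot.groupby("participant_id").size() == 72).all()
        counts = rot.groupby(["participant_id", "condition"]).size()
        assert (counts == 24).all()


class TestDeterminism:
    def test_same_seed_regenerates_bit_identically(self):
        c1 = generate_cohort(tiny_config(), seed=5)
        c2 = generate_cohort(tiny_config(), seed=5)
        pd.testing.assert_frame_equal(c1.participants, c2.participants)
        pd.testing.assert_frame_equal(c1.trials["A1"], c2.trials["A1"])
        pd.testing.assert_frame_equal(c1.mrs, c2.mrs)
        pid = c1.participants["participant_id"].iloc[0]
        pd.testing.assert_frame_equal(c1.roi[pid], c2.roi[pid])

    def test_regression_generators_are_seed_stable(self):
        a = generate_moderation_sample(50, TER_IPS_GABA_COEFFS, seed=3)
        b = generate_moderation_sample(50, TER_IPS_GABA_COEFFS, seed=3)
        pd.testing.assert_frame_equal(a, b)
        a = generate_model59_sample(50, M59_GABA_INTELLIGENCE, seed=3)
        b = generate_model59_sample(50, M59_GABA_INTELLIGENCE, seed=3)
        pd.testing.assert_frame_equal(a, b)


class TestUnitVariance:
    def test_generated_variables_have_unit_population_variance(self):
        df = generate_moderation_sample(200_000, TER_IPS_GABA_COEFFS, seed=0)
        assert df["y"].var() == pytest.approx(1.0, abs=0.02)
        df = generate_model59_sample(200_000, M59_GABA_INTELLIGENCE, seed=0)
        assert df["m"].var() == pytest.approx(1.0, abs=0.02)
        assert df["y"].var() == pytest.approx(1.0, abs=0.02)

    def test_overloaded_coefficients_rejected(self):
        bad = dict(TER_IPS_GABA_COEFFS, age=0.99)
        with pytest.raises(ValueError, match="< 1"):
            generate_moderation_sample(10, bad)


class TestMrsObservables:
    def test_partial_volume_inversion_round_trip(self, tiny_cohort):
        mrs = tiny_cohort.mrs
        rec = tissue_correct(mrs["raw_conc"], mrs["f_gm"], mrs["f_wm"],
                             mrs["f_csf"])
        np.testing.assert_allclose(rec, mrs["truth_conc"], atol=1e-10)

    def test_planted_quality_violators_are_flagged(self, rng):
        truth = pd.DataFrame(
            {
                "participant_id": [f"P{i}" for i in range(30)],
                "wave": "A1",
                "region": "ips",
                "metabolite": "gaba",
                "truth_conc": 2.0,
            }
        )
        recs = generate_mrs_observables(truth, CohortConfig(), rng, plant_crlb=3)
        _, log = apply_mrs_exclusions(recs)
        assert (log["reason"] == "crlb_not_detectable").sum() == 3

    def test_water_series_round_trip(self, tiny_cohort):
        grp = tiny_cohort.water.groupby(["participant_id", "region"])
        (pid, region), sub = next(iter(grp))
        fit = fit_water_t2(sub["te_ms"], sub["integral"])
        assert sorted(sub["te_ms"]) == list(WATER_TE_GRID_MS)
        assert fit.t2_tissue_ == pytest.approx(sub["truth_t2"].iloc[0], rel=1e-6)


class TestIntelligence:
    def test_scores_bounded_and_monotone(self, rng):
        latent = np.sort(rng.standard_normal(500) * 2)
        scores = generate_intelligence(latent, rng)
        assert scores.min() >= 0 and scores.max() <= 30
        assert np.all(np.diff(scores) >= 0)

    def test_null_paths_decouple_scores_from_neurochemistry(self):
        cfg = tiny_config(
            band_sizes={b: 120 for b in ("6-7", "10-11", "14-15", "16-17", "18+")},
            retention_a2=0.0,
            trial_mode="analytic",
            iq_model={"age": 0.0, "glutamate": 0.0, "gaba": 0.0,
                      "glutamate:age": 0.0, "gaba:age": 0.0,
                      "ter": 0.0, "ter:age": 0.0},
        )
        cohort = generate_cohort(cfg, seed=21)
        tbl = cohort.participants
        r = np.corrcoef(tbl["iq_a1"], tbl["gaba_ips_z_a1"])[0, 1]
        assert abs(r) < 0.12  # ~3 sigma at n = 600


class TestExactRecoveryChain:
    def test_noise_free_outcome_recovers_generating_coefficients(self):
        # measurement chain exactness: analytic moments -> EZ inversion,
        # partial-volume inversion, exact-correlation ROI series; only the
        # non-decision-time equation is made residual-free so its generating
        # coefficients are identified exactly
        from devddm.connectivity import connectivity_score
        from devddm.inference import ModeratedRegression
        from devddm.pipeline import estimate_from_moments

        cfg = tiny_config(
            band_sizes={b: 12 for b in ("6-7", "10-11", "14-15", "16-17", "18+")},
            retention_a2=0.0,
            trial_mode="analytic",
            roi_mode="exact",
            task_dev_sd=0.0,
            tissue_frac_sd=0.0,
            equation_noise={"ter": 0.0},
        )
        cohort = generate_cohort(cfg, seed=4)
        tbl = cohort.participants.set_index("participant_id")

        # behavior: EZ inversion of analytic attention moments -> latent ndt
        params = estimate_from_moments(
            cohort.moments["A1"].query("task == 'attention'")
        ).set_index("participant_id")
        ter_z = (params["ter"] - cfg.ter_base_s["attention"]) / cfg.ter_sd_s

        # MRS: partial-volume inversion -> latent neurochemistry
        mrs = cohort.mrs.query("region == 'ips' and wave == 'A1'")
        conc = tissue_correct(mrs["raw_conc"], mrs["f_gm"], mrs["f_wm"],
                              mrs["f_csf"])
        chem = mrs.assign(conc=conc).pivot_table(
            index="participant_id", columns="metabolite", values="conc"
        )
        glu = (chem["glutamate"] / cfg.metabolite_mean["glutamate"] - 1) / cfg.metabolite_cv
        gaba = (chem["gaba"] / cfg.metabolite_mean["gaba"] - 1) / cfg.metabolite_cv

        # connectivity: exact sample equicorrelation -> latent coupling
        conn_z = pd.Series(
            {
                pid: connectivity_score(
                    ts.drop(columns="fd"), highpass_hz=None
                ).z
                for pid, ts in cohort.roi.items()
            }
        )
        np.testing.assert_allclose(conn_z, tbl["conn_target_z"], atol=1e-10)
        conn = (conn_z - cfg.conn_base_z) / cfg.conn_sd_z

        age = tbl["age_a1"]
        df = pd.DataFrame(
            {
                "ter": ter_z,
                "glu": glu,
                "gaba": gaba,
                "conn": conn,
                "age": (age - age.mean()) / age.std(ddof=1),
            }
        ).dropna()
        assert len(df) == 60
        fit = ModeratedRegression(
            "ter",
            ["glu", "gaba", "age", "glu:age", "gaba:age", "conn", "conn:age"],
            standardize=False,
        ).fit(df)
        expected = cfg.ter_model
        assert fit.coef_["glu:age"] == pytest.approx(expected["glutamate:age"], abs=1e-6)
        assert fit.coef_["gaba:age"] == pytest.approx(expected["gaba:age"], abs=1e-6)
        assert fit.coef_["glu"] == pytest.approx(expected["glutamate"], abs=1e-6)
        assert fit.coef_["conn:age"] == pytest.approx(expected["connectivity:age"], abs=1e-6)
        assert fit.coef_["age"] == pytest.approx(expected["age"], abs=1e-6)
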