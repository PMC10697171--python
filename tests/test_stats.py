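import numpy as np
import pandas as pd
import pytest

from palpebra.datasets import (
    best_fit_counts,
    participant_records,
    rolling_direction_counts,
)
from palpebra.stats import (
    RollingCounts,
    build_observation_table,
    cell_mean,
    demographics_summary,
    estimate_contrast,
    expected_rolling_direction,
    fit_comfort_model,
    fit_ipf_mixed_model,
    profile_parallelism_test,
    rolling_agreement,
)
from palpebra.trace_io import ANGLE_CONDITIONS, ValidationError

from conftest import segmented


# ---------------------------------------------------------------------------
# observation table
# ---------------------------------------------------------------------------

class TestObservationTable:
    def test_row_counts_match_selector_counts(self, small_study):
        from palpebra.kinematics import (
            resting_open_points,
            spontaneous_min_points,
            volitional_min_points,
        )

        cfg, recordings, traces, truth = small_study
        items = list(segmented(recordings, traces))
        table = build_observation_table(items)
        expected = 0
        for rec, trace, seg in items:
            expected += len(resting_open_points(trace, seg))
            for e in seg.events:
                if e.type == "spontaneous":
                    expected += len(spontaneous_min_points(e))
                else:
                    expected += len(volitional_min_points(e))
        assert len(table) == expected

    def test_baseline_rows_labelled_baseline(self, small_study):
        cfg, recordings, traces, _ = small_study
        table = build_observation_table(segmented(recordings, traces))
        rid = [r for r in recordings if r.condition == "baseline"][0]
        sub = table[table.recording_id == rid.recording_id]
        assert (sub.condition == "baseline").all()
        assert set(sub.state) == {"open", "spont_blink", "vol_blink"}


# ---------------------------------------------------------------------------
# mixed models
# ---------------------------------------------------------------------------

def exact_table(n_participants=6, intercepts=None):
    """Observation table generated exactly from the model with zero random
    variances: cell value = baseline + condition effect + state effect."""
    cond_eff = {"baseline": 0.0, "angle_30": 1.7, "angle_180": 2.6}
    state_eff = {"open": 0.0, "spont_blink": -2.5, "vol_blink": -4.1}
    rows = []
    for p in range(n_participants):
        u = 0.0 if intercepts is None else intercepts[p]
        for cond, ce in cond_eff.items():
            for state, se in state_eff.items():
                for k in range(4):
                    rows.append(
                        {
                            "recording_id": f"P{p}_{cond}",
                            "participant_id": f"P{p}",
                            "eye": "left",
                            "condition": cond,
                            "state": state,
                            "ipf_mm": 4.5 + u + ce + se,
                            "comfort": None,
                        }
                    )
    return pd.DataFrame(rows)


class TestIPFModel:
    def test_exact_identification_noise_free(self):
        """Data generated exactly from the model: fixed effects recover the
        generating offsets to 1e-6."""
        table = exact_table()
        m = fit_ipf_mixed_model(table)
        fe = m.fixed_effects
        assert fe["Intercept"].estimate == pytest.approx(4.5, abs=1e-6)
        assert fe["condition[angle_180]"].estimate == pytest.approx(2.6, abs=1e-6)
        assert fe["state[spont_blink]"].estimate == pytest.approx(-2.5, abs=1e-6)
        est, _, _, _ = cell_mean(m, "angle_30", "vol_blink")
        assert est == pytest.approx(4.5 + 1.7 - 4.1, abs=1e-6)

    def test_wald_ci_consistency(self, small_study):
        """ci95 = estimate +/- 1.96 se for every term, to 1e-9."""
        cfg, recordings, traces, _ = small_study
        table = build_observation_table(segmented(recordings, traces))
        m = fit_ipf_mixed_model(table)
        for fe in m.fixed_effects.values():
            assert fe.ci95_lo == pytest.approx(fe.estimate - 1.96 * fe.se,
                                               abs=1e-9)
            assert fe.ci95_hi == pytest.approx(fe.estimate + 1.96 * fe.se,
                                               abs=1e-9)

    def test_agrees_with_statsmodels_on_well_conditioned_data(self):
        """Independent cross-check: on data with an honest residual spread,
        the sufficient-statistics REML fit matches statsmodels MixedLM
        (fixed effects, SEs, variance components)."""
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(5150)
        rows = []
        for p in range(10):
            u = rng.normal(0, 1.2)
            for cond in ("baseline", "angle_30", "angle_180"):
                for state in ("open", "spont_blink"):
                    mu = 5 + u + {"baseline": 0, "angle_30": 1.5,
                                  "angle_180": 2.5}[cond] \
                        + {"open": 0, "spont_blink": -2.2}[state]
                    for _ in range(6):
                        rows.append(
                            {"recording_id": f"P{p}_{cond}",
                             "participant_id": f"P{p}", "eye": "left",
                             "condition": cond, "state": state,
                             "ipf_mm": mu + rng.normal(0, 0.8),
                             "comfort": None}
                        )
        df = pd.DataFrame(rows)
        mine = fit_ipf_mixed_model(df)

        sm_df = df.copy()
        sm_df["eye_cond"] = sm_df.eye + ":" + sm_df.condition
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sm_model = smf.mixedlm(
                "ipf_mm ~ C(condition, Treatment('baseline'))"
                " * C(state, Treatment('open'))",
                data=sm_df, groups=sm_df["participant_id"],
                vc_formula={"angle_within_eye": "0 + C(eye_cond)"},
                re_formula="1",
            )
            sm_res = sm_model.fit(reml=True)
        from palpebra.stats import _clean_term

        sm_params = np.asarray(sm_res.fe_params)
        sm_se = np.asarray(sm_res.bse_fe)
        for j, name in enumerate(sm_model.exog_names):
            fe = mine.fixed_effects[_clean_term(name)]
            assert fe.estimate == pytest.approx(sm_params[j], abs=2e-3)
            # statsmodels' default optimizer stops slightly short on the
            # intercept-variance direction (lme4 below is the tight oracle)
            assert fe.se == pytest.approx(sm_se[j], rel=0.15)
        assert mine.random_variances["participant"] == pytest.approx(
            float(sm_res.cov_re.iloc[0, 0]), rel=0.30, abs=0.05
        )
        assert mine.random_variances["residual"] == pytest.approx(
            float(sm_res.scale), rel=0.05
        )

    def test_agrees_with_lme4_reference(self, tmp_path):
        """Tight cross-check against lme4 REML on the same data: fixed
        effects, SEs, and variance components to 4 significant figures."""
        import shutil
        import subprocess

        assert shutil.which("Rscript"), "Rscript expected on PATH"
        rng = np.random.default_rng(5150)
        rows = []
        for p in range(10):
            u = rng.normal(0, 1.2)
            for cond in ("baseline", "angle_30", "angle_180"):
                for state in ("open", "spont_blink"):
                    mu = 5 + u + {"baseline": 0, "angle_30": 1.5,
                                  "angle_180": 2.5}[cond] \
                        + {"open": 0, "spont_blink": -2.2}[state]
                    for _ in range(6):
                        rows.append(
                            {"recording_id": f"P{p}_{cond}",
                             "participant_id": f"P{p}", "eye": "left",
                             "condition": cond, "state": state,
                             "ipf_mm": mu + rng.normal(0, 0.8),
                             "comfort": None}
                        )
        df = pd.DataFrame(rows)
        mine = fit_ipf_mixed_model(df)
        csv = tmp_path / "d.csv"
        d = df.copy()
        d["eye_cond"] = d.eye + ":" + d.condition
        d.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            'suppressMessages(library(lme4))\n'
            f'd <- read.csv("{csv}")\n'
            'd$condition <- relevel(factor(d$condition), ref="baseline")\n'
            'd$state <- relevel(factor(d$state), ref="open")\n'
            'm <- lmer(ipf_mm ~ condition*state + (1|participant_id)'
            ' + (1|participant_id:eye_cond), data=d, REML=TRUE)\n'
            'v <- as.data.frame(VarCorr(m))\n'
            'co <- summary(m)$coefficients\n'
            'cat(v$vcov[v$grp=="participant_id"], '
            'v$vcov[v$grp=="Residual"], '
            'co["(Intercept)","Estimate"], co["(Intercept)","Std. Error"], '
            'co["conditionangle_180","Estimate"], '
            'co["conditionangle_180","Std. Error"], sep="\\n")\n'
        )
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        vals = [float(x) for x in out.stdout.split()]
        part_var, resid, b0, se0, b180, se180 = vals
        assert mine.random_variances["participant"] == pytest.approx(part_var,
                                                                     rel=1e-3)
        assert mine.random_variances["residual"] == pytest.approx(resid,
                                                                  rel=1e-3)
        fe = mine.fixed_effects
        assert fe["Intercept"].estimate == pytest.approx(b0, abs=1e-4)
        assert fe["Intercept"].se == pytest.approx(se0, rel=1e-3)
        assert fe["condition[angle_180]"].estimate == pytest.approx(b180,
                                                                    abs=1e-4)
        assert fe["condition[angle_180]"].se == pytest.approx(se180, rel=1e-3)

    def test_se_grows_with_noise(self):
        """Doubling the residual noise inflates fixed-effect SEs."""
        rng = np.random.default_rng(77)
        def noisy_table(sd, seed):
            r = np.random.default_rng(seed)
            t = exact_table(intercepts=r.normal(0, 1.0, size=6))
            t = t.copy()
            t["ipf_mm"] = t["ipf_mm"] + r.normal(0, sd, size=len(t))
            return t
        ses_lo = [fit_ipf_mixed_model(noisy_table(0.1, s)).fixed_effects[
            "condition[angle_180]"].se for s in range(3)]
        ses_hi = [fit_ipf_mixed_model(noisy_table(0.4, s)).fixed_effects[
            "condition[angle_180]"].se for s in range(3)]
        assert np.mean(ses_hi) > np.mean(ses_lo)

    def test_requires_two_participants(self):
        table = exact_table(n_participants=1)
        with pytest.raises(ValidationError):
            fit_ipf_mixed_model(table)


@pytest.fixture(scope="module")
def contrast_model():
    rng = np.random.default_rng(4)
    return fit_ipf_mixed_model(exact_table(intercepts=rng.normal(0, 1, size=6)))


class TestContrast:
    @pytest.fixture
    def model(self, contrast_model):
        return contrast_model

    def test_self_contrast_is_null(self, model):
        diff, z, p = estimate_contrast(model, "condition[angle_180]",
                                       "condition[angle_180]")
        assert diff == 0.0 and p == 1.0

    def test_antisymmetry(self, model):
        d1, z1, _ = estimate_contrast(model, "condition[angle_180]",
                                      "condition[angle_30]")
        d2, z2, _ = estimate_contrast(model, "condition[angle_30]",
                                      "condition[angle_180]")
        assert d1 == pytest.approx(-d2)
        assert z1 == pytest.approx(-z2)

    def test_exact_data_gives_generating_difference(self, model):
        diff, _, _ = estimate_contrast(model, "condition[angle_180]",
                                       "condition[angle_30]")
        assert diff == pytest.approx(2.6 - 1.7, abs=1e-6)

    def test_unknown_term_rejected(self, model):
        with pytest.raises(ValidationError):
            estimate_contrast(model, "condition[angle_180]", "nope")


class TestComfortModel:
    def test_constant_comfort_degenerate(self):
        table = exact_table()
        table["comfort"] = 7
        m = fit_comfort_model(table)
        assert m.degenerate
        assert all(
            fe.estimate == 0.0
            for name, fe in m.fixed_effects.items() if name != "Intercept"
        )

    def test_recovers_device_effect(self, small_study):
        cfg, recordings, traces, _ = small_study
        table = build_observation_table(segmented(recordings, traces))
        m = fit_comfort_model(table)
        eff = np.mean(
            [m.fixed_effects[f"condition[{c}]"].estimate
             for c in ANGLE_CONDITIONS if f"condition[{c}]" in m.fixed_effects]
        )
        assert eff == pytest.approx(1.6, abs=1.2)

    def test_permuted_labels_destroy_effect(self, small_study):
        """Permuting condition labels across recordings yields p-values
        without systematic enrichment at small values."""
        cfg, recordings, traces, _ = small_study
        table = build_observation_table(segmented(recordings, traces))
        rng = np.random.default_rng(9)
        pvals = []
        base = table.drop_duplicates("recording_id").dropna(subset=["comfort"])
        for _ in range(60):
            perm = base.copy()
            perm["condition"] = rng.permutation(perm["condition"].to_numpy())
            if perm["condition"].nunique() < 2:
                continue
            m = fit_comfort_model(perm)
            zs = [fe.z for name, fe in m.fixed_effects.items()
                  if name.startswith("condition[")]
            pvals.append(np.mean(np.abs(zs)))
        observed = fit_comfort_model(base)
        obs_z = np.mean([abs(fe.z) for name, fe in
                         observed.fixed_effects.items()
                         if name.startswith("condition[")])
        # the observed mean |z| should exceed the vast majority of permuted
        assert obs_z > np.quantile(pvals, 0.9)


# ---------------------------------------------------------------------------
# profile analysis
# ---------------------------------------------------------------------------

def profile_table(n_eyes, angle_effects_per_eye, noise_sd, n_per_cell, seed):
    rng = np.random.default_rng(seed)
    rows = []
    for e in range(n_eyes):
        intercept = 5 + rng.normal(0, 1.5)
        for a, cond in enumerate(ANGLE_CONDITIONS):
            mu = intercept + angle_effects_per_eye[e][a]
            for _ in range(n_per_cell):
                rows.append(
                    {"participant_id": f"E{e}", "eye": "left",
                     "condition": cond, "state": "open",
                     "ipf_mm": mu + rng.normal(0, noise_sd)}
                )
    return pd.DataFrame(rows)


class TestProfileAnalysis:
    shared = [1.0, 0.5, 0.8, 1.2, 2.0]

    def test_identical_profiles_accept_null(self):
        table = profile_table(6, [self.shared] * 6, 0.0, 10, 2)
        res = profile_parallelism_test(table, "open")
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p > 0.99

    def test_opposite_responses_rejected(self):
        up = [0.0, 0.5, 1.0, 1.5, 2.0]
        down = [2.0, 1.5, 1.0, 0.5, 0.0]
        table = profile_table(2, [up, down], 0.1, 10, 3)
        res = profile_parallelism_test(table, "open")
        assert res.p < 0.001

    def test_segments_are_adjacent_angle_differences(self):
        table = profile_table(3, [self.shared] * 3, 0.0, 5, 4)
        res = profile_parallelism_test(table, "open")
        segs = res.segments[res.segments.eye_id == "E0_left"].diff_mm.to_numpy()
        np.testing.assert_allclose(segs, np.diff(self.shared), atol=1e-9)

    def test_type_one_error_calibrated(self):
        """Empirical size at alpha=0.05 under the parallel null (quick
        check; the full 2000-replicate version runs in acceptance)."""
        from palpebra.validation import parallelism_null_size

        res = parallelism_null_size(n_replicates=400, seed=6)
        assert res["type1_error"] == pytest.approx(0.05, abs=0.03)

    def test_requires_complete_eyes(self):
        table = profile_table(2, [self.shared] * 2, 0.1, 5, 5)
        table = table[table.condition != "angle_90"]
        with pytest.raises(ValidationError):
            profile_parallelism_test(table, "open")


# ---------------------------------------------------------------------------
# rolling direction and demographics
# ---------------------------------------------------------------------------

class TestRolling:
    def test_lookup_examples(self):
        assert expected_rolling_direction("type1", 0) == "min"
        assert expected_rolling_direction("type2", 180) == "in"

    def test_lookup_total_over_grid(self):
        for mt in ("type1", "type2"):
            for a in (0, 30, 60, 90, 180):
                assert expected_rolling_direction(mt, a) in {"min", "out", "in"}

    def test_unknown_angle_rejected(self):
        with pytest.raises(ValidationError):
            expected_rolling_direction("type1", 45)

    def test_agreement_examples(self):
        c = RollingCounts("type1", 0, 9, 10, "min", "min")
        assert rolling_agreement(c) == 0.90
        c = RollingCounts("type2", 60, 3, 11, "min", "min")
        assert rolling_agreement(c) == 0.27

    def test_perfect_agreement(self):
        for k in (1, 5, 12):
            c = RollingCounts("type1", 0, k, k, "min", "min")
            assert rolling_agreement(c) == 1.00

    def test_observed_bounded_by_expected(self):
        with pytest.raises(ValidationError):
            RollingCounts("type1", 0, 11, 10, "min", "min")

    def test_table_agreements_reproduced(self):
        """All ten printed agreement values recomputed exactly."""
        expected = {
            ("type1", 0): 0.90, ("type1", 30): 0.57, ("type1", 60): 0.38,
            ("type1", 90): 0.63, ("type1", 180): 0.75,
            ("type2", 0): 0.92, ("type2", 30): 0.58, ("type2", 60): 0.27,
            ("type2", 90): 0.64, ("type2", 180): 0.92,
        }
        for c in rolling_direction_counts():
            assert rolling_agreement(c) == expected[(c.magnet_type, c.angle_deg)]
            assert expected_rolling_direction(c.magnet_type, c.angle_deg) == \
                c.expected_direction

    def test_row_totals(self):
        counts = rolling_direction_counts()
        for mt, obs_total, exp_total in (("type1", 27, 41), ("type2", 39, 58)):
            rows = [c for c in counts if c.magnet_type == mt]
            assert sum(c.observed for c in rows) == obs_total
            assert sum(c.expected for c in rows) == exp_total


class TestDemographics:
    def test_study_cohort_summary(self):
        summary = demographics_summary(participant_records())
        assert summary["median_age_yr"] == 51
        assert summary["gender_counts"]["F"] == 9
        assert summary["side_counts"]["right"] == 6
        assert summary["n_contributing"] == 16
        assert summary["n_unique_individuals"] == 18

    def test_single_record(self):
        from palpebra.stats import ParticipantRecord

        rec = ParticipantRecord("X1", 33, "F", "left")
        assert demographics_summary([rec])["median_age_yr"] == 33

    def test_best_fit_custom_frame_share(self):
        counts = best_fit_counts()
        total = sum(counts["frame"].values())
        pct = round(100 * counts["frame"]["custom"] / total)
        assert pct == 59
        assert sum(counts["angle"].values()) == 17
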