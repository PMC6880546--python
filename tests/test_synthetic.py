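"""Synthetic cohort generator: determinism, invariants of the generated data,
the mode-discriminating cross-time score correlation, and persistence."""

import logging

import numpy as np
import pandas as pd
import pytest

from methalc.pipeline import state_from_cohort
from methalc.synthetic import (
    SimulationConfig,
    aries_timepoints,
    read_cohort,
    simulate_cohort,
    write_cohort,
)

logging.disable(logging.WARNING)

MOTHER_TPS = tuple(t for t in aries_timepoints() if t.generation == "mother")


def small_config(**kw):
    kw.setdefault("n_pairs", 150)
    kw.setdefault("time_points", MOTHER_TPS)
    kw.setdefault("n_background_cpgs", 5)
    kw.setdefault("target_r2_audit", 0.02)
    kw.setdefault("seed", 7)
    return SimulationConfig(**kw)


class TestConfigValidation:
    def test_bad_mixture_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            small_config(category_mix={"non": 0.5, "light": 0.2, "at_risk": 0.2, "heavy": 0.2})

    def test_zero_individuals_refused(self):
        with pytest.raises(ValueError, match="n_pairs"):
            small_config(n_pairs=0)

    def test_unknown_mode(self):
        with pytest.raises(ValueError, match="mode"):
            small_config(mode="magic")

    def test_infeasible_audit_target_reports_bound(self):
        with pytest.raises(ValueError, match="feasible bound"):
            simulate_cohort(small_config(target_r2_audit=0.5))


@pytest.fixture(scope="module")
def cohort():
    return simulate_cohort(small_config())


class TestGeneratedData:

    def test_betas_within_unit_interval(self, cohort):
        for meth in cohort.methylation.values():
            arr = meth.values.to_numpy()
            assert arr.min() > 0 and arr.max() < 1
        assert all(
            tp["clipping_fraction"] < 0.01
            for tp in cohort.ground_truth["time_points"].values()
        )

    def test_audit_bounds_and_nondrinker_floor(self, cohort):
        ph = cohort.phenotypes["midlife"]
        assert ph["audit"].between(0, 40).all()
        assert (ph.loc[ph["intake_gday"] == 0, "audit"] == 0).all()

    def test_nondrinking_timepoint_has_zero_intake(self, cohort):
        assert (cohort.phenotypes["pregnancy"]["intake_gday"] == 0).all()

    def test_category_mixture_near_target(self):
        cohort = simulate_cohort(small_config(n_pairs=4000))
        mix = cohort.ground_truth["time_points"]["midlife"]["achieved_category_mix"]
        assert mix["non"] == pytest.approx(0.05, abs=0.02)
        assert mix["light"] == pytest.approx(0.71, abs=0.04)
        assert mix["heavy"] == pytest.approx(0.015, abs=0.012)

    def test_covariate_tables_complete(self, cohort):
        cov = cohort.covariates["midlife"]
        assert {"age", "sex", "bmi", "smoking"} <= set(cov.columns)
        wbc = [c for c in cov.columns if c.startswith("wbc_")]
        assert np.allclose(cov[wbc].sum(axis=1), 1.0)
        assert (cov[wbc] >= 0).all().all()


class TestDeterminismAndModes:
    def test_seed_determinism_byte_identical(self, tmp_path):
        a = simulate_cohort(small_config(seed=3))
        b = simulate_cohort(small_config(seed=3))
        write_cohort(a, tmp_path / "a")
        write_cohort(b, tmp_path / "b")
        for pa in sorted((tmp_path / "a").iterdir()):
            pb = tmp_path / "b" / pa.name
            assert pa.read_bytes() == pb.read_bytes()

    def test_different_seed_differs(self):
        a = simulate_cohort(small_config(seed=3))
        b = simulate_cohort(small_config(seed=4))
        assert not np.allclose(a.methylation["midlife"].values, b.methylation["midlife"].values)

    def _cross_time_score_corr(self, mode, **kw):
        cfg = small_config(n_pairs=400, mode=mode, **kw)
        cohort = simulate_cohort(cfg)
        state = state_from_cohort(cohort)
        s1 = state.score("pregnancy", "dnamalc.144").scores
        s2 = state.score("midlife", "dnamalc.144").scores
        return float(np.corrcoef(s1, s2)[0, 1])

    def test_genetic_mode_scores_stable_across_time(self):
        assert self._cross_time_score_corr("genetic_stable") > 0.8

    def test_exposure_mode_scores_uncorrelated_across_time(self):
        # pregnancy carries no alcohol signal in exposure mode
        assert abs(self._cross_time_score_corr("exposure_concurrent")) < 0.15

    def test_null_mode_score_outcome_r2_centred_at_zero(self):
        from methalc.evaluation import variance_explained

        vals = []
        for seed in range(40):
            cfg = small_config(n_pairs=250, mode="null", seed=seed)
            cohort = simulate_cohort(cfg)
            state = state_from_cohort(cohort)
            res = variance_explained(
                state.score("midlife", "dnamalc.144"),
                cohort.phenotypes["midlife"]["log_intake"],
            )
            vals.append(res.adj_r2)
        assert abs(float(np.mean(vals))) < 0.005

    def test_smoking_confounded_direction(self):
        """Adjusting for smoking removes the injected smoking signal, so the
        smoking-adjusted score-intake R2 drops below the unadjusted one."""
        from methalc.evaluation import variance_explained
        from methalc.pipeline import run_sensitivity

        diffs = []
        for seed in range(5):
            cfg = small_config(
                n_pairs=800, mode="smoking_confounded", smoking_confound_scale=3.0, seed=seed
            )
            cohort = simulate_cohort(cfg)
            state = state_from_cohort(cohort)
            primary = variance_explained(
                state.score("midlife", "dnamalc.144"), cohort.phenotypes["midlife"]["log_intake"]
            ).adj_r2
            sens = run_sensitivity(state, "adjust_smoking", ["midlife"])
            t = sens["r2"]
            adj = float(
                t[(t["set"] == "dnamalc.144") & (t["outcome"] == "log_intake")]["adj_r2_pct"].iloc[0]
            ) / 100
            diffs.append(primary - adj)
        assert float(np.mean(diffs)) > 0


class TestPersistence:
    def test_write_read_round_trip(self, tmp_path):
        cohort = simulate_cohort(small_config(n_pairs=40))
        write_cohort(cohort, tmp_path)
        back = read_cohort(tmp_path)
        for tp, meth in cohort.methylation.items():
            re = back["methylation"][tp]
            assert np.allclose(re.to_numpy(), meth.values.to_numpy(), atol=1e-12)
        assert (tmp_path / "ground_truth.json").exists()

    def test_row_counts_match_config(self, tmp_path):
        cohort = simulate_cohort(SimulationConfig(n_pairs=60, seed=1, target_r2_audit=0.02))
        files = write_cohort(cohort, tmp_path)
        assert len(cohort.methylation) == 5  # two maternal + three offspring waves
        for tp, meth in cohort.methylation.items():
            df = pd.read_csv(tmp_path / f"meth_{tp}.tsv", sep="\t", index_col=0)
            assert df.shape == (60, 144 + 56)
        assert len(files) == 3 * 5 + 2 + 1
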