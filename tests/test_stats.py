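"""Behavioral preprocessing rules and the two mixed-model fitters."""

import numpy as np
import pandas as pd
import pytest

import hipporpe as hp
from hipporpe.stats import SeparationWarning, add_repetition


def toy_table(n_participants=4, trials=40, rt=1.0, correct=1, condition="early"):
    rows = []
    for p in range(n_participants):
        for t in range(trials):
            role = ("prototype", "rule_follower", "exception")[t % 3]
            rows.append({
                "participant_id": f"P{p}", "condition": condition,
                "block": 1 + t // 14, "trial_index": t + 1,
                "stimulus_id": "PA1", "role": role, "category": "A",
                "phase": "learning", "correct": correct, "rt": rt,
            })
    return add_repetition(pd.DataFrame(rows))


class TestPreprocess:
    def test_clean_participant_retained(self):
        table = toy_table()
        kept, report = hp.preprocess_behavior(table)
        assert len(kept) == len(table)
        assert report.excluded_participants == ()

    def test_rt_rule_excludes_participant(self):
        table = toy_table()
        rows = table.index[table["participant_id"] == "P0"]
        table.loc[rows[: int(0.25 * len(rows))], "rt"] = 2.5
        kept, report = hp.preprocess_behavior(table)
        assert [pid for pid, _ in report.excluded_participants] == ["P0"]
        assert "P0" not in set(kept["participant_id"])

    def test_accuracy_rule_excludes_participant(self):
        table = toy_table()
        table.loc[table["participant_id"] == "P1", "correct"] = 0
        kept, report = hp.preprocess_behavior(table)
        assert [pid for pid, _ in report.excluded_participants] == ["P1"]

    def test_out_of_range_trials_dropped(self):
        table = toy_table()
        table.loc[table.index[:3], "rt"] = 0.05  # 3 of 160 trials: below 20%
        kept, report = hp.preprocess_behavior(table)
        assert report.n_trials_dropped_rt == 3
        assert (kept["rt"] >= 0.15).all()

    def test_repetition_cap(self):
        table = toy_table(n_participants=1, trials=40 * 3)
        kept, report = hp.preprocess_behavior(table)
        assert kept["repetition"].max() == 36
        assert report.n_trials_dropped_repetition > 0

    def test_idempotent(self):
        table = toy_table()
        rows = table.index[table["participant_id"] == "P0"]
        table.loc[rows[:25], "rt"] = 2.5
        once, _ = hp.preprocess_behavior(table)
        twice, report = hp.preprocess_behavior(once)
        pd.testing.assert_frame_equal(once, twice)
        assert report.excluded_participants == ()

    def test_schema_violations_rejected(self):
        bad = toy_table()
        bad.loc[bad.index[5], "correct"] = 2
        with pytest.raises(ValueError, match="non-binary"):
            hp.preprocess_behavior(bad)
        with pytest.raises(ValueError, match="missing columns"):
            hp.preprocess_behavior(pd.DataFrame({"participant_id": ["a"]}))


class TestBehavioralGlme:
    def test_separation_is_flagged(self):
        table = toy_table(n_participants=6, trials=30)
        table.loc[table["role"] == "exception", "correct"] = 0  # perfect cell separation
        with pytest.warns(SeparationWarning):
            hp.fit_behavioral_glme(table, "base")

    def test_null_condition_effect_calibration(self):
        """Data generated with no condition effect yield a condition
        estimate within 2 SE of zero in most replicates."""
        cfg_kwargs = dict(
            intercepts={(r, c): v for r, v in (("prototype", 1.2), ("rule_follower", 0.8),
                                               ("exception", -0.4)) for c in ("early", "delayed")},
            slopes={(r, c): 0.0 for r in ("prototype", "rule_follower", "exception")
                    for c in ("early", "delayed")},
        )
        hits = 0
        n_rep = 12
        for rep in range(n_rep):
            cfg = hp.BehavioralGenConfig(n_participants=25, seed=500 + rep,
                                         include_test_block=False, **cfg_kwargs)
            data = hp.generate_participants(cfg)
            fit = hp.fit_behavioral_glme(data.table, "base")
            est = fit.coef("condition[delayed]")
            se = fit.se("condition[delayed]")
            hits += abs(est) <= 2.0 * se
        assert hits >= n_rep - 2

    def test_contrast_arithmetic(self):
        cfg = hp.BehavioralGenConfig(n_participants=20, seed=77, include_test_block=False)
        data = hp.generate_participants(cfg)
        fit = hp.fit_behavioral_glme(data.table, "base")
        # (rule-follower vs exception) + (prototype vs rule-follower)
        # equals (prototype vs exception) within the same fit
        rf = fit.coef("role[rule_follower]")
        pr = fit.coef("role[prototype]")
        rf_to_pr, _ = fit.contrast({"role[prototype]": 1.0, "role[rule_follower]": -1.0})
        assert rf + rf_to_pr == pytest.approx(pr, abs=1e-10)

    def test_agrees_with_variational_reference(self):
        """Cross-check the Gauss-Hermite ML fit against statsmodels'
        variational-Bayes binomial mixed model on one dataset."""
        from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

        cfg = hp.BehavioralGenConfig(n_participants=20, seed=31, include_test_block=False)
        table = hp.generate_participants(cfg).table
        fit = hp.fit_behavioral_glme(table, "base")
        vb = BinomialBayesMixedGLM.from_formula(
            "correct ~ C(role, Treatment('exception')) * C(condition, Treatment('early'))",
            {"participant": "0 + C(participant_id)"}, table).fit_vb()
        reference = dict(zip(vb.model.exog_names, vb.fe_mean))
        for term, ref_name in [
            ("Intercept", "Intercept"),
            ("role[prototype]", "C(role, Treatment('exception'))[T.prototype]"),
            ("condition[delayed]", "C(condition, Treatment('early'))[T.delayed]"),
        ]:
            assert fit.coef(term) == pytest.approx(reference[ref_name], abs=0.15)

    def test_bic_is_finite_and_reported(self):
        cfg = hp.BehavioralGenConfig(n_participants=12, seed=5, include_test_block=False)
        fit = hp.fit_behavioral_glme(hp.generate_participants(cfg).table, "base")
        assert np.isfinite(fit.bic)
        fit_rep = hp.fit_behavioral_glme(hp.generate_participants(cfg).table, "with_repetition")
        assert any("centered_repetition" in t for t in fit_rep.terms)


class TestModelAccuracyLmm:
    def _table(self, accuracy_fn, n_batches=30):
        rows = []
        rng = np.random.default_rng(0)
        for condition in ("early", "delayed"):
            for b in range(n_batches):
                for role in ("prototype", "rule_follower", "exception"):
                    for cat in ("A", "B"):
                        rows.append({
                            "batch": f"{condition}{b}", "condition": condition,
                            "stimulus_id": f"X{cat}", "role": role, "category": cat,
                            "checkpoint": 144,
                            "accuracy": accuracy_fn(role, condition, cat, rng),
                        })
        return pd.DataFrame(rows)

    def test_constant_table_gives_zero_effects(self):
        fit = hp.fit_model_accuracy_lmm(self._table(lambda *_: 0.5), "overall")
        assert fit.coef("Intercept") == pytest.approx(0.5, abs=1e-6)
        for term in fit.terms:
            if term != "Intercept":
                assert fit.coef(term) == pytest.approx(0.0, abs=1e-6)

    def test_recovers_injected_exception_shift(self):
        def gen(role, condition, cat, rng):
            base = 0.6 + rng.normal(0, 0.02)
            if role == "exception" and condition == "delayed":
                base += 0.05
            return base

        fit = hp.fit_model_accuracy_lmm(self._table(gen, n_batches=120), "overall")
        assert fit.coef("condition[delayed]") == pytest.approx(0.05, abs=0.012)

    def test_exception_contrast_set_signs(self):
        def gen(role, condition, cat, rng):
            base = 0.5 + rng.normal(0, 0.02)
            if role == "exception":
                if cat == "B" and condition == "delayed":
                    base += 0.18
                if cat == "A" and condition == "delayed":
                    base -= 0.09
            return base

        table = self._table(gen, n_batches=80)
        fit = hp.fit_model_accuracy_lmm(table[table["role"] == "exception"],
                                        "exceptions_by_category")
        assert fit.coef("condition[delayed]") == pytest.approx(0.18, abs=0.02)
        assert fit.coef("category[A]:condition[delayed]") == pytest.approx(-0.27, abs=0.03)

    def test_logit_sensitivity_flag(self):
        fit = hp.fit_model_accuracy_lmm(self._table(lambda *_: 0.6), "overall",
                                        logit_outcome=True)
        assert fit.model_info["outcome"] == "logit(accuracy)"
        assert fit.coef("Intercept") == pytest.approx(np.log(0.6 / 0.4), abs=1e-4)
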