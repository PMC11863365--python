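import numpy as np
import pandas as pd
import pytest

import lipidsens as ls
from lipidsens.evaluate import r_squared


def _quant_frame(pred: dict, truth: dict) -> pd.DataFrame:
    rows = []
    for (sid, lid), p in pred.items():
        rows.append(
            {"sample_id": sid, "lipid_id": lid, "predicted_conc": p,
             "true_conc": truth[lid]}
        )
    return pd.DataFrame(rows)


class TestPercentErrorSummary:
    def test_perfect_predictions(self):
        pred = {(f"s{i}", f"l{j}"): 2.0 for i in range(3) for j in range(3)}
        rep = ls.percent_error_summary(_quant_frame(pred, {f"l{j}": 2.0 for j in range(3)}))
        assert rep.global_mean_error == 0.0
        assert rep.precision == 0.0
        assert rep.outlier_ids == []

    def test_constant_bias_gives_error_without_imprecision(self):
        pred = {(f"s{i}", "l0"): 3.0 for i in range(4)}
        pred.update({(f"s{i}", "l1"): 2.0 for i in range(4)})
        rep = ls.percent_error_summary(_quant_frame(pred, {"l0": 2.0, "l1": 2.0}))
        per = rep.per_lipid.set_index("lipid_id")
        assert per.loc["l0", "mean_ape"] == pytest.approx(50.0)
        assert per.loc["l0", "cv_pct"] == pytest.approx(0.0)

    def test_precision_equals_hand_computed_mean_cv(self):
        rng = np.random.default_rng(2)
        lipids = ["a", "b", "c"]
        pred = {(f"s{i}", lid): float(rng.uniform(1, 5)) for i in range(5) for lid in lipids}
        rep = ls.percent_error_summary(_quant_frame(pred, {lid: 2.0 for lid in lipids}))
        cvs = []
        for lid in lipids:
            vals = np.array([pred[(f"s{i}", lid)] for i in range(5)])
            cvs.append(100.0 * vals.std(ddof=1) / vals.mean())
        assert rep.precision == pytest.approx(np.mean(cvs), rel=1e-12)

    def test_multiplicative_noise_matches_folded_normal_mean(self):
        """Mean |N(0, 0.1)| = 0.1 * sqrt(2/pi) ~ 7.98 % mean APE."""
        rng = np.random.default_rng(4)
        truth = {f"l{j}": 2.0 for j in range(200)}
        pred = {
            (f"s{i}", lid): 2.0 * (1.0 + rng.normal(0, 0.1))
            for i in range(50) for lid in truth
        }
        rep = ls.percent_error_summary(_quant_frame(pred, truth))
        assert rep.global_mean_error == pytest.approx(100 * 0.1 * np.sqrt(2 / np.pi), rel=0.05)

    def test_rows_without_truth_dropped(self):
        df = _quant_frame({("s0", "l0"): 2.0, ("s0", "l1"): 3.0}, {"l0": 2.0, "l1": 2.0})
        df.loc[df["lipid_id"] == "l1", "true_conc"] = np.nan
        rep = ls.percent_error_summary(df)
        assert list(rep.per_lipid["lipid_id"]) == ["l0"]


class TestOutlierRule:
    def test_homogeneous_errors_no_outliers(self):
        errs = pd.Series([18.0, 20.0, 21.0, 19.0, 22.0, 20.5], index=list("abcdef"))
        assert ls.outlier_rule(errs) == []

    def test_single_extreme_lipid_flagged(self):
        errs = pd.Series([20, 22, 19, 21, 200.0], index=list("abcde"), dtype=float)
        assert ls.outlier_rule(errs) == ["e"]

    def test_with_outliers_mean_at_least_without(self):
        rng = np.random.default_rng(8)
        pred = {}
        truth = {}
        for j in range(12):
            lid = f"l{j}"
            truth[lid] = 2.0
            bias = 4.0 if j == 0 else 1.0 + rng.uniform(-0.2, 0.2)
            for i in range(4):
                pred[(f"s{i}", lid)] = 2.0 * bias
        rep = ls.percent_error_summary(_quant_frame(pred, truth))
        assert rep.outlier_ids == ["l0"]
        assert rep.global_mean_error >= rep.global_mean_error_outliers_removed

    def test_small_sets_never_flagged(self):
        errs = pd.Series([1.0, 2.0, 300.0], index=list("abc"))
        assert ls.outlier_rule(errs) == []


class TestRSquared:
    def test_perfect_and_degenerate(self):
        assert r_squared([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
        assert np.isnan(r_squared([2, 2, 2], [1, 2, 3]))

    def test_can_be_strongly_negative_out_of_sample(self):
        assert r_squared([1.0, 1.1, 0.9], [10.0, 12.0, 9.0]) < -100


class TestHoldouts:
    def test_single_lipid_held_class_reports_ape_not_r2(self, positive_training):
        _, X, y = positive_training
        labels = pd.Series("bulk", index=X.index)
        labels.iloc[0] = "solo"
        rep = ls.holdout_by_class(X, y, labels, "solo", seed=0)
        assert np.isnan(rep.r2_pred_vs_true_mR)
        assert len(rep.per_lipid) == 1
        assert np.isfinite(rep.per_lipid["mean_ape"]).all()

    def test_empty_class_rejected(self, positive_training):
        _, X, y = positive_training
        labels = pd.Series("bulk", index=X.index)
        with pytest.raises(ValueError, match="no members"):
            ls.holdout_by_class(X, y, labels, "ghost")

    def test_size_holdout_picks_k_extremes_per_class(self, positive_training, default_study):
        _, X, y = positive_training
        labels = default_study.class_labels().loc[X.index]
        masses = default_study.masses().loc[X.index]
        rep = ls.holdout_by_size(X, y, masses, labels, "largest", 1, seed=0)
        held = set(rep.per_lipid["lipid_id"])
        eligible = [c for c, ids in X.index.to_series().groupby(labels) if len(ids) > 1]
        assert len(held) == len(eligible)
        for cls in eligible:
            members = X.index[labels == cls]
            heaviest = masses.loc[members].idxmax()
            assert heaviest in held

    def test_invalid_direction_rejected(self, positive_training, default_study):
        _, X, y = positive_training
        labels = default_study.class_labels().loc[X.index]
        masses = default_study.masses().loc[X.index]
        with pytest.raises(ValueError, match="largest"):
            ls.holdout_by_size(X, y, masses, labels, "medium")


class TestClassHoldoutOrdering:
    def test_same_law_class_beats_out_of_law_class(self):
        """A held class drawn from the shared descriptor law is predicted far
        better than one carrying a class-specific offset outside the training
        range (per replicate seed)."""
        from dataclasses import replace

        from lipidsens.calibration import calibrate_mode
        from lipidsens.pipeline import recovery_config
        from lipidsens.simulate import simulate_study

        def smooth(seed):
            return replace(
                recovery_config(seed),
                informative_descriptors=[
                    "MolWt", "MolLogP", "TPSA", "NumRotatableBonds", "FractionCSP3"],
                informative_weights=[1.0, 0.5, -0.5, 0.3, -0.4],
            )

        for seed in range(3):
            r2 = {}
            for tag, cfg in (("in", smooth(seed)),
                             ("out", replace(smooth(seed), out_of_law_class="DG"))):
                study = simulate_study(cfg)
                cal = calibrate_mode(study.panel, study.responses, "positive")
                X, y = ls.build_training_table(cal, study.descriptors)
                rep = ls.holdout_by_class(X, y, study.class_labels(), "DG", seed=seed)
                r2[tag] = rep.r2_pred_vs_true_mR
            assert r2["in"] > r2["out"] + 5.0


class TestRecovery:
    def test_recovery_values_and_flags(self):
        matrix = pd.Series({"a": 100.0, "b": 120.0, "c": 0.0, "d": 50.0})
        neat = pd.Series({"a": 100.0, "b": 100.0, "c": 100.0, "d": 0.0})
        rep = ls.recovery(matrix, neat).set_index("lipid_id")
        assert rep.loc["a", "recovery_pct"] == pytest.approx(100.0)
        assert rep.loc["b", "recovery_pct"] == pytest.approx(120.0)
        assert rep.loc["b", "flag"] == "possible_enhancement"
        assert rep.loc["c", "recovery_pct"] == pytest.approx(0.0)
        assert np.isnan(rep.loc["d", "recovery_pct"])
        assert rep.loc["d", "flag"] == "undefined_neat_zero"

    def test_disjoint_tables_rejected(self):
        with pytest.raises(ValueError, match="both"):
            ls.recovery(pd.Series({"a": 1.0}), pd.Series({"b": 1.0}))

    def test_simulated_matrix_effect_recovered(self):
        """Neat-spike samples differ from matrix samples exactly by the
        per-lipid matrix factor (up to noise)."""
        from dataclasses import replace

        cfg = replace(
            ls.SimulationConfig(), matrix_effect_sd=0.4, n_neat_spike_samples=3,
            noise_sd=0.0, seed=21,
        )
        study = ls.simulate_study(cfg)
        mode = "positive"
        matrix_ids = study.responses.sample_ids("study_sample", mode)
        neat_ids = study.responses.sample_ids("neat_spike", mode)
        rep = ls.recovery(
            study.responses.areas.loc[matrix_ids].mean(),
            study.responses.areas.loc[neat_ids].mean(),
        ).set_index("lipid_id")
        for lid, factor in study.matrix_factors.items():
            if lid in rep.index:
                assert rep.loc[lid, "recovery_pct"] == pytest.approx(100.0 * factor, rel=1e-9)
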