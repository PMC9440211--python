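"""Training pipeline: targets, localization, ridge fitting, diagnostics."""

import math

import numpy as np
import pandas as pd
import pytest

from promotercalc.energy_model import FEATURE_NAMES, InsufficientContextError
from promotercalc.simulate import simulate_dataset, simulate_ground_truth
from promotercalc.training import (
    CATEGORICAL_BLOCKS,
    FEATURE_GROUPS,
    PromoterDataset,
    Pwm,
    center_blocks,
    feature_drop_analysis,
    fit_interaction_model,
    locate_motifs,
    positive_control_check,
    prepare_targets,
    train_model,
    variance_decomposition,
)

from .conftest import random_dna


def _dataset_from_rates(rates):
    rows = [
        {"id": f"v{i}", "sequence": "ACGT" * 30, "tss": 60, "tx_mean": r}
        for i, r in enumerate(rates)
    ]
    return PromoterDataset(pd.DataFrame(rows))


def _recovery_r2(truth, fitted):
    t = np.array([center_blocks(truth.coefficients)[n] for n in FEATURE_NAMES])
    f = np.array([fitted.coefficients[n] for n in FEATURE_NAMES])
    return 1.0 - ((t - f) ** 2).sum() / ((t - t.mean()) ** 2).sum()


class TestPrepareTargets:
    def test_geometric_rates_give_integer_logs(self):
        ds = _dataset_from_rates([1.0, math.e, math.e**2])
        y, ref = prepare_targets(ds)
        assert y.to_numpy() == pytest.approx([0.0, 1.0, 2.0])
        assert ref == "v1"  # middle record is nearest the log-mean-center

    def test_single_record(self):
        y, ref = prepare_targets(_dataset_from_rates([7.0]))
        assert y.to_numpy() == pytest.approx([0.0])
        assert ref == "v0"

    def test_invariant_to_uniform_scaling(self):
        a, _ = prepare_targets(_dataset_from_rates([2.0, 8.0, 32.0]))
        b, _ = prepare_targets(_dataset_from_rates([20.0, 80.0, 320.0]))
        assert a.to_numpy() == pytest.approx(b.to_numpy())

    def test_non_positive_rate_rejected(self):
        with pytest.raises(ValueError):
            _dataset_from_rates([1.0, 0.0])


class TestLocateMotifs:
    def test_embedded_consensus_found(self, rng):
        up = random_dna(rng, 24)
        spacer, disc = random_dna(rng, 17), random_dna(rng, 7)
        seq = up + "TTGACA" + spacer + "TATAAT" + disc + random_dna(rng, 25)
        tss = len(up) + 6 + 17 + 6 + 7
        cfg = locate_motifs(seq, tss)
        assert cfg.hex35 == "TTGACA"
        assert cfg.hex10 == "TATAAT"
        assert cfg.spacer_length == 17
        assert cfg.disc_length == 7

    def test_score_ties_resolve_to_17_spacer(self, rng):
        # uninformative PWMs make every placement equal-scoring
        flat = {"hex35": Pwm.from_consensus("TTGACA", match=0.25),
                "hex10": Pwm.from_consensus("TATAAT", match=0.25)}
        seq = random_dna(rng, 130)
        cfg = locate_motifs(seq, 90, pwms=flat)
        assert cfg.spacer_length == 17
        assert cfg.disc_length == 5

    def test_tss_too_close_to_start_rejected(self, rng):
        with pytest.raises(InsufficientContextError):
            locate_motifs(random_dna(rng, 100), 10)


class TestTrainModel:
    def test_noiseless_recovery_near_ols(self, tables):
        truth = simulate_ground_truth(seed=11, tables=tables)
        ds = simulate_dataset(truth, 900, seed=12, noise_sigma=0.0, tables=tables)
        params, report = train_model(ds, alphas=[1e-8], seed=0, tables=tables)
        assert _recovery_r2(truth, params) >= 0.999
        assert report.r2_test >= 0.999
        assert report.chosen_alpha == 1e-8

    def test_seed_determinism(self, tables):
        truth = simulate_ground_truth(seed=11, tables=tables)
        ds = simulate_dataset(truth, 300, seed=12, noise_sigma=0.2, tables=tables)
        p1, r1 = train_model(ds, alphas=[0.1, 1.0], seed=5, tables=tables)
        p2, r2 = train_model(ds, alphas=[0.1, 1.0], seed=5, tables=tables)
        assert p1.coefficients == p2.coefficients
        assert r1.to_json() == r2.to_json()

    def test_too_few_records_for_folds(self, tables):
        truth = simulate_ground_truth(seed=11, tables=tables)
        ds = simulate_dataset(truth, 9, seed=1, tables=tables, test_fraction=0.0)
        with pytest.raises(ValueError):
            train_model(ds, k_folds=10, tables=tables)

    def test_learning_curve_recorded(self, tables):
        truth = simulate_ground_truth(seed=11, tables=tables)
        ds = simulate_dataset(truth, 400, seed=3, noise_sigma=0.2, tables=tables)
        _, report = train_model(ds, alphas=[0.1], seed=0, tables=tables)
        assert [pt["n_train"] for pt in report.learning_curve] == sorted(
            pt["n_train"] for pt in report.learning_curve
        )
        assert len(report.learning_curve) == 4


class TestFeatureDrop:
    @pytest.fixture(scope="class")
    def drop_table(self, tables):
        cfg_truth = simulate_ground_truth(seed=21, tables=tables)
        # silence the ITR so its group is genuinely uninformative
        cfg_truth = cfg_truth.replace_coefficients({"itr_rloop": 0.0})
        ds = simulate_dataset(cfg_truth, 600, seed=22, noise_sigma=0.1, tables=tables)
        return feature_drop_analysis(
            ds, groups=["hex10", "itr_rloop"], alphas=[1e-3], seed=0, tables=tables
        )

    def test_one_row_per_group(self, drop_table):
        assert list(drop_table["group"]) == ["hex10", "itr_rloop"]

    def test_null_group_has_negligible_delta(self, drop_table):
        row = drop_table.set_index("group").loc["itr_rloop"]
        assert abs(row["delta_test_mae"]) < 0.02

    def test_signal_group_degrades_fit(self, drop_table):
        row = drop_table.set_index("group").loc["hex10"]
        assert row["delta_test_mae"] > 0.05

    def test_unknown_group_rejected(self, tables):
        truth = simulate_ground_truth(seed=21, tables=tables)
        ds = simulate_dataset(truth, 50, seed=2, tables=tables)
        with pytest.raises(ValueError):
            feature_drop_analysis(ds, groups=["nonsense"], tables=tables)


class TestVarianceDecomposition:
    def test_single_varying_region_takes_all_variance(self, tables, rng):
        truth = simulate_ground_truth(seed=31, tables=tables)
        # records differ only in the -10 hexamer
        up, spacer, disc, itr = (random_dna(rng, n) for n in (20, 17, 6, 20))
        rows = []
        hexamers = ["TATAAT", "GGGGGG", "CCCCCC", "ACGTAC", "TTTTTT", "GACGTC"]
        from promotercalc.energy_model import CompiledModel, parse_configuration

        cm = CompiledModel(truth, tables)
        for i, h10 in enumerate(hexamers):
            seq = up + "TTGACA" + spacer + h10 + disc + itr
            cfg = parse_configuration(seq, 55, spacer_length=17, disc_length=6)
            dg = cm.breakdown(cfg).dg_total
            rows.append(
                {"id": f"h{i}", "sequence": seq, "tss": 55, "tx_mean": math.exp(-dg),
                 "spacer_length": 17, "disc_length": 6}
            )
        ds = PromoterDataset(pd.DataFrame(rows))
        fr = variance_decomposition(truth, ds, tables=tables)
        assert fr["dg_10"] == pytest.approx(1.0, abs=1e-9)
        assert fr["residual"] == pytest.approx(0.0, abs=1e-9)
        for term in ("dg_up", "dg_35", "dg_spacer", "dg_disc", "dg_itr"):
            assert fr[term] == pytest.approx(0.0, abs=1e-9)

    def test_fractions_sum_to_one(self, tables):
        truth = simulate_ground_truth(seed=31, tables=tables)
        ds = simulate_dataset(truth, 200, seed=32, noise_sigma=0.3, tables=tables)
        fr = variance_decomposition(truth, ds, tables=tables)
        assert sum(fr.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(-1e-9 <= v <= 1 + 1e-9 for v in fr.values())

    def test_single_term_matches_correlation_oracle(self, tables):
        # with one varying term, the sequential SS fraction is the squared
        # correlation between that term's energy and the measured log rate
        truth = simulate_ground_truth(seed=31, tables=tables)
        ds = simulate_dataset(truth, 120, seed=33, noise_sigma=0.5, tables=tables)
        fr = variance_decomposition(truth, ds, tables=tables)
        from promotercalc.energy_model import CompiledModel
        from promotercalc.training import dataset_configurations

        cm = CompiledModel(truth, tables)
        configs = dataset_configurations(ds)
        terms = np.array([[getattr(cm.breakdown(c), t) for t in
                           ("dg_up", "dg_35", "dg_spacer", "dg_10ext", "dg_10", "dg_disc", "dg_itr")]
                          for c in configs])
        y, _ = prepare_targets(ds)
        # oracle for the first term in the sequential order (dg_up)
        r = np.corrcoef(terms[:, 0], y.to_numpy())[0, 1]
        assert fr["dg_up"] == pytest.approx(r**2, abs=1e-9)

    def test_zero_variance_rejected(self, tables):
        truth = simulate_ground_truth(seed=31, tables=tables)
        ds = _dataset_from_rates([2.0, 2.0, 2.0])
        with pytest.raises(ValueError):
            variance_decomposition(truth, ds, tables=tables)


class TestInteractionModel:
    @pytest.fixture(scope="class")
    def linear_data(self, tables):
        truth = simulate_ground_truth(seed=41, tables=tables)
        ds = simulate_dataset(truth, 5000, seed=42, noise_sigma=0.1, tables=tables)
        return truth, ds

    def test_exactly_30_interaction_coefficients(self, linear_data, tables):
        truth, ds = linear_data
        report = fit_interaction_model(ds, truth, tables=tables)
        assert report.n_interaction_coefficients == 30
        assert report.rank_deficient  # ordered duplicate products guarantee it

    def test_no_planted_interactions_recovered_as_null(self, linear_data, tables):
        truth, ds = linear_data
        report = fit_interaction_model(ds, truth, tables=tables)
        assert max(abs(v) for v in report.interaction_coefficients.values()) < 0.05

    def test_planted_interaction_sign_recovered(self, linear_data, tables):
        truth, ds = linear_data
        from promotercalc.energy_model import CompiledModel
        from promotercalc.training import dataset_configurations

        cm = CompiledModel(truth, tables)
        configs = dataset_configurations(ds)
        e35 = np.array([cm.breakdown(c).dg_35 for c in configs])
        e10 = np.array([cm.breakdown(c).dg_10 for c in configs])
        rec = ds.records.copy()
        rec["tx_mean"] = rec["tx_mean"] * np.exp(-0.3 * e35 * e10)
        planted = PromoterDataset(rec)
        report = fit_interaction_model(planted, truth, tables=tables)
        paired = (
            report.interaction_coefficients["hex35*hex10"]
            + report.interaction_coefficients["hex10*hex35"]
        )
        assert paired < -0.1  # dG-product term drives log-rate down jointly


class TestPositiveControls:
    def test_hand_set_canonical_minima_pass(self, zero_params):
        params = zero_params.replace_coefficients(
            {"hex35_1_TTG": -1, "hex35_2_ACA": -1, "hex10_1_TAT": -1,
             "hex10_2_AAT": -1, "ext10_TG": -1, "spacer_len_17": -1}
        )
        assert all(c["passed"] for c in positive_control_check(params))

    def test_all_zero_params_reported_as_tie(self, zero_params):
        results = positive_control_check(zero_params)
        assert all(not c["passed"] for c in results)
        assert all("tie" in c["reason"] for c in results)

    def test_trained_synthetic_model_recovers_canonical_motifs(self, tables):
        truth = simulate_ground_truth(seed=51, tables=tables)
        ds = simulate_dataset(truth, 1200, seed=52, noise_sigma=0.1, tables=tables)
        params, report = train_model(ds, alphas=[1e-4], seed=0, tables=tables)
        assert all(c["passed"] for c in report.positive_controls)
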