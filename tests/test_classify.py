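import numpy as np
import pandas as pd
import pytest

from mweeg import classify, spectral, sterp, synth
from mweeg.containers import CHANNELS
from mweeg.synth import MIND_WANDERING, ON_TASK


def _feature_inputs(n=6, drop_trial=None):
    """Minimal consistent erp/spectral/label frames for n trials."""
    rng = np.random.default_rng(0)
    trial_ids = np.arange(n)
    erp_rows = []
    for comp, ch in [("P1", "A10"), ("P1", "B7"), ("N1", "A10"),
                     ("N1", "B7"), ("P3", "A19")]:
        for t in trial_ids:
            if drop_trial is not None and t == drop_trial and comp == "P3":
                continue
            erp_rows.append({"trial_id": t, "component": comp, "channel": ch,
                             "W": rng.normal(), "t_ms": 100.0, "s_ms": 100.0,
                             "found": "ok"})
    spec_rows = []
    for band in ("alpha", "theta"):
        for period in ("baseline", "ASO"):
            for ch in CHANNELS:
                for t in trial_ids:
                    spec_rows.append({"trial_id": t, "kind": "power",
                                      "band": band, "site_or_pair": ch,
                                      "period": period, "value": rng.random()})
            for a, b in spectral.SITE_PAIRS:
                for t in trial_ids:
                    spec_rows.append({"trial_id": t, "kind": "ispc",
                                      "band": band, "site_or_pair": f"{a}-{b}",
                                      "period": period, "value": rng.random()})
    labels = pd.DataFrame({"trial_id": trial_ids,
                           "state": [ON_TASK, MIND_WANDERING] * (n // 2),
                           "source_probe": 0})
    return pd.DataFrame(erp_rows), pd.DataFrame(spec_rows), labels


class TestAssembleFeatures:
    def test_25_columns_in_documented_order(self):
        erp, spec, labels = _feature_inputs()
        table = classify.assemble_features(erp, spec, labels)
        assert table.shape == (6, 27)
        assert list(table.columns[2:]) == list(classify.FEATURE_COLUMNS)
        assert "ispc_theta_A10-A19" in table.columns

    def test_ispc_block_droppable(self):
        erp, spec, labels = _feature_inputs()
        table = classify.assemble_features(erp, spec, labels, include_ispc=False)
        assert len([c for c in table.columns if c not in ("trial_id", "state")]) == 13

    def test_missing_feature_for_labeled_trial_raises(self):
        erp, spec, labels = _feature_inputs(drop_trial=2)
        with pytest.raises(ValueError):
            classify.assemble_features(erp, spec, labels)


class TestZscore:
    def test_global_scope_standardizes_columns(self, gaussian_table):
        t = classify.zscore(gaussian_table(n=50, seed=1))
        for col in [c for c in t.columns if c.startswith("pow_")]:
            assert t[col].mean() == pytest.approx(0.0, abs=1e-12)
            assert t[col].std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_constant_column_dropped_with_warning(self, gaussian_table):
        t = gaussian_table(n=20)
        t["pow_const"] = 1.0
        with pytest.warns(UserWarning, match="pow_const"):
            out = classify.zscore(t)
        assert "pow_const" not in out.columns

    def test_train_fold_scope_leaves_table_untouched(self, gaussian_table):
        t = gaussian_table(n=20)
        out = classify.zscore(t, scope="train_fold_only")
        pd.testing.assert_frame_equal(out, t)

    def test_fold_scaling_uses_train_statistics_only(self):
        Xtr = np.array([[0.0], [2.0], [4.0]])
        Xte = np.array([[100.0]])
        tr, te = classify._train_scale(Xtr.copy(), Xte.copy())
        assert te[0, 0] == pytest.approx((100.0 - 2.0) / 2.0)
        assert tr.mean() == pytest.approx(0.0)


class TestOversample:
    def test_70_30_becomes_balanced(self):
        rng = np.random.default_rng(0)
        X = np.arange(100).reshape(-1, 1).astype(float)
        y = np.array([MIND_WANDERING] * 70 + [ON_TASK] * 30)
        Xb, yb = classify.oversample(X, y, rng)
        assert (yb == MIND_WANDERING).sum() == (yb == ON_TASK).sum() == 70
        # majority rows untouched, in place
        np.testing.assert_array_equal(Xb[:100], X)
        # duplicates drawn from the minority pool only
        assert set(Xb[100:, 0]) <= set(X[70:, 0])

    def test_balanced_input_unchanged(self):
        rng = np.random.default_rng(0)
        X = np.zeros((10, 2))
        y = np.array([MIND_WANDERING] * 5 + [ON_TASK] * 5)
        Xb, yb = classify.oversample(X, y, rng)
        assert yb.size == 10

    def test_extreme_imbalance(self):
        rng = np.random.default_rng(0)
        X = np.arange(11).reshape(-1, 1).astype(float)
        y = np.array([ON_TASK] * 10 + [MIND_WANDERING])
        Xb, yb = classify.oversample(X, y, rng)
        assert (yb == MIND_WANDERING).sum() == 10
        assert set(Xb[11:, 0]) == {10.0}

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            classify.oversample(np.zeros((3, 1)),
                                np.array([ON_TASK] * 3),
                                np.random.default_rng(0))


class TestGridSearch:
    def test_single_point_grid_returned(self, gaussian_table):
        t = gaussian_table(n=40, d=1.0)
        X = t[[c for c in t.columns if c.startswith("pow_")]].to_numpy()
        y = t["state"].to_numpy()
        spec = classify.ModelSpec(C_grid=(3.0,), gamma_grid=(0.5,), seed=0)
        C, gamma, _ = classify.grid_search(X, y, spec)
        assert (C, gamma) == (3.0, 0.5)

    def test_separable_data_reaches_perfect_inner_accuracy(self, gaussian_table):
        t = gaussian_table(n=60, d=8.0, seed=2)
        X = t[[c for c in t.columns if c.startswith("pow_")]].to_numpy()
        y = t["state"].to_numpy()
        spec = classify.ModelSpec(C_grid=(1.0, 10.0), gamma_grid=(0.01, 0.1), seed=0)
        _, _, acc = classify.grid_search(X, y, spec)
        assert acc == 1.0

    def test_deterministic_under_fixed_seed(self, gaussian_table):
        t = gaussian_table(n=40, d=0.5, seed=3)
        X = t[[c for c in t.columns if c.startswith("pow_")]].to_numpy()
        y = t["state"].to_numpy()
        spec = classify.ModelSpec(C_grid=(0.5, 1.0), gamma_grid=(0.1, 0.2), seed=7)
        assert classify.grid_search(X, y, spec) == classify.grid_search(X, y, spec)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            classify.ModelSpec(C_grid=())


class TestLoocv:
    def test_separable_features_classify_nearly_perfectly(self, gaussian_table):
        t = gaussian_table(n=60, d=8.0, seed=4)
        spec = classify.ModelSpec(C_grid=(1.0,), gamma_grid=(0.1,), seed=0)
        preds, m = classify.loocv(t, spec)
        assert m["accuracy"] >= 0.95
        assert len(preds) == 60

    def test_smallest_valid_input_runs(self):
        t = pd.DataFrame({"trial_id": [0, 1, 2, 3],
                          "state": [MIND_WANDERING, ON_TASK] * 2,
                          "pow_a": [1.0, -1.0, 1.1, -1.2]})
        spec = classify.ModelSpec(C_grid=(1.0,), gamma_grid=(1.0,),
                                  inner_folds=2, seed=0)
        preds, _ = classify.loocv(t, spec)
        assert len(preds) == 4

    def test_single_class_table_raises(self, gaussian_table):
        t = gaussian_table(n=10)
        t["state"] = MIND_WANDERING
        with pytest.raises(ValueError):
            classify.loocv(t, classify.ModelSpec(C_grid=(1.0,), gamma_grid=(1.0,)))

    def test_metrics_identity_holds_exactly(self, gaussian_table):
        t = gaussian_table(n=40, d=1.0, seed=5, mw_frac=0.3)
        spec = classify.ModelSpec(C_grid=(1.0,), gamma_grid=(0.1,), seed=0)
        _, m = classify.loocv(t, spec)
        lhs = m["accuracy"] * (m["n_mw"] + m["n_ot"])
        rhs = m["sensitivity"] * m["n_mw"] + m["specificity"] * m["n_ot"]
        assert lhs == pytest.approx(rhs, abs=1e-9)


class TestCrossTask:
    def test_exchangeable_tasks_transfer_like_loocv(self, gaussian_table):
        spec = classify.ModelSpec(C_grid=(1.0,), gamma_grid=(0.1,), seed=0)
        diffs = []
        for seed in range(6):
            a = gaussian_table(n=120, d=1.5, seed=seed)
            b = gaussian_table(n=120, d=1.5, seed=100 + seed)
            _, within = classify.loocv(a, spec)
            _, transfer = classify.cross_task_predict(a, b, spec)
            diffs.append(transfer["accuracy"] - within["accuracy"])
        assert abs(np.mean(diffs)) < 0.05

    def test_shuffled_test_features_fall_to_chance(self, gaussian_table):
        spec = classify.ModelSpec(C_grid=(1.0,), gamma_grid=(0.1,), seed=0)
        accs = []
        for seed in range(5):
            a = gaussian_table(n=150, d=2.0, seed=seed)
            b = gaussian_table(n=150, d=2.0, seed=50 + seed)
            rng = np.random.default_rng(seed)
            for col in [c for c in b.columns if c.startswith("pow_")]:
                b[col] = rng.permutation(b[col].to_numpy())
            _, m = classify.cross_task_predict(a, b, spec)
            accs.append(m["accuracy"])
        assert abs(np.mean(accs) - 0.5) < 0.1

    def test_column_mismatch_raises(self, gaussian_table):
        a = gaussian_table(n=20)
        b = gaussian_table(n=20).rename(columns={"pow_m0": "pow_other"})
        with pytest.raises(ValueError):
            classify.cross_task_predict(a, b,
                                        classify.ModelSpec(C_grid=(1.0,),
                                                           gamma_grid=(1.0,)))

    def test_test_fold_never_oversampled(self, gaussian_table):
        a = gaussian_table(n=40, d=1.0, seed=6, mw_frac=0.3)
        b = gaussian_table(n=30, d=1.0, seed=7, mw_frac=0.7)
        spec = classify.ModelSpec(C_grid=(1.0,), gamma_grid=(0.1,), seed=0)
        preds, _ = classify.cross_task_predict(a, b, spec)
        # every test trial appears exactly once, none duplicated
        assert sorted(preds["trial_id"]) == sorted(b["trial_id"])


class TestSingleMarkers:
    def test_26_rows_for_25_markers_plus_full_model(self, gaussian_table):
        t = gaussian_table(n=30, d=2.0, n_markers=3, seed=8)
        spec = classify.ModelSpec(C_grid=(1.0,), gamma_grid=(0.5,), seed=0)
        out = classify.single_marker_models(t, spec)
        assert len(out) == 3 + 1
        assert out["marker"].tolist()[-1] == "full_model"

    def test_effect_marker_beats_noise_marker(self, gaussian_table):
        rng = np.random.default_rng(9)
        t = gaussian_table(n=200, d=0.0, n_markers=1, seed=9)
        t["pow_effect"] = rng.standard_normal(200)
        t.loc[t.state == MIND_WANDERING, "pow_effect"] += 2.0
        spec = classify.ModelSpec(C_grid=(1.0,), gamma_grid=(0.5,), seed=0)
        out = classify.single_marker_models(t, spec).set_index("marker")
        assert out.loc["pow_effect", "accuracy"] > 0.5
        assert abs(out.loc["pow_m0", "accuracy"] - 0.5) < 0.15
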