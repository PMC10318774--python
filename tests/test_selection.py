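"""Backward elimination, the optimization grid, and final selection."""

import numpy as np
import pandas as pd
import pytest

from polyprisk.cohort import LabeledDataset, make_labels, split_train_test
from polyprisk.estimator import PolypRiskClassifier, cv_mcc
from polyprisk.metrics import mcc as mcc_counts
from polyprisk.selection import (
    CandidateModel,
    ThresholdData,
    backward_eliminate,
    optimize_bandwidth,
    prepare_threshold_data,
    run_grid,
    select_best,
)
from polyprisk.synthetic import FeatureLaw, SyntheticSpec, generate_cohort


def _planted_dataset(seed, n=600, deltas=(1.0, 1.0), n_noise=3, prevalence=0.5):
    laws = [FeatureLaw(f"sig_{i}", "normal", 0.0, 1.0, delta=d) for i, d in enumerate(deltas)]
    laws += [FeatureLaw(f"noise_{i}", "normal", float(i), 1.0 + i) for i in range(n_noise)]
    spec = SyntheticSpec(
        n_male=n, n_female=0, prevalence_male=prevalence, features=laws, seed=seed
    )
    return make_labels(generate_cohort(spec), 0, spec.schema(), sex="male")


class TestBackwardElimination:
    def test_floor_input_yields_single_candidate(self):
        ds = _planted_dataset(0, n=200, deltas=(1.0,), n_noise=2)
        est = PolypRiskClassifier(mode="none")
        path = backward_eliminate(ds, est, cv=3, seed=0, floor=3)
        assert len(path) == 1 and len(path[0].features) == 3

    def test_path_length_and_nesting(self):
        ds = _planted_dataset(1)
        est = PolypRiskClassifier(mode="sigmoid_kde", exponent=1)
        path = backward_eliminate(ds, est, cv=3, seed=1, floor=3)
        p = ds.X.shape[1]
        assert len(path) == p - 3 + 1
        for a, b in zip(path, path[1:]):
            assert set(b.features) < set(a.features)
            assert len(a.features) - len(b.features) == 1

    def test_planted_signal_survives_to_floor(self):
        wins = 0
        for seed in range(10):
            ds = _planted_dataset(seed)
            train, _ = split_train_test(ds, 0.25, seed)
            est = PolypRiskClassifier(
                classifier="logistic_regression", mode="sigmoid_kde", random_state=seed
            )
            path = backward_eliminate(train, est, cv=5, seed=seed, floor=3)
            if {"sig_0", "sig_1"} <= set(path[-1].features):
                wins += 1
        assert wins >= 8

    def test_deterministic(self):
        ds = _planted_dataset(3, n=300)
        est = PolypRiskClassifier(mode="kde")
        p1 = backward_eliminate(ds, est, cv=3, seed=5)
        p2 = backward_eliminate(ds, est, cv=3, seed=5)
        assert [c.features for c in p1] == [c.features for c in p2]
        assert [c.cv_mcc for c in p1] == [c.cv_mcc for c in p2]


class TestBandwidthSearch:
    def test_single_element_grid_returned(self):
        ds = _planted_dataset(0, n=200, deltas=(1.0,), n_noise=2)
        est = PolypRiskClassifier(mode="kde", features=["sig_0"])
        assert optimize_bandwidth(ds, "sig_0", est, h_grid=[0.37], cv=3) == 0.37

    def test_degenerate_feature_gets_silverman_default(self):
        X = pd.DataFrame({"flat": np.ones(100), "ok": np.arange(100.0)})
        y = np.array([0, 1] * 50)
        ds = LabeledDataset(X, y, "male", 0)
        est = PolypRiskClassifier(mode="kde")
        with pytest.warns(UserWarning, match="degenerate"):
            h = optimize_bandwidth(ds, "flat", est, cv=2)
        assert h > 0

    def test_bimodal_signal_prefers_small_bandwidth(self, rng):
        """Signal separable only at small widths: the positive class sits in
        two tight clusters inside the negative class's spread."""
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            n = 400
            y = (r.random(n) < 0.5).astype(int)
            x = np.where(
                y == 1,
                np.where(r.random(n) < 0.5, r.normal(0, 0.04, n), r.normal(1, 0.04, n)),
                r.normal(0.5, 0.45, n),
            )
            ds = LabeledDataset(pd.DataFrame({"f": x}), y, "male", 0)
            est = PolypRiskClassifier(
                classifier="logistic_regression", mode="kde", random_state=seed
            )
            from polyprisk.kde import silverman_bandwidth

            h0 = silverman_bandwidth(x[y == 1])
            grid = [h0 * f for f in (0.25, 0.5, 1, 2, 4)]
            h = optimize_bandwidth(ds, "f", est, h_grid=grid, cv=5, seed=seed)
            if h <= h0 * 0.5:
                hits += 1
        assert hits >= 8


class TestRunGrid:
    def _data(self, seed=0):
        ds = _planted_dataset(seed, n=240, deltas=(1.2,), n_noise=2)
        train, test = split_train_test(ds, 0.25, seed)
        return {0: ThresholdData(0, train, test)}

    def test_mode_none_has_no_exponent(self):
        data = self._data()
        _, table = run_grid(
            data, sex="male", modes=("none",), zoo=("lda", "ridge"), cv=3
        )
        assert table["exponent"].isna().all()
        assert len(table) == 2

    def test_grid_combinatorics(self, small_cohort):
        spec, records = small_cohort
        data = prepare_threshold_data(
            records, spec.schema(), "male", thresholds=(0, 6, 8, 10), seed=0
        )
        _, table = run_grid(
            data, sex="male", modes=("none", "kde", "sigmoid_kde"),
            exponents=(1, 2, 3, 4), zoo=("lda", "logistic_regression"), cv=3,
        )
        # 4 thresholds x (1 none + 2 modes x 4 exponents) x 2 classifiers
        assert len(table) == 4 * (1 + 2 * 4) * 2

    def test_cv_mcc_matches_fold_recomputation(self):
        ds = _planted_dataset(2, n=300)
        est = PolypRiskClassifier(mode="sigmoid_kde", exponent=2)
        mean, fold_mccs, folds = cv_mcc(est, ds.X, ds.y, cv=5, seed=2, return_folds=True)
        recomputed = []
        for f in folds:
            yt, yp = f["y_true"], f["y_pred"]
            tp = int(((yt == 1) & (yp == 1)).sum())
            tn = int(((yt == 0) & (yp == 0)).sum())
            fp = int(((yt == 0) & (yp == 1)).sum())
            fn = int(((yt == 1) & (yp == 0)).sum())
            recomputed.append(mcc_counts(tp, tn, fp, fn))
        assert fold_mccs == pytest.approx(recomputed)
        assert mean == pytest.approx(np.mean(recomputed))


class TestSelectBest:
    def _candidates_and_data(self, seed):
        ds = _planted_dataset(seed, n=400, deltas=(1.5,), n_noise=4)
        train, test = split_train_test(ds, 0.25, seed)
        data = {0: ThresholdData(0, train, test)}
        noise_feats = [c for c in ds.X.columns if c.startswith("noise")]

        def cand(features):
            est = PolypRiskClassifier(
                classifier="logistic_regression", mode="none", features=list(features),
                random_state=seed,
            )
            return CandidateModel(
                sex="male", threshold_mm=0, mode="none", exponent=None,
                classifier="logistic_regression", features=tuple(features),
                cv_mcc=cv_mcc(est, train.X, train.y, cv=3, seed=seed), seed=seed,
            )

        dominant = cand(["sig_0"])
        noise_cands = [cand([f]) for f in noise_feats]
        return [dominant] + noise_cands, data, dominant

    def test_dominant_model_selected(self):
        hits = 0
        for seed in range(10):
            cands, data, dominant = self._candidates_and_data(seed)
            sel = select_best(cands, data, k=len(cands))
            if sel.best.features == dominant.features:
                hits += 1
        assert hits >= 9

    def test_k1_equals_cv_argmax_on_test(self):
        cands, data, _ = self._candidates_and_data(0)
        sel = select_best(cands, data, k=1)
        cv_best = max(cands, key=lambda c: c.cv_mcc)
        assert sel.best.features == cv_best.features

    def test_report_self_consistent(self):
        cands, data, _ = self._candidates_and_data(1)
        sel = select_best(cands, data, k=3)
        td = data[0]
        pred = sel.estimator.predict(td.test.X)
        tp = int(((td.test.y == 1) & (pred == 1)).sum())
        tn = int(((td.test.y == 0) & (pred == 0)).sum())
        assert sel.report.tp == tp and sel.report.tn == tn

    def test_k_exceeding_candidates_warns_and_uses_all(self):
        cands, data, _ = self._candidates_and_data(2)
        with pytest.warns(UserWarning, match="exceeds"):
            sel = select_best(cands[:2], data, k=10)
        assert len(sel.evaluated) == 2


class TestPolypScore:
    def test_separated_classes_score_in_order(self):
        X = pd.DataFrame({"a": np.r_[np.zeros(20), np.ones(20)],
                          "b": np.r_[np.zeros(20), np.ones(20)]})
        y = np.r_[np.zeros(20, int), np.ones(20, int)]
        X += np.random.default_rng(0).normal(0, 0.01, X.shape)
        est = PolypRiskClassifier(classifier="logistic_regression", mode="none").fit(X, y)
        s = est.polyp_score(X)
        assert s[y == 1].min() > s[y == 0].max()

    def test_decision_function_scaling_is_monotone(self):
        ds = _planted_dataset(4, n=200)
        est = PolypRiskClassifier(classifier="ridge", mode="none").fit(ds.X, ds.y)
        d = est.classifier_.decision_function(
            est.transformer_.transform(ds.X.fillna(est.medians_)).to_numpy()
        )
        s = est.polyp_score(ds.X)
        assert (s >= 0).all() and (s <= 1).all()
        order_d = np.argsort(d, kind="stable")
        order_s = np.argsort(s, kind="stable")
        assert (order_d == order_s).all()

    def test_scores_deterministic_across_calls(self):
        ds = _planted_dataset(5, n=200)
        est = PolypRiskClassifier(mode="sigmoid_kde", exponent=3).fit(ds.X, ds.y)
        np.testing.assert_array_equal(est.polyp_score(ds.X), est.polyp_score(ds.X))

    def test_unfitted_model_raises(self):
        est = PolypRiskClassifier()
        with pytest.raises(Exception):
            est.polyp_score(pd.DataFrame({"a": [1.0]}))
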