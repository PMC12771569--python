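"""Feature assembly, kernel reduction, block-grouped CV, prediction."""

import numpy as np
import pandas as pd
import pytest

from mindstate import stateclf as sc
from mindstate.epoching import UNLABELED
from mindstate.errors import DataError


def synthetic_table(rng, n_per_class=30, n_features=20, sep=4.0, n_blocks=6,
                    unlabeled=0):
    """Three Gaussian clusters (one per state) spread over blocks."""
    rows, X = [], []
    centers = {"ON": 0.0, "MW": sep, "MB": 2 * sep}
    trial = 0
    for state, c in centers.items():
        for i in range(n_per_class):
            x = rng.standard_normal(n_features)
            x[:5] += c
            X.append(x)
            rows.append({"trial": trial, "subject": "S0",
                         "block": trial % n_blocks, "label": state})
            trial += 1
    for i in range(unlabeled):
        state = ["ON", "MW", "MB"][i % 3]
        x = rng.standard_normal(n_features)
        x[:5] += centers[state]
        X.append(x)
        rows.append({"trial": trial, "subject": "S0", "block": trial % n_blocks,
                     "label": UNLABELED})
        trial += 1
    X = pd.DataFrame(np.array(X), columns=[f"f{i}" for i in range(n_features)])
    return sc.FeatureTable(X=X, meta=pd.DataFrame(rows))


class TestFeatureAssembly:
    def test_row_counts_and_column_order(self, rng, stim_epochs):
        from mindstate import connectivity as cn
        from mindstate import markers as mk
        from mindstate.experiments import row_average_epochs
        sub = stim_epochs.select(np.arange(10))
        mm = mk.compute_marker_matrix(sub)
        conn = {"alpha": cn.band_wsmi(row_average_epochs(sub), "alpha")}
        t1 = sc.build_feature_table(sub, mm, conn)
        t2 = sc.build_feature_table(sub, mm, conn)
        assert len(t1.X) == 10
        # 7 markers x 32 channels + 6 row pairs + 3 ERP windows x 32 channels
        assert t1.X.shape[1] == 7 * 32 + 6 + 3 * 32
        assert t1.feature_names == t2.feature_names
        assert t1.labeled_mask.sum() == (sub.metadata["state_label"] != UNLABELED).sum()

    def test_trial_mismatch_rejected(self, rng, stim_epochs):
        from mindstate import markers as mk
        sub = stim_epochs.select(np.arange(10))
        mm = mk.compute_marker_matrix(stim_epochs.select(np.arange(9)))
        with pytest.raises(DataError, match="mismatch"):
            sc.build_feature_table(sub, mm, None)


class TestKernelReducer:
    def test_deterministic_for_fixed_seed(self, rng):
        X = rng.standard_normal((40, 10))
        a = sc.KernelReducer(rng=np.random.default_rng(3)).fit_transform(X)
        b = sc.KernelReducer(rng=np.random.default_rng(3)).fit_transform(X)
        assert np.array_equal(a, b)

    def test_transform_does_not_refit(self, rng):
        Xtr = rng.standard_normal((30, 8))
        red = sc.KernelReducer(rng=np.random.default_rng(0))
        red.fit(Xtr)
        before = (red.n_components_, red.gamma_, red.mu_.copy())
        red.transform(rng.standard_normal((100, 8)) * 50 + 10)
        assert red.n_components_ == before[0]
        assert red.gamma_ == before[1]
        assert np.array_equal(red.mu_, before[2])

    def test_constant_features_dropped(self, rng):
        X = rng.standard_normal((25, 6))
        X[:, 2] = 7.0
        red = sc.KernelReducer(rng=np.random.default_rng(0))
        red.fit(X)
        assert not red.keep_[2]
        assert red.transform(X).shape[0] == 25

    def test_curve_capacity(self, rng):
        # low-dimensional curve: leading components carry >95% of the
        # kernel spectrum by construction of the retention rule
        t = rng.uniform(-2, 2, 60)
        X = np.stack([t, t ** 2], axis=1) + 0.01 * rng.standard_normal((60, 2))
        red = sc.KernelReducer(target_var=0.95, rng=np.random.default_rng(0))
        emb = red.fit_transform(X)
        ev = red.model_.eigenvalues_
        assert ev[: red.n_components_].sum() / ev.sum() >= 0.95

    def test_reduce_dim_wrapper(self, rng):
        table = synthetic_table(rng)
        reduced, red = sc.reduce_dim(table, rng=np.random.default_rng(1))
        assert len(reduced.X) == len(table.X)
        assert reduced.X.shape[1] == red.n_components_


class TestCrossval:
    def test_separable_clusters_high_accuracy(self, rng):
        table = synthetic_table(rng, sep=5.0)
        rep = sc.fit_crossval(table, np.random.default_rng(0), n_trees=100)
        assert rep.balanced_accuracy > 0.95

    def test_shuffled_labels_at_chance(self, rng):
        table = synthetic_table(rng, sep=5.0)
        meta = table.meta.copy()
        meta["label"] = np.random.default_rng(5).permutation(meta["label"].to_numpy())
        shuffled = sc.FeatureTable(X=table.X, meta=meta)
        rep = sc.fit_crossval(shuffled, np.random.default_rng(0), n_trees=50)
        assert 0.2 < rep.balanced_accuracy < 0.5

    def test_global_shift_invariance(self, rng):
        table = synthetic_table(rng, sep=3.0)
        shifted = sc.FeatureTable(X=table.X + 100.0, meta=table.meta.copy())
        a = sc.fit_crossval(table, np.random.default_rng(2), n_trees=50)
        b = sc.fit_crossval(shifted, np.random.default_rng(2), n_trees=50)
        assert a.balanced_accuracy == pytest.approx(b.balanced_accuracy, abs=0.08)

    def test_single_block_rejected(self, rng):
        table = synthetic_table(rng, n_blocks=1)
        with pytest.raises(DataError):
            sc.fit_crossval(table, np.random.default_rng(0), n_trees=20)


class TestPermutationChance:
    def test_null_median_near_one_third(self, rng):
        table = synthetic_table(rng, n_per_class=25, sep=0.0)
        rep = sc.permutation_chance(table, n_perm=60, rng=np.random.default_rng(0),
                                    n_trees=30)
        assert 0.25 < np.median(rep.null_scores) < 0.42

    def test_p_value_floor(self, rng):
        table = synthetic_table(rng, sep=5.0)
        rep = sc.permutation_chance(table, n_perm=30, rng=np.random.default_rng(0),
                                    n_trees=30)
        assert rep.p_value >= 1.0 / 31.0


class TestNoLeakage:
    def test_canary_feature_does_not_inflate_accuracy(self, rng):
        # a feature encoding the label ONLY in held-out blocks must not
        # raise CV accuracy if preprocessing and fitting are train-only
        table = synthetic_table(rng, sep=0.0, n_features=10)
        base = sc.fit_crossval(table, np.random.default_rng(4), n_trees=50)
        codes = table.meta["label"].map({"ON": 0.0, "MW": 1.0, "MB": 2.0})
        X = table.X.copy()
        # canary valid only in block 0; noise elsewhere
        canary = rng.standard_normal(len(X))
        in_block = (table.meta["block"] == 0).to_numpy()
        canary[in_block] = codes[in_block] * 10.0
        X["canary"] = canary
        poisoned = sc.FeatureTable(X=X, meta=table.meta.copy())
        rep = sc.fit_crossval(poisoned, np.random.default_rng(4), n_trees=50)
        assert rep.balanced_accuracy <= base.balanced_accuracy + 0.15


class TestPrediction:
    def test_probabilities_sum_to_one_and_cover_unlabeled(self, rng):
        table = synthetic_table(rng, sep=4.0, unlabeled=30)
        fitted = sc.fit_full(table, np.random.default_rng(0), n_trees=50)
        preds = sc.predict_unlabeled(fitted, table)
        assert len(preds) == 30
        probs = preds[[f"proba_{c}" for c in sc.CLASS_ORDER]].to_numpy()
        assert np.allclose(probs.sum(axis=1), 1.0)

    def test_separable_unlabeled_recovered(self, rng):
        table = synthetic_table(rng, sep=5.0, unlabeled=30)
        fitted = sc.fit_full(table, np.random.default_rng(0), n_trees=50)
        preds = sc.predict_unlabeled(fitted, table)
        truth = [["ON", "MW", "MB"][i % 3] for i in range(30)]
        assert (preds["predicted"].to_numpy() == np.array(truth)).mean() > 0.9

    def test_feature_name_mismatch_rejected(self, rng):
        table = synthetic_table(rng, unlabeled=5)
        fitted = sc.fit_full(table, np.random.default_rng(0), n_trees=20)
        bad = sc.FeatureTable(X=table.X.rename(columns={"f0": "weird"}),
                              meta=table.meta.copy())
        with pytest.raises(DataError):
            sc.predict_unlabeled(fitted, bad)

    def test_validation_identity_when_predictions_match_labels(self, rng):
        from mindstate import behavior as bh
        rows = []
        rng2 = np.random.default_rng(8)
        params = {"ON": (0.05, 0.2, 450), "MW": (0.1, 0.5, 420), "MB": (0.25, 0.4, 600)}
        for t in range(300):
            state = ["ON", "MW", "MB"][t % 3]
            miss, fa, rt = params[state]
            nogo = (t // 3) % 9 == 0    # No-Go trials present in every state
            responded = (rng2.random() < fa) if nogo else (rng2.random() >= miss)
            rows.append({"trial": t, "subject": "S0", "block": 0,
                         "go_nogo": "nogo" if nogo else "go",
                         "responded": responded,
                         "rt_ms": float(rng2.normal(rt, 30)) if responded else None,
                         "state_label": state})
        tab = pd.DataFrame(rows)
        preds = pd.DataFrame({"trial": tab["trial"], "predicted": tab["state_label"]})
        out = sc.validate_predictions(preds, tab)
        labeled_summary = bh.summarize_behavior(tab, drop_unlabeled=False)
        merged_summary = out["summary"]
        a = labeled_summary.sort_values("state")["miss_rate"].to_numpy()
        b = merged_summary.sort_values("state")["miss_rate"].to_numpy()
        assert np.allclose(a, b, equal_nan=True)
        assert out["recovered"]
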