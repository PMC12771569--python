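"""Trial-by-trial mind-state prediction from the multivariate marker set.

Features from stimulus-centered epochs (normalized band power, sample
entropy, compression complexity per channel; band-wise wSMI per region pair;
windowed ERP amplitudes per channel) feed an imputation -> standardization ->
kernel-PCA -> random-forest pipeline.  Evaluation is leave-one-block-out
cross-validation (trials are temporally clustered, so block-grouped folds
avoid proximity leakage), scored with pooled balanced accuracy; chance level
comes from label permutations that re-run the identical CV.  The fitted
pipeline then predicts the mind state of unlabeled trials (those more than
5 s away from any probe), which are validated behaviorally.

No-leakage contract: imputation medians, standardization moments, the kernel
PCA embedding and the forest are all fitted on training folds only.  Because
none of the preprocessing sees the labels, permutations reuse the fold-wise
embeddings and refit only the forest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA, KernelPCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import balanced_accuracy_score

from .connectivity import ConnectivityResult
from .epoching import UNLABELED, EpochSet
from .errors import DataError
from .markers import MarkerMatrix

logger = logging.getLogger(__name__)

#: class order used for tie-breaking (ties resolve toward ON)
CLASS_ORDER = ("ON", "MW", "MB")

#: post-stimulus ERP summary windows, seconds
ERP_WINDOWS = ((0.08, 0.15), (0.15, 0.35), (0.35, 0.70))

N_TREES = 300


# ---------------------------------------------------------------------------
# feature assembly
# ---------------------------------------------------------------------------

@dataclass
class FeatureTable:
    """One row per stimulus epoch: features + (label, block, subject, trial)."""

    X: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self):
        if len(self.X) != len(self.meta):
            raise DataError("feature rows and metadata rows differ")

    @property
    def labeled_mask(self) -> np.ndarray:
        return (self.meta["label"] != UNLABELED).to_numpy()

    @property
    def feature_names(self) -> list:
        return list(self.X.columns)


def erp_window_features(epochs: EpochSet, windows=ERP_WINDOWS) -> pd.DataFrame:
    """Per-channel mean amplitude in each post-stimulus window."""
    cols = {}
    t = epochs.times
    for (lo, hi) in windows:
        sel = (t >= lo) & (t < hi)
        mean = epochs.data[:, :, sel].mean(axis=2)
        for c, name in enumerate(epochs.channel_names):
            cols[f"erp_{int(lo * 1000)}_{int(hi * 1000)}_{name}"] = mean[:, c]
    return pd.DataFrame(cols)


def build_feature_table(stim_epochs: EpochSet, markers: MarkerMatrix,
                        connectivity: dict | None = None,
                        erp_summaries: pd.DataFrame | None = None) -> FeatureTable:
    """Row-aligned concatenation of all marker groups.

    ``connectivity`` maps band name to a per-trial ConnectivityResult whose
    upper-triangle entries become features.  Labeled rows are those the 5-s
    rule labeled in the epoch metadata; everything else is unlabeled.
    """
    n = stim_epochs.n_trials
    if markers.n_trials != n:
        raise DataError(f"trial-id mismatch: epochs have {n} trials, markers {markers.n_trials}")
    blocks = {}
    for m, name in enumerate(markers.marker_names):
        for c, ch in enumerate(markers.channel_names):
            blocks[f"{name}_{ch}"] = markers.values[:, c, m]
    if connectivity:
        for band_name in sorted(connectivity):
            conn: ConnectivityResult = connectivity[band_name]
            if conn.matrix.shape[0] != n:
                raise DataError(
                    f"trial-id mismatch: connectivity[{band_name}] has {conn.matrix.shape[0]} trials")
            iu = np.triu_indices(conn.n_nodes, k=1)
            for i, j in zip(*iu):
                blocks[f"{conn.metric}_{band_name}_{conn.node_names[i]}-{conn.node_names[j]}"] = \
                    conn.matrix[:, i, j]
    if erp_summaries is None:
        erp_summaries = erp_window_features(stim_epochs)
    if len(erp_summaries) != n:
        raise DataError("trial-id mismatch: erp_summaries")
    for col in erp_summaries.columns:
        blocks[col] = erp_summaries[col].to_numpy()

    X = pd.DataFrame(blocks)
    meta = pd.DataFrame({
        "trial": np.arange(n),
        "subject": stim_epochs.metadata["subject"].to_numpy(),
        "block": stim_epochs.metadata["block"].to_numpy(),
        "label": stim_epochs.metadata["state_label"].to_numpy(),
    })
    return FeatureTable(X=X, meta=meta)


# ---------------------------------------------------------------------------
# dimensionality reduction
# ---------------------------------------------------------------------------

class KernelReducer:
    """Standardize -> (kernel) PCA, fitted on training rows only.

    RBF kernel width follows the median pairwise-distance heuristic
    (``gamma = 1 / (2 median^2)``); components are kept up to
    ``target_var`` cumulative (kernel) eigenvalue mass, capped at
    ``n_rows - 1``.  Constant features are dropped with a warning before
    fitting.  ``linear=True`` swaps in ordinary PCA.
    """

    def __init__(self, target_var: float = 0.95, linear: bool = False,
                 rng: np.random.Generator | None = None):
        self.target_var = target_var
        self.linear = linear
        self.rng = rng or np.random.default_rng()
        self.fitted_ = False

    def _impute(self, X: np.ndarray) -> np.ndarray:
        X = np.where(np.isfinite(X), X, np.nan)
        return np.where(np.isnan(X), self.medians_, X)

    def fit(self, X: np.ndarray) -> "KernelReducer":
        X = np.asarray(X, dtype=float)
        with np.errstate(all="ignore"):
            self.medians_ = np.nanmedian(np.where(np.isfinite(X), X, np.nan), axis=0)
        self.medians_ = np.where(np.isfinite(self.medians_), self.medians_, 0.0)
        X = self._impute(X)
        sd = X.std(axis=0)
        self.keep_ = sd > 0
        if not self.keep_.all():
            logger.warning("dropping %d constant feature(s)", int((~self.keep_).sum()))
        self.mu_ = X.mean(axis=0)[self.keep_]
        self.sd_ = sd[self.keep_]
        Z = (X[:, self.keep_] - self.mu_) / self.sd_
        n = Z.shape[0]
        if n < 2:
            raise DataError("need >= 2 rows to fit the reducer")
        if self.linear:
            self.model_ = PCA(n_components=min(n - 1, Z.shape[1]),
                              random_state=int(self.rng.integers(2 ** 31 - 1)))
            emb = self.model_.fit_transform(Z)
            ev = self.model_.explained_variance_
        else:
            sub = Z if n <= 400 else Z[self.rng.choice(n, 400, replace=False)]
            d2 = np.sum((sub[:, None, :] - sub[None, :, :]) ** 2, axis=-1)
            med = np.median(d2[np.triu_indices(sub.shape[0], k=1)])
            self.gamma_ = 1.0 / (2.0 * med) if med > 0 else 1.0 / Z.shape[1]
            self.model_ = KernelPCA(n_components=n - 1, kernel="rbf", gamma=self.gamma_,
                                    random_state=int(self.rng.integers(2 ** 31 - 1)))
            emb = self.model_.fit_transform(Z)
            ev = self.model_.eigenvalues_
        frac = np.cumsum(ev) / ev.sum()
        self.n_components_ = int(np.searchsorted(frac, self.target_var) + 1)
        self.fitted_ = True
        self._train_embedding = emb[:, : self.n_components_]
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if not self.fitted_:
            raise DataError("reducer not fitted")
        X = self._impute(np.asarray(X, dtype=float))
        Z = (X[:, self.keep_] - self.mu_) / self.sd_
        return self.model_.transform(Z)[:, : self.n_components_]

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        self.fit(X)
        return self._train_embedding


def reduce_dim(table: FeatureTable, target_var: float = 0.95,
               rng: np.random.Generator | None = None, linear: bool = False):
    """Fit a :class:`KernelReducer` on the table and return (reduced table,
    fitted reducer); downstream CV fits its own per-fold reducers."""
    red = KernelReducer(target_var=target_var, linear=linear, rng=rng)
    emb = red.fit_transform(table.X.to_numpy())
    cols = [f"pc{i + 1}" for i in range(emb.shape[1])]
    return FeatureTable(X=pd.DataFrame(emb, columns=cols), meta=table.meta.copy()), red


# ---------------------------------------------------------------------------
# block-grouped cross-validation
# ---------------------------------------------------------------------------

@dataclass
class StateClassifierReport:
    subject: str
    balanced_accuracy: float
    fold_predictions: pd.DataFrame
    null_scores: np.ndarray | None = None
    p_value: float | None = None
    n_labeled: int = 0
    classes: tuple = CLASS_ORDER
    pipeline: object | None = None
    extras: dict = field(default_factory=dict)


def _prepared_folds(table: FeatureTable, rng: np.random.Generator,
                    target_var: float = 0.95, linear: bool = False):
    """Per-fold label-blind preprocessing for leave-one-block-out CV.

    Returns (folds, y, blocks): each fold carries the embedded train/test
    features and row indices into the labeled subset.
    """
    lab = table.labeled_mask
    X = table.X.to_numpy()[lab]
    y = table.meta.loc[lab, "label"].to_numpy()
    blocks = table.meta.loc[lab, "block"].to_numpy()
    uniq = np.unique(blocks)
    if uniq.size < 2:
        raise DataError("need >= 2 blocks for block-grouped CV")
    folds = []
    for b in uniq:
        te = np.flatnonzero(blocks == b)
        tr = np.flatnonzero(blocks != b)
        if np.unique(y[tr]).size < 2:
            raise DataError(f"training folds for block {b} contain < 2 classes")
        red = KernelReducer(target_var=target_var, linear=linear,
                            rng=np.random.default_rng(int(rng.integers(2 ** 31 - 1))))
        Ztr = red.fit_transform(X[tr])
        Zte = red.transform(X[te])
        folds.append({"train": tr, "test": te, "Ztr": Ztr, "Zte": Zte})
    return folds, y, blocks


def _forest(rng: np.random.Generator, n_trees: int = N_TREES) -> RandomForestClassifier:
    return RandomForestClassifier(n_estimators=n_trees, class_weight="balanced_subsample",
                                  random_state=int(rng.integers(2 ** 31 - 1)), n_jobs=1)


def _balanced_rows(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Row indices downsampling every class to the smallest class count.

    Labeled trials arrive in probe clusters, so class counts can be very
    uneven; training the forest on a balanced subsample keeps majority
    classes from absorbing the decision space (class weights alone do not,
    because within-cluster trials are strongly correlated).
    """
    classes, counts = np.unique(y, return_counts=True)
    n_min = counts.min()
    keep = np.concatenate([
        rng.choice(np.flatnonzero(y == c), n_min, replace=False) for c in classes
    ])
    return np.sort(keep)


def _run_cv(folds, y, rng: np.random.Generator, n_trees: int = N_TREES):
    """One CV pass: pooled held-out predictions and balanced accuracy."""
    pred = np.empty(y.size, dtype=object)
    proba = np.full((y.size, len(CLASS_ORDER)), np.nan)
    for f in folds:
        clf = _forest(rng, n_trees)
        y_tr = y[f["train"]]
        rows = _balanced_rows(y_tr, rng)
        clf.fit(f["Ztr"][rows], y_tr[rows])
        pr = clf.predict_proba(f["Zte"])
        cols = {c: i for i, c in enumerate(clf.classes_)}
        for k, cls in enumerate(CLASS_ORDER):
            if cls in cols:
                proba[f["test"], k] = pr[:, cols[cls]]
        proba[f["test"]] = np.nan_to_num(proba[f["test"]], nan=0.0)
        pred[f["test"]] = np.asarray(CLASS_ORDER)[np.argmax(proba[f["test"]], axis=1)]
    score = balanced_accuracy_score(y, pred.astype(str))
    return score, pred, proba


def fit_crossval(table: FeatureTable, rng: np.random.Generator | None = None,
                 target_var: float = 0.95, linear: bool = False,
                 n_trees: int = N_TREES, _folds_cache=None) -> StateClassifierReport:
    """Leave-one-block-out CV on the labeled rows of ``table``.

    Pipeline per fold: impute (train medians) -> standardize -> kernel PCA ->
    random forest (class-balanced subsampling; 300 trees by default).
    Score = balanced accuracy of the pooled held-out predictions.
    """
    rng = rng or np.random.default_rng()
    folds, y, blocks = _folds_cache or _prepared_folds(table, rng, target_var, linear)
    score, pred, proba = _run_cv(folds, y, rng, n_trees)
    lab_idx = np.flatnonzero(table.labeled_mask)
    fold_pred = pd.DataFrame({"trial": table.meta.loc[lab_idx, "trial"].to_numpy(),
                              "block": blocks, "label": y, "predicted": pred.astype(str)})
    for k, cls in enumerate(CLASS_ORDER):
        fold_pred[f"proba_{cls}"] = proba[:, k]
    subject = str(table.meta["subject"].iloc[0]) if len(table.meta) else "?"
    return StateClassifierReport(subject=subject, balanced_accuracy=float(score),
                                 fold_predictions=fold_pred, n_labeled=int(y.size),
                                 extras={"folds": folds, "y": y})


def permutation_chance(table: FeatureTable, n_perm: int = 500,
                       rng: np.random.Generator | None = None,
                       report: StateClassifierReport | None = None,
                       target_var: float = 0.95, linear: bool = False,
                       n_trees: int = N_TREES) -> StateClassifierReport:
    """Permutation chance level: labels shuffled within subject (class counts
    preserved), full CV re-run each time; the label-blind fold embeddings are
    reused.  Empirical p uses the add-one estimator."""
    if n_perm < 100:
        logger.warning("n_perm=%d < 100: unstable null tails", n_perm)
    rng = rng or np.random.default_rng()
    if report is None or "folds" not in report.extras:
        report = fit_crossval(table, rng, target_var=target_var, linear=linear, n_trees=n_trees)
    folds, y = report.extras["folds"], report.extras["y"]
    null = np.empty(n_perm)
    for i in range(n_perm):
        y_perm = rng.permutation(y)
        # a permutation may empty a class from some training fold; score what runs
        try:
            null[i], _, _ = _run_cv(folds, y_perm, rng, n_trees)
        except ValueError:
            null[i] = np.nan
    null = null[~np.isnan(null)]
    p = (1.0 + (null >= report.balanced_accuracy).sum()) / (null.size + 1.0)
    report.null_scores = null
    report.p_value = float(p)
    return report


def group_chance_test(true_scores, null_medians) -> float:
    """Group-level comparison of true vs permuted-median scores across
    subjects (rank-sum test)."""
    return float(stats.ranksums(np.asarray(true_scores), np.asarray(null_medians),
                                alternative="greater").pvalue)


# ---------------------------------------------------------------------------
# prediction of unlabeled trials and behavioral validation
# ---------------------------------------------------------------------------

@dataclass
class FittedPipeline:
    reducer: KernelReducer
    forest: RandomForestClassifier
    feature_names: list
    classes: tuple = CLASS_ORDER


def fit_full(table: FeatureTable, rng: np.random.Generator | None = None,
             target_var: float = 0.95, linear: bool = False,
             n_trees: int = N_TREES) -> FittedPipeline:
    """Fit the full pipeline on all labeled rows (for unlabeled prediction)."""
    rng = rng or np.random.default_rng()
    lab = table.labeled_mask
    if lab.sum() < 2:
        raise DataError("need labeled rows to fit")
    red = KernelReducer(target_var=target_var, linear=linear,
                        rng=np.random.default_rng(int(rng.integers(2 ** 31 - 1))))
    Z = red.fit_transform(table.X.to_numpy()[lab])
    y = table.meta.loc[lab, "label"].to_numpy()
    rows = _balanced_rows(y, rng)
    clf = _forest(rng, n_trees)
    clf.fit(Z[rows], y[rows])
    return FittedPipeline(reducer=red, forest=clf, feature_names=table.feature_names)


def predict_unlabeled(fitted: FittedPipeline, table: FeatureTable) -> pd.DataFrame:
    """Predict the mind state of every unlabeled row.

    Returns trial ids, class probabilities and the argmax state (ties broken
    toward ON, then MW).
    """
    if list(table.feature_names) != list(fitted.feature_names):
        raise DataError("feature-name mismatch between fitted pipeline and table")
    unl = ~table.labeled_mask
    Z = fitted.reducer.transform(table.X.to_numpy()[unl])
    pr = fitted.forest.predict_proba(Z)
    cols = {c: i for i, c in enumerate(fitted.forest.classes_)}
    proba = np.zeros((Z.shape[0], len(CLASS_ORDER)))
    for k, cls in enumerate(CLASS_ORDER):
        if cls in cols:
            proba[:, k] = pr[:, cols[cls]]
    pred = np.asarray(CLASS_ORDER)[np.argmax(proba, axis=1)]
    out = pd.DataFrame({"trial": table.meta.loc[unl, "trial"].to_numpy(),
                        "predicted": pred})
    for k, cls in enumerate(CLASS_ORDER):
        out[f"proba_{cls}"] = proba[:, k]
    return out


def validate_predictions(predictions: pd.DataFrame, table: pd.DataFrame,
                         rng: np.random.Generator | None = None) -> dict:
    """Behavioral validation of predicted states.

    Joins predictions to the trial behavior table, recomputes the per-state
    behavior summary under predicted labels, and reports whether the
    reported-state behavioral signature is recovered: most misses and slowest
    RTs in predicted MB, more FAs in predicted MW than predicted ON.
    """
    from .behavior import summarize_behavior

    tab = table.copy()
    if "trial" not in tab.columns:
        tab["trial"] = np.arange(len(tab))
    merged = tab.merge(predictions[["trial", "predicted"]], on="trial", how="inner")
    if len(merged) == 0:
        raise DataError("predictions not joinable to behavior table")
    merged["state_label"] = merged["predicted"]
    summary = summarize_behavior(merged, drop_unlabeled=False)
    piv = summary.groupby("state").agg(
        miss_rate=("miss_rate", "mean"), fa_rate=("fa_rate", "mean"),
        rt_median=("rt_median", "mean")).reindex(list(CLASS_ORDER))
    present = [s for s in CLASS_ORDER if s in summary["state"].unique()]
    for s in set(CLASS_ORDER) - set(present):
        logger.warning("predicted class %s empty; skipped in validation", s)
    checks = {}
    if {"ON", "MW", "MB"} <= set(present):
        checks["mb_most_misses"] = bool(
            piv.loc["MB", "miss_rate"] > max(piv.loc["ON", "miss_rate"], piv.loc["MW", "miss_rate"]))
        checks["mb_slowest_rt"] = bool(
            piv.loc["MB", "rt_median"] > max(piv.loc["ON", "rt_median"], piv.loc["MW", "rt_median"]))
        checks["mw_more_fa_than_on"] = bool(piv.loc["MW", "fa_rate"] > piv.loc["ON", "fa_rate"])
    return {"summary": summary, "by_state": piv, "checks": checks,
            "recovered": bool(checks and all(checks.values()))}
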