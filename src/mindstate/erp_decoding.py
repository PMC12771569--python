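"""ERP averages/contrasts and per-timepoint MVPA decoding.

The temporal decoder trains, at every timepoint, a regularized linear
discriminative model on the channel amplitudes (diagonal-covariance LDA on
within-fold standardized features) under stratified k-fold cross-validation,
and scores it with the ROC AUC of the held-out decision values.  Because the
model is linear in sufficient statistics, the whole curve — and the full
label-permutation null — is computed with batched matrix operations: the
permutation chance distribution re-runs the identical CV on shuffled labels.

Significance is the add-one permutation p-value per timepoint,
Benjamini-Hochberg corrected across timepoints.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .epoching import EpochSet
from .errors import DataError, ParameterError
from .groupstats import fdr_bh

logger = logging.getLogger(__name__)

#: variance ridge added to the (standardized) pooled per-feature variance
VAR_RIDGE = 0.1


@dataclass
class ErpResult:
    """Per-group mean waveforms (groups x channels x time) and trial counts."""

    groups: list
    mean: np.ndarray
    counts: list
    times: np.ndarray
    channel_names: list


@dataclass
class ContrastMap:
    """Per channel x timepoint state contrast with BH-FDR mask."""

    pair: tuple
    effect: np.ndarray       # (channels, time): mean(A) - mean(B)
    p: np.ndarray
    q: np.ndarray
    mask: np.ndarray         # q < alpha
    times: np.ndarray
    channel_names: list
    alpha: float = 0.05


@dataclass
class DecodingCurve:
    """Per-timepoint cross-validated ROC AUC with permutation null."""

    times: np.ndarray
    auc: np.ndarray
    n_per_class: dict
    null_quantiles: np.ndarray | None = None   # (3, time): 2.5 / 50 / 97.5%
    p: np.ndarray | None = None
    significant: np.ndarray | None = None
    alpha: float = 0.05


def compute_erp(epochs: EpochSet, group_by: str = "state_label",
                category: str | None = None) -> ErpResult:
    """Mean waveform per level of ``group_by`` (empty groups are omitted with
    a warning); optionally restricted to one stimulus category."""
    meta = epochs.metadata
    data = epochs.data
    if category is not None:
        keep = (meta["stimulus_category"] == category).to_numpy()
        data, meta = data[keep], meta[keep]
    groups, means, counts = [], [], []
    for g, sub in meta.groupby(group_by, sort=True):
        idx = sub.index.to_numpy()
        if idx.size == 0:
            logger.warning("group %r empty; omitted", g)
            continue
        groups.append(g)
        means.append(data[idx].mean(axis=0))
        counts.append(int(idx.size))
    if not groups:
        raise DataError("no non-empty groups")
    return ErpResult(groups=groups, mean=np.stack(means), counts=counts,
                     times=epochs.times, channel_names=list(epochs.channel_names))


def erp_state_contrast(epochs: EpochSet, pair: tuple, alpha: float = 0.05) -> ContrastMap:
    """Channel x time contrast between two states with joint BH-FDR masking.

    Multi-subject input (>= 2 subjects with both states) uses the two-stage
    hierarchical contrast: subject-level trial means, then a paired t-test
    across subjects.  Single-subject input uses a Welch t-test over trials.
    """
    a, b = pair
    meta = epochs.metadata
    present = set(meta["state_label"].unique())
    missing = [s for s in pair if s not in present]
    if missing:
        raise DataError(f"state(s) {missing} absent; present: {sorted(present)}")
    subjects = meta["subject"].unique() if "subject" in meta else ["_single"]
    per_subject = []
    if len(subjects) >= 2:
        for s in subjects:
            sel = meta["subject"] == s
            ia = np.flatnonzero(sel & (meta["state_label"] == a))
            ib = np.flatnonzero(sel & (meta["state_label"] == b))
            if ia.size and ib.size:
                per_subject.append(epochs.data[ia].mean(axis=0) - epochs.data[ib].mean(axis=0))
    if len(per_subject) >= 2:
        diffs = np.stack(per_subject)
        effect = diffs.mean(axis=0)
        tstat, p = stats.ttest_1samp(diffs, 0.0, axis=0)
    else:
        xa = epochs.data[np.flatnonzero(meta["state_label"] == a)]
        xb = epochs.data[np.flatnonzero(meta["state_label"] == b)]
        effect = xa.mean(axis=0) - xb.mean(axis=0)
        tstat, p = stats.ttest_ind(xa, xb, axis=0, equal_var=False)
    q, mask = fdr_bh(p.ravel(), q=alpha)
    return ContrastMap(pair=pair, effect=effect, p=p,
                       q=q.reshape(p.shape), mask=mask.reshape(p.shape),
                       times=epochs.times, channel_names=list(epochs.channel_names),
                       alpha=alpha)


def balance_subsample(epochs: EpochSet, by: str = "state_label",
                      rng: np.random.Generator | None = None) -> EpochSet:
    """Downsample every group to the smallest group's size, without
    replacement (seeded)."""
    rng = rng or np.random.default_rng()
    meta = epochs.metadata
    groups = meta.groupby(by, sort=True).indices
    if len(groups) < 2:
        raise DataError("need >= 2 non-empty groups to balance")
    sizes = {g: len(ix) for g, ix in groups.items()}
    if min(sizes.values()) == 0:
        raise DataError(f"empty group in {sizes}")
    n_min = min(sizes.values())
    keep = np.concatenate([
        np.sort(rng.choice(ix, size=n_min, replace=False)) for ix in groups.values()
    ])
    return epochs.select(np.sort(keep))


# ---------------------------------------------------------------------------
# batched diagonal-LDA temporal decoding
# ---------------------------------------------------------------------------

def _stratified_folds(y: np.ndarray, n_folds: int, rng: np.random.Generator):
    from sklearn.model_selection import StratifiedKFold
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                          random_state=int(rng.integers(2 ** 31 - 1)))
    return list(skf.split(np.zeros(y.size), y))


def _cv_auc_batched(X: np.ndarray, labels: np.ndarray, folds,
                    return_details: bool = False):
    """Cross-validated per-timepoint AUC for one or many label vectors.

    ``X`` is (trials, channels, time); ``labels`` is (trials, P) of 0/1 for P
    label assignments (column 0 is typically the observed labels, the rest
    permutations).  Returns AUC of shape (time, P): the unweighted mean of
    per-fold Mann-Whitney AUCs of the diagonal-LDA decision values.
    """
    n, C, T = X.shape
    L = labels.astype(float)
    if L.ndim == 1:
        L = L[:, None]
    P = L.shape[1]
    auc_sum = np.zeros((T, P))
    auc_cnt = np.zeros((T, P))
    details = []
    for tr, te in folds:
        Xtr, Xte = X[tr], X[te]
        mu = Xtr.mean(axis=0, keepdims=True)
        sd = Xtr.std(axis=0, keepdims=True)
        sd[sd == 0] = 1.0
        Ztr = ((Xtr - mu) / sd).reshape(tr.size, C * T)
        Zte = ((Xte - mu) / sd).reshape(te.size, C * T)
        Ltr, Lte = L[tr], L[te]
        n1 = Ltr.sum(axis=0)                      # (P,)
        n0 = tr.size - n1
        valid_tr = (n1 > 0) & (n0 > 0)
        s1 = Ztr.T @ Ltr                          # (CT, P)
        s_all = Ztr.sum(axis=0)[:, None]
        with np.errstate(invalid="ignore", divide="ignore"):
            m1 = s1 / n1
            m0 = (s_all - s1) / n0
            s2 = (Ztr ** 2).sum(axis=0)[:, None]
            var = (s2 - n1 * m1 ** 2 - n0 * m0 ** 2) / np.maximum(tr.size - 2, 1)
        w = (m1 - m0) / (var + VAR_RIDGE)         # (CT, P)
        # decision value per timepoint: sum over channels of w * z
        Wt = w.reshape(C, T, P)
        scores = np.einsum("nct,ctp->ntp", Zte.reshape(te.size, C, T), Wt, optimize=True)
        ranks = stats.rankdata(scores, axis=0)
        n1te = Lte.sum(axis=0)
        n0te = te.size - n1te
        valid = valid_tr & (n1te > 0) & (n0te > 0)
        sum_r1 = np.einsum("ntp,np->tp", ranks, Lte, optimize=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            auc = (sum_r1 - n1te * (n1te + 1) / 2.0) / (n0te * n1te)
        auc[:, ~valid] = 0.0
        auc_sum += auc
        auc_cnt += valid[None, :]
        if return_details:
            details.append({"test_idx": te, "scores": scores[:, :, 0],
                            "y_test": L[te, 0].astype(int)})
    if (auc_cnt == 0).any():
        logger.warning("some label columns had no valid fold (class collapse)")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = auc_sum / np.maximum(auc_cnt, 1)
    return (out, details) if return_details else out


def _binary_labels(meta: pd.DataFrame, label_col: str):
    lab = meta[label_col].to_numpy()
    classes = sorted(pd.unique(lab))
    if len(classes) != 2:
        raise DataError(f"need exactly 2 classes in {label_col!r}, got {classes}")
    return (lab == classes[1]).astype(int), classes


def temporal_decode(epochs: EpochSet, label_col: str = "stimulus_category",
                    n_folds: int = 5, rng: np.random.Generator | None = None,
                    return_details: bool = False):
    """Per-timepoint cross-validated ROC AUC for a binary trial label."""
    rng = rng or np.random.default_rng()
    y, classes = _binary_labels(epochs.metadata, label_col)
    if min(np.bincount(y)) < n_folds:
        raise DataError(f"each class needs >= {n_folds} trials")
    folds = _stratified_folds(y, n_folds, rng)
    res = _cv_auc_batched(epochs.data, y[:, None], folds, return_details=return_details)
    auc, details = res if return_details else (res, None)
    curve = DecodingCurve(times=epochs.times, auc=auc[:, 0],
                          n_per_class={c: int(n) for c, n in zip(classes, np.bincount(y))})
    return (curve, details) if return_details else curve


def decode_significance(curve: DecodingCurve, epochs: EpochSet, n_perm: int = 500,
                        rng: np.random.Generator | None = None,
                        label_col: str = "stimulus_category",
                        n_folds: int = 5, alpha: float = 0.05) -> DecodingCurve:
    """Permutation-null significance for a decoding curve.

    The null re-runs the identical CV with label-shuffled columns; the
    per-timepoint empirical p is ``(1 + #{null >= observed}) / (n_perm + 1)``
    (never below its add-one bound), BH-FDR corrected across timepoints.
    """
    if n_perm < 100:
        logger.warning("n_perm=%d < 100: unstable null tails", n_perm)
    rng = rng or np.random.default_rng()
    y, _ = _binary_labels(epochs.metadata, label_col)
    folds = _stratified_folds(y, n_folds, rng)
    L = np.empty((y.size, n_perm + 1), dtype=int)
    L[:, 0] = y
    for p in range(1, n_perm + 1):
        L[:, p] = rng.permutation(y)
    auc = _cv_auc_batched(epochs.data, L, folds)
    obs = auc[:, 0]
    null = auc[:, 1:]
    pvals = (1.0 + (null >= obs[:, None]).sum(axis=1)) / (n_perm + 1.0)
    q, mask = fdr_bh(pvals, q=alpha)
    quant = np.percentile(null, [2.5, 50.0, 97.5], axis=1)
    return replace(curve, auc=obs, null_quantiles=quant, p=pvals,
                   significant=mask, alpha=alpha)
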