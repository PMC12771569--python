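"""Behavioral metrics per mind state: misses, false alarms, response times.

A miss is an unanswered Go trial; a false alarm (FA) an answered No-Go trial;
RT statistics are computed over responded Go trials only.  Responses landing
after the following stimulus still belong to their own stimulus when they
fall within the maximum SOA (the grace rule for the null-ISI design).

State contrasts use the two-stage surrogate for the study's mixed models:
subject-level rates/medians, then paired Wilcoxon signed-rank tests across
subjects, BH-FDR corrected over the measure x pair family.  A
``mixed_model_backend`` hook accepts an external callable for users who want
the full hierarchical model instead.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats

from .epoching import UNLABELED, EpochSet
from .errors import DataError
from .groupstats import fdr_bh

logger = logging.getLogger(__name__)

MEASURES = ("miss_rate", "fa_rate", "rt_median")


def behavior_table(epochs: EpochSet, label_col: str = "state_label") -> pd.DataFrame:
    """One row per trial from stimulus-epoch metadata (a BehaviorTable)."""
    meta = epochs.metadata
    tab = pd.DataFrame({
        "subject": meta["subject"],
        "block": meta["block"],
        "go_nogo": meta["go_nogo"],
        "responded": meta["responded"].astype(bool),
        "rt_ms": meta["rt_ms"],
        "state_label": meta[label_col],
    })
    bad = tab["rt_ms"].notna() & ~tab["responded"]
    if bad.any():
        raise DataError("rt present on unresponded trial(s)")
    return tab


def summarize_behavior(table: pd.DataFrame, drop_unlabeled: bool = True) -> pd.DataFrame:
    """Per subject x state: miss_rate, fa_rate, rt_median, rt_mean, counts.

    Cells with no Go (resp. no No-Go) trials get NaN rates, flagged rather
    than imputed, and are excluded from downstream contrasts.
    """
    if len(table) == 0:
        raise DataError("empty behavior table")
    tab = table
    if drop_unlabeled:
        tab = tab[tab["state_label"] != UNLABELED]
    rows = []
    for (subject, state), sub in tab.groupby(["subject", "state_label"], sort=True):
        go = sub[sub["go_nogo"] == "go"]
        nogo = sub[sub["go_nogo"] == "nogo"]
        go_resp = go[go["responded"]]
        rows.append({
            "subject": subject, "state": state,
            "n_trials": len(sub), "n_go": len(go), "n_nogo": len(nogo),
            "miss_rate": 1.0 - len(go_resp) / len(go) if len(go) else np.nan,
            "fa_rate": float(nogo["responded"].mean()) if len(nogo) else np.nan,
            "rt_median": float(go_resp["rt_ms"].median()) if len(go_resp) else np.nan,
            "rt_mean": float(go_resp["rt_ms"].mean()) if len(go_resp) else np.nan,
        })
    return pd.DataFrame(rows)


def _bootstrap_p(table: pd.DataFrame, measure: str, pair, n_boot: int,
                 rng: np.random.Generator) -> tuple:
    """Within-subject trial bootstrap for the single-subject synthetic mode:
    two-sided p for measure(A) - measure(B) != 0."""
    def stat(sub):
        go = sub[sub["go_nogo"] == "go"]
        nogo = sub[sub["go_nogo"] == "nogo"]
        if measure == "miss_rate":
            return 1.0 - go["responded"].mean() if len(go) else np.nan
        if measure == "fa_rate":
            return nogo["responded"].mean() if len(nogo) else np.nan
        r = go[go["responded"]]["rt_ms"]
        return r.median() if len(r) else np.nan

    ga = table[table["state_label"] == pair[0]]
    gb = table[table["state_label"] == pair[1]]
    obs = stat(ga) - stat(gb)
    if np.isnan(obs):
        return np.nan, 1.0
    deltas = np.empty(n_boot)
    for i in range(n_boot):
        ra = ga.sample(len(ga), replace=True, random_state=int(rng.integers(2 ** 31 - 1)))
        rb = gb.sample(len(gb), replace=True, random_state=int(rng.integers(2 ** 31 - 1)))
        deltas[i] = stat(ra) - stat(rb)
    deltas = deltas[~np.isnan(deltas)]
    if deltas.size == 0:
        return float(obs), 1.0
    # two-sided percentile p: does the bootstrap distribution cross 0?
    frac = (deltas <= 0).mean() if obs > 0 else (deltas >= 0).mean()
    p = min(1.0, 2.0 * max(frac, 1.0 / (deltas.size + 1)))
    return float(obs), float(p)


def behavior_state_contrast(summary: pd.DataFrame, pairs=None,
                            table: pd.DataFrame | None = None,
                            n_boot: int = 500,
                            rng: np.random.Generator | None = None,
                            alpha: float = 0.05,
                            mixed_model_backend=None) -> pd.DataFrame:
    """Pairwise state effects per measure with BH-FDR over the family.

    Group mode (>= 2 subjects): paired Wilcoxon signed-rank on subject-level
    values.  Single-subject mode needs the trial ``table`` and uses a
    within-subject bootstrap.  Effect sign follows pair order and is
    antisymmetric under reversal.

    ``mixed_model_backend`` is a hook for users who want the full
    hierarchical model instead of the two-stage surrogate: a callable
    ``backend(trial_table, measure, pair) -> (effect, p)`` that receives the
    raw trial table; it then replaces the built-in test for every contrast
    (``table`` must be provided).
    """
    states = sorted(summary["state"].unique())
    if len(states) < 2:
        raise DataError("need >= 2 states")
    if pairs is None:
        pairs = list(itertools.combinations(states, 2))
    subjects = summary["subject"].unique()
    rng = rng or np.random.default_rng()
    rows = []
    for measure in MEASURES:
        wide = summary.pivot(index="subject", columns="state", values=measure)
        for pair in pairs:
            if mixed_model_backend is not None:
                if table is None:
                    raise DataError("mixed_model_backend needs the trial table")
                effect, p = mixed_model_backend(table, measure, pair)
            elif len(subjects) >= 2:
                d = (wide[pair[0]] - wide[pair[1]]).dropna().to_numpy()
                if d.size < 2:
                    effect, p = (float(d.mean()) if d.size else np.nan), 1.0
                elif np.allclose(d, 0):
                    effect, p = 0.0, 1.0
                else:
                    effect = float(d.mean())
                    p = float(stats.wilcoxon(d, zero_method="wilcox").pvalue)
            else:
                if table is None:
                    raise DataError("single-subject mode needs the trial table")
                effect, p = _bootstrap_p(table, measure, pair, n_boot, rng)
            rows.append({"measure": measure, "state_a": pair[0], "state_b": pair[1],
                         "effect": effect, "p": p})
    out = pd.DataFrame(rows)
    q, mask = fdr_bh(out["p"].fillna(1.0).to_numpy(), q=alpha)
    out["q"] = q
    out["significant"] = mask
    return out
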