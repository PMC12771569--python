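"""Seeded end-to-end recovery studies on synthetic sessions.

Each study generates fresh sessions from the planted-signature defaults,
runs the corresponding analysis stage, and scores whether the planted
physiology is recovered — the package's built-in validation experiments:

* :func:`frontback_recovery` — MB-MW fast-power/complexity contrast signs by
  scalp row (the front-back dissociation),
* :func:`dissociation_recovery` — PLV up with wSMI down in MB vs ON on the
  coupled channel pairs,
* :func:`decoding_recovery` — per-state stimulus-category decoding pattern
  (early+late for ON, sparser late for MW, nothing for MB),
* :func:`classifier_study` — per-subject mind-state classification against
  its permutation null, prediction of unlabeled trials, and behavioral
  validation of the predictions.

Problem sizes here are deliberately desk-scale (short sessions for the
marker/connectivity studies, a 50-tree forest and a few dozen permutations
for the classifier study); docs/methods.md discusses the choices.
"""

from __future__ import annotations

import logging
from dataclasses import replace as dc_replace

import numpy as np
import pandas as pd

from . import behavior as bh
from . import connectivity as cn
from . import epoching as ep
from . import erp_decoding as ed
from . import markers as mk
from . import stateclf as sc
from . import synthgen as sg

logger = logging.getLogger(__name__)

#: decoding windows (s after stimulus onset) for the planted category code
EARLY_WINDOW = (0.14, 0.28)
LATE_WINDOW = (0.33, 0.64)

STUDY_TREES = 50


def small_session_config(seed: int, **overrides) -> sg.SessionConfig:
    """Short session (3 blocks x 80 s) for marker/connectivity recovery.

    Equal, short (15 s) dwell makes every state visit often enough that each
    contributes 5-s ground-truth segments even in a 4-minute session; the
    default prevalence-weighted dwells are for full-scale sessions.
    """
    kw = dict(n_blocks=3, block_duration=80.0, state_dwell=15.0, seed=seed)
    kw.update(overrides)
    return sg.SessionConfig(**kw)


def truth_labeled_stimuli(recording: sg.ContinuousRecording,
                          window=(-0.25, 0.75)) -> ep.EpochSet:
    """Stimulus epochs labeled by the generator's latent state at onset
    (validation path; bypasses the probe-based 5-s rule)."""
    epochs = ep.epoch_stimuli(recording, window=window)
    labels = [recording.truth_state_at(s) for s in epochs.metadata["onset_sample"]]
    meta = epochs.metadata.copy()
    meta["state_label"] = labels
    return dc_replace(epochs, metadata=meta)


def row_average_epochs(epochs: ep.EpochSet) -> ep.EpochSet:
    """Average channels within each scalp row -> 4-node epochs (F, C, P, O)."""
    rows = sg.channel_rows(epochs.data.shape[1])
    data = np.stack([epochs.data[:, rows == r, :].mean(axis=1)
                     for r in range(len(sg.ROWS))], axis=1)
    return ep.EpochSet(data=data, fs=epochs.fs, window=epochs.window,
                       metadata=epochs.metadata.copy(), channel_names=list(sg.ROWS))


def decimate_epochs(epochs: ep.EpochSet, factor: int = 2) -> ep.EpochSet:
    """Subsample the time axis (anti-aliasing is not needed for per-timepoint
    decoding of slow evoked components)."""
    data = epochs.data[:, :, ::factor]
    return ep.EpochSet(data=data, fs=epochs.fs / factor, window=epochs.window,
                       metadata=epochs.metadata.copy(),
                       channel_names=list(epochs.channel_names))


# ---------------------------------------------------------------------------
# front-back marker recovery
# ---------------------------------------------------------------------------

def frontback_recovery(n_sessions: int = 20, base_seed: int = 0,
                       epochs_per_state: int = 6) -> dict:
    """Sign recovery of the planted MB-MW front-back gradient.

    Per seed: cut 5-s ground-truth state epochs, compute markers, and check
    that the MB-MW contrast of the fast-band (beta+gamma) power fraction and
    of sample entropy is positive on the frontal row and negative on the
    occipital row.
    """
    successes, details = [], []
    for i in range(n_sessions):
        cfg = small_session_config(base_seed + i)
        rec = sg.generate_session(cfg)
        epochs = ep.epoch_truth_segments(rec, window_s=5.0, max_per_state=epochs_per_state)
        mm = mk.compute_marker_matrix(epochs)
        states = mm.metadata["state_label"].to_numpy()
        if not {"MB", "MW"} <= set(states):
            successes.append(False)
            details.append({"seed": cfg.seed, "note": "missing state"})
            continue
        rows = sg.channel_rows(len(mm.channel_names))
        fast = mm.marker("psd_beta") + mm.marker("psd_gamma")
        se = mm.marker("sampen")
        ok = True
        for vals in (fast, se):
            mb = vals[states == "MB"].mean(axis=0)
            mw = vals[states == "MW"].mean(axis=0)
            contrast = mb - mw
            front = contrast[rows == 0].mean()
            back = contrast[rows == 3].mean()
            ok &= (front > 0) and (back < 0)
        successes.append(bool(ok))
        details.append({"seed": cfg.seed, "ok": bool(ok)})
    return {"rate": float(np.mean(successes)), "successes": successes, "details": details}


# ---------------------------------------------------------------------------
# PLV / wSMI dissociation recovery
# ---------------------------------------------------------------------------

def dissociation_recovery(n_sessions: int = 20, base_seed: int = 0,
                          epochs_per_state: int = 6) -> dict:
    """Per seed: PLV(MB) > PLV(ON) and wSMI(MB) < wSMI(ON) in the coupling
    band on the planted channel pairs — phase synchrony rises while
    information sharing collapses during mind blanking."""
    band = mk.BandDefinition("alpha", *sg.SessionConfig().coupling_band)
    successes = []
    for i in range(n_sessions):
        cfg = small_session_config(base_seed + i)
        rec = sg.generate_session(cfg)
        epochs = ep.epoch_truth_segments(rec, window_s=5.0, max_per_state=epochs_per_state)
        states = epochs.metadata["state_label"].to_numpy()
        if not {"ON", "MB"} <= set(states):
            successes.append(False)
            continue
        pairs = list(cfg.coupling_pairs)
        per = {}
        for s in ("ON", "MB"):
            sub = epochs.select(states == s)
            w = cn.band_wsmi(sub, band, pairs=pairs).matrix.mean(axis=0)
            p = cn.band_plv(sub, band, pairs=pairs).matrix.mean(axis=0)
            per[s] = (np.mean([w[a, b] for a, b in pairs]),
                      np.mean([p[a, b] for a, b in pairs]))
        wsmi_ok = per["MB"][0] < per["ON"][0]
        plv_ok = per["MB"][1] > per["ON"][1]
        successes.append(bool(wsmi_ok and plv_ok))
    return {"rate": float(np.mean(successes)), "successes": successes}


# ---------------------------------------------------------------------------
# temporal decoding pattern recovery
# ---------------------------------------------------------------------------

def _window_counts(curve: ed.DecodingCurve):
    t = curve.times
    sig = curve.significant
    early = int(sig[(t >= EARLY_WINDOW[0]) & (t < EARLY_WINDOW[1])].sum())
    late = int(sig[(t >= LATE_WINDOW[0]) & (t < LATE_WINDOW[1])].sum())
    return early, late, int(sig.sum())


def decoding_recovery(n_sessions: int = 20, n_perm: int = 500, base_seed: int = 0,
                      n_type1: int = 5) -> dict:
    """Per-state stimulus-category decoding with permutation significance.

    Per seed, after balancing trial counts across states: ON must show
    significant early and late decoding, MW strictly fewer significant late
    timepoints than ON, MB no significant timepoint at all.  A label-shuffled
    type-I arm counts post-FDR discoveries on the first ``n_type1`` seeds.
    """
    successes, type1_discoveries = [], []
    for i in range(n_sessions):
        # equal, short dwell keeps per-state trial counts comparable before balancing
        cfg = small_session_config(base_seed + 1000 + i, n_blocks=4,
                                   block_duration=150.0, state_dwell=15.0)
        rec = sg.generate_session(cfg)
        epochs = ed.balance_subsample(
            ep.baseline_correct(truth_labeled_stimuli(rec)),
            by="state_label", rng=np.random.default_rng(cfg.seed + 1))
        epochs = decimate_epochs(epochs, 2)
        counts = {}
        ok = True
        for s in ("ON", "MW", "MB"):
            sub = epochs.select((epochs.metadata["state_label"] == s).to_numpy())
            rng = np.random.default_rng(cfg.seed + 7)
            try:
                curve = ed.temporal_decode(sub, rng=rng)
                curve = ed.decode_significance(curve, sub, n_perm=n_perm,
                                               rng=np.random.default_rng(cfg.seed + 11))
            except Exception as exc:      # class imbalance in a tiny state
                logger.warning("decode failed for %s: %s", s, exc)
                ok = False
                break
            counts[s] = _window_counts(curve)
        if ok and len(counts) == 3:
            on_e, on_l, _ = counts["ON"]
            _, mw_l, _ = counts["MW"]
            _, _, mb_tot = counts["MB"]
            ok = (on_e >= 1) and (on_l >= 1) and (mw_l < on_l) and (mb_tot == 0)
        successes.append(bool(ok))
        if i < n_type1:
            sub = epochs.select((epochs.metadata["state_label"] == "ON").to_numpy())
            meta = sub.metadata.copy()
            meta["stimulus_category"] = np.random.default_rng(cfg.seed + 13).permutation(
                meta["stimulus_category"].to_numpy())
            shuffled = dc_replace(sub, metadata=meta)
            curve = ed.temporal_decode(shuffled, rng=np.random.default_rng(cfg.seed + 17))
            curve = ed.decode_significance(curve, shuffled, n_perm=n_perm,
                                           rng=np.random.default_rng(cfg.seed + 19))
            type1_discoveries.append(int(curve.significant.sum()))
    return {"rate": float(np.mean(successes)), "successes": successes,
            "type1_discoveries": type1_discoveries,
            "type1_mean": float(np.mean(type1_discoveries)) if type1_discoveries else 0.0}


# ---------------------------------------------------------------------------
# trial-by-trial classifier study
# ---------------------------------------------------------------------------

def subject_features(recording: sg.ContinuousRecording,
                     bands=("delta", "theta", "alpha"),
                     decimate: int = 1) -> sc.FeatureTable:
    """Stimulus-epoch feature table for one subject: per-channel markers,
    row-ROI wSMI per band, and windowed ERP amplitudes; labels from the
    probe-based 5-s rule.  ``decimate`` subsamples the time axis before
    marker extraction (a compute-scale knob; markers remain discriminative
    at an effective 125 Hz)."""
    stim = ep.epoch_stimuli(recording)
    stim = ep.label_trials(stim, recording)
    stim = ep.baseline_correct(stim)
    if decimate > 1:
        stim = decimate_epochs(stim, decimate)
    mm = mk.compute_marker_matrix(stim)
    rows = row_average_epochs(stim)
    conn = {b: cn.band_wsmi(rows, b) for b in bands}
    return sc.build_feature_table(stim, mm, conn)


#: classifier-study sessions: equal 40-s dwell keeps all three states
#: represented among the ~25 probes of a 25-minute session
CLASSIFIER_SESSION = {"state_dwell": 25.0, "n_blocks": 6, "block_duration": 250.0}


def classifier_study(n_subjects: int = 20, n_perm: int = 20, base_seed: int = 0,
                     n_trees: int = STUDY_TREES, session_overrides: dict | None = None,
                     decimate: int = 2) -> dict:
    """Per-subject mind-state classification with permutation chance level,
    unlabeled-trial prediction and behavioral validation.

    Subjects that do not report all three states in their labeled trials are
    excluded (mirroring the study's inclusion rule).  Returns per-subject
    balanced accuracies, null medians, the group rank-sum p-value, behavioral
    validation checks, and pooled descriptive behavior statistics.
    """
    scores, null_medians, pvals, validations = [], [], [], []
    n_go = n_miss = n_nogo = n_fa = 0
    probe_counts = {"ON": 0, "MW": 0, "MB": 0}
    excluded = 0
    for i in range(n_subjects):
        cfg = sg.SessionConfig(seed=base_seed + 5000 + i, subject=f"S{i:02d}",
                               **(CLASSIFIER_SESSION if session_overrides is None
                                  else session_overrides))
        rec = sg.generate_session(cfg)
        # descriptive behavior over all trials
        ev = rec.events_frame()
        stim_ev = ev[ev["kind"] == "stimulus"]
        go = stim_ev[stim_ev["go_nogo"] == "go"]
        nogo = stim_ev[stim_ev["go_nogo"] == "nogo"]
        n_go += len(go)
        n_miss += int(go["rt_ms"].isna().sum())
        n_nogo += len(nogo)
        n_fa += int(nogo["rt_ms"].notna().sum())
        for a in ev.loc[ev["kind"] == "probe_answer", "probe_answer"]:
            probe_counts[ep.merge_report(a)] += 1

        table = subject_features(rec, decimate=decimate)
        lab = table.meta.loc[table.labeled_mask, "label"]
        if lab.value_counts().reindex(sc.CLASS_ORDER).fillna(0).min() < 2:
            excluded += 1
            continue
        rng = np.random.default_rng(cfg.seed)
        try:
            report = sc.fit_crossval(table, rng, n_trees=n_trees)
            report = sc.permutation_chance(table, n_perm=n_perm, rng=rng,
                                           report=report, n_trees=n_trees)
        except Exception as exc:
            logger.warning("subject %s skipped: %s", cfg.subject, exc)
            excluded += 1
            continue
        scores.append(report.balanced_accuracy)
        null_medians.append(float(np.median(report.null_scores)))
        pvals.append(report.p_value)

        # the final prediction pipeline runs once per subject: full ensemble
        fitted = sc.fit_full(table, rng, n_trees=sc.N_TREES)
        preds = sc.predict_unlabeled(fitted, table)
        stim = ep.label_trials(ep.epoch_stimuli(rec), rec)
        tab = bh.behavior_table(stim)
        tab["trial"] = np.arange(len(tab))
        validations.append(sc.validate_predictions(preds, tab))

    group_p = sc.group_chance_test(scores, null_medians) if len(scores) >= 2 else np.nan
    return _assemble_study(scores, null_medians, pvals, group_p, validations,
                           excluded, n_go, n_miss, n_nogo, n_fa, probe_counts)


def _assemble_study(scores, null_medians, pvals, group_p, validations, excluded,
                    n_go, n_miss, n_nogo, n_fa, probe_counts):
    recovery = [v["recovered"] for v in validations]
    n_probes = sum(probe_counts.values())
    return {
        "scores": scores,
        "null_medians": null_medians,
        "p_values": pvals,
        "group_p": float(group_p),
        "median_score": float(np.median(scores)) if scores else np.nan,
        "median_null": float(np.median(null_medians)) if null_medians else np.nan,
        "validations": validations,
        "behavior_recovery_rate": float(np.mean(recovery)) if recovery else np.nan,
        "n_included": len(scores),
        "n_excluded": excluded,
        "overall_miss_rate": n_miss / n_go if n_go else np.nan,
        "overall_fa_rate": n_fa / n_nogo if n_nogo else np.nan,
        "probe_proportions": {k: v / n_probes for k, v in probe_counts.items()} if n_probes else {},
    }


def descriptive_study(n_subjects: int = 6, base_seed: int = 0) -> dict:
    """Behavioral descriptives under the default (reported-prevalence) conditions.

    Uses the default session configuration (state occupancy ~52/35/16%,
    miss/FA/RT parameters anchored to the published descriptives) and pools the labeled-trial
    behavior across subjects: overall miss and FA rates, probe-report
    proportions, and the across-subject state contrasts.
    """
    from . import groupstats as gs

    n_go = n_miss = n_nogo = n_fa = 0
    probe_counts = {"ON": 0, "MW": 0, "MB": 0}
    summaries = []
    for i in range(n_subjects):
        cfg = sg.SessionConfig(seed=base_seed + 9000 + i, subject=f"D{i:02d}")
        rec = sg.generate_session(cfg)
        ev = rec.events_frame()
        stim_ev = ev[ev["kind"] == "stimulus"]
        go = stim_ev[stim_ev["go_nogo"] == "go"]
        nogo = stim_ev[stim_ev["go_nogo"] == "nogo"]
        n_go += len(go)
        n_miss += int(go["rt_ms"].isna().sum())
        n_nogo += len(nogo)
        n_fa += int(nogo["rt_ms"].notna().sum())
        for a in ev.loc[ev["kind"] == "probe_answer", "probe_answer"]:
            probe_counts[ep.merge_report(a)] += 1
        stim = ep.label_trials(ep.epoch_stimuli(rec), rec)
        summaries.append(bh.summarize_behavior(bh.behavior_table(stim)))
    summary = pd.concat(summaries, ignore_index=True)
    contrasts = bh.behavior_state_contrast(summary)
    n_probes = sum(probe_counts.values())
    return {
        "overall_miss_rate": n_miss / n_go if n_go else np.nan,
        "overall_fa_rate": n_fa / n_nogo if n_nogo else np.nan,
        "probe_proportions": {k: v / n_probes for k, v in probe_counts.items()} if n_probes else {},
        "summary": summary,
        "contrasts": contrasts,
    }
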