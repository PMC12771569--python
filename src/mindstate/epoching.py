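"""Epoching and the trial-labeling rule.

Cuts continuous recordings into 5-s pre-probe epochs and stimulus-centered
epochs (-0.25 to 0.75 s), and labels stimulus trials with the next probe's
reported state when the stimulus falls within 5 s of the probe onset
("don't remember" reports are merged into MB).  Windows are half-open
``[lo, hi)`` in seconds relative to the anchor; sample index = round(t * fs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd

from .errors import DataError, ParameterError
from .synthgen import ContinuousRecording

logger = logging.getLogger(__name__)

UNLABELED = "unlabeled"

#: the reported-state labeling horizon, seconds before probe onset
LABEL_WINDOW_S = 5.0


@dataclass
class EpochSet:
    """Trials x channels x time with per-trial metadata.

    ``window`` is (lo, hi) seconds relative to the anchor event and
    ``n_time = round((hi - lo) * fs)``.  Metadata is one row per trial and
    carries subject, block, stimulus category, go/nogo, RT, response flag,
    time to the next probe and the (possibly unlabeled) state label.
    """

    data: np.ndarray
    fs: float
    window: tuple
    metadata: pd.DataFrame
    channel_names: list = field(default_factory=list)

    def __post_init__(self):
        n_time = int(round((self.window[1] - self.window[0]) * self.fs))
        if self.data.shape[2] != n_time:
            raise DataError(
                f"window {self.window} implies {n_time} samples, data has {self.data.shape[2]}")
        if len(self.metadata) != self.data.shape[0]:
            raise DataError("metadata rows must match trials")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        n_time = self.data.shape[2]
        return self.window[0] + np.arange(n_time) / self.fs

    def select(self, mask) -> "EpochSet":
        mask = np.asarray(mask)
        if mask.size == 0:
            idx = np.array([], dtype=int)
        elif mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask.astype(int)
        return replace(self, data=self.data[idx],
                       metadata=self.metadata.iloc[idx].reset_index(drop=True))

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data, compression="gzip")
            f.attrs["fs"] = self.fs
            f.attrs["window"] = self.window
            f.attrs["channel_names"] = [str(c) for c in self.channel_names]
            f.create_dataset("metadata", data=self.metadata.to_json().encode())

    @classmethod
    def load(cls, path) -> "EpochSet":
        import io

        with h5py.File(path, "r") as f:
            meta = pd.read_json(io.StringIO(bytes(f["metadata"][()]).decode()))
            return cls(data=f["data"][()], fs=float(f.attrs["fs"]),
                       window=tuple(f.attrs["window"]),
                       metadata=meta.reset_index(drop=True),
                       channel_names=list(f.attrs["channel_names"]))


def merge_report(answer: str) -> str:
    """Map a probe answer to its analysis label (DR is merged into MB)."""
    return "MB" if answer == "DR" else answer


def _probe_table(recording: ContinuousRecording) -> pd.DataFrame:
    """Probe onsets paired with their (merged) answers, sorted by onset."""
    onsets, answers, vig, blocks = [], [], [], []
    pending = None
    pending_block = 0
    for e in recording.events:
        if e.kind == "probe_onset":
            pending = e.onset
            pending_block = e.block
        elif e.kind == "probe_answer":
            onsets.append(pending if pending is not None else e.onset)
            answers.append(merge_report(e.probe_answer))
            vig.append(e.vigilance)
            blocks.append(pending_block if pending is not None else e.block)
            pending = None
    return pd.DataFrame({"onset": onsets, "answer": answers, "vigilance": vig,
                         "block": blocks}).sort_values("onset").reset_index(drop=True)


def epoch_preprobe(recording: ContinuousRecording, window_s: float = LABEL_WINDOW_S) -> EpochSet:
    """One epoch per probe covering ``[probe_onset - window_s, probe_onset)``.

    Probes too close to the recording start are skipped with a logged warning.
    """
    if window_s <= 0:
        raise ParameterError("window_s must be > 0")
    probes = _probe_table(recording)
    if len(probes) == 0:
        raise DataError("recording has no probes")
    n_time = int(round(window_s * recording.fs))
    epochs, meta, skipped = [], [], 0
    for _, p in probes.iterrows():
        stop = int(p["onset"])
        start = stop - n_time
        if start < 0:
            skipped += 1
            continue
        epochs.append(recording.data[:, start:stop])
        meta.append({"subject": recording.subject, "block": int(p.get("block", 0)),
                     "probe_onset": stop, "state_label": p["answer"],
                     "vigilance": p["vigilance"]})
    if skipped:
        logger.warning("skipped %d probe(s) too close to recording start", skipped)
    data = np.stack(epochs) if epochs else np.empty((0, recording.data.shape[0], n_time))
    return EpochSet(data=data, fs=recording.fs, window=(-window_s, 0.0),
                    metadata=pd.DataFrame(meta) if meta else pd.DataFrame(
                        columns=["subject", "block", "probe_onset", "state_label", "vigilance"]),
                    channel_names=list(recording.channel_names))


def epoch_stimuli(recording: ContinuousRecording,
                  window: tuple = (-0.25, 0.75)) -> EpochSet:
    """One epoch per stimulus over ``window`` seconds around onset, with
    category/go-nogo/RT/block metadata carried through row-for-row."""
    lo, hi = window
    if hi <= lo:
        raise ParameterError("window must satisfy lo < hi")
    fs = recording.fs
    n_time = int(round((hi - lo) * fs))
    off = int(round(lo * fs))
    stims = [e for e in recording.events if e.kind == "stimulus"]
    if not stims:
        raise DataError("recording has no stimulus events")
    epochs, meta, skipped = [], [], 0
    for e in stims:
        start = e.onset + off
        stop = start + n_time
        if start < 0 or stop > recording.n_samples:
            skipped += 1
            continue
        epochs.append(recording.data[:, start:stop])
        meta.append({"subject": recording.subject, "block": e.block,
                     "onset_sample": e.onset,
                     "stimulus_category": e.stimulus_category,
                     "go_nogo": e.go_nogo,
                     "responded": e.rt_ms is not None,
                     "rt_ms": e.rt_ms,
                     "state_label": UNLABELED,
                     "time_to_probe": np.nan})
    if skipped:
        logger.warning("skipped %d stimulus epoch(s) at recording boundary", skipped)
    return EpochSet(data=np.stack(epochs), fs=fs, window=(lo, hi),
                    metadata=pd.DataFrame(meta),
                    channel_names=list(recording.channel_names))


def label_trials(stim_epochs: EpochSet, probes) -> EpochSet:
    """Apply the 5-s labeling rule.

    A stimulus trial receives the next probe's merged answer iff
    ``0 < probe_onset - stimulus_onset <= 5 s`` (boundary inclusive); the
    nearest following probe wins when probe intervals overlap.  All other
    trials stay unlabeled.  Pure function of event times: permuting trial
    order permutes labels identically.
    """
    if isinstance(probes, ContinuousRecording):
        probes = _probe_table(probes)
    probes = probes.sort_values("onset").reset_index(drop=True)
    fs = stim_epochs.fs
    horizon = int(round(LABEL_WINDOW_S * fs))
    p_onsets = probes["onset"].to_numpy()
    p_answers = probes["answer"].to_numpy()

    meta = stim_epochs.metadata.copy()
    labels, ttp = [], []
    for onset in meta["onset_sample"].to_numpy():
        j = np.searchsorted(p_onsets, onset, side="left")
        # nearest following probe with 0 < gap <= horizon
        while j < p_onsets.size and p_onsets[j] <= onset:
            j += 1
        if j < p_onsets.size and 0 < p_onsets[j] - onset <= horizon:
            labels.append(merge_report(p_answers[j]))
            ttp.append((p_onsets[j] - onset) / fs)
        else:
            labels.append(UNLABELED)
            ttp.append(np.nan)
    meta["state_label"] = labels
    meta["time_to_probe"] = ttp
    return replace(stim_epochs, metadata=meta)


def baseline_correct(epochs: EpochSet, baseline: tuple = (-0.25, 0.0)) -> EpochSet:
    """Subtract the per-trial, per-channel mean over ``baseline`` (idempotent)."""
    lo, hi = baseline
    wlo, whi = epochs.window
    if not (wlo <= lo < hi <= whi):
        raise ParameterError(f"baseline {baseline} must lie inside epoch window {epochs.window}")
    i0 = int(round((lo - wlo) * epochs.fs))
    i1 = int(round((hi - wlo) * epochs.fs))
    if i1 <= i0:
        raise ParameterError("empty baseline window")
    mean = epochs.data[:, :, i0:i1].mean(axis=2, keepdims=True)
    return replace(epochs, data=epochs.data - mean)


def epoch_truth_segments(recording: ContinuousRecording, window_s: float = 5.0,
                         max_per_state: int | None = None) -> EpochSet:
    """Non-overlapping ``window_s`` epochs cut inside constant ground-truth
    state segments — a generator-validation path that bypasses probes.

    The state label comes from ``truth_states``, so this must only be used to
    check marker recovery against the planted signatures, never as an analysis
    stage for real data (where no ground truth exists).
    """
    fs = recording.fs
    n_time = int(round(window_s * fs))
    st = recording.truth_states
    bounds = np.flatnonzero(np.diff(st)) + 1
    starts = np.concatenate([[0], bounds])
    stops = np.concatenate([bounds, [st.size]])
    epochs, meta = [], []
    from .synthgen import STATES
    counts = {s: 0 for s in STATES}
    for a, b in zip(starts, stops):
        state = STATES[st[a]]
        pos = a
        while pos + n_time <= b:
            if max_per_state is not None and counts[state] >= max_per_state:
                break
            epochs.append(recording.data[:, pos:pos + n_time])
            meta.append({"subject": recording.subject, "block": int(pos // st.size),
                         "state_label": state, "onset_sample": int(pos)})
            counts[state] += 1
            pos += n_time
    if not epochs:
        raise DataError("no truth segment long enough for the requested window")
    return EpochSet(data=np.stack(epochs), fs=fs, window=(-window_s, 0.0),
                    metadata=pd.DataFrame(meta),
                    channel_names=list(recording.channel_names))
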