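"""Synthetic SART-session generator with planted mind-state signatures.

Generates complete experience-sampling sessions — continuous multichannel EEG,
a Go/No-Go stimulus train, responses, and mind-state probes — in which the
three latent mind states (ON task, mind wandering MW, mind blanking MB) leave
parameterized, recoverable fingerprints:

* spectral: state- and scalp-row-dependent band power (the front-back gradient),
* evoked: a posterior P1 in every state and a central P3b that is full in ON,
  reduced and delayed in MW, and absent in MB, plus a stimulus-category-coded
  component that supports temporal decoding,
* coupling: channel pairs share a narrowband source either at zero lag
  (linear, phase-locking) or lagged through a rank-preserving monotone
  distortion (nonlinear, information-sharing),
* behavior: per-state miss/false-alarm probabilities and log-normal RTs.

The generative model is: 1/f background + band-limited oscillations with
per-state row gains + additive ERP bump templates + coupled shared sources.
Every draw comes from one `numpy` Generator seeded by the config, so an
identical config yields a bit-identical session.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError, ParameterError

logger = logging.getLogger(__name__)

#: Canonical state order; integer codes index into this tuple.
STATES = ("ON", "MW", "MB")

#: Scalp rows, frontal to occipital. 32 channels = 4 rows x 8.
ROWS = ("F", "C", "P", "O")

#: Baseline oscillation amplitude per band (uV of band-limited SD at row gain 1).
BAND_BASE_AMP = {
    "delta": 3.0,
    "theta": 2.5,
    "alpha": 3.0,
    "beta": 2.0,
    "gamma": 1.4,
}

#: Default band edges in Hz (conventional ranges tiling 1-45 Hz).
DEFAULT_BAND_EDGES = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "gamma": (30.0, 45.0),
}

_FLAT = {b: (1.0, 1.0, 1.0, 1.0) for b in BAND_BASE_AMP}


@dataclass
class SignalParams:
    """Per-state EEG signal parameters.

    ``band_power_map`` maps band name to a gain per scalp row (frontal,
    central, parietal, occipital); it multiplies the baseline band amplitude
    and plants the front-back gradient.  Couplings are shared-variance
    fractions in [0, 1]: ``linear_coupling`` adds an identical zero-lag
    narrowband source to both channels of each coupled pair (detected by PLV,
    discounted by wSMI's identical-pattern weighting), ``nonlinear_coupling``
    adds a lagged, cubically distorted (rank-preserving) copy to the second
    channel (detected by wSMI, diluted for PLV).  ``p3b_amp = 0`` encodes an
    absent P3b.
    """

    band_power_map: dict = field(default_factory=lambda: dict(_FLAT))
    p1_amp: float = 4.0          # uV, posterior row
    p1_latency: float = 125.0    # ms to bump center
    p1_duration: float = 80.0    # ms bump width
    p3b_amp: float = 5.0         # uV, central row
    p3b_latency: float = 400.0   # ms, bump onset
    p3b_duration: float = 250.0  # ms
    cat_early_amp: float = 1.8   # uV, occipital, signed by stimulus category
    cat_late_amp: float = 1.5    # uV, central, signed by stimulus category
    cat_late_center: float = 470.0    # ms, center of the late category code
    cat_late_duration: float = 220.0  # ms
    linear_coupling: float = 0.1
    nonlinear_coupling: float = 0.1
    noise_sd: float = 3.0        # uV of 1/f background

    def validate(self) -> None:
        for name in ("linear_coupling", "nonlinear_coupling"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1], got {v}")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be non-negative")


@dataclass
class BehaviorParams:
    """Per-state behavior: miss/FA probabilities and log-normal RT (ms)."""

    miss_prob: float = 0.05
    fa_prob: float = 0.2
    rt_mu: float = 500.0     # median of the log-normal, ms
    rt_sigma: float = 0.2    # log-space sigma

    def validate(self) -> None:
        for name in ("miss_prob", "fa_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1], got {v}")
        if self.rt_mu <= 0:
            raise ParameterError("rt_mu must be > 0")


def default_state_params() -> dict:
    """Planted per-state signal profiles.

    Fast-band (beta/gamma) row gains carry the front-back dissociation:
    relative fast power in MB is raised frontally and suppressed posteriorly
    compared to MW, which shows the opposite profile.  ON is flat.
    """
    # ON late category code is sustained (~250-580 ms), MW's shorter and weaker
    on = SignalParams(cat_early_amp=3.0, cat_late_amp=2.5,
                      cat_late_center=420.0, cat_late_duration=340.0)
    # MW: frontal slowing (fronto-central theta, reduced frontal fast power),
    # posterior fast activity preserved; reduced/delayed P3b.
    mw = SignalParams(
        band_power_map={**_FLAT,
                        "theta": (1.3, 1.1, 1.0, 1.0),
                        "beta": (0.55, 1.1, 1.25, 1.45),
                        "gamma": (0.55, 1.1, 1.25, 1.45)},
        p3b_amp=2.5, p3b_latency=450.0, p3b_duration=150.0,
        cat_early_amp=3.0, cat_late_amp=1.0,
        linear_coupling=0.3, nonlinear_coupling=0.4,
    )
    # MB: posterior slow-wave extension (delta) with frontal fast activity;
    # absent P3b and no category code.
    mb = SignalParams(
        band_power_map={**_FLAT,
                        "delta": (1.0, 1.0, 1.25, 1.4),
                        "beta": (1.6, 1.2, 0.75, 0.5),
                        "gamma": (1.6, 1.2, 0.75, 0.5)},
        p3b_amp=0.0,
        cat_early_amp=0.0, cat_late_amp=0.0,
        linear_coupling=0.8, nonlinear_coupling=0.1,
    )
    on.linear_coupling, on.nonlinear_coupling = 0.1, 0.7
    return {"ON": on, "MW": mw, "MB": mb}


def default_behavior_params() -> dict:
    """Per-state behavior anchored to the printed descriptives: overall ~10%
    misses and ~37% FA at the reported state prevalences, orderings misses
    MB>MW>ON, RT MB slowest / MW fastest, FA MW,MB > ON, and MB misses kept
    below the 20% the study reports for that state."""
    return {
        "ON": BehaviorParams(miss_prob=0.05, fa_prob=0.20, rt_mu=500.0, rt_sigma=0.20),
        "MW": BehaviorParams(miss_prob=0.09, fa_prob=0.55, rt_mu=440.0, rt_sigma=0.20),
        "MB": BehaviorParams(miss_prob=0.19, fa_prob=0.40, rt_mu=620.0, rt_sigma=0.25),
    }


def default_state_dwell() -> dict:
    # Stationary occupancy of the semi-Markov chain is ~ proportional to the
    # mean dwell, so these approximate the reported 52/35/16% probe shares.
    return {"ON": 47.0, "MW": 32.0, "MB": 15.0}


@dataclass
class SessionConfig:
    """Everything needed to generate one synthetic session deterministically."""

    n_channels: int = 32
    fs: float = 250.0
    n_blocks: int = 6
    block_duration: float = 150.0           # s
    soa_range: tuple = (750.0, 1250.0)      # ms
    nogo_rate: float = 1.0 / 9.0
    probe_interval_range: tuple = (40.0, 70.0)  # s
    state_dwell: dict | float = field(default_factory=default_state_dwell)
    state_params: dict = field(default_factory=default_state_params)
    behavior_params: dict = field(default_factory=default_behavior_params)
    coupling_pairs: tuple = ((2, 18), (5, 21))  # (frontal, parietal) channel indices
    coupling_band: tuple = (8.0, 12.0)          # Hz, shared-source band
    coupling_lag: int = 7                        # samples, nonlinear-path lag
    report_noise: float = 0.0
    subject: str = "S00"
    seed: int = 0

    def dwell_of(self, state: str) -> float:
        if isinstance(self.state_dwell, dict):
            return float(self.state_dwell[state])
        return float(self.state_dwell)

    @property
    def n_samples(self) -> int:
        return int(round(self.n_blocks * self.block_duration * self.fs))

    @property
    def block_samples(self) -> int:
        return int(round(self.block_duration * self.fs))

    def validate(self) -> None:
        lo, hi = self.soa_range
        if not (0 < lo <= hi):
            raise ParameterError(f"soa_range must satisfy 0 < lo <= hi, got {self.soa_range}")
        if not 0.0 < self.nogo_rate < 1.0:
            raise ParameterError(f"nogo_rate must be in (0, 1), got {self.nogo_rate}")
        plo, phi = self.probe_interval_range
        if not (0 < plo <= phi):
            raise ParameterError(f"probe_interval_range must satisfy 0 < lo <= hi, got {self.probe_interval_range}")
        for s in STATES:
            if self.dwell_of(s) <= 0:
                raise ParameterError(f"state_dwell[{s}] must be > 0")
            self.state_params[s].validate()
            self.behavior_params[s].validate()
        if self.block_duration * 1000.0 < hi:
            raise ConfigurationError("block shorter than one SOA")
        if self.n_channels % len(ROWS):
            raise ConfigurationError("n_channels must be a multiple of 4 (one per scalp row)")


@dataclass
class Event:
    """One timestamped event in a recording (sample-indexed)."""

    onset: int
    kind: str                      # stimulus | response | probe_onset | probe_answer
    stimulus_category: str | None = None   # face | digit
    go_nogo: str | None = None             # go | nogo
    rt_ms: float | None = None             # stimulus rows: RT of the owned response
    probe_answer: str | None = None        # ON | MW | MB | DR
    vigilance: int | None = None           # 1-4
    block: int = 0


@dataclass
class ContinuousRecording:
    """One synthetic session: channels x samples EEG plus the event stream.

    ``truth_states`` is the generator's per-sample latent state (codes into
    :data:`STATES`); it is ground truth for validation only and is never
    serialized with the analysis fixtures.
    """

    data: np.ndarray            # (n_channels, n_samples), uV
    fs: float
    channel_names: list
    channel_positions: dict     # name -> (x, y)
    events: list                # list[Event], sorted by onset
    truth_states: np.ndarray    # (n_samples,), int8
    subject: str = "S00"

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def events_frame(self) -> pd.DataFrame:
        rows = [dataclasses.asdict(e) for e in self.events]
        return pd.DataFrame(rows)

    def truth_state_at(self, sample: int) -> str:
        return STATES[self.truth_states[int(sample)]]


def channel_layout(n_channels: int = 32):
    """Names and 2-D positions for ``n_channels`` in 4 frontal->occipital rows."""
    per_row = n_channels // len(ROWS)
    ys = np.linspace(0.8, -0.8, len(ROWS))
    xs = np.linspace(-0.8, 0.8, per_row)
    names, pos = [], {}
    for ri, row in enumerate(ROWS):
        for ci in range(per_row):
            name = f"{row}{ci + 1}"
            names.append(name)
            pos[name] = (float(xs[ci]), float(ys[ri]))
    return names, pos


def channel_rows(n_channels: int = 32) -> np.ndarray:
    """Row index (0=frontal .. 3=occipital) of each channel."""
    per_row = n_channels // len(ROWS)
    return np.repeat(np.arange(len(ROWS)), per_row)


# ---------------------------------------------------------------------------
# latent state schedule
# ---------------------------------------------------------------------------

def generate_state_timecourse(config: SessionConfig, rng: np.random.Generator,
                              init_state: str | None = None) -> np.ndarray:
    """Per-sample latent state codes for the whole session.

    Semi-Markov schedule: exponential dwell with per-state mean, truncated at
    block boundaries (each block starts a fresh segment).  The next state is
    drawn uniformly among the two others, so visit frequencies equalize and
    stationary occupancy is proportional to the per-state mean dwell.
    """
    for s in STATES:
        if config.dwell_of(s) <= 0:
            raise ParameterError("state_dwell must be > 0")
    fs = config.fs
    n_total = config.n_samples
    out = np.empty(n_total, dtype=np.int8)
    dwell = np.array([config.dwell_of(s) for s in STATES])
    if np.isinf(dwell).any():
        weights = np.isinf(dwell) / np.isinf(dwell).sum()
    else:
        weights = dwell / dwell.sum()

    for b in range(config.n_blocks):
        start = b * config.block_samples
        stop = min(start + config.block_samples, n_total)
        if init_state is not None and b == 0:
            state = STATES.index(init_state)
        else:
            state = int(rng.choice(len(STATES), p=weights))
        pos = start
        while pos < stop:
            mean = dwell[state]
            seg = stop - pos if math.isinf(mean) else max(1, int(round(rng.exponential(mean) * fs)))
            seg = min(seg, stop - pos)
            out[pos:pos + seg] = state
            pos += seg
            others = [i for i in range(len(STATES)) if i != state]
            state = int(others[rng.integers(len(others))])
    return out


# ---------------------------------------------------------------------------
# signal building blocks
# ---------------------------------------------------------------------------

def _shaped_noise(rng, shape, fs, spectral_shape):
    """Gaussian noise with the given one-sided amplitude shape, unit SD.

    Synthesized in the frequency domain at an FFT-friendly padded length and
    truncated, so long sessions stay cheap.
    """
    from scipy.fft import next_fast_len

    if np.isscalar(shape):
        shape = (shape,)
    n = shape[-1]
    n_fft = next_fast_len(n)
    freqs = np.fft.rfftfreq(n_fft, 1.0 / fs)
    amp = spectral_shape(freqs)
    spec = (rng.standard_normal(shape[:-1] + (freqs.size,))
            + 1j * rng.standard_normal(shape[:-1] + (freqs.size,))) * amp
    x = np.fft.irfft(spec, n=n_fft, axis=-1)[..., :n]
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _pink_noise(rng, n_channels, n_samples, fs):
    """1/f-power background restricted to 1-45 Hz, unit SD per channel."""

    def shape_fn(freqs):
        amp = np.zeros_like(freqs)
        band = (freqs >= 1.0) & (freqs <= 45.0)
        amp[band] = 1.0 / np.sqrt(freqs[band])
        return amp

    return _shaped_noise(rng, (n_channels, n_samples), fs, shape_fn)


def _band_noise(rng, shape, fs, f_lo, f_hi):
    """Band-limited Gaussian noise (flat in-band spectrum), unit SD."""
    return _shaped_noise(rng, shape, fs,
                         lambda freqs: ((freqs >= f_lo) & (freqs <= f_hi)).astype(float))


def _monotone_distortion(x: np.ndarray) -> np.ndarray:
    """Rank-preserving cubic distortion, rescaled to unit SD.

    Strictly increasing, so rank patterns (and hence symbolic transforms) are
    preserved while the waveform — and its phase spectrum — is warped.
    """
    sd = x.std() or 1.0
    y = x + (x ** 3) / (3.0 * sd ** 2)
    return y / (y.std() or 1.0)


def _bump(fs: float, center_ms: float, duration_ms: float):
    """Hann bump template and its onset offset in samples (peak = 1)."""
    n = max(3, int(round(duration_ms / 1000.0 * fs)))
    t = np.arange(n) / max(n - 1, 1)
    w = 0.5 * (1.0 - np.cos(2.0 * np.pi * t))
    onset = int(round((center_ms - duration_ms / 2.0) / 1000.0 * fs))
    return w, onset


def _add_template(data, ch_idx, onset_sample, template, amp):
    if amp == 0.0:
        return
    start = onset_sample
    stop = min(start + template.size, data.shape[1])
    if start < 0 or start >= stop:
        return
    data[np.ix_(ch_idx, np.arange(start, stop))] += amp * template[: stop - start]


# ---------------------------------------------------------------------------
# session generation
# ---------------------------------------------------------------------------

def generate_session(config: SessionConfig) -> ContinuousRecording:
    """Generate one complete synthetic session from ``config`` (seeded)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    fs = config.fs
    n_ch, n = config.n_channels, config.n_samples
    rows = channel_rows(n_ch)
    names, positions = channel_layout(n_ch)

    states = generate_state_timecourse(config, rng)

    # background
    data = _pink_noise(rng, n_ch, n, fs)
    for ci in range(n_ch):
        data[ci] *= config.state_params[STATES[0]].noise_sd  # noise_sd shared across states
    # allow per-state noise_sd via envelope if they differ
    sds = np.array([config.state_params[s].noise_sd for s in STATES])
    if not np.allclose(sds, sds[0]):
        data *= (sds[states] / sds[0])[None, :]

    # band oscillations with state x row gain envelopes
    gain_tab = {}   # band -> (n_states, n_rows)
    for band in BAND_BASE_AMP:
        gain_tab[band] = np.array(
            [config.state_params[s].band_power_map.get(band, (1.0,) * len(ROWS)) for s in STATES]
        )
    for band, (f_lo, f_hi) in DEFAULT_BAND_EDGES.items():
        osc = _band_noise(rng, (n_ch, n), fs, f_lo, f_hi)
        gains = gain_tab[band]            # (n_states, n_rows)
        for r in range(len(ROWS)):
            env = BAND_BASE_AMP[band] * gains[states, r]
            sel = rows == r
            data[sel] += osc[sel] * env[None, :]

    # coupled channel pairs: shared narrowband source per pair
    lin_env = np.array([config.state_params[s].linear_coupling for s in STATES])[states]
    nl_env = np.array([config.state_params[s].nonlinear_coupling for s in STATES])[states]
    f_lo, f_hi = config.coupling_band
    alpha_amp = BAND_BASE_AMP["alpha"]
    lin_amp = alpha_amp * np.sqrt(lin_env / np.clip(1.0 - lin_env, 0.05, None)) * 1.5
    nl_amp = alpha_amp * np.sqrt(nl_env / np.clip(1.0 - nl_env, 0.05, None)) * 1.5
    lag = int(config.coupling_lag)
    for (a, b) in config.coupling_pairs:
        s_lin = _band_noise(rng, (n,), fs, f_lo, f_hi)
        s_nl = _band_noise(rng, (n,), fs, f_lo, f_hi)
        s_nl_lag = np.roll(s_nl, lag)
        data[a] += lin_amp * s_lin + nl_amp * s_nl
        data[b] += lin_amp * s_lin + nl_amp * _monotone_distortion(s_nl_lag)

    # event stream: stimuli + responses per block, then probes per block
    events: list[Event] = []
    ch_central = np.where(rows == 1)[0]
    ch_occip = np.where(rows == 3)[0]
    soa_lo, soa_hi = config.soa_range

    for b in range(config.n_blocks):
        t0 = b * config.block_duration
        t_end = (b + 1) * config.block_duration
        t = t0 + 0.5
        while t + 0.8 < t_end:
            onset = int(round(t * fs))
            if onset >= n:
                break
            state = STATES[states[onset]]
            sp = config.state_params[state]
            bp = config.behavior_params[state]
            category = "face" if rng.random() < 0.5 else "digit"
            nogo = rng.random() < config.nogo_rate
            sign = 1.0 if category == "face" else -1.0

            # evoked templates
            w, off = _bump(fs, sp.p1_latency, sp.p1_duration)
            _add_template(data, ch_occip, onset + off, w, sp.p1_amp)
            w, off = _bump(fs, 200.0, 80.0)
            _add_template(data, ch_occip, onset + off, w, sign * sp.cat_early_amp)
            w, off = _bump(fs, sp.p3b_latency + sp.p3b_duration / 2.0, sp.p3b_duration)
            _add_template(data, ch_central, onset + off, w, sp.p3b_amp)
            w, off = _bump(fs, sp.cat_late_center, sp.cat_late_duration)
            _add_template(data, ch_central, onset + off, w, sign * sp.cat_late_amp)

            # behavior
            rt = None
            if nogo:
                responded = rng.random() < bp.fa_prob
            else:
                responded = rng.random() >= bp.miss_prob
            if responded:
                rt = float(np.clip(rng.lognormal(np.log(bp.rt_mu), bp.rt_sigma), 150.0, 1200.0))
            events.append(Event(onset=onset, kind="stimulus", stimulus_category=category,
                                go_nogo="nogo" if nogo else "go", rt_ms=rt, block=b))
            if rt is not None:
                r_onset = onset + int(round(rt / 1000.0 * fs))
                if r_onset < n:
                    events.append(Event(onset=r_onset, kind="response", block=b))
            t += rng.uniform(soa_lo, soa_hi) / 1000.0

        p_lo, p_hi = config.probe_interval_range
        t = t0 + rng.uniform(p_lo, p_hi)
        while t < t_end - 2.0:
            onset = int(round(t * fs))
            state = STATES[states[onset]]
            answer = state
            if config.report_noise > 0 and rng.random() < config.report_noise:
                answer = ["ON", "MW", "MB", "DR"][int(rng.integers(4))]
            vig_mu = {"ON": 3.5, "MW": 3.0, "MB": 2.5}[state]
            vigilance = int(np.clip(round(rng.normal(vig_mu, 0.7)), 1, 4))
            events.append(Event(onset=onset, kind="probe_onset", block=b))
            a_onset = min(onset + int(round(2.0 * fs)), n - 1)
            events.append(Event(onset=a_onset, kind="probe_answer", probe_answer=answer,
                                vigilance=vigilance, block=b))
            t += rng.uniform(p_lo, p_hi)

    events.sort(key=lambda e: (e.onset, e.kind))
    return ContinuousRecording(data=data, fs=fs, channel_names=names,
                               channel_positions=positions, events=events,
                               truth_states=states, subject=config.subject)


# ---------------------------------------------------------------------------
# fixture IO (EDF + TSV)
# ---------------------------------------------------------------------------

_EVENT_COLS = ["onset_sample", "kind", "category", "go_nogo", "rt_ms", "block"]
_PROBE_COLS = ["onset_sample", "answer", "vigilance"]


def _write_edf(path: Path, data: np.ndarray, fs: float, names: list) -> None:
    """Minimal 16-bit EDF writer (one data record per second)."""
    n_ch, n = data.shape
    spr = int(round(fs))
    n_rec = int(np.ceil(n / spr))
    padded = np.zeros((n_ch, n_rec * spr))
    padded[:, :n] = data
    phys = float(max(1.0, np.abs(padded).max()))
    dig_min, dig_max = -32768, 32767
    scale = (dig_max - 1) / phys

    def f(x, width):
        s = str(x)[:width]
        return s.ljust(width).encode("ascii")

    hdr = b"".join([
        f("0", 8), f("X X X X", 80), f("Startdate X X X X", 80),
        f("01.01.00", 8), f("00.00.00", 8), f(256 + 256 * n_ch, 8), f("", 44),
        f(n_rec, 8), f("1", 8), f(n_ch, 4),
    ])
    sig = b"".join([
        b"".join(f(nm, 16) for nm in names),
        b"".join(f("synthetic EEG", 80) for _ in names),
        b"".join(f("uV", 8) for _ in names),
        b"".join(f(f"{-phys:.1f}"[:8], 8) for _ in names),
        b"".join(f(f"{phys:.1f}"[:8], 8) for _ in names),
        b"".join(f(dig_min, 8) for _ in names),
        b"".join(f(dig_max, 8) for _ in names),
        b"".join(f("", 80) for _ in names),
        b"".join(f(spr, 8) for _ in names),
        b"".join(f("", 32) for _ in names),
    ])
    digital = np.clip(np.round(padded * scale), dig_min, dig_max).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(hdr + sig)
        for r in range(n_rec):
            fh.write(digital[:, r * spr:(r + 1) * spr].tobytes())


def write_fixture(recording: ContinuousRecording, path) -> dict:
    """Write a session to disk: ``<stem>.edf`` EEG plus ``<stem>_events.tsv``
    and ``<stem>_probes.tsv``.  Returns the paths written."""
    path = Path(path)
    if path.suffix.lower() != ".edf":
        raise FormatError(f"unsupported EEG extension {path.suffix!r}; use .edf")
    path.parent.mkdir(parents=True, exist_ok=True)
    _write_edf(path, recording.data, recording.fs, recording.channel_names)

    ev = recording.events_frame()
    if len(ev) == 0:
        ev = pd.DataFrame(columns=["onset", "kind", "stimulus_category", "go_nogo",
                                   "rt_ms", "probe_answer", "vigilance", "block"])
    stim = ev[ev["kind"].isin(["stimulus", "response"])].copy()
    events_tsv = pd.DataFrame({
        "onset_sample": stim["onset"].astype(int) if len(stim) else pd.Series(dtype=int),
        "kind": stim["kind"], "category": stim["stimulus_category"],
        "go_nogo": stim["go_nogo"], "rt_ms": stim["rt_ms"], "block": stim["block"],
    })
    answers = ev[ev["kind"] == "probe_answer"].reset_index(drop=True)
    onsets = ev[ev["kind"] == "probe_onset"].reset_index(drop=True)
    probes_tsv = pd.DataFrame({
        "onset_sample": onsets["onset"].astype(int) if len(onsets) else pd.Series(dtype=int),
        "answer": answers["probe_answer"] if len(answers) else pd.Series(dtype=object),
        "vigilance": answers["vigilance"] if len(answers) else pd.Series(dtype=float),
    })
    ev_path = path.with_name(path.stem + "_events.tsv")
    pr_path = path.with_name(path.stem + "_probes.tsv")
    events_tsv.to_csv(ev_path, sep="\t", index=False)
    probes_tsv.to_csv(pr_path, sep="\t", index=False)
    return {"eeg": path, "events": ev_path, "probes": pr_path}


def read_fixture(path) -> ContinuousRecording:
    """Read a session written by :func:`write_fixture` (EDF via mne)."""
    import mne

    path = Path(path)
    if path.suffix.lower() != ".edf":
        raise FormatError(f"unsupported EEG extension {path.suffix!r}; use .edf")
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne returns volts
    fs = float(raw.info["sfreq"])
    names = list(raw.ch_names)
    _, positions = channel_layout(len(names))

    events: list[Event] = []
    ev = pd.read_csv(path.with_name(path.stem + "_events.tsv"), sep="\t")
    for _, r in ev.iterrows():
        events.append(Event(onset=int(r["onset_sample"]), kind=r["kind"],
                            stimulus_category=r["category"] if pd.notna(r["category"]) else None,
                            go_nogo=r["go_nogo"] if pd.notna(r["go_nogo"]) else None,
                            rt_ms=float(r["rt_ms"]) if pd.notna(r["rt_ms"]) else None,
                            block=int(r["block"])))
    pr = pd.read_csv(path.with_name(path.stem + "_probes.tsv"), sep="\t")
    for _, r in pr.iterrows():
        events.append(Event(onset=int(r["onset_sample"]), kind="probe_onset"))
        events.append(Event(onset=int(r["onset_sample"]), kind="probe_answer",
                            probe_answer=r["answer"],
                            vigilance=int(r["vigilance"]) if pd.notna(r["vigilance"]) else None))
    events.sort(key=lambda e: (e.onset, e.kind))
    return ContinuousRecording(data=data, fs=fs, channel_names=names,
                               channel_positions=positions, events=events,
                               truth_states=np.zeros(data.shape[1], dtype=np.int8))
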