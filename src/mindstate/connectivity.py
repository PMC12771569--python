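"""Symbolic information sharing (wSMI) and phase locking (PLV).

wSMI symbolizes each band-passed signal into rank patterns of ``k = 3``
samples spaced ``tau`` apart, then computes the mutual information of the
co-occurring symbol pairs, zero-weighting pairs that are identical or exact
sign-flips of each other — the pattern pairs a common source seen through
volume conduction produces.  The result is normalized by ln 6 (the entropy
ceiling for 3! patterns), so wSMI(x, x) = 0 by construction.

PLV is the resultant length of the phase-difference distribution between the
analytic signals of two band-passed series: 1 for a constant phase lag, near
0 for independent narrowband noise.  It captures strictly linear phase
coupling, which is how the two metrics dissociate: a lagged, monotonically
distorted dependence raises wSMI but is diluted in PLV, while a zero-lag
common component saturates PLV yet is discarded by wSMI's weighting.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .epoching import EpochSet
from .errors import DataError, ParameterError
from .markers import BandDefinition, band_by_name

logger = logging.getLogger(__name__)

KERNEL = 3
N_SYMBOLS = 6

#: rank patterns in lexicographic order; symbol id = index
PATTERNS = tuple(itertools.permutations(range(KERNEL)))

#: id of the time-reversed-rank ("opposite") pattern for each symbol
OPPOSITE = tuple(PATTERNS.index(tuple(KERNEL - 1 - r for r in p)) for p in PATTERNS)

#: wSMI weight table: 0 on identical and opposite pairs, 1 elsewhere
WEIGHTS = np.ones((N_SYMBOLS, N_SYMBOLS))
for _i in range(N_SYMBOLS):
    WEIGHTS[_i, _i] = 0.0
    WEIGHTS[_i, OPPOSITE[_i]] = 0.0


def default_tau(fs: float, band: BandDefinition) -> int:
    """Symbol lag so the 3-sample kernel spans ~one cycle of the band's upper
    edge: ``tau = max(1, round(fs / (3 f_hi)))`` (delta 21, theta 10, alpha 7
    samples at fs = 250)."""
    return max(1, int(round(fs / (KERNEL * band.f_hi))))


@dataclass
class SymbolicSeries:
    symbols: np.ndarray   # int8 in {0..5}
    k: int
    tau: int
    source_length: int


def symbolic_transform(series: np.ndarray, k: int = KERNEL, tau: int = 1) -> SymbolicSeries:
    """Rank-pattern symbols of ``(x[t], x[t+tau], x[t+2 tau])``.

    Ties break earlier-index-smaller (stable sort), and the output length is
    ``n - (k - 1) * tau``.
    """
    if k != KERNEL:
        raise ParameterError("only k = 3 is supported")
    x = np.asarray(series, dtype=float)
    n_out = x.size - (k - 1) * tau
    if n_out <= 0:
        raise DataError(f"series length {x.size} <= required minimum {(k - 1) * tau + 1}")
    emb = np.stack([x[i * tau: i * tau + n_out] for i in range(k)], axis=1)
    order = np.argsort(emb, axis=1, kind="stable")
    ranks = np.empty_like(order)
    rows = np.arange(n_out)[:, None]
    ranks[rows, order] = np.arange(k)[None, :]
    # pattern id in lexicographic order of the rank triple
    lut = np.full((k,) * k, -1, dtype=np.int8)
    for pid, p in enumerate(PATTERNS):
        lut[p] = pid
    symbols = lut[ranks[:, 0], ranks[:, 1], ranks[:, 2]]
    return SymbolicSeries(symbols=symbols.astype(np.int8), k=k, tau=tau,
                          source_length=x.size)


def _mi_terms(joint, px, py):
    """p log(p / (px py)) on the support of the joint distribution."""
    terms = np.zeros_like(joint)
    nz = joint > 0
    terms[nz] = joint[nz] * np.log(joint[nz] / (px[:, None] * py[None, :])[nz])
    return terms


def wsmi(x_series, y_series, k: int = KERNEL, tau: int = 1) -> float:
    """Weighted symbolic mutual information, normalized to [0, 1] by ln 6.

    Maximum-likelihood joint/marginal symbol probabilities, with weight 0 on
    identical and sign-flip symbol pairs.  Degenerate (single-symbol) inputs
    return 0.
    """
    if np.asarray(x_series).size != np.asarray(y_series).size:
        raise DataError("series must have equal lengths")
    sx = symbolic_transform(x_series, k, tau).symbols.astype(np.int64)
    sy = symbolic_transform(y_series, k, tau).symbols.astype(np.int64)
    n = sx.size
    joint = np.bincount(sx * N_SYMBOLS + sy, minlength=N_SYMBOLS * N_SYMBOLS).reshape(
        N_SYMBOLS, N_SYMBOLS) / n
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    if (px > 0).sum() < 2 or (py > 0).sum() < 2:
        logger.info("degenerate symbol distribution; wSMI = 0")
        return 0.0
    terms = _mi_terms(joint, px, py)
    return float((WEIGHTS * terms).sum() / np.log(N_SYMBOLS))


# ---------------------------------------------------------------------------
# filtering and PLV
# ---------------------------------------------------------------------------

def bandpass(x: np.ndarray, fs: float, band: BandDefinition) -> np.ndarray:
    """Zero-phase FIR band-pass (Hamming design, ~3 cycles of f_lo long,
    capped so filtfilt stays valid on short epochs)."""
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    if band.f_hi >= fs / 2:
        raise ParameterError(f"band {band.name} upper edge {band.f_hi} >= Nyquist {fs / 2}")
    numtaps = int(round(3 * fs / band.f_lo)) | 1
    max_taps = max(9, (n // 3) | 1)
    numtaps = min(numtaps, max_taps)
    b = sps.firwin(numtaps, [band.f_lo, band.f_hi], pass_zero=False, window="hamming", fs=fs)
    padlen = min(3 * numtaps, n - 1)
    return sps.filtfilt(b, [1.0], x, axis=-1, padlen=padlen)


def _trim(n: int, fraction: float = 0.1) -> slice:
    k = int(round(n * fraction))
    return slice(k, n - k if n - k > k else n)


def plv(x_series, y_series, band: BandDefinition, fs: float) -> float:
    """Phase-locking value in [0, 1]; the edge 10% of samples on each side is
    discarded before averaging to suppress filter/Hilbert edge effects.
    Zero-variance input yields NaN (flagged sentinel)."""
    x = np.asarray(x_series, dtype=float)
    y = np.asarray(y_series, dtype=float)
    if x.size != y.size:
        raise DataError("series must have equal lengths")
    if x.std() == 0 or y.std() == 0:
        logger.warning("zero-variance input to plv; returning sentinel")
        return float("nan")
    xb = bandpass(x, fs, band)
    yb = bandpass(y, fs, band)
    phix = np.angle(sps.hilbert(xb))
    phiy = np.angle(sps.hilbert(yb))
    sel = _trim(x.size)
    return float(np.abs(np.mean(np.exp(1j * (phix[sel] - phiy[sel])))))


# ---------------------------------------------------------------------------
# per-epoch connectivity stacks
# ---------------------------------------------------------------------------

@dataclass
class ConnectivityResult:
    """Per-trial symmetric connectivity matrices for one band and metric."""

    band: BandDefinition
    metric: str                   # "wsmi" | "plv"
    matrix: np.ndarray            # (trials, nodes, nodes); diagonal flagged/0 or 1
    node_names: list
    node_kind: str = "channel"    # channel | source | roi
    metadata: pd.DataFrame | None = None

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[-1]

    def mean_for(self, state: str) -> np.ndarray:
        mask = (self.metadata["state_label"] == state).to_numpy()
        return self.matrix[mask].mean(axis=0)


def _resolve_band(band) -> BandDefinition:
    return band_by_name(band) if isinstance(band, str) else band


def band_wsmi(epochs: EpochSet, band, tau: int | None = None,
              pairs=None) -> ConnectivityResult:
    """wSMI between every channel pair of each epoch, after zero-phase
    band-pass and 10% edge trimming, using the band's default tau."""
    band = _resolve_band(band)
    if band.f_hi >= epochs.fs / 2:
        raise ParameterError("band above Nyquist")
    if tau is None:
        tau = default_tau(epochs.fs, band)
    n_t, n_c, n_s = epochs.data.shape
    sel = _trim(n_s)
    out = np.zeros((n_t, n_c, n_c))
    pair_list = pairs if pairs is not None else list(itertools.combinations(range(n_c), 2))
    needed = sorted({c for pr in pair_list for c in pr})
    filt_all = bandpass(epochs.data[:, needed], epochs.fs, band)[:, :, sel]
    col = {c: k for k, c in enumerate(needed)}
    for t in range(n_t):
        filt = filt_all[t]
        symbols = {c: symbolic_transform(filt[col[c]], tau=tau).symbols.astype(np.int64)
                   for c in needed}
        for (i, j) in pair_list:
            si, sj = symbols[i], symbols[j]
            n = si.size
            joint = np.bincount(si * N_SYMBOLS + sj, minlength=36).reshape(6, 6) / n
            px, py = joint.sum(axis=1), joint.sum(axis=0)
            if (px > 0).sum() < 2 or (py > 0).sum() < 2:
                continue
            v = float((WEIGHTS * _mi_terms(joint, px, py)).sum() / np.log(N_SYMBOLS))
            out[t, i, j] = out[t, j, i] = v
    return ConnectivityResult(band=band, metric="wsmi", matrix=out,
                              node_names=list(epochs.channel_names) or list(range(n_c)),
                              node_kind="channel", metadata=epochs.metadata.copy())


def band_plv(epochs: EpochSet, band, pairs=None) -> ConnectivityResult:
    """PLV between every channel pair of each epoch."""
    band = _resolve_band(band)
    if band.f_hi >= epochs.fs / 2:
        raise ParameterError("band above Nyquist")
    n_t, n_c, n_s = epochs.data.shape
    sel = _trim(n_s)
    out = np.zeros((n_t, n_c, n_c))
    pair_list = pairs if pairs is not None else list(itertools.combinations(range(n_c), 2))
    needed = sorted({c for pr in pair_list for c in pr})
    filt_all = bandpass(epochs.data[:, needed], epochs.fs, band)
    col = {c: k for k, c in enumerate(needed)}
    for t in range(n_t):
        phases = np.angle(sps.hilbert(filt_all[t], axis=-1))[:, sel]
        np.fill_diagonal(out[t], 1.0)
        for (i, j) in pair_list:
            v = float(np.abs(np.mean(np.exp(1j * (phases[col[i]] - phases[col[j]])))))
            out[t, i, j] = out[t, j, i] = v
    return ConnectivityResult(band=band, metric="plv", matrix=out,
                              node_names=list(epochs.channel_names) or list(range(n_c)),
                              node_kind="channel", metadata=epochs.metadata.copy())


# ---------------------------------------------------------------------------
# ROI aggregation (source-space style)
# ---------------------------------------------------------------------------

ROI_REGIONS = ("frontal", "limbic", "temporal", "parietal", "occipital")


@dataclass
class RoiScheme:
    """Assignment of sources to 10 ROIs (5 regions x left/right)."""

    roi_names: list
    assignment: np.ndarray   # (n_sources,) int index into roi_names

    def __post_init__(self):
        self.assignment = np.asarray(self.assignment)
        if (self.assignment < 0).any() or (self.assignment >= len(self.roi_names)).any():
            raise DataError("every source must be assigned to exactly one ROI")

    @property
    def n_rois(self) -> int:
        return len(self.roi_names)

    @classmethod
    def desikan_killiany_lobes(cls, n_sources: int = 68) -> "RoiScheme":
        """68 cortical sources grouped into 5 lobes x 2 hemispheres.

        Synthetic stand-in for the Desikan-Killiany lobe grouping: sources
        alternate hemispheres and are distributed over regions in fixed
        proportion; it preserves the 10-ROI / 45-pair structure without an
        atlas file.
        """
        names = [f"{r}-{h}" for r in ROI_REGIONS for h in ("left", "right")]
        per_region = n_sources // (2 * len(ROI_REGIONS))
        assignment = []
        for ri in range(len(ROI_REGIONS)):
            for h in range(2):
                assignment.extend([2 * ri + h] * per_region)
        while len(assignment) < n_sources:
            assignment.append(len(names) - 1)
        return cls(roi_names=names, assignment=np.array(assignment[:n_sources]))


def roi_aggregate(source_conn: ConnectivityResult, scheme: RoiScheme) -> ConnectivityResult:
    """Average source-pair values into ROI-pair values (10x10 symmetric; the
    45 off-diagonal pairs are the reported connections)."""
    mat = source_conn.matrix
    single = mat.ndim == 2
    if single:
        mat = mat[None]
    n_src = mat.shape[-1]
    if scheme.assignment.size != n_src:
        raise DataError(f"scheme assigns {scheme.assignment.size} sources, matrix has {n_src}")
    R = scheme.n_rois
    out = np.zeros((mat.shape[0], R, R))
    members = [np.flatnonzero(scheme.assignment == r) for r in range(R)]
    for a in range(R):
        for b in range(R):
            if a == b:
                ia = members[a]
                if ia.size > 1:
                    sub = mat[:, ia][:, :, ia]
                    iu = np.triu_indices(ia.size, k=1)
                    out[:, a, a] = sub[:, iu[0], iu[1]].mean(axis=-1)
                continue
            sub = mat[:, members[a]][:, :, members[b]]
            out[:, a, b] = sub.reshape(mat.shape[0], -1).mean(axis=-1)
    if single:
        out = out[0]
    return ConnectivityResult(band=source_conn.band, metric=source_conn.metric,
                              matrix=out, node_names=list(scheme.roi_names),
                              node_kind="roi", metadata=source_conn.metadata)


def n_roi_pairs(scheme: RoiScheme) -> int:
    return scheme.n_rois * (scheme.n_rois - 1) // 2


# ---------------------------------------------------------------------------
# PLV/wSMI dissociation
# ---------------------------------------------------------------------------

def plv_wsmi_dissociation_check(epochs_by_state: dict, band,
                                pairs=None) -> pd.DataFrame:
    """Mean state differences of PLV and wSMI per connection.

    For every ordered state pair (A, B) present, reports
    ``delta = mean_A - mean_B`` for both metrics on each connection, so the
    planted MB profile (zero-lag phase coupling up, lagged nonlinear coupling
    down) shows as PLV delta > 0 with wSMI delta < 0 for MB - ON.
    """
    band = _resolve_band(band)
    states = [s for s, ep in epochs_by_state.items() if ep is not None and ep.n_trials > 0]
    if len(states) < 2:
        raise DataError("need >= 2 states with epochs")
    per_state = {}
    for s in states:
        ep = epochs_by_state[s]
        w = band_wsmi(ep, band, pairs=pairs)
        p = band_plv(ep, band, pairs=pairs)
        per_state[s] = {"wsmi": w.matrix.mean(axis=0), "plv": p.matrix.mean(axis=0)}
        node_names = w.node_names
    n_c = per_state[states[0]]["wsmi"].shape[0]
    pair_list = pairs if pairs is not None else list(itertools.combinations(range(n_c), 2))
    rows = []
    for a in states:
        for b in states:
            if a == b:
                continue
            for metric in ("wsmi", "plv"):
                d = per_state[a][metric] - per_state[b][metric]
                for (i, j) in pair_list:
                    rows.append({"state_a": a, "state_b": b, "metric": metric,
                                 "node_i": node_names[i], "node_j": node_names[j],
                                 "delta": float(d[i, j])})
    return pd.DataFrame(rows)
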