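"""Per-trial, per-channel spectral and complexity markers.

Three marker classes track background cortical dynamics:

* normalized band power — Welch PSD integrated over the delta, theta, alpha,
  beta and gamma bands, divided by the total power over their union, so the
  five fractions sum to 1 per trial and channel;
* sample entropy (SampEn) — the negative log conditional probability that
  templates of length ``m`` that match within a Chebyshev radius
  ``r = r_factor * SD`` still match at length ``m + 1`` (self-matches
  excluded);
* compression complexity (KC) — the signal is binarized around its median,
  bit-packed, and deflate-compressed at maximum level; KC is the compressed /
  packed byte ratio, a practical stand-in for Kolmogorov complexity.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd
from numba import njit
from scipy import signal as sps

from .epoching import EpochSet
from .errors import DataError, ParameterError

logger = logging.getLogger(__name__)

#: sentinel for undefined marker values (degenerate SampEn); excluded, not imputed
SENTINEL = np.nan

BAND_NAMES = ("delta", "theta", "alpha", "beta", "gamma")


@dataclass(frozen=True)
class BandDefinition:
    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self):
        if not 0 < self.f_lo < self.f_hi:
            raise ParameterError(f"band {self.name}: need 0 < f_lo < f_hi")


DEFAULT_BANDS = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 12.0),
    BandDefinition("beta", 12.0, 30.0),
    BandDefinition("gamma", 30.0, 45.0),
)


def band_by_name(name: str, bands=DEFAULT_BANDS) -> BandDefinition:
    for b in bands:
        if b.name == name:
            return b
    raise ParameterError(f"unknown band {name!r}")


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------

def psd_welch(series: np.ndarray, fs: float, nperseg: int | None = None,
              overlap: float = 0.5):
    """Welch PSD with Hann segments; returns (frequencies, densities).

    Densities are in uV^2/Hz and satisfy Parseval within segmentation error:
    the integral approximates the detrended signal variance.
    """
    x = np.asarray(series, dtype=float)
    if nperseg is None:
        nperseg = min(x.size, int(round(fs)))
    if x.size < nperseg:
        raise DataError(f"series length {x.size} < required minimum nperseg={nperseg}")
    noverlap = int(round(nperseg * overlap))
    freqs, pxx = sps.welch(x, fs=fs, window="hann", nperseg=nperseg,
                           noverlap=noverlap, detrend="constant")
    return freqs, pxx


def welch_batch(X: np.ndarray, fs: float, nperseg: int, overlap: float = 0.5):
    """Vectorized Welch PSD for a batch of series (rows of ``X``).

    Same estimator as :func:`psd_welch` (Hann window, constant detrend per
    segment, one-sided density scaling); implemented with stride tricks and a
    single batched FFT so marker extraction over tens of thousands of
    trial-channel series stays cheap.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[-1]
    if n < nperseg:
        raise DataError(f"series length {n} < required minimum nperseg={nperseg}")
    step = nperseg - int(round(nperseg * overlap))
    n_seg = 1 + (n - nperseg) // step
    idx = np.arange(nperseg)[None, :] + step * np.arange(n_seg)[:, None]
    segs = X[..., idx]                                    # (..., n_seg, nperseg)
    segs = segs - segs.mean(axis=-1, keepdims=True)
    win = sps.get_window("hann", nperseg)
    spec = np.fft.rfft(segs * win, axis=-1)
    pxx = (spec.real ** 2 + spec.imag ** 2) / (fs * (win ** 2).sum())
    pxx[..., 1:] *= 2.0
    if nperseg % 2 == 0:
        pxx[..., -1] /= 2.0
    freqs = np.fft.rfftfreq(nperseg, 1.0 / fs)
    return freqs, pxx.mean(axis=-2)


def normalized_band_power(spectrum, bands=DEFAULT_BANDS) -> np.ndarray:
    """Per-band power fraction: band integral / integral over the band union."""
    freqs, pxx = spectrum
    freqs = np.asarray(freqs)
    pxx = np.asarray(pxx)
    powers = np.empty(len(bands))
    for i, b in enumerate(bands):
        sel = (freqs >= b.f_lo) & (freqs < b.f_hi)
        if not sel.any():
            raise ParameterError(f"band {b.name} [{b.f_lo}, {b.f_hi}) contains no spectral bins")
        powers[i] = pxx[sel].sum()
    total = powers.sum()
    if total == 0:
        return np.full(len(bands), 1.0 / len(bands))
    return powers / total


# ---------------------------------------------------------------------------
# complexity
# ---------------------------------------------------------------------------

@njit(cache=False)
def _sampen_counts_batch(X, m, r):
    # X: (N, n) batch of series; r: (N,) per-series radius
    N = X.shape[0]
    out = np.empty((N, 2), dtype=np.int64)
    for s in range(N):
        A = 0
        B = 0
        nt = X.shape[1] - m
        for i in range(nt - 1):
            for j in range(i + 1, nt):
                d = 0.0
                for k in range(m):
                    dk = abs(X[s, i + k] - X[s, j + k])
                    if dk > d:
                        d = dk
                if d <= r[s]:
                    B += 1
                    if abs(X[s, i + m] - X[s, j + m]) <= r[s]:
                        A += 1
        out[s, 0] = A
        out[s, 1] = B
    return out


@njit(cache=False)
def _sampen_counts(x, m, r):
    # Template pairs (i < j) within Chebyshev distance r, at lengths m and m+1.
    # The same n - m templates are used for both lengths (standard estimator).
    nt = x.shape[0] - m
    A = 0
    B = 0
    for i in range(nt - 1):
        for j in range(i + 1, nt):
            d = 0.0
            for k in range(m):
                dk = abs(x[i + k] - x[j + k])
                if dk > d:
                    d = dk
            if d <= r:
                B += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    A += 1
    return A, B


def sample_entropy(series: np.ndarray, m: int = 2, r_factor: float = 0.2) -> float:
    """SampEn(m, r) in nats; ``r = r_factor * SD(series)``.

    Returns NaN (flagged sentinel) when no template pairs match at either
    length, which happens for very short or pathological inputs.
    """
    x = np.ascontiguousarray(series, dtype=np.float64)
    if x.size < 10 * m:
        raise DataError(f"series length {x.size} < required minimum {10 * m}")
    r = r_factor * float(x.std())
    A, B = _sampen_counts(x, m, r)
    if A == 0 or B == 0:
        logger.warning("degenerate SampEn (A=%d, B=%d); returning sentinel", A, B)
        return SENTINEL
    return float(-np.log(A / B))


def kolmogorov_complexity(series: np.ndarray) -> float:
    """Compression complexity: deflate(level 9) bytes / packed bytes of the
    median-binarized signal.  Low for regular signals, near (or just above) 1
    for incompressible ones."""
    x = np.asarray(series, dtype=float)
    if x.size < 64:
        raise DataError(f"series length {x.size} < required minimum 64")
    med = np.median(x)
    bits = (x >= med).astype(np.uint8)
    if bits.all() and (x > med).any():
        # median sits on the lower of two values (e.g. binary input): the
        # >= split would be degenerate, use the strict split instead
        bits = (x > med).astype(np.uint8)
    packed = np.packbits(bits).tobytes()
    compressed = zlib.compress(packed, level=9)
    return len(compressed) / len(packed)


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

@dataclass
class MarkerMatrix:
    """values: trials x channels x markers, with names and trial metadata."""

    values: np.ndarray
    marker_names: list
    metadata: pd.DataFrame
    channel_names: list = field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    def marker(self, name: str) -> np.ndarray:
        return self.values[:, :, self.marker_names.index(name)]

    def to_tidy(self) -> pd.DataFrame:
        n_t, n_c, n_m = self.values.shape
        t, c, m = np.meshgrid(np.arange(n_t), np.arange(n_c), np.arange(n_m), indexing="ij")
        df = pd.DataFrame({
            "trial": t.ravel(),
            "channel": np.asarray(self.channel_names)[c.ravel()] if self.channel_names else c.ravel(),
            "marker": np.asarray(self.marker_names)[m.ravel()],
            "value": self.values.ravel(),
        })
        return df

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("values", data=self.values, compression="gzip")
            f.attrs["marker_names"] = list(self.marker_names)
            f.attrs["channel_names"] = [str(c) for c in self.channel_names]
            f.create_dataset("metadata", data=self.metadata.to_json().encode())

    @classmethod
    def load(cls, path) -> "MarkerMatrix":
        import io

        with h5py.File(path, "r") as f:
            meta = pd.read_json(io.StringIO(bytes(f["metadata"][()]).decode()))
            return cls(values=f["values"][()],
                       marker_names=list(f.attrs["marker_names"]),
                       metadata=meta.reset_index(drop=True),
                       channel_names=list(f.attrs["channel_names"]))


def compute_marker_matrix(epochs: EpochSet, bands=DEFAULT_BANDS,
                          nperseg: int | None = None,
                          sampen_m: int = 2, sampen_r: float = 0.2) -> MarkerMatrix:
    """All markers for every trial and channel of ``epochs``.

    Welch segments default to 1 s for epochs of at least 2 s and half the
    epoch otherwise (so there are always >= 2, usually >= 4 segments).
    """
    if epochs.n_trials == 0:
        raise DataError("empty EpochSet")
    n_t, n_c, n_s = epochs.data.shape
    fs = epochs.fs
    if nperseg is None:
        nperseg = int(round(fs)) if n_s >= 2 * fs else max(16, n_s // 2)
    names = [f"psd_{b.name}" for b in bands] + ["sampen", "kc"]
    values = np.empty((n_t, n_c, len(names)))
    flat = np.ascontiguousarray(epochs.data.reshape(n_t * n_c, n_s))

    # spectra: one batched Welch pass, band integrals by mask
    freqs, pxx = welch_batch(flat, fs, nperseg=nperseg)
    masks = np.stack([(freqs >= b.f_lo) & (freqs < b.f_hi) for b in bands])
    for b, msk in zip(bands, masks):
        if not msk.any():
            raise ParameterError(f"band {b.name} [{b.f_lo}, {b.f_hi}) contains no spectral bins")
    band_power = pxx @ masks.T.astype(float)               # (N, n_bands)
    total = band_power.sum(axis=1, keepdims=True)
    total[total == 0] = 1.0
    values[:, :, :len(bands)] = (band_power / total).reshape(n_t, n_c, len(bands))

    # complexity
    if n_s < 10 * sampen_m or n_s < 64:
        raise DataError(f"epochs too short ({n_s} samples) for complexity markers")
    r = sampen_r * flat.std(axis=1)
    counts = _sampen_counts_batch(flat, sampen_m, r)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = -np.log(counts[:, 0] / counts[:, 1])
    se[(counts[:, 0] == 0) | (counts[:, 1] == 0)] = SENTINEL
    n_flagged = int(np.isnan(se).sum())
    values[:, :, len(bands)] = se.reshape(n_t, n_c)
    values[:, :, len(bands) + 1] = np.fromiter(
        (kolmogorov_complexity(x) for x in flat), dtype=float, count=n_t * n_c,
    ).reshape(n_t, n_c)

    if n_flagged > 0.2 * n_t * n_c:
        logger.warning("more than 20%% of SampEn values are flagged sentinels (%d of %d)",
                       n_flagged, n_t * n_c)
    return MarkerMatrix(values=values, marker_names=names,
                        metadata=epochs.metadata.copy(),
                        channel_names=list(epochs.channel_names))
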