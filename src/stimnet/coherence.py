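"""Multitaper coherence networks on half-second windows.

Functional interactions between intracranial channels are estimated as
magnitude-squared coherence from a multitaper (DPSS) spectral estimate with
time-bandwidth product 5 and 8 tapers, averaged over the frequency bins of
four canonical bands: alpha/theta (5-15 Hz), beta (15-25 Hz), low gamma
(30-40 Hz), and high gamma (95-105 Hz).  Each analysis window yields one
symmetric adjacency matrix per band; the upper triangle, unravelled in
row-major order, is the network's configuration vector of length
E = N(N-1)/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.signal.windows import dpss

from .errors import AlignmentError, BandResolutionError, NyquistError

__all__ = [
    "BandSpec",
    "DEFAULT_BANDS",
    "CoherenceNetwork",
    "multitaper_coherence",
    "tapered_spectra",
    "band_adjacency",
    "configuration_vector",
    "reconstruct_adjacency",
]


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band, closed interval [lo, hi] in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 <= self.lo < self.hi):
            raise ValueError(f"invalid band range ({self.lo}, {self.hi})")

    def contains(self, freqs: np.ndarray) -> np.ndarray:
        """Boolean mask of bin centers falling inside the band (closed)."""
        return (freqs >= self.lo) & (freqs <= self.hi)


DEFAULT_BANDS: tuple[BandSpec, ...] = (
    BandSpec("alpha_theta", 5.0, 15.0),
    BandSpec("beta", 15.0, 25.0),
    BandSpec("low_gamma", 30.0, 40.0),
    BandSpec("high_gamma", 95.0, 105.0),
)


@dataclass
class CoherenceNetwork:
    """Per-window, per-band functional network.

    ``A`` is symmetric with entries in [0, 1] and zero diagonal; ``config``
    is the upper triangle of ``A`` in row-major order.
    """

    A: np.ndarray
    band: BandSpec
    window_id: str | None = None
    config: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.config = configuration_vector(self.A)

    @property
    def n_nodes(self) -> int:
        return self.A.shape[0]


@lru_cache(maxsize=32)
def _dpss_tapers(n: int, tw: float, k: int) -> np.ndarray:
    return dpss(n, tw, Kmax=k, sym=False)


def tapered_spectra(
    signals: np.ndarray, fs: float, tw: float = 5.0, k: int = 8
) -> tuple[np.ndarray, np.ndarray]:
    """Eigenspectra of each channel: (freqs, X[channels, tapers, bins]).

    Per-channel mean is removed before tapering so constant offsets do not
    dominate the DC bin.
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    n = signals.shape[1]
    tapers = _dpss_tapers(n, tw, k)  # (k, n), unit energy
    demeaned = signals - signals.mean(axis=1, keepdims=True)
    # (channels, k, n) -> rfft along time
    tapered = demeaned[:, None, :] * tapers[None, :, :]
    spectra = np.fft.rfft(tapered, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return freqs, spectra


def multitaper_coherence(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    tw: float = 5.0,
    k: int = 8,
) -> tuple[np.ndarray, np.ndarray]:
    """Magnitude-squared coherence spectrum between two signals.

    Parameters
    ----------
    x, y
        Equal-length signal vectors (at least ``0.5 * fs`` samples).
    fs
        Sampling rate in Hz.
    tw, k
        DPSS time-bandwidth product and number of tapers.

    Returns
    -------
    freqs, coh
        Bin center frequencies and per-bin coherence in [0, 1].  Bins where
        either signal has zero power are returned as NaN (flagged, not
        raised), which occurs only for constant inputs.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise AlignmentError(f"signal lengths differ: {x.size} vs {y.size}")
    freqs, spectra = tapered_spectra(np.vstack([x, y]), fs, tw=tw, k=k)
    X, Y = spectra[0], spectra[1]
    sxx = np.mean(np.abs(X) ** 2, axis=0)
    syy = np.mean(np.abs(Y) ** 2, axis=0)
    sxy = np.mean(X * np.conj(Y), axis=0)
    denom = sxx * syy
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.where(denom > 0, np.abs(sxy) ** 2 / denom, np.nan)
    return freqs, np.clip(coh, 0.0, 1.0)


def band_adjacency(
    signals: np.ndarray,
    fs: float,
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS,
    tw: float = 5.0,
    k: int = 8,
    window_id: str | None = None,
) -> dict[str, CoherenceNetwork]:
    """Per-band coherence adjacency over all channel pairs of a window.

    ``A_ij`` is the arithmetic mean of magnitude-squared coherence over the
    bins whose center frequency falls in the band (closed interval); the
    diagonal is zero.  All pairs share one set of tapered eigenspectra, so
    this is algebraically identical to calling :func:`multitaper_coherence`
    per pair (asserted against that brute-force loop in the test suite).
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    n_ch = signals.shape[0]
    if n_ch < 2:
        raise AlignmentError("need at least 2 channels to build a network")
    nyq = fs / 2.0
    for band in bands:
        if band.hi >= nyq:
            raise NyquistError(
                f"band {band.name} upper edge {band.hi} Hz >= Nyquist {nyq} Hz"
            )
    freqs, spectra = tapered_spectra(signals, fs, tw=tw, k=k)
    # cross-spectra averaged over tapers for every ordered pair at once
    sxy = np.einsum("ikf,jkf->ijf", spectra, np.conj(spectra)) / spectra.shape[1]
    auto = np.real(np.einsum("iif->if", sxy))
    denom = auto[:, None, :] * auto[None, :, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.where(denom > 0, np.abs(sxy) ** 2 / denom, np.nan)
    coh = np.clip(coh, 0.0, 1.0)

    out: dict[str, CoherenceNetwork] = {}
    for band in bands:
        mask = band.contains(freqs)
        if not mask.any():
            raise BandResolutionError(
                f"band {band.name} has no frequency bins at fs={fs}, "
                f"window length {signals.shape[1]} samples"
            )
        A = coh[:, :, mask].mean(axis=-1)
        np.fill_diagonal(A, 0.0)
        A = 0.5 * (A + A.T)  # symmetrize away float round-off
        out[band.name] = CoherenceNetwork(A=A, band=band, window_id=window_id)
    return out


def configuration_vector(A: np.ndarray) -> np.ndarray:
    """Upper triangle of a symmetric matrix in row-major order (length E)."""
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise AlignmentError(f"expected square matrix, got shape {A.shape}")
    iu, ju = np.triu_indices(A.shape[0], k=1)
    return A[iu, ju].copy()


def reconstruct_adjacency(config: np.ndarray) -> np.ndarray:
    """Inverse of :func:`configuration_vector` (zero diagonal)."""
    config = np.asarray(config, dtype=float).ravel()
    e = config.size
    n = int(round((1 + np.sqrt(1 + 8 * e)) / 2))
    if n * (n - 1) // 2 != e:
        raise AlignmentError(f"length {e} is not a triangular number")
    A = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    A[iu, ju] = config
    A[ju, iu] = config
    return A
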