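"""Memory-encoding brain-state classifier on spectral power features.

A logistic model scores the probability that a window of multichannel
activity reflects a "good memory encoding" state, from log band power in
eight logarithmically spaced frequency bands (default 3-180 Hz) per
channel.  The stimulation analysis evaluates the classifier on each
trial's pre- and post-stimulation windows and reports the mean change in
state probability across trials, which is then related across sessions to
the modal controllability of the stimulated region.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from sklearn.linear_model import LogisticRegression

from .coherence import tapered_spectra
from .errors import (
    AlignmentError,
    DegenerateStatisticError,
    InsufficientDataError,
    InvalidConfigError,
    NyquistError,
)

__all__ = [
    "PowerFeatures",
    "StateClassifier",
    "default_band_edges",
    "spectral_power_features",
    "train_state_classifier",
    "state_probability_change",
    "controllability_state_corr",
]


def default_band_edges(
    lo: float = 3.0, hi: float = 180.0, n_bands: int = 8
) -> np.ndarray:
    """n_bands + 1 logarithmically spaced band edges in Hz."""
    return np.logspace(np.log10(lo), np.log10(hi), n_bands + 1)


@dataclass
class PowerFeatures:
    """Log band power per channel: ``matrix`` [channels x n_bands]."""

    matrix: np.ndarray
    band_edges: np.ndarray
    window_id: str | None = None

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        self.band_edges = np.asarray(self.band_edges, dtype=float)
        if np.any(np.diff(self.band_edges) <= 0):
            raise InvalidConfigError("band edges must be strictly increasing")
        if not np.all(np.isfinite(self.matrix)):
            raise InvalidConfigError("power features must be finite")

    def flatten(self) -> np.ndarray:
        return self.matrix.ravel()


def spectral_power_features(
    window_signals: np.ndarray,
    fs: float,
    band_edges: np.ndarray | None = None,
    tw: float = 5.0,
    k: int = 8,
    window_id: str | None = None,
) -> PowerFeatures:
    """Per-channel log mean multitaper power in each band.

    Bands are half-open [lo, hi) except the last, closed at the top edge.
    Doubling the signal amplitude raises every feature by log(4).
    """
    if band_edges is None:
        band_edges = default_band_edges()
    band_edges = np.asarray(band_edges, dtype=float)
    if band_edges[-1] > fs / 2:
        raise NyquistError(
            f"top band edge {band_edges[-1]} Hz above Nyquist {fs / 2} Hz"
        )
    signals = np.atleast_2d(np.asarray(window_signals, dtype=float))
    freqs, spectra = tapered_spectra(signals, fs, tw=tw, k=k)
    psd = np.mean(np.abs(spectra) ** 2, axis=1)  # [channels, bins]
    feats = np.empty((signals.shape[0], band_edges.size - 1))
    for b in range(band_edges.size - 1):
        lo, hi = band_edges[b], band_edges[b + 1]
        mask = (freqs >= lo) & ((freqs < hi) | ((b == band_edges.size - 2) & (freqs <= hi)))
        if not mask.any():
            raise InvalidConfigError(
                f"band [{lo:.1f}, {hi:.1f}) Hz has no frequency bins"
            )
        power = psd[:, mask].mean(axis=1)
        feats[:, b] = np.log(np.maximum(power, 1e-300))
    return PowerFeatures(matrix=feats, band_edges=band_edges, window_id=window_id)


@dataclass
class StateClassifier:
    """L2-regularized logistic classifier over flattened power features.

    Features are z-scored with the training-set mean/scale stored on the
    classifier, so evaluation windows are transformed identically.
    """

    weights: np.ndarray
    intercept: float
    feature_mean: np.ndarray
    feature_scale: np.ndarray
    band_edges: np.ndarray
    n_train: int
    class_balance: float
    regularization: float

    def _transform(self, features: PowerFeatures | np.ndarray) -> np.ndarray:
        x = (
            features.flatten()
            if isinstance(features, PowerFeatures)
            else np.asarray(features, dtype=float).ravel()
        )
        if x.size != self.weights.size:
            raise AlignmentError(
                f"feature layout mismatch: {x.size} vs {self.weights.size}"
            )
        return (x - self.feature_mean) / self.feature_scale

    def predict_proba(self, features: PowerFeatures | np.ndarray) -> float:
        """Probability of the good-encoding state, in (0, 1)."""
        z = self._transform(features)
        score = float(z @ self.weights + self.intercept)
        return float(1.0 / (1.0 + np.exp(-score)))

    def to_json(self) -> str:
        return json.dumps(
            {
                "weights": self.weights.tolist(),
                "intercept": self.intercept,
                "feature_mean": self.feature_mean.tolist(),
                "feature_scale": self.feature_scale.tolist(),
                "band_edges": self.band_edges.tolist(),
                "n_train": self.n_train,
                "class_balance": self.class_balance,
                "regularization": self.regularization,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "StateClassifier":
        d = json.loads(text)
        return cls(
            weights=np.asarray(d["weights"]),
            intercept=float(d["intercept"]),
            feature_mean=np.asarray(d["feature_mean"]),
            feature_scale=np.asarray(d["feature_scale"]),
            band_edges=np.asarray(d["band_edges"]),
            n_train=int(d["n_train"]),
            class_balance=float(d["class_balance"]),
            regularization=float(d["regularization"]),
        )


def train_state_classifier(
    features: np.ndarray,
    labels: np.ndarray,
    regularization: float = 1.0,
    band_edges: np.ndarray | None = None,
) -> StateClassifier:
    """Fit the logistic state classifier (deterministic lbfgs solver).

    ``features`` is [n_windows x p] of flattened log band powers; ``labels``
    are binary (1 = good encoding).  Features are z-scored on the training
    set.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(labels).astype(int).ravel()
    if X.shape[0] != y.size:
        raise AlignmentError("features and labels disagree in length")
    if X.shape[0] < 20:
        raise InsufficientDataError("need >= 20 training windows")
    if len(np.unique(y)) < 2:
        raise InvalidConfigError("both classes must be present")
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Xz = (X - mean) / scale
    clf = LogisticRegression(
        C=regularization, solver="lbfgs", max_iter=2000, tol=1e-8
    )
    clf.fit(Xz, y)
    return StateClassifier(
        weights=clf.coef_.ravel().copy(),
        intercept=float(clf.intercept_[0]),
        feature_mean=mean,
        feature_scale=scale,
        band_edges=band_edges if band_edges is not None else default_band_edges(),
        n_train=X.shape[0],
        class_balance=float(y.mean()),
        regularization=regularization,
    )


def state_probability_change(
    clf: StateClassifier,
    pre: PowerFeatures | np.ndarray,
    post: PowerFeatures | np.ndarray,
) -> float:
    """Delta p = p(good state | post) - p(good state | pre), in [-1, 1]."""
    return clf.predict_proba(post) - clf.predict_proba(pre)


def controllability_state_corr(
    phi_stim: np.ndarray, mean_delta_p: np.ndarray
) -> tuple[float, float]:
    """Pearson correlation across sessions between the stimulated region's
    modal controllability and the mean state-probability change."""
    x = np.asarray(phi_stim, dtype=float)
    y = np.asarray(mean_delta_p, dtype=float)
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    if x.size < 3:
        raise InsufficientDataError("need >= 3 sessions")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise DegenerateStatisticError("constant input to Pearson correlation")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
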