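"""Synthetic sessions with known ground truth.

Every downstream stage (referencing, screening, coherence networks,
reconfiguration metrics, controllability, cohort statistics, the
memory-state classifier) is exercised on generated data whose coupling
structure, stimulation effects, and planted classifier signal are known
exactly.

Signal construction.  Per frequency band, each channel receives a
band-limited Gaussian component; components across channels are mixed so
that their correlation matrix equals the requested coupling matrix C (made
positive semidefinite by eigenvalue clipping when needed).  Because
magnitude-squared coherence between two jointly Gaussian band components
with correlation c is c**2, the expected in-band coherence is an analytic,
monotone function of the coupling: ~= c**2 at high SNR, 1 at c = 1, and the
multitaper estimator's bias floor at c = 0.  A broadband white noise floor
(default 5 uV against 20 uV band components concentrated in 10-Hz bands)
leaves in-band coherence essentially unchanged.

Stimulation effects.  Post-stimulation response windows (the 1 s starting
100 ms after stimulation offset) are re-synthesized with a perturbed
coupling matrix C' = clip(C + g * W, 0, 1).  The per-trial gain g is
``effect_gain + intensity_slope * I/I_max`` for that band, where I is the
trial's amplitude x pulse-frequency x duration.  W routes the effect:
"global" perturbs every edge equally; "stim_routed" spreads a fixed
perturbation budget over nodes in proportion to their baseline coupling
with the stimulation node, so downstream nodes that cohere strongly with
the stimulated site change most.  Samples outside response windows are
untouched, and the stimulation epoch itself is overwritten with a saturated
square-wave artifact so the discard/buffer rules are exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

from .coherence import DEFAULT_BANDS, BandSpec
from .control import StructuralNetwork
from .errors import (
    GenerationError,
    InvalidConfigError,
    NyquistError,
    ScheduleError,
)
from .preproc import BUFFER_SECONDS, Recording, window_samples
from .schedule import (
    ParameterGrid,
    SessionSchedule,
    draw_trial_schedule,
)

__all__ = [
    "GroundTruthEffects",
    "default_ground_truth",
    "synth_coupled_timeseries",
    "inject_stim_effects",
    "saturate_stim_epochs",
    "synth_structural_network",
    "synth_recall_features",
    "synth_session",
]

DEFAULT_BAND_AMPLITUDE_UV = 20.0
DEFAULT_NOISE_SD_UV = 5.0
DEFAULT_FS_HZ = 500.0


# ---------------------------------------------------------------------------
# low-level signal machinery


def _band_limited_noise(
    shape: tuple[int, int], fs: float, lo: float, hi: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance Gaussian noise restricted to [lo, hi] Hz, per row."""
    n, length = shape
    white = rng.standard_normal((n, length))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(length, d=1.0 / fs)
    spec[:, ~((freqs >= lo) & (freqs <= hi))] = 0.0
    x = np.fft.irfft(spec, n=length, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _mixing_matrix(coupling: np.ndarray) -> np.ndarray:
    """L with L L^T ~= I + offdiag(coupling), rows scaled to unit variance.

    The target correlation matrix is projected to the PSD cone by clipping
    negative eigenvalues at zero; for feasible couplings the realized
    correlations equal the requested ones exactly.
    """
    R = np.asarray(coupling, dtype=float).copy()
    np.fill_diagonal(R, 1.0)
    lam, V = np.linalg.eigh(R)
    lam = np.clip(lam, 0.0, None)
    L = V * np.sqrt(lam)
    var = np.sum(L**2, axis=1)
    var[var == 0] = 1.0
    return L / np.sqrt(var)[:, None]


def _validate_coupling(C: np.ndarray, n: int, band: str) -> np.ndarray:
    C = np.asarray(C, dtype=float)
    if C.shape != (n, n):
        raise InvalidConfigError(f"coupling for {band} must be [{n}x{n}]")
    if not np.allclose(C, C.T):
        raise InvalidConfigError(f"coupling for {band} must be symmetric")
    if not np.allclose(np.diag(C), 0.0):
        raise InvalidConfigError(f"coupling for {band} must have zero diagonal")
    if np.any(C < 0) or np.any(C > 1):
        raise InvalidConfigError(f"coupling for {band} entries must be in [0, 1]")
    return C


def _coupling_dict(
    coupling: dict[str, np.ndarray] | np.ndarray,
    n: int,
    bands: tuple[BandSpec, ...],
) -> dict[str, np.ndarray]:
    if isinstance(coupling, dict):
        return {b.name: _validate_coupling(coupling[b.name], n, b.name) for b in bands}
    C = _validate_coupling(np.asarray(coupling), n, "all bands")
    return {b.name: C for b in bands}


def _render_segment(
    coupling: dict[str, np.ndarray],
    n_channels: int,
    n_samples: int,
    fs: float,
    bands: tuple[BandSpec, ...],
    band_amplitude: float,
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    sig = noise_sd * rng.standard_normal((n_channels, n_samples))
    for band in bands:
        eps = _band_limited_noise((n_channels, n_samples), fs, band.lo, band.hi, rng)
        sig += band_amplitude * (_mixing_matrix(coupling[band.name]) @ eps)
    return sig


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class GroundTruthEffects:
    """Known coupling structure and stimulation effects of a session.

    ``coupling`` holds one symmetric [N x N] matrix per band (zero diagonal,
    entries in [0, 1]).  ``effect_gain`` / ``intensity_slope`` give the
    per-band signed coupling change applied in post-stimulation windows:
    g = effect_gain + intensity_slope * I / I_max.  ``routing`` is "global"
    or "stim_routed" per band.
    """

    coupling: dict[str, np.ndarray]
    stim_node: str
    seed: int = 0
    effect_gain: dict[str, float] = field(default_factory=dict)
    intensity_slope: dict[str, float] = field(default_factory=dict)
    routing: dict[str, str] = field(default_factory=dict)
    band_amplitude: float = DEFAULT_BAND_AMPLITUDE_UV
    noise_sd: float = DEFAULT_NOISE_SD_UV

    def trial_gain(self, band: str, intensity_norm: float) -> float:
        return self.effect_gain.get(band, 0.0) + self.intensity_slope.get(
            band, 0.0
        ) * intensity_norm

    def is_null(self) -> bool:
        return all(v == 0 for v in self.effect_gain.values()) and all(
            v == 0 for v in self.intensity_slope.values()
        )

    def routing_weights(self, band: str, labels: list[str]) -> np.ndarray:
        """Edge-weight matrix W multiplying the trial gain, diag zero."""
        n = len(labels)
        mode = self.routing.get(band, "global")
        if mode == "global":
            W = np.ones((n, n))
        elif mode == "stim_routed":
            # effect spreads through the stimulation node's baseline
            # coherence partners: edge ij responds with the product of its
            # endpoints' (normalized) couplings to the stimulated site, so
            # strongly coupled downstream pairs change most.  The product
            # form carries genuine pairwise interaction structure, which is
            # what remains observable after common-average referencing
            # (purely additive per-node structure is absorbed by it).
            si = labels.index(self.stim_node)
            c = self.coupling[band][:, si].copy()
            c[si] = c.max() if c.max() > 0 else 1.0
            total = c.sum()
            s = n * c / total if total > 0 else np.ones(n)
            W = np.outer(s, s)
        else:
            raise InvalidConfigError(f"unknown routing mode {mode!r}")
        np.fill_diagonal(W, 0.0)
        return W


def default_ground_truth(
    labels: list[str],
    seed: int = 0,
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS,
    coupling_ranges: dict[str, tuple[float, float]] | None = None,
    stim_node: str | None = None,
    **effects,
) -> GroundTruthEffects:
    """Random heterogeneous baseline couplings; null effects by default.

    Per band, pairwise couplings are drawn uniformly from the band's range
    (default 0.15-0.45; 0.35-0.65 for high gamma, so suppressive effects
    have headroom).  Extra keyword arguments (``effect_gain``,
    ``intensity_slope``, ``routing``...) pass through to
    :class:`GroundTruthEffects`.
    """
    n = len(labels)
    if n < 2:
        raise InvalidConfigError("need >= 2 channels")
    if coupling_ranges is None:
        coupling_ranges = {b.name: (0.15, 0.45) for b in bands}
        if "high_gamma" in coupling_ranges:
            coupling_ranges["high_gamma"] = (0.35, 0.65)
    rng = np.random.default_rng(seed)
    coupling: dict[str, np.ndarray] = {}
    for band in bands:
        lo, hi = coupling_ranges[band.name]
        C = np.zeros((n, n))
        iu, ju = np.triu_indices(n, k=1)
        vals = rng.uniform(lo, hi, size=iu.size)
        C[iu, ju] = vals
        C[ju, iu] = vals
        coupling[band.name] = C
    return GroundTruthEffects(
        coupling=coupling,
        stim_node=stim_node if stim_node is not None else labels[0],
        seed=seed,
        **effects,
    )


# ---------------------------------------------------------------------------
# generators


def synth_coupled_timeseries(
    n_channels: int,
    fs: float,
    duration: float,
    coupling: dict[str, np.ndarray] | np.ndarray,
    noise_sd: float = DEFAULT_NOISE_SD_UV,
    seed: int | np.random.Generator = 0,
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS,
    band_amplitude: float = DEFAULT_BAND_AMPLITUDE_UV,
    labels: list[str] | None = None,
) -> Recording:
    """Multichannel recording with per-band coherent coupling.

    Channel pairs with coupling c in a band exhibit expected in-band
    multitaper coherence ~= c**2 (exactly 1 at c = 1 with no broadband
    noise; the estimator's bias floor at c = 0).
    """
    max_hi = max(b.hi for b in bands)
    if fs < 2 * max_hi:
        raise NyquistError(
            f"fs={fs} Hz cannot resolve bands up to {max_hi} Hz (need >= {2 * max_hi})"
        )
    if labels is None:
        labels = [f"ch{i:02d}" for i in range(n_channels)]
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n_samples = int(round(duration * fs))
    cdict = _coupling_dict(coupling, n_channels, bands)
    sig = _render_segment(
        cdict, n_channels, n_samples, fs, bands, band_amplitude, noise_sd, rng
    )
    return Recording(signal=sig, fs=fs, labels=labels, reference="raw")


def inject_stim_effects(
    rec: Recording,
    schedule: SessionSchedule,
    truth: GroundTruthEffects,
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS,
) -> Recording:
    """Apply ground-truth coupling changes to post-stimulation windows.

    Each trial's two response windows (1 s starting 100 ms after
    stimulation offset) are re-synthesized under the perturbed coupling;
    every sample outside those windows is copied unchanged.  With all
    effects zero the input is returned bitwise-identical.
    """
    if truth.stim_node not in rec.labels:
        raise ScheduleError(f"stim node {truth.stim_node!r} not in recording")
    fs = rec.fs
    n_win = window_samples(fs)
    n_buf = int(round(BUFFER_SECONDS * fs))
    spans = []
    for trial in schedule.trials:
        start = int(round(trial.offset * fs)) + n_buf
        stop = start + 2 * n_win
        if stop > rec.n_samples:
            raise ScheduleError("trial response window extends past recording end")
        spans.append((start, stop))
    if truth.is_null():
        return rec

    intensities = [f * a * d for f, a, d in schedule.grid.combinations()]
    i_min, i_max = min(intensities), max(intensities)
    log_span = np.log(i_max / i_min) if i_max > i_min else 1.0
    weights = {b.name: truth.routing_weights(b.name, rec.labels) for b in bands}
    signal = rec.signal.copy()
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 911]))
    for trial, (start, stop) in zip(schedule.trials, spans):
        intensity = trial.amplitude * trial.pulse_frequency * trial.duration
        # dose normalized on a log scale: the grid spans a 240-fold
        # intensity range, so log spacing spreads the planted dose-response
        # across trials instead of compressing it near zero
        i_norm = float(np.log(intensity / i_min) / log_span)
        perturbed: dict[str, np.ndarray] = {}
        for band in bands:
            g = truth.trial_gain(band.name, i_norm)
            C = truth.coupling[band.name]
            perturbed[band.name] = np.clip(C + g * weights[band.name], 0.0, 1.0)
        # render a 4x padded stretch and keep the middle: short circularly
        # band-limited segments have coarser spectral granularity than the
        # continuous background and bias coherence low in the narrow bands
        span = stop - start
        padded = _render_segment(
            perturbed,
            rec.n_channels,
            4 * span,
            fs,
            bands,
            truth.band_amplitude,
            truth.noise_sd,
            rng,
        )
        mid = (4 * span) // 2 - span // 2
        signal[:, start:stop] = padded[:, mid : mid + span]
    return replace(rec, signal=signal)


def saturate_stim_epochs(
    rec: Recording,
    schedule: SessionSchedule,
    level: float = 1000.0,
) -> Recording:
    """Overwrite stimulation epochs on the stimulated pair with a saturated
    square wave at the pulse frequency (opposite polarity on the two
    contacts), emulating amplifier saturation during current delivery."""
    signal = rec.signal.copy()
    fs = rec.fs
    for trial in schedule.trials:
        start = int(round(trial.onset * fs))
        stop = int(round(trial.offset * fs))
        t = np.arange(stop - start) / fs
        wave = level * np.sign(np.sin(2 * np.pi * trial.pulse_frequency * t) + 1e-12)
        for polarity, lb in zip((1.0, -1.0), trial.stim_pair):
            if lb in rec.labels:
                signal[rec.labels.index(lb), start:stop] = polarity * wave
    return replace(rec, signal=signal)


def synth_structural_network(
    n_rois: int,
    topology: str = "heavy_tailed",
    hemisphere_split: bool = True,
    seed: int = 0,
) -> StructuralNetwork:
    """Weighted structural connectome with ROI metadata.

    ``heavy_tailed`` uses a preferential-attachment graph with lognormal
    edge weights, giving a heavy-tailed strength distribution on which
    strong modal controllers are weak hubs; ``lattice`` is a ring lattice
    with 4 neighbors; ``ring`` a unit-weight cycle.  Centroids are placed
    in a 3-D box with the two hemispheres separated along x when
    ``hemisphere_split`` is set.
    """
    if n_rois < 2:
        raise InvalidConfigError("n_rois must be >= 2")
    rng = np.random.default_rng(seed)
    if topology == "heavy_tailed":
        m = min(3, n_rois - 1)
        g = nx.barabasi_albert_graph(n_rois, m, seed=int(rng.integers(2**31)))
        S = np.zeros((n_rois, n_rois))
        for i, j in g.edges():
            w = float(rng.lognormal(mean=0.0, sigma=1.0))
            S[i, j] = S[j, i] = w
    elif topology == "lattice":
        k = min(4, n_rois - 1 - (n_rois - 1) % 2)
        g = nx.watts_strogatz_graph(n_rois, max(k, 2), p=0.0)
        S = nx.to_numpy_array(g)
    elif topology == "ring":
        g = nx.cycle_graph(n_rois)
        S = nx.to_numpy_array(g)
    else:
        raise InvalidConfigError(f"unknown topology {topology!r}")

    half = n_rois // 2
    if hemisphere_split:
        hemisphere = ["L"] * half + ["R"] * (n_rois - half)
        x = np.where(
            np.arange(n_rois) < half,
            rng.uniform(-70, -5, n_rois),
            rng.uniform(5, 70, n_rois),
        )
    else:
        hemisphere = ["L"] * n_rois
        x = rng.uniform(-70, 70, n_rois)
    centroids = np.column_stack(
        [x, rng.uniform(-60, 60, n_rois), rng.uniform(-50, 60, n_rois)]
    )
    labels = [f"roi{i:04d}" for i in range(n_rois)]
    return StructuralNetwork(
        S=S, roi_labels=labels, hemisphere=hemisphere, centroids=centroids
    )


def synth_recall_features(
    n_trials: int,
    n_channels: int,
    planted_weights: np.ndarray | None = None,
    noise_sd: float = 1.0,
    seed: int = 0,
    n_bands: int = 8,
    max_retries: int = 20,
) -> tuple[np.ndarray, np.ndarray]:
    """Recall-labeled feature sets from a planted logistic model.

    Features are standard normal [n_trials x (n_channels * n_bands)];
    labels are Bernoulli(sigmoid(X @ w + noise_sd * eps)).  Draws are
    repeated (fresh labels) until both classes are present with balance in
    [0.2, 0.8]; a persistent degenerate draw raises
    :class:`GenerationError`.
    """
    if n_trials < 20:
        raise InvalidConfigError("need n_trials >= 20")
    rng = np.random.default_rng(seed)
    p_features = n_channels * n_bands
    if planted_weights is None:
        planted_weights = np.zeros(p_features)
    w = np.asarray(planted_weights, dtype=float).ravel()
    if w.size != p_features:
        raise InvalidConfigError(
            f"planted_weights length {w.size} != {p_features} features"
        )
    X = rng.standard_normal((n_trials, p_features))
    for _ in range(max_retries):
        logits = X @ w + noise_sd * rng.standard_normal(n_trials)
        y = (rng.uniform(size=n_trials) < 1.0 / (1.0 + np.exp(-logits))).astype(int)
        balance = y.mean()
        if 0.2 <= balance <= 0.8:
            return X, y
    raise GenerationError(
        f"class balance outside [0.2, 0.8] after {max_retries} retries"
    )


def synth_session(
    n_channels: int = 8,
    n_trials: int = 20,
    fs: float = DEFAULT_FS_HZ,
    seed: int = 0,
    truth: GroundTruthEffects | None = None,
    grid: ParameterGrid | None = None,
    baseline_seconds: float = 30.0,
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS,
    **truth_kwargs,
) -> tuple[Recording, SessionSchedule, GroundTruthEffects]:
    """One complete synthetic session: schedule, recording, ground truth.

    Seeds for the schedule, the baseline signal, and the effect injection
    are derived from ``seed``, so identical seeds give identical sessions.
    Extra keyword arguments go to :func:`default_ground_truth` (e.g.
    ``effect_gain={"alpha_theta": 0.25}``).
    """
    ss = np.random.SeedSequence(seed)
    s_sched, s_truth, s_sig = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(3))
    labels = [f"ch{i:02d}" for i in range(n_channels)]
    schedule = draw_trial_schedule(
        grid=grid,
        n_trials=n_trials,
        seed=s_sched,
        baseline_seconds=baseline_seconds,
        stim_pair=(labels[0], labels[1]),
    )
    if truth is None:
        truth = default_ground_truth(labels, seed=s_truth, bands=bands, **truth_kwargs)
    duration = schedule.end_time + 2.0
    rec = synth_coupled_timeseries(
        n_channels,
        fs,
        duration,
        truth.coupling,
        noise_sd=truth.noise_sd,
        seed=s_sig,
        bands=bands,
        band_amplitude=truth.band_amplitude,
        labels=labels,
    )
    rec = inject_stim_effects(rec, schedule, truth, bands=bands)
    rec = saturate_stim_epochs(rec, schedule)
    return rec, schedule, truth
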