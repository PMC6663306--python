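"""End-to-end session and cohort runs on synthetic or loaded data.

``run_session`` takes a recording + schedule (or synthesizes one), screens
and re-references it, builds per-window coherence networks, computes
stimulation and surrogate reconfiguration metrics, and returns a
:class:`SessionResult`.  ``run_cohort`` aggregates session results into the
cross-session statistics: stimulation-vs-surrogate rank-sum tests per band
and metric, one-sample t tests on within-session dose correlations,
sign tests on downstream-prediction correlations, and Spearman
correlations of session outcomes against the stimulated node's baseline
strength — each family Bonferroni-corrected over the four bands.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .coherence import DEFAULT_BANDS, BandSpec, band_adjacency
from .errors import (
    DegenerateStatisticError,
    InsufficientDataError,
)
from .memory import StateClassifier, spectral_power_features, state_probability_change
from .preproc import (
    EpochWindow,
    Recording,
    common_average_reference,
    extract_epochs,
    screen_artifact_electrodes,
    window_samples,
)
from .reconfig import (
    ReconfigRecord,
    reconfig_record,
    surrogate_baseline,
)
from .schedule import ParameterGrid, SessionSchedule
from .stats import (
    bonferroni,
    group_sign_test,
    stim_vs_baseline_test,
    within_session_spearman,
)
from .synth import GroundTruthEffects, default_ground_truth, synth_session

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "SessionResult",
    "run_session",
    "run_cohort",
    "session_band_tests",
    "PLANTED_EFFECTS",
    "planted_truth_kwargs",
]

METRICS = ("delta_mean_k", "delta_var_k", "config_similarity")

# The qualitative planted-effect structure used by the recovery suite:
# a low-frequency coupling gain and an intensity-dependent high-frequency
# suppression, both routed through the stimulation node's baseline
# coherence partners.
PLANTED_EFFECTS: dict = {
    "effect_gain": {"alpha_theta": 0.35},
    "intensity_slope": {"high_gamma": -0.7},
    "routing": {"alpha_theta": "stim_routed", "high_gamma": "stim_routed"},
}


def planted_truth_kwargs() -> dict:
    """A fresh copy of the planted-effect keyword arguments."""
    return json.loads(json.dumps(PLANTED_EFFECTS))


@dataclass
class RunConfig:
    """All pipeline defaults in one serializable object."""

    n_channels: int = 8
    n_trials: int = 20
    fs: float = 500.0
    baseline_seconds: float = 30.0
    window_seconds: float = 0.5
    buffer_seconds: float = 0.1
    time_bandwidth: float = 5.0
    n_tapers: int = 8
    screening_alpha: float = 0.05
    bonferroni_family: int = 4
    analyze_post600: bool = False
    band_names: tuple[str, ...] = tuple(b.name for b in DEFAULT_BANDS)
    band_ranges: tuple[tuple[float, float], ...] = tuple(
        (b.lo, b.hi) for b in DEFAULT_BANDS
    )

    @property
    def bands(self) -> tuple[BandSpec, ...]:
        return tuple(
            BandSpec(n, lo, hi)
            for n, (lo, hi) in zip(self.band_names, self.band_ranges)
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "band_names" in d:
            d["band_names"] = tuple(d["band_names"])
        if "band_ranges" in d:
            d["band_ranges"] = tuple(tuple(r) for r in d["band_ranges"])
        return cls(**d)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class SessionResult:
    """Everything measured in one session, per band."""

    seed: int
    config_hash: str
    labels: list[str]
    discarded_channels: list[str]
    stim_node: str
    intensities: np.ndarray
    # per band: per-trial metric arrays for stimulation and surrogate pairs
    stim_records: dict[str, list[ReconfigRecord]]
    surrogate_records: dict[str, list[ReconfigRecord]]
    baseline_strength_stim_node: dict[str, float]
    baseline_coh_to_stim: dict[str, np.ndarray]  # downstream nodes only
    downstream_rho: dict[str, tuple[float, float]]  # (rho_mean, rho_var)
    intensity_rho: dict[str, dict[str, float]]  # band -> metric -> rho
    mean_delta_p: float | None = None
    extras: dict = field(default_factory=dict)

    def trial_values(self, band: str, metric: str, group: str = "stim") -> np.ndarray:
        records = (
            self.stim_records[band] if group == "stim" else self.surrogate_records[band]
        )
        key = {
            "delta_mean_k": "delta_mean_k",
            "delta_var_k": "delta_var_k",
            "config_similarity": "config_similarity",
        }[metric]
        return np.array([getattr(r, key) for r in records])

    def session_mean(self, band: str, metric: str, group: str = "stim") -> float:
        vals = self.trial_values(band, metric, group)
        return float(np.nanmean(vals)) if vals.size else float("nan")


def _window_signals(rec: Recording, start: int, stop: int) -> np.ndarray:
    return rec.signal[:, start:stop]


def run_session(
    config: RunConfig | None = None,
    seed: int = 0,
    recording: Recording | None = None,
    schedule: SessionSchedule | None = None,
    truth: GroundTruthEffects | None = None,
    grid: ParameterGrid | None = None,
    classifier: StateClassifier | None = None,
    stim_node: str | None = None,
    truth_kwargs: dict | None = None,
) -> SessionResult:
    """Run the full single-session analysis.

    With no recording/schedule given, a synthetic session is generated from
    ``config`` and ``seed`` (``truth_kwargs`` are forwarded to the ground
    truth, e.g. ``planted_truth_kwargs()``).  Deterministic for fixed
    inputs and seed.
    """
    if config is None:
        config = RunConfig()
    bands = config.bands
    if recording is None or schedule is None:
        recording, schedule, truth = synth_session(
            n_channels=config.n_channels,
            n_trials=config.n_trials,
            fs=config.fs,
            seed=seed,
            truth=truth,
            grid=grid,
            baseline_seconds=config.baseline_seconds,
            bands=bands,
            **(truth_kwargs or {}),
        )
    if stim_node is None:
        stim_node = (
            truth.stim_node if truth is not None else schedule.trials[0].stim_pair[0]
        )

    kept, discarded, _ = screen_artifact_electrodes(
        recording, schedule, alpha=config.screening_alpha
    )
    rec = common_average_reference(recording.subset(kept))
    windows = extract_epochs(rec, schedule)
    tw, k = config.time_bandwidth, config.n_tapers

    def nets_for(w: EpochWindow):
        return band_adjacency(
            w.extract(rec), rec.fs, bands=bands, tw=tw, k=k
        )

    # baseline networks -> mean baseline adjacency per band
    base_windows = [w for w in windows if w.role == "baseline"]
    base_sum = {b.name: None for b in bands}
    for w in base_windows:
        nets = nets_for(w)
        for name, net in nets.items():
            base_sum[name] = net.A if base_sum[name] is None else base_sum[name] + net.A
    baseline_A = {name: A / len(base_windows) for name, A in base_sum.items()}

    si = rec.labels.index(stim_node)
    n_ch = rec.n_channels
    baseline_strength = {
        name: float(A[si].sum() / (n_ch - 1)) for name, A in baseline_A.items()
    }
    downstream_idx = [i for i in range(n_ch) if i != si]

    # The downstream predictor -- baseline coherence between the stimulation
    # node and each other node -- is measured on the raw (pre-reference)
    # recording.  With a small montage the stimulation node contributes a
    # non-negligible share of the common average, so referencing partials
    # out exactly the shared variance that defines its coherence partners
    # and inverts the profile; at clinical channel counts (~100) the two
    # versions coincide.
    raw_base = recording.subset(kept)
    raw_sum: dict[str, np.ndarray | None] = {b.name: None for b in bands}
    for w in base_windows:
        nets = band_adjacency(w.extract(raw_base), rec.fs, bands=bands, tw=tw, k=k)
        for name, net in nets.items():
            raw_sum[name] = net.A if raw_sum[name] is None else raw_sum[name] + net.A
    baseline_coh_to_stim = {
        name: (A / len(base_windows))[si, downstream_idx]
        for name, A in raw_sum.items()
    }

    # stimulation trial pairs (pre vs post100, optionally post600)
    by_trial: dict[int, dict[str, EpochWindow]] = {}
    for w in windows:
        if w.trial_index is not None:
            by_trial.setdefault(w.trial_index, {})[w.role] = w

    stim_records: dict[str, list[ReconfigRecord]] = {b.name: [] for b in bands}
    post600_records: dict[str, list[ReconfigRecord]] = {b.name: [] for b in bands}
    delta_p_trials: list[float] = []
    for ti in sorted(by_trial):
        roles = by_trial[ti]
        pre_nets = nets_for(roles["pre"])
        post_nets = nets_for(roles["post100"])
        for name in pre_nets:
            stim_records[name].append(
                reconfig_record(pre_nets[name], post_nets[name], trial_index=ti)
            )
        if config.analyze_post600:
            p6 = nets_for(roles["post600"])
            for name in pre_nets:
                post600_records[name].append(
                    reconfig_record(pre_nets[name], p6[name], trial_index=ti)
                )
        if classifier is not None:
            f_pre = spectral_power_features(
                roles["pre"].extract(rec), rec.fs, classifier.band_edges, tw=tw, k=k
            )
            f_post = spectral_power_features(
                roles["post100"].extract(rec), rec.fs, classifier.band_edges, tw=tw, k=k
            )
            delta_p_trials.append(
                state_probability_change(classifier, f_pre, f_post)
            )

    # surrogate pairs from the baseline span, matched geometry
    surro = surrogate_baseline(schedule, seed=seed)
    n_win = window_samples(rec.fs, config.window_seconds)
    surrogate_records: dict[str, list[ReconfigRecord]] = {b.name: [] for b in bands}
    for ti, (t_pre, t_post) in enumerate(surro.pairs):
        s_pre = int(round(t_pre * rec.fs))
        s_post = int(round(t_post * rec.fs))
        pre_nets = band_adjacency(
            _window_signals(rec, s_pre, s_pre + n_win), rec.fs, bands=bands, tw=tw, k=k
        )
        post_nets = band_adjacency(
            _window_signals(rec, s_post, s_post + n_win), rec.fs, bands=bands, tw=tw, k=k
        )
        for name in pre_nets:
            surrogate_records[name].append(
                reconfig_record(pre_nets[name], post_nets[name], trial_index=ti)
            )

    # dose-response and downstream prediction
    intensities = schedule.intensities()
    intensity_rho: dict[str, dict[str, float]] = {}
    downstream_rho: dict[str, tuple[float, float]] = {}
    for band in bands:
        name = band.name
        intensity_rho[name] = {}
        for metric in METRICS:
            vals = np.array(
                [getattr(r, _REC_ATTR[metric]) for r in stim_records[name]]
            )
            try:
                rho = within_session_spearman(intensities[: vals.size], vals)
            except (InsufficientDataError, DegenerateStatisticError):
                rho = float("nan")
            intensity_rho[name][metric] = rho
        dk = np.array([r.delta_k for r in stim_records[name]])  # [trials, nodes]
        dk_down = dk[:, downstream_idx]
        try:
            rho_mean = within_session_spearman(
                baseline_coh_to_stim[name], dk_down.mean(axis=0)
            )
            rho_var = within_session_spearman(
                baseline_coh_to_stim[name], dk_down.var(axis=0)
            )
        except (InsufficientDataError, DegenerateStatisticError):
            rho_mean = rho_var = float("nan")
        downstream_rho[name] = (rho_mean, rho_var)

    result = SessionResult(
        seed=seed,
        config_hash=config.hash(),
        labels=list(rec.labels),
        discarded_channels=discarded,
        stim_node=stim_node,
        intensities=intensities,
        stim_records=stim_records,
        surrogate_records=surrogate_records,
        baseline_strength_stim_node=baseline_strength,
        baseline_coh_to_stim=baseline_coh_to_stim,
        downstream_rho=downstream_rho,
        intensity_rho=intensity_rho,
        mean_delta_p=(float(np.mean(delta_p_trials)) if delta_p_trials else None),
    )
    if config.analyze_post600:
        result.extras["post600_records"] = post600_records
    return result


_REC_ATTR = {
    "delta_mean_k": "delta_mean_k",
    "delta_var_k": "delta_var_k",
    "config_similarity": "config_similarity",
}


def session_band_tests(
    result: SessionResult, metric: str, family: int = 4
) -> pd.DataFrame:
    """Within-session stim-vs-surrogate rank-sum per band, Bonferroni over bands."""
    rows = []
    for band in result.stim_records:
        res = stim_vs_baseline_test(
            result.trial_values(band, metric, "stim"),
            result.trial_values(band, metric, "surrogate"),
        )
        rows.append(
            {
                "band": band,
                "metric": metric,
                "U": res.U,
                "p_raw": res.p,
                "rank_correlation": res.rank_correlation,
                "n1": res.n1,
                "n2": res.n2,
            }
        )
    df = pd.DataFrame(rows)
    df["p_adj"] = bonferroni(df["p_raw"].to_numpy(), m=family)
    return df


def run_cohort(
    sessions: list[SessionResult],
    family: int = 4,
) -> pd.DataFrame:
    """Cross-session statistics over a cohort of session results.

    One row per (analysis, band, metric) with the statistic, raw and
    Bonferroni-adjusted p (family = the four bands), effect size, and n.
    Cross-session tests are skipped with a warning for cohorts of fewer
    than 3 sessions.
    """
    if not sessions:
        raise InsufficientDataError("empty cohort")
    band_names = list(sessions[0].stim_records)
    for s in sessions:
        if list(s.stim_records) != band_names:
            raise InsufficientDataError("sessions have heterogeneous band configs")
    if len(sessions) < 3:
        logger.warning(
            "cohort of %d session(s): cross-session tests skipped", len(sessions)
        )
        return pd.DataFrame()

    rows = []

    def add(analysis, band, metric, statistic, p, effect, effect_name, n):
        rows.append(
            {
                "analysis": analysis,
                "band": band,
                "metric": metric,
                "statistic": statistic,
                "p_raw": p,
                "effect": effect,
                "effect_name": effect_name,
                "n": n,
            }
        )

    # 1) stimulation vs surrogate session means
    for metric in METRICS:
        for band in band_names:
            stim = np.array([s.session_mean(band, metric, "stim") for s in sessions])
            surr = np.array(
                [s.session_mean(band, metric, "surrogate") for s in sessions]
            )
            try:
                res = stim_vs_baseline_test(stim, surr)
                add(
                    "stim_vs_surrogate", band, metric, res.U, res.p,
                    res.rank_correlation, "rank_correlation", len(sessions),
                )
            except DegenerateStatisticError:
                add("stim_vs_surrogate", band, metric, np.nan, np.nan,
                    np.nan, "rank_correlation", len(sessions))

    # 2) dose-response: t test on within-session intensity correlations
    for metric in METRICS:
        for band in band_names:
            rhos = np.array([s.intensity_rho[band][metric] for s in sessions])
            try:
                res = group_sign_test(rhos)
                add("intensity", band, metric, res.t, res.p, res.cohens_d,
                    "cohens_d", res.n)
            except (InsufficientDataError, DegenerateStatisticError):
                add("intensity", band, metric, np.nan, np.nan, np.nan,
                    "cohens_d", len(sessions))

    # 3) downstream prediction: sign test on per-session Spearman rho
    for which, idx in (("delta_k_mean", 0), ("delta_k_var", 1)):
        for band in band_names:
            rhos = np.array([s.downstream_rho[band][idx] for s in sessions])
            try:
                res = group_sign_test(rhos)
                add("downstream", band, which, res.t, res.p, res.cohens_d,
                    "cohens_d", res.n)
            except (InsufficientDataError, DegenerateStatisticError):
                add("downstream", band, which, np.nan, np.nan, np.nan,
                    "cohens_d", len(sessions))

    # 4) stimulation-location: session outcome vs stim-node baseline strength
    for metric in METRICS:
        for band in band_names:
            strength = np.array(
                [s.baseline_strength_stim_node[band] for s in sessions]
            )
            outcome = np.array(
                [s.session_mean(band, metric, "stim") for s in sessions]
            )
            try:
                rho = within_session_spearman(strength, outcome)
                # permutation-free p from the exact t approximation
                n = len(sessions)
                t = rho * np.sqrt((n - 2) / max(1e-12, 1 - rho**2))
                from scipy import stats as sps

                p = float(2 * sps.t.sf(abs(t), df=n - 2))
                add("stim_location", band, metric, rho, p, rho, "spearman_rho", n)
            except (InsufficientDataError, DegenerateStatisticError):
                add("stim_location", band, metric, np.nan, np.nan, np.nan,
                    "spearman_rho", len(sessions))

    df = pd.DataFrame(rows)
    df["p_adj"] = np.nan
    for (analysis, metric), idx in df.groupby(["analysis", "metric"]).groups.items():
        sub = df.loc[idx, "p_raw"].to_numpy()
        valid = ~np.isnan(sub)
        adj = np.full(sub.size, np.nan)
        if valid.any():
            adj[valid] = bonferroni(sub[valid], m=max(family, int(valid.sum())))
        df.loc[idx, "p_adj"] = adj
    return df
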