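"""Cohort-level statistics.

Stimulation-vs-baseline comparisons use the Wilcoxon rank-sum
(Mann-Whitney) test with a rank-biserial correlation effect size,
1 - 2U/(n1 n2).  Dose and location analyses use within-session Spearman
rank correlations summarized across sessions by a one-sample t test with
Cohen's d.  Structure-function coupling is an edge-wise Pearson r computed
separately on intra- and inter-hemispheric edges and Fisher z-transformed.
Multiple comparisons across the four frequency bands are Bonferroni
corrected (family size 4).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import (
    DegenerateStatisticError,
    InsufficientDataError,
    InvalidConfigError,
)
from .schedule import StimTrial

logger = logging.getLogger(__name__)

__all__ = [
    "RankSumResult",
    "TTestResult",
    "stim_intensity",
    "stim_vs_baseline_test",
    "within_session_spearman",
    "group_sign_test",
    "downstream_prediction",
    "structure_function_corr",
    "bonferroni",
    "FISHER_Z_CAP",
]

# atanh cap keeping perfect-correlation toys finite
FISHER_Z_CAP = float(np.arctanh(1 - 1e-15))


@dataclass
class RankSumResult:
    U: float
    p: float
    rank_correlation: float  # rank-biserial, 1 - 2U/(n1*n2)
    n1: int
    n2: int


@dataclass
class TTestResult:
    t: float
    p: float
    cohens_d: float
    n: int


def stim_intensity(trial: StimTrial) -> float:
    """Amplitude (mA) x pulse frequency (Hz) x duration (s)."""
    if trial.amplitude <= 0 or trial.pulse_frequency <= 0 or trial.duration <= 0:
        raise InvalidConfigError("intensity requires positive trial parameters")
    return trial.amplitude * trial.pulse_frequency * trial.duration


def stim_vs_baseline_test(
    stim_values: np.ndarray, surrogate_values: np.ndarray
) -> RankSumResult:
    """Rank-sum comparison of stimulation vs surrogate-baseline collections.

    Returns the Mann-Whitney U of the stimulation group, its two-sided p
    (normal approximation with tie correction), and the rank-biserial
    correlation 1 - 2U/(n1 n2): positive when stimulation values rank
    *below* baseline, in keeping with U counting baseline wins.  The sign
    convention is symmetric; the magnitude is what the effect size reports.
    """
    x = np.asarray(stim_values, dtype=float)
    y = np.asarray(surrogate_values, dtype=float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    if x.size < 2 or y.size < 2:
        raise InsufficientDataError("need >= 2 values per group")
    pooled = np.concatenate([x, y])
    if np.allclose(pooled, pooled[0]):
        raise DegenerateStatisticError("all pooled values identical")
    # "auto" gives the exact permutation null for small tie-free samples and
    # the tie-corrected normal approximation otherwise
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    u = float(res.statistic)
    rbc = 1.0 - 2.0 * u / (x.size * y.size)
    return RankSumResult(
        U=u, p=float(res.pvalue), rank_correlation=rbc, n1=x.size, n2=y.size
    )


def within_session_spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation (average ranks for ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    if x.size < 3:
        raise InsufficientDataError("need >= 3 paired observations")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise DegenerateStatisticError("constant input to Spearman correlation")
    return float(sps.spearmanr(x, y).statistic)


def group_sign_test(values: np.ndarray) -> TTestResult:
    """One-sample t test of session-level values against zero.

    Cohen's d = mean / sd (sample sd, ddof=1).
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 3:
        raise InsufficientDataError("need >= 3 sessions")
    sd = v.std(ddof=1)
    if np.isclose(sd, 0.0):
        raise DegenerateStatisticError("zero variance across sessions")
    res = sps.ttest_1samp(v, 0.0)
    return TTestResult(
        t=float(res.statistic),
        p=float(res.pvalue),
        cohens_d=float(v.mean() / sd),
        n=v.size,
    )


def downstream_prediction(
    baseline_coh_to_stim: np.ndarray,
    delta_k_mean: np.ndarray,
    delta_k_var: np.ndarray,
) -> tuple[float, float]:
    """Does baseline coherence with the stimulation node predict downstream
    strength modulation?

    Inputs are per-downstream-node vectors (the stimulation node excluded):
    baseline coherence to the stimulation node, and the across-trial mean
    and variance of |delta k|.  Returns Spearman rho against the mean and
    against the variance.
    """
    rho_mean = within_session_spearman(baseline_coh_to_stim, delta_k_mean)
    rho_var = within_session_spearman(baseline_coh_to_stim, delta_k_var)
    return rho_mean, rho_var


def structure_function_corr(
    S_sensed: np.ndarray,
    baseline_coherence: np.ndarray,
    hemisphere: list[str],
) -> dict[str, float]:
    """Edge-wise structure-function correlation, Fisher z, by hemisphere.

    Pearson r between corresponding structural and coherence edge weights
    over intra-hemispheric edges and, separately, inter-hemispheric edges;
    z = atanh(r), capped at atanh(1 - 1e-15).  A partition with fewer than
    3 edges is skipped with a warning (key absent from the result).
    """
    S = np.asarray(S_sensed, dtype=float)
    C = np.asarray(baseline_coherence, dtype=float)
    if S.shape != C.shape or S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise InvalidConfigError("matrices must be square and same shape")
    n = S.shape[0]
    if len(hemisphere) != n:
        raise InvalidConfigError("one hemisphere label per node required")
    iu, ju = np.triu_indices(n, k=1)
    same = np.array([hemisphere[i] == hemisphere[j] for i, j in zip(iu, ju)])
    out: dict[str, float] = {}
    for key, mask in (("intra", same), ("inter", ~same)):
        if mask.sum() < 3:
            logger.warning("%s-hemispheric partition has <3 edges; skipped", key)
            continue
        s_e, c_e = S[iu[mask], ju[mask]], C[iu[mask], ju[mask]]
        if np.allclose(s_e, s_e[0]) or np.allclose(c_e, c_e[0]):
            logger.warning("%s-hemispheric partition degenerate; skipped", key)
            continue
        r = float(np.corrcoef(s_e, c_e)[0, 1])
        out[key] = float(np.clip(np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15)),
                                 -FISHER_Z_CAP, FISHER_Z_CAP))
    return out


def bonferroni(pvals: np.ndarray | list[float], m: int | None = None) -> np.ndarray:
    """p_adj = min(1, p * m); default family size = number of tests."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise InvalidConfigError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise InvalidConfigError("family size smaller than number of tests")
    return np.minimum(1.0, p * m)
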