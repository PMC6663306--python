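"""Network reconfiguration metrics between window pairs.

Node scale: the signed change in mean and (population) variance of node
strengths between two windows, and the per-node magnitude of strength
change |k_i(post) - k_i(pre)|.  Edge scale: configuration similarity, the
Pearson correlation between the two windows' upper-triangle edge vectors.
Surrogate baseline trials replicate each true trial's pre/post geometry
(0.5-s windows separated by the stimulation duration plus the 100-ms
buffer) on the pre-session baseline, sampled with replacement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .coherence import CoherenceNetwork
from .errors import (
    AlignmentError,
    DegenerateStatisticError,
    InsufficientDataError,
)
from .preproc import BUFFER_SECONDS, WINDOW_SECONDS
from .schedule import SessionSchedule

logger = logging.getLogger(__name__)

__all__ = [
    "ReconfigRecord",
    "SurrogateTrialSet",
    "node_strengths",
    "delta_strength_stats",
    "delta_node_magnitude",
    "configuration_similarity",
    "reconfig_record",
    "surrogate_baseline",
]


@dataclass
class ReconfigRecord:
    """Reconfiguration metrics of one window pair in one band."""

    trial_index: int | None
    band: str
    delta_mean_k: float
    delta_var_k: float
    delta_k: np.ndarray  # per-node |change in strength|, >= 0
    config_similarity: float  # NaN when undefined (zero-variance vector)


@dataclass
class SurrogateTrialSet:
    """Baseline window pairs matched to the true trials' geometry.

    ``pairs[i]`` holds the start times (seconds) of the pre and post
    windows of the surrogate matched to true trial i; the separation
    between pre-window end and post-window start equals that trial's
    stimulation duration plus the post-stimulation buffer.
    """

    pairs: list[tuple[float, float]]
    seed: int

    @property
    def count(self) -> int:
        return len(self.pairs)


def _as_matrix(net: CoherenceNetwork | np.ndarray) -> np.ndarray:
    return net.A if isinstance(net, CoherenceNetwork) else np.asarray(net, float)


def node_strengths(net: CoherenceNetwork | np.ndarray) -> np.ndarray:
    """k_i = (1/(N-1)) sum_j A_ij."""
    A = _as_matrix(net)
    n = A.shape[0]
    if n < 2:
        raise AlignmentError("strength needs >= 2 nodes")
    return A.sum(axis=1) / (n - 1)


def _check_same_nodes(pre: np.ndarray, post: np.ndarray) -> None:
    if pre.shape != post.shape:
        raise AlignmentError(
            f"window networks have different node sets: {pre.shape} vs {post.shape}"
        )


def delta_strength_stats(
    pre: CoherenceNetwork | np.ndarray, post: CoherenceNetwork | np.ndarray
) -> tuple[float, float]:
    """(mean, population variance) of node strengths, post minus pre."""
    A_pre, A_post = _as_matrix(pre), _as_matrix(post)
    _check_same_nodes(A_pre, A_post)
    k_pre, k_post = node_strengths(A_pre), node_strengths(A_post)
    return (
        float(k_post.mean() - k_pre.mean()),
        float(k_post.var() - k_pre.var()),
    )


def delta_node_magnitude(
    pre: CoherenceNetwork | np.ndarray, post: CoherenceNetwork | np.ndarray
) -> np.ndarray:
    """|k_i(post) - k_i(pre)| per node."""
    A_pre, A_post = _as_matrix(pre), _as_matrix(post)
    _check_same_nodes(A_pre, A_post)
    return np.abs(node_strengths(A_post) - node_strengths(A_pre))


def configuration_similarity(
    pre: CoherenceNetwork | np.ndarray, post: CoherenceNetwork | np.ndarray
) -> float:
    """Pearson correlation between the two configuration vectors.

    Raises :class:`DegenerateStatisticError` when either vector has zero
    variance; callers aggregating over trials catch this, log, and exclude
    the pair (see :func:`reconfig_record`).
    """
    from .coherence import configuration_vector

    a = (
        pre.config
        if isinstance(pre, CoherenceNetwork)
        else configuration_vector(np.asarray(pre, float))
    )
    b = (
        post.config
        if isinstance(post, CoherenceNetwork)
        else configuration_vector(np.asarray(post, float))
    )
    if a.size != b.size:
        raise AlignmentError("configuration vectors differ in length")
    if a.size < 3:
        raise InsufficientDataError("need >= 3 edges for configuration similarity")
    if np.isclose(a.std(), 0.0) or np.isclose(b.std(), 0.0):
        raise DegenerateStatisticError("zero-variance configuration vector")
    return float(np.corrcoef(a, b)[0, 1])


def reconfig_record(
    pre: CoherenceNetwork,
    post: CoherenceNetwork,
    trial_index: int | None = None,
) -> ReconfigRecord:
    """All reconfiguration metrics for one window pair in one band."""
    dmean, dvar = delta_strength_stats(pre, post)
    dk = delta_node_magnitude(pre, post)
    try:
        sim = configuration_similarity(pre, post)
    except DegenerateStatisticError:
        logger.warning(
            "undefined configuration similarity (trial %s, band %s); "
            "recorded as NaN and excluded from session averages",
            trial_index,
            pre.band.name,
        )
        sim = float("nan")
    return ReconfigRecord(
        trial_index=trial_index,
        band=pre.band.name,
        delta_mean_k=dmean,
        delta_var_k=dvar,
        delta_k=dk,
        config_similarity=sim,
    )


def surrogate_baseline(
    schedule: SessionSchedule,
    seed: int = 0,
    buffer_seconds: float = BUFFER_SECONDS,
    window_seconds: float = WINDOW_SECONDS,
) -> SurrogateTrialSet:
    """Sample one baseline window pair per true trial, with replacement.

    Each surrogate mirrors its trial's pre/post100 layout: a pre window of
    ``window_seconds`` followed, after a gap of stimulation duration +
    ``buffer_seconds``, by a post window of the same length.  Start times
    are uniform over the feasible portion of the baseline span.
    """
    rng = np.random.default_rng(seed)
    b0, b1 = schedule.baseline_span
    pairs: list[tuple[float, float]] = []
    for trial in schedule.trials:
        gap = trial.duration + buffer_seconds
        layout = 2 * window_seconds + gap
        if b1 - b0 < layout:
            raise InsufficientDataError(
                f"baseline span {b1 - b0:.2f}s shorter than surrogate layout "
                f"{layout:.2f}s"
            )
        start = float(rng.uniform(b0, b1 - layout))
        pairs.append((start, start + window_seconds + gap))
    return SurrogateTrialSet(pairs=pairs, seed=seed)
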