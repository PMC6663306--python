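"""Stimulation trial schedules and the randomized parameter grid.

Each trial delivers a biphasic pulse train whose pulse frequency, amplitude
and duration are drawn independently and uniformly from fixed lists —
5 frequencies x 3 amplitudes x 3 durations = 45 combinations — with an
inter-stimulation interval drawn uniformly from 2.75-3.25 s.  The amplitude
grid defaults to {1, 2, 3} mA: the clinical protocol uses the
subject-specific maximum safe amplitude minus {0, 0.5, 1} mA (0.125-3.0 mA
across subjects), so a fixed three-level grid stands in for it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .errors import InvalidConfigError

__all__ = [
    "PULSE_FREQUENCIES_HZ",
    "AMPLITUDES_MA",
    "DURATIONS_S",
    "ISI_RANGE_S",
    "PULSE_WIDTH_US",
    "ParameterGrid",
    "StimTrial",
    "SessionSchedule",
    "draw_trial_schedule",
]

PULSE_FREQUENCIES_HZ = (10.0, 25.0, 50.0, 100.0, 200.0)
AMPLITUDES_MA = (1.0, 2.0, 3.0)
DURATIONS_S = (0.25, 0.5, 1.0)
ISI_RANGE_S = (2.75, 3.25)
PULSE_WIDTH_US = 600.0

# mean trials per clinical mapping session (protocol reference value):
# sessions oversample the 45-combination grid by more than 36x
MEAN_TRIALS_PER_SESSION = 1655.0


@dataclass(frozen=True)
class ParameterGrid:
    """The per-trial sampling lists for the stimulation parameters."""

    pulse_frequencies: tuple[float, ...] = PULSE_FREQUENCIES_HZ
    amplitudes: tuple[float, ...] = AMPLITUDES_MA
    durations: tuple[float, ...] = DURATIONS_S

    def __post_init__(self) -> None:
        for name in ("pulse_frequencies", "amplitudes", "durations"):
            vals = getattr(self, name)
            if len(vals) == 0:
                raise InvalidConfigError(f"parameter list '{name}' is empty")
            if any(v <= 0 for v in vals):
                raise InvalidConfigError(f"parameter list '{name}' must be positive")

    @property
    def n_combinations(self) -> int:
        return (
            len(self.pulse_frequencies) * len(self.amplitudes) * len(self.durations)
        )

    def combinations(self) -> list[tuple[float, float, float]]:
        """All (pulse_frequency, amplitude, duration) triples."""
        return list(
            product(self.pulse_frequencies, self.amplitudes, self.durations)
        )


@dataclass(frozen=True)
class StimTrial:
    """One stimulation trial.

    ``isi`` is the interval from the previous trial's stimulation offset (or
    from the baseline end, for the first trial) to this trial's onset.
    """

    onset: float
    duration: float
    amplitude: float
    pulse_frequency: float
    stim_pair: tuple[str, str]
    isi: float
    pulse_width_us: float = PULSE_WIDTH_US

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise InvalidConfigError("trial onset must be >= 0")
        if self.duration <= 0 or self.amplitude <= 0 or self.pulse_frequency <= 0:
            raise InvalidConfigError("trial parameters must be positive")

    @property
    def offset(self) -> float:
        return self.onset + self.duration


@dataclass
class SessionSchedule:
    """Baseline span plus the ordered stimulation trials of one session."""

    baseline_span: tuple[float, float]
    trials: list[StimTrial]
    grid: ParameterGrid = field(default_factory=ParameterGrid)

    def __post_init__(self) -> None:
        if self.baseline_span[1] <= self.baseline_span[0]:
            raise InvalidConfigError("baseline span must have positive length")
        prev_offset = None
        for trial in self.trials:
            if trial.onset < self.baseline_span[1]:
                raise InvalidConfigError("baseline must precede every trial")
            if prev_offset is not None and trial.onset < prev_offset:
                raise InvalidConfigError("trials overlap or are out of order")
            prev_offset = trial.offset

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def end_time(self) -> float:
        if not self.trials:
            return self.baseline_span[1]
        return self.trials[-1].offset

    def intensities(self) -> np.ndarray:
        """Per-trial intensity: amplitude x pulse frequency x duration."""
        return np.array(
            [t.amplitude * t.pulse_frequency * t.duration for t in self.trials]
        )


def draw_trial_schedule(
    grid: ParameterGrid | None = None,
    n_trials: int = 100,
    isi_range: tuple[float, float] = ISI_RANGE_S,
    seed: int | np.random.Generator = 0,
    baseline_seconds: float = 30.0,
    stim_pair: tuple[str, str] = ("ch00", "ch01"),
) -> SessionSchedule:
    """Draw a session schedule with i.i.d. uniform parameter choices.

    Each trial's pulse frequency, amplitude and duration are drawn uniformly
    and independently from the grid lists; the inter-stimulation interval is
    uniform over ``isi_range``.  Onsets are laid out sequentially: the first
    trial begins one ISI after the 30-s baseline ends, and each subsequent
    trial begins one ISI after the previous stimulation offset.
    """
    if grid is None:
        grid = ParameterGrid()
    if n_trials < 0:
        raise InvalidConfigError("n_trials must be >= 0")
    if isi_range[0] <= 0 or isi_range[1] < isi_range[0]:
        raise InvalidConfigError("invalid ISI range")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )

    trials: list[StimTrial] = []
    t_prev_offset = baseline_seconds
    for _ in range(n_trials):
        freq = float(rng.choice(grid.pulse_frequencies))
        amp = float(rng.choice(grid.amplitudes))
        dur = float(rng.choice(grid.durations))
        isi = float(rng.uniform(*isi_range))
        onset = t_prev_offset + isi
        trial = StimTrial(
            onset=onset,
            duration=dur,
            amplitude=amp,
            pulse_frequency=freq,
            stim_pair=stim_pair,
            isi=isi,
        )
        trials.append(trial)
        t_prev_offset = trial.offset
    return SessionSchedule(
        baseline_span=(0.0, baseline_seconds), trials=trials, grid=grid
    )
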