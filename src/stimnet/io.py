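"""Readers and writers for the pipeline's on-disk formats.

Recordings are HDF5 (``/signal`` [channels x samples], ``/fs``,
``/labels``); schedules, connectomes, ROI tables, epoch tables and result
tables are TSV with header rows; classifiers and run summaries are JSON.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .control import StructuralNetwork
from .preproc import EpochWindow, Recording
from .reconfig import ReconfigRecord
from .schedule import ParameterGrid, SessionSchedule, StimTrial

__all__ = [
    "write_recording_h5",
    "read_recording_h5",
    "read_recording_edf",
    "write_schedule_tsv",
    "read_schedule_tsv",
    "write_structural_tsv",
    "read_structural_tsv",
    "write_epochs_tsv",
    "write_records_tsv",
    "write_networks_h5",
]


def write_recording_h5(path: str | Path, rec: Recording) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("signal", data=rec.signal)
        f.create_dataset("fs", data=float(rec.fs))
        f.create_dataset(
            "labels", data=np.array(rec.labels, dtype=h5py.string_dtype())
        )
        f.attrs["reference"] = rec.reference


def read_recording_h5(path: str | Path) -> Recording:
    with h5py.File(path, "r") as f:
        return Recording(
            signal=f["signal"][()],
            fs=float(f["fs"][()]),
            labels=[s.decode() if isinstance(s, bytes) else s for s in f["labels"][()]],
            reference=str(f.attrs.get("reference", "raw")),
        )


def read_recording_edf(path: str | Path) -> Recording:
    """Read an EDF recording via MNE (optional dependency)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("EDF input requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return Recording(
        signal=raw.get_data() * 1e6,  # volts -> microvolts
        fs=float(raw.info["sfreq"]),
        labels=list(raw.ch_names),
        reference="raw",
    )


_SCHEDULE_COLS = [
    "onset_s",
    "duration_s",
    "amplitude_mA",
    "pulse_hz",
    "stim_anode",
    "stim_cathode",
]


def write_schedule_tsv(path: str | Path, schedule: SessionSchedule) -> None:
    rows = [
        {
            "onset_s": t.onset,
            "duration_s": t.duration,
            "amplitude_mA": t.amplitude,
            "pulse_hz": t.pulse_frequency,
            "stim_anode": t.stim_pair[0],
            "stim_cathode": t.stim_pair[1],
        }
        for t in schedule.trials
    ]
    df = pd.DataFrame(rows, columns=_SCHEDULE_COLS)
    df.to_csv(path, sep="\t", index=False)


def read_schedule_tsv(
    path: str | Path,
    baseline_span: tuple[float, float] = (0.0, 30.0),
    grid: ParameterGrid | None = None,
) -> SessionSchedule:
    """Read a schedule TSV; ISIs are reconstructed from consecutive onsets."""
    df = pd.read_csv(path, sep="\t")
    trials: list[StimTrial] = []
    prev_offset = baseline_span[1]
    for row in df.itertuples(index=False):
        isi = float(row.onset_s) - prev_offset
        trials.append(
            StimTrial(
                onset=float(row.onset_s),
                duration=float(row.duration_s),
                amplitude=float(row.amplitude_mA),
                pulse_frequency=float(row.pulse_hz),
                stim_pair=(str(row.stim_anode), str(row.stim_cathode)),
                isi=isi,
            )
        )
        prev_offset = trials[-1].offset
    kwargs = {"grid": grid} if grid is not None else {}
    return SessionSchedule(baseline_span=baseline_span, trials=trials, **kwargs)


def write_structural_tsv(
    matrix_path: str | Path, roi_path: str | Path, net: StructuralNetwork
) -> None:
    pd.DataFrame(net.S, columns=net.roi_labels).to_csv(
        matrix_path, sep="\t", index=False
    )
    pd.DataFrame(
        {
            "label": net.roi_labels,
            "hemisphere": net.hemisphere,
            "x": net.centroids[:, 0],
            "y": net.centroids[:, 1],
            "z": net.centroids[:, 2],
        }
    ).to_csv(roi_path, sep="\t", index=False)


def read_structural_tsv(
    matrix_path: str | Path, roi_path: str | Path
) -> StructuralNetwork:
    S = pd.read_csv(matrix_path, sep="\t").to_numpy(dtype=float)
    roi = pd.read_csv(roi_path, sep="\t")
    return StructuralNetwork(
        S=S,
        roi_labels=[str(lb) for lb in roi["label"]],
        hemisphere=[str(h) for h in roi["hemisphere"]],
        centroids=roi[["x", "y", "z"]].to_numpy(dtype=float),
    )


def write_epochs_tsv(path: str | Path, windows: list[EpochWindow]) -> None:
    pd.DataFrame(
        {
            "trial_index": [w.trial_index for w in windows],
            "role": [w.role for w in windows],
            "start_sample": [w.start for w in windows],
            "end_sample": [w.stop for w in windows],
        }
    ).to_csv(path, sep="\t", index=False)


def write_records_tsv(path: str | Path, records: list[ReconfigRecord]) -> None:
    pd.DataFrame(
        {
            "trial": [r.trial_index for r in records],
            "band": [r.band for r in records],
            "delta_mean_k": [r.delta_mean_k for r in records],
            "delta_var_k": [r.delta_var_k for r in records],
            "config_sim": [r.config_similarity for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


def write_networks_h5(
    path: str | Path, networks: dict[str, dict[str, np.ndarray]]
) -> None:
    """``networks[band][window_id]`` -> dataset /coherence/{band}/{window_id}."""
    with h5py.File(path, "w") as f:
        grp = f.create_group("coherence")
        for band, by_window in networks.items():
            bg = grp.create_group(band)
            for window_id, A in by_window.items():
                bg.create_dataset(str(window_id), data=np.asarray(A))
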