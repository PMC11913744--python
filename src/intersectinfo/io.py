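"""Session container I/O.

One session = an HDF5 container with datasets ``/F``, ``/Fneu``, ``/spikes``
(and, once preprocessing has run, ``/dff``) plus ``frame_rate`` and ``seed``
attributes, alongside a trial-table CSV with the fixed column set
``trial_id, stimulus, choice, outcome, onset_frame, offset_frame, excluded``.
Real recordings coerced to this schema can be fed through the same pipeline.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .synthetic import (FluorescenceMatrix, OUTCOME_MAP, TRIAL_COLUMNS)

__all__ = [
    "write_session", "read_session", "write_trials", "read_trials",
    "validate_trials",
]

_VALID_STIMULI = {"Go", "No-go"} | {str(k) for k in range(1, 7)}
_VALID_CHOICES = {"Lick", "No-lick"}
_VALID_OUTCOMES = {"Hit", "FA", "CR", "Miss"}


def validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Schema check for a trial table; raises naming the offending row/field."""
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    for col, valid in [("stimulus", _VALID_STIMULI),
                       ("choice", _VALID_CHOICES),
                       ("outcome", _VALID_OUTCOMES)]:
        bad = ~trials[col].astype(str).isin(valid)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"invalid {col} label {trials[col].iloc[row]!r} at row {row}")
    if (trials["onset_frame"] >= trials["offset_frame"]).any():
        row = int((trials["onset_frame"] >= trials["offset_frame"]).idxmax())
        raise ValueError(f"onset_frame >= offset_frame at row {row}")
    go_nogo = trials["stimulus"].isin({"Go", "No-go"})
    if go_nogo.all():
        expected = [OUTCOME_MAP[(s, c)] for s, c in
                    zip(trials["stimulus"], trials["choice"])]
        bad = trials["outcome"].to_numpy() != np.asarray(expected)
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"outcome inconsistent with (stimulus, choice) at row {row}")
    return trials


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    validate_trials(trials)
    trials.loc[:, TRIAL_COLUMNS].to_csv(path, index=False)


def read_trials(path: str | Path) -> pd.DataFrame:
    trials = pd.read_csv(path)
    trials["excluded"] = trials["excluded"].astype(bool)
    return validate_trials(trials)


def write_session(path: str | Path, fluor: FluorescenceMatrix,
                  spikes: np.ndarray | None = None, seed: int = 0,
                  dff: np.ndarray | None = None) -> None:
    with h5py.File(path, "w") as h5:
        h5.create_dataset("F", data=fluor.F)
        h5.create_dataset("Fneu", data=fluor.Fneu)
        if spikes is not None:
            h5.create_dataset("spikes", data=spikes)
        if dff is not None:
            h5.create_dataset("dff", data=dff)
        h5.attrs["frame_rate"] = fluor.frame_rate
        h5.attrs["seed"] = seed


def read_session(path: str | Path
                 ) -> tuple[FluorescenceMatrix, np.ndarray | None, dict]:
    """Returns (fluorescence, spikes-or-None, attrs dict incl. any /dff)."""
    with h5py.File(path, "r") as h5:
        for name in ("F", "Fneu"):
            if name not in h5:
                raise ValueError(f"session file missing dataset /{name}")
        fluor = FluorescenceMatrix(F=h5["F"][()], Fneu=h5["Fneu"][()],
                                   frame_rate=float(h5.attrs["frame_rate"]))
        spikes = h5["spikes"][()] if "spikes" in h5 else None
        attrs = dict(h5.attrs)
        if "dff" in h5:
            attrs["dff"] = h5["dff"][()]
    return fluor, spikes, attrs
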