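"""Epoched multichannel data container and its on-disk HDF5 format.

The :class:`EpochSet` is the in-memory currency of the whole pipeline:
a ``trials x channels x samples`` array with a time axis in seconds
relative to stimulus onset, channel names and roles, and a per-trial
metadata table (stimulus class, attention side, cue validity, stimulus
duration, reaction time, correctness, target onset).

Channel roles distinguish three kinds of signal:

``neural``
    sensor channels that enter the decoder as features,
``modulator``
    designated phase-providing channels (the analogue of a virtual
    channel or anatomical parcel time course),
``gaze``
    eye-tracker channels used only by the gaze-leakage control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "phasedecode-epochs-1"

VALID_ROLES = ("neural", "modulator", "gaze")

#: trial-table columns the simulator writes and select_trials understands
STANDARD_TRIAL_COLUMNS = (
    "orientation",      # "CW" | "CCW"  (the binary stimulus class)
    "attend",           # "left" | "right"
    "cue_valid",        # bool
    "stim_duration",    # seconds, stimulus onset to stimulus change
    "rt",               # seconds
    "correct",          # bool
    "target_onset",     # seconds relative to stimulus onset
)


class SchemaError(ValueError):
    """The on-disk container declares an unsupported schema version."""


class ShapeError(ValueError):
    """Container fields are mutually inconsistent in shape."""


@dataclass
class EpochSet:
    """Epoched multichannel time series with per-trial metadata."""

    data: np.ndarray                # (n_trials, n_channels, n_samples)
    times: np.ndarray               # (n_samples,) seconds
    fs: float                       # Hz
    channel_names: list[str]
    channel_roles: list[str]
    trial_table: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.times = np.asarray(self.times, dtype=np.float64)
        if self.data.ndim != 3:
            raise ShapeError("data must be trials x channels x samples")
        n_trials, n_channels, n_samples = self.data.shape
        if self.times.shape != (n_samples,):
            raise ShapeError(
                f"times has length {self.times.size}, data has {n_samples} samples"
            )
        if len(self.channel_names) != n_channels:
            raise ShapeError(
                f"{len(self.channel_names)} channel names for {n_channels} channels"
            )
        if len(self.channel_roles) != n_channels:
            raise ShapeError(
                f"{len(self.channel_roles)} channel roles for {n_channels} channels"
            )
        for role in self.channel_roles:
            if role not in VALID_ROLES:
                raise ValueError(f"unknown channel role {role!r}")
        if len(self.trial_table) != n_trials:
            raise ShapeError(
                f"trial table has {len(self.trial_table)} rows, data has "
                f"{n_trials} trials"
            )
        if n_samples >= 2:
            dt = np.diff(self.times)
            if not np.allclose(dt, 1.0 / self.fs, rtol=1e-6, atol=1e-9):
                raise ShapeError("times vector inconsistent with sampling rate fs")
        self.trial_table = self.trial_table.reset_index(drop=True)

    # -- basic geometry ----------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    # -- channel lookup ----------------------------------------------------
    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"no channel named {name!r}") from None

    def channels_with_role(self, role: str) -> np.ndarray:
        """Indices of all channels carrying ``role``."""
        if role not in VALID_ROLES:
            raise ValueError(f"unknown channel role {role!r}")
        return np.array(
            [i for i, r in enumerate(self.channel_roles) if r == role], dtype=int
        )

    def get_channel(self, name: str) -> np.ndarray:
        """Single-channel view, shape (n_trials, n_samples)."""
        return self.data[:, self.channel_index(name), :]

    def subset_trials(self, rows: np.ndarray) -> "EpochSet":
        rows = np.asarray(rows)
        if rows.dtype == bool:
            rows = np.flatnonzero(rows)
        return EpochSet(
            data=self.data[rows],
            times=self.times.copy(),
            fs=self.fs,
            channel_names=list(self.channel_names),
            channel_roles=list(self.channel_roles),
            trial_table=self.trial_table.iloc[rows].reset_index(drop=True),
        )


# ---------------------------------------------------------------------------
# HDF5 round trip
# ---------------------------------------------------------------------------

_STR = h5py.string_dtype(encoding="utf-8")


def write_epochs(epochs: EpochSet, path) -> None:
    """Write an :class:`EpochSet` to ``path`` (HDF5, schema above)."""
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["fs"] = float(epochs.fs)
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("times", data=epochs.times)
        ch = f.create_group("channels")
        ch.create_dataset("names", data=epochs.channel_names, dtype=_STR)
        ch.create_dataset("roles", data=epochs.channel_roles, dtype=_STR)
        tr = f.create_group("trials")
        tr.attrs["columns"] = list(epochs.trial_table.columns)
        for col in epochs.trial_table.columns:
            values = epochs.trial_table[col].to_numpy()
            if values.dtype == object or values.dtype.kind in "US":
                tr.create_dataset(col, data=[str(v) for v in values], dtype=_STR)
            else:
                tr.create_dataset(col, data=values)


def read_epochs(path) -> EpochSet:
    """Read an :class:`EpochSet`; raises :class:`SchemaError` /
    :class:`ShapeError` with distinct messages on malformed files."""
    with h5py.File(path, "r") as f:
        version = f.attrs.get("schema_version")
        if version != SCHEMA_VERSION:
            raise SchemaError(
                f"unsupported epochs schema {version!r}; expected {SCHEMA_VERSION!r}"
            )
        data = f["data"][()]
        times = f["times"][()]
        fs = float(f.attrs["fs"])
        names = [s.decode() if isinstance(s, bytes) else str(s)
                 for s in f["channels/names"][()]]
        roles = [s.decode() if isinstance(s, bytes) else str(s)
                 for s in f["channels/roles"][()]]
        columns = list(f["trials"].attrs["columns"])
        table = {}
        for col in columns:
            values = f[f"trials/{col}"][()]
            if values.dtype.kind in "OS":
                values = np.array(
                    [s.decode() if isinstance(s, bytes) else str(s) for s in values]
                )
            table[col] = values
    n_trials = data.shape[0] if data.ndim == 3 else -1
    for col, values in table.items():
        if len(values) != n_trials:
            raise ShapeError(
                f"trial column {col!r} has {len(values)} rows, data has "
                f"{n_trials} trials"
            )
    return EpochSet(
        data=data,
        times=times,
        fs=fs,
        channel_names=names,
        channel_roles=roles,
        trial_table=pd.DataFrame(table),
    )


# ---------------------------------------------------------------------------
# Trial selection
# ---------------------------------------------------------------------------

def select_trials(
    epochs: EpochSet,
    rules: Mapping[str, object] | None = None,
    return_report: bool = False,
):
    """Subset trials by equality rules on trial-table columns.

    ``rules`` maps column name -> required value.  The default reproduces
    the standard selection: validly cued, correctly answered trials with a
    1.0 s stimulus duration.  Dropped counts are logged per rule (applied
    sequentially, so counts are marginal).
    """
    if rules is None:
        rules = {"cue_valid": True, "correct": True, "stim_duration": 1.0}
    keep = np.ones(epochs.n_trials, dtype=bool)
    report: dict[str, int] = {}
    for col, value in rules.items():
        if col not in epochs.trial_table.columns:
            raise KeyError(f"trial table has no column {col!r}")
        colvals = epochs.trial_table[col].to_numpy()
        if isinstance(value, float):
            match = np.isclose(colvals.astype(float), value)
        else:
            match = colvals == value
        dropped = int(np.sum(keep & ~match))
        report[col] = dropped
        keep &= match
        logger.info("select_trials: rule %s==%r dropped %d trials", col, value, dropped)
    if not keep.any():
        raise ValueError("trial selection left zero trials")
    out = epochs.subset_trials(keep)
    if return_report:
        return out, report
    return out
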