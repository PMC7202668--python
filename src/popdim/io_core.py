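"""Containers and I/O for trial-structured population spike counts.

A recording session is a spike-count tensor (neurons x trials x time bins)
plus a trial table describing the two-armed bandit task: block identity,
condition (What = image-based reward, Where = direction-based reward),
acquisition/reversal phase, the chosen image and saccade direction, and the
reward outcome.  Every analysis stage in :mod:`popdim` consumes this pair.

Time is measured in milliseconds relative to the alignment event (cue onset
for the choice analyses, reward delivery for the outcome analyses), with
half-open count windows ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

SCHEMA_VERSION = 1

CONDITIONS = ("What", "Where")
PHASES = ("acquisition", "reversal")

#: Required columns of the trial table, in canonical order.
TRIAL_COLUMNS = (
    "block_id",
    "condition",
    "phase",
    "trial_in_block",
    "trial_in_phase",
    "chosen_image",
    "chosen_direction",
    "reward",
    "reversal_trial",
)

_INT_COLUMNS = (
    "block_id",
    "trial_in_block",
    "trial_in_phase",
    "chosen_image",
    "chosen_direction",
    "reward",
    "reversal_trial",
)


class SessionFormatError(ValueError):
    """Raised when a persisted session does not match the expected schema."""


class InvalidWindowError(ValueError):
    """Raised for empty, reversed or overlapping count windows."""


@dataclass
class SessionData:
    """Spike counts plus trial table for one recording session.

    Parameters
    ----------
    counts
        Array ``(n_neurons, n_trials, n_bins)`` of nonnegative spike counts.
        Counts are integers under a Poisson observation model; the Gaussian
        surrogate model used for closed-form checks may produce nonnegative
        floats.
    trials
        Table with one row per trial and the columns in :data:`TRIAL_COLUMNS`.
        ``trial_in_block``/``trial_in_phase`` are 1-based, matching task
        bookkeeping; array indexing throughout the package is 0-based.
    bin_edges
        Array ``(n_bins, 2)`` of ``[start, end)`` window edges in ms relative
        to the alignment event.
    session_id
        Free-form label.
    """

    counts: np.ndarray
    trials: pd.DataFrame
    bin_edges: np.ndarray
    session_id: str = "session"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.validate()

    # -- basic geometry ----------------------------------------------------
    @property
    def n_neurons(self) -> int:
        return self.counts.shape[0]

    @property
    def n_trials(self) -> int:
        return self.counts.shape[1]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[2]

    @property
    def block_ids(self) -> np.ndarray:
        return np.unique(self.trials["block_id"].to_numpy())

    def validate(self) -> None:
        if self.counts.ndim != 3:
            raise ValueError("counts must be (n_neurons, n_trials, n_bins)")
        if np.any(self.counts < 0):
            raise ValueError("spike counts must be nonnegative")
        if self.bin_edges.shape != (self.counts.shape[2], 2):
            raise ValueError("bin_edges must be (n_bins, 2)")
        if np.any(self.bin_edges[:, 1] <= self.bin_edges[:, 0]):
            raise InvalidWindowError("bin widths must be positive")
        missing = [c for c in TRIAL_COLUMNS if c not in self.trials.columns]
        if missing:
            raise ValueError(f"trial table missing columns: {missing}")
        if len(self.trials) != self.counts.shape[1]:
            raise ValueError("trial table length does not match counts")
        if len(self.trials) == 0:
            return
        t = self.trials
        if not t["condition"].isin(CONDITIONS).all():
            raise ValueError("condition must be 'What' or 'Where'")
        if not t["phase"].isin(PHASES).all():
            raise ValueError("phase must be 'acquisition' or 'reversal'")
        for col in ("chosen_image", "chosen_direction"):
            if not t[col].isin((1, 2)).all():
                raise ValueError(f"{col} must be 1 or 2")
        if not t["reward"].isin((0, 1)).all():
            raise ValueError("reward must be 0 or 1")
        # phase is 'reversal' exactly from the reversal trial onward
        is_rev = t["trial_in_block"].to_numpy() >= t["reversal_trial"].to_numpy()
        if not np.array_equal(is_rev, (t["phase"] == "reversal").to_numpy()):
            raise ValueError("phase labels inconsistent with reversal_trial")
        # one condition per block
        per_block = t.groupby("block_id")["condition"].nunique()
        if (per_block > 1).any():
            raise ValueError("blocks must have a single condition")


def class_labels(trials: pd.DataFrame, mode: str = "choice") -> np.ndarray:
    """Binary class label (1 or 2) for each trial.

    ``mode='choice'`` resolves to the chosen image in What blocks and the
    chosen direction in Where blocks — the quantity the animal is learning
    about.  ``mode='reward'`` relabels trials by outcome (1 = rewarded,
    2 = unrewarded), which turns every choice analysis into its
    reward-locked analogue.
    """
    if mode == "choice":
        return np.where(
            trials["condition"].to_numpy() == "What",
            trials["chosen_image"].to_numpy(),
            trials["chosen_direction"].to_numpy(),
        ).astype(np.int64)
    if mode == "reward":
        return (2 - trials["reward"].to_numpy()).astype(np.int64)
    raise ValueError(f"unknown label mode {mode!r}")


def bin_spikes(
    spike_times: Sequence[np.ndarray],
    events: np.ndarray,
    windows: Sequence[tuple[float, float]],
) -> np.ndarray:
    """Count spikes of each neuron in half-open windows around each event.

    Parameters
    ----------
    spike_times
        Per-neuron arrays of spike times (ms, session clock).
    events
        Per-trial alignment times (ms, same clock), e.g. cue onsets.
    windows
        ``[start, end)`` offsets in ms relative to the event.  Windows must
        be non-overlapping with positive width.

    Returns
    -------
    ``(n_neurons, n_trials, n_windows)`` integer array.
    """
    wins = np.asarray(windows, dtype=float)
    if wins.ndim != 2 or wins.shape[1] != 2:
        raise InvalidWindowError("windows must be a list of (start, end) pairs")
    if np.any(wins[:, 1] <= wins[:, 0]):
        raise InvalidWindowError("window end must exceed start")
    order = np.argsort(wins[:, 0])
    if np.any(wins[order[1:], 0] < wins[order[:-1], 1]):
        raise InvalidWindowError("windows must not overlap")

    events = np.asarray(events, dtype=float)
    # absolute window bounds: (n_trials, n_windows, 2)
    bounds = events[:, None, None] + wins[None, :, :]
    counts = np.zeros((len(spike_times), len(events), len(wins)), dtype=np.int64)
    for j, st in enumerate(spike_times):
        st = np.sort(np.asarray(st, dtype=float))
        lo = np.searchsorted(st, bounds[:, :, 0], side="left")
        hi = np.searchsorted(st, bounds[:, :, 1], side="left")
        counts[j] = hi - lo
    return counts


def select_trials(
    session: SessionData,
    condition: str | None = None,
    phase: str | None = None,
    min_trial_in_phase: int | None = None,
    choice: int | None = None,
    block: int | None = None,
    reward: int | None = None,
) -> np.ndarray:
    """Indices (0-based, original order) of trials matching all filters.

    ``min_trial_in_phase=5`` reproduces the removal of the first four trials
    of each phase, which are treated as learning trials and excluded from
    subspace estimation.
    """
    t = session.trials
    mask = np.ones(len(t), dtype=bool)
    if condition is not None:
        if condition not in CONDITIONS:
            raise ValueError(f"unknown condition {condition!r}")
        mask &= (t["condition"] == condition).to_numpy()
    if phase is not None:
        if phase not in PHASES:
            raise ValueError(f"unknown phase {phase!r}")
        mask &= (t["phase"] == phase).to_numpy()
    if min_trial_in_phase is not None:
        mask &= t["trial_in_phase"].to_numpy() >= min_trial_in_phase
    if choice is not None:
        mask &= class_labels(t, "choice") == choice
    if block is not None:
        mask &= t["block_id"].to_numpy() == block
    if reward is not None:
        mask &= t["reward"].to_numpy() == reward
    return np.flatnonzero(mask)


# -- persistence -----------------------------------------------------------

def _trials_path(path: Path) -> Path:
    return path.with_suffix(".trials.csv")


def save_session(session: SessionData, path: str | Path) -> Path:
    """Write a session as an HDF5 array store plus a CSV trial table.

    ``path`` names the HDF5 file; the trial table is written alongside with
    a ``.trials.csv`` suffix.  The round trip is exact for counts, edges and
    every trial-table column.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["session_id"] = session.session_id
        f.create_dataset("counts", data=session.counts)
        f.create_dataset("bin_edges", data=session.bin_edges)
    session.trials.loc[:, list(TRIAL_COLUMNS)].to_csv(_trials_path(path), index=False)
    return path


def load_session(path: str | Path) -> SessionData:
    """Load a session written by :func:`save_session`."""
    path = Path(path)
    try:
        with h5py.File(path, "r") as f:
            if f.attrs.get("schema_version") != SCHEMA_VERSION:
                raise SessionFormatError(
                    f"{path}: unsupported or missing schema version"
                )
            counts = f["counts"][()]
            bin_edges = f["bin_edges"][()]
            session_id = str(f.attrs["session_id"])
    except OSError as exc:  # truncated / non-HDF5 file
        raise SessionFormatError(f"{path}: not a readable session file") from exc
    dtypes = {c: np.int64 for c in _INT_COLUMNS}
    dtypes.update({"condition": str, "phase": str})
    try:
        trials = pd.read_csv(_trials_path(path), dtype=dtypes)
    except (OSError, ValueError) as exc:
        raise SessionFormatError(f"{path}: trial table unreadable") from exc
    if list(trials.columns) != list(TRIAL_COLUMNS):
        raise SessionFormatError(f"{path}: trial table columns do not match schema")
    return SessionData(counts=counts, trials=trials, bin_edges=bin_edges,
                       session_id=session_id)
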