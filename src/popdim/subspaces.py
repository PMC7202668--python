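"""Informative directions and the mean/discriminant matrices U and W.

The informative (linear discriminant) direction of a block and phase is the
difference of choice-conditioned mean population vectors, ``w = mu2 - mu1``,
estimated per 250 ms analysis bin.  The noise covariance is approximated by
the identity, which makes ``w`` both the discriminant line and the column
unit of all downstream spectral analyses.  Mean vectors are collected into
``U`` (neurons x bins*choices*phases*blocks) and their differences into
``W`` (neurons x bins*phases*blocks); at the full task shape these have 192
and 96 columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import SessionData, class_labels, select_trials

PHASE_ORDER = ("acquisition", "reversal")

__all__ = [
    "InsufficientTrialsError",
    "MeanMatrix",
    "DiscriminantMatrix",
    "phase_trial_indices",
    "choice_means",
    "informative_direction",
    "cv_direction",
    "cv_basis",
    "usable_blocks",
    "build_U",
    "build_W",
]


class InsufficientTrialsError(ValueError):
    """A choice class has no (or too few) analyzable trials."""


def phase_trial_indices(
    session: SessionData,
    block: int,
    phase: str,
    min_trial_in_phase: int = 5,
    remove_scope: str = "phase",
) -> np.ndarray:
    """Analyzed trials of one block phase, in task order.

    The first four trials are treated as learning trials and removed.  The
    removal is counted per phase by default (``min_trial_in_phase``); with
    ``remove_scope='block'`` only the first four trials of the block are
    dropped, leaving the start of the reversal phase in.
    """
    if remove_scope == "phase":
        return select_trials(session, phase=phase, block=block,
                             min_trial_in_phase=min_trial_in_phase)
    if remove_scope == "block":
        idx = select_trials(session, phase=phase, block=block)
        tib = session.trials["trial_in_block"].to_numpy()[idx]
        return idx[tib >= min_trial_in_phase]
    raise ValueError(f"unknown remove_scope {remove_scope!r}")


def choice_means(
    session: SessionData,
    block: int,
    phase: str,
    bin_idx: int,
    trial_subset: np.ndarray | None = None,
    label_mode: str = "choice",
    min_trial_in_phase: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-neuron mean counts for the two classes of one block phase bin.

    Raises :class:`InsufficientTrialsError` if either class is absent from
    the analyzed trials — such blocks are excluded from analysis.
    """
    if trial_subset is None:
        trial_subset = phase_trial_indices(session, block, phase,
                                           min_trial_in_phase)
    trial_subset = np.asarray(trial_subset)
    labels = class_labels(session.trials.iloc[trial_subset], label_mode)
    x = session.counts[:, trial_subset, bin_idx]
    means = []
    for cls in (1, 2):
        sel = labels == cls
        if not sel.any():
            raise InsufficientTrialsError(
                f"block {block} {phase}: no analyzed trials of class {cls}"
            )
        means.append(x[:, sel].mean(axis=1))
    return means[0], means[1]


def informative_direction(mu1: np.ndarray, mu2: np.ndarray) -> np.ndarray:
    """Discriminant direction ``w = mu2 - mu1`` (no normalization)."""
    mu1 = np.asarray(mu1, dtype=float)
    mu2 = np.asarray(mu2, dtype=float)
    if mu1.shape != mu2.shape:
        raise ValueError("mean vectors must have equal length")
    return mu2 - mu1


def _cv_training_positions(n: int, pos: int) -> np.ndarray:
    """Training positions for leave-3-out at position ``pos`` of ``n``
    analyzed trials: the tested trial and its existing neighbors (in
    analyzed-trial order) are excluded."""
    drop = {pos - 1, pos, pos + 1}
    return np.array([i for i in range(n) if i not in drop], dtype=int)


def cv_direction(
    session: SessionData,
    block: int,
    phase: str,
    bin_idx: int,
    test_trial: int,
    label_mode: str = "choice",
    min_trial_in_phase: int = 5,
) -> np.ndarray:
    """Leave-3-out discriminant for one tested trial.

    ``test_trial`` is a session trial index that must be among the analyzed
    trials of the phase.  The tested trial and its preceding and following
    analyzed trials are left out of the mean estimates; at phase edges only
    the existing neighbors are dropped (leave-2-out).
    """
    idx = phase_trial_indices(session, block, phase, min_trial_in_phase)
    where = np.flatnonzero(idx == test_trial)
    if where.size != 1:
        raise ValueError("test_trial is not an analyzed trial of this phase")
    train = idx[_cv_training_positions(len(idx), int(where[0]))]
    mu1, mu2 = choice_means(session, block, phase, bin_idx, trial_subset=train,
                            label_mode=label_mode)
    return informative_direction(mu1, mu2)


def cv_basis(
    session: SessionData,
    block: int,
    phase: str,
    test_trial: int,
    bins: tuple[int, int] = (0, 1),
    label_mode: str = "choice",
    min_trial_in_phase: int = 5,
) -> np.ndarray:
    """Two-column (per-bin) leave-3-out basis for one tested trial."""
    cols = [
        cv_direction(session, block, phase, b, test_trial, label_mode,
                     min_trial_in_phase)
        for b in bins
    ]
    return np.stack(cols, axis=1)


def usable_blocks(
    session: SessionData,
    min_trials: int = 4,
    label_mode: str = "choice",
    min_trial_in_phase: int = 5,
) -> list[int]:
    """Blocks whose every phase x class cell has at least ``min_trials``
    analyzed trials.  Blocks where one option was chosen almost exclusively
    fail this rule and are not analyzed."""
    out = []
    for block in session.block_ids:
        ok = True
        for phase in PHASE_ORDER:
            idx = phase_trial_indices(session, int(block), phase,
                                      min_trial_in_phase)
            labels = class_labels(session.trials.iloc[idx], label_mode)
            if min(int((labels == 1).sum()), int((labels == 2).sum())) < min_trials:
                ok = False
                break
        if ok:
            out.append(int(block))
    return out


@dataclass
class MeanMatrix:
    """Neuron x condition matrix of choice-conditioned means.

    Column order is deterministic: block-major, then phase (acquisition,
    reversal), then choice (1, 2), then bin.  ``labels`` carries one row per
    column with block_id, condition, phase, choice and bin.
    """

    matrix: np.ndarray
    labels: pd.DataFrame

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def columns(self, **filters) -> np.ndarray:
        """Boolean column mask for equality filters on the label table."""
        mask = np.ones(self.n_columns, dtype=bool)
        for key, val in filters.items():
            mask &= (self.labels[key] == val).to_numpy()
        return mask

    def submatrix(self, **filters) -> np.ndarray:
        return self.matrix[:, self.columns(**filters)]


@dataclass
class DiscriminantMatrix(MeanMatrix):
    """Neuron x condition matrix of discriminant directions ``w``."""

    def basis(self, block: int, phase: str) -> np.ndarray:
        """Per-bin two-column subspace basis of one block phase."""
        mask = self.columns(block_id=block, phase=phase)
        cols = self.labels.index[mask]
        order = np.argsort(self.labels.loc[cols, "bin"].to_numpy())
        return self.matrix[:, np.asarray(cols)[order]]

    def stacked(self, block: int, phase: str) -> np.ndarray:
        """The two per-bin directions stacked into one long vector."""
        return self.basis(block, phase).T.reshape(-1)


def build_U(
    session: SessionData,
    blocks: list[int] | None = None,
    min_trials: int = 4,
    label_mode: str = "choice",
    min_trial_in_phase: int = 5,
) -> MeanMatrix:
    """Assemble the mean matrix U over usable blocks.

    At the full task shape (24 usable blocks, 2 phases, 2 choices, 2 bins)
    U has 192 columns.
    """
    if blocks is None:
        blocks = usable_blocks(session, min_trials, label_mode,
                               min_trial_in_phase)
    if not blocks:
        raise InsufficientTrialsError("no usable blocks")
    cond_of = session.trials.groupby("block_id")["condition"].first()
    cols, rows = [], []
    for block in blocks:
        for phase in PHASE_ORDER:
            mus = {}
            for b in range(session.n_bins):
                mus[b] = choice_means(session, block, phase, b,
                                      label_mode=label_mode,
                                      min_trial_in_phase=min_trial_in_phase)
            for choice in (1, 2):
                for b in range(session.n_bins):
                    cols.append(mus[b][choice - 1])
                    rows.append((block, cond_of.loc[block], phase, choice, b))
    labels = pd.DataFrame(rows, columns=["block_id", "condition", "phase",
                                         "choice", "bin"])
    return MeanMatrix(np.stack(cols, axis=1), labels)


def build_W(
    session: SessionData,
    blocks: list[int] | None = None,
    min_trials: int = 4,
    label_mode: str = "choice",
    min_trial_in_phase: int = 5,
) -> DiscriminantMatrix:
    """Assemble the discriminant matrix W over usable blocks.

    Columns are ``mu2 - mu1`` of the matching cells of U (pooled over
    analyzed trials; the pooled direction equals the average of the
    leave-3-out directions up to edge effects).  At the full task shape W
    has 96 columns.
    """
    u = build_U(session, blocks, min_trials, label_mode, min_trial_in_phase)
    cols, rows = [], []
    lab = u.labels
    for (block, cond, phase, b), grp in lab.groupby(
        ["block_id", "condition", "phase", "bin"], sort=False
    ):
        i1 = grp.index[grp["choice"] == 1][0]
        i2 = grp.index[grp["choice"] == 2][0]
        cols.append(informative_direction(u.matrix[:, i1], u.matrix[:, i2]))
        rows.append((block, cond, phase, b))
    labels = pd.DataFrame(rows, columns=["block_id", "condition", "phase", "bin"])
    return DiscriminantMatrix(np.stack(cols, axis=1), labels)
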