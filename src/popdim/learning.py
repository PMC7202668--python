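"""Trial-wise learning trajectories in discriminant subspaces.

The learning index for a single trial is the difference of Mahalanobis
distances from its subspace projection ``z`` to the learned distributions
of the two options:

``delta_information = M_other - M_chosen``,
``M_i = (z - u_i)^T Q^{-1} (z - u_i)``.

It is positive when activity lies nearer the chosen option's learned
distribution, and grows over trials as population activity converges to
the learned pattern.  Curves are computed in the block's own subspace
(within, with distribution parameters estimated from post-learning trials
of the same phase, leave-one-out) and in other same-condition blocks'
subspaces (x-block, scored against the source block's own distributions
without re-estimating means after projection).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import SessionData, class_labels, select_trials
from .information import _shrink_if_needed, project
from .subspaces import (
    DiscriminantMatrix,
    PHASE_ORDER,
    build_W,
    phase_trial_indices,
    usable_blocks,
)

__all__ = [
    "delta_information",
    "learning_curves",
    "reversal_trajectory",
    "Trajectory",
]


def delta_information(
    z: np.ndarray,
    mean_chosen: np.ndarray,
    mean_other: np.ndarray,
    q: np.ndarray,
) -> float | np.ndarray:
    """``M_other - M_chosen`` for one or many projected trials.

    Antisymmetric under swapping the chosen/other labels; zero when ``z``
    is equidistant from both centroids under ``Q``.
    """
    q = _shrink_if_needed(np.asarray(q, dtype=float))
    qinv = np.linalg.inv(q)
    z = np.asarray(z, dtype=float)
    dc = z - np.asarray(mean_chosen, dtype=float)
    do = z - np.asarray(mean_other, dtype=float)
    if z.ndim == 1:
        return float(do @ qinv @ do - dc @ qinv @ dc)
    return np.einsum("ti,ij,tj->t", do, qinv, do) - np.einsum(
        "ti,ij,tj->t", dc, qinv, dc)


def _class_stats(z: np.ndarray, lab: np.ndarray):
    """Class means and pooled within-class covariance of projected trials."""
    means = {}
    s = np.zeros((2, 2))
    dof = 0
    for cls in (1, 2):
        zc = z[lab == cls]
        if len(zc) < 2:
            return None
        means[cls] = zc.mean(axis=0)
        zc = zc - means[cls]
        s += zc.T @ zc
        dof += len(zc) - 1
    return means, s / dof


def _delta_within(z: np.ndarray, lab: np.ndarray, learned: np.ndarray
                  ) -> np.ndarray:
    """Within-subspace delta-information, leave-one-out on learned trials."""
    out = np.full(len(z), np.nan)
    for k in range(len(z)):
        mask = learned.copy()
        mask[k] = False
        st = _class_stats(z[mask], lab[mask])
        if st is None:
            continue
        means, q = st
        chosen, other = lab[k], 3 - lab[k]
        out[k] = delta_information(z[k], means[chosen], means[other], q)
    return out


def learning_curves(
    session: SessionData,
    w: DiscriminantMatrix | None = None,
    subspaces: tuple[str, ...] = ("within", "x-block"),
    max_trial: int = 25,
    align: str = "phase",
    phases: tuple[str, ...] = ("acquisition",),
    min_learned_trial: int = 5,
    min_trials: int = 4,
) -> pd.DataFrame:
    """Delta-information learning curves per condition and subspace.

    ``align='phase'`` scores trials of the phases in ``phases`` on the
    trial-in-phase axis (1..``max_trial``); the default restricts to the
    acquisition phase so that trial 1 reflects initial learning rather than
    post-reversal carry-over.  ``align='reversal'`` scores only reversal-phase trials,
    in the acquisition-phase and reversal-phase frames of the same block
    (subspace labels ``acquisition-frame`` / ``reversal-frame``), indexed by
    trials after the reversal.
    """
    blocks = usable_blocks(session, min_trials)
    if w is None:
        w = build_W(session, blocks, min_trials)
    cond_of = session.trials.groupby("block_id")["condition"].first()
    tin = session.trials["trial_in_phase"].to_numpy()
    records = []

    for block in blocks:
        cond = cond_of.loc[block]
        for phase in PHASE_ORDER:
            idx = select_trials(session, block=block, phase=phase)
            if len(idx) == 0:
                continue
            lab = class_labels(session.trials.iloc[idx], "choice")
            x = session.counts[:, idx, :].astype(float)
            t_phase = tin[idx]
            learned = t_phase >= min_learned_trial

            if align == "phase" and phase not in phases:
                continue
            if align == "reversal":
                if phase != "reversal":
                    continue
                frames = {
                    "reversal-frame": ("reversal", True),
                    "acquisition-frame": ("acquisition", False),
                }
                for name, (src_phase, reestimate) in frames.items():
                    basis = w.basis(block, src_phase)
                    z = project(x, basis)
                    if reestimate:
                        dvals = _delta_within(z, lab, learned)
                    else:
                        src_idx = phase_trial_indices(session, block, src_phase,
                                                      min_learned_trial)
                        src_lab = class_labels(session.trials.iloc[src_idx],
                                               "choice")
                        z_src = project(
                            session.counts[:, src_idx, :].astype(float), basis)
                        st = _class_stats(z_src, src_lab)
                        if st is None:
                            continue
                        means, q = st
                        dvals = np.array([
                            delta_information(z[k], means[lab[k]],
                                              means[3 - lab[k]], q)
                            for k in range(len(z))
                        ])
                    for k in range(len(z)):
                        if t_phase[k] <= max_trial and np.isfinite(dvals[k]):
                            records.append((cond, name, int(t_phase[k]),
                                            float(dvals[k])))
                continue

            if "within" in subspaces:
                z = project(x, w.basis(block, phase))
                dvals = _delta_within(z, lab, learned)
                for k in range(len(z)):
                    if t_phase[k] <= max_trial and np.isfinite(dvals[k]):
                        records.append((cond, "within", int(t_phase[k]),
                                        float(dvals[k])))

            if "x-block" in subspaces:
                sources = [b for b in blocks
                           if b != block and cond_of.loc[b] == cond]
                per_src = []
                for src in sources:
                    basis = w.basis(src, phase)
                    src_idx = phase_trial_indices(session, src, phase,
                                                  min_learned_trial)
                    src_lab = class_labels(session.trials.iloc[src_idx],
                                           "choice")
                    z_src = project(session.counts[:, src_idx, :].astype(float),
                                    basis)
                    st = _class_stats(z_src, src_lab)
                    if st is None:
                        continue
                    means, q = st
                    z = project(x, basis)
                    per_src.append(np.array([
                        delta_information(z[k], means[lab[k]],
                                          means[3 - lab[k]], q)
                        for k in range(len(z))
                    ]))
                if per_src:
                    dvals = np.mean(per_src, axis=0)
                    for k in range(len(idx)):
                        if t_phase[k] <= max_trial:
                            records.append((cond, "x-block", int(t_phase[k]),
                                            float(dvals[k])))

    frame = pd.DataFrame(records, columns=["condition", "subspace", "trial",
                                           "delta_information"])
    if frame.empty:
        return frame
    agg = (frame.groupby(["condition", "subspace", "trial"])
           ["delta_information"].agg(["mean", "sem", "count"]).reset_index())
    return agg.rename(columns={"mean": "delta_information",
                               "count": "n"})


@dataclass
class Trajectory:
    """Single-trial coordinates of one block in one phase's 2-D frame.

    The frame is the block-phase discriminant subspace (one dimension per
    analysis bin) rotated into the eigenbasis of the 2x2 covariance of the
    projected coordinates, matching the convention of plotting rotations
    within the subspace spanned by the two time bins.
    """

    frame_phase: str
    points: pd.DataFrame  # trial_in_block, phase, choice, dim1, dim2, post_reversal_index


def reversal_trajectory(
    session: SessionData,
    block: int,
    w: DiscriminantMatrix | None = None,
    min_trials: int = 4,
) -> tuple[Trajectory, Trajectory]:
    """Project every trial of a block into each phase's own 2-D subspace.

    Returns the acquisition-frame and reversal-frame trajectories; trials
    after the reversal carry a 1-based ``post_reversal_index``.
    """
    if w is None:
        w = build_W(session, [block], min_trials)
    idx = select_trials(session, block=block)
    if len(idx) == 0:
        raise ValueError(f"block {block} has no trials")
    t = session.trials.iloc[idx]
    lab = class_labels(t, "choice")
    x = session.counts[:, idx, :].astype(float)
    rev = t["reversal_trial"].to_numpy()[0]
    post = t["trial_in_block"].to_numpy() - rev + 1
    post = np.where(post >= 1, post, 0)

    out = []
    for frame_phase in PHASE_ORDER:
        basis = w.basis(block, frame_phase)
        z = project(x, basis)
        # rotate into the eigenbasis of the projected covariance
        zc = z - z.mean(axis=0)
        _, vecs = np.linalg.eigh(zc.T @ zc / max(len(z) - 1, 1))
        rot = z @ vecs[:, ::-1]
        pts = pd.DataFrame({
            "trial_in_block": t["trial_in_block"].to_numpy(),
            "phase": t["phase"].to_numpy(),
            "choice": lab,
            "dim1": rot[:, 0],
            "dim2": rot[:, 1],
            "post_reversal_index": post,
        })
        out.append(Trajectory(frame_phase, pts))
    return out[0], out[1]
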