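"""Cross-projection information, decoding and principal angles.

Single trials are projected into a block-phase subspace spanned by the two
per-bin discriminant directions, ``z = W^T x``.  Linear information about
the choice along a direction ``w_s`` is the signal-to-noise ratio

``I = (w_s^T (mu2 - mu1))^2 / (w_s^T Q w_s)``

estimated after projection (for the scalar measure the two bins are stacked
into one long vector).  The predicted error fraction is the upper Gaussian
tail at ``sqrt(I)/2``.  Measured decoding projects trials into the subspace,
re-estimates class means there (leave-one-out), and classifies each trial
to the nearest centroid under the Mahalanobis metric with a pooled noise
covariance estimated leave-one-block-out.

Subspaces can come from the same block and phase (within), the opposite
phase of the same block (x-phase), other blocks of the same condition
(x-block) or blocks of the other condition (x-cond); comparing these
quantifies how much choice information different learning episodes share.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import SessionData, class_labels
from .subspaces import (
    DiscriminantMatrix,
    PHASE_ORDER,
    _cv_training_positions,
    build_W,
    phase_trial_indices,
    usable_blocks,
)

logger = logging.getLogger(__name__)

PAIRINGS = ("within", "x-phase", "x-block", "x-cond")

__all__ = [
    "InfoResult",
    "DecodeResult",
    "DegenerateNoiseError",
    "project",
    "stacked_projection",
    "information",
    "predicted_error",
    "principal_angle",
    "nearest_centroid_mahalanobis",
    "decode",
    "pairing_report",
    "PAIRINGS",
]


class DegenerateNoiseError(ValueError):
    """Projected noise variance is zero; information is undefined."""


@dataclass
class InfoResult:
    information: float
    predicted_error: float
    signal: float
    noise: float
    pairing: str = ""


@dataclass
class DecodeResult:
    fraction_correct: float
    assignments: np.ndarray
    cv_scheme: str


# -- projections -----------------------------------------------------------

def project(x: np.ndarray, basis: np.ndarray) -> np.ndarray:
    """Project per-bin activity into a per-bin basis.

    ``x`` is ``(n_neurons, n_bins)`` for one trial or
    ``(n_neurons, n_trials, n_bins)`` for many; ``basis`` is
    ``(n_neurons, n_bins)`` with one direction per bin.  Returns the
    bin-matched coordinates ``z`` (one per bin).
    """
    x = np.asarray(x, dtype=float)
    basis = np.asarray(basis, dtype=float)
    if x.shape[0] != basis.shape[0] or x.shape[-1] != basis.shape[1]:
        raise ValueError("activity and basis dimensions do not conform")
    if x.ndim == 2:
        return np.einsum("nb,nb->b", x, basis)
    return np.einsum("ntb,nb->tb", x, basis)


def stacked_projection(x: np.ndarray, basis: np.ndarray) -> np.ndarray:
    """Scalar projection onto the stacked (bin-concatenated) direction."""
    z = project(x, basis)
    return z.sum(axis=-1)


# -- information -----------------------------------------------------------

def _pooled_var(z1: np.ndarray, z2: np.ndarray) -> float:
    n1, n2 = len(z1), len(z2)
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least two trials per choice")
    return float(((n1 - 1) * np.var(z1, ddof=1) + (n2 - 1) * np.var(z2, ddof=1))
                 / (n1 + n2 - 2))


def information(
    x_by_choice: tuple[np.ndarray, np.ndarray],
    w_s: np.ndarray,
) -> InfoResult:
    """Choice information along a (stacked) direction ``w_s``.

    ``x_by_choice`` holds the stacked trial vectors of each class, shape
    ``(n_trials_i, d)``.  Means and variance are estimated after projecting
    onto ``w_s``; the ratio is invariant to rescaling of ``w_s``.
    """
    w_s = np.asarray(w_s, dtype=float)
    if not np.any(w_s):
        raise ValueError("w_s must be nonzero")
    z1 = np.asarray(x_by_choice[0], dtype=float) @ w_s
    z2 = np.asarray(x_by_choice[1], dtype=float) @ w_s
    var = _pooled_var(z1, z2)
    if var <= 0:
        raise DegenerateNoiseError("projected variance is zero")
    i = float((z2.mean() - z1.mean()) ** 2 / var)
    return InfoResult(i, predicted_error(i), signal=abs(z2.mean() - z1.mean()),
                      noise=var)


def predicted_error(i: float) -> float:
    """Predicted error fraction: upper Gaussian tail at ``sqrt(I)/2``.

    Equals 0.5 at zero information and decreases monotonically to 0.
    """
    if i < 0:
        raise ValueError("information must be nonnegative")
    return float(stats.norm.sf(np.sqrt(i) / 2.0))


# -- principal angles ------------------------------------------------------

def _orthonormalize(w: np.ndarray) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.ndim == 1:
        w = w[:, None]
    norms = np.linalg.norm(w, axis=0)
    w = w[:, norms > 0]
    if w.shape[1] == 0:
        raise ValueError("subspace basis is zero")
    q, r = np.linalg.qr(w)
    keep = np.abs(np.diag(r)) > 1e-12 * max(1.0, np.abs(r).max())
    return q[:, keep]


def principal_angle(w_a: np.ndarray, w_b: np.ndarray,
                    method: str = "spectral") -> float:
    """First principal angle between two subspaces, in degrees [0, 90].

    Bases are orthonormalized; the cosine is the largest singular value of
    their cross-Gram matrix.  ``method='mean'`` reports the angle of the
    root-mean-square cosine over all principal directions instead.
    """
    qa = _orthonormalize(w_a)
    qb = _orthonormalize(w_b)
    s = np.linalg.svd(qa.T @ qb, compute_uv=False)
    s = np.clip(s, 0.0, 1.0)
    if method == "spectral":
        c = s.max()
    elif method == "mean":
        c = float(np.sqrt(np.mean(s**2)))
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(np.degrees(np.arccos(c)))


# -- Mahalanobis nearest-centroid decoding ---------------------------------

def _shrink_if_needed(q: np.ndarray, gamma: float = 0.05) -> np.ndarray:
    """Blend toward a scaled identity when the covariance is ill-conditioned."""
    eig = np.linalg.eigvalsh(q)
    if eig[0] <= 0 or eig[-1] / max(eig[0], 1e-300) > 1e10:
        logger.warning("projected covariance ill-conditioned; applying "
                       "shrinkage gamma=%.2f", gamma)
        target = np.eye(q.shape[0]) * (np.trace(q) / q.shape[0] + 1e-12)
        q = (1 - gamma) * q + gamma * target
    return q


def nearest_centroid_mahalanobis(
    z: np.ndarray,
    labels: np.ndarray,
    q: np.ndarray,
    loo_means: bool = True,
) -> DecodeResult:
    """Classify projected trials to the nearest class centroid.

    Class means are re-estimated from the projected data themselves,
    leaving the scored trial out of its own class mean when ``loo_means``.
    Distances use the Mahalanobis metric with covariance ``q``; ties break
    toward class 1.
    """
    z = np.atleast_2d(np.asarray(z, dtype=float))
    labels = np.asarray(labels)
    q = _shrink_if_needed(np.asarray(q, dtype=float))
    qinv = np.linalg.inv(q)
    means, counts = {}, {}
    for cls in (1, 2):
        sel = labels == cls
        if sel.sum() < 2:
            raise ValueError("need at least two trials per class")
        means[cls] = z[sel].mean(axis=0)
        counts[cls] = int(sel.sum())
    assign = np.zeros(len(z), dtype=np.int64)
    for k in range(len(z)):
        dists = {}
        for cls in (1, 2):
            mu = means[cls]
            if loo_means and labels[k] == cls:
                mu = (counts[cls] * mu - z[k]) / (counts[cls] - 1)
            d = z[k] - mu
            dists[cls] = float(d @ qinv @ d)
        assign[k] = 2 if dists[2] < dists[1] else 1
    frac = float((assign == labels).mean())
    return DecodeResult(frac, assign, "loo-means" if loo_means else "plugin-means")


# -- session-level machinery ----------------------------------------------

class _Cells:
    """Per block-phase trial bundles of a session, cached for reuse."""

    def __init__(self, session: SessionData, blocks: list[int],
                 label_mode: str, min_trial_in_phase: int):
        self.session = session
        self.blocks = blocks
        self.cells: list[tuple[int, str]] = []
        self.idx: dict[tuple[int, str], np.ndarray] = {}
        self.labels: dict[tuple[int, str], np.ndarray] = {}
        self.x: dict[tuple[int, str], np.ndarray] = {}
        self.condition: dict[int, str] = {}
        cond_of = session.trials.groupby("block_id")["condition"].first()
        for block in blocks:
            self.condition[block] = cond_of.loc[block]
            for phase in PHASE_ORDER:
                key = (block, phase)
                idx = phase_trial_indices(session, block, phase,
                                          min_trial_in_phase)
                self.cells.append(key)
                self.idx[key] = idx
                self.labels[key] = class_labels(session.trials.iloc[idx],
                                                label_mode)
                self.x[key] = session.counts[:, idx, :].astype(float)

    def sources(self, target: tuple[int, str], pairing: str) -> list[tuple[int, str]]:
        block, phase = target
        cond = self.condition[block]
        if pairing == "within":
            return [target]
        if pairing == "x-phase":
            other = PHASE_ORDER[1 - PHASE_ORDER.index(phase)]
            return [(block, other)]
        if pairing == "x-block":
            return [(b, phase) for b in self.blocks
                    if b != block and self.condition[b] == cond]
        if pairing == "x-cond":
            return [(b, phase) for b in self.blocks
                    if self.condition[b] != cond]
        raise ValueError(f"unknown pairing {pairing!r}")


def _projection_tables(cells: _Cells, w: DiscriminantMatrix):
    """Project every cell's trials into every source basis; accumulate the
    class-centered scatter needed for leave-one-block-out pooled Q."""
    zmap: dict[tuple, dict[tuple, np.ndarray]] = {}
    ss: dict[tuple, dict[int, np.ndarray]] = {}
    df: dict[tuple, dict[int, int]] = {}
    for src in cells.cells:
        basis = w.basis(*src)
        zmap[src] = {}
        ss[src] = {}
        df[src] = {}
        for cell in cells.cells:
            z = project(cells.x[cell], basis)
            zmap[src][cell] = z
            lab = cells.labels[cell]
            s = np.zeros((2, 2))
            n_classes = 0
            for cls in (1, 2):
                zc = z[lab == cls]
                if len(zc) > 0:
                    zc = zc - zc.mean(axis=0)
                    s += zc.T @ zc
                    n_classes += 1
            block = cell[0]
            ss[src][block] = ss[src].get(block, np.zeros((2, 2))) + s
            df[src][block] = df[src].get(block, 0) + len(z) - n_classes
    return zmap, ss, df


def _q_loo(ss: dict, df: dict, exclude_block: int) -> np.ndarray:
    s = sum(v for b, v in ss.items() if b != exclude_block)
    d = sum(v for b, v in df.items() if b != exclude_block)
    if d < 2:
        raise ValueError("insufficient trials for pooled covariance")
    return s / d


def _info_from_scalars(z: np.ndarray, lab: np.ndarray) -> tuple[float, float]:
    z1, z2 = z[lab == 1], z[lab == 2]
    var = _pooled_var(z1, z2)
    if var <= 0:
        raise DegenerateNoiseError("projected variance is zero")
    i = float((z2.mean() - z1.mean()) ** 2 / var)
    return i, predicted_error(i)


def _signal_noise(z: np.ndarray, lab: np.ndarray) -> tuple[float, float]:
    m1 = z[lab == 1].mean(axis=0)
    m2 = z[lab == 2].mean(axis=0)
    s = np.zeros((2, 2))
    n = 0
    for cls, m in ((1, m1), (2, m2)):
        zc = z[lab == cls] - m
        s += zc.T @ zc
        n += len(zc) - 1
    return float(np.linalg.norm(m2 - m1)), float(np.trace(s / n))


def _within_cv(cells: _Cells, cell, q: np.ndarray) -> tuple[float, float, float]:
    """Leave-3-out information and decoding for a cell's own subspace.

    For each tested trial the discriminant is re-estimated without the trial
    and its neighbors, the cell's trials are projected with that fold's
    basis, class means are taken over the training trials, and the tested
    trial is scored.  Returns (information, predicted_error, fraction_correct).
    """
    x = cells.x[cell]                       # (N, T, 2)
    lab = cells.labels[cell]
    n = x.shape[1]
    z_scalar = np.zeros(n)
    correct = np.zeros(n, dtype=bool)
    qinv = np.linalg.inv(_shrink_if_needed(q))
    for p in range(n):
        train = _cv_training_positions(n, p)
        lab_t = lab[train]
        if min((lab_t == 1).sum(), (lab_t == 2).sum()) < 1:
            raise ValueError("cv fold empties a choice class")
        xt = x[:, train, :]
        basis = np.stack(
            [xt[:, lab_t == 2, b].mean(axis=1) - xt[:, lab_t == 1, b].mean(axis=1)
             for b in range(x.shape[2])], axis=1)
        z_all = project(x, basis)
        z_scalar[p] = z_all[p].sum()
        dists = {}
        for cls in (1, 2):
            mu = z_all[train][lab_t == cls].mean(axis=0)
            d = z_all[p] - mu
            dists[cls] = float(d @ qinv @ d)
        pred = 2 if dists[2] < dists[1] else 1
        correct[p] = pred == lab[p]
    i, err = _info_from_scalars(z_scalar, lab)
    return i, err, float(correct.mean())


def decode(
    session: SessionData,
    pairing: str,
    target: tuple[int, str] | None = None,
    w: DiscriminantMatrix | None = None,
    label_mode: str = "choice",
    min_trials: int = 4,
    min_trial_in_phase: int = 5,
) -> pd.DataFrame:
    """Decoding for one pairing (all target cells, or a single one).

    Thin wrapper over :func:`pairing_report` restricted to one pairing.
    """
    rep = pairing_report(session, w=w, pairings=(pairing,),
                         label_mode=label_mode, min_trials=min_trials,
                         min_trial_in_phase=min_trial_in_phase)
    if target is not None:
        rep = rep[(rep["block_id"] == target[0]) & (rep["phase"] == target[1])]
    return rep.reset_index(drop=True)


def pairing_report(
    session: SessionData,
    w: DiscriminantMatrix | None = None,
    pairings: tuple[str, ...] = PAIRINGS,
    label_mode: str = "choice",
    include_decode: bool = True,
    min_trials: int = 4,
    min_trial_in_phase: int = 5,
) -> pd.DataFrame:
    """Information, predicted error, signal, noise, principal angle and
    (optionally) measured decoding for every target cell and pairing.

    For x-block and x-cond the target is evaluated against each source
    block's subspace separately and the metrics averaged.  Within-subspace
    rows always use leave-3-out cross-validation of the discriminant (for
    both information and decoding); ``include_decode`` controls only the
    cross-subspace nearest-centroid classification.  All decoding uses
    leave-one-block-out pooled projected covariances.
    """
    blocks = usable_blocks(session, min_trials, label_mode, min_trial_in_phase)
    if not blocks:
        raise ValueError("no usable blocks")
    if w is None:
        w = build_W(session, blocks, min_trials, label_mode, min_trial_in_phase)
    cells = _Cells(session, blocks, label_mode, min_trial_in_phase)
    zmap, ss, df = _projection_tables(cells, w)

    rows = []
    for target in cells.cells:
        block, phase = target
        own_basis = w.basis(block, phase)
        for pairing in pairings:
            srcs = cells.sources(target, pairing)
            infos, errs, sigs, noises, fracs, angles = [], [], [], [], [], []
            for src in srcs:
                q = _q_loo(ss[src], df[src], exclude_block=block)
                if pairing == "within":
                    # the within estimate is always leave-3-out
                    # cross-validated; projecting onto the pooled direction
                    # would overfit the same trials it was estimated from
                    i, err, frac = _within_cv(cells, target, q)
                    fracs.append(frac)
                    angles.append(0.0)
                else:
                    z = zmap[src][target]
                    lab = cells.labels[target]
                    i, err = _info_from_scalars(z.sum(axis=1), lab)
                    if include_decode:
                        res = nearest_centroid_mahalanobis(z, lab, q)
                        fracs.append(res.fraction_correct)
                    angles.append(principal_angle(own_basis, w.basis(*src)))
                sig, noi = _signal_noise(zmap[src][target], cells.labels[target])
                infos.append(i)
                errs.append(err)
                sigs.append(sig)
                noises.append(noi)
            rows.append({
                "session_id": session.session_id,
                "condition": cells.condition[block],
                "block_id": block,
                "phase": phase,
                "pairing": pairing,
                "information": float(np.mean(infos)),
                "predicted_error": float(np.mean(errs)),
                "signal": float(np.mean(sigs)),
                "noise": float(np.mean(noises)),
                "fraction_correct": float(np.mean(fracs)) if fracs else np.nan,
                "principal_angle_deg": float(np.mean(angles)),
                "n_trials": len(cells.idx[target]),
                "n_sources": len(srcs),
            })
    return pd.DataFrame(rows)
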