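"""Spectral dimensionality of the mean and discriminant matrices.

Dimensionality is measured on the eigenvalues of ``M M^T`` (equivalently
the squared singular values of ``M``), where ``M`` is a neuron x condition
matrix of trial-averaged vectors (U) or discriminant directions (W).  The
headline quantity is the smallest number of dimensions whose cumulative
variance fraction reaches a threshold (k80, k90).  No column centering is
applied by default, matching the direct decomposition of ``W W^T``;
centering is available as an option and changes the thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_core import SessionData
from .subspaces import (
    MeanMatrix,
    PHASE_ORDER,
    build_U,
    choice_means,
    phase_trial_indices,
    usable_blocks,
)

__all__ = [
    "SpectrumResult",
    "BlockAccumulationCurve",
    "spectrum",
    "condition_split_spectra",
    "dims_vs_blocks",
    "remove_first_pc",
    "crossval_variance",
]


@dataclass
class SpectrumResult:
    """Eigenvalues of ``M M^T`` and derived cumulative-variance summaries."""

    eigenvalues: np.ndarray      # descending, padded with zeros to n_columns
    cumulative: np.ndarray       # cumulative variance fraction
    dims_at_threshold: dict[float, int]
    label: str = ""

    def dims_at(self, threshold: float) -> int:
        """Smallest k (1-based) with cumulative variance >= threshold."""
        return int(np.searchsorted(self.cumulative, threshold - 1e-12) + 1)


def spectrum(
    m: np.ndarray,
    center: bool = False,
    thresholds: tuple[float, ...] = (0.8, 0.9),
    label: str = "",
) -> SpectrumResult:
    """Eigen-spectrum of ``M M^T`` with cumulative variance fractions.

    Eigenvalues are the squared singular values of ``M``, padded with zeros
    up to the number of columns so the cumulative fraction always ends at 1.
    """
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[1] < 1:
        raise ValueError("need a 2-D matrix with at least one column")
    if center:
        m = m - m.mean(axis=1, keepdims=True)
    s = np.linalg.svd(m, compute_uv=False)
    ev = np.zeros(m.shape[1])
    k = min(len(s), m.shape[1])
    ev[:k] = s[:k] ** 2
    total = ev.sum()
    if total <= 0:
        raise ValueError("matrix has no variance; spectrum undefined")
    cum = np.cumsum(ev) / total
    res = SpectrumResult(ev, cum, {}, label)
    res.dims_at_threshold = {t: res.dims_at(t) for t in thresholds}
    return res


def condition_split_spectra(
    mat: MeanMatrix, center: bool = False,
    thresholds: tuple[float, ...] = (0.8, 0.9),
) -> dict[str, SpectrumResult]:
    """Independent spectra of the What and Where column subsets."""
    out = {}
    for cond in ("What", "Where"):
        cols = mat.columns(condition=cond)
        if not cols.any():
            raise ValueError(f"no columns for condition {cond}")
        out[cond] = spectrum(mat.matrix[:, cols], center, thresholds, label=cond)
    return out


@dataclass
class BlockAccumulationCurve:
    """Threshold dimensionality as blocks are aggregated at random."""

    n_blocks: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    threshold: float
    n_resamples: int
    seed: int | None


def dims_vs_blocks(
    mat: MeanMatrix,
    threshold: float = 0.8,
    n_resamples: int = 100,
    seed: int | None = None,
    condition: str | None = None,
) -> BlockAccumulationCurve:
    """Dimensionality at ``threshold`` for random block subsets of growing
    size.  The final point uses all blocks exactly once (zero spread)."""
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    labels = mat.labels
    mask = np.ones(len(labels), dtype=bool)
    if condition is not None:
        mask = (labels["condition"] == condition).to_numpy()
    blocks = np.unique(labels.loc[mask, "block_id"].to_numpy())
    rng = np.random.default_rng(seed)
    grid = np.arange(1, len(blocks) + 1)
    means, sds = [], []
    for b in grid:
        if b == len(blocks):
            draws = [blocks]
        else:
            draws = [rng.choice(blocks, size=b, replace=False)
                     for _ in range(n_resamples)]
        vals = []
        for subset in draws:
            sel = mask & labels["block_id"].isin(subset).to_numpy()
            vals.append(spectrum(mat.matrix[:, sel]).dims_at(threshold))
        means.append(np.mean(vals))
        sds.append(np.std(vals))
    return BlockAccumulationCurve(grid, np.array(means), np.array(sds),
                                  threshold, n_resamples, seed)


def remove_first_pc(m: np.ndarray) -> np.ndarray:
    """Deflate the leading left singular vector: ``M - u1 u1^T M``."""
    m = np.asarray(m, dtype=float)
    u, s, vt = np.linalg.svd(m, full_matrices=False)
    u1 = u[:, :1]
    return m - u1 @ (u1.T @ m)


def crossval_variance(
    session: SessionData,
    blocks: list[int] | None = None,
    condition: str | None = None,
    n_folds: int = 20,
    seed: int | None = None,
    min_trials: int = 4,
    min_trial_in_phase: int = 5,
) -> dict[str, np.ndarray]:
    """Cumulative variance of held-out single trials in the mean-vector
    eigenbasis.

    Each fold removes one analyzed trial of each choice from one random
    block phase, recomputes the affected columns of U, takes the SVD of the
    perturbed matrix, and measures how much of the held-out trial vectors'
    squared norm the leading eigendimensions capture (per analysis bin).
    Because single trials carry Poisson noise outside the mean subspace,
    the held-out curve lies far below the within-sample curve.

    Returns ``{'cumulative': held-out curve, 'insample': U's own curve}``.
    """
    if blocks is None:
        blocks = usable_blocks(session, min_trials, min_trial_in_phase=min_trial_in_phase)
    u = build_U(session, blocks, min_trials, min_trial_in_phase=min_trial_in_phase)
    if condition is not None:
        keep = u.columns(condition=condition)
        base = u.matrix[:, keep]
        labels = u.labels.loc[keep].reset_index(drop=True)
        blocks = [b for b in blocks if b in set(labels["block_id"])]
    else:
        base = u.matrix
        labels = u.labels
    rng = np.random.default_rng(seed)
    from .io_core import class_labels as _labels

    n_cols = base.shape[1]
    curves = []
    cells = [(b, ph) for b in blocks for ph in PHASE_ORDER]
    for _ in range(n_folds):
        block, phase = cells[rng.integers(len(cells))]
        idx = phase_trial_indices(session, block, phase, min_trial_in_phase)
        lab = _labels(session.trials.iloc[idx], "choice")
        held = []
        for cls in (1, 2):
            cand = idx[lab == cls]
            if len(cand) < 2:
                held = []
                break
            held.append(int(rng.choice(cand)))
        if not held:
            continue
        train = np.array([i for i in idx if i not in held])
        m = base.copy()
        for b in range(session.n_bins):
            mu1, mu2 = choice_means(session, block, phase, b, trial_subset=train)
            for choice, mu in ((1, mu1), (2, mu2)):
                col = (
                    (labels["block_id"] == block)
                    & (labels["phase"] == phase)
                    & (labels["choice"] == choice)
                    & (labels["bin"] == b)
                ).to_numpy()
                m[:, col] = mu[:, None]
        basis = np.linalg.svd(m, full_matrices=False)[0]
        for k_held in held:
            for b in range(session.n_bins):
                x = session.counts[:, k_held, b].astype(float)
                denom = float(x @ x)
                if denom == 0:
                    continue
                proj = basis.T @ x
                cum = np.cumsum(proj**2) / denom
                curve = np.ones(n_cols)
                curve[: len(cum)] = np.minimum(cum, 1.0)
                if len(cum) < n_cols:
                    curve[len(cum):] = curve[len(cum) - 1]
                curves.append(curve)
    if not curves:
        raise ValueError("insufficient trials for cross-validated variance")
    return {
        "cumulative": np.mean(curves, axis=0),
        "insample": spectrum(base).cumulative,
    }
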