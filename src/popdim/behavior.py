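"""Behavioral modeling and the single-neuron tuning screen.

Covers Rescorla-Wagner value estimation by maximum likelihood (delta rule
``V <- V + alpha * (r - V)`` with softmax choice), interpolated and smoothed
choice-accuracy curves, a binomial trials-to-criterion statistic, and a
per-neuron linear-model screen (fraction of neurons with each task factor
significant at p < 0.05, with image nested under block and the RW value as
a continuous regressor).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io_core import SessionData, class_labels

__all__ = [
    "RWFit",
    "AccuracyCurve",
    "rw_values",
    "rw_fit",
    "accuracy_curve",
    "trials_to_criterion",
    "single_neuron_screen",
]


@dataclass
class RWFit:
    alpha: float
    beta: float
    values: pd.DataFrame      # per-trial v1, v2, v_chosen (pre-update)
    log_likelihood: float


def rw_values(
    choices: np.ndarray, rewards: np.ndarray, alpha: float, v0: float = 0.5
) -> np.ndarray:
    """Pre-choice option values of a delta-rule learner over one block.

    Returns ``(n_trials, 2)``; values stay in [0, 1] for binary rewards and
    ``v0`` in [0, 1].
    """
    v = np.array([v0, v0], dtype=float)
    out = np.zeros((len(choices), 2))
    for t, (c, r) in enumerate(zip(choices, rewards)):
        out[t] = v
        v[c - 1] += alpha * (r - v[c - 1])
    return out


def _session_blocks(session: SessionData, condition: str | None = None):
    t = session.trials
    for block, grp in t.groupby("block_id"):
        if condition is not None and grp["condition"].iloc[0] != condition:
            continue
        yield block, grp


def _neg_loglik(params, blocks):
    alpha, beta = params
    ll = 0.0
    for choices, rewards in blocks:
        v = rw_values(choices, rewards, alpha)
        dv = beta * (v[:, 1] - v[:, 0])
        # log p(choice): -log(1 + exp(-+dv)), numerically stable
        z = np.where(choices == 2, dv, -dv)
        ll += -np.logaddexp(0.0, -z).sum()
    return -ll


def rw_fit(
    session: SessionData,
    condition: str | None = None,
    bounds: tuple = ((1e-3, 1.0), (1e-2, 50.0)),
) -> RWFit:
    """Maximum-likelihood Rescorla-Wagner fit for one session.

    Values reset to 0.5 at each block start (new images); alpha and beta
    are fit jointly across the session's blocks by L-BFGS-B from a small
    grid of starts.  The per-trial value table (including the pre-update
    value of the chosen option, the continuous regressor of the
    single-neuron screen) is returned alongside.
    """
    blocks = []
    for _, grp in _session_blocks(session, condition):
        blocks.append((class_labels(grp, "choice"), grp["reward"].to_numpy()))
    if not blocks:
        raise ValueError("no blocks to fit")
    if all((c == c[0]).all() for c, _ in blocks):
        warnings.warn("single-choice data: beta is unidentifiable")
    best = None
    for a0 in (0.1, 0.3, 0.6):
        for b0 in (1.0, 5.0):
            res = optimize.minimize(_neg_loglik, x0=[a0, b0], args=(blocks,),
                                    method="L-BFGS-B", bounds=bounds)
            if best is None or res.fun < best.fun:
                best = res
    alpha, beta = best.x

    rows = []
    for block, grp in _session_blocks(session, condition):
        choices = class_labels(grp, "choice")
        v = rw_values(choices, grp["reward"].to_numpy(), alpha)
        for i, (c, row_idx) in enumerate(zip(choices, grp.index)):
            rows.append((row_idx, block, v[i, 0], v[i, 1], v[i, c - 1]))
    values = pd.DataFrame(rows, columns=["trial_index", "block_id", "v1", "v2",
                                         "v_chosen"]).set_index("trial_index")
    return RWFit(float(alpha), float(beta), values, -float(best.fun))


@dataclass
class AccuracyCurve:
    """Phase-interpolated, kernel-smoothed accuracy with across-session sem."""

    grid: np.ndarray           # 1..n_acq + n_rev interpolated trial axis
    mean: np.ndarray
    sem: np.ndarray
    n_acquisition: int
    kernel_sd: float


def _gaussian_smooth(y: np.ndarray, sd: float) -> np.ndarray:
    if sd <= 0:
        return y
    half = int(np.ceil(4 * sd))
    k = np.exp(-0.5 * (np.arange(-half, half + 1) / sd) ** 2)
    k /= k.sum()
    pad = np.pad(y, half, mode="edge")
    return np.convolve(pad, k, mode="valid")


def accuracy_curve(
    sessions: list[SessionData],
    condition: str | None = None,
    grid: tuple[int, int] = (30, 45),
    kernel_sd: float = 1.0,
) -> AccuracyCurve:
    """Probability of choosing the currently better option across the block.

    Because reversal trials vary across blocks, each phase is linearly
    interpolated to a common length (acquisition then reversal) before
    averaging; the averaged curve is smoothed with a Gaussian kernel
    (sd in trials).  Interpolation preserves phase endpoint values exactly.
    """
    n_acq, n_rev = grid
    per_session = []
    for session in sessions:
        per_block = []
        for _, grp in _session_blocks(session, condition):
            choice = class_labels(grp, "choice")
            rev = grp["reversal_trial"].iloc[0]
            tib = grp["trial_in_block"].to_numpy()
            better0 = _infer_better(grp)
            better = np.where(tib < rev, better0, 3 - better0)
            correct = (choice == better).astype(float)
            parts = []
            for sel, n_out in ((tib < rev, n_acq), (tib >= rev, n_rev)):
                y = correct[sel]
                xi = np.linspace(0.0, 1.0, n_out)
                xo = np.linspace(0.0, 1.0, len(y)) if len(y) > 1 else [0.0]
                parts.append(np.interp(xi, xo, y))
            per_block.append(np.concatenate(parts))
        if per_block:
            per_session.append(np.mean(per_block, axis=0))
    if not per_session:
        raise ValueError("no blocks for accuracy curve")
    arr = np.stack(per_session)
    mean = _gaussian_smooth(arr.mean(axis=0), kernel_sd)
    sem = (arr.std(axis=0, ddof=1) / np.sqrt(len(arr))
           if len(arr) > 1 else np.zeros(arr.shape[1]))
    return AccuracyCurve(np.arange(1, n_acq + n_rev + 1), mean, sem, n_acq,
                         kernel_sd)


def _infer_better(grp: pd.DataFrame) -> int:
    """Initially better option of a block, inferred from reward frequencies
    per chosen option in the acquisition phase (the generator's schedule is
    not observable directly, matching real data)."""
    acq = grp[grp["phase"] == "acquisition"]
    choice = class_labels(acq, "choice")
    rates = []
    for cls in (1, 2):
        r = acq["reward"].to_numpy()[choice == cls]
        rates.append(r.mean() if len(r) else 0.0)
    return 1 if rates[0] >= rates[1] else 2


def trials_to_criterion(
    sessions: list[SessionData],
    condition: str | None = None,
    alpha: float = 0.05,
    max_trial: int | None = None,
) -> int | None:
    """First trial-in-phase at which accuracy exceeds chance.

    Pools acquisition-phase blocks across sessions; per trial index, a
    one-sided binomial test of choosing the better option against p = 0.5.
    Returns the first index with p < alpha, or None.
    """
    correct_by_trial: dict[int, list[int]] = {}
    n_blocks = 0
    for session in sessions:
        for _, grp in _session_blocks(session, condition):
            n_blocks += 1
            acq = grp[grp["phase"] == "acquisition"]
            choice = class_labels(acq, "choice")
            better0 = _infer_better(grp)
            for t, c in zip(acq["trial_in_phase"].to_numpy(), choice):
                correct_by_trial.setdefault(int(t), []).append(int(c == better0))
    if n_blocks < 2:
        raise ValueError("need at least two blocks")
    for t in sorted(correct_by_trial):
        if max_trial is not None and t > max_trial:
            break
        hits = correct_by_trial[t]
        p = stats.binomtest(sum(hits), len(hits), 0.5,
                            alternative="greater").pvalue
        if p < alpha:
            return t
    return None


# -- single-neuron screen --------------------------------------------------

def _design_matrices(trials: pd.DataFrame, value: np.ndarray):
    """Full design and per-factor reduced designs for the screen.

    Factors: block (categorical), image nested in block, direction, reward,
    and the continuous RW value of the choice.  Treatment coding; each
    factor's test drops its columns from the full design (extra
    sum-of-squares F-test).
    """
    n = len(trials)
    blocks = np.sort(trials["block_id"].unique())
    cols: dict[str, list[np.ndarray]] = {
        "block": [], "image": [], "direction": [], "reward": [], "value": []}
    for b in blocks[1:]:
        cols["block"].append((trials["block_id"] == b).to_numpy(float))
    for b in blocks:
        in_b = (trials["block_id"] == b).to_numpy()
        cols["image"].append(((trials["chosen_image"] == 2).to_numpy() & in_b
                              ).astype(float))
    cols["direction"].append((trials["chosen_direction"] == 2).to_numpy(float))
    cols["reward"].append(trials["reward"].to_numpy(float))
    cols["value"].append(value.astype(float))

    dropped = [name for name, cl in cols.items()
               if not any(np.ptp(c) > 0 for c in cl)]
    for name in dropped:
        warnings.warn(f"screen factor {name!r} is constant; dropped")
        del cols[name]
    factor_names = list(cols)
    full = np.column_stack([np.ones(n)] + [c for cl in cols.values() for c in cl])
    reduced = {}
    for name in factor_names:
        keep = [np.ones(n)]
        for other, cl in cols.items():
            if other != name:
                keep.extend(cl)
        reduced[name] = np.column_stack(keep)
    return full, reduced


def _rss(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, int]:
    """Residual sum of squares of OLS of each column of y on x, plus rank."""
    q, r = np.linalg.qr(x)
    rank = int((np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r).max())).sum())
    fitted = q @ (q.T @ y)
    resid = y - fitted
    return (resid**2).sum(axis=0), rank


def single_neuron_screen(
    session: SessionData,
    rw: RWFit | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fraction of neurons significant for each task factor per time bin.

    Conditions are screened separately (image identity is only meaningful
    within What blocks' labeling but the factor structure is shared).  Each
    neuron's counts in each bin are regressed on the full design; a factor
    is significant when its extra-sum-of-squares F-test has p < alpha.  No
    multiple-comparison correction is applied; on null data the expected
    fraction per factor is the nominal level alpha.
    """
    rows = []
    for condition in ("What", "Where"):
        sel = (session.trials["condition"] == condition).to_numpy()
        if not sel.any():
            continue
        trials = session.trials.loc[sel]
        fit = rw if rw is not None else rw_fit(session, condition)
        value = fit.values["v_chosen"].reindex(trials.index).to_numpy()
        full, reduced = _design_matrices(trials, value)
        n = len(trials)
        for b in range(session.n_bins):
            y = session.counts[:, sel, b].astype(float).T   # trials x neurons
            rss_full, rank_full = _rss(full, y)
            df_resid = n - rank_full
            if df_resid < 1:
                raise ValueError("design is saturated; no residual df")
            for name, xr in reduced.items():
                rss_red, rank_red = _rss(xr, y)
                df_num = rank_full - rank_red
                if df_num < 1:
                    warnings.warn(f"factor {name!r} rank-deficient; dropped")
                    continue
                f = ((rss_red - rss_full) / df_num) / (rss_full / df_resid)
                f = np.where(rss_full > 0, f, 0.0)
                p = stats.f.sf(f, df_num, df_resid)
                rows.append({
                    "condition": condition,
                    "bin": b,
                    "factor": name,
                    "fraction_significant": float((p < alpha).mean()),
                    "n_neurons": y.shape[1],
                })
    return pd.DataFrame(rows)
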