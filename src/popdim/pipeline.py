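"""End-to-end orchestration: simulate, analyze, and summarize a session.

Runs the full analysis chain on a generated session — behavior, mean and
discriminant matrices, spectral dimensionality (overall, per condition,
block-accumulation, first-PC-removed, cross-validated), cross-projection
information and decoding, learning curves — and repeats the dimensionality
and information analyses on reward-locked activity with trials relabeled by
outcome (the reward analyses reuse every choice-analysis operation through
the label adapter; no duplicated code paths).

The summary is a plain dict (JSON-serializable) and is bit-reproducible
from the configuration and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import behavior as bhv
from . import dimensionality as dim
from . import learning as lrn
from .information import pairing_report
from .io_core import save_session
from .subspaces import build_U, build_W, usable_blocks
from .synthetic import GeneratorConfig, simulate_session

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    seed: int = 0
    thresholds: tuple[float, ...] = (0.8, 0.9)
    n_resamples: int = 50
    min_trials: int = 4
    include_decode: bool = True
    include_reward: bool = True
    include_screen: bool = False
    max_learning_trial: int = 25
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        gen = GeneratorConfig(**raw.pop("generator", {}))
        return cls(generator=gen, **raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = dataclasses.asdict(self)
        with open(path, "w") as f:
            yaml.safe_dump(raw, f, sort_keys=True)


def _spectra_block(u, w, thresholds):
    out = {
        "U": dim.spectrum(u.matrix, thresholds=thresholds).dims_at_threshold,
        "W": dim.spectrum(w.matrix, thresholds=thresholds).dims_at_threshold,
    }
    for name, mat in (("U", u), ("W", w)):
        try:
            split = dim.condition_split_spectra(mat, thresholds=thresholds)
        except ValueError:
            continue
        for cond, res in split.items():
            out[f"{name}_{cond}"] = res.dims_at_threshold
        if name == "W":
            out["W_first_pc_removed"] = {
                cond: dim.spectrum(
                    dim.remove_first_pc(mat.submatrix(condition=cond)),
                    thresholds=thresholds,
                ).dims_at_threshold
                for cond in split
            }
    return {k: {str(t): v for t, v in d.items()} for k, d in out.items()}


def run_pipeline(config: RunConfig) -> dict:
    """Run the complete analysis pipeline and return the summary dict.

    When ``config.out_dir`` is set, the session, the per-pairing table, the
    learning curves and the JSON summary are written there.
    """
    t0 = time.time()
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)]
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    summary: dict = {"seed": config.seed, "stages": {}}

    def stage(name):
        summary["stages"][name] = round(time.time() - t0, 2)
        logger.info("stage %s done at %.1fs", name, time.time() - t0)

    session, truth = simulate_session(config.generator, seed=seeds[0])
    if out_dir:
        save_session(session, out_dir / "session.h5")
    stage("simulate")

    # behavior
    fit = bhv.rw_fit(session)
    curve = bhv.accuracy_curve([session])
    summary["behavior"] = {
        "alpha_hat": fit.alpha,
        "beta_hat": fit.beta,
        "log_likelihood": fit.log_likelihood,
        "accuracy_final_acquisition": float(curve.mean[curve.n_acquisition - 1]),
        "trials_to_criterion": {
            cond: bhv.trials_to_criterion([session], cond)
            for cond in ("What", "Where")
        },
    }
    if config.include_screen:
        screen = bhv.single_neuron_screen(session, rw=fit)
        summary["screen"] = screen.to_dict(orient="records")
    stage("behavior")

    # dimensionality
    blocks = usable_blocks(session, config.min_trials)
    u = build_U(session, blocks, config.min_trials)
    w = build_W(session, blocks, config.min_trials)
    summary["n_usable_blocks"] = len(blocks)
    summary["dims"] = _spectra_block(u, w, config.thresholds)
    summary["dims"]["W_vs_blocks"] = {
        cond: dim.dims_vs_blocks(w, 0.8, config.n_resamples, seeds[1],
                                 condition=cond).mean.tolist()
        for cond in ("What", "Where")
    }
    cv = dim.crossval_variance(session, blocks, n_folds=20, seed=seeds[2],
                               min_trials=config.min_trials)
    summary["dims"]["crossval_final_fraction"] = float(cv["cumulative"][-1])
    stage("dimensionality")

    # information / decoding
    report = pairing_report(session, w=w,
                                 include_decode=config.include_decode,
                                 min_trials=config.min_trials)
    if out_dir:
        report.to_csv(out_dir / "pairing_report.csv", index=False)
    pooled = (report.groupby(["condition", "pairing"])
              [["information", "predicted_error", "fraction_correct",
                "signal", "noise", "principal_angle_deg"]]
              .mean(numeric_only=True))
    summary["information"] = {
        f"{cond}/{pairing}": {k: (None if np.isnan(v) else float(v))
                              for k, v in row.items()}
        for (cond, pairing), row in pooled.iterrows()
    }
    stage("information")

    # learning dynamics
    curves = lrn.learning_curves(session, w=w,
                                 max_trial=config.max_learning_trial)
    if out_dir:
        curves.to_csv(out_dir / "learning_curves.csv", index=False)
    summary["learning"] = {
        f"{cond}/{sub}": grp.sort_values("trial")["delta_information"].tolist()
        for (cond, sub), grp in curves.groupby(["condition", "subspace"])
    }
    stage("learning")

    # reward-locked analyses via the outcome label adapter
    if config.include_reward:
        r_session, _ = simulate_session(config.generator, seed=seeds[0],
                                        alignment="reward")
        r_blocks = usable_blocks(r_session, config.min_trials,
                                 label_mode="reward")
        if r_blocks:
            r_u = build_U(r_session, r_blocks, config.min_trials,
                          label_mode="reward")
            r_w = build_W(r_session, r_blocks, config.min_trials,
                          label_mode="reward")
            summary["reward"] = {
                "n_usable_blocks": len(r_blocks),
                "dims": _spectra_block(r_u, r_w, config.thresholds),
            }
            r_report = pairing_report(r_session, w=r_w,
                                           label_mode="reward",
                                           include_decode=config.include_decode,
                                           min_trials=config.min_trials)
            r_pooled = (r_report.groupby(["condition", "pairing"])
                        ["information"].mean())
            summary["reward"]["information"] = {
                f"{c}/{p}": float(v) for (c, p), v in r_pooled.items()
            }
        stage("reward")

    summary["runtime_s"] = round(time.time() - t0, 2)
    if out_dir:
        with open(out_dir / "summary.json", "w") as f:
            json.dump(summary, f, indent=2, sort_keys=True)
    return summary
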