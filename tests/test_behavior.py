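import dataclasses

import numpy as np
import pytest

from popdim.behavior import (
    accuracy_curve,
    rw_fit,
    rw_values,
    single_neuron_screen,
    trials_to_criterion,
)
from popdim.synthetic import GeneratorConfig, simulate_session


class TestRWValues:
    def test_memoryless_limit_tracks_last_outcome(self):
        choices = np.array([1, 1, 2, 1, 2])
        rewards = np.array([1, 0, 1, 1, 0])
        v = rw_values(choices, rewards, alpha=1.0)
        # after each update the chosen option's value equals its last reward
        assert v[2, 0] == 0.0 and v[3, 1] == 1.0 and v[4, 0] == 1.0

    def test_constant_reward_geometric_closed_form(self):
        n = 6
        choices = np.ones(n, dtype=int)
        rewards = np.ones(n, dtype=int)
        v = rw_values(choices, rewards, alpha=0.5)
        # value before trial t+1 is 1 - 0.5^t starting from v0 = 0.5
        for t in range(n):
            assert v[t, 0] == pytest.approx(1 - 0.5 ** (t + 1) * 2 * 0.5)
        assert v[-1, 0] == pytest.approx(1 - 0.5 ** n * 2 * 0.5)

    def test_values_bounded_in_unit_interval(self):
        rng = np.random.default_rng(0)
        choices = rng.integers(1, 3, 100)
        rewards = rng.integers(0, 2, 100)
        v = rw_values(choices, rewards, alpha=0.9)
        assert (v >= 0).all() and (v <= 1).all()

    def test_option_relabeling_permutes_value_series(self):
        rng = np.random.default_rng(1)
        choices = rng.integers(1, 3, 50)
        rewards = rng.integers(0, 2, 50)
        v = rw_values(choices, rewards, alpha=0.4)
        v_swapped = rw_values(3 - choices, rewards, alpha=0.4)
        np.testing.assert_allclose(v, v_swapped[:, ::-1])


class TestRWFit:
    def test_recovers_simulated_learning_rate(self):
        errs = []
        for seed in range(3):
            session, _ = simulate_session(
                GeneratorConfig(n_neurons=100, n_blocks_per_condition=6),
                seed=700 + seed)
            fit = rw_fit(session)
            errs.append(abs(fit.alpha - 0.3))
        assert np.mean(errs) < 0.1

    def test_log_likelihood_is_negative_and_value_table_aligned(self, tiny):
        session, _ = tiny
        fit = rw_fit(session)
        assert fit.log_likelihood < 0
        assert len(fit.values) == session.n_trials
        assert (fit.values["v_chosen"].between(0, 1)).all()


class TestAccuracyCurve:
    def test_random_agent_stays_near_chance(self):
        cfg = GeneratorConfig(n_neurons=60, n_blocks_per_condition=4)
        session, _ = simulate_session(cfg, seed=7, policy="random")
        curve = accuracy_curve([session])
        assert abs(curve.mean.mean() - 0.5) < 0.06

    def test_learning_agent_shows_reversal_dip_and_recovery(self):
        sessions = [simulate_session(GeneratorConfig(), seed=800 + s)[0]
                    for s in range(3)]
        curve = accuracy_curve(sessions)
        n_acq = curve.n_acquisition
        late_acq = curve.mean[n_acq - 5: n_acq].mean()
        early_rev = curve.mean[n_acq: n_acq + 3].mean()
        late_rev = curve.mean[-10:].mean()
        assert late_acq > 0.65
        assert early_rev < late_acq - 0.1   # dip right after the flip
        assert late_rev > early_rev + 0.1   # and recovery
        assert curve.mean.min() >= 0 and curve.mean.max() <= 1

    def test_unsmoothed_endpoints_equal_block_averages(self):
        session, _ = simulate_session(
            GeneratorConfig(n_neurons=60, n_blocks_per_condition=3), seed=9)
        curve = accuracy_curve([session], condition="What", kernel_sd=0.0)
        t = session.trials[session.trials.condition == "What"]
        first = []
        for _, grp in t.groupby("block_id"):
            from popdim.io_core import class_labels
            from popdim.behavior import _infer_better
            acq = grp[grp.phase == "acquisition"]
            first.append(float(class_labels(acq).iloc[0] if hasattr(
                class_labels(acq), "iloc") else class_labels(acq)[0]
                == _infer_better(grp)))
        assert curve.mean[0] == pytest.approx(np.mean(first))


class TestTrialsToCriterion:
    def test_perfect_agent_reaches_criterion_immediately(self):
        cfg = GeneratorConfig(n_neurons=100, n_blocks_per_condition=6)
        session, _ = simulate_session(cfg, seed=11, policy="optimal")
        assert trials_to_criterion([session], "What") == 1

    def test_random_agent_never_reaches_criterion(self):
        cfg = GeneratorConfig(n_neurons=100, n_blocks_per_condition=6)
        session, _ = simulate_session(cfg, seed=12, policy="random")
        assert trials_to_criterion([session], "What", max_trial=25) is None

    def test_learning_agent_reaches_criterion_early(self):
        sessions = [simulate_session(GeneratorConfig(), seed=900 + s)[0]
                    for s in range(2)]
        for cond in ("What", "Where"):
            t = trials_to_criterion(sessions, cond)
            assert t is not None and t <= 10


class TestSingleNeuronScreen:
    def test_direction_loading_dominates_in_where_blocks(self, default_session):
        session, _ = default_session
        screen = single_neuron_screen(session)
        where = screen[screen.condition == "Where"]
        direction = where[where.factor == "direction"]["fraction_significant"].mean()
        image = where[where.factor == "image"]["fraction_significant"].mean()
        assert direction > image + 0.2

    def test_matches_statsmodels_f_test(self, default_session):
        """The vectorized extra-sum-of-squares F-test agrees with a per-model
        statsmodels Wald F-test on the same design."""
        import statsmodels.api as sm
        from popdim.behavior import _design_matrices, _rss, rw_fit
        from scipy import stats

        session, _ = default_session
        sel = (session.trials.condition == "What").to_numpy()
        trials = session.trials.loc[sel]
        fit = rw_fit(session, "What")
        value = fit.values["v_chosen"].reindex(trials.index).to_numpy()
        full, reduced = _design_matrices(trials, value)
        y = session.counts[:5, sel, 0].astype(float).T
        rss_full, rank_full = _rss(full, y)
        df_resid = len(trials) - rank_full
        for name in ("direction", "reward", "value"):
            rss_red, rank_red = _rss(reduced[name], y)
            f_mine = ((rss_red - rss_full) / (rank_full - rank_red)) / \
                (rss_full / df_resid)
            p_mine = stats.f.sf(f_mine, rank_full - rank_red, df_resid)
            for j in range(y.shape[1]):
                res = sm.OLS(y[:, j], full).fit()
                # restriction: the dropped column(s) are zero
                drop = [i for i in range(full.shape[1])
                        if not any(np.allclose(full[:, i], reduced[name][:, k])
                                   for k in range(reduced[name].shape[1]))]
                r = np.zeros((len(drop), full.shape[1]))
                for row, i in enumerate(drop):
                    r[row, i] = 1.0
                ftest = res.f_test(r)
                assert p_mine[j] == pytest.approx(float(ftest.pvalue), abs=1e-8)

    def test_finer_bins_reduce_significant_fractions(self):
        base = GeneratorConfig(n_neurons=100, n_blocks_per_condition=6)
        coarse, _ = simulate_session(base, seed=21)
        fine, _ = simulate_session(
            dataclasses.replace(base, bin_ms=125.0, n_bins=4), seed=21)
        s_coarse = single_neuron_screen(coarse)
        s_fine = single_neuron_screen(fine)
        sig = ["direction", "image", "value"]
        f_coarse = s_coarse[s_coarse.factor.isin(sig)]["fraction_significant"].mean()
        f_fine = s_fine[s_fine.factor.isin(sig)]["fraction_significant"].mean()
        assert f_fine < f_coarse
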