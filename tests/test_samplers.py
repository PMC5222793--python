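"""Adaptive samplers: staircase arithmetic, Psi/qCSF entropy scores, FIG."""

import math

import numpy as np
import pytest

from csfbayes.engine import (EngineConfig, TrialRecord, build_prior,
                             entropy, infer, likelihood_surface,
                             point_estimate)
from csfbayes.model import ObserverParams, Stimulus, StimulusGrid, detect_prob
from csfbayes.observer import SimulatedObserver, preset
from csfbayes.samplers import (STAIRCASE_CONVERGENCE_P, FigSampler, PsiSampler,
                               QcsfSampler, StaircaseSampler, _PsiRun,
                               make_sampler, prior_mean_params)


def rng(seed=0):
    return np.random.default_rng(seed)


def _drive(sampler, observer_params, budget, seed=0):
    obs = SimulatedObserver(observer_params, rng(seed))
    trials = []
    for t in range(budget):
        stim = sampler.propose()
        tr = TrialRecord(t, stim, obs.respond(stim))
        sampler.observe(tr)
        trials.append(tr)
    return trials


class TestStaircase:
    def _fresh(self, budget=108, seed=1, **kw):
        return StaircaseSampler(StimulusGrid(), budget, rng(seed), **kw)

    def test_down_step_after_positive(self):
        s = self._fresh()
        i = 5  # some sf index
        f = float(s.stim_grid.sfs[i])
        s.counts[i] = 4  # warmup finished
        s.level[i] = 0.1
        s.observe(TrialRecord(0, Stimulus(f, 0.1), 1))
        # 0.1 * 0.9 = 0.09 -> nearest log10 grid node
        assert s.level[i] == pytest.approx(0.09)
        assert s.stim_grid.snap_contrast(s.level[i]) == pytest.approx(10 ** -1.04)

    def test_up_then_down_from_0p1(self):
        s = self._fresh()
        i = 3
        f = float(s.stim_grid.sfs[i])
        s.counts[i] = 4
        s.level[i] = 0.1
        s.observe(TrialRecord(0, Stimulus(f, 0.1), 0))
        s.observe(TrialRecord(1, Stimulus(f, s.level[i]), 1))
        assert s.level[i] == pytest.approx(0.1 * (4 / 3) * 0.9)
        assert s.stim_grid.snap_contrast(s.level[i]) == pytest.approx(10 ** -0.92)

    def test_warmup_uses_cubed_factors(self):
        s = self._fresh()
        i = 0
        f = float(s.stim_grid.sfs[i])
        start = s.level[i]
        s.observe(TrialRecord(0, Stimulus(f, start), 0))
        assert s.level[i] == pytest.approx(start * (4 / 3) ** 3)
        s.observe(TrialRecord(1, Stimulus(f, s.level[i]), 1))
        assert s.level[i] == pytest.approx(start * (4 / 3) ** 3 * 0.9 ** 3)

    def test_all_positive_run_is_monotone_non_increasing(self):
        s = self._fresh(budget=24)
        seen = {}
        for t in range(24):
            stim = s.propose()
            prev = seen.setdefault(stim.sf, stim.contrast)
            assert stim.contrast <= prev + 1e-12
            seen[stim.sf] = stim.contrast
            s.observe(TrialRecord(t, stim, 1))

    def test_threshold_arithmetic_and_warmup_exclusion(self):
        s = self._fresh()
        i = 7
        f = float(s.stim_grid.sfs[i])
        # warmup contrasts must not affect the estimate
        for warm in ([1.0] * 4, [0.001] * 4):
            s.log_history[i] = [math.log(c) for c in warm + [0.01, 0.02, 0.04, 0.08]]
            expected = 1.0 / math.exp(np.mean(np.log([0.01, 0.02, 0.04, 0.08])))
            assert s.threshold(f) == pytest.approx(expected, rel=1e-12)
        s.log_history[i] = [0.0] * 4 + [math.log(0.01)] * 5
        assert s.threshold(f) == pytest.approx(100.0, rel=1e-12)

    def test_threshold_requires_post_warmup_trials(self):
        s = self._fresh()
        s.log_history[0] = [0.0] * 4
        with pytest.raises(ValueError):
            s.threshold(float(s.stim_grid.sfs[0]))

    def test_interleaving_allocates_budget_evenly(self):
        s = self._fresh(budget=108)
        counts = np.bincount(s.schedule, minlength=12)
        assert np.all(counts == 9)
        s2 = self._fresh(budget=50, seed=4)
        counts = np.bincount(s2.schedule, minlength=12)
        assert counts.sum() == 50
        assert set(counts) <= {4, 5}

    def test_proposals_on_grid_and_clamped(self):
        s = self._fresh(budget=60, seed=3)
        obs = preset("amblyope")
        for tr in _drive(s, obs, 60, seed=5):
            assert 0.001 <= tr.stim.contrast <= 1.0
            assert np.isclose(s.stim_grid.contrasts, tr.stim.contrast).any()
            assert np.isclose(s.stim_grid.sfs, tr.stim.sf).any()

    def test_long_run_converges_near_weighted_updown_point(self):
        # single-frequency staircase against a lapse-free logistic observer:
        # the long-run mean log contrast sits at the ~0.73 detection point
        sg = StimulusGrid(sfs=np.array([3.2]))
        theta = ObserverParams(M=100, A=0.8, F=4.0, beta=4.0, gamma=0.5,
                               delta=1e-9)
        s = StaircaseSampler(sg, 10_000, rng(2))
        trials = _drive(s, theta, 10_000, seed=7)
        tail = np.log([t.stim.contrast for t in trials[200:]])
        # contrast where detection probability equals the equilibrium p*
        pstar = STAIRCASE_CONVERGENCE_P
        alpha = 1.0 / (100 * 3.2 ** 0.8 * math.exp(-3.2 / 4))
        c_star = alpha * math.exp(math.log(
            (pstar - 0.5) / (0.5 - (pstar - 0.5))) / 4.0)
        err_db = 20 * abs(np.mean(tail) - math.log(c_star)) / math.log(10)
        assert err_db < 1.0


class TestPsi:
    def test_point_mass_posterior_ties_all_contrasts(self):
        run = _PsiRun(StimulusGrid().contrasts, prior_alpha_mean=-2.0)
        run.w[:] = 0.0
        run.w[100] = 1.0
        gains = run.info_gain()
        assert np.all(np.abs(gains) < 1e-12)
        picks = {run.propose_index(rng(k)) for k in range(30)}
        assert len(picks) > 5  # uniform tie-breaking explores the grid

    def test_two_node_toy_matches_brute_force_expected_entropy(self):
        contrasts = np.array([0.01, 0.1, 0.9])
        run = _PsiRun(contrasts, prior_alpha_mean=-1.0, n_alpha=2, n_beta=1)
        run.w = np.array([0.5, 0.5])
        # independent two-branch expected entropy, straight from definitions
        def expected_entropy(ci):
            P = run.P[ci]
            outs = []
            for r, lik in ((1, P), (0, 1 - P)):
                w = run.w * lik
                s = w.sum()
                w = w / s
                h = -(w[w > 0] * np.log(w[w > 0])).sum()
                outs.append((s, h))
            return sum(s * h for s, h in outs)
        brute = np.array([expected_entropy(i) for i in range(3)])
        h_now = -(run.w * np.log(run.w)).sum()
        mi = run.info_gain()
        assert np.allclose(h_now - mi, brute, atol=1e-12)
        assert run.propose_index(rng(0)) == int(np.argmin(brute))

    def test_selected_contrast_never_increases_expected_entropy(self):
        run = _PsiRun(StimulusGrid().contrasts, prior_alpha_mean=-2.0)
        r = rng(3)
        for t in range(20):
            gains = run.info_gain()
            assert gains.max() >= -1e-12  # information never hurts in expectation
            ci = run.propose_index(r)
            assert gains[ci] == pytest.approx(gains.max())
            run.observe(ci, int(r.random() < 0.7))

    def test_threshold_sensitivity_examples(self):
        run = _PsiRun(StimulusGrid().contrasts, prior_alpha_mean=-2.0,
                      n_alpha=5, n_beta=1)
        run.alpha_axis = np.linspace(-3, -1, 5)
        run.w = np.zeros(5)
        run.w[2] = 1.0  # point mass at alpha = -2
        assert run.threshold_sensitivity() == pytest.approx(100.0)
        run.w = np.array([0.5, 0, 0, 0, 0.5])  # alpha in {-3, -1}
        assert run.threshold_sensitivity() == pytest.approx(100.0)

    def test_schedule_respected_and_even(self):
        s = PsiSampler(StimulusGrid(), 48, rng(1))
        trials = _drive(s, preset("normal"), 48, seed=2)
        per_sf = {}
        for tr in trials:
            per_sf[tr.stim.sf] = per_sf.get(tr.stim.sf, 0) + 1
        assert all(v == 4 for v in per_sf.values()) and len(per_sf) == 12

    def test_threshold_requires_trials(self):
        s = PsiSampler(StimulusGrid(), 12, rng(1))
        with pytest.raises(ValueError):
            s.threshold(0.5)


class TestQcsf:
    def _small(self, seed=0, **kw):
        kw.setdefault("selection_grid_sizes", (8, 8, 8, 3, 3))
        kw.setdefault("candidate_subsample", 25)
        return QcsfSampler(StimulusGrid(), 108, rng(seed), **kw)

    def test_info_gain_matches_kernel_path(self):
        s = self._small(seed=5)
        _drive(s, preset("normal"), 15, seed=6)
        grid = s.posterior.grid
        mass = s.posterior.mass.reshape(-1, grid.sizes[3], grid.sizes[4])
        from csfbayes.samplers import _qcsf_predictives, _binary_entropy
        idx = np.arange(0, len(s._stimuli), 97)
        p1, hterm = _qcsf_predictives(mass, s._ln_s_table,
                                      s._cand_sf_idx[idx], s._cand_lnc[idx],
                                      grid.beta_lin, grid.range_coef, grid.gamma)
        kernel_scores = _binary_entropy(p1) - hterm
        direct = np.array([s.info_gain(s._stimuli[i]) for i in idx])
        assert np.allclose(kernel_scores, direct, atol=1e-10)

    def test_expected_entropy_not_above_current(self):
        s = self._small(seed=2)
        h_now = entropy(s.posterior)
        for i in range(0, len(s._stimuli), 211):
            assert s.expected_posterior_entropy(s._stimuli[i]) <= h_now + 1e-9

    def test_three_candidate_toy_against_hand_computation(self):
        s = self._small(seed=1)
        _drive(s, preset("normal"), 10, seed=3)
        cands = [Stimulus(3.2, 0.005), Stimulus(3.2, 0.02), Stimulus(22.6, 1.0)]
        # hand-computed two-branch expected entropies from the raw surfaces
        brute = []
        for stim in cands:
            P = likelihood_surface(s.posterior.grid, stim).ravel()
            w = s.posterior.mass.ravel()
            eh = 0.0
            for lik in (P, 1 - P):
                ww = w * lik
                tot = ww.sum()
                ww = ww / tot
                eh += tot * float(-(ww[ww > 0] * np.log(ww[ww > 0])).sum())
            brute.append(eh)
        computed = [s.expected_posterior_entropy(c) for c in cands]
        assert np.allclose(computed, brute, atol=1e-10)

    def test_point_mass_posterior_ties_uniformly(self):
        s = self._small(seed=9, candidate_subsample=None)
        s.posterior.mass[:] = 0.0
        s.posterior.mass[4, 4, 4, 1, 1] = 1.0
        gains = [s.info_gain(s._stimuli[i]) for i in range(0, 1812, 151)]
        assert np.all(np.abs(gains) < 1e-12)

    def test_proposals_on_grid(self):
        s = self._small(seed=4)
        for tr in _drive(s, preset("normal"), 20, seed=5):
            assert np.isclose(s.stim_grid.contrasts, tr.stim.contrast).any()


class TestFig:
    def _sampler(self, seed=0, **kw):
        kw.setdefault("engine_config", EngineConfig(grid_sizes=(10, 10, 10, 4, 4)))
        return FigSampler(StimulusGrid(), 108, rng(seed), **kw)

    def test_initial_matrix_is_ridge(self):
        s = self._sampler()
        assert np.allclose(s.J, 1e-8 * np.eye(4))

    def test_information_matrix_psd_and_det_monotone(self):
        s = self._sampler(seed=3)
        dets = [np.linalg.det(s.J)]
        for tr in _drive(s, preset("normal"), 30, seed=4):
            pass
        # replay growth with fresh sampler to capture dets each step
        s = self._sampler(seed=3)
        obs = SimulatedObserver(preset("normal"), rng(4))
        for t in range(30):
            stim = s.propose()
            s.observe(TrialRecord(t, stim, obs.respond(stim)))
            eig = np.linalg.eigvalsh((s.J + s.J.T) / 2)
            assert np.all(eig > -1e-12)
            dets.append(np.linalg.det(s.J))
        assert all(b >= a - 1e-15 for a, b in zip(dets, dets[1:]))

    def test_theta_hat_tracks_engine_point_estimate(self):
        s = self._sampler(seed=6)
        cfg = EngineConfig(grid_sizes=(10, 10, 10, 4, 4))
        trials = _drive(s, preset("normal"), 12, seed=7)
        independent = point_estimate(infer(trials, cfg))
        online = point_estimate(s.posterior)
        assert np.allclose(online.log10_means, independent.log10_means, atol=1e-10)

    def test_zero_gradient_candidate_excluded_from_top(self):
        s = self._sampler(seed=1)
        theta = point_estimate(s.posterior).params
        P, g = s._grad_and_p(theta)
        info = s.candidate_info(P, g)
        scores = np.linalg.det(s.J[None] + info)
        # a saturated candidate (P ~ gamma, zero gradient) scores only det(J)
        dead = np.argmin(np.abs(P - theta.gamma))
        assert scores[dead] <= np.partition(scores, -200)[-200]

    def test_single_parameter_reduction_matches_brute_force_scan(self):
        # only M free: the top-information contrast at fixed sf must match an
        # exhaustive scalar Fisher information scan over all 151 contrasts
        sg = StimulusGrid(sfs=np.array([3.2]))
        cfg = EngineConfig(grid_sizes=(16, 1, 1, 1, 1))
        s = FigSampler(sg, 10, rng(0), engine_config=cfg)
        theta = point_estimate(s.posterior).params
        P, g = s._grad_and_p(theta)
        fisher_m = g[:, 0] ** 2 / (P * (1 - P))
        brute = np.empty(151)
        for i, c in enumerate(sg.contrasts):
            h = 1e-6
            p0 = detect_prob(Stimulus(3.2, float(c)),
                             theta.with_(M=10 ** (math.log10(theta.M) - h)))
            p1 = detect_prob(Stimulus(3.2, float(c)),
                             theta.with_(M=10 ** (math.log10(theta.M) + h)))
            p = detect_prob(Stimulus(3.2, float(c)), theta)
            brute[i] = ((p1 - p0) / (2 * h)) ** 2 / (p * (1 - p))
        assert np.argmax(fisher_m) == np.argmax(brute)
        assert np.allclose(fisher_m, brute, rtol=1e-4)

    def test_top_decile_selection_uniform(self):
        s = self._sampler(seed=2)
        theta = point_estimate(s.posterior).params
        P, g = s._grad_and_p(theta)
        info = s.candidate_info(P, g)
        scores = np.linalg.det(s.J[None] + info)
        k = int(math.ceil(0.10 * scores.size))
        top = set(np.argpartition(scores, scores.size - k)[scores.size - k:])
        r = rng(11)
        picks = []
        for _ in range(1000):
            stim = s.propose()
            i = int(np.flatnonzero((s._cand_sf == stim.sf)
                                   & (s._cand_c == stim.contrast))[0])
            picks.append(i)
        assert set(picks) <= top
        # frequency approximately uniform over the top set (binomial error)
        counts = np.bincount(picks, minlength=scores.size)[list(top)]
        expected = 1000 / k
        assert counts.max() <= expected + 5 * math.sqrt(expected)


class TestFactory:
    def test_factory_names(self):
        sg = StimulusGrid()
        for name, cls in [("staircase", StaircaseSampler), ("psi", PsiSampler)]:
            assert isinstance(make_sampler(name, sg, 12, rng(0)), cls)
        with pytest.raises(ValueError, match="staircase"):
            make_sampler("quest", sg, 12, rng(0))

    def test_prior_mean_params(self):
        p = prior_mean_params()
        assert p.M == pytest.approx(100.0)
        assert p.A == pytest.approx(10 ** -0.30)
        assert p.F == pytest.approx(10 ** 0.78)

    def test_fixed_seed_reproduces_trial_sequence(self):
        for name in ("staircase", "psi"):
            sg = StimulusGrid()
            a = _drive(make_sampler(name, sg, 36, rng(42)), preset("normal"), 36, seed=9)
            b = _drive(make_sampler(name, sg, 36, rng(42)), preset("normal"), 36, seed=9)
            assert [(t.stim.sf, t.stim.contrast, t.response) for t in a] == \
                   [(t.stim.sf, t.stim.contrast, t.response) for t in b]
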