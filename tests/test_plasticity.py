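"""STDP windows, neuromodulatory gating, pairing traces, eligibility, rules."""

import numpy as np
import pytest

from snplast import plasticity as pl
from snplast.plasticity import (
    DynamicReward,
    NegativeFeedback,
    PairingTraces,
    RStdp,
    SnPlast,
    TrialOutcome,
)


class TestWindows:
    def test_symmetric_window_values(self):
        assert pl.stdp_window(0.0) == 1.0
        assert pl.stdp_window(0.010) == pytest.approx(np.e**-1)
        assert pl.stdp_window(-0.010) == pytest.approx(np.e**-1)
        assert pl.stdp_window(0.100) == pytest.approx(np.e**-10)

    def test_asymmetric_window_cases(self):
        assert pl.asymmetric_window(0.0, 1.0, -0.5) == pytest.approx(0.25)
        assert pl.asymmetric_window(0.010, 1.0, -0.5) == pytest.approx(np.e**-1)
        assert pl.asymmetric_window(-0.010, 1.0, -0.5) == pytest.approx(-0.5 * np.e**-1)

    def test_antisymmetric_window_integrates_to_zero(self):
        fwd = np.linspace(1e-6, 0.2, 50000)
        s = np.concatenate([-fwd[::-1], [0.0], fwd])
        vals = pl.asymmetric_window(s, 1.0, -1.0)
        # window mass scale is 2*tau = 0.02; the integral cancels exactly
        assert np.trapezoid(vals, s) == pytest.approx(0.0, abs=1e-12)

    def test_neuromod_gate(self):
        assert pl.neuromod_gate(False, True, 0.002, 0.01) == (-1, 0.002)
        assert pl.neuromod_gate(False, False, 0.002, 0.01) == (0, 0.0)
        assert pl.neuromod_gate(True, True, 0.002, 0.01) == (1, 0.01)
        assert pl.neuromod_gate(True, False, 0.002, 0.01) == (1, 0.01)


class TestEligibilityDecay:
    def test_exponential_decay_with_alpha(self):
        e = np.array([1.0, 2.0])
        out = pl.eligibility_decay(e, dt=2.0, alpha=1)
        assert np.allclose(out, e * np.e**-1)

    def test_alpha_zero_is_identity(self):
        e = np.array([1.0, 2.0])
        assert pl.eligibility_decay(e, dt=10.0, alpha=0) is e
        assert pl.eligibility_decay(e, dt=0.0, alpha=1) is e


class TestPairingTraces:
    def test_matches_direct_double_sum(self, rng):
        """Trace accumulation equals the explicit sum over all spike pairs."""
        dt = 1e-3
        n_steps = 400
        pre = rng.random(n_steps) < 0.25
        post = rng.random(n_steps) < 0.08
        traces = PairingTraces(n_pre=1, n_post=1)
        total = 0.0
        for n in range(n_steps):
            total += traces.step([pre[n]], [post[n]], dt)[0, 0]
        pre_t = np.nonzero(pre)[0] * dt
        post_t = np.nonzero(post)[0] * dt
        direct = pl.pair_sum(pre_t, post_t, pl.stdp_window)
        assert total == pytest.approx(direct, rel=1e-9)

    def test_single_pair_examples(self):
        traces = PairingTraces(n_pre=1, n_post=1)
        inc = traces.step([1], [0], 1e-3)
        assert inc[0, 0] == 0.0
        for _ in range(9):
            inc = traces.step([0], [0], 1e-3)
        inc = traces.step([0], [1], 1e-3)  # post 10 ms after pre
        assert inc[0, 0] == pytest.approx(np.e**-1)

    def test_same_bin_pair_counts_w0(self):
        traces = PairingTraces(n_pre=1, n_post=1)
        inc = traces.step([1], [1], 1e-3)
        assert inc[0, 0] == pytest.approx(1.0)

    def test_far_pairs_contribute_negligibly(self):
        """Pairs 100 ms apart fall below 5e-5 (the de facto cutoff)."""
        traces = PairingTraces(n_pre=1, n_post=1)
        traces.step([1], [0], 1e-3)
        for _ in range(99):
            traces.step([0], [0], 1e-3)
        inc = traces.step([0], [1], 1e-3)
        assert 0.0 < inc[0, 0] < 5e-5

    def test_accumulation_is_linear_in_spike_sets(self, rng):
        """Accumulating P1 then P2 equals accumulating P1 union P2."""
        dt = 1e-3
        n_steps = 300
        pre1 = rng.random(n_steps) < 0.1
        pre2 = rng.random(n_steps) < 0.1
        post = rng.random(n_steps) < 0.1

        def run(pre_counts):
            tr = PairingTraces(n_pre=1, n_post=1)
            return sum(tr.step([pre_counts[n]], [post[n]], dt)[0, 0]
                       for n in range(n_steps))

        together = run(pre1.astype(int) + pre2.astype(int))
        assert together == pytest.approx(run(pre1) + run(pre2), rel=1e-9)


class TestRetroactiveConversion:
    """The headline mechanism: dopamine converts cholinergic depression into
    potentiation through the decayed eligibility trace."""

    def test_closed_form_net_change_for_single_pairing(self):
        eta_ach, eta_da, tau_e = 0.002, 0.01, 2.0
        lag = 0.004  # pre->post lag, window value W
        w_window = pl.stdp_window(lag)
        for delay in (0.1, 0.5, 1.0, 2.0, 5.0):
            w0 = 2.0
            # online depression at pairing time
            w1 = w0 - eta_ach * w_window
            # dopaminergic potentiation of the decayed trace at reward
            elig = w_window * np.exp(-delay / tau_e)
            w2 = w1 + eta_da * elig
            net_change = -eta_ach * w_window + eta_da * w_window * np.exp(-delay / tau_e)
            assert w2 - w0 == pytest.approx(net_change, abs=1e-15)

    def test_conversion_positive_iff_reward_soon_enough(self):
        eta_ach, eta_da, tau_e = 0.002, 0.01, 2.0
        cutoff = tau_e * np.log(eta_da / eta_ach)
        for delay in (0.5 * cutoff, 0.9 * cutoff):
            assert -eta_ach + eta_da * np.exp(-delay / tau_e) > 0
        for delay in (1.1 * cutoff, 2 * cutoff):
            assert -eta_ach + eta_da * np.exp(-delay / tau_e) < 0


class TestRules:
    W_MIN, W_MAX = 1.0, 3.0

    def _mask(self, shape):
        return np.ones(shape, dtype=bool)

    def test_snplast_reward_applies_eta_da_times_trace(self):
        rule = SnPlast(ach=True, eta_ach=0.002, eta_da=0.01)
        w = np.full((2, 2), 2.0)
        elig = np.array([[1.0, 0.0], [0.0, 500.0]])
        out = rule.end_of_trial(w, elig, TrialOutcome(True),
                                self.W_MIN, self.W_MAX, self._mask((2, 2)))
        assert out[0, 0] == pytest.approx(2.01)
        assert out[1, 1] == self.W_MAX  # clipped

    def test_snplast_unrewarded_trial_leaves_weights(self):
        rule = SnPlast(ach=False, eta_ach=0.002, eta_da=0.01)
        w = np.full((2, 2), 2.0)
        out = rule.end_of_trial(w, np.ones((2, 2)), TrialOutcome(False),
                                self.W_MIN, self.W_MAX, self._mask((2, 2)))
        assert np.array_equal(out, w)
        assert rule.online_rate == 0.0  # no depression either

    def test_rstdp_gates_on_reward(self):
        rule = RStdp(a_pp=1.0, a_pn=-0.5)
        w = np.full((2, 2), 2.0)
        elig = np.full((2, 2), 10.0)
        same = rule.end_of_trial(w, elig, TrialOutcome(False),
                                 self.W_MIN, self.W_MAX, self._mask((2, 2)))
        assert np.array_equal(same, w)
        up = rule.end_of_trial(w, elig, TrialOutcome(True),
                               self.W_MIN, self.W_MAX, self._mask((2, 2)))
        assert np.allclose(up, np.minimum(2.0 + 0.01 * 10.0, self.W_MAX))

    def test_masked_entries_stay_frozen_at_zero(self):
        rule = SnPlast(ach=True, eta_ach=0.002, eta_da=0.01)
        mask = np.array([[True, False]])
        w = np.array([[2.0, 0.0]])
        out = rule.end_of_trial(w, np.full((1, 2), 100.0), TrialOutcome(True),
                                self.W_MIN, self.W_MAX, mask)
        assert out[0, 1] == 0.0

    def test_dynamic_reward_signal_recursion(self):
        rule = DynamicReward(beta=0.75)
        assert rule.signal(0) == 0.0  # Rbar(1) = R(1) forces rho(1) = 0
        assert rule.signal(1) == pytest.approx(0.25)  # Rbar(2) = 0.75

    def test_dynamic_reward_first_trial_is_neutral_for_any_outcome(self):
        for r in (0, 1):
            rule = DynamicReward()
            assert rule.signal(r) == 0.0

    def test_dynamic_reward_saturates_under_constant_success(self):
        rule = DynamicReward(beta=0.75)
        vals = [rule.signal(1) for _ in range(20)]
        assert vals[-1] == pytest.approx(0.0, abs=1e-10)
        assert all(v >= 0 for v in vals)

    def test_dynamic_reward_depresses_after_omission(self):
        rule = DynamicReward(beta=0.75)
        for _ in range(10):
            rule.signal(1)
        w = np.full((1, 1), 2.0)
        out = rule.end_of_trial(w, np.full((1, 1), 10.0), TrialOutcome(False),
                                self.W_MIN, self.W_MAX, self._mask((1, 1)))
        assert out[0, 0] < 2.0

    def test_negative_feedback_three_outcomes(self):
        rule = NegativeFeedback()
        w = np.full((1, 1), 2.0)
        elig = np.full((1, 1), 10.0)
        mask = self._mask((1, 1))
        neither = rule.end_of_trial(w, elig, TrialOutcome(False, entered_old=False),
                                    self.W_MIN, self.W_MAX, mask)
        assert np.array_equal(neither, w)
        old = rule.end_of_trial(w, elig, TrialOutcome(False, entered_old=True),
                                self.W_MIN, self.W_MAX, mask)
        assert old[0, 0] == pytest.approx(1.9)
        new = rule.end_of_trial(w, elig, TrialOutcome(True),
                                self.W_MIN, self.W_MAX, mask)
        assert new[0, 0] == pytest.approx(2.1)

    def test_clipping_fuzz_never_escapes_bounds(self, rng):
        rule = SnPlast(ach=True, eta_ach=0.5, eta_da=0.5)
        mask = rng.random((4, 5)) < 0.8
        w = np.where(mask, 2.0, 0.0)
        for _ in range(50):
            elig = rng.normal(scale=30.0, size=(4, 5))
            w = rule.end_of_trial(w, elig, TrialOutcome(True),
                                  self.W_MIN, self.W_MAX, mask)
            assert np.all(w[mask] >= self.W_MIN) and np.all(w[mask] <= self.W_MAX)
            assert np.all(w[~mask] == 0.0)


class TestEngineEligibilityOracle:
    def test_engine_trace_matches_reference_accumulation(self, open_sim):
        """The engine's eligibility matrix equals the reference pairing-trace
        accumulation with exponential decay, fed the same recorded spikes."""
        w = open_sim.initial_weights()
        r = open_sim.run_trial(777, w, t_max=0.5, debug=True)
        pre_rec, post_rec = r["pre_rec"], r["post_rec"]
        dt, tau_e = open_sim.dt, 2.0
        traces = PairingTraces(n_pre=open_sim.grid.n, n_post=open_sim.pop.n)
        elig = np.zeros((open_sim.pop.n, open_sim.grid.n))
        for n in range(pre_rec.shape[0]):
            elig *= np.exp(-dt / tau_e)
            elig += traces.step(pre_rec[n], post_rec[n], dt)
        # engine returns the trace decayed to t_end; t_end == t_max here
        assert r["status"] == 0
        np.testing.assert_allclose(r["elig"], elig, rtol=1e-6, atol=1e-12)
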