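"""The four plasticity rules acting on the feed-forward synapse matrix.

All rules share the same skeleton: every pre/post spike pair contributes a
window value W(t_post - t_pre) to a per-synapse pairing sum, which is turned
into a weight change by a neuromodulatory gate and learning rate,
either online (cholinergic depression) or at reward / end of trial through
an exponentially decaying eligibility trace.

 * sn-Plast (+ACh): symmetric window exp(-|lag|/tau); acetylcholine gates
   continuous depression of active synapses during exploration (A=-1,
   applied online), and dopamine at reward retroactively potentiates the
   eligibility trace (A=+1, trace decays with tau_e).
 * sn-Plast (-ACh): dopaminergic potentiation only; weights untouched on
   unrewarded trials.
 * r-STDP: classical asymmetric window with amplitudes A_pre-post / A_post-pre;
   the accumulated (signed) trace is applied only when the trial is rewarded.
 * dynamic reward signal: as -ACh but the end-of-trial update is scaled by
   rho(tr) = R(tr) - Rbar(tr), the surprise relative to a moving average of
   past rewards.
 * negative feedback: as -ACh, but entering the previously rewarded location
   applies the trace with inverted sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

TAU_PAIR = 0.010  # s, STDP window time constant
TAU_E = 2.0  # s, eligibility-trace time constant


# -- windows ----------------------------------------------------------------


def stdp_window(lag, tau: float = TAU_PAIR):
    """Symmetric, positive window W(x) = exp(-|x|/tau)."""
    return np.exp(-np.abs(np.asarray(lag, dtype=float)) / tau)


def asymmetric_window(lag, a_pp: float, a_pn: float, tau: float = TAU_PAIR):
    """Classical STDP window with separate pre-post / post-pre amplitudes.

    W2(s) = A_pre-post * exp(-s/tau) for s > 0, A_post-pre * exp(s/tau) for
    s < 0, and the average of the two amplitudes at s = 0.
    """
    s = np.asarray(lag, dtype=float)
    out = np.where(
        s > 0,
        a_pp * np.exp(-s / tau),
        np.where(s < 0, a_pn * np.exp(s / tau), 0.5 * (a_pp + a_pn)),
    )
    return out


def neuromod_gate(da: bool, ach: bool, eta_ach: float, eta_da: float):
    """Neuromodulator gate A and learning rate eta.

    (-DA, +ACh) -> (-1, eta_ACh): exploration depresses active synapses.
    (-DA, -ACh) -> (0, 0): no update without any neuromodulator.
    (+DA, +/-ACh) -> (+1, eta_DA): reward potentiates regardless of ACh.
    """
    if da:
        return 1, eta_da
    if ach:
        return -1, eta_ach
    return 0, 0.0


# -- pairing / eligibility reference implementations ------------------------


def pair_sum(pre_times, post_times, window) -> float:
    """Direct double sum of window(t_post - t_pre) over all spike pairs."""
    pre = np.asarray(pre_times, dtype=float)
    post = np.asarray(post_times, dtype=float)
    if pre.size == 0 or post.size == 0:
        return 0.0
    lags = post[:, None] - pre[None, :]
    return float(np.sum(window(lags)))


def eligibility_at(t: float, pre_times, post_times, window, tau_e: float = TAU_E,
                   alpha: int = 1) -> float:
    """Eligibility trace at time t by direct summation.

    Each pair contributes window(lag) * exp(-alpha * (t - t_pair)/tau_e),
    where t_pair is the later of the two spikes.  With alpha = 0 this is the
    plain running pairing sum.
    """
    pre = np.asarray(pre_times, dtype=float)
    post = np.asarray(post_times, dtype=float)
    total = 0.0
    for tp in post:
        for ti in pre:
            t_pair = max(tp, ti)
            if t_pair > t:
                continue
            total += float(window(tp - ti)) * np.exp(-alpha * (t - t_pair) / tau_e)
    return total


def eligibility_decay(e: np.ndarray, dt: float, tau_e: float = TAU_E,
                      alpha: int = 1) -> np.ndarray:
    """Advance an eligibility accumulator by dt (no-op when alpha = 0)."""
    if alpha == 0 or dt == 0.0:
        return e
    return e * np.exp(-dt / tau_e)


@dataclass
class PairingTraces:
    """Exact exponential-trace accumulator for STDP pairing sums.

    Maintains presynaptic and postsynaptic traces that decay with the window
    time constant; each new spike pairs with the partner trace, reproducing
    the full double sum over spike pairs without enumerating them.  Spikes
    landing in the same timestep pair with weight W(0).
    """

    n_pre: int
    n_post: int
    a_pp: float = 1.0  # weight of pre-before-post pairs
    a_pn: float = 1.0  # weight of post-before-pre pairs
    tau: float = TAU_PAIR
    pre_trace: np.ndarray = field(default=None)
    post_trace: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.pre_trace is None:
            self.pre_trace = np.zeros(self.n_pre)
            self.post_trace = np.zeros(self.n_post)

    def step(self, pre_spikes, post_spikes, dt: float) -> np.ndarray:
        """Advance by dt and return this step's pairing increment matrix.

        ``pre_spikes``/``post_spikes`` are spike counts (0/1 in the
        continuous model; the 4 kHz discrete place cell may emit several per
        step).  The increment has shape (n_post, n_pre).
        """
        decay = np.exp(-dt / self.tau)
        self.pre_trace *= decay
        self.post_trace *= decay
        pre = np.asarray(pre_spikes, dtype=float)
        post = np.asarray(post_spikes, dtype=float)
        inc = (
            self.a_pp * np.outer(post, self.pre_trace)
            + self.a_pn * np.outer(self.post_trace, pre)
            + 0.5 * (self.a_pp + self.a_pn) * np.outer(post, pre)
        )
        self.pre_trace += pre
        self.post_trace += post
        return inc


def clip_weights(w: np.ndarray, w_min: float, w_max: float,
                 mask: np.ndarray | None = None) -> np.ndarray:
    """Clip to bounds; boundary-masked entries stay frozen at zero."""
    w = np.clip(w, w_min, w_max)
    if mask is not None:
        w[~mask] = 0.0
    return w


# -- rules ------------------------------------------------------------------


@dataclass
class TrialOutcome:
    """What the rule needs to know at the end of a trial."""

    rewarded: bool
    entered_old: bool = False


@dataclass
class SnPlast:
    """Sequentially neuromodulated STDP, with or without cholinergic depression."""

    ach: bool
    eta_ach: float
    eta_da: float
    tau: float = TAU_PAIR
    tau_e: float = TAU_E

    # engine hooks
    a_pp: float = 1.0
    a_pn: float = 1.0

    @property
    def online_rate(self) -> float:
        """Learning rate of the online depression (0 disables it)."""
        return self.eta_ach if self.ach else 0.0

    def end_of_trial(self, w, elig, outcome: TrialOutcome, w_min, w_max, mask):
        if outcome.rewarded:
            w = clip_weights(w + self.eta_da * elig, w_min, w_max, mask)
        return w


@dataclass
class RStdp:
    """Reward-modulated STDP: asymmetric window, updates gated to rewarded trials."""

    a_pp: float
    a_pn: float
    eta: float = 0.01
    tau: float = TAU_PAIR
    tau_e: float = TAU_E
    online_rate: float = 0.0
    ach: bool = False

    def end_of_trial(self, w, elig, outcome: TrialOutcome, w_min, w_max, mask):
        if outcome.rewarded:
            w = clip_weights(w + self.eta * elig, w_min, w_max, mask)
        return w


@dataclass
class DynamicReward:
    """STDP scaled by the surprise rho(tr) = R(tr) - Rbar(tr).

    Rbar(tr) = beta*R(tr) + (1-beta)*Rbar(tr-1), with Rbar(1) = R(1) — so the
    first trial's update is exactly zero whatever its outcome.
    """

    beta: float = 0.75
    eta: float = 0.01
    tau: float = TAU_PAIR
    tau_e: float = TAU_E
    online_rate: float = 0.0
    ach: bool = False
    a_pp: float = 1.0
    a_pn: float = 1.0
    r_bar: float | None = None

    def signal(self, r: int) -> float:
        """Consume one trial outcome and return rho(tr); updates the average."""
        if self.r_bar is None:
            self.r_bar = float(r)
        else:
            self.r_bar = self.beta * r + (1.0 - self.beta) * self.r_bar
        return r - self.r_bar

    def end_of_trial(self, w, elig, outcome: TrialOutcome, w_min, w_max, mask):
        rho = self.signal(1 if outcome.rewarded else 0)
        return clip_weights(w + self.eta * rho * elig, w_min, w_max, mask)

    def reset(self):
        self.r_bar = None


@dataclass
class NegativeFeedback:
    """Dopamine-like trace update whose sign flips at the omitted reward.

    A_feedback = +1 on reaching the (new) reward, -1 on navigating to the
    previously rewarded location, 0 otherwise.
    """

    eta: float = 0.01
    tau: float = TAU_PAIR
    tau_e: float = TAU_E
    online_rate: float = 0.0
    ach: bool = False
    a_pp: float = 1.0
    a_pn: float = 1.0

    def end_of_trial(self, w, elig, outcome: TrialOutcome, w_min, w_max, mask):
        if outcome.rewarded:
            a_fb = 1.0
        elif outcome.entered_old:
            a_fb = -1.0
        else:
            return w
        return clip_weights(w + self.eta * a_fb * elig, w_min, w_max, mask)


def make_rule(name: str, params: dict) -> object:
    """Rule factory keyed by config name."""
    if name == "snplast_ach":
        return SnPlast(ach=True, eta_ach=params["eta_ach"], eta_da=params["eta_da"])
    if name == "snplast_noach":
        return SnPlast(ach=False, eta_ach=params["eta_ach"], eta_da=params["eta_da"])
    if name == "rstdp":
        return RStdp(a_pp=params["a_pp"], a_pn=params["a_pn"],
                     eta=params.get("eta", 0.01))
    if name == "dynamic_reward":
        return DynamicReward(beta=params.get("beta", 0.75), eta=params.get("eta", 0.01))
    if name == "negative_feedback":
        return NegativeFeedback(eta=params.get("eta", 0.01))
    raise ValueError(f"unknown rule: {name!r}")
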