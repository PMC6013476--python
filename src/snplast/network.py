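"""Place-cell input layer and SRM0 action-neuron population.

Place cells fire as inhomogeneous Poisson processes whose rate is a Gaussian
function of the agent's distance from the cell centre.  Action neurons are
simplified spike-response-model (SRM0) units: the membrane potential is a sum
of EPSP kernels from feed-forward and lateral input spikes plus a post-spike
refractory kernel, and firing is stochastic with an exponential escape rate.
Lateral connectivity implements winner-take-all competition: uniform
inhibition plus (in the continuous model) local excitation between neurons
with similar preferred directions.

The functions here are the readable reference implementations used by the
unit tests and by the analysis layer; `snplast._engine` contains the
numba-compiled state-based equivalent used to run whole experiments, and is
pinned to these references by oracle tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np

from .geometry import HALF

# Membrane / escape-noise constants shared by both models (ms expressed in s)
TAU_M = 0.020
TAU_S = 0.005
CHI = -5.0  # mV, refractory scale
THETA = 16.0  # mV, threshold
TAU_GAMMA = 0.050
NU_GAMMA = 0.020

# Continuous-model ring parameters
W_MINUS = -300.0
W_PLUS = 100.0
PSI = 20.0


@dataclass(frozen=True)
class PlaceCellGrid:
    """Square grid of Gaussian place fields covering the environment."""

    centres: np.ndarray  # (N, 2)
    sigma: float
    peak_rate: float  # Hz

    @property
    def n(self) -> int:
        return self.centres.shape[0]

    def rates(self, p) -> np.ndarray:
        """Firing rate of every cell with the agent at p (Hz).

        lambda_i = peak * exp(-||p - x_i||^2 / sigma^2), a Gaussian place
        field whose width parameter sigma is also the grid spacing.
        """
        d2 = np.sum((self.centres - np.asarray(p, dtype=float)) ** 2, axis=1)
        return self.peak_rate * np.exp(-d2 / self.sigma**2)


def make_place_grid(variant: str) -> PlaceCellGrid:
    """Standard grids: 11x11 / sigma=0.4 (open field), 21x21 / sigma=0.2 (T-maze)."""
    if variant in ("open", "open_obstacles"):
        sigma = 0.4
    elif variant == "tmaze":
        sigma = 0.2
    else:
        raise ValueError(f"no continuous place grid for {variant!r}")
    axis = np.arange(-HALF, HALF + sigma / 2, sigma)
    xx, yy = np.meshgrid(axis, axis)
    centres = np.column_stack([xx.ravel(), yy.ravel()])
    return PlaceCellGrid(centres=centres, sigma=sigma, peak_rate=400.0)


@dataclass(frozen=True)
class ActionPopulation:
    """The output layer: N direction-tuned (or arm-tuned) SRM0 neurons."""

    n: int
    eps0: float
    lam0: float  # Hz, escape rate at threshold
    delta_u: float  # mV
    a0: float = 0.08  # step length per dt (continuous model)
    tau_m: float = TAU_M
    tau_s: float = TAU_S
    chi: float = CHI
    theta: float = THETA

    @property
    def thetas(self) -> np.ndarray:
        """Preferred angles 2*pi*j/N (0 = east, pi/2 = north)."""
        return 2.0 * np.pi * np.arange(self.n) / self.n

    @property
    def directions(self) -> np.ndarray:
        """Preferred displacement vectors a_j of length a0."""
        th = self.thetas
        return self.a0 * np.column_stack([np.cos(th), np.sin(th)])


def continuous_action_population(variant: str) -> ActionPopulation:
    eps0 = 10.0 if variant == "tmaze" else 20.0
    return ActionPopulation(n=40, eps0=eps0, lam0=60.0, delta_u=2.0)


def discrete_action_population() -> ActionPopulation:
    return ActionPopulation(n=8, eps0=20.0, lam0=100.0, delta_u=0.5)


# -- kernels ----------------------------------------------------------------


def epsp_kernel(t, eps0: float, tau_m: float = TAU_M, tau_s: float = TAU_S):
    """EPSP: eps0/(tau_m - tau_s) * (exp(-t/tau_m) - exp(-t/tau_s)) for t >= 0.

    The normalizing time constants are expressed in ms (the natural unit of
    the membrane kernel), so a unit-weight EPSP with eps0 = 20 peaks near
    0.63 mV around t = 10 ms; times may be passed in seconds.
    """
    t = np.asarray(t, dtype=float)
    norm = eps0 / ((tau_m - tau_s) * 1e3)
    out = norm * (np.exp(-t / tau_m) - np.exp(-t / tau_s))
    return np.where(t >= 0.0, out, 0.0)


def rate_kernel(t, tau=TAU_GAMMA, nu=NU_GAMMA):
    """Unit-mass filter gamma used to estimate instantaneous firing rates."""
    t = np.asarray(t, dtype=float)
    out = (np.exp(-t / tau) - np.exp(-t / nu)) / (tau - nu)
    return np.where(t >= 0.0, out, 0.0)


def escape_rate(u, lam0: float, delta_u: float, theta: float = THETA):
    """Stochastic-firing intensity lambda(u) = lam0 * exp((u - theta)/delta_u)."""
    return lam0 * np.exp((np.asarray(u, dtype=float) - theta) / delta_u)


def sample_spikes(rates, dt: float, rng: np.random.Generator) -> np.ndarray:
    """One Bernoulli thinning step of an inhomogeneous Poisson process.

    Each unit spikes independently with probability rate*dt (clipped to 1).
    """
    rates = np.asarray(rates, dtype=float)
    p = rates * dt
    if np.any(p > 0.2):
        warnings.warn(
            "rate*dt exceeds 0.2; Bernoulli thinning is a poor Poisson "
            "approximation at this resolution",
            stacklevel=2,
        )
    return rng.random(rates.shape) < np.minimum(p, 1.0)


# -- lateral connectivity ---------------------------------------------------


def lateral_weights_continuous(
    n: int = 40, w_minus: float = W_MINUS, w_plus: float = W_PLUS, psi: float = PSI
) -> np.ndarray:
    """Ring connectivity: uniform inhibition plus local excitation.

    w_jk = w_minus/N + w_plus * f(j,k)/Z with
    f(j,k) = (1 - delta_jk) * exp(psi * cos(theta_j - theta_k)).
    Z normalizes each row of f to unit sum, so a neuron distributes a total
    excitation of w_plus over its neighbourhood while receiving a total
    inhibition of w_minus from the ring; with w_minus = -300 and
    w_plus = 100 the net recurrent drive is inhibitory and the activity
    settles into a single soft bump instead of saturating.  The diagonal
    carries only the inhibitory offset and is excluded from the membrane sum.
    """
    th = 2.0 * np.pi * np.arange(n) / n
    dtheta = th[:, None] - th[None, :]
    f = np.exp(psi * np.cos(dtheta))
    np.fill_diagonal(f, 0.0)
    z = f.sum(axis=1, keepdims=True)
    return w_minus / n + w_plus * f / z


def lateral_weights_discrete(n: int = 8, w_lat: float = -250.0) -> np.ndarray:
    """All-to-all inhibition with no self-connections."""
    w = np.full((n, n), w_lat)
    np.fill_diagonal(w, 0.0)
    return w


# -- direct (kernel-sum) reference dynamics ---------------------------------


def membrane_potential_direct(
    t: float,
    feed_spikes: list[tuple[float, int]],
    lat_spikes_per_neuron: list[list[float]],
    w_feed: np.ndarray,
    w_lat: np.ndarray,
    pop: ActionPopulation,
) -> np.ndarray:
    """Evaluate the SRM0 membrane potential of every neuron at time t.

    Direct evaluation over stored spike lists: feed-forward EPSPs, lateral
    EPSPs (k != j) and the refractory kernel, with the reset semantics that
    only input spikes arriving at or after the neuron's last spike before t
    contribute.  ``feed_spikes`` is a list of (time, place-cell index);
    ``lat_spikes_per_neuron[k]`` the spike times of action neuron k;
    ``w_feed`` has shape (N_action, N_place).
    """
    n = pop.n
    u = np.zeros(n)
    for j in range(n):
        own = [s for s in lat_spikes_per_neuron[j] if s < t]
        t_hat = max(own) if own else -np.inf
        for (s, i) in feed_spikes:
            if t_hat <= s < t:
                u[j] += w_feed[j, i] * float(
                    epsp_kernel(t - s, pop.eps0, pop.tau_m, pop.tau_s)
                )
        for k in range(n):
            if k == j:
                continue
            for s in lat_spikes_per_neuron[k]:
                if t_hat <= s < t:
                    u[j] += w_lat[j, k] * float(
                        epsp_kernel(t - s, pop.eps0, pop.tau_m, pop.tau_s)
                    )
        if np.isfinite(t_hat):
            u[j] += pop.chi * np.exp(-(t - t_hat) / pop.tau_m)
    return u


def rate_trace_direct(t: float, spike_times, tau=TAU_GAMMA, nu=NU_GAMMA) -> float:
    """Filtered-rate estimate at time t by direct kernel summation."""
    s = np.asarray([s for s in spike_times if s < t], dtype=float)
    if s.size == 0:
        return 0.0
    return float(np.sum(rate_kernel(t - s, tau, nu)))


@dataclass
class RateTrace:
    """State-based implementation of the rate filter as two leaky sums.

    rho(t) = (A - B)/(tau - nu) with A, B decaying with time constants tau
    and nu and incremented by 1 at each spike; exactly reproduces the kernel
    convolution at the sampling times.
    """

    n: int
    tau: float = TAU_GAMMA
    nu: float = NU_GAMMA
    a: np.ndarray = field(default=None)
    b: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.a is None:
            self.a = np.zeros(self.n)
            self.b = np.zeros(self.n)

    def step(self, spikes, dt: float) -> np.ndarray:
        """Advance by dt, then register this step's spikes; returns rho before
        the new spikes (the kernel vanishes at lag 0)."""
        self.a *= np.exp(-dt / self.tau)
        self.b *= np.exp(-dt / self.nu)
        rho = (self.a - self.b) / (self.tau - self.nu)
        spikes = np.asarray(spikes)
        self.a += spikes
        self.b += spikes
        return rho

    @property
    def value(self) -> np.ndarray:
        return (self.a - self.b) / (self.tau - self.nu)
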