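# Model and methods

`snplast` simulates reward-driven maze navigation in a one-layer spiking
network whose feed-forward synapses learn under sequentially neuromodulated
spike-timing-dependent plasticity (sn-Plast): acetylcholine biases plasticity
toward depression during exploration, and dopamine, delivered at reward,
retroactively converts the eligibility trace of recent activity into
potentiation.  Three comparator rules (classical reward-modulated STDP, a
dynamic reward signal, and a targeted negative-feedback signal) run in the
same network.

## Network

**Place cells.** The agent's position x(t) drives an input layer of Gaussian
place fields, `lambda_i(x) = 400 Hz * exp(-||x - x_i||^2 / sigma^2)`, on a
square grid with spacing sigma (0.4 a.u. / 121 cells in the 4x4 open field;
0.2 a.u. / 441 cells for the T-maze, whose corridor is cropped out of the
same plane).  Spiking is an inhomogeneous Poisson process, simulated by
per-timestep Bernoulli thinning.  The radial-arm maze is a discrete,
single-state version: one place cell firing at 4000 Hz (Poisson counts per
bin) and one action neuron per arm.

**Action neurons.** N direction-tuned SRM0 neurons (N = 40 continuous, 8
discrete) with membrane potential given by summed EPSP kernels
`eps(t) = eps0/(tau_m - tau_s) (e^{-t/tau_m} - e^{-t/tau_s})`
(tau_m = 20 ms, tau_s = 5 ms; eps0 = 20, or 10 in the T-maze; the
normalizing constant is taken over ms, so a unit-weight EPSP peaks at
~0.63 mV for eps0 = 20), a refractory kernel chi*e^{-t/tau_m} with
chi = -5 mV that also resets all input accumulated before the spike, and
exponential escape noise `lambda(u) = lambda0 exp((u - theta)/delta_u)` with
theta = 16 mV (lambda0 = 60 Hz, delta_u = 2 mV continuous; 100 Hz, 0.5 mV
discrete).

**Lateral connectivity.** The continuous ring uses
`w_jk = w_-/N + w_+ f(j,k)/Z` with `f(j,k) = (1-delta_jk) e^{psi cos(theta_j
- theta_k)}`, w_- = -300, w_+ = 100, psi = 20.  The normalization Z was left
open by the source description; we take Z as the row sum of f, so each
neuron distributes a total excitation of w_+ across its neighbourhood while
receiving a total inhibition of w_-.  The alternative (peak-normalizing Z so
the nearest neighbour receives w_+) makes recurrent excitation (total +330)
exceed inhibition and the activity bump saturates at the escape-rate ceiling,
which destroys weight-dependent steering; with the sum normalization a
single soft bump forms and weight differences of order one change behaviour.
The discrete model uses uniform inhibition w_lat = -250.

**Action selection.** Each neuron's firing rate is estimated by filtering
its spike train with the unit-mass kernel gamma (tau_gamma = 50 ms,
nu_gamma = 20 ms).  The continuous agent moves every timestep by the
population vector `a(t) = (1/N) sum_j rho_j a_j` with preferred
displacements a_j of length a0 = 0.08 a.u.; rho is counted in spikes per
timestep, so a0 is the displacement contributed by a neuron firing once per
step.  This scale is the one genuinely free constant of the navigation
layer; it was fixed by requiring the plasticity-free agent's task statistics
to sit at their published level (measured 38.6% successful trials vs 37%)
and then left alone.  Where the T-maze restricts the available actions
(stem: upward angles [pi/4, 3pi/4]; top bar: the horizontal union
[-pi/4, pi/4] u [3pi/4, 5pi/4]), disallowed neurons neither spike nor
contribute, and the 1/N average runs over the available neurons.  The
discrete agent makes a single decision at T_max = 5 s: the arm of the
neuron with the highest filtered rate, exact ties uniform.

**Navigation.** Moves that would leave the maze (or cross an obstacle) are
replaced by a bounce: the agent is displaced by d = 0.01 a.u. along the
inward normal of the violated boundary (normals are summed and normalized at
corners).  Finding the reward ends the trial after a 300 ms consummatory
pause with place-cell activity silenced; all dynamic state (spike
histories, potentials, traces, accumulators) resets between trials.

## Plasticity

All rules share one pairing machinery: every pre/post spike pair
contributes W(t_post - t_pre) to its synapse, accumulated exactly with
exponential pre/post traces (no lag cutoff).  sn-Plast uses the symmetric
window W(s) = e^{-|s|/tau} (tau = 10 ms); r-STDP the classical asymmetric
window with amplitudes (A_pre-post, A_post-pre) and value
(A_pre-post + A_post-pre)/2 at s = 0.

* **sn-Plast +ACh**: pairings depress the synapse online
  (eta_ACh per pairing) while a parallel eligibility trace decays with
  tau_e = 2 s; at reward the trace is added with gain eta_DA.  A pairing at
  delay D before reward therefore changes the weight by
  `-eta_ACh W + eta_DA W e^{-D/tau_e}`, positive for all
  D < tau_e ln(eta_DA/eta_ACh): dopamine retroactively converts depression
  into potentiation.
* **sn-Plast -ACh**: the depression term is absent; unrewarded trials leave
  weights bit-identical.
* **r-STDP**: the signed trace is applied (eta = 0.01) only when the trial
  is rewarded; with A_pre-post = A_post-pre = +1 it reproduces -ACh exactly
  (a bit-identity we test).  Following the narrative description, unrewarded
  trials leave weights unchanged (the gate equation alone would permit
  updates at the end of every trial).
* **Dynamic reward signal**: the -ACh update scaled by
  rho(tr) = R(tr) - Rbar(tr), Rbar(tr) = 0.75 R(tr) + 0.25 Rbar(tr-1),
  Rbar(1) = R(1) — so the first trial's update is exactly zero, as the
  printed definitions force.
* **Negative feedback**: the trace is applied with sign +1 at the (new)
  reward, -1 when the agent navigates to the previously rewarded location,
  0 otherwise.

Weights start at w_in, are clipped to [w_min, w_max] after every update
(radial 2/[1,5], T-maze 3/[1,5], open field 2/[1,3]), and feed-forward
weights from boundary place cells to outward directions are frozen at zero
(realized as: frozen wherever one step of length a0 from the cell centre
leaves the maze).  Learning rates: eta_ACh/eta_DA = 0.001/0.01 (radial),
0.1/0.3 (T-maze), 0.002/0.01 (open field).

## Integration

Neural dynamics and navigation advance together at dt = 1 ms (a config
key).  All kernels are differences of exponentials maintained as pairs of
leaky accumulators, which reproduces the continuous-time convolutions
exactly at the sampling instants; the test suite pins the compiled engine to
direct kernel-sum evaluation (< 1e-9 mV for membrane potentials, < 1e-6
relative for rate traces and pairing sums).  The radial maze alone
integrates at dt = 0.1 ms: its escape noise is sharp (delta_u = 0.5 mV), and
at 1 ms all eight neurons cross threshold within one bin before lateral
inhibition (EPSP rise time ~ms) can intervene, so the winner-take-all race
degenerates into synchronized volleys that depress every arm at once.  At
0.1 ms the first spiker suppresses the rest, one arm is chosen per trial,
and cholinergic exploration becomes exactly systematic.  Spike probabilities
are min(lambda dt, 1); the discrete model's 4000 Hz place cell uses Poisson
counts per bin, which pair multiplicatively.

## Experiments and analyses

Protocols follow the published designs: radial and T-maze tasks (T_max =
5 s), the open-field task (T_max = 15 s, reward disc radius 0.3 at
(1.5, 1.5) then (-1.5, -1.5) from trial 21), the obstacle variant (bars
0.4 x 0.8 a.u. at x = +/-1.2; reward (0, 1.5) then (0, -1.5)), the
early-stopping variant in which phase-2 trials also end upon entering the
old zone, and unrewarded exploration.  Occupancy is the time- and
simulation-averaged place-cell activity normalized over the grid; KL
divergences are in nats with a smoothing mass of 1e-12 of the total added
to the reference distribution only.  The uniform-location benchmark (BEE)
samples i.i.d. positions; the action-space benchmark (BEA) is a fixed-speed
random walk whose speed we set to 0.0015 a.u./step, the measured mean agent
step, since the source fixes the speed without stating it — at that speed
the walk stays near the start and the published KL magnitudes are
reproduced, whereas a faster walk blankets the field and collapses them.

Seeding: each trial's generator seed derives from
SeedSequence([master, simulation, trial]); identical configurations and
master seeds give bit-identical experiments.

## Problem sizes

The statistics in `scripts/acceptance.py` use M = 1000 simulations for the
radial maze and the occupancy/KL analyses, M = 500 (radial +ACh), M = 300
(T-maze exploration), M = 100 for the 40-trial relearning experiments and
M = 50 for the no-plasticity baseline; the test suite uses smaller M with
binomial tolerance bands widened accordingly.

## What the model does and does not capture

The synthetic environments are the study's own object, not a stand-in for
recorded data: all conclusions are about this network.  Known limitations:

* **T-maze exploration under +ACh is not reproduced.**  With the printed
  T-maze learning rate (eta_ACh = 0.1) and the full pairing sum at 400 Hz
  place rates, depression floors the weights at the T-junction within tens
  of milliseconds, so the activity bump flips between the two horizontal
  directions faster than the ~0.4 s needed to commit to an arm, and a
  fully depressed stem (drive 12.6 mV < theta) navigates too slowly to
  recover within T_max.  The open-field results require exactly this fast
  online depression (the single-trial occupancy split between conditions
  and the gradual multi-trial unlearning), so no single pairing
  normalization we found satisfies both; we keep the open-field-consistent
  one and report the T-maze statistic as computed.  Rewarded T-maze
  behaviour without acetylcholine (arm entry ~1/2, geometric discovery) is
  unaffected.
* The obstacle-field experiment shows the right qualitative pattern
  (non-discovery and old-path perseverance worse than the plain field) but
  milder than published; our agents round the small bars more readily.
* KL(-ACh||BEE) computes slightly above its published value (~0.05 vs
  0.03); the statistic is sensitive to the (unstated) occupancy binning and
  integration step.
* No synaptic delays, conductances, or noise injection into weights or
  activity; plasticity acts on feed-forward synapses only.
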