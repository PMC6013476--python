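"""Trial and experiment protocols.

An *experiment* is M independent simulations; each simulation is a sequence
of trials sharing one feed-forward weight matrix.  Trials run the spiking
dynamics at dt resolution, apply the plasticity rule (online cholinergic
depression and/or end-of-trial trace updates), and terminate on reward
(followed by a 300 ms consummatory pause during which place-cell activity is
suppressed, so nothing else happens), on entry into a maze arm (T-maze), on
entry into the old reward zone (early-stopping variants), or at T_max.

Seeding: every trial draws its generator seed from
``SeedSequence([master, sim_index, trial_index])``, so a (config, master
seed) pair reproduces an experiment bit-for-bit, and simulations are
independent streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _engine
from .geometry import MazeGeometry, RewardZone, make_maze, standard_zones
from .network import (
    ActionPopulation,
    PlaceCellGrid,
    continuous_action_population,
    discrete_action_population,
    lateral_weights_continuous,
    make_place_grid,
)
from .plasticity import SnPlast, TrialOutcome
from .config import DT, PAUSE, preset

CONSUMMATORY_PAUSE = PAUSE

_KIND = {"open": _engine.OPEN, "open_obstacles": _engine.OBSTACLES, "tmaze": _engine.TMAZE}


def trial_seed(master: int, sim: int, trial: int) -> int:
    """Deterministic per-trial engine seed (collision-free via SeedSequence)."""
    return int(np.random.SeedSequence([int(master), int(sim), int(trial)]).generate_state(1)[0])


def derive_seeds(master: int, m: int) -> np.ndarray:
    """Per-simulation seeds recorded in the run manifest."""
    return np.array([trial_seed(master, s, 0) for s in range(m)], dtype=np.uint32)


@dataclass
class TrialRecord:
    sim: int
    trial: int
    success: bool
    t_rew: float | None
    duration: float
    bounces: int
    entered_old: bool = False
    visited_left: bool = False
    visited_right: bool = False
    arm: int | None = None
    trajectory: np.ndarray | None = None
    actions: np.ndarray | None = None


@dataclass
class ExperimentResult:
    config: dict
    master_seed: int
    trials: list[TrialRecord] = field(default_factory=list)
    weight_snapshots: dict = field(default_factory=dict)  # (sim, trial) -> w copy
    occupancy: np.ndarray | None = None  # summed place rates, all sims

    def table(self) -> pd.DataFrame:
        rows = []
        for r in self.trials:
            rows.append(
                dict(sim=r.sim, trial=r.trial, success=r.success,
                     t_rew=np.nan if r.t_rew is None else r.t_rew,
                     duration=r.duration, bounces=r.bounces,
                     entered_old=r.entered_old, visited_left=r.visited_left,
                     visited_right=r.visited_right,
                     arm=-1 if r.arm is None else r.arm)
            )
        return pd.DataFrame(rows)


# -- continuous-model simulation state --------------------------------------


class ContinuousSim:
    """Network + geometry bundle for one continuous-model simulation."""

    def __init__(self, variant: str, dt: float = DT):
        self.variant = variant
        self.p = preset(variant)
        self.dt = dt
        self.maze: MazeGeometry = make_maze(variant)
        self.grid: PlaceCellGrid = make_place_grid(variant)
        self.pop: ActionPopulation = continuous_action_population(variant)
        w_lat = lateral_weights_continuous(self.pop.n)
        np.fill_diagonal(w_lat, 0.0)  # self term excluded from the membrane sum
        self.w_lat = w_lat
        # geometry mask is (place x action); engine weights are (action x place)
        self.wmask = self.maze.boundary_weight_mask(
            self.grid.centres, self.pop.directions
        ).T.copy()
        self.obstacles = np.array(self.maze.obstacles, dtype=float).reshape(-1, 4)
        self.thetas = self.pop.thetas
        self.dirs = self.pop.directions

    def initial_weights(self) -> np.ndarray:
        w = np.full((self.pop.n, self.grid.n), float(self.p["w_in"]))
        w[~self.wmask] = 0.0
        return w

    def run_trial(
        self,
        seed: int,
        w: np.ndarray,
        *,
        new_zone: RewardZone | None = None,
        old_zone: RewardZone | None = None,
        early_stop: bool = False,
        tmaze_task: int = 0,
        eta_online: float = 0.0,
        a_pp: float = 1.0,
        a_pn: float = 1.0,
        t_max: float | None = None,
        record_every: int = 0,
        debug: bool = False,
    ):
        p = self.p
        t_max = p["t_max"] if t_max is None else t_max
        n_steps = int(round(t_max / self.dt))
        if record_every > 0:
            n_rec_max = (n_steps + record_every - 1) // record_every
            traj = np.zeros((n_rec_max, 2))
            acts = np.zeros((n_rec_max, 2))
        else:
            traj = np.zeros((1, 2))
            acts = np.zeros((1, 2))
        if debug:
            u_rec = np.zeros((n_steps, self.pop.n))
            pre_rec = np.zeros((n_steps, self.grid.n), dtype=np.int8)
            post_rec = np.zeros((n_steps, self.pop.n), dtype=np.int8)
        else:
            u_rec = np.zeros((1, 1))
            pre_rec = np.zeros((1, 1), dtype=np.int8)
            post_rec = np.zeros((1, 1), dtype=np.int8)

        has_new = new_zone is not None and new_zone.kind == "disc"
        has_old = old_zone is not None and old_zone.kind == "disc"
        ncx, ncy, nr = (0.0, 0.0, 0.0)
        if has_new:
            ncx, ncy = new_zone.centre
            nr = new_zone.radius
        ocx, ocy, orr = (0.0, 0.0, 0.0)
        if has_old:
            ocx, ocy = old_zone.centre
            orr = old_zone.radius

        out = _engine.run_continuous_trial(
            seed,
            _KIND[self.variant], self.maze.half, self.maze.bounce_d,
            self.obstacles, float(self.maze.start[0]), float(self.maze.start[1]),
            self.grid.centres, self.grid.sigma, self.grid.peak_rate,
            self.dirs, self.thetas, self.w_lat,
            self.pop.eps0, self.pop.tau_m, self.pop.tau_s, self.pop.chi,
            self.pop.theta, self.pop.lam0, self.pop.delta_u,
            0.050, 0.020,
            w, self.wmask, float(p["w_min"]), float(p["w_max"]),
            self.dt, t_max,
            has_new, ncx, ncy, nr,
            has_old, ocx, ocy, orr, early_stop,
            tmaze_task,
            eta_online, 0.010, 2.0, a_pp, a_pn,
            record_every, traj, acts,
            debug, u_rec, pre_rec, post_rec,
        )
        (status, t_end, bounces, vis_l, vis_r, entered_old, elig, occ, n_rec,
         x, y) = out
        res = dict(
            status=status, t_end=t_end, bounces=bounces,
            visited_left=vis_l, visited_right=vis_r, entered_old=entered_old,
            elig=elig, occ=occ, traj=traj[:n_rec], acts=acts[:n_rec],
            final_pos=(x, y),
        )
        if debug:
            res.update(u_rec=u_rec, pre_rec=pre_rec, post_rec=post_rec)
        return res


# -- radial-arm maze (discrete model) ---------------------------------------


def run_radial_experiment(
    ach: bool,
    m: int,
    n_trials: int,
    master_seed: int,
    *,
    rewarded: bool = True,
    rewarded_arm: int = 0,
    stop_after_first_reward: bool = False,
    dt: float | None = None,
) -> ExperimentResult:
    """Radial-maze task: 5 s of spiking then a single winner-take-all choice.

    With ``rewarded=False`` the maze contains no reward (exploration test).
    Arm choices, per-trial success and the weight vector evolve per the rule.
    """
    p = preset("radial")
    if dt is None:
        dt = p["dt"]
    pop = discrete_action_population()
    eta_online = p["eta_ach"] if ach else 0.0
    result = ExperimentResult(
        config=dict(maze="radial", ach=ach, m=m, n_trials=n_trials,
                    rewarded=rewarded, rewarded_arm=rewarded_arm),
        master_seed=master_seed,
    )
    for sim in range(m):
        w = np.full(pop.n, float(p["w_in"]))
        for tr in range(n_trials):
            seed = trial_seed(master_seed, sim, tr)
            winner, elig = _engine.run_discrete_trial(
                seed, p["lam_pc"], w, p["w_lat"],
                pop.eps0, pop.tau_m, pop.tau_s, pop.chi, pop.theta,
                pop.lam0, pop.delta_u, 0.050, 0.020,
                float(p["w_min"]), float(p["w_max"]),
                dt, p["t_max"], eta_online, 0.010, 2.0,
            )
            success = rewarded and (winner == rewarded_arm)
            if success:
                w = np.clip(w + p["eta_da"] * elig, p["w_min"], p["w_max"])
            result.trials.append(
                TrialRecord(sim=sim, trial=tr + 1, success=success,
                            t_rew=p["t_max"] if success else None,
                            duration=p["t_max"] + (PAUSE if success else 0.0),
                            bounces=0, arm=int(winner))
            )
            if success and stop_after_first_reward:
                break
    return result


# -- T-maze ------------------------------------------------------------------


def run_tmaze_experiment(
    ach: bool,
    m: int,
    n_trials: int,
    master_seed: int,
    *,
    rewarded: bool = True,
    dt: float = DT,
) -> ExperimentResult:
    """T-maze task: trials end on arm entry (right arm rewarded) or at T_max.

    With ``rewarded=False`` both arms are unrewarded and the per-trial arm
    visits are recorded (systematic-exploration test).
    """
    p = preset("tmaze")
    result = ExperimentResult(
        config=dict(maze="tmaze", ach=ach, m=m, n_trials=n_trials,
                    rewarded=rewarded),
        master_seed=master_seed,
    )
    sim_state = ContinuousSim("tmaze", dt=dt)
    rule = SnPlast(ach=ach, eta_ach=p["eta_ach"], eta_da=p["eta_da"])
    tmaze_task = 1 if rewarded else 2
    for sim in range(m):
        w = sim_state.initial_weights()
        for tr in range(n_trials):
            seed = trial_seed(master_seed, sim, tr)
            r = sim_state.run_trial(
                seed, w, tmaze_task=tmaze_task,
                eta_online=rule.online_rate,
            )
            success = r["status"] == _engine.REWARDED
            if success:
                w = rule.end_of_trial(
                    w, r["elig"], TrialOutcome(True),
                    p["w_min"], p["w_max"], sim_state.wmask,
                )
            result.trials.append(
                TrialRecord(sim=sim, trial=tr + 1, success=success,
                            t_rew=r["t_end"] if success else None,
                            duration=r["t_end"] + (PAUSE if success else 0.0),
                            bounces=r["bounces"],
                            visited_left=r["visited_left"],
                            visited_right=r["visited_right"] or success)
            )
    return result


# -- open field / obstacle field ---------------------------------------------


def run_open_field_experiment(
    rule,
    m: int,
    master_seed: int,
    *,
    variant: str = "open",
    trials_phase1: int = 20,
    trials_phase2: int = 0,
    early_stop_phase2: bool = False,
    snapshot_trials: tuple[int, ...] = (),
    record_every: int = 0,
    dt: float = DT,
) -> ExperimentResult:
    """The standard learning / relearning task (reward relocated after phase 1).

    Phase 1 rewards the first standard zone; phase 2 moves the reward to the
    second zone, with the first zone kept as the (inactive) "old" location for
    visit counting.  With ``early_stop_phase2`` a phase-2 trial also
    terminates, unrewarded, when the agent enters the old zone.
    """
    zone1, zone2 = standard_zones(variant)
    p = preset(variant)
    sim_state = ContinuousSim(variant, dt=dt)
    result = ExperimentResult(
        config=dict(maze=variant, rule=type(rule).__name__, m=m,
                    trials_phase1=trials_phase1, trials_phase2=trials_phase2,
                    early_stop_phase2=early_stop_phase2),
        master_seed=master_seed,
    )
    n_total = trials_phase1 + trials_phase2
    for sim in range(m):
        w = sim_state.initial_weights()
        if hasattr(rule, "reset"):
            rule.reset()
        for tr in range(1, n_total + 1):
            if tr in snapshot_trials:
                result.weight_snapshots[(sim, tr)] = w.copy()
            phase2 = tr > trials_phase1
            seed = trial_seed(master_seed, sim, tr)
            r = sim_state.run_trial(
                seed, w,
                new_zone=zone2 if phase2 else zone1,
                old_zone=zone1 if phase2 else None,
                early_stop=early_stop_phase2 and phase2,
                eta_online=rule.online_rate,
                a_pp=rule.a_pp, a_pn=rule.a_pn,
                record_every=record_every,
            )
            success = r["status"] == _engine.REWARDED
            outcome = TrialOutcome(rewarded=success, entered_old=r["entered_old"])
            w = rule.end_of_trial(w, r["elig"], outcome,
                                  p["w_min"], p["w_max"], sim_state.wmask)
            result.trials.append(
                TrialRecord(sim=sim, trial=tr, success=success,
                            t_rew=r["t_end"] if success else None,
                            duration=r["t_end"] + (PAUSE if success else 0.0),
                            bounces=r["bounces"], entered_old=r["entered_old"],
                            trajectory=r["traj"] if record_every else None,
                            actions=r["acts"] if record_every else None)
            )
    return result


def run_unrewarded_exploration(
    ach: bool,
    m: int,
    master_seed: int,
    *,
    variant: str = "open",
    record_every: int = 10,
    dt: float = DT,
) -> ExperimentResult:
    """Open-field exploration with no reward: one T_max trial per simulation.

    Accumulates the occupancy statistic (time- and simulation-summed
    place-cell rates) used by the KL analyses, plus per-trial bounce counts
    and sampled action vectors.
    """
    p = preset(variant)
    sim_state = ContinuousSim(variant, dt=dt)
    rule = SnPlast(ach=ach, eta_ach=p["eta_ach"], eta_da=p["eta_da"])
    occ = np.zeros(sim_state.grid.n)
    result = ExperimentResult(
        config=dict(maze=variant, ach=ach, m=m, task="unrewarded"),
        master_seed=master_seed,
    )
    for sim in range(m):
        w = sim_state.initial_weights()
        seed = trial_seed(master_seed, sim, 0)
        r = sim_state.run_trial(
            seed, w, eta_online=rule.online_rate, record_every=record_every,
        )
        occ += r["occ"]
        result.trials.append(
            TrialRecord(sim=sim, trial=1, success=False, t_rew=None,
                        duration=r["t_end"], bounces=r["bounces"],
                        trajectory=r["traj"], actions=r["acts"])
        )
    result.occupancy = occ
    return result


# -- benchmark walkers -------------------------------------------------------


def benchmark_bee(m: int, master_seed: int, *, t_max: float = 15.0,
                  dt: float = DT) -> np.ndarray:
    """Uniform-location benchmark: summed place-cell rates at i.i.d. positions."""
    sim_state = ContinuousSim("open", dt=dt)
    n_steps = int(round(t_max / dt))
    occ = np.zeros(sim_state.grid.n)
    for sim in range(m):
        seed = trial_seed(master_seed, sim, 0)
        occ += _engine.bee_occupancy(
            seed, n_steps, sim_state.maze.half,
            sim_state.grid.centres, sim_state.grid.sigma, sim_state.grid.peak_rate,
        )
    return occ


BEA_SPEED = 0.0015  # a.u. per step: the mean agent step magnitude in exploration


def benchmark_bea(m: int, master_seed: int, *, speed: float = BEA_SPEED,
                  t_max: float = 15.0, dt: float = DT) -> np.ndarray:
    """Fixed-speed random-walk benchmark from the centre of the open field.

    The angle is redrawn uniformly every timestep, so with the speed fixed at
    the typical agent step the walk diffuses only ~0.2 a.u. from the start
    over a trial; the agent covers ground the benchmark cannot, because its
    winner-take-all bump keeps successive actions aligned.
    """
    sim_state = ContinuousSim("open", dt=dt)
    n_steps = int(round(t_max / dt))
    occ = np.zeros(sim_state.grid.n)
    for sim in range(m):
        seed = trial_seed(master_seed, sim, 0)
        occ += _engine.bea_occupancy(
            seed, n_steps, sim_state.maze.half, sim_state.maze.bounce_d, speed,
            sim_state.grid.centres, sim_state.grid.sigma, sim_state.grid.peak_rate,
        )
    return occ


def run_from_config(cfg: dict) -> ExperimentResult:
    """Dispatch a validated configuration (see `config.load_config`) to the
    appropriate experiment runner."""
    from .plasticity import make_rule

    maze = cfg["maze"]
    rule_name = cfg["rule"]
    if maze == "radial":
        return run_radial_experiment(
            ach=rule_name == "snplast_ach", m=cfg["m"],
            n_trials=cfg["trials_phase1"], master_seed=cfg["seed"],
        )
    if maze == "tmaze":
        return run_tmaze_experiment(
            ach=rule_name == "snplast_ach", m=cfg["m"],
            n_trials=cfg["trials_phase1"], master_seed=cfg["seed"],
            dt=cfg["dt"],
        )
    rule = make_rule(rule_name, cfg["params"])
    return run_open_field_experiment(
        rule, cfg["m"], cfg["seed"], variant=maze,
        trials_phase1=cfg["trials_phase1"], trials_phase2=cfg["trials_phase2"],
        early_stop_phase2=cfg["early_stop_phase2"],
        snapshot_trials=cfg["snapshot_trials"],
        record_every=cfg["record_every"], dt=cfg["dt"],
    )


# -- action selection (reference ops) ----------------------------------------


def select_action_continuous(rho, directions, allowed=None) -> np.ndarray:
    """a(t) = (1/N) * sum_j rho_j * a_j, the population vector of the ring.

    N is the number of available action neurons: the full population
    normally, the restricted subset where the maze disallows directions
    (whose neurons contribute neither spikes nor direction).
    """
    rho = np.asarray(rho, dtype=float)
    directions = np.asarray(directions, dtype=float)
    n = rho.shape[0]
    if allowed is not None:
        allowed = np.asarray(allowed, dtype=bool)
        rho = np.where(allowed, rho, 0.0)
        n = max(int(allowed.sum()), 1)
    return directions.T @ rho / n


def select_action_discrete(rho, rng: np.random.Generator) -> int:
    """argmax of the filtered rates; exact ties broken uniformly at random."""
    rho = np.asarray(rho, dtype=float)
    best = rho.max()
    ties = np.flatnonzero(rho == best)
    if ties.size == 1:
        return int(ties[0])
    return int(rng.choice(ties))
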