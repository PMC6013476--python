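"""Layered configuration: per-maze presets, rule presets, user overrides.

Every physical constant of the model lives here (or in the geometry/network
modules it parameterizes) rather than as a literal inside the dynamics, and
a loaded configuration is validated before an experiment runs.
"""

from __future__ import annotations

import copy

import yaml

DT = 0.001  # s, integration timestep for neural dynamics and navigation
PAUSE = 0.3  # s, consummatory pause appended to rewarded trials

# Per-environment synapse bounds and learning rates, plus the neuron-model
# constants that differ between the discrete and continuous variants.
PRESETS: dict[str, dict] = {
    # The radial maze integrates at 0.1 ms: its escape noise is sharp
    # (delta_u = 0.5 mV), so the first-spike race that decides the
    # winner-take-all competition needs sub-ms resolution to resolve a single
    # leader before lateral inhibition (EPSP rise time ~ms) can act.
    "radial": dict(
        w_min=1.0, w_max=5.0, w_in=2.0, eta_ach=0.001, eta_da=0.01,
        t_max=5.0, lam_pc=4000.0, n_actions=8, lam0=100.0, delta_u=0.5,
        eps0=20.0, w_lat=-250.0, dt=1e-4,
    ),
    "tmaze": dict(
        w_min=1.0, w_max=5.0, w_in=3.0, eta_ach=0.1, eta_da=0.3,
        t_max=5.0, lam_pc=400.0, sigma=0.2, n_actions=40, lam0=60.0,
        delta_u=2.0, eps0=10.0,
    ),
    "open": dict(
        w_min=1.0, w_max=3.0, w_in=2.0, eta_ach=0.002, eta_da=0.01,
        t_max=15.0, lam_pc=400.0, sigma=0.4, n_actions=40, lam0=60.0,
        delta_u=2.0, eps0=20.0,
    ),
}
PRESETS["open_obstacles"] = dict(PRESETS["open"])

RULE_PRESETS: dict[str, dict] = {
    "snplast_ach": {},
    "snplast_noach": {},
    "rstdp": dict(eta=0.01, a_pp=1.0, a_pn=1.0),
    "dynamic_reward": dict(eta=0.01, beta=0.75),
    "negative_feedback": dict(eta=0.01),
}

MAZES = tuple(PRESETS)
RULES = tuple(RULE_PRESETS)


def preset(variant: str) -> dict:
    if variant not in PRESETS:
        raise ValueError(f"unknown maze variant: {variant!r} (expected one of {MAZES})")
    return dict(PRESETS[variant])


def load_config(path_or_dict) -> dict:
    """Load and validate an experiment configuration.

    Required keys: ``maze`` and ``rule``; optional: ``m``, ``seed``,
    ``trials_phase1``, ``trials_phase2``, ``early_stop_phase2``, ``dt``, and a
    ``params`` block overriding preset values.  Unknown keys are rejected.
    """
    if isinstance(path_or_dict, dict):
        raw = copy.deepcopy(path_or_dict)
    else:
        with open(path_or_dict) as fh:
            raw = yaml.safe_load(fh) or {}
    known = {
        "maze", "rule", "m", "seed", "trials_phase1", "trials_phase2",
        "early_stop_phase2", "dt", "params", "record_every", "snapshot_trials",
        "zone_centre",
    }
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    maze = raw.get("maze")
    if maze not in MAZES:
        raise ValueError(f"config key 'maze' must be one of {MAZES}, got {maze!r}")
    rule = raw.get("rule")
    if rule not in RULES:
        raise ValueError(f"config key 'rule' must be one of {RULES}, got {rule!r}")
    if maze == "radial" and rule not in ("snplast_ach", "snplast_noach"):
        raise ValueError("the radial maze runs only the sn-Plast rules")
    cfg = dict(
        maze=maze, rule=rule,
        m=int(raw.get("m", 1)), seed=int(raw.get("seed", 0)),
        trials_phase1=int(raw.get("trials_phase1", 20)),
        trials_phase2=int(raw.get("trials_phase2", 0)),
        early_stop_phase2=bool(raw.get("early_stop_phase2", False)),
        dt=float(raw.get("dt", DT)),
        record_every=int(raw.get("record_every", 0)),
        snapshot_trials=tuple(raw.get("snapshot_trials", ())),
    )
    if "zone_centre" in raw and raw["zone_centre"] is not None:
        cfg["zone_centre"] = tuple(float(v) for v in raw["zone_centre"])
    params = dict(PRESETS[maze])
    params.update(RULE_PRESETS[rule])
    params.update(raw.get("params", {}) or {})
    cfg["params"] = params
    _validate_zone_sanity(cfg)
    return cfg


def _validate_zone_sanity(cfg: dict) -> None:
    from .geometry import make_maze, standard_zones

    if cfg["maze"] == "radial":
        return
    maze = make_maze(cfg["maze"])
    zones = list(standard_zones(cfg["maze"]))
    if "zone_centre" in cfg:
        from .geometry import RewardZone

        zones.append(RewardZone("disc", centre=cfg["zone_centre"]))
    for zone in zones:
        if zone is not None and zone.kind == "disc" and not maze.contains(zone.centre):
            raise ValueError(f"reward zone centred at {zone.centre} is outside the maze")
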