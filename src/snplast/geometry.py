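"""Maze environments: boundaries, obstacles, bounce rule, reward zones.

All four environments live on (a subset of) a square plane of side 4 a.u.
centred on the origin.  The radial-arm maze is purely symbolic (a single
decision among eight arms, no 2-D trajectory); the T-maze, open field and
obstacle field are continuous 2-D mazes in which the agent moves every
timestep and is bounced back by a fixed distance ``d`` whenever a move
would cross a wall or an obstacle face.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# Default dimensions (a.u.)
SIDE = 4.0
HALF = SIDE / 2.0
BOUNCE_D = 0.01

# Obstacle field: two vertical bars centred on the x axis.
OBS_SX = 0.4
OBS_SY = 0.8
OBS_X1 = -1.2
OBS_X2 = 1.2

# T-maze: stem length 3.2, width 0.6; two arms of length 1.7, width 0.8,
# carved out of the 4x4 plane with the arms forming a top bar.
STEM_HALF_W = 0.3
STEM_Y_LO = -2.0
STEM_Y_HI = 1.2
BAR_Y_LO = 1.2
BAR_Y_HI = 2.0
TMAZE_X_RIGHT = 1.0
TMAZE_X_LEFT = -1.0


@dataclass(frozen=True)
class MoveOutcome:
    position: np.ndarray
    bounced: bool


@dataclass(frozen=True)
class RewardZone:
    """Reward test: a disc, a T-maze arm-crossing line, or a radial arm index.

    Exactly one of the three kinds is active, selected by ``kind``.
    """

    kind: str  # {"disc", "arm-crossing", "arm-index"}
    centre: tuple[float, float] | None = None
    radius: float = 0.3
    side: str = "right"  # arm-crossing: which vertical line
    arm: int | None = None  # radial maze: rewarded arm index

    def reached(self, p) -> bool:
        if self.kind == "disc":
            dx = p[0] - self.centre[0]
            dy = p[1] - self.centre[1]
            return dx * dx + dy * dy <= self.radius * self.radius
        if self.kind == "arm-crossing":
            if self.side == "right":
                return p[0] >= TMAZE_X_RIGHT
            return p[0] <= TMAZE_X_LEFT
        raise ValueError("arm-index zones are tested against arm choices, not positions")

    def reached_arm(self, arm: int) -> bool:
        if self.kind != "arm-index":
            raise ValueError(f"not an arm-index zone: {self.kind}")
        return arm == self.arm


@dataclass(frozen=True)
class MazeGeometry:
    """One of the four environments.

    ``variant`` is one of ``radial``, ``tmaze``, ``open``, ``open_obstacles``.
    Obstacles are axis-aligned rectangles stored as (xmin, xmax, ymin, ymax).
    """

    variant: str
    half: float = HALF
    bounce_d: float = BOUNCE_D
    obstacles: tuple[tuple[float, float, float, float], ...] = ()
    start: tuple[float, float] = (0.0, 0.0)
    n_arms: int = 8  # radial only

    @property
    def continuous(self) -> bool:
        return self.variant != "radial"

    # -- point membership ---------------------------------------------------

    def contains(self, p) -> bool:
        """True iff p lies inside the maze and outside all obstacles."""
        x, y = float(p[0]), float(p[1])
        if not (-self.half <= x <= self.half and -self.half <= y <= self.half):
            return False
        if self.variant == "tmaze":
            in_stem = abs(x) <= STEM_HALF_W and STEM_Y_LO <= y <= STEM_Y_HI
            in_bar = BAR_Y_LO <= y <= BAR_Y_HI
            if not (in_stem or in_bar):
                return False
        for (xmin, xmax, ymin, ymax) in self.obstacles:
            if xmin < x < xmax and ymin < y < ymax:
                return False
        return True

    # -- movement -----------------------------------------------------------

    def _inward_unit(self, p) -> np.ndarray:
        """Unit vector pointing away from the boundary element(s) nearest p.

        Used for the bounce: the sum of the inward normals of all violated
        (or nearest) faces, normalized.  For a wall this is the single inward
        normal; at a corner it is the normalized sum of the two.
        """
        x, y = float(p[0]), float(p[1])
        n = np.zeros(2)
        h = self.half
        tol = 1e-12
        if self.variant == "tmaze":
            in_bar = y >= BAR_Y_LO
            if in_bar:
                if x <= -h + tol:
                    n[0] += 1.0
                if x >= h - tol:
                    n[0] -= 1.0
                if y >= BAR_Y_HI - tol:
                    n[1] -= 1.0
                if y <= BAR_Y_LO + tol and abs(x) > STEM_HALF_W:
                    n[1] += 1.0
            else:
                if x <= -STEM_HALF_W + tol:
                    n[0] += 1.0
                if x >= STEM_HALF_W - tol:
                    n[0] -= 1.0
                if y <= STEM_Y_LO + tol:
                    n[1] += 1.0
        else:
            if x <= -h + tol:
                n[0] += 1.0
            if x >= h - tol:
                n[0] -= 1.0
            if y <= -h + tol:
                n[1] += 1.0
            if y >= h - tol:
                n[1] -= 1.0
            for (xmin, xmax, ymin, ymax) in self.obstacles:
                # nearest face of an obstacle the agent is pressed against
                if xmin - tol <= x <= xmax + tol and ymin - tol <= y <= ymax + tol:
                    dists = (x - xmin, xmax - x, y - ymin, ymax - y)
                    k = int(np.argmin(dists))
                    n += ((-1, 0), (1, 0), (0, -1), (0, 1))[k]
        norm = np.hypot(n[0], n[1])
        if norm == 0.0:
            return n
        return n / norm

    def apply_move(self, p, delta) -> MoveOutcome:
        """One navigation update: either take the step or bounce back by d.

        If ``p + delta`` stays inside, the move is taken.  Otherwise the agent
        is instantly displaced by ``bounce_d`` along the inward normal of the
        violated boundary (it "turns by 180 degrees"), and the outcome is
        flagged as a bounce.  The returned position is always inside.
        """
        p = np.asarray(p, dtype=float)
        if not self.contains(p):
            raise ValueError(f"position {p} outside maze {self.variant}")
        cand = p + np.asarray(delta, dtype=float)
        if self.contains(cand):
            return MoveOutcome(cand, False)
        u = self._bounce_normal(p, cand)
        new = p + self.bounce_d * u
        if not self.contains(new):
            # pathological corner: stay put rather than escape the maze
            new = p
        return MoveOutcome(new, True)

    def _bounce_normal(self, p, cand) -> np.ndarray:
        """Inward unit vector opposing the boundary the candidate move violates."""
        x, y = float(cand[0]), float(cand[1])
        n = np.zeros(2)
        h = self.half
        if x < -h:
            n[0] += 1.0
        if x > h:
            n[0] -= 1.0
        if y < -h:
            n[1] += 1.0
        if y > h:
            n[1] -= 1.0
        if self.variant == "tmaze" and n[0] == 0.0 and n[1] == 0.0:
            # inside the bounding square but outside stem ∪ bar
            if float(p[1]) < BAR_Y_LO:  # leaving through a stem side wall / shoulder
                if x > STEM_HALF_W:
                    n[0] -= 1.0
                elif x < -STEM_HALF_W:
                    n[0] += 1.0
                else:
                    n[1] += 1.0
            else:  # dropping out of the bar outside the stem
                n[1] += 1.0
        for (xmin, xmax, ymin, ymax) in self.obstacles:
            if xmin < x < xmax and ymin < y < ymax:
                # push back across the face nearest the pre-move position
                px, py = float(p[0]), float(p[1])
                dists = (abs(px - xmin), abs(px - xmax), abs(py - ymin), abs(py - ymax))
                k = int(np.argmin(dists))
                n += ((-1, 0), (1, 0), (0, -1), (0, 1))[k]
        norm = np.hypot(n[0], n[1])
        if norm == 0.0:
            return self._inward_unit(p)
        return n / norm

    # -- masks --------------------------------------------------------------

    def boundary_weight_mask(self, place_centres, action_dirs) -> np.ndarray:
        """Allowed (True) mask over place x action feed-forward weights.

        An entry is False — the weight is frozen at zero — iff stepping once
        from the place-cell centre along the action direction leaves the maze.
        Interior cells keep all their weights; cells on a wall lose the
        outward directions; grid cells lying outside the corridor of the
        T-maze (or inside an obstacle) lose all of them.
        """
        centres = np.asarray(place_centres, dtype=float)
        dirs = np.asarray(action_dirs, dtype=float)
        mask = np.empty((centres.shape[0], dirs.shape[0]), dtype=bool)
        for i, c in enumerate(centres):
            for j, a in enumerate(dirs):
                mask[i, j] = self.contains(c + a)
        return mask

    def allowed_action_mask(self, p, thetas) -> np.ndarray:
        """T-maze action restriction at position p.

        In the stem only upward directions (θ in [π/4, 3π/4]) are available;
        in the top bar only horizontal ones (θ in [−π/4, π/4] ∪ [3π/4, 5π/4]).
        θ is the polar angle of the direction (0 = east, π/2 = north).
        """
        if self.variant != "tmaze":
            raise ValueError("action restriction applies to the T-maze only")
        th = np.mod(np.asarray(thetas, dtype=float), 2.0 * np.pi)
        if float(p[1]) < BAR_Y_LO:
            return (th >= np.pi / 4) & (th <= 3 * np.pi / 4)
        horiz_right = (th <= np.pi / 4) | (th >= 7 * np.pi / 4)
        horiz_left = (th >= 3 * np.pi / 4) & (th <= 5 * np.pi / 4)
        return horiz_right | horiz_left


def make_maze(variant: str) -> MazeGeometry:
    """Build one of the four standard environments by config key."""
    if variant == "open":
        return MazeGeometry("open", start=(0.0, 0.0))
    if variant == "open_obstacles":
        obs = tuple(
            (cx - OBS_SX / 2, cx + OBS_SX / 2, -OBS_SY / 2, OBS_SY / 2)
            for cx in (OBS_X1, OBS_X2)
        )
        return MazeGeometry("open_obstacles", obstacles=obs, start=(0.0, 0.0))
    if variant == "tmaze":
        return MazeGeometry("tmaze", start=(0.0, -2.0))
    if variant == "radial":
        return MazeGeometry("radial", n_arms=8)
    raise ValueError(f"unknown maze variant: {variant!r}")


def standard_zones(variant: str) -> tuple[RewardZone, RewardZone | None]:
    """The (phase-1, phase-2) reward zones used in the standard tasks."""
    if variant == "open":
        return (
            RewardZone("disc", centre=(1.5, 1.5)),
            RewardZone("disc", centre=(-1.5, -1.5)),
        )
    if variant == "open_obstacles":
        return (
            RewardZone("disc", centre=(0.0, 1.5)),
            RewardZone("disc", centre=(0.0, -1.5)),
        )
    if variant == "tmaze":
        return RewardZone("arm-crossing", side="right"), None
    if variant == "radial":
        return RewardZone("arm-index", arm=0), None
    raise ValueError(f"unknown maze variant: {variant!r}")
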