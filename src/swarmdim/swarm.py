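"""Self-propelled-particle swarms and simulated observer scores.

The swarm model is a discrete-time Vicsek-type system: each agent moves at
constant speed and, at every step, re-orients toward the mean heading of its
neighbours within a fixed interaction radius (itself included), optionally
biased toward the nearest attractive stimulus, and perturbed by uniform
angular noise.  Groups of such particles, rendered as moving blobs, stand in
for overhead video of animal groups; the noise half-width ``noise_eta``
controls how ordered the group motion is.

Observer scores emulate humans rating group coordination on an integer
collective-behaviour scale (CBM, 1-12), statistically tied to the true
manifold dimensionality of the group's motion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SwarmParams",
    "SwarmTrajectory",
    "ObserverScorePair",
    "NOISE_PRESETS",
    "simulate_swarm",
    "polarization",
    "simulate_observer_scores",
    "save_trajectory",
    "load_trajectory",
    "save_observer_scores",
    "load_observer_scores",
]

#: Named angular-noise half-widths (radians) spanning the ordered and
#: disordered regimes of the alignment model.
NOISE_PRESETS: dict[str, float] = {"low": 0.1, "moderate": 1.0, "high": 2.5}

_BOUNDARIES = ("reflective", "periodic")


@dataclass(frozen=True)
class SwarmParams:
    """Parameters of the self-propelled-particle model.

    Attributes
    ----------
    n_agents:
        Number of particles (>= 1).
    domain_size:
        Side of the square arena, arbitrary length units.
    speed:
        Distance travelled per step (> 0).
    noise_eta:
        Half-width of the uniform heading perturbation, radians, in [0, pi].
    interaction_radius:
        Alignment neighbourhood radius (same units as positions).
    stimuli:
        0, 1 or 2 attractive planar points inside the arena.
    stimulus_strength:
        Dimensionless weight mixing the attraction direction into the
        alignment direction (0 = pure alignment).
    boundary:
        ``"reflective"`` (particles bounce off the walls) or ``"periodic"``
        (particles leaving one wall reappear on the opposite wall).
    seed:
        Seed for initial conditions and noise.
    """

    n_agents: int = 50
    domain_size: float = 10.0
    speed: float = 0.05
    noise_eta: float = 0.1
    interaction_radius: float = 1.5
    stimuli: tuple[tuple[float, float], ...] = ()
    stimulus_strength: float = 0.0
    boundary: str = "reflective"
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "stimuli", tuple(tuple(map(float, s)) for s in self.stimuli))
        for name in ("domain_size", "speed", "noise_eta", "interaction_radius",
                     "stimulus_strength"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.n_agents < 1:
            raise ValueError("n_agents must be >= 1")
        if self.speed <= 0:
            raise ValueError("speed must be > 0")
        if not 0.0 <= self.noise_eta <= math.pi:
            raise ValueError("noise_eta must lie in [0, pi]")
        if self.interaction_radius < 0:
            raise ValueError("interaction_radius must be >= 0")
        if len(self.stimuli) > 2:
            raise ValueError("at most two stimuli are supported")
        if any(not (math.isfinite(x) and math.isfinite(y)) for x, y in self.stimuli):
            raise ValueError("stimulus coordinates must be finite")
        if self.boundary not in _BOUNDARIES:
            raise ValueError(f"boundary must be one of {_BOUNDARIES}")

    def with_noise(self, preset: str) -> "SwarmParams":
        """Return a copy using a named noise preset (low/moderate/high)."""
        return replace(self, noise_eta=NOISE_PRESETS[preset])


@dataclass
class SwarmTrajectory:
    """Recorded particle states: the first row is the initial condition.

    ``positions`` has shape (steps, n_agents, 2) and ``headings``
    (steps, n_agents); all positions lie in [0, domain_size]^2.
    """

    positions: np.ndarray
    headings: np.ndarray
    params: SwarmParams = field(repr=False)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.headings = np.asarray(self.headings, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 2:
            raise ValueError("positions must have shape (steps, n_agents, 2)")
        if self.headings.shape != self.positions.shape[:2]:
            raise ValueError("headings shape must match positions")

    @property
    def n_steps(self) -> int:
        return self.positions.shape[0]

    @property
    def n_agents(self) -> int:
        return self.positions.shape[1]

    def polarization_series(self) -> np.ndarray:
        """Polarization of the group at every recorded step."""
        return np.array([polarization(h) for h in self.headings])


@dataclass(frozen=True)
class ObserverScorePair:
    """Two independent observer CBM scores (integers 1-12) for one trial."""

    trial_id: str
    cbm_a: int
    cbm_b: int

    def __post_init__(self) -> None:
        for v in (self.cbm_a, self.cbm_b):
            if not 1 <= v <= 12:
                raise ValueError(f"CBM scores must lie in 1..12, got {v}")

    @property
    def disagreement(self) -> int:
        return abs(self.cbm_a - self.cbm_b)


def polarization(headings: Sequence[float] | np.ndarray) -> float:
    """Magnitude of the mean unit-heading vector; 1 = fully aligned.

    Raises
    ------
    ValueError
        If no headings are given.
    """
    h = np.asarray(headings, dtype=float).ravel()
    if h.size == 0:
        raise ValueError("polarization requires at least one heading")
    return float(np.hypot(np.cos(h).mean(), np.sin(h).mean()))


def _alignment_direction(pos: np.ndarray, head: np.ndarray, radius: float) -> np.ndarray:
    """Mean-of-neighbours heading vectors (self always included)."""
    diff = pos[:, None, :] - pos[None, :, :]
    within = (diff ** 2).sum(-1) <= radius ** 2
    ux, uy = np.cos(head), np.sin(head)
    ax = within @ ux
    ay = within @ uy
    return np.stack([ax, ay], axis=1)


def simulate_swarm(
    params: SwarmParams,
    n_steps: int,
    initial_positions: np.ndarray | None = None,
    initial_headings: np.ndarray | None = None,
) -> SwarmTrajectory:
    """Run the alignment/attraction/noise dynamics for ``n_steps`` states.

    The returned trajectory records ``n_steps`` states, the first of which is
    the initial condition (uniform random positions and headings drawn from
    ``params.seed`` unless explicit arrays are given); each later state is
    one Vicsek update of the previous one.  Deterministic for a fixed seed.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng(params.seed)
    L = params.domain_size
    n = params.n_agents
    pos = rng.uniform(0.0, L, size=(n, 2))
    head = rng.uniform(-math.pi, math.pi, size=n)
    if initial_positions is not None:
        pos = np.array(initial_positions, dtype=float).reshape(n, 2)
        if pos.min() < 0 or pos.max() > L:
            raise ValueError("initial positions outside the domain")
    if initial_headings is not None:
        head = np.array(initial_headings, dtype=float).reshape(n)

    stimuli = np.array(params.stimuli, dtype=float).reshape(-1, 2)
    positions = np.empty((n_steps, n, 2))
    headings = np.empty((n_steps, n))
    positions[0], headings[0] = pos, head

    for t in range(1, n_steps):
        direction = _alignment_direction(pos, head, params.interaction_radius)
        norms = np.linalg.norm(direction, axis=1, keepdims=True)
        np.divide(direction, norms, out=direction, where=norms > 0)
        if stimuli.size and params.stimulus_strength > 0:
            to_stim = stimuli[None, :, :] - pos[:, None, :]
            d2 = (to_stim ** 2).sum(-1)
            nearest = to_stim[np.arange(n), d2.argmin(axis=1)]
            sn = np.linalg.norm(nearest, axis=1, keepdims=True)
            np.divide(nearest, sn, out=nearest, where=sn > 0)
            direction = direction + params.stimulus_strength * nearest
        new_head = np.arctan2(direction[:, 1], direction[:, 0])
        # degenerate cancellation: keep the previous heading
        degenerate = (direction == 0).all(axis=1)
        new_head[degenerate] = head[degenerate]
        if params.noise_eta > 0:
            new_head = new_head + rng.uniform(-params.noise_eta, params.noise_eta, size=n)

        new_pos = pos + params.speed * np.stack([np.cos(new_head), np.sin(new_head)], axis=1)
        if params.boundary == "periodic":
            new_pos = np.mod(new_pos, L)
        else:
            new_pos, new_head = _reflect(new_pos, new_head, L)
        pos = new_pos
        head = np.mod(new_head + math.pi, 2 * math.pi) - math.pi
        positions[t], headings[t] = pos, head

    return SwarmTrajectory(positions, headings, params)


def _reflect(pos: np.ndarray, head: np.ndarray, L: float) -> tuple[np.ndarray, np.ndarray]:
    """Specular reflection at the four walls; one bounce per axis suffices
    for speeds below the domain size."""
    pos = pos.copy()
    head = head.copy()
    for axis in range(2):
        low = pos[:, axis] < 0
        high = pos[:, axis] > L
        pos[low, axis] = -pos[low, axis]
        pos[high, axis] = 2 * L - pos[high, axis]
        flip = low | high
        if axis == 0:
            head[flip] = math.pi - head[flip]
        else:
            head[flip] = -head[flip]
    return pos, head


def simulate_observer_scores(
    true_dims: Sequence[int] | np.ndarray,
    noise_sd: float,
    seed: int,
    slope: float = 1.0,
    intercept: float = 0.0,
) -> list[ObserverScorePair]:
    """Simulate paired observer CBM ratings from true trial dimensionalities.

    Each of the two independent observers reports
    ``clip(round(slope * dim + intercept + N(0, noise_sd)), 1, 12)``.  The
    default identity map reflects that the CBM scale was constructed to be
    directly comparable with the embedding dimensionality (low score = high
    coordination).
    """
    dims = np.asarray(true_dims, dtype=float)
    if dims.size and dims.min() < 1:
        raise ValueError("true_dims entries must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    out = []
    for i, d in enumerate(dims):
        raw = slope * d + intercept + rng.normal(0.0, noise_sd, size=2) if noise_sd > 0 \
            else np.full(2, slope * d + intercept)
        scores = np.clip(np.floor(raw + 0.5), 1, 12).astype(int)
        out.append(ObserverScorePair(trial_id=f"trial{i:03d}", cbm_a=int(scores[0]),
                                     cbm_b=int(scores[1])))
    return out


# ---------------------------------------------------------------------------
# persistence

def save_trajectory(traj: SwarmTrajectory, csv_path: str | Path) -> None:
    """Write (step, agent, x, y, heading) rows plus a YAML sidecar of params."""
    csv_path = Path(csv_path)
    steps, agents = traj.headings.shape
    step_idx = np.repeat(np.arange(steps), agents)
    agent_idx = np.tile(np.arange(agents), steps)
    df = pd.DataFrame(
        {
            "step": step_idx,
            "agent": agent_idx,
            "x": traj.positions[:, :, 0].ravel(),
            "y": traj.positions[:, :, 1].ravel(),
            "heading": traj.headings.ravel(),
        }
    )
    df.to_csv(csv_path, index=False)
    cfg = {
        "n_agents": traj.params.n_agents,
        "domain_size": traj.params.domain_size,
        "speed": traj.params.speed,
        "noise_eta": traj.params.noise_eta,
        "interaction_radius": traj.params.interaction_radius,
        "stimuli": [list(s) for s in traj.params.stimuli],
        "stimulus_strength": traj.params.stimulus_strength,
        "boundary": traj.params.boundary,
        "seed": traj.params.seed,
    }
    csv_path.with_suffix(".yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))


def load_trajectory(csv_path: str | Path) -> SwarmTrajectory:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    cfg = yaml.safe_load(csv_path.with_suffix(".yaml").read_text())
    cfg["stimuli"] = tuple(tuple(s) for s in cfg.get("stimuli", ()))
    params = SwarmParams(**cfg)
    steps = int(df["step"].max()) + 1
    agents = int(df["agent"].max()) + 1
    df = df.sort_values(["step", "agent"])
    positions = df[["x", "y"]].to_numpy().reshape(steps, agents, 2)
    headings = df["heading"].to_numpy().reshape(steps, agents)
    return SwarmTrajectory(positions, headings, params)


def save_observer_scores(scores: Sequence[ObserverScorePair], path: str | Path) -> None:
    pd.DataFrame(
        [(s.trial_id, s.cbm_a, s.cbm_b) for s in scores],
        columns=["trial_id", "cbm_a", "cbm_b"],
    ).to_csv(path, index=False)


def load_observer_scores(path: str | Path) -> list[ObserverScorePair]:
    df = pd.read_csv(path)
    return [
        ObserverScorePair(str(r.trial_id), int(r.cbm_a), int(r.cbm_b))
        for r in df.itertuples(index=False)
    ]
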