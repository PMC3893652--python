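"""Rendering swarm trajectories to grey-scale frames, plus geometric
manifold point clouds used as ground truth for the embedding core.

Agents are drawn as dark filled discs on a light background, emulating
animals filmed from above against an arena floor.  World coordinates are
mapped linearly to pixels (the square arena scaled to fit the frame; the
image y-axis points down); a pixel belongs to a disc when its centre lies
within the disc radius, inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ingest import FrameStack, flatten
from .swarm import SwarmTrajectory

__all__ = ["RenderSpec", "ManifoldCloud", "render_frames", "make_manifold_cloud"]

_CLOUD_KINDS = ("line", "circle", "plane", "swiss_roll")
_INTRINSIC_DIM = {"line": 1, "circle": 1, "plane": 2, "swiss_roll": 2}
# dimensionality of the natural coordinates before the random orthogonal embedding
_NATURAL_DIM = {"line": 1, "circle": 2, "plane": 2, "swiss_roll": 3}


@dataclass(frozen=True)
class RenderSpec:
    """Raster geometry and grey levels for rendering.

    Defaults follow the test-scale profile (160 x 107, same 3:2 aspect as a
    960 x 640 recording); ``full_resolution()`` gives the full-resolution profile.
    """

    width: int = 160
    height: int = 107
    agent_radius: int = 4
    background_intensity: int = 220
    agent_intensity: int = 30

    def __post_init__(self) -> None:
        if self.width < 8 or self.height < 8:
            raise ValueError("frames must be at least 8 x 8 pixels")
        for name in ("background_intensity", "agent_intensity"):
            v = getattr(self, name)
            if not 0 <= v <= 255:
                raise ValueError(f"{name} must lie in 0..255")
        if self.agent_intensity == self.background_intensity:
            raise ValueError("agent and background intensities must differ")
        if self.agent_radius < 0:
            raise ValueError("agent_radius must be >= 0")

    @classmethod
    def full_resolution(cls) -> "RenderSpec":
        """Full-resolution 960 x 640 profile."""
        return cls(width=960, height=640, agent_radius=8)


@dataclass
class ManifoldCloud:
    """Points sampled on a known manifold, used as embedding ground truth."""

    points: np.ndarray
    kind: str
    intrinsic_dim: int
    noise_sd: float

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.kind not in _CLOUD_KINDS:
            raise ValueError(f"unknown cloud kind {self.kind!r}")
        if self.points.shape[1] < self.intrinsic_dim:
            raise ValueError("ambient dimension below intrinsic dimension")


def render_frames(trajectory: SwarmTrajectory, spec: RenderSpec) -> FrameStack:
    """Rasterize each recorded step as one grey frame.

    The square arena is scaled to fit inside the frame (its side spans the
    smaller frame dimension, so the whole arena is always visible, as when
    a camera captures the entire experimental space); the image y-axis
    points down.  Discs are clipped at the frame borders.  Raises if any
    agent lies outside the arena (the renderer relies on the simulator
    keeping particles inside).
    """
    pos = trajectory.positions
    L = trajectory.params.domain_size
    if pos.size and (pos.min() < 0 or pos.max() > L):
        raise ValueError("agent positions outside [0, domain_size]^2")
    scale = min(spec.width, spec.height) / L
    r = spec.agent_radius
    frames = np.full(
        (trajectory.n_steps, spec.height, spec.width),
        spec.background_intensity,
        dtype=np.uint8,
    )
    ys, xs = np.mgrid[0:spec.height, 0:spec.width]
    for t in range(trajectory.n_steps):
        frame = frames[t]
        for cx, cy in pos[t] * scale:
            x0 = max(0, int(np.floor(cx - r)))
            x1 = min(spec.width, int(np.ceil(cx + r)) + 1)
            y0 = max(0, int(np.floor(cy - r)))
            y1 = min(spec.height, int(np.ceil(cy + r)) + 1)
            if x0 >= x1 or y0 >= y1:
                continue
            mask = (xs[y0:y1, x0:x1] - cx) ** 2 + (ys[y0:y1, x0:x1] - cy) ** 2 <= r ** 2
            frame[y0:y1, x0:x1][mask] = spec.agent_intensity
    return FrameStack(
        data=flatten(frames),
        width=spec.width,
        height=spec.height,
        fps=30.0,
        sampling_period=1,
    )


def make_manifold_cloud(
    kind: str,
    n: int,
    ambient_dim: int,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ManifoldCloud:
    """Sample ``n`` points on a named manifold and embed them in
    ``ambient_dim`` dimensions via a seeded random orthogonal map, adding
    isotropic Gaussian noise of scale ``noise_sd``.

    Kinds: ``line`` and ``circle`` (intrinsic dimension 1), ``plane`` and
    ``swiss_roll`` (intrinsic dimension 2).  ``ambient_dim`` must be at
    least the dimension of the natural coordinates (1, 2, 2 and 3
    respectively).
    """
    if kind not in _CLOUD_KINDS:
        raise ValueError(f"unknown cloud kind {kind!r}; choose from {_CLOUD_KINDS}")
    if n < 10:
        raise ValueError("n must be >= 10")
    k = _NATURAL_DIM[kind]
    if ambient_dim < k:
        raise ValueError(f"{kind} needs ambient_dim >= {k}")
    rng = np.random.default_rng(seed)
    if kind == "line":
        t = np.sort(rng.uniform(0.0, 10.0, size=n))
        natural = t[:, None]
    elif kind == "circle":
        theta = rng.uniform(0.0, 2 * np.pi, size=n)
        natural = np.column_stack([np.cos(theta), np.sin(theta)]) * 5.0
    elif kind == "plane":
        natural = rng.uniform(0.0, 10.0, size=(n, 2))
    else:  # swiss_roll
        # Archimedean spiral (r = t, one full turn) swept along y.  The
        # sheet width (30) is comparable to the unrolled spiral length
        # (~49) so both intrinsic directions carry appreciable spread,
        # while the gap between turns stays large relative to the sampling
        # density, avoiding between-turn shortcuts in the neighbour graph.
        t = np.pi * (1.5 + 2.0 * rng.uniform(size=n))
        y = rng.uniform(0.0, 30.0, size=n)
        natural = np.column_stack([t * np.cos(t), y, t * np.sin(t)])
    # random orthogonal map: first k columns of the QR factor of a Gaussian
    gauss = rng.standard_normal((ambient_dim, ambient_dim))
    q, _ = np.linalg.qr(gauss)
    points = natural @ q[:, :k].T
    if noise_sd > 0:
        points = points + rng.normal(0.0, noise_sd, size=points.shape)
    return ManifoldCloud(points=points, kind=kind,
                         intrinsic_dim=_INTRINSIC_DIM[kind], noise_sd=noise_sd)
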