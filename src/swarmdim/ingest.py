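"""Frame loading, grey-scale conversion, temporal sampling and flattening.

A trial video is reduced to an ``n x d`` matrix ``Z`` of grey levels: one row
per retained frame, one column per pixel.  Frames are subsampled at a period
``s`` chosen inversely proportional to the characteristic on-screen speed of
the species, so that consecutive retained frames differ by a comparable
amount of motion across species.  With the standard recording profile
(30 fps) every built-in species preset retains exactly 900 frames.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np

__all__ = [
    "FrameStack",
    "SamplingPlan",
    "SPECIES_PRESETS",
    "to_grayscale",
    "compute_sampling_period",
    "sample_frames",
    "flatten",
    "unflatten",
    "load_frame_directory",
    "save_frame_stack",
    "load_frame_stack",
]

_GREY_WEIGHTS = np.array([0.299, 0.587, 0.114])  # broadcast-standard luminance


@dataclass
class FrameStack:
    """An ordered stack of grey-scale frames flattened to pixel rows.

    ``data`` is an ``n x d`` integer matrix with entries in {0, ..., 255}
    and ``d = width * height``.
    """

    data: np.ndarray
    width: int
    height: int
    fps: float = 30.0
    sampling_period: int = 1

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (frames x pixels) matrix")
        if self.data.shape[0] < 2:
            raise ValueError("a frame stack needs at least two frames")
        if self.data.shape[1] != self.width * self.height:
            raise ValueError(
                f"pixel count {self.data.shape[1]} != width*height "
                f"{self.width * self.height}"
            )
        if self.data.size and (self.data.min() < 0 or self.data.max() > 255):
            raise ValueError("grey levels must lie in 0..255")
        if self.sampling_period < 1:
            raise ValueError("sampling_period must be >= 1")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.data.shape[1]

    def frame(self, i: int) -> np.ndarray:
        """Frame ``i`` reshaped back to (height, width)."""
        return unflatten(self.data[i], self.height, self.width)


@dataclass(frozen=True)
class SamplingPlan:
    """Temporal sampling profile of one species/condition.

    ``T`` seconds of video at ``fps`` frames/second, subsampled every ``s``
    frames; ``v_pix`` is the characteristic species speed in pixels/frame
    (relative to the fastest, reference species).
    """

    T: float
    fps: float
    s: int
    v_pix: float = 1.0

    def __post_init__(self) -> None:
        if self.s < 1 or int(self.s) != self.s:
            raise ValueError("s must be a positive integer number of frames")
        if self.T * self.fps < self.s:
            raise ValueError("video shorter than one sampling period")

    @property
    def total_frames(self) -> int:
        return int(self.T * self.fps)

    @property
    def retained_frames(self) -> int:
        """Frames kept when sampling indices 0, s, 2s, ..."""
        return int(np.ceil(self.total_frames / self.s))


#: Recording profiles per species (video length T in seconds, sampling
#: period s in frames, at 30 fps).  Every profile retains T*30/s = 900
#: frames.  ``v_pix`` is expressed relative to the fastest species (fish in
#: the presence of stimuli, sampled every frame); fish slow down by a factor
#: of twenty when no stimulus is present, hence the separate profile.
SPECIES_PRESETS: dict[str, SamplingPlan] = {
    "ants": SamplingPlan(T=390, fps=30, s=13, v_pix=1 / 13),
    "fish": SamplingPlan(T=30, fps=30, s=1, v_pix=1.0),
    "fish-nostim": SamplingPlan(T=600, fps=30, s=20, v_pix=1 / 20),
    "frogs": SamplingPlan(T=480, fps=30, s=16, v_pix=1 / 16),
    "chickens": SamplingPlan(T=480, fps=30, s=16, v_pix=1 / 16),
    "humans": SamplingPlan(T=600, fps=30, s=20, v_pix=1 / 20),
}

_TARGET_FRAMES = 900


def to_grayscale(rgb_frame: np.ndarray) -> np.ndarray:
    """Convert an ``h x w x 3`` RGB frame to integer grey levels.

    Uses the broadcast-standard luminance weights (0.299, 0.587, 0.114) and
    rounds half away from zero; channel values must be in 0..255.
    """
    arr = np.asarray(rgb_frame)
    if arr.ndim == 2:
        return arr.astype(np.uint8)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected h x w x 3 RGB input, got shape {arr.shape}")
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("channel values must lie in 0..255")
    grey = arr.astype(float) @ _GREY_WEIGHTS
    return np.floor(grey + 0.5).astype(np.uint8)


def compute_sampling_period(v_pix: float, v_ref: float, s_ref: int = 1) -> int:
    """Sampling period in frames, inversely proportional to species speed.

    ``s = round(s_ref * v_ref / v_pix)``, never below 1.  The reference
    species is the fastest one (sampled at ``s_ref`` frames with speed
    ``v_ref``); slower species are sampled proportionally more sparsely so
    that per-sample displacement is comparable.
    """
    if v_pix <= 0 or v_ref <= 0 or s_ref <= 0:
        raise ValueError("speeds and the reference period must be positive")
    return max(1, int(np.floor(s_ref * v_ref / v_pix + 0.5)))


def sample_frames(stack: FrameStack, s: int) -> FrameStack:
    """Retain frames at indices 0, s, 2s, ...; updates the sampling period."""
    if s < 1:
        raise ValueError("sampling period must be >= 1")
    data = stack.data[::s]
    if data.shape[0] < 2:
        raise ValueError(f"sampling every {s} frames retains fewer than 2 frames")
    return FrameStack(
        data=data,
        width=stack.width,
        height=stack.height,
        fps=stack.fps,
        sampling_period=stack.sampling_period * s,
    )


def apply_plan(stack: FrameStack, plan: SamplingPlan) -> FrameStack:
    """Sample a stack per a species plan, warning if the retained count is
    not the standard 900 frames."""
    out = sample_frames(stack, plan.s)
    if out.n_frames != _TARGET_FRAMES:
        warnings.warn(
            f"plan retains {out.n_frames} frames, not the standard "
            f"{_TARGET_FRAMES}",
            stacklevel=2,
        )
    return out


def flatten(frames: Sequence[np.ndarray] | np.ndarray) -> np.ndarray:
    """Stack ``h x w`` frames into an ``n x (h*w)`` matrix, row-major scan."""
    frames = [np.asarray(f) for f in frames]
    if not frames:
        raise ValueError("no frames to flatten")
    shape = frames[0].shape
    if any(f.shape != shape for f in frames):
        raise ValueError("all frames must share the same dimensions")
    if len(shape) != 2:
        raise ValueError("frames must be 2-D grey images")
    return np.stack([f.reshape(-1) for f in frames])


def unflatten(row: np.ndarray, height: int, width: int) -> np.ndarray:
    return np.asarray(row).reshape(height, width)


def load_frame_directory(path: str | Path, fps: float = 30.0) -> FrameStack:
    """Load a directory of PNG/TIFF/JPEG frames (lexicographic order) as a
    grey-scale FrameStack; RGB frames are converted on the fly."""
    path = Path(path)
    files = sorted(
        p for p in path.iterdir()
        if p.suffix.lower() in {".png", ".tif", ".tiff", ".jpg", ".jpeg"}
    )
    if len(files) < 2:
        raise ValueError(f"need at least two frames in {path}")
    frames = []
    for f in files:
        img = iio.imread(f)
        if img.ndim == 3:
            img = img[..., :3]
            img = to_grayscale(img)
        frames.append(img)
    h, w = frames[0].shape
    return FrameStack(data=flatten(frames), width=w, height=h, fps=fps)


def save_frame_stack(stack: FrameStack, out_dir: str | Path) -> list[Path]:
    """Write frames as zero-padded 8-bit grey PNGs (frame_0000.png, ...)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i in range(stack.n_frames):
        p = out_dir / f"frame_{i:05d}.png"
        iio.imwrite(p, stack.frame(i).astype(np.uint8))
        paths.append(p)
    return paths


def load_frame_stack(out_dir: str | Path, fps: float = 30.0) -> FrameStack:
    return load_frame_directory(out_dir, fps=fps)
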