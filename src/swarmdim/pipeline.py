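"""End-to-end orchestration: simulate -> render -> ingest -> embed -> stats.

A *run* mimics the structure of the video study: several synthetic
"species" (swarm presets that differ in alignment noise), each observed
under 0, 1 and 2 attractive stimuli, with replicate trials per cell.  Every
trial yields an embedding dimensionality; simulated observers then score
the trials on the CBM scale, the most observer-consistent trials per cell
are selected, and the dimensionality/CBM correlation plus the species and
condition ANOVAs (with protected post-hoc tests) are computed.

All randomness flows from a single master seed through
``numpy.random.SeedSequence`` spawning, so identical configurations
reproduce byte-identical trial tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import stats as bstats
from .ingest import FrameStack
from .isomap import EmbeddingResult, isomap
from .render import RenderSpec, render_frames
from .swarm import (NOISE_PRESETS, SwarmParams, SwarmTrajectory,
                    simulate_observer_scores, simulate_swarm)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ExperimentReport", "default_species", "run_trial",
           "run_experiment", "stimuli_for_condition"]


def default_species() -> dict[str, SwarmParams]:
    """Two synthetic species differing only in alignment noise: an ordered
    ("schooling") group at the low-noise preset and a disordered one at the
    high-noise preset."""
    base = SwarmParams(n_agents=40, domain_size=10.0, speed=0.08,
                      interaction_radius=3.0, boundary="periodic",
                      stimulus_strength=0.5)
    return {
        "ordered": replace(base, noise_eta=NOISE_PRESETS["low"]),
        "disordered": replace(base, noise_eta=NOISE_PRESETS["high"]),
    }


def stimuli_for_condition(condition: int, domain_size: float) -> tuple[tuple[float, float], ...]:
    """Place 0, 1 or 2 attractive stimuli in the arena (one central, or two
    separated along the horizontal midline)."""
    if condition == 0:
        return ()
    if condition == 1:
        return ((0.5 * domain_size, 0.5 * domain_size),)
    if condition == 2:
        return ((0.3 * domain_size, 0.5 * domain_size),
                (0.7 * domain_size, 0.5 * domain_size))
    raise ValueError("condition must be 0, 1 or 2")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full synthetic study.

    Defaults reproduce the standard analysis profile (nu=11, d_max=11,
    threshold=0.05) at a test-scale render (160 x 107 pixels, 300 frames)
    so a full run completes in minutes; ``full_resolution`` switches to
    960 x 640 with 900 frames.
    """

    species: dict[str, SwarmParams] = field(default_factory=default_species)
    render: RenderSpec = field(default_factory=RenderSpec)
    n_frames: int = 300
    sampling_period: int = 20
    nu: int = 11
    d_max: int = 11
    threshold: float = 0.05
    n_trials: int = 3
    conditions: tuple[int, ...] = (0, 1, 2)
    observer_noise_sd: float = 1.0
    select_k: int = 3
    master_seed: int = 0
    full_resolution: bool = False

    def effective_render(self) -> RenderSpec:
        return RenderSpec.full_resolution() if self.full_resolution else self.render

    def effective_frames(self) -> int:
        return 900 if self.full_resolution else self.n_frames

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "species": {
                    k: {f: getattr(v, f) for f in
                        ("n_agents", "domain_size", "speed", "noise_eta",
                         "interaction_radius", "stimulus_strength", "boundary")}
                    for k, v in sorted(self.species.items())
                },
                "render": [self.effective_render().width, self.effective_render().height,
                           self.effective_render().agent_radius],
                "n_frames": self.effective_frames(),
                "sampling_period": self.sampling_period,
                "nu": self.nu, "d_max": self.d_max, "threshold": self.threshold,
                "n_trials": self.n_trials, "conditions": list(self.conditions),
                "observer_noise_sd": self.observer_noise_sd,
                "select_k": self.select_k, "master_seed": self.master_seed,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ExperimentReport:
    """Aggregated outputs of a full synthetic study."""

    trials: pd.DataFrame
    selected: pd.DataFrame
    correlation: bstats.CorrelationResult
    two_way: bstats.AnovaResult
    species_posthoc: bstats.PosthocTable
    condition_posthoc: bstats.PosthocTable
    one_way_by_species: dict[str, bstats.AnovaResult]
    one_way_posthoc: dict[str, bstats.PosthocTable]
    config_hash: str

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.trials.to_csv(out / "trials.csv", index=False)
        self.selected.to_csv(out / "selected_trials.csv", index=False)
        self.two_way.to_frame().assign(config=self.config_hash).to_csv(
            out / "two_way_anova.csv", index=False)
        self.species_posthoc.to_frame().to_csv(out / "posthoc_species.csv", index=False)
        self.condition_posthoc.to_frame().to_csv(out / "posthoc_condition.csv", index=False)
        for sp, res in self.one_way_by_species.items():
            res.to_frame().to_csv(out / f"one_way_{sp}.csv", index=False)
        (out / "correlation.json").write_text(json.dumps(
            {
                "r": self.correlation.r,
                "r_squared": self.correlation.r_squared,
                "t": self.correlation.t,
                "df": self.correlation.df,
                "p": self.correlation.p,
                "config": self.config_hash,
            },
            indent=2,
        ))


def _trial_seed(master_seed: int, species_index: int, condition: int, trial: int) -> int:
    ss = np.random.SeedSequence(entropy=master_seed,
                                spawn_key=(species_index, condition, trial))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))


def run_trial(
    config: RunConfig,
    species: str,
    condition: int,
    trial_seed: int,
    keep_frames: bool = False,
) -> tuple[EmbeddingResult, FrameStack | None]:
    """Simulate one trial, render it and estimate its dimensionality.

    Fully deterministic given (config, trial_seed).  Stage failures raise
    with the failing stage named.
    """
    params = config.species[species]
    params = replace(
        params,
        seed=trial_seed,
        stimuli=stimuli_for_condition(condition, params.domain_size),
    )
    timings: dict[str, float] = {}
    stage = "simulate"
    try:
        t0 = time.perf_counter()
        s = config.sampling_period
        traj = simulate_swarm(params, n_steps=config.effective_frames() * s)
        timings[stage] = time.perf_counter() - t0
        stage = "sample"
        # speed-scaled temporal sampling: retain every s-th state so that
        # per-retained-frame motion is comparable to the blob size
        t0 = time.perf_counter()
        traj = SwarmTrajectory(traj.positions[::s], traj.headings[::s], params)
        timings[stage] = time.perf_counter() - t0
        stage = "render"
        t0 = time.perf_counter()
        stack = render_frames(traj, config.effective_render())
        timings[stage] = time.perf_counter() - t0
        stage = "embed"
        t0 = time.perf_counter()
        result = isomap(
            stack.data,
            nu=config.nu,
            d_max=config.d_max,
            threshold=config.threshold,
        )
        timings[stage] = time.perf_counter() - t0
    except Exception:
        logger.exception("trial failed at stage %r (species=%s condition=%d seed=%d)",
                         stage, species, condition, trial_seed)
        raise
    logger.info(
        "trial species=%s condition=%d seed=%d: d=%d retained=%.2f timings=%s",
        species, condition, trial_seed, result.dimensionality,
        result.retained_fraction, {k: round(v, 2) for k, v in timings.items()},
    )
    return result, (stack if keep_frames else None)


def run_experiment(config: RunConfig, out_dir: str | Path | None = None) -> ExperimentReport:
    """Run the full synthetic study and its statistical analysis."""
    if len(config.species) < 2:
        raise ValueError("need at least two synthetic species")
    if config.n_trials < config.select_k:
        raise ValueError("need at least select_k trials per cell")
    records: list[bstats.TrialRecord] = []
    dims: list[int] = []
    meta: list[tuple[str, int, str]] = []
    for si, sp in enumerate(sorted(config.species)):
        for cond in config.conditions:
            for trial in range(config.n_trials):
                seed = _trial_seed(config.master_seed, si, cond, trial)
                result, _ = run_trial(config, sp, cond, seed)
                dims.append(result.dimensionality)
                meta.append((sp, cond, f"{sp}-c{cond}-t{trial:02d}"))

    obs_seed = int(
        np.random.SeedSequence(entropy=config.master_seed, spawn_key=(999,))
        .generate_state(1, dtype=np.uint32)[0] % (2**31 - 1)
    )
    scores = simulate_observer_scores(dims, noise_sd=config.observer_noise_sd,
                                      seed=obs_seed)
    for (sp, cond, tid), d, s in zip(meta, dims, scores):
        records.append(bstats.TrialRecord(
            species=sp, condition=cond, trial_id=tid, dimensionality=d,
            cbm_a=s.cbm_a, cbm_b=s.cbm_b,
        ))

    selected = bstats.select_reliable_trials(records, k=config.select_k)
    corr = bstats.correlation_test(
        [t.dimensionality for t in selected],
        [t.cbm_mean for t in selected],
    )
    two_way = bstats.two_way_anova(selected)
    sp_post = bstats.fisher_plsd(two_way, selected, factor="species")
    cond_post = bstats.fisher_plsd(two_way, selected, factor="condition")
    one_way = {}
    one_way_post = {}
    for sp in sorted(config.species):
        sub = [t for t in selected if t.species == sp]
        res = bstats.one_way_anova(sub, factor="condition")
        one_way[sp] = res
        one_way_post[sp] = bstats.fisher_plsd(res, sub, factor="condition")

    report = ExperimentReport(
        trials=bstats.trials_to_frame(records),
        selected=bstats.trials_to_frame(selected),
        correlation=corr,
        two_way=two_way,
        species_posthoc=sp_post,
        condition_posthoc=cond_post,
        one_way_by_species=one_way,
        one_way_posthoc=one_way_post,
        config_hash=config.config_hash(),
    )
    if out_dir is not None:
        report.save(out_dir)
    return report


def save_config(config: RunConfig, path: str | Path) -> None:
    """Persist a RunConfig as a YAML document."""
    payload = {
        "n_frames": config.n_frames,
        "sampling_period": config.sampling_period,
        "nu": config.nu,
        "d_max": config.d_max,
        "threshold": config.threshold,
        "n_trials": config.n_trials,
        "conditions": list(config.conditions),
        "observer_noise_sd": config.observer_noise_sd,
        "select_k": config.select_k,
        "master_seed": config.master_seed,
        "full_resolution": config.full_resolution,
        "render": {
            "width": config.render.width,
            "height": config.render.height,
            "agent_radius": config.render.agent_radius,
        },
        "species": {
            name: {
                "n_agents": p.n_agents,
                "domain_size": p.domain_size,
                "speed": p.speed,
                "noise_eta": p.noise_eta,
                "interaction_radius": p.interaction_radius,
                "stimulus_strength": p.stimulus_strength,
                "boundary": p.boundary,
            }
            for name, p in config.species.items()
        },
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def load_config(path: str | Path) -> RunConfig:
    payload = yaml.safe_load(Path(path).read_text())
    render = RenderSpec(**payload.pop("render", {}))
    species = {
        name: SwarmParams(**kw) for name, kw in payload.pop("species", {}).items()
    } or default_species()
    payload["conditions"] = tuple(payload.get("conditions", (0, 1, 2)))
    return RunConfig(species=species, render=render, **payload)
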