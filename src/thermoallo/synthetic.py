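"""Synthetic study generator: speed tables and raw arena trajectories.

The generator emulates the design of the beetle experiment the analysis
targets: 125 individuals of 8 species in log-spaced body-mass classes
spanning 10–303 mg, measured singly in a 490 mm circular arena filmed at
38 frames/s across 14 temperature levels evenly spaced from 8 to 32 degrees C.
Expected exploratory speed at each (mass, temperature) follows the
allometric–thermal model; observed speeds scatter around it, by default
multiplicatively log-normally (speeds are positive and the residual spread
grows with the mean).  Note that log-normal noise shifts the conditional
mean: E[v] = model * exp(sigma_log**2 / 2).

Raw trajectories are produced by a two-state (move/pause) correlated random
walk: while moving, per-frame speeds are log-normal around the individual's
target speed (mean-corrected) and the heading diffuses by wrapped-normal
steps; while paused, sub-threshold positional jitter below the 0.3 mm/s stop
threshold mimics the spurious motion of an inactive tracked animal.  The
walk reflects off the arena wall.  Everything is a deterministic function of
its configuration and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .allomodel import AlloTPCParams, CARABID_PARAMS, eval_allo_tpc
from .trajectory import Trajectory

__all__ = [
    "StudyDesign",
    "NoiseModel",
    "WalkConfig",
    "generate_speed_dataset",
    "generate_trajectory",
    "generate_study",
    "write_study",
]

HABITAT_GROUPS = ("forest", "open", "riparian")


@dataclass(frozen=True)
class StudyDesign:
    """Sampling design of a synthetic study."""

    n_individuals: int | None = 125
    n_species: int = 8
    mass_range: tuple[float, float] = (10.0, 303.0)
    temperature_levels: tuple = tuple(np.linspace(8.0, 32.0, 14))
    records_per_level: int = 3
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.mass_range
        if not (0 < lo <= hi):
            raise ValueError("mass_range must be positive and ordered")
        levels = np.asarray(self.temperature_levels, dtype=float)
        if levels.size < 1 or levels.min() < 0 or levels.max() > 60:
            raise ValueError("temperature levels must lie within [0, 60] C")
        n = self.resolved_n
        if n < self.n_species:
            raise ValueError("need at least one individual per species")

    @property
    def resolved_n(self) -> int:
        if self.n_individuals is not None:
            return self.n_individuals
        return len(self.temperature_levels) * self.records_per_level


@dataclass(frozen=True)
class NoiseModel:
    """Residual scatter around the allometric–thermal expectation.

    ``lognormal``: observed = expected * exp(N(0, sigma)) — multiplicative,
    keeps speeds positive.  ``gaussian``: observed = expected + N(0, sigma)
    in m/s, clipped at zero.  ``species_effect_sd`` adds a per-species
    additive offset (m/s); the default 0 encodes the absence of detectable
    species-specific deviations.
    """

    kind: str = "lognormal"
    sigma: float = 0.30
    species_effect_sd: float = 0.0

    def __post_init__(self):
        if self.kind not in ("lognormal", "gaussian"):
            raise ValueError("noise kind must be 'lognormal' or 'gaussian'")
        if self.sigma < 0 or self.species_effect_sd < 0:
            raise ValueError("noise dispersions must be >= 0")


@dataclass(frozen=True)
class WalkConfig:
    """Two-state correlated random walk in a circular arena."""

    arena_radius: float = 245.0       # mm (490 mm diameter arena)
    frame_rate: float = 38.0          # Hz
    duration: float = 3600.0          # s (one-hour recording)
    move_to_pause_prob: float = 0.005  # per frame
    pause_to_move_prob: float = 0.02   # per frame
    turning_sd: float = 0.3           # rad per frame while moving
    within_bout_speed_cv: float = 0.3  # CV of per-frame move speeds
    pause_jitter_max: float = 0.25    # mm/s, below the stop threshold

    def __post_init__(self):
        for p in (self.move_to_pause_prob, self.pause_to_move_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("transition probabilities must be in [0, 1]")
        if self.arena_radius <= 0 or self.frame_rate <= 0 \
                or self.duration <= 0:
            raise ValueError("arena radius, frame rate and duration must "
                             "be positive")


def _species_table(design: StudyDesign) -> pd.DataFrame:
    lo, hi = design.mass_range
    centers = np.geomspace(lo * 1.3, hi / 1.3, design.n_species) \
        if design.n_species > 1 else np.array([math.sqrt(lo * hi)])
    return pd.DataFrame({
        "species": [f"species_{i + 1:02d}" for i in range(design.n_species)],
        "mass_class_mg": centers,
        "habitat_group": [HABITAT_GROUPS[i % len(HABITAT_GROUPS)]
                          for i in range(design.n_species)],
    })


def generate_speed_dataset(design: StudyDesign = StudyDesign(),
                           truth: AlloTPCParams = CARABID_PARAMS,
                           noise: NoiseModel = NoiseModel(),
                           seed: int | None = None) -> pd.DataFrame:
    """Draw an individual-records table from the generative model.

    Species occupy log-spaced body-mass classes spanning ``mass_range``;
    individual masses jitter log-normally within class (clipped to the
    range).  Temperature levels cycle through the design's gradient so each
    level receives an (almost) equal share of individuals.  Expected speed
    is the allometric–thermal model at (mass, temperature); observed speed
    adds the configured noise.  Fully reproducible for a given seed
    (``seed`` overrides ``design.seed``).
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    n = design.resolved_n
    levels = np.asarray(design.temperature_levels, dtype=float)
    spp = _species_table(design)

    temp = levels[np.arange(n) % levels.size]
    sp_idx = rng.permutation(np.resize(np.arange(design.n_species), n))
    centers = spp["mass_class_mg"].to_numpy()[sp_idx]
    lo, hi = design.mass_range
    mass = np.clip(centers * np.exp(rng.normal(0.0, 0.15, size=n)), lo, hi)

    mu = eval_allo_tpc(truth, mass, temp)
    if noise.kind == "lognormal":
        speed = mu * np.exp(rng.normal(0.0, noise.sigma, size=n))
    else:
        speed = np.clip(mu + rng.normal(0.0, noise.sigma, size=n), 0.0, None)
    if noise.species_effect_sd > 0:
        offsets = rng.normal(0.0, noise.species_effect_sd,
                             size=design.n_species)
        speed = np.clip(speed + offsets[sp_idx], 0.0, None)

    return pd.DataFrame({
        "individual_id": [f"ind_{i + 1:03d}" for i in range(n)],
        "species": spp["species"].to_numpy()[sp_idx],
        "habitat_group": spp["habitat_group"].to_numpy()[sp_idx],
        "mass_mg": mass,
        "temperature_C": temp,
        "speed_m_s": speed,
    })


def generate_trajectory(cfg: WalkConfig, target_speed: float,
                        seed: int = 0,
                        individual_id: str = "sim") -> Trajectory:
    """Simulate one tracked individual with a given mean active speed (m/s).

    The per-frame move speeds are mean-corrected log-normal, so the
    within-bout mean speed converges to ``target_speed``; recovered
    exploratory speed is therefore approximately unbiased for the target
    (boundary reflections aside).
    """
    if not target_speed > 0:
        raise ValueError("target_speed must be > 0")
    v_mm = target_speed * 1000.0
    dt = 1.0 / cfg.frame_rate
    if v_mm * dt > cfg.arena_radius:
        raise ValueError(
            "target speed crosses the arena in under two frames; "
            "reduce the speed or enlarge the arena")
    n_frames = int(round(cfg.duration * cfg.frame_rate)) + 1
    n_steps = n_frames - 1
    rng = np.random.default_rng(seed)

    cv = cfg.within_bout_speed_cv
    s_log = math.sqrt(math.log1p(cv * cv)) if cv > 0 else 0.0
    move_speeds = v_mm * np.exp(
        rng.normal(-0.5 * s_log * s_log, s_log, size=n_steps)) \
        if s_log > 0 else np.full(n_steps, v_mm)
    turns = rng.normal(0.0, cfg.turning_sd, size=n_steps)
    u_state = rng.random(n_steps)
    pause_speeds = rng.uniform(0.0, cfg.pause_jitter_max, size=n_steps)
    pause_headings = rng.uniform(0.0, 2.0 * math.pi, size=n_steps)

    x = np.empty(n_frames)
    y = np.empty(n_frames)
    # start mid-radius to delay the first wall contact
    theta0 = rng.uniform(0.0, 2.0 * math.pi)
    x[0] = 0.5 * cfg.arena_radius * math.cos(theta0)
    y[0] = 0.5 * cfg.arena_radius * math.sin(theta0)
    heading = rng.uniform(0.0, 2.0 * math.pi)
    moving = cfg.move_to_pause_prob < 1.0
    R = cfg.arena_radius

    for i in range(n_steps):
        if moving:
            if u_state[i] < cfg.move_to_pause_prob:
                moving = False
        else:
            if u_state[i] < cfg.pause_to_move_prob:
                moving = True
        if moving:
            heading += turns[i]
            step = move_speeds[i] * dt
            dx = step * math.cos(heading)
            dy = step * math.sin(heading)
        else:
            step = pause_speeds[i] * dt
            dx = step * math.cos(pause_headings[i])
            dy = step * math.sin(pause_headings[i])
        nx, ny = x[i] + dx, y[i] + dy
        r = math.hypot(nx, ny)
        if r > R:
            # fold radially inside and reflect the heading off the wall
            scale = (2.0 * R - r) / r
            nx *= scale
            ny *= scale
            norm = math.hypot(nx, ny)
            if norm > 0 and moving:
                ux, uy = nx / norm, ny / norm
                hx, hy = math.cos(heading), math.sin(heading)
                dot = hx * ux + hy * uy
                heading = math.atan2(hy - 2 * dot * uy, hx - 2 * dot * ux)
        x[i + 1], y[i + 1] = nx, ny

    t = np.arange(n_frames) * dt
    return Trajectory(individual_id=individual_id, t=t, x=x, y=y,
                      frame_rate=cfg.frame_rate)


def generate_study(design: StudyDesign = StudyDesign(),
                   truth: AlloTPCParams = CARABID_PARAMS,
                   noise: NoiseModel = NoiseModel(),
                   walk_cfg: WalkConfig = WalkConfig(),
                   seed: int | None = None
                   ) -> tuple[dict[str, Trajectory], pd.DataFrame]:
    """End-to-end fixture: one trajectory per individual plus metadata.

    Each individual's walk targets the speed drawn from the allometric–
    thermal model plus noise, so pushing the output through the trajectory
    pipeline and refitting approximately recovers the generating parameters.
    Returns ``(trajectories, metadata)`` where metadata has the columns the
    trajectory module's readers expect plus the unobserved ``target_speed``.
    """
    base_seed = design.seed if seed is None else seed
    records = generate_speed_dataset(design, truth, noise, seed=base_seed)
    child_seeds = np.random.SeedSequence(base_seed).spawn(len(records))
    trajectories: dict[str, Trajectory] = {}
    for (_, row), ss in zip(records.iterrows(), child_seeds):
        ind = row["individual_id"]
        trajectories[ind] = generate_trajectory(
            walk_cfg, float(row["speed_m_s"]),
            seed=ss.generate_state(1)[0] % (2 ** 31), individual_id=ind)
    metadata = records.rename(columns={"individual_id": "id",
                                       "speed_m_s": "target_speed"})
    return trajectories, metadata


def write_study(trajectories: dict[str, Trajectory], metadata: pd.DataFrame,
                outdir) -> None:
    """Write one trajectory CSV per individual plus ``metadata.csv``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for ind, traj in trajectories.items():
        pd.DataFrame({"id": ind, "t": traj.t, "x": traj.x,
                      "y": traj.y}).to_csv(
            outdir / f"{ind}.csv", index=False)
    metadata.to_csv(outdir / "metadata.csv", index=False)
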