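"""Agent-based simulator of grouped fly trajectories in a circular arena.

The generator emulates the statistical structure the downstream analysis
assumes for two strains of grouped *Drosophila*: a normally active, socially
engaged genotype and a hypoactive one that interacts less often but dwells
longer in each interaction, with both showing boundary preference
(thigmotaxis).

Dynamics are a discrete-time correlated random walk.  Per step each moving
fly turns by Gaussian heading noise plus a wall-attraction term (steering
toward the boundary while in the arena interior) plus a social term
(steering toward the nearest fly within ``social_radius``); its speed is
drawn fresh each step and zeroed during pauses.  Pauses have geometric
durations.  Social interactions are generated by paired "engagement holds":
when two free flies come within ``social_radius``, with per-step probability
``social_strength`` they stop, face each other, and stay put for a shared
geometric dwell with mean ``interaction_hold_s`` seconds, followed by a
short refractory period.  ``social_strength`` therefore acts both as a
turning bias and as the interaction propensity; ``interaction_hold_s``
controls interaction duration.  The boundary is a billiard wall: steps that
would exit the arena are reflected, preserving step length.

A fixed seed reproduces output bit-for-bit; one RNG stream per group.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .trajectory_io import ArenaSpec, TrajectoryTable

# steering gains (deg of turn per deg of error, per step); internal constants
_WALL_TURN_GAIN = 0.15
_SOCIAL_TURN_GAIN = 0.25
_WALL_ENGAGE_FRAC = 0.7  # wall attraction active while r < frac * R_eff
# Post-hold lockouts. The global refractory (per fly) scales with the mean
# hold so long-dwelling genotypes stay mostly engaged while short-dwelling
# ones keep moving; the pair refractory prevents a just-disengaged pair from
# immediately re-engaging, forcing partner turnover.
_REFRACTORY_HOLD_FACTOR = 1.0
_REFRACTORY_MIN_S = 1.0
_PAIR_REFRACTORY_S = 30.0


@dataclass(frozen=True)
class SimConfig:
    """Full parameterisation of one simulated fly group.

    Speeds in mm/s, durations in s, angles in degrees, lengths in mm;
    probabilities are per simulation step.
    """

    n_flies: int = 30
    duration_s: float = 900.0
    fps: float = 60.0
    arena: ArenaSpec = dataclasses.field(default_factory=ArenaSpec)
    mean_speed: float = 8.0
    speed_sd: float = 2.0
    heading_noise_sd: float = 20.0
    pause_prob: float = 0.01
    pause_mean_s: float = 1.0
    wall_bias: float = 0.6
    social_radius: float = 5.0
    social_strength: float = 0.4
    interaction_hold_s: float = 1.5
    body_length_mean: float = 2.5
    body_length_sd: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        checks = [
            ("n_flies", self.n_flies >= 2),
            ("duration_s", self.duration_s > 0),
            ("fps", self.fps > 0),
            ("mean_speed", self.mean_speed >= 0),
            ("speed_sd", self.speed_sd >= 0),
            ("heading_noise_sd", self.heading_noise_sd >= 0),
            ("pause_prob", 0.0 <= self.pause_prob <= 1.0),
            ("pause_mean_s", self.pause_mean_s >= 0),
            ("wall_bias", 0.0 <= self.wall_bias <= 1.0),
            ("social_radius", self.social_radius >= 0),
            ("social_strength", 0.0 <= self.social_strength <= 1.0),
            ("interaction_hold_s", self.interaction_hold_s >= 0),
            ("body_length_mean", self.body_length_mean > 0),
            ("body_length_sd", self.body_length_sd >= 0),
        ]
        for name, ok in checks:
            if not ok:
                raise ConfigurationError(
                    f"SimConfig.{name} = {getattr(self, name)!r} is out of range"
                )


def _load_presets() -> dict:
    text = resources.files("flysin").joinpath("presets.yaml").read_text()
    return yaml.safe_load(text)


def preset(name: str) -> SimConfig:
    """Return the full :class:`SimConfig` for a named genotype preset.

    ``active_social`` stands in for a normally active wild-type-like group,
    ``hypoactive_asocial`` for a hypoactive strain with fewer but longer
    interactions.
    """
    presets = _load_presets()
    if name not in presets:
        raise KeyError(
            f"unknown preset {name!r}; available presets: {sorted(presets)}"
        )
    fields = dict(presets[name])
    arena = ArenaSpec.from_dict(fields.pop("arena")) if "arena" in fields else ArenaSpec()
    cfg = SimConfig(arena=arena, **fields)
    cfg.validate()
    return cfg


def _wrap_deg(a):
    """Wrap angle differences into (-180, 180]."""
    return (np.asarray(a, dtype=float) + 180.0) % 360.0 - 180.0


def _reflect_into_circle(p0: np.ndarray, p1: np.ndarray, heading: np.ndarray,
                         radius: float) -> None:
    """Billiard-reflect steps ending outside the circle; in place.

    Step length is preserved, so the displacement between the recorded
    positions never exceeds the drawn step length.
    """
    r1 = np.hypot(p1[:, 0], p1[:, 1])
    for k in np.flatnonzero(r1 > radius):
        a = p0[k]
        v = p1[k] - a
        aa = float(v @ v)
        if aa == 0.0 or float(a @ a) > radius * radius:
            # degenerate or already outside: clamp radially
            rr = np.hypot(p1[k, 0], p1[k, 1])
            p1[k] *= (radius * (1.0 - 1e-9)) / rr
            continue
        bb = 2.0 * float(a @ v)
        cc = float(a @ a) - radius * radius
        t = (-bb + math.sqrt(bb * bb - 4.0 * aa * cc)) / (2.0 * aa)
        h = a + t * v
        n = h / np.hypot(h[0], h[1])
        w = (1.0 - t) * v
        w = w - 2.0 * float(w @ n) * n
        p = h + w
        rr = np.hypot(p[0], p[1])
        if rr > radius:
            p *= (radius * (1.0 - 1e-9)) / rr
        p1[k] = p
        if w[0] != 0.0 or w[1] != 0.0:
            heading[k] = math.degrees(math.atan2(w[1], w[0])) % 360.0


def simulate_group(config: SimConfig) -> TrajectoryTable:
    """Simulate one group and return its canonical trajectory table."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_flies
    fps = config.fps
    # the emitted table must carry the simulation frame rate
    arena = dataclasses.replace(config.arena, fps=fps)
    n_frames = int(round(config.duration_s * fps))
    r_eff = arena.radius - config.body_length_mean

    body_length = np.clip(
        rng.normal(config.body_length_mean, config.body_length_sd, n), 1.0, None
    )

    # initial state: uniform over the inner 90% disc, uniform headings
    rho = 0.9 * r_eff * np.sqrt(rng.uniform(size=n))
    phi = rng.uniform(0.0, 360.0, n)
    pos = np.column_stack([rho * np.cos(np.radians(phi)),
                           rho * np.sin(np.radians(phi))])
    heading = rng.uniform(0.0, 360.0, n)

    pause_left = np.zeros(n, dtype=np.int64)
    hold_left = np.zeros(n, dtype=np.int64)
    refractory = np.zeros(n, dtype=np.int64)
    pair_refractory = np.zeros((n, n), dtype=np.int64)
    partner = np.full(n, -1, dtype=np.int64)

    p_pause_len = 1.0 / max(1.0, config.pause_mean_s * fps)
    p_hold_len = 1.0 / max(1.0, config.interaction_hold_s * fps)
    refractory_frames = int(round(
        max(_REFRACTORY_MIN_S,
            _REFRACTORY_HOLD_FACTOR * config.interaction_hold_s) * fps))
    pair_refractory_frames = int(round(_PAIR_REFRACTORY_S * fps))

    xs = np.empty((n_frames, n))
    ys = np.empty((n_frames, n))
    hs = np.empty((n_frames, n))
    xs[0], ys[0], hs[0] = pos[:, 0], pos[:, 1], heading

    for t in range(1, n_frames):
        holding = hold_left > 0
        paused = (pause_left > 0) & ~holding

        # release finished holds -> per-fly and per-pair refractory
        hold_left[holding] -= 1
        released = holding & (hold_left == 0)
        refractory[released] = refractory_frames
        for i in np.flatnonzero(released):
            j = partner[i]
            if j >= 0:
                pair_refractory[i, j] = pair_refractory[j, i] = \
                    pair_refractory_frames
                # disengage and leave: turn away from the ex-partner
                dx, dy = pos[i] - pos[j]
                if dx != 0.0 or dy != 0.0:
                    heading[i] = math.degrees(math.atan2(dy, dx)) % 360.0
            partner[i] = -1
        pause_left[paused] -= 1
        np.maximum(refractory - 1, 0, out=refractory)
        np.maximum(pair_refractory - 1, 0, out=pair_refractory)

        moving = ~holding & ~paused

        # pause entry
        if config.pause_prob > 0:
            starts = moving & (rng.uniform(size=n) < config.pause_prob)
            if starts.any():
                pause_left[starts] = rng.geometric(p_pause_len, int(starts.sum()))
                moving &= ~starts

        # pairwise distances for social terms; attraction and engagement
        # both target free (not currently held) flies only
        diff = pos[None, :, :] - pos[:, None, :]
        dist = np.hypot(diff[..., 0], diff[..., 1])
        np.fill_diagonal(dist, np.inf)
        dist_free = np.where((hold_left > 0)[None, :], np.inf, dist)
        nearest = np.argmin(dist_free, axis=1)
        nearest_d = dist_free[np.arange(n), nearest]
        in_social = nearest_d <= config.social_radius

        # engagement holds: paired, shared dwell, propensity = social_strength
        if config.interaction_hold_s > 0 and config.social_strength > 0:
            trig = (moving & in_social & (refractory == 0)
                    & (rng.uniform(size=n) < config.social_strength))
            for i in rng.permutation(np.flatnonzero(trig)):
                if hold_left[i] > 0:
                    continue
                # nearest eligible partner within the social radius
                cand = np.flatnonzero(
                    (dist[i] <= config.social_radius) & (hold_left == 0)
                    & (refractory == 0) & (pair_refractory[i] == 0))
                if cand.size == 0:
                    continue
                j = int(cand[np.argmin(dist[i, cand])])
                d = int(rng.geometric(p_hold_len))
                hold_left[i] = hold_left[j] = d
                partner[i], partner[j] = j, i
                pause_left[i] = pause_left[j] = 0
                moving[i] = moving[j] = False
                # face each other for the duration of the engagement
                dx, dy = pos[j] - pos[i]
                ang = math.degrees(math.atan2(dy, dx))
                heading[i] = ang % 360.0
                heading[j] = (ang + 180.0) % 360.0

        # held pairs close the remaining gap and stand in contact
        for i in np.flatnonzero(hold_left > 0):
            j = partner[i]
            if j < 0:
                continue
            dx, dy = pos[j] - pos[i]
            d_ij = math.hypot(dx, dy)
            gap = d_ij - config.body_length_mean
            if gap > 1e-9 and d_ij > 0:
                step = min(config.mean_speed / fps, gap / 2.0)
                pos[i, 0] += step * dx / d_ij
                pos[i, 1] += step * dy / d_ij
            if d_ij > 0:
                heading[i] = math.degrees(math.atan2(dy, dx)) % 360.0

        # steering and stepping for the remaining movers
        idx = np.flatnonzero(moving)
        if idx.size:
            turn = rng.normal(0.0, config.heading_noise_sd, idx.size)
            if config.wall_bias > 0:
                r = np.hypot(pos[idx, 0], pos[idx, 1])
                outward = np.degrees(np.arctan2(pos[idx, 1], pos[idx, 0]))
                err = _wrap_deg(outward - heading[idx])
                interior = r < _WALL_ENGAGE_FRAC * r_eff
                turn += np.where(interior,
                                 config.wall_bias * _WALL_TURN_GAIN * err, 0.0)
            if config.social_strength > 0:
                soc = in_social[idx] & (refractory[idx] == 0)
                tgt = nearest[idx]
                to_n = np.degrees(np.arctan2(pos[tgt, 1] - pos[idx, 1],
                                             pos[tgt, 0] - pos[idx, 0]))
                err = _wrap_deg(to_n - heading[idx])
                turn += np.where(soc,
                                 config.social_strength * _SOCIAL_TURN_GAIN * err,
                                 0.0)
            heading[idx] = (heading[idx] + turn) % 360.0
            speed = np.clip(rng.normal(config.mean_speed, config.speed_sd,
                                       idx.size), 0.0, None)
            step = speed / fps
            old = pos[idx].copy()
            pos[idx, 0] += step * np.cos(np.radians(heading[idx]))
            pos[idx, 1] += step * np.sin(np.radians(heading[idx]))
            new = pos[idx]
            sub_head = heading[idx]
            _reflect_into_circle(old, new, sub_head, r_eff)
            pos[idx] = new
            heading[idx] = sub_head

        xs[t], ys[t], hs[t] = pos[:, 0], pos[:, 1], heading

    frames = np.tile(np.arange(n_frames, dtype=np.int64), n)
    df = pd.DataFrame(
        {
            "fly_id": np.repeat(np.arange(n, dtype=np.int64), n_frames),
            "frame": frames,
            "x_mm": xs.T.ravel(),
            "y_mm": ys.T.ravel(),
            "heading_deg": hs.T.ravel(),
            "body_length_mm": np.repeat(body_length, n_frames),
        }
    )
    return TrajectoryTable.from_dataframe(df, arena)


def simulate_experiment(preset_name: str, n_groups: int, base_seed: int,
                        **overrides) -> list[TrajectoryTable]:
    """Simulate ``n_groups`` independent replicate groups of one preset.

    Group ``k`` uses seed ``base_seed + k``.  Keyword overrides (for example
    ``duration_s=120, fps=30``) are applied to the preset config before
    simulation.
    """
    if n_groups < 1:
        raise ConfigurationError("n_groups must be >= 1")
    cfg = preset(preset_name)
    if overrides:
        cfg = dataclasses.replace(cfg, **overrides)
        cfg.validate()
    tables = []
    for k in range(n_groups):
        tables.append(
            simulate_group(dataclasses.replace(cfg, seed=int(base_seed) + k))
        )
    return tables
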