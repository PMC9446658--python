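"""BrainDriver-style race track and vehicle simulation.

The track is an ordered sequence of zones (left curve, right curve,
headlight, no-input) totalling 500 m, raced against a 240 s limit.  The
vehicle moves at ``v_correct`` while the zone's required command is
active, ``v_wrong`` while an incorrect command is active (any command is
incorrect in a no-input zone), and ``v_none`` otherwise.  An emitted
command stays active until the next emission or the next zone boundary.

A simple pilot model (per-zone command accuracy, reaction latency, false
commands in no-input zones) and a TSD-level closed-loop harness produce
seeded race-time distributions for evaluating decoder configurations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .decoder import DecoderConfig

ZONE_TYPES = ("LEFT_CURVE", "RIGHT_CURVE", "HEADLIGHT", "NO_INPUT")
ZONE_COMMAND = {
    "LEFT_CURVE": "LEFT",
    "RIGHT_CURVE": "RIGHT",
    "HEADLIGHT": "LIGHT",
    "NO_INPUT": None,
}
COMMAND_LABEL = {"LEFT": "L", "RIGHT": "R", "LIGHT": "F"}
TRACK_LENGTH_M = 500.0
TIME_LIMIT_S = 240.0


@dataclass(frozen=True)
class Zone:
    kind: str
    length_m: float

    def __post_init__(self) -> None:
        if self.kind not in ZONE_TYPES:
            raise ValueError(f"unknown zone type {self.kind!r}")
        if self.length_m <= 0:
            raise ValueError("zone length must be positive")


@dataclass(frozen=True)
class RaceTrack:
    zones: tuple[Zone, ...]
    total_length_m: float = TRACK_LENGTH_M
    time_limit_s: float = TIME_LIMIT_S

    def __post_init__(self) -> None:
        total = sum(z.length_m for z in self.zones)
        if abs(total - self.total_length_m) > 1e-6:
            raise ValueError(
                f"zone lengths sum to {total} m, expected {self.total_length_m} m"
            )

    @property
    def boundaries_m(self) -> np.ndarray:
        return np.cumsum([z.length_m for z in self.zones])


@dataclass(frozen=True)
class VehicleModel:
    """Speeds (m/s) for correct / no / wrong command states."""

    v_correct: float = 4.0
    v_none: float = 2.5
    v_wrong: float = 1.5

    def __post_init__(self) -> None:
        if not (self.v_correct > self.v_none > self.v_wrong > 0):
            raise ValueError("require v_correct > v_none > v_wrong > 0")


@dataclass(frozen=True)
class PilotModel:
    """Abstraction of pilot + BCI: per-zone command behaviour."""

    accuracy: float = 0.8
    latency_s: float = 1.0
    false_command_rate: float = 0.1  # probability of a command in NO_INPUT zones

    def __post_init__(self) -> None:
        for p in (self.accuracy, self.false_command_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if self.latency_s < 0:
            raise ValueError("latency must be >= 0")


@dataclass
class RaceResult:
    finished: bool
    time_s: float | None
    distance_m: float
    log: pd.DataFrame  # per-segment speed/command/zone record

    def __post_init__(self) -> None:
        if self.finished and self.time_s is None:
            raise ValueError("finished race must report a time")


def build_track(
    zones: list[tuple[str, float]] | None = None,
    seed: int | None = None,
    vehicle: VehicleModel | None = None,
    total_length_m: float = TRACK_LENGTH_M,
    time_limit_s: float = TIME_LIMIT_S,
) -> RaceTrack:
    """Build a race track from an explicit zone spec or randomly.

    The default random track draws zone traverse times uniformly in
    6.5-7.5 s at ``v_none`` (so every zone falls inside the nominal 6-8 s
    zone duration after rescaling to the exact total length), contains all
    four zone types, and is seed-reproducible.
    """
    if zones is not None:
        zs = tuple(Zone(kind, length) for kind, length in zones)
        return RaceTrack(zones=zs, total_length_m=total_length_m, time_limit_s=time_limit_s)
    vehicle = vehicle or VehicleModel()
    rng = np.random.default_rng(seed)
    n_zones = int(round(total_length_m / (7.0 * vehicle.v_none)))
    durations = rng.uniform(6.5, 7.5, size=n_zones)
    lengths = durations * vehicle.v_none
    lengths *= total_length_m / lengths.sum()
    kinds = [ZONE_TYPES[i % 4] for i in range(n_zones)]
    rng.shuffle(kinds)
    zs = tuple(Zone(k, l) for k, l in zip(kinds, lengths))
    return RaceTrack(zones=zs, total_length_m=total_length_m, time_limit_s=time_limit_s)


def _pilot_commands(
    track: RaceTrack, pilot: PilotModel, rng: np.random.Generator
) -> list[tuple[str, str | None]]:
    """Per-zone command decision: (zone kind, issued command or None)."""
    out = []
    for zone in track.zones:
        required = ZONE_COMMAND[zone.kind]
        if required is None:
            if rng.random() < pilot.false_command_rate:
                out.append((zone.kind, rng.choice(["LEFT", "RIGHT", "LIGHT"])))
            else:
                out.append((zone.kind, None))
        else:
            if rng.random() < pilot.accuracy:
                out.append((zone.kind, required))
            else:
                wrong = [c for c in ("LEFT", "RIGHT", "LIGHT") if c != required]
                out.append((zone.kind, rng.choice(wrong)))
    return out


def simulate_race(
    track: RaceTrack,
    vehicle: VehicleModel,
    commands: list[tuple[float, str]] | None = None,
    pilot: PilotModel | None = None,
    seed: int | None = None,
) -> RaceResult:
    """Run one race from a timed command stream or a pilot model.

    ``commands`` is a time-ordered list of (time_s, command) emissions; a
    command stays active until the next emission or the next zone boundary.
    With a ``pilot`` instead, each zone gets at most one command, issued
    ``latency_s`` after zone entry.  The race ends on crossing the total
    length or at the time limit (distance recorded).
    """
    boundaries = track.boundaries_m
    limit = track.time_limit_s

    if pilot is not None:
        if commands is not None:
            raise ValueError("give either commands or a pilot model, not both")
        zone_cmds = _pilot_commands(track, pilot, np.random.default_rng(seed))
        latency = pilot.latency_s
    else:
        zone_cmds = None
        latency = 0.0
        commands = sorted(commands or [], key=lambda c: c[0])

    t, d = 0.0, 0.0
    zone_i = 0
    zone_entry_t = 0.0
    active: str | None = None
    cmd_i = 0
    segments = []

    def speed_in(zone: Zone, cmd: str | None) -> float:
        required = ZONE_COMMAND[zone.kind]
        if cmd is None:
            return vehicle.v_none
        return vehicle.v_correct if cmd == required else vehicle.v_wrong

    while d < track.total_length_m - 1e-12 and t < limit - 1e-12:
        zone = track.zones[zone_i]
        zone_end = boundaries[zone_i]
        # next command event time, if any
        if zone_cmds is not None:
            zc = zone_cmds[zone_i][1]
            next_cmd_t = zone_entry_t + latency if (zc is not None and active is None and t < zone_entry_t + latency + 1e-12) else np.inf
            pending = zc
        else:
            next_cmd_t = commands[cmd_i][0] if cmd_i < len(commands) else np.inf
            pending = commands[cmd_i][1] if cmd_i < len(commands) else None
        if next_cmd_t <= t + 1e-12 and pending is not None:
            active = pending
            if zone_cmds is None:
                cmd_i += 1
                continue
        v = speed_in(zone, active)
        t_zone = t + (zone_end - d) / v
        t_next = min(t_zone, next_cmd_t if next_cmd_t > t + 1e-12 else np.inf, limit)
        dt = t_next - t
        segments.append(
            {"t0": t, "t1": t_next, "zone": zone.kind, "command": active, "speed": v}
        )
        d += v * dt
        t = t_next
        if abs(d - zone_end) < 1e-9 and zone_i < len(track.zones) - 1:
            zone_i += 1
            zone_entry_t = t
            active = None  # command persistence ends at the zone boundary

    log = pd.DataFrame(segments, columns=["t0", "t1", "zone", "command", "speed"])
    if d >= track.total_length_m - 1e-9:
        return RaceResult(finished=True, time_s=t, distance_m=track.total_length_m, log=log)
    return RaceResult(finished=False, time_s=None, distance_m=d, log=log)


def _closed_loop_race(
    track: RaceTrack,
    vehicle: VehicleModel,
    erd_depth: float,
    config: DecoderConfig,
    rng: np.random.Generator,
    latency_s: float = 1.0,
    tsd_gain: float = 1.2,
    noise_sd: float = 1.0,
) -> RaceResult:
    """One closed-loop race: vehicle and decoder stepped together at 25 Hz.

    At each frame the synthetic pilot "intends" the required command of
    the zone the vehicle is actually in (after a reaction latency from
    zone entry), driving the pairwise TSD signs with amplitude
    ``tsd_gain * erd_depth`` on top of temporally smoothed Gaussian noise
    (real TSDs are strongly autocorrelated through the 1 s log-variance
    window).  No-input zones drive TX toward relax.  At erd_depth = 0 the
    TSDs are pure noise and the decoder operates at chance, occasionally
    emitting spurious (almost always wrong) commands.
    """
    from .decoder import DecoderState, StabilityGate, deadband_step, gate1, smooth_ma

    rate = config.frame_rate_hz
    n = int(track.time_limit_s * rate) + 1
    noise = {
        k: smooth_ma(rng.standard_normal(n) * noise_sd, window_s=1.0, rate_hz=rate)
        for k in ("lr", "fr", "lf", "tx")
    }
    drive = {"L": {"lr": 1, "lf": 1}, "R": {"lr": -1, "fr": -1}, "F": {"fr": 1, "lf": -1}}
    amp = tsd_gain * erd_depth
    boundaries = track.boundaries_m

    gate2 = StabilityGate(config.stability_frames)
    state = DecoderState()
    t, d = 0.0, 0.0
    dt = 1.0 / rate
    zone_i, zone_entry_t = 0, 0.0
    active: str | None = None
    segments = []
    while d < track.total_length_m - 1e-9 and t < track.time_limit_s - 1e-9:
        zone = track.zones[zone_i]
        required = ZONE_COMMAND[zone.kind]
        i = int(round(t * rate))
        vals = {k: noise[k][i] for k in noise}
        if t - zone_entry_t >= latency_s:
            if required is None:
                vals["tx"] -= amp
            else:
                label = COMMAND_LABEL[required]
                vals["tx"] += amp
                for ch, sign in drive[label].items():
                    vals[ch] += sign * amp
        cand = gate1(vals["lr"], vals["fr"], vals["lf"], vals["tx"])
        stab = gate2.update(cand)
        state, cmd = deadband_step(state, config, stab, vals["tx"] > 0, t)
        if cmd is not None:
            gate2.rearm()
            active = cmd.command
        v = (
            vehicle.v_none
            if active is None
            else (vehicle.v_correct if active == required else vehicle.v_wrong)
        )
        step = min(v * dt, track.total_length_m - d)
        segments.append(
            {"t0": t, "t1": t + step / v, "zone": zone.kind, "command": active, "speed": v}
        )
        d += step
        t += step / v
        while zone_i < len(boundaries) - 1 and d >= boundaries[zone_i] - 1e-9:
            zone_i += 1
            zone_entry_t = t
            active = None
    log = pd.DataFrame(segments, columns=["t0", "t1", "zone", "command", "speed"])
    if d >= track.total_length_m - 1e-9:
        return RaceResult(finished=True, time_s=t, distance_m=track.total_length_m, log=log)
    return RaceResult(finished=False, time_s=None, distance_m=d, log=log)


def closed_loop_eval(
    track: RaceTrack,
    vehicle: VehicleModel,
    erd_depth: float,
    decoder_config: DecoderConfig | None = None,
    n_races: int = 20,
    seed: int = 0,
    model_bundle_dir: str | Path | None = None,
) -> tuple[list[RaceResult], dict]:
    """Closed-loop evaluation: synthetic TSD -> decoder -> race, repeated.

    Returns the per-race results and a summary (mean/std completion time
    over finished races, finish rate, mean distance).  When a model bundle
    directory is named it must exist (its decoder scaling metadata would
    come from the calibration run).
    """
    if model_bundle_dir is not None and not Path(model_bundle_dir).exists():
        raise FileNotFoundError(f"model bundle not found: {model_bundle_dir}")
    decoder_config = decoder_config or DecoderConfig()
    ss = np.random.SeedSequence(seed)
    results = []
    for child in ss.spawn(n_races):
        rng = np.random.default_rng(child)
        results.append(_closed_loop_race(track, vehicle, erd_depth, decoder_config, rng))
    finished = [r.time_s for r in results if r.finished]
    summary = {
        "n_races": n_races,
        "finish_rate": len(finished) / n_races,
        "mean_time_s": float(np.mean(finished)) if finished else None,
        "std_time_s": float(np.std(finished)) if finished else None,
        "mean_distance_m": float(np.mean([r.distance_m for r in results])),
    }
    return results, summary


def track_to_json(track: RaceTrack, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "total_length_m": track.total_length_m,
                "time_limit_s": track.time_limit_s,
                "zones": [{"kind": z.kind, "length_m": z.length_m} for z in track.zones],
            },
            indent=1,
        )
    )


def track_from_json(path: str | Path) -> RaceTrack:
    raw = json.loads(Path(path).read_text())
    return RaceTrack(
        zones=tuple(Zone(z["kind"], z["length_m"]) for z in raw["zones"]),
        total_length_m=raw["total_length_m"],
        time_limit_s=raw["time_limit_s"],
    )
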