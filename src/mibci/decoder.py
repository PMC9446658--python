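"""Online control path: TSD post-processing, multi-classifier agreement,
stability gating, dead-band control, and game-command translation.

The multi-class decoder combines the signed outputs of the four binary
classifiers.  A class label becomes a candidate only when both of its
pairwise task-vs-task classifiers vote for it and the task-vs-relax (TX)
classifier indicates a task state (gate 1).  The candidate must persist
for 300 ms (gate 2) before it becomes a command.  After an emission, a
dead-band timer blocks further commands; the pilot can break the dead-band
early by sustaining a task state, once the dead-band-break delay has
elapsed, for the break-hold duration.
"""

from __future__ import annotations

import math
import socket
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

FRAME_RATE_HZ = 25.0

DEFAULT_COMMAND_MAP = {"L": "LEFT", "R": "RIGHT", "F": "LIGHT"}

# which pairwise classifiers vote for each class; the sign convention is
# TSD > 0 => first letter of the pair
_PAIR_CLASSES = {"lr": ("L", "R"), "fr": ("F", "R"), "lf": ("L", "F")}


@dataclass(frozen=True)
class DecoderConfig:
    stability_ms: float = 300.0
    deadband_s: float = 6.0
    deadband_break_s: float = 3.0
    break_hold_s: float = 1.0
    frame_rate_hz: float = FRAME_RATE_HZ
    require_different_after_break: bool = False
    command_map: dict = field(default_factory=lambda: dict(DEFAULT_COMMAND_MAP))
    task_color: str = "green"  # Triad composite-ball colour in the task state

    def __post_init__(self) -> None:
        if not (self.deadband_break_s < self.deadband_s):
            raise ValueError("deadband_break_s must be < deadband_s")
        for name in ("stability_ms", "deadband_s", "deadband_break_s", "break_hold_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def stability_frames(self) -> int:
        return math.ceil(self.stability_ms / 1000.0 * self.frame_rate_hz)


@dataclass
class DecoderState:
    """Mutable gating state carried between frames."""

    candidate: str | None = None
    candidate_since: float = -np.inf
    last_command: str | None = None
    last_emission: float = -np.inf
    deadband_active: bool = False
    broke_deadband: bool = False
    tx_task_since: float = np.inf
    last_time: float = -np.inf


@dataclass(frozen=True)
class GameCommand:
    command: str
    time_s: float
    source_label: str
    break_flag: bool = False


def correct_baseline(trace: np.ndarray, offset: float, scale: float = 1.0) -> np.ndarray:
    """Baseline-correct a TSD trace: (trace - offset) * scale.

    The offset zeroes the run-start rest baseline; the scale maps the TSD
    range to the game's controllable range.
    """
    if scale == 0:
        raise ValueError("scale must be nonzero")
    return (np.asarray(trace, dtype=float) - offset) * scale


def estimate_offset(trace: np.ndarray, rest_slice: slice = slice(None)) -> float:
    """Automatic baseline offset: median TSD over a rest segment."""
    return float(np.median(np.asarray(trace)[rest_slice]))


def smooth_ma(trace: np.ndarray, window_s: float = 1.0, rate_hz: float = FRAME_RATE_HZ) -> np.ndarray:
    """Causal moving average over a trailing window.

    Early frames average over whatever history exists, so a constant trace
    is unchanged and a unit step ramps linearly to 1 over one window.
    """
    x = np.asarray(trace, dtype=float)
    win = max(1, int(round(window_s * rate_hz)))
    if win == 1:
        return x.copy()
    csum = np.concatenate([[0.0], np.cumsum(x)])
    n = len(x)
    starts = np.maximum(0, np.arange(1, n + 1) - win)
    return (csum[1:] - csum[starts]) / (np.arange(1, n + 1) - starts)


def gate1(lr_sign: float, fr_sign: float, lf_sign: float, tx_sign: float) -> str | None:
    """Agreement gate: the class endorsed by both of its pairwise
    classifiers, provided TX indicates a task state; None otherwise.

    Of the 8 possible task-vs-task vote patterns, 6 give a unique winner
    and 2 are cyclic (no class gets two votes).
    """
    if tx_sign <= 0:
        return None
    votes = []
    for name, sign in (("lr", lr_sign), ("fr", fr_sign), ("lf", lf_sign)):
        a, b = _PAIR_CLASSES[name]
        votes.append(a if sign > 0 else b)
    for cls in ("L", "F", "R"):
        if votes.count(cls) == 2:
            return cls
    return None


class StabilityGate:
    """Gate 2: a candidate becomes a stabilized event after it has been
    the uninterrupted candidate for ``stability_frames`` consecutive
    frames.  Firing resets the streak, so a continuously held candidate
    re-fires every ``n_frames`` frames — a suppressed command can recur
    while the pilot sustains the intention (this is what lets a sustained
    task state break the dead-band downstream).  An emission re-arms the
    gate explicitly."""

    def __init__(self, n_frames: int):
        self.n_frames = n_frames
        self._current: str | None = None
        self._streak = 0

    def update(self, candidate: str | None) -> str | None:
        if candidate != self._current:
            self._current = candidate
            self._streak = 0
        if candidate is None:
            return None
        self._streak += 1
        if self._streak >= self.n_frames:
            self._streak = 0
            return candidate
        return None

    def rearm(self) -> None:
        self._streak = 0


def stability_gate(candidates: list[str | None], n_frames: int) -> list[tuple[int, str]]:
    """Offline application of the stability gate to a candidate stream.

    Returns (frame index, label) for each stabilized event.
    """
    gate = StabilityGate(n_frames)
    events = []
    for i, cand in enumerate(candidates):
        out = gate.update(cand)
        if out is not None:
            events.append((i, out))
    return events


def deadband_step(
    state: DecoderState,
    config: DecoderConfig,
    stabilized: str | None,
    tx_is_task: bool,
    now: float,
) -> tuple[DecoderState, GameCommand | None]:
    """One dead-band controller step; returns the new state and the emitted
    command, if any.

    While the dead-band is active, stabilized events are suppressed unless
    the break conditions hold: at least ``deadband_break_s`` since the last
    emission AND TX has continuously indicated a task for at least
    ``break_hold_s``.  An emission (re)starts the dead-band.
    """
    if now < state.last_time:
        raise ValueError("timestamps must be monotone")
    st = replace(state, last_time=now)

    # track the TX task streak on the raw TX state
    if tx_is_task:
        if not np.isfinite(st.tx_task_since):
            st = replace(st, tx_task_since=now)
    else:
        st = replace(st, tx_task_since=np.inf)

    if st.deadband_active and now - st.last_emission >= config.deadband_s:
        st = replace(st, deadband_active=False)

    if stabilized is None:
        return st, None

    emit = False
    break_flag = False
    if not st.deadband_active:
        emit = True
    else:
        since_emit = now - st.last_emission
        streak = now - st.tx_task_since if np.isfinite(st.tx_task_since) else 0.0
        if since_emit >= config.deadband_break_s and streak >= config.break_hold_s:
            if not (config.require_different_after_break and stabilized == st.last_command):
                emit = True
                break_flag = True
    if not emit:
        return st, None
    cmd = GameCommand(
        command=translate(stabilized, config.command_map).command,
        time_s=now,
        source_label=stabilized,
        break_flag=break_flag,
    )
    st = replace(
        st,
        last_command=stabilized,
        last_emission=now,
        deadband_active=True,
        broke_deadband=break_flag,
    )
    return st, cmd


def translate(label: str, command_map: dict | None = None) -> GameCommand:
    """Map a decoded class label to its game command (L->LEFT, R->RIGHT,
    F->LIGHT by default); the relax class never reaches the translator."""
    cmap = command_map or DEFAULT_COMMAND_MAP
    if label not in cmap:
        raise ValueError(f"no game command for label {label!r}")
    return GameCommand(command=cmap[label], time_s=np.nan, source_label=label)


def decode_stream(
    tsd_frames: pd.DataFrame,
    config: DecoderConfig | None = None,
) -> pd.DataFrame:
    """Run the full decode path over a TSD stream.

    ``tsd_frames`` columns: time (s), lr, fr, lf, tx (baseline-corrected
    TSDs; positive = first class of the pair, tx > 0 = task).  Returns the
    command log (time, command, label, break_flag).  The path is fully
    deterministic: identical inputs yield identical logs.
    """
    config = config or DecoderConfig()
    gate2 = StabilityGate(config.stability_frames)
    state = DecoderState()
    rows = []
    for row in tsd_frames.itertuples(index=False):
        cand = gate1(row.lr, row.fr, row.lf, row.tx)
        stab = gate2.update(cand)
        state, cmd = deadband_step(state, config, stab, row.tx > 0, row.time)
        if cmd is not None:
            gate2.rearm()
            rows.append(
                {
                    "time": cmd.time_s,
                    "command": cmd.command,
                    "label": cmd.source_label,
                    "break_flag": cmd.break_flag,
                }
            )
    log = pd.DataFrame(rows, columns=["time", "command", "label", "break_flag"])
    return log.astype({"time": float, "command": str, "label": str, "break_flag": bool})


# vertices of the Triad triangle (unit circumradius): L top, F lower-left,
# R lower-right; invented geometry — only the edge/linear-combination
# behaviour is specified by the paradigm
TRIAD_VERTICES = {
    "L": np.array([0.0, 1.0]),
    "F": np.array([-math.sqrt(3) / 2, -0.5]),
    "R": np.array([math.sqrt(3) / 2, -0.5]),
}


def triad_position(
    lr: float, fr: float, lf: float, tx: float
) -> tuple[np.ndarray, str]:
    """Map the four TSDs to the Triad display: a 2-D point plus state.

    Each pairwise TSD (clipped to [-1, 1]) positions a point on its
    triangle edge, linear from the midpoint toward the favoured vertex;
    the composite point is the mean of the three edge points.  The state
    (task vs relax) follows the TX sign.
    """
    edges = {"lr": lr, "fr": fr, "lf": lf}
    pts = []
    for name, value in edges.items():
        a, b = _PAIR_CLASSES[name]
        v = float(np.clip(value, -1.0, 1.0))
        mid = (TRIAD_VERTICES[a] + TRIAD_VERTICES[b]) / 2.0
        pts.append(mid + v / 2.0 * (TRIAD_VERTICES[a] - TRIAD_VERTICES[b]))
    state = "task" if tx > 0 else "relax"
    return np.mean(pts, axis=0), state


class UDPCommandSink:
    """Optional one-byte-per-command UDP sink mimicking the game protocol."""

    CODES = {"LEFT": 1, "RIGHT": 2, "LIGHT": 3}

    def __init__(self, host: str, port: int):
        self.addr = (host, port)
        self.sock = socket.socket(socket.AF_INET, socket.SOCK_DGRAM)

    def send(self, command: GameCommand) -> None:
        self.sock.sendto(bytes([self.CODES[command.command]]), self.addr)
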