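"""Virtual therapy-device engine: executes one protocol at a time on a
simulated clock, applies real-time modifications, and answers status queries.

The engine replaces the proprietary therapy workstation with a deterministic
state machine.  Time is advanced explicitly through :meth:`TreatmentEngine.
advance_clock`, which makes runs exactly reproducible; a wall-clock driver
(:class:`WallClockDriver`) wraps it for interactive use.

Device model
------------
* Transducer motion runs at a finite configurable speed (default 5 mm/s
  translation, 10 deg/s rotation) so the moving/idle indicator is
  meaningful.
* Reflected acoustic power is a fixed configurable fraction of forward
  power (default 2%).
* At most one ultrasound exposure is active at a time; starting a new one
  stops the previous one.
* Per-element drive state (active mask, phase and amplitude overrides) is
  set by ``rnd`` commands and persists until overridden.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Any, Optional

import numpy as np

from .protocols import (
    CONTINUOUS,
    MOVE,
    PAUSE,
    PULSED,
    RND,
    Command,
    Modification,
    ProtocolError,
    TreatmentProtocol,
    validate_attribute,
)


class EngineBusyError(RuntimeError):
    """A protocol is already executing."""


class EngineError(RuntimeError):
    """Invalid engine operation (unknown target, bad goto, ...)."""


EVENT_TYPES = (
    "command_started",
    "command_finished",
    "modification_applied",
    "exposure_on",
    "exposure_off",
    "move_started",
    "move_finished",
)


@dataclass(frozen=True)
class EngineEvent:
    time_s: float
    type: str
    detail: dict[str, Any] = field(default_factory=dict)


@dataclass(frozen=True)
class StatusSnapshot:
    """Queryable device state, mirroring the hardware status indicators:
    transducer position, forward/reflected acoustic power, ultrasound
    on/off, transducer moving/idle, and the current time index."""

    transducer_position_mm: tuple[float, float, float]
    rot_lr_deg: float
    rot_hf_deg: float
    forward_power_w: float
    reflected_power_w: float
    ultrasound_on: bool
    transducer_moving: bool
    current_time_index_s: float
    current_command_position: Optional[int]
    protocol_state: str  # idle | running | paused | finished

    def to_json_dict(self) -> dict[str, Any]:
        return {
            "transducer_position_mm": list(self.transducer_position_mm),
            "rot_lr_deg": self.rot_lr_deg,
            "rot_hf_deg": self.rot_hf_deg,
            "forward_power_w": self.forward_power_w,
            "reflected_power_w": self.reflected_power_w,
            "ultrasound_on": self.ultrasound_on,
            "transducer_moving": self.transducer_moving,
            "current_time_index_s": self.current_time_index_s,
            "current_command_position": self.current_command_position,
            "protocol_state": self.protocol_state,
        }


@dataclass
class _ActiveCommand:
    position: int
    start_s: float
    finish_s: float  # math.inf for indefinite


class TreatmentEngine:
    """Executes treatment protocols on a simulated device clock."""

    def __init__(self, n_elements: int = 256, move_speed_mm_s: float = 5.0,
                 rotation_speed_deg_s: float = 10.0,
                 reflected_fraction: float = 0.02) -> None:
        self.n_elements = int(n_elements)
        self.move_speed_mm_s = float(move_speed_mm_s)
        self.rotation_speed_deg_s = float(rotation_speed_deg_s)
        self.reflected_fraction = float(reflected_fraction)

        self._t = 0.0
        self._events: list[EngineEvent] = []
        self._protocol: Optional[TreatmentProtocol] = None
        self._commands: list[Command] = []
        self._rebase = 0.0
        self._pointer = 0
        self._seq_ready = 0.0  # completion time of the last started command
        self._active: list[_ActiveCommand] = []
        self._state = "idle"

        # device state
        self._position = np.zeros(3)
        self._angles = np.zeros(2)  # (rot_lr, rot_hf)
        self._move: Optional[dict[str, Any]] = None
        self._active_mask = np.zeros(self.n_elements, dtype=bool)
        self._phase_overrides = np.zeros(self.n_elements)
        self._amp_overrides = np.ones(self.n_elements)
        self._exposure: Optional[dict[str, Any]] = None

    # -- public API --------------------------------------------------------

    @property
    def clock_s(self) -> float:
        return self._t

    @property
    def event_log(self) -> tuple[EngineEvent, ...]:
        return tuple(self._events)

    def execute_protocol(self, protocol: TreatmentProtocol) -> str:
        """Begin executing ``protocol``.  Only one protocol runs at a time."""
        if self._state in ("running", "paused"):
            raise EngineBusyError(
                f"protocol {self._protocol.identifier!r} is already executing"
            )
        for cmd in protocol.commands:
            if cmd.kind == RND and len(cmd.attributes["active_mask"]) != self.n_elements:
                raise ProtocolError(
                    f"rnd command {cmd.index}: mask length "
                    f"{len(cmd.attributes['active_mask'])} != {self.n_elements} elements"
                )
        self._protocol = protocol
        self._commands = list(protocol.commands)
        self._rebase = self._t
        self._pointer = 0
        self._seq_ready = self._t
        self._active = []
        self._state = "running"
        self._process_until(self._t)
        return protocol.identifier

    def execute_modification(self, modification: Modification) -> dict[str, Any]:
        """Apply a modification to the live protocol.

        All edits are applied atomically; if ``goto_position`` is set,
        execution resumes at that command with its time index rebased to
        the current clock (restart semantics).
        """
        if self._protocol is None:
            raise EngineError("no protocol loaded")
        if modification.target_protocol != self._protocol.identifier:
            raise EngineError(
                f"modification targets {modification.target_protocol!r} but "
                f"{self._protocol.identifier!r} is loaded"
            )
        n = len(self._commands)
        staged: list[tuple[int, str, Any]] = []
        for pos, attr, value in modification.edits:
            if not (0 <= pos < n):
                raise EngineError(f"edit position {pos} outside protocol (n={n})")
            kind = self._commands[pos].kind
            staged.append((pos, attr, validate_attribute(kind, attr, value)))
        goto = modification.goto_position
        if goto is not None and not (0 <= goto < n):
            raise EngineError(f"goto position {goto} outside protocol (n={n})")

        for pos, attr, value in staged:
            cmd = self._commands[pos]
            new_attrs = dict(cmd.attributes)
            new_attrs[attr] = value
            self._commands[pos] = replace(cmd, attributes=new_attrs)
            self._refresh_active(pos, attr)
        self._log("modification_applied", {
            "identifier": modification.identifier,
            "edits": [[p, a] for p, a, _ in staged],
            "goto_position": goto,
        })
        if goto is not None:
            self._abort_active()
            self._rebase = self._t - self._commands[goto].time_index_s
            self._pointer = goto
            self._seq_ready = self._t
            self._state = "running"
            self._process_until(self._t)
        return {"applied": modification.identifier, "n_edits": len(staged)}

    def query_status(self) -> StatusSnapshot:
        """Pure read of device state; never advances the clock."""
        pos, angles = self._pose_at(self._t)
        on = self._exposure is not None
        fwd = float(self._exposure["acoustic_power_w"]) if on else 0.0
        active_pos = [a.position for a in self._active]
        if active_pos:
            current = max(active_pos)
        elif self._pointer > 0 and self._state != "idle":
            current = self._pointer - 1
        else:
            current = None
        return StatusSnapshot(
            transducer_position_mm=tuple(float(v) for v in pos),
            rot_lr_deg=float(angles[0]),
            rot_hf_deg=float(angles[1]),
            forward_power_w=fwd,
            reflected_power_w=fwd * self.reflected_fraction,
            ultrasound_on=on,
            transducer_moving=self._move is not None,
            current_time_index_s=self._t - self._rebase if self._protocol else 0.0,
            current_command_position=current,
            protocol_state=self._state,
        )

    def advance_clock(self, dt_s: float) -> list[EngineEvent]:
        """Advance the simulated clock by ``dt_s``, dispatching commands and
        returning the events emitted.  Deterministic."""
        if dt_s < 0:
            raise ValueError("dt_s must be >= 0")
        mark = len(self._events)
        self._process_until(self._t + dt_s)
        return list(self._events[mark:])

    def drive_state(self) -> dict[str, Any]:
        """Current acoustic drive, for the physics backends: element mask,
        phase/amplitude overrides, the active exposure (if any) with the
        focal offset selected by its trajectory at the current clock, and
        the transducer pose."""
        pos, angles = self._pose_at(self._t)
        exp = None
        if self._exposure is not None:
            e = self._exposure
            traj = e["trajectory"]
            offset = (0.0, 0.0, 0.0)
            if traj is not None:
                offset = traj.point_at(self._t - e["start_s"])
            exp = {
                "kind": e["kind"],
                "acoustic_power_w": e["acoustic_power_w"],
                "frequency_mhz": e["frequency_mhz"],
                "duty_cycle": e.get("duty_cycle", 1.0),
                "start_s": e["start_s"],
                "focal_offset_mm": tuple(offset),
                "trajectory_points_mm": (
                    None if traj is None else [tuple(p) for p in traj.points]
                ),
                "trajectory_interval_ms": (
                    None if traj is None else traj.interval_ms
                ),
            }
        return {
            "active_mask": self._active_mask.copy(),
            "phases_rad": self._phase_overrides.copy(),
            "amplitudes": self._amp_overrides.copy(),
            "exposure": exp,
            "transducer_position_mm": tuple(float(v) for v in pos),
            "rot_lr_deg": float(angles[0]),
            "rot_hf_deg": float(angles[1]),
        }

    # -- internals ---------------------------------------------------------

    def _log(self, type_: str, detail: dict[str, Any]) -> None:
        self._events.append(EngineEvent(time_s=self._t, type=type_, detail=detail))

    def _pose_at(self, t: float):
        if self._move is not None:
            m = self._move
            frac = 1.0 if m["t1"] == m["t0"] else (t - m["t0"]) / (m["t1"] - m["t0"])
            frac = min(max(frac, 0.0), 1.0)
            pos = m["p0"] + frac * (m["p1"] - m["p0"])
            ang = m["a0"] + frac * (m["a1"] - m["a0"])
            return pos, ang
        return self._position, self._angles

    def _next_start_time(self) -> float:
        """Commands run strictly in order: a command starts at the later of
        its scheduled time index and the completion of its predecessor."""
        if self._protocol is None or self._pointer >= len(self._commands):
            return math.inf
        sched = self._rebase + self._commands[self._pointer].time_index_s
        return max(sched, self._seq_ready)

    def _process_until(self, target: float) -> None:
        while True:
            next_start = self._next_start_time()
            next_finish = min((a.finish_s for a in self._active), default=math.inf)
            t_event = min(next_start, next_finish)
            if t_event > target:
                self._t = target
                break
            self._t = t_event
            for a in sorted([a for a in self._active if a.finish_s <= self._t],
                            key=lambda a: a.position):
                self._finish_command(a)
            while self._next_start_time() <= self._t:
                self._seq_ready = self._start_command(self._pointer)
                self._pointer += 1
        self._update_state()

    def _start_command(self, pos: int) -> float:
        cmd = self._commands[pos]
        self._log("command_started", {"position": pos, "kind": cmd.kind})
        finish = self._t
        if cmd.kind in (CONTINUOUS, PULSED):
            self._stop_exposure()
            a = cmd.attributes
            self._exposure = {
                "position": pos,
                "kind": cmd.kind,
                "acoustic_power_w": a["acoustic_power_w"],
                "frequency_mhz": a["frequency_mhz"],
                "trajectory": a["trajectory"],
                "start_s": self._t,
            }
            if cmd.kind == PULSED:
                self._exposure["duty_cycle"] = a["duty_cycle"]
            traj = a["trajectory"]
            pose, _ = self._pose_at(self._t)
            self._log("exposure_on", {
                "position": pos,
                "kind": cmd.kind,
                "acoustic_power_w": a["acoustic_power_w"],
                "frequency_mhz": a["frequency_mhz"],
                "transducer_position_mm": [float(v) for v in pose],
                "trajectory_points_mm": (
                    None if traj is None else [list(p) for p in traj.points]
                ),
                "trajectory_interval_ms": (
                    None if traj is None else traj.interval_ms
                ),
            })
            finish = self._t + a["duration_s"]
        elif cmd.kind == MOVE:
            a = cmd.attributes
            p1 = np.asarray(a["position_mm"], dtype=float)
            ang1 = np.array([a["rot_lr_deg"], a["rot_hf_deg"]])
            dist = float(np.linalg.norm(p1 - self._position))
            dang = float(np.max(np.abs(ang1 - self._angles)))
            travel = max(dist / self.move_speed_mm_s,
                         dang / self.rotation_speed_deg_s)
            self._log("move_started", {"position": pos,
                                       "target_mm": [float(v) for v in p1]})
            if travel > 0:
                self._move = {"t0": self._t, "t1": self._t + travel,
                              "p0": self._position.copy(), "p1": p1,
                              "a0": self._angles.copy(), "a1": ang1,
                              "position": pos}
                finish = self._t + travel
            else:
                self._log("move_finished", {"position": pos})
        elif cmd.kind == PAUSE:
            a = cmd.attributes
            if a["duration_s"] is not None:
                finish = self._t + a["duration_s"]
            elif a["wait_for_previous"]:
                # dispatch is sequential, so the predecessor has already
                # completed when this starts: a pure synchronization point
                finish = self._t
            else:
                finish = math.inf  # indefinite hold; released by a goto
        elif cmd.kind == RND:
            a = cmd.attributes
            self._active_mask = np.asarray(a["active_mask"], dtype=bool).copy()
            if a["phases_rad"] is not None:
                self._phase_overrides = np.asarray(a["phases_rad"], dtype=float).copy()
            if a["amplitudes"] is not None:
                self._amp_overrides = np.asarray(a["amplitudes"], dtype=float).copy()
        if finish <= self._t:
            self._finish_command(_ActiveCommand(pos, self._t, self._t), record=False)
        else:
            self._active.append(_ActiveCommand(pos, self._t, finish))
        return finish

    def _finish_command(self, a: _ActiveCommand, record: bool = True) -> None:
        cmd = self._commands[a.position]
        if cmd.kind in (CONTINUOUS, PULSED):
            if self._exposure is not None and self._exposure["position"] == a.position:
                self._stop_exposure()
        elif cmd.kind == MOVE and self._move is not None \
                and self._move["position"] == a.position:
            self._position = self._move["p1"].copy()
            self._angles = self._move["a1"].copy()
            self._move = None
            self._log("move_finished", {"position": a.position})
        self._log("command_finished", {"position": a.position, "kind": cmd.kind})
        if record:
            self._active.remove(a)

    def _stop_exposure(self) -> None:
        if self._exposure is not None:
            self._log("exposure_off", {"position": self._exposure["position"]})
            self._exposure = None

    def _abort_active(self) -> None:
        """Stop everything in flight (goto/restart semantics)."""
        self._stop_exposure()
        if self._move is not None:
            pos, ang = self._pose_at(self._t)
            self._position = np.asarray(pos, dtype=float).copy()
            self._angles = np.asarray(ang, dtype=float).copy()
            self._move = None
        self._active = []

    def _refresh_active(self, pos: int, attr: str) -> None:
        """Propagate an edit into a currently active command."""
        cmd = self._commands[pos]
        rec = next((x for x in self._active if x.position == pos), None)
        if rec is None:
            return
        if cmd.kind in (CONTINUOUS, PULSED):
            if self._exposure is not None and self._exposure["position"] == pos:
                a = cmd.attributes
                self._exposure.update({
                    "acoustic_power_w": a["acoustic_power_w"],
                    "frequency_mhz": a["frequency_mhz"],
                    "trajectory": a["trajectory"],
                })
                if cmd.kind == PULSED:
                    self._exposure["duty_cycle"] = a["duty_cycle"]
            if attr == "duration_s":
                rec.finish_s = rec.start_s + cmd.attributes["duration_s"]
        elif cmd.kind == PAUSE and attr == "duration_s":
            d = cmd.attributes["duration_s"]
            rec.finish_s = math.inf if d is None else rec.start_s + d
        if pos == self._pointer - 1:
            self._seq_ready = rec.finish_s

    def _update_state(self) -> None:
        if self._protocol is None:
            self._state = "idle"
            return
        if self._pointer >= len(self._commands) and not self._active:
            self._state = "finished"
            return
        if self._active and all(
            self._commands[a.position].kind == PAUSE for a in self._active
        ) and self._exposure is None and self._move is None:
            self._state = "paused"
        else:
            self._state = "running"


class WallClockDriver:
    """Drives a :class:`TreatmentEngine` from wall time for interactive use;
    the simulated clock remains the single time base."""

    def __init__(self, engine: TreatmentEngine, time_source=None) -> None:
        import time as _time
        self.engine = engine
        self._now = time_source if time_source is not None else _time.monotonic
        self._last = self._now()

    def tick(self) -> list[EngineEvent]:
        now = self._now()
        dt, self._last = now - self._last, now
        return self.engine.advance_clock(max(dt, 0.0))
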