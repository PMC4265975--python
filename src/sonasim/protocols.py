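"""Treatment protocols: immutable command model, builders and JSON round-trip.

A treatment protocol is a small program for an MR-guided focused-ultrasound
device: an ordered list of commands, each with an order ``index`` and a
``time_index_s`` giving the scheduled start on the device clock.  Five
command kinds exist:

``continuous_exposure``
    Continuous ultrasound delivery at a given acoustic power and frequency,
    optionally steering the focal point electronically along a trajectory.
``pulsed_exposure``
    As above, but gated into tone bursts with a controllable duty cycle,
    pulse repetition rate and cycles per burst.
``move_transducer``
    Mechanical repositioning with 5 degrees of freedom (3-D Cartesian plus
    rotations about the left-right and head-foot axes).
``pause``
    A non-operational state of fixed duration, or waiting for the previous
    command to complete, or an indefinite hold (both fields unset).
``rnd``
    Low-level per-element control: active/inactive masks and optional phase
    and amplitude overrides for each transducer element.

Protocols are modified at run time through :class:`Modification` objects
that name the target protocol, the command positions to edit, and an
optional position at which execution resumes.

All objects are immutable; builders validate their inputs and never mutate
them.  The JSON wire format is frozen under the schema tags
``sonasim-protocol/1`` and ``sonasim-modification/1``.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Any, Optional, Sequence, Union

PROTOCOL_SCHEMA = "sonasim-protocol/1"
MODIFICATION_SCHEMA = "sonasim-modification/1"

DEFAULT_N_ELEMENTS = 256

CONTINUOUS = "continuous_exposure"
PULSED = "pulsed_exposure"
MOVE = "move_transducer"
PAUSE = "pause"
RND = "rnd"
COMMAND_KINDS = (CONTINUOUS, PULSED, MOVE, PAUSE, RND)

#: Nominal operating band of the therapy transducer (MHz); outside it the
#: builders emit a warning rather than an error.
FREQUENCY_BAND_MHZ = (1.0, 1.5)


class ProtocolError(ValueError):
    """Raised when a protocol, command or modification is invalid."""


@dataclass(frozen=True)
class MechanicalLimits:
    """Configurable travel limits of the positioning system.

    The hardware envelope is not public; these defaults are generous desk
    values that comfortably contain the heating-pattern applications.
    """

    max_abs_lr_mm: float = 100.0
    max_abs_hf_mm: float = 100.0
    min_z_mm: float = -60.0
    max_z_mm: float = 60.0
    max_abs_rotation_deg: float = 30.0


DEFAULT_LIMITS = MechanicalLimits()


@dataclass(frozen=True)
class FocusTrajectory:
    """Electronic-steering path: offsets from the natural focus (mm, device
    frame) and the dwell time per point (``interval_ms``).  During an
    exposure the focal point cycles through the list repeatedly."""

    points: tuple[tuple[float, float, float], ...]
    interval_ms: float

    def __post_init__(self) -> None:
        pts = tuple(tuple(float(c) for c in p) for p in self.points)
        if len(pts) == 0:
            raise ProtocolError("trajectory.points must be non-empty")
        for p in pts:
            if len(p) != 3:
                raise ProtocolError("trajectory points must be 3-D offsets")
            if not all(math.isfinite(c) for c in p):
                raise ProtocolError("trajectory offsets must be finite")
        if not (self.interval_ms > 0):
            raise ProtocolError("trajectory.interval_ms must be > 0")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "interval_ms", float(self.interval_ms))

    @property
    def n_points(self) -> int:
        return len(self.points)

    def point_at(self, elapsed_s: float) -> tuple[float, float, float]:
        """Focal offset active at ``elapsed_s`` after exposure start."""
        hop = int(elapsed_s / (self.interval_ms * 1e-3))
        return self.points[hop % self.n_points]


@dataclass(frozen=True)
class Command:
    index: int
    time_index_s: float
    kind: str
    attributes: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in COMMAND_KINDS:
            raise ProtocolError(f"unknown command kind {self.kind!r}")
        if self.index < 0:
            raise ProtocolError("command index must be >= 0")
        if not (self.time_index_s >= 0):
            raise ProtocolError("time_index_s must be >= 0")


@dataclass(frozen=True)
class TreatmentProtocol:
    identifier: str
    commands: tuple[Command, ...]

    def __post_init__(self) -> None:
        if not self.identifier:
            raise ProtocolError("protocol identifier must be non-empty")
        object.__setattr__(self, "commands", tuple(self.commands))


@dataclass(frozen=True)
class Modification:
    """An edit set for a loaded protocol.

    ``edits`` are ``(position, attribute, value)`` triples addressing the
    target protocol's commands by order index; ``goto_position``, if given,
    is the command position at which execution resumes after the edits are
    applied.
    """

    identifier: str
    target_protocol: str
    edits: tuple[tuple[int, str, Any], ...]
    goto_position: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.identifier:
            raise ProtocolError("modification identifier must be non-empty")
        if not self.target_protocol:
            raise ProtocolError("target protocol identifier must be non-empty")
        object.__setattr__(
            self, "edits", tuple((int(p), str(a), v) for p, a, v in self.edits)
        )


# ---------------------------------------------------------------------------
# field validators

def _require(cond: bool, message: str) -> None:
    if not cond:
        raise ProtocolError(message)


def _check_power(v: Any) -> float:
    _require(isinstance(v, (int, float)) and math.isfinite(v) and v > 0,
             "acoustic_power_w must be a positive finite number")
    return float(v)


def _check_frequency(v: Any) -> float:
    _require(isinstance(v, (int, float)) and math.isfinite(v) and v > 0,
             "frequency_mhz must be a positive finite number")
    lo, hi = FREQUENCY_BAND_MHZ
    if not (lo <= v <= hi):
        warnings.warn(
            f"frequency {v} MHz is outside the nominal {lo}-{hi} MHz band",
            stacklevel=3,
        )
    return float(v)


def _check_duration(v: Any) -> float:
    if v is None:
        return math.inf
    _require(isinstance(v, (int, float)) and v > 0,
             "duration_s must be positive (None / inf for unbounded)")
    return float(v)


def _check_trajectory(v: Any) -> Optional[FocusTrajectory]:
    if v is None:
        return None
    if isinstance(v, FocusTrajectory):
        return v
    if isinstance(v, dict):
        return FocusTrajectory(points=tuple(tuple(p) for p in v["points"]),
                               interval_ms=v["interval_ms"])
    raise ProtocolError("trajectory must be a FocusTrajectory or None")


def _check_duty_cycle(v: Any) -> float:
    _require(isinstance(v, (int, float)) and 0 < v <= 1,
             "duty_cycle must lie in (0, 1]")
    return float(v)


def _check_prf(v: Any) -> float:
    _require(isinstance(v, (int, float)) and math.isfinite(v) and v > 0,
             "pulse_repetition_rate_hz must be positive")
    return float(v)


def _check_cycles(v: Any) -> int:
    _require(isinstance(v, (int, float)) and v == int(v) and v > 0,
             "cycles_per_burst must be a positive integer")
    return int(v)


def _check_flag(v: Any) -> bool:
    _require(isinstance(v, (bool, int)), "expected a boolean flag")
    return bool(v)


def _check_position(v: Any) -> tuple[float, float, float]:
    seq = tuple(float(c) for c in v)
    _require(len(seq) == 3 and all(math.isfinite(c) for c in seq),
             "position_mm must be three finite coordinates")
    return seq


def _check_angle(v: Any) -> float:
    _require(isinstance(v, (int, float)) and math.isfinite(v),
             "rotation angle must be finite")
    return float(v)


def _check_optional_duration(v: Any) -> Optional[float]:
    if v is None:
        return None
    _require(isinstance(v, (int, float)) and v >= 0,
             "pause duration_s must be >= 0")
    return float(v)


def _check_bool_array(v: Any) -> tuple[bool, ...]:
    return tuple(bool(x) for x in v)


def _check_float_array(v: Any) -> Optional[tuple[float, ...]]:
    if v is None:
        return None
    out = tuple(float(x) for x in v)
    _require(all(math.isfinite(x) for x in out), "array entries must be finite")
    return out


#: Attribute registry per command kind: name -> validator.  Used by the
#: builders, by modification-edit validation and by the JSON reader.
KIND_FIELDS: dict[str, dict[str, Any]] = {
    CONTINUOUS: {
        "acoustic_power_w": _check_power,
        "frequency_mhz": _check_frequency,
        "trajectory": _check_trajectory,
        "duration_s": _check_duration,
    },
    PULSED: {
        "acoustic_power_w": _check_power,
        "frequency_mhz": _check_frequency,
        "duty_cycle": _check_duty_cycle,
        "pulse_repetition_rate_hz": _check_prf,
        "cycles_per_burst": _check_cycles,
        "external_trigger": _check_flag,
        "trajectory": _check_trajectory,
        "duration_s": _check_duration,
    },
    MOVE: {
        "position_mm": _check_position,
        "rot_lr_deg": _check_angle,
        "rot_hf_deg": _check_angle,
    },
    PAUSE: {
        "duration_s": _check_optional_duration,
        "wait_for_previous": _check_flag,
    },
    RND: {
        "active_mask": _check_bool_array,
        "phases_rad": _check_float_array,
        "amplitudes": _check_float_array,
    },
}


def validate_attribute(kind: str, name: str, value: Any) -> Any:
    """Validate one attribute value for a command kind; returns the
    normalized value or raises :class:`ProtocolError`."""
    fields = KIND_FIELDS.get(kind)
    if fields is None:
        raise ProtocolError(f"unknown command kind {kind!r}")
    if name not in fields:
        raise ProtocolError(f"command kind {kind!r} has no attribute {name!r}")
    return fields[name](value)


# ---------------------------------------------------------------------------
# builders

def build_continuous_exposure(acoustic_power_w: float, frequency_mhz: float,
                              trajectory: Optional[FocusTrajectory],
                              duration_s: float,
                              time_index_s: float = 0.0) -> Command:
    """Start of a continuous ultrasound exposure.

    ``duration_s`` may be ``math.inf`` (or ``None``) for an open-ended
    exposure that is stopped by a later modification.
    """
    attrs = {
        "acoustic_power_w": _check_power(acoustic_power_w),
        "frequency_mhz": _check_frequency(frequency_mhz),
        "trajectory": _check_trajectory(trajectory),
        "duration_s": _check_duration(duration_s),
    }
    return Command(index=0, time_index_s=float(time_index_s),
                   kind=CONTINUOUS, attributes=attrs)


def build_pulsed_exposure(acoustic_power_w: float, frequency_mhz: float,
                          duty_cycle: float, pulse_repetition_rate_hz: float,
                          cycles_per_burst: int,
                          trajectory: Optional[FocusTrajectory],
                          duration_s: float, time_index_s: float = 0.0,
                          external_trigger: bool = False) -> Command:
    """Start of a pulsed exposure: tone bursts of ``cycles_per_burst``
    cycles repeated at ``pulse_repetition_rate_hz``.  The implied burst
    length is ``cycles_per_burst / frequency``."""
    attrs = {
        "acoustic_power_w": _check_power(acoustic_power_w),
        "frequency_mhz": _check_frequency(frequency_mhz),
        "duty_cycle": _check_duty_cycle(duty_cycle),
        "pulse_repetition_rate_hz": _check_prf(pulse_repetition_rate_hz),
        "cycles_per_burst": _check_cycles(cycles_per_burst),
        "external_trigger": _check_flag(external_trigger),
        "trajectory": _check_trajectory(trajectory),
        "duration_s": _check_duration(duration_s),
    }
    burst = attrs["cycles_per_burst"] / (attrs["frequency_mhz"] * 1e6)
    period = 1.0 / attrs["pulse_repetition_rate_hz"]
    if burst > period:
        raise ProtocolError(
            f"burst length {burst:.3g} s exceeds the repetition period {period:.3g} s"
        )
    return Command(index=0, time_index_s=float(time_index_s),
                   kind=PULSED, attributes=attrs)


def burst_duration_s(command: Command) -> float:
    """Length of one tone burst of a pulsed exposure (s)."""
    _require(command.kind == PULSED, "burst_duration_s needs a pulsed exposure")
    a = command.attributes
    return a["cycles_per_burst"] / (a["frequency_mhz"] * 1e6)


def n_bursts(command: Command) -> int:
    """Number of bursts scheduled over the exposure duration."""
    _require(command.kind == PULSED, "n_bursts needs a pulsed exposure")
    a = command.attributes
    if math.isinf(a["duration_s"]):
        raise ProtocolError("unbounded exposure has no finite burst count")
    # a burst starts at every full repetition period within the duration
    return int(round(a["duration_s"] * a["pulse_repetition_rate_hz"]))


def build_move(position_mm: Sequence[float], rot_lr_deg: float = 0.0,
               rot_hf_deg: float = 0.0, time_index_s: float = 0.0,
               limits: MechanicalLimits = DEFAULT_LIMITS) -> Command:
    """Transducer movement: 3-D Cartesian target plus rotations about the
    left-right and head-foot axes, validated against mechanical limits."""
    pos = _check_position(position_mm)
    if abs(pos[0]) > limits.max_abs_lr_mm:
        raise ProtocolError(f"LR target {pos[0]} mm exceeds +/-{limits.max_abs_lr_mm} mm")
    if abs(pos[1]) > limits.max_abs_hf_mm:
        raise ProtocolError(f"HF target {pos[1]} mm exceeds +/-{limits.max_abs_hf_mm} mm")
    if not (limits.min_z_mm <= pos[2] <= limits.max_z_mm):
        raise ProtocolError(
            f"beam-axis target {pos[2]} mm outside [{limits.min_z_mm}, {limits.max_z_mm}] mm"
        )
    for label, ang in (("rot_lr_deg", rot_lr_deg), ("rot_hf_deg", rot_hf_deg)):
        _check_angle(ang)
        if abs(ang) > limits.max_abs_rotation_deg:
            raise ProtocolError(
                f"{label}={ang} deg exceeds +/-{limits.max_abs_rotation_deg} deg"
            )
    attrs = {"position_mm": pos, "rot_lr_deg": float(rot_lr_deg),
             "rot_hf_deg": float(rot_hf_deg)}
    return Command(index=0, time_index_s=float(time_index_s), kind=MOVE,
                   attributes=attrs)


def build_pause(duration_s: Optional[float] = None,
                wait_for_previous: bool = False,
                time_index_s: float = 0.0) -> Command:
    """Non-operational state.  A fixed ``duration_s``, waiting for the
    previous command, or (both unset) an indefinite hold that a later
    modification releases."""
    attrs = {"duration_s": _check_optional_duration(duration_s),
             "wait_for_previous": _check_flag(wait_for_previous)}
    return Command(index=0, time_index_s=float(time_index_s), kind=PAUSE,
                   attributes=attrs)


def build_rnd(active_mask: Sequence[bool],
              phases_rad: Optional[Sequence[float]] = None,
              amplitudes: Optional[Sequence[float]] = None,
              time_index_s: float = 0.0,
              n_elements: int = DEFAULT_N_ELEMENTS) -> Command:
    """Low-level element control: per-element active mask with optional
    phase/amplitude overrides; omitted overrides leave the element state
    unchanged."""
    mask = _check_bool_array(active_mask)
    if len(mask) != n_elements:
        raise ProtocolError(
            f"active_mask has length {len(mask)}, expected {n_elements}"
        )
    phases = _check_float_array(phases_rad)
    if phases is not None and len(phases) != n_elements:
        raise ProtocolError(
            f"phases_rad has length {len(phases)}, expected {n_elements}"
        )
    amps = _check_float_array(amplitudes)
    if amps is not None:
        if len(amps) != n_elements:
            raise ProtocolError(
                f"amplitudes has length {len(amps)}, expected {n_elements}"
            )
        if not all(0.0 <= a <= 1.0 for a in amps):
            raise ProtocolError("amplitudes must lie in [0, 1]")
    attrs = {"active_mask": mask, "phases_rad": phases, "amplitudes": amps}
    return Command(index=0, time_index_s=float(time_index_s), kind=RND,
                   attributes=attrs)


def assemble_protocol(identifier: str,
                      commands: Sequence[Command]) -> TreatmentProtocol:
    """Assemble commands into a protocol: re-index 0..n-1 preserving order
    and check that time indices are non-decreasing.  Idempotent."""
    if not identifier:
        raise ProtocolError("protocol identifier must be non-empty")
    cmds = list(commands)
    if not cmds:
        raise ProtocolError("a protocol needs at least one command")
    reindexed = tuple(replace(c, index=i) for i, c in enumerate(cmds))
    for a, b in zip(reindexed, reindexed[1:]):
        if b.time_index_s < a.time_index_s:
            raise ProtocolError(
                f"time indices decrease between commands {a.index} "
                f"({a.time_index_s} s) and {b.index} ({b.time_index_s} s)"
            )
    return TreatmentProtocol(identifier=identifier, commands=reindexed)


def build_modification(identifier: str,
                       target: Union[str, TreatmentProtocol],
                       edits: Sequence[tuple[int, str, Any]],
                       goto_position: Optional[int] = None) -> Modification:
    """Build a modification.  If ``target`` is a protocol object the edits
    and the goto position are validated against it immediately; a string
    target defers validation to the engine."""
    protocol = target if isinstance(target, TreatmentProtocol) else None
    target_id = target.identifier if protocol is not None else str(target)
    norm_edits = []
    for pos, attr, value in edits:
        pos = int(pos)
        if protocol is not None:
            if not (0 <= pos < len(protocol.commands)):
                raise ProtocolError(f"edit position {pos} not in target protocol")
            kind = protocol.commands[pos].kind
            value = validate_attribute(kind, attr, value)
        norm_edits.append((pos, attr, value))
    if goto_position is not None and protocol is not None:
        if not (0 <= goto_position < len(protocol.commands)):
            raise ProtocolError(f"goto position {goto_position} not in target protocol")
    return Modification(identifier=identifier, target_protocol=target_id,
                        edits=tuple(norm_edits), goto_position=goto_position)


# ---------------------------------------------------------------------------
# JSON (de)serialization — frozen wire format

def _attr_to_json(value: Any) -> Any:
    if isinstance(value, FocusTrajectory):
        return {"points": [list(p) for p in value.points],
                "interval_ms": value.interval_ms}
    if isinstance(value, float) and math.isinf(value):
        return None  # unbounded duration
    if isinstance(value, tuple):
        return list(value)
    return value


def _command_to_json(c: Command) -> dict[str, Any]:
    return {
        "index": c.index,
        "time_index_s": c.time_index_s,
        "kind": c.kind,
        "attributes": {k: _attr_to_json(v) for k, v in c.attributes.items()},
    }


def serialize(obj: Union[TreatmentProtocol, Modification]) -> str:
    """Serialize a protocol or modification to its canonical JSON text."""
    if isinstance(obj, TreatmentProtocol):
        doc = {
            "schema": PROTOCOL_SCHEMA,
            "identifier": obj.identifier,
            "commands": [_command_to_json(c) for c in obj.commands],
        }
    elif isinstance(obj, Modification):
        doc = {
            "schema": MODIFICATION_SCHEMA,
            "identifier": obj.identifier,
            "target_protocol": obj.target_protocol,
            "edits": [
                {"position": p, "attribute": a, "value": _attr_to_json(v)}
                for p, a, v in obj.edits
            ],
            "goto_position": obj.goto_position,
        }
    else:
        raise ProtocolError(f"cannot serialize {type(obj).__name__}")
    return json.dumps(doc, sort_keys=True)


def _parse_command(doc: Any, path: str) -> Command:
    try:
        kind = doc["kind"]
        raw = doc["attributes"]
        index = int(doc["index"])
        time_index = float(doc["time_index_s"])
    except (KeyError, TypeError, ValueError) as exc:
        raise ProtocolError(f"malformed command at {path}: {exc}") from exc
    fields = KIND_FIELDS.get(kind)
    if fields is None:
        raise ProtocolError(f"unknown command kind {kind!r} at {path}.kind")
    attrs = {}
    for name, check in fields.items():
        if name not in raw:
            raise ProtocolError(f"missing attribute at {path}.attributes.{name}")
        try:
            attrs[name] = check(raw[name])
        except ProtocolError as exc:
            raise ProtocolError(f"at {path}.attributes.{name}: {exc}") from exc
    extra = set(raw) - set(fields)
    if extra:
        raise ProtocolError(f"unknown attributes {sorted(extra)} at {path}.attributes")
    return Command(index=index, time_index_s=time_index, kind=kind,
                   attributes=attrs)


def deserialize(text: str) -> Union[TreatmentProtocol, Modification]:
    """Parse JSON text into a protocol or modification; schema violations
    raise :class:`ProtocolError` naming the JSON path."""
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ProtocolError(f"invalid JSON: {exc}") from exc
    if not isinstance(doc, dict) or "schema" not in doc:
        raise ProtocolError("missing 'schema' field at $")
    schema = doc["schema"]
    if schema == PROTOCOL_SCHEMA:
        try:
            identifier = doc["identifier"]
            raw_commands = doc["commands"]
        except KeyError as exc:
            raise ProtocolError(f"missing field {exc} at $") from exc
        commands = [
            _parse_command(c, f"$.commands[{i}]") for i, c in enumerate(raw_commands)
        ]
        protocol = TreatmentProtocol(identifier=identifier,
                                     commands=tuple(commands))
        expected = list(range(len(commands)))
        if [c.index for c in commands] != expected:
            raise ProtocolError("command indices are not 0..n-1 at $.commands")
        return protocol
    if schema == MODIFICATION_SCHEMA:
        try:
            edits = tuple(
                (e["position"], e["attribute"], e["value"]) for e in doc["edits"]
            )
            return Modification(
                identifier=doc["identifier"],
                target_protocol=doc["target_protocol"],
                edits=edits,
                goto_position=doc.get("goto_position"),
            )
        except (KeyError, TypeError) as exc:
            raise ProtocolError(f"malformed modification: {exc}") from exc
    raise ProtocolError(f"unknown schema {schema!r} at $.schema")
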