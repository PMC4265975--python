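"""Protocol model: builders, validation, assembly and JSON round-trip."""

import json
import math

import pytest
from hypothesis import given, settings, strategies as st

from sonasim import protocols as pr


def line_trajectory(n=10, step=2.0, interval_ms=25.0):
    return pr.FocusTrajectory(
        points=tuple((i * step - (n - 1) * step / 2, 0.0, 0.0) for i in range(n)),
        interval_ms=interval_ms,
    )


def hydrophone_protocol(element=0, n=256):
    duty = 40 / 1.2e6 * 40.0
    return pr.assemble_protocol("ElementScan", [
        pr.build_rnd([False] * n, n_elements=n),
        pr.build_rnd([i == element for i in range(n)], n_elements=n),
        pr.build_pulsed_exposure(10.0, 1.2, duty, 40.0, 40, None, 1.8),
        pr.build_pause(duration_s=0.0, time_index_s=1.8),
        pr.build_pause(time_index_s=1.8),
    ])


def letter_protocol():
    return pr.assemble_protocol("HIFU_Pattern", [
        pr.build_move((-37.5, 0.0, 0.0)),
        pr.build_pause(duration_s=2.0),
        pr.build_continuous_exposure(80.0, 1.2, line_trajectory(), 8.0),
        pr.build_pause(duration_s=0.0),
        pr.build_pause(),
    ])


class TestBuilders:
    def test_continuous_exposure_carries_attributes(self):
        traj = line_trajectory()
        cmd = pr.build_continuous_exposure(80.0, 1.2, traj, 8.0)
        assert cmd.kind == pr.CONTINUOUS
        assert cmd.attributes["acoustic_power_w"] == 80.0
        assert cmd.attributes["trajectory"] is traj
        assert cmd.attributes["duration_s"] == 8.0

    def test_static_focus_exposure(self):
        cmd = pr.build_continuous_exposure(10.0, 1.2, None, 5.0)
        assert cmd.attributes["trajectory"] is None

    @pytest.mark.parametrize("power,duration", [(0.0, 5.0), (-1.0, 5.0),
                                                (10.0, 0.0), (10.0, -2.0)])
    def test_nonpositive_power_or_duration_rejected(self, power, duration):
        with pytest.raises(pr.ProtocolError):
            pr.build_continuous_exposure(power, 1.2, None, duration)

    def test_frequency_outside_band_warns(self):
        with pytest.warns(UserWarning, match="band"):
            pr.build_continuous_exposure(10.0, 3.0, None, 5.0)

    def test_pulsed_burst_length_and_count(self):
        cmd = pr.build_pulsed_exposure(10.0, 1.2, 40 / 1.2e6 * 40, 40.0, 40,
                                       None, 1.8)
        assert pr.burst_duration_s(cmd) == pytest.approx(40 / 1.2e6)  # 33.33 us
        assert pr.n_bursts(cmd) == 72  # 1.8 s at 40 Hz

    def test_duty_cycle_limits(self):
        # duty_cycle = 1 is the continuous limit within one period
        cmd = pr.build_pulsed_exposure(10.0, 1.2, 1.0, 40.0, 30000, None, 1.0)
        assert cmd.attributes["duty_cycle"] == 1.0
        for bad in (0.0, 1.5, -0.1):
            with pytest.raises(pr.ProtocolError):
                pr.build_pulsed_exposure(10.0, 1.2, bad, 40.0, 40, None, 1.0)

    def test_move_validates_each_axis(self):
        assert pr.build_move((0.0, 0.0, 0.0)).kind == pr.MOVE  # no-op move
        with pytest.raises(pr.ProtocolError, match="LR"):
            pr.build_move((150.0, 0.0, 0.0))
        with pytest.raises(pr.ProtocolError, match="rot_lr"):
            pr.build_move((0.0, 0.0, 0.0), rot_lr_deg=45.0)

    def test_pause_variants(self):
        assert pr.build_pause(duration_s=2.0).attributes["duration_s"] == 2.0
        assert pr.build_pause(wait_for_previous=True).attributes["duration_s"] is None
        assert pr.build_pause(duration_s=0.0).attributes["duration_s"] == 0.0

    def test_rnd_masks_and_lengths(self):
        cmd = pr.build_rnd([i == 7 for i in range(256)])
        assert sum(cmd.attributes["active_mask"]) == 1
        cmd = pr.build_rnd([True] * 256, phases_rad=[0.0] * 256)
        assert set(cmd.attributes["phases_rad"]) == {0.0}
        with pytest.raises(pr.ProtocolError, match="length"):
            pr.build_rnd([True] * 255)
        with pytest.raises(pr.ProtocolError):
            pr.build_rnd([True] * 256, amplitudes=[2.0] * 256)

    def test_builders_do_not_mutate_inputs(self):
        mask = [True] * 256
        pr.build_rnd(mask)
        assert mask == [True] * 256
        a = pr.build_continuous_exposure(80.0, 1.2, line_trajectory(), 8.0)
        b = pr.build_continuous_exposure(80.0, 1.2, line_trajectory(), 8.0)
        assert a == b


class TestTrajectory:
    def test_requires_points_and_interval(self):
        with pytest.raises(pr.ProtocolError):
            pr.FocusTrajectory(points=(), interval_ms=25.0)
        with pytest.raises(pr.ProtocolError):
            pr.FocusTrajectory(points=((0, 0, 0),), interval_ms=0.0)
        with pytest.raises(pr.ProtocolError):
            pr.FocusTrajectory(points=((0, 0, math.inf),), interval_ms=25.0)

    def test_cycles_through_points(self):
        traj = line_trajectory(n=10, interval_ms=25.0)
        assert traj.point_at(0.0) == traj.points[0]
        assert traj.point_at(0.026) == traj.points[1]
        # the list repeats for the whole exposure: 8 s / 0.25 s = 32 passes
        assert traj.point_at(0.25) == traj.points[0]
        assert traj.point_at(7.999) == traj.points[9]


class TestAssembly:
    def test_reindexes_preserving_order(self):
        cmds = [pr.build_pause(duration_s=1.0, time_index_s=float(i))
                for i in range(3)]
        proto = pr.assemble_protocol("P", cmds)
        assert [c.index for c in proto.commands] == [0, 1, 2]

    def test_idempotent(self):
        proto = hydrophone_protocol()
        again = pr.assemble_protocol(proto.identifier, proto.commands)
        assert again == proto

    def test_decreasing_time_index_rejected(self):
        cmds = [pr.build_pause(duration_s=1.0, time_index_s=5.0),
                pr.build_pause(duration_s=1.0, time_index_s=2.0)]
        with pytest.raises(pr.ProtocolError, match="0"):
            pr.assemble_protocol("P", cmds)

    def test_empty_rejected(self):
        with pytest.raises(pr.ProtocolError):
            pr.assemble_protocol("P", [])
        with pytest.raises(pr.ProtocolError):
            pr.assemble_protocol("", [pr.build_pause(duration_s=1.0)])


class TestModification:
    def test_power_edit(self):
        proto = letter_protocol()
        mod = pr.build_modification("UpdateExposure", proto,
                                    edits=[(2, "acoustic_power_w", 20.0)])
        assert mod.target_protocol == "HIFU_Pattern"
        assert mod.edits == ((2, "acoustic_power_w", 20.0),)

    def test_unknown_attribute_rejected(self):
        proto = letter_protocol()
        with pytest.raises(pr.ProtocolError, match="no attribute"):
            pr.build_modification("Bad", proto, edits=[(2, "colour", 1)])

    def test_position_and_goto_validated(self):
        proto = letter_protocol()
        with pytest.raises(pr.ProtocolError):
            pr.build_modification("Bad", proto,
                                  edits=[(9, "acoustic_power_w", 20.0)])
        with pytest.raises(pr.ProtocolError, match="goto"):
            pr.build_modification("Bad", proto, edits=[], goto_position=9)


class TestSerialization:
    @pytest.mark.parametrize("make", [hydrophone_protocol, letter_protocol])
    def test_round_trip_identity(self, make):
        obj = make()
        assert pr.deserialize(pr.serialize(obj)) == obj

    def test_modification_round_trip(self):
        mod = pr.build_modification("M1", letter_protocol(),
                                    edits=[(2, "acoustic_power_w", 20.0)],
                                    goto_position=0)
        assert pr.deserialize(pr.serialize(mod)) == mod

    def test_hand_written_minimal_json(self):
        doc = {
            "schema": "sonasim-protocol/1",
            "identifier": "Protocol_1",
            "commands": [{
                "index": 0, "time_index_s": 0.0, "kind": "pause",
                "attributes": {"duration_s": 2.0, "wait_for_previous": False},
            }],
        }
        proto = pr.deserialize(json.dumps(doc))
        assert proto.identifier == "Protocol_1"
        assert proto.commands[0].attributes["duration_s"] == 2.0

    def test_infinite_duration_serializes_as_null(self):
        proto = pr.assemble_protocol("P", [
            pr.build_continuous_exposure(10.0, 1.2, None, math.inf)
        ])
        doc = json.loads(pr.serialize(proto))
        assert doc["commands"][0]["attributes"]["duration_s"] is None
        assert pr.deserialize(pr.serialize(proto)) == proto

    def test_truncated_json_rejected(self):
        text = pr.serialize(letter_protocol())
        with pytest.raises(pr.ProtocolError, match="JSON"):
            pr.deserialize(text[: len(text) // 2])

    def test_schema_violation_names_path(self):
        doc = {
            "schema": "sonasim-protocol/1", "identifier": "P",
            "commands": [{"index": 0, "time_index_s": 0.0, "kind": "pause",
                          "attributes": {"duration_s": -1.0,
                                         "wait_for_previous": False}}],
        }
        with pytest.raises(pr.ProtocolError, match=r"\$\.commands\[0\]"):
            pr.deserialize(json.dumps(doc))


@st.composite
def protocols_strategy(draw):
    n = draw(st.integers(min_value=1, max_value=5))
    t = 0.0
    cmds = []
    for _ in range(n):
        t += draw(st.floats(min_value=0.0, max_value=5.0))
        choice = draw(st.integers(0, 3))
        if choice == 0:
            cmds.append(pr.build_pause(
                duration_s=draw(st.floats(0.0, 10.0)), time_index_s=t))
        elif choice == 1:
            cmds.append(pr.build_continuous_exposure(
                draw(st.floats(0.1, 200.0)), draw(st.floats(1.0, 1.5)),
                None, draw(st.floats(0.1, 10.0)), time_index_s=t))
        elif choice == 2:
            cmds.append(pr.build_move(
                (draw(st.floats(-50, 50)), draw(st.floats(-50, 50)), 0.0),
                time_index_s=t))
        else:
            cmds.append(pr.build_rnd(
                [draw(st.booleans()) for _ in range(8)], n_elements=8,
                time_index_s=t))
    return pr.assemble_protocol("Random", cmds)


@settings(max_examples=50, derandomize=True, deadline=None)
@given(protocols_strategy())
def test_serialization_round_trip_property(proto):
    """deserialize(serialize(.)) is the identity on arbitrary valid
    protocols, and assembly of an assembled protocol changes nothing."""
    assert pr.deserialize(pr.serialize(proto)) == proto
    assert pr.assemble_protocol(proto.identifier, proto.commands) == proto
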