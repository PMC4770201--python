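from collections import defaultdict

import pytest

from dmfsynth.dmf_protocol import (
    LayoutCapacityError,
    ProtocolBuilder,
    RoutingBlockedError,
    ThermalProgram,
    default_layout,
    route,
    schedule_pcr_lane,
    serial_dilution_routine,
)


class TestRoute:
    def test_straight_line_on_empty_grid(self):
        path = route((0, 0), (0, 5), occupancy=[])
        assert len(path) == 6
        assert path[0] == (0, 0) and path[-1] == (0, 5)

    def test_obstacle_forces_detour(self):
        direct = route((0, 2), (8, 2), occupancy=[])
        detour = route((0, 2), (8, 2), occupancy=[(4, 2)])
        assert len(detour) >= len(direct)
        assert all(max(abs(c[0] - 4), abs(c[1] - 2)) >= 2
                   for c in detour[1:])

    def test_blocked_corridor_raises(self):
        wall = [(x, 1) for x in range(0, 12, 2)]
        with pytest.raises(RoutingBlockedError):
            route((5, 0), (5, 3), occupancy=wall, grid=(12, 4))

    def test_deterministic(self):
        a = route((1, 1), (9, 7), occupancy=[(4, 4)])
        b = route((1, 1), (9, 7), occupancy=[(4, 4)])
        assert a == b


class TestThermalProgram:
    def test_dwells_follow_recipe(self):
        p = ThermalProgram(anneal_c=62.0, cycles=1, product_len_kb=1.0)
        assert p.dwells == (5.0, 5.0, 15.0)
        assert p.period_s == 15.0

    def test_extension_scales_with_length(self):
        p = ThermalProgram(anneal_c=62.0, cycles=1, product_len_kb=2.0)
        assert p.extension_s == 30.0

    def test_anneal_bounds(self):
        with pytest.raises(ValueError):
            ThermalProgram(anneal_c=80.0, cycles=1)
        with pytest.raises(ValueError):
            ThermalProgram(anneal_c=62.0, cycles=0)


class TestSerialDilutionRoutine:
    def test_k6_structure(self):
        prot = serial_dilution_routine(6)
        kinds = defaultdict(int)
        for op in prot.ops:
            if op.node and op.node.startswith("dilution"):
                kinds[op.kind] += 1
        assert kinds["MERGE"] == 6 and kinds["SPLIT"] == 6 and kinds["TRASH"] == 6
        assert all(op.diluent_merge for op in prot.ops if op.kind == "MERGE")
        assert prot.well_formed() == []

    def test_k0_is_a_no_op(self):
        prot = serial_dilution_routine(0)
        assert not any(op.kind in ("MERGE", "SPLIT") for op in prot.ops)

    def test_insufficient_diluent_raises(self):
        layout = default_layout({"sample": {"m": 1.0}, "diluent": {}})
        small = layout.reservoirs["diluent"]
        object.__setattr__(small, "capacity_ul", 0.5)  # 500 nl < 6 steps
        b = ProtocolBuilder(layout)
        d = b.dispense("sample")
        with pytest.raises(LayoutCapacityError):
            b.serial_dilution(d, 6, "diluent")


class TestPcrLaneSchedule:
    program = ThermalProgram(anneal_c=62.0, cycles=30, product_len_kb=1.0)

    def _station_occupancy_ok(self, protocol):
        by_t = defaultdict(list)
        for op in protocol.ops:
            if op.kind == "HOLD":
                by_t[op.t].append(op.zone)
        return all(len(set(zones)) == len(zones) for zones in by_t.values())

    def test_three_droplets_distinct_stations_always(self):
        prot = schedule_pcr_lane(3, self.program)
        assert self._station_occupancy_ok(prot)
        assert prot.well_formed() == []

    def test_capacity_limited_to_temperature_zones(self):
        with pytest.raises(LayoutCapacityError):
            schedule_pcr_lane(4, self.program)

    def test_single_droplet_cycle_time(self):
        # one cycle at 1 kb: dwell pattern 5 / 5 / 15 s, over-dwelled to the
        # 15 s rotation period per station
        prog = ThermalProgram(anneal_c=62.0, cycles=1, product_len_kb=1.0)
        prot = schedule_pcr_lane(1, prog)
        holds = [op for op in prot.ops if op.kind == "HOLD"]
        assert all(h.duration >= d for h, d in zip(holds, prog.dwells))

    def test_throughput_nearly_tripled(self):
        m1 = max(op.t + op.duration for op in schedule_pcr_lane(1, self.program).ops)
        m3 = max(op.t + op.duration for op in schedule_pcr_lane(3, self.program).ops)
        assert m3 / m1 <= 1.34


class TestCompiledPopProtocol:
    def test_dilution_ledger_structure(self, pop_plan, pop_protocol):
        # exactly (stages - 1) inter-stage dilution routines of 6 steps each
        dilution_merges = defaultdict(int)
        for op in pop_protocol.ops:
            if op.kind == "MERGE" and op.diluent_merge:
                dilution_merges[op.node] += 1
        assert len(dilution_merges) == len(pop_plan.stages) - 1
        assert all(v == 6 for v in dilution_merges.values())

    def test_one_thermocycle_block_per_stage(self, pop_plan, pop_protocol):
        stage_holds = defaultdict(set)
        for op in pop_protocol.ops:
            if op.kind == "HOLD" and op.node and op.node.startswith("pop_stage"):
                stage_holds[op.node].add(op.zone)
        assert len(stage_holds) == len(pop_plan.stages)

    def test_well_formed(self, pop_protocol):
        assert pop_protocol.well_formed() == []

    def test_elutes_exactly_one_product(self, pop_protocol):
        assert sum(1 for op in pop_protocol.ops if op.kind == "ELUTE") == 1


class TestCompiledMcadProtocol:
    def test_24_elutions(self, azurin_protocol):
        assert sum(1 for op in azurin_protocol.ops if op.kind == "ELUTE") == 24

    def test_well_formed(self, azurin_protocol):
        assert azurin_protocol.well_formed() == []

    def test_every_op_traceable_to_a_plan_node(self, azurin_protocol):
        assert all(op.node for op in azurin_protocol.ops)


class TestLayoutCapacity:
    def test_too_many_reagents_rejected(self):
        reagents = {f"r{i}": {} for i in range(31)}
        with pytest.raises(LayoutCapacityError):
            default_layout(reagents)

    def test_thirty_reagents_fit(self):
        layout = default_layout({f"r{i}": {} for i in range(30)})
        assert len(layout.reservoirs) == 30
        groups = {r.group for r in layout.reservoirs.values()}
        assert groups == {"A", "C", "D", "E"}
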