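"""Virtual EWOD cartridge model and droplet-protocol compilation.

The cartridge is a rectangular electrode grid with reservoir ports on the top
edge, a storage/parking area, a dilution zone, collection (elution) wells,
a waste port, and a PCR lane of fixed-temperature stations.  Thermal ramping
is done by shuttling droplets between stations; several droplets share one
lane by rotating around it phase-shifted ("circular-permutation PCR"), which
multiplies lane throughput.

The compiler turns assembly plans (inside-out extension plans or library
construction DAGs) into timed droplet operations.  All routing is
collision-aware: a moving droplet never comes within one electrode of a
stationary one (the DNA cross-contamination spacing rule), except on the
final approach of an intended merge.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass, field, asdict
from typing import Iterable

from .seqcore import NucSequence, tm_nn, DEFAULT_TM_CONFIG, UnsupportedBaseError
from .pop_planner import PopPlan
from .mcad_planner import (
    ConstructionPlan,
    JOIN_CYCLES,
    AMPLIFICATION_CYCLES,
    ANNEAL_TM_OFFSET,
)

__all__ = [
    "Cell",
    "Reservoir",
    "PcrStation",
    "CartridgeLayout",
    "DropletOp",
    "ThermalProgram",
    "Protocol",
    "ProtocolBuilder",
    "RoutingBlockedError",
    "LayoutCapacityError",
    "route",
    "serial_dilution_routine",
    "schedule_pcr_lane",
    "compile_protocol",
    "default_layout",
    "AVOGADRO",
    "UNIT_VOLUME_NL",
    "TEMPLATE_COPIES_PER_DROPLET",
    "PRIMER_COPIES_PER_DROPLET",
]

Cell = tuple[int, int]

AVOGADRO = 6.02214076e23
#: Droplet unit volume on this cartridge geometry.
UNIT_VOLUME_NL = 300.0
#: 1 fmol of template per unit assembly droplet.
TEMPLATE_COPIES_PER_DROPLET = int(1e-15 * AVOGADRO)
#: 0.1 pmol of each primer per unit assembly droplet (bulk amount, molecules).
PRIMER_COPIES_PER_DROPLET = 0.1e-12 * AVOGADRO

TRANSIT_S_PER_ELECTRODE = 0.1


class RoutingBlockedError(RuntimeError):
    """No collision-free path exists between the requested electrodes."""


class LayoutCapacityError(RuntimeError):
    """The plan needs more reservoirs / parking space than the cartridge has."""


@dataclass(frozen=True)
class Reservoir:
    name: str
    group: str
    port: Cell
    capacity_ul: float = 20.0
    dead_volume_frac: float = 0.05
    #: Species -> amount per unit (300 nl) droplet.  ``int`` values are
    #: discrete molecule counts, ``float`` values are bulk amounts.
    contents: dict[str, float] = field(default_factory=dict)

    @property
    def usable_nl(self) -> float:
        return self.capacity_ul * 1e3 * (1.0 - self.dead_volume_frac)


@dataclass(frozen=True)
class PcrStation:
    name: str
    temp_c: float | None  # None = ambient rest station on the ring
    anchor: Cell


@dataclass
class CartridgeLayout:
    width: int = 40
    height: int = 20
    unit_volume_nl: float = UNIT_VOLUME_NL
    reservoirs: dict[str, Reservoir] = field(default_factory=dict)
    #: PCR ring stations in rotation order: 95 -> anneal -> extend -> rest.
    pcr_stations: list[PcrStation] = field(default_factory=list)
    #: Parking anchors in the storage area.
    storage_anchors: list[Cell] = field(default_factory=list)
    #: Work cells of the dilution zone.
    dilution_cells: list[Cell] = field(default_factory=list)
    elution_wells: dict[str, Cell] = field(default_factory=dict)
    waste_cell: Cell = (38, 19)

    def station(self, name: str) -> PcrStation:
        for s in self.pcr_stations:
            if s.name == name:
                return s
        raise KeyError(name)

    def in_grid(self, cell: Cell) -> bool:
        x, y = cell
        return 0 <= x < self.width and 0 <= y < self.height


#: Reservoir wells per group on the standard cartridge (30 in total).
_GROUP_SIZES = {"A": 8, "C": 8, "D": 7, "E": 7}


def default_layout(reagents: dict[str, dict[str, float]] | None = None) -> CartridgeLayout:
    """The standard 40x20 cartridge: 30 reservoir wells in groups A/C/D/E
    along the top edge, a storage area of 30 spaced parking anchors with
    routing corridors, a dilution row, elution wells on the right edge and
    a 4-station PCR ring at the bottom.

    ``reagents`` maps reagent names to per-droplet contents; they are
    assigned to wells in order.  Raises :class:`LayoutCapacityError` when
    there are more reagents than wells.
    """
    layout = CartridgeLayout()
    ports = []
    x = 0
    for group, size in _GROUP_SIZES.items():
        for i in range(size):
            ports.append((group, f"{group}{i + 1}", (x, 0)))
            x += 1
    layout._free_wells = ports  # type: ignore[attr-defined]
    layout.pcr_stations = [
        PcrStation("pcr_95", 95.0, (2, 18)),
        PcrStation("pcr_anneal", 62.0, (8, 18)),
        PcrStation("pcr_extend", 72.0, (14, 18)),
        PcrStation("pcr_rest", None, (20, 18)),
    ]
    # 4-electrode anchor pitch keeps a free routing corridor between any two
    # parked droplets under the one-electrode contamination spacing.
    layout.storage_anchors = [
        (xx, yy) for yy in (3, 7, 11) for xx in range(1, 38, 4)
    ]
    layout.dilution_cells = [(4, 15), (6, 15)]
    layout.elution_wells = {f"E{i + 1}": (39, 2 + 2 * i) for i in range(6)}
    if reagents:
        for name, contents in reagents.items():
            assign_reservoir(layout, name, contents)
    return layout


def assign_reservoir(layout: CartridgeLayout, name: str,
                     contents: dict[str, float], capacity_ul: float = 20.0) -> Reservoir:
    free = getattr(layout, "_free_wells", None)
    if not free:
        raise LayoutCapacityError(
            f"no reservoir well left for reagent {name!r}: all 30 wells assigned"
        )
    group, well, port = free.pop(0)
    res = Reservoir(name=name, group=group, port=port, capacity_ul=capacity_ul,
                    contents=dict(contents))
    layout.reservoirs[name] = res
    return res


@dataclass(frozen=True)
class ThermalProgram:
    """One thermocycling recipe: denature / anneal / extend dwells per cycle.

    Extension dwell scales with product length (15 s per kb).  A hot-start
    activation hold (95 C) is applied once, at the droplet's first visit to
    the denature station.
    """

    anneal_c: float
    cycles: int
    denature_s: float = 5.0
    anneal_s: float = 5.0
    extension_s_per_kb: float = 15.0
    product_len_kb: float = 1.0
    activation_s: float = 0.0

    def __post_init__(self) -> None:
        if not (40.0 <= self.anneal_c <= 72.0):
            raise ValueError(f"anneal temperature {self.anneal_c} outside [40, 72] C")
        if self.cycles < 1:
            raise ValueError("cycles must be >= 1")

    @property
    def extension_s(self) -> float:
        return self.extension_s_per_kb * self.product_len_kb

    @property
    def dwells(self) -> tuple[float, float, float]:
        return (self.denature_s, self.anneal_s, self.extension_s)

    @property
    def period_s(self) -> float:
        """Lane rotation period: the longest phase dwell (shorter phases
        over-dwell so that co-rotating droplets stay lock-stepped)."""
        return max(self.dwells)


@dataclass
class DropletOp:
    kind: str  # DISPENSE | MOVE | MERGE | SPLIT | HOLD | TRASH | ELUTE
    t: float
    duration: float = 0.0
    droplet: str | None = None
    reservoir: str | None = None
    volume_nl: float | None = None
    path: tuple[Cell, ...] | None = None
    merge_exempt: str | None = None  # partner a MOVE may approach
    src: tuple[str, str] | None = None  # MERGE inputs
    out: str | None = None  # MERGE output
    outs: tuple[str, str] | None = None  # SPLIT outputs
    positions: tuple[Cell, Cell] | None = None  # SPLIT output cells
    zone: str | None = None  # HOLD zone / station name
    well: str | None = None  # ELUTE well
    diluent_merge: bool = False
    node: str | None = None  # provenance: plan node / routine tag

    def to_record(self) -> dict:
        return {k: v for k, v in asdict(self).items()
                if v is not None and v is not False}


@dataclass
class Protocol:
    layout: CartridgeLayout
    ops: list[DropletOp]

    def to_jsonl(self) -> str:
        return "\n".join(json.dumps(op.to_record()) for op in self.ops)

    def well_formed(self) -> list[str]:
        """Linear scan: every droplet defined before use and terminated."""
        problems: list[str] = []
        live: set[str] = set()
        for i, op in enumerate(self.ops):
            used: list[str] = []
            if op.kind == "DISPENSE":
                live.add(op.droplet)
                continue
            if op.kind in ("MOVE", "HOLD", "TRASH", "ELUTE"):
                used = [op.droplet]
            elif op.kind == "MERGE":
                used = list(op.src)
            elif op.kind == "SPLIT":
                used = [op.droplet]
            for d in used:
                if d not in live:
                    problems.append(f"op {i}: droplet {d!r} used before definition")
            if op.kind == "MERGE":
                live.difference_update(op.src)
                live.add(op.out)
            elif op.kind == "SPLIT":
                live.discard(op.droplet)
                live.update(op.outs)
            elif op.kind in ("TRASH", "ELUTE"):
                live.discard(op.droplet)
        for d in sorted(live):
            problems.append(f"droplet {d!r} never trashed or eluted")
        return problems


def _chebyshev(a: Cell, b: Cell) -> int:
    return max(abs(a[0] - b[0]), abs(a[1] - b[1]))


def route(
    start: Cell,
    goal: Cell,
    occupancy: Iterable[Cell],
    grid: tuple[int, int] = (32, 16),
    exempt: Iterable[Cell] = (),
) -> tuple[Cell, ...]:
    """Shortest grid path avoiding electrodes within one electrode of any
    other droplet (contamination spacing).  Deterministic row-major
    tie-break.  Raises :class:`RoutingBlockedError` when no path exists.
    """
    w, h = grid
    exempt = set(exempt)
    blocked: set[Cell] = set()
    for oc in occupancy:
        if oc in exempt:
            continue
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                blocked.add((oc[0] + dx, oc[1] + dy))
    blocked.discard(start)
    if goal in blocked:
        raise RoutingBlockedError(f"goal {goal} within contamination spacing of another droplet")
    if not (0 <= start[0] < w and 0 <= start[1] < h) or not (0 <= goal[0] < w and 0 <= goal[1] < h):
        raise ValueError("endpoints must lie on the grid")
    prev: dict[Cell, Cell] = {start: start}
    q: deque[Cell] = deque([start])
    while q:
        cur = q.popleft()
        if cur == goal:
            path = [cur]
            while prev[path[-1]] != path[-1]:
                path.append(prev[path[-1]])
            return tuple(reversed(path))
        x, y = cur
        for nxt in ((x, y - 1), (x - 1, y), (x + 1, y), (x, y + 1)):
            if not (0 <= nxt[0] < w and 0 <= nxt[1] < h):
                continue
            if nxt in blocked or nxt in prev:
                continue
            prev[nxt] = cur
            q.append(nxt)
    raise RoutingBlockedError(f"no collision-free path from {start} to {goal}")


class ProtocolBuilder:
    """Stateful compiler core: tracks the clock, droplet positions and
    parking slots while emitting timed droplet operations."""

    def __init__(self, layout: CartridgeLayout):
        self.layout = layout
        self.ops: list[DropletOp] = []
        self.t = 0.0
        self._n = 0
        self.positions: dict[str, Cell] = {}
        self.volumes: dict[str, float] = {}
        self._parking: dict[Cell, str | None] = {c: None for c in layout.storage_anchors}

    # -- low-level op emission -------------------------------------------
    def _new_id(self) -> str:
        self._n += 1
        return f"d{self._n:04d}"

    def _emit(self, op: DropletOp) -> DropletOp:
        self.ops.append(op)
        return op

    def dispense(self, reservoir: str, volume_nl: float | None = None,
                 node: str | None = None) -> str:
        res = self.layout.reservoirs[reservoir]
        vol = self.layout.unit_volume_nl if volume_nl is None else volume_nl
        d = self._new_id()
        self._emit(DropletOp("DISPENSE", self.t, 1.0, droplet=d, reservoir=reservoir,
                             volume_nl=vol, node=node))
        self.t += 1.0
        self.positions[d] = res.port
        self.volumes[d] = vol
        return d

    def move(self, droplet: str, goal: Cell, *, merge_exempt: str | None = None,
             node: str | None = None) -> None:
        start = self.positions[droplet]
        if start == goal:
            return
        others = {d: p for d, p in self.positions.items() if d != droplet}
        exempt_cells = {others[merge_exempt]} if merge_exempt in others else set()
        path = route(start, goal, others.values(),
                     (self.layout.width, self.layout.height), exempt_cells)
        dur = TRANSIT_S_PER_ELECTRODE * (len(path) - 1)
        self._emit(DropletOp("MOVE", self.t, dur, droplet=droplet, path=path,
                             merge_exempt=merge_exempt, node=node))
        self.t += dur
        self.positions[droplet] = goal
        self._release_parking(start)

    def merge(self, a: str, b: str, *, diluent: bool = False,
              node: str | None = None) -> str:
        """Route ``b`` next to ``a`` and coalesce them at ``a``'s electrode."""
        pa = self.positions[a]
        if _chebyshev(self.positions[b], pa) > 1:
            target = self._adjacent_free(pa, exclude={self.positions[b]})
            self.move(b, target, merge_exempt=a, node=node)
        c = self._new_id()
        self._emit(DropletOp("MERGE", self.t, 1.0, src=(a, b), out=c,
                             diluent_merge=diluent, node=node))
        self.t += 1.0
        self.positions[c] = pa
        self.volumes[c] = self.volumes[a] + self.volumes[b]
        for d in (a, b):
            self._release_parking(self.positions[d])
            del self.positions[d], self.volumes[d]
        return c

    def split(self, c: str, node: str | None = None) -> tuple[str, str]:
        pc = self.positions[c]
        p2 = self._adjacent_free(pc)
        a, b = self._new_id(), self._new_id()
        self._emit(DropletOp("SPLIT", self.t, 1.0, droplet=c, outs=(a, b),
                             positions=(pc, p2), node=node))
        self.t += 1.0
        half = self.volumes[c] / 2.0
        del self.positions[c]
        vol = self.volumes.pop(c)
        self.positions[a], self.positions[b] = pc, p2
        self.volumes[a] = self.volumes[b] = half
        return a, b

    def hold(self, droplet: str, zone: str, seconds: float,
             node: str | None = None, at: float | None = None) -> None:
        t0 = self.t if at is None else at
        self._emit(DropletOp("HOLD", t0, seconds, droplet=droplet, zone=zone, node=node))
        if at is None:
            self.t += seconds

    def trash(self, droplet: str, node: str | None = None) -> None:
        self.move(droplet, self._near_waste(), node=node)
        self._emit(DropletOp("TRASH", self.t, 1.0, droplet=droplet, node=node))
        self.t += 1.0
        self._release_parking(self.positions[droplet])
        del self.positions[droplet], self.volumes[droplet]

    def elute(self, droplet: str, well: str, node: str | None = None) -> None:
        self.move(droplet, self.layout.elution_wells[well], node=node)
        self._emit(DropletOp("ELUTE", self.t, 1.0, droplet=droplet, well=well, node=node))
        self.t += 1.0
        self._release_parking(self.positions[droplet])
        del self.positions[droplet], self.volumes[droplet]

    # -- placement helpers ------------------------------------------------
    def _release_parking(self, cell: Cell) -> None:
        if cell in self._parking:
            self._parking[cell] = None

    def park(self, droplet: str, node: str | None = None) -> Cell:
        for cell, occ in self._parking.items():
            if occ is not None and occ not in self.positions:
                self._parking[cell] = occ = None  # stale registration
            if occ is None and all(
                _chebyshev(cell, p) >= 2
                for d, p in self.positions.items() if d != droplet
            ):
                self.move(droplet, cell, node=node)
                self._parking[cell] = droplet
                return cell
        raise LayoutCapacityError("storage area full: no free parking anchor")

    def _adjacent_free(self, cell: Cell, exclude: set[Cell] = frozenset()) -> Cell:
        for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            cand = (cell[0] + dx, cell[1] + dy)
            if not self.layout.in_grid(cand) or cand in exclude:
                continue
            if all(_chebyshev(cand, p) >= 2 or p == cell
                   for p in self.positions.values()):
                return cand
        raise RoutingBlockedError(f"no free electrode adjacent to {cell}")

    def _near_waste(self) -> Cell:
        wx, wy = self.layout.waste_cell
        return (wx, wy)

    # -- routines ---------------------------------------------------------
    def serial_dilution(self, droplet: str, k: int, diluent_reservoir: str,
                        node: str | None = None) -> str:
        """k iterations of merge(+1 unit diluent) / split / trash-one-half.

        The droplet's volume is unchanged; its concentration falls 2-fold
        per step (recorded in the simulator's dilution ledger).
        """
        if k < 0:
            raise ValueError("k must be >= 0")
        res = self.layout.reservoirs[diluent_reservoir]
        need = k * self.layout.unit_volume_nl
        if need > res.usable_nl:
            raise LayoutCapacityError(
                f"dilution needs {need:.0f} nl of {diluent_reservoir!r}; only "
                f"{res.usable_nl:.0f} nl usable (dead volume {res.dead_volume_frac:.0%})"
            )
        tag = node or f"dilution_k{k}"
        work = self.layout.dilution_cells[0]
        if k and self.positions[droplet] != work:
            self.move(droplet, work, node=tag)
        for _ in range(k):
            dil = self.dispense(diluent_reservoir, node=tag)
            merged = self.merge(droplet, dil, diluent=True, node=tag)
            keep, spill = self.split(merged, node=tag)
            self.trash(spill, node=tag)
            droplet = keep
        return droplet

    def thermocycle(self, droplets: list[str], program: ThermalProgram,
                    node: str | None = None) -> None:
        """Run droplets around the PCR ring, phase-shifted.

        All co-rotating droplets advance one station per rotation period;
        the period is the longest phase dwell, so shorter phases over-dwell.
        With up to three droplets and four ring stations there is always a
        free station to rotate into, so occupancy stays pairwise distinct.
        """
        stations = self.layout.pcr_stations
        n_temp = sum(1 for s in stations if s.temp_c is not None)
        if len(droplets) > n_temp:
            raise LayoutCapacityError(
                f"{len(droplets)} droplets exceed the {n_temp} temperature zones of the lane"
            )
        period = program.period_s
        # Entry: droplet i starts at station i (phase-shifted).
        at: dict[str, int] = {}
        for i, d in enumerate(droplets):
            self.move(d, stations[i].anchor, node=node)
            at[d] = i
        occupied = {i: d for d, i in at.items()}
        cycles_done = {d: 0 for d in droplets}
        # PCR state: index of the next phase station (0=denature) expected.
        expect = {d: 0 for d in droplets}
        activated = {d: program.activation_s <= 0 for d in droplets}
        free = next(i for i in range(len(stations)) if i not in occupied)

        def hold_all() -> None:
            t0 = self.t
            dur = period
            for d, i in at.items():
                st = stations[i]
                extra = 0.0
                if st.name == "pcr_95" and not activated[d]:
                    extra = program.activation_s
                    activated[d] = True
                dur = max(dur, period + extra)
            for d, i in at.items():
                st = stations[i]
                self.hold(d, st.name, dur, node=node, at=t0)
                if st.temp_c is not None:
                    phase = {95.0: 0, 62.0: 1, 72.0: 2}.get(st.temp_c)
                    if phase == expect[d]:
                        expect[d] += 1
                        if expect[d] == 3:
                            expect[d] = 0
                            cycles_done[d] += 1
            self.t = t0 + dur

        hold_all()
        while any(cycles_done[d] < program.cycles for d in droplets):
            # rotate: fill the free station from behind, cascading.
            ns = len(stations)
            for step in range(1, ns):
                src = (free - step) % ns
                if src in occupied:
                    d = occupied.pop(src)
                    dst = (src + 1) % ns
                    self.move(d, stations[dst].anchor, node=node)
                    occupied[dst] = d
                    at[d] = dst
            free = (free - (ns - 1)) % ns
            hold_all()
        for d in droplets:
            self.park(d, node=node)

    def protocol(self) -> Protocol:
        return Protocol(self.layout, self.ops)


# ---------------------------------------------------------------------------
# Spec-level convenience wrappers


def serial_dilution_routine(k: int, layout: CartridgeLayout | None = None,
                            contents: dict[str, float] | None = None,
                            diluent_reservoir: str = "diluent") -> Protocol:
    """A standalone protocol: dispense one sample droplet and dilute it 2-fold
    ``k`` times (k=6 gives the 64x inter-stage dilution)."""
    layout = layout or default_layout({
        "sample": contents or {"marker": 1.0},
        diluent_reservoir: {},
    })
    b = ProtocolBuilder(layout)
    d = b.dispense("sample", node="sample")
    d = b.serial_dilution(d, k, diluent_reservoir)
    b.elute(d, next(iter(layout.elution_wells)), node="diluted_sample")
    return b.protocol()


def schedule_pcr_lane(n_droplets: int, program: ThermalProgram,
                      layout: CartridgeLayout | None = None) -> Protocol:
    """A standalone lane schedule for 1-3 blank droplets (rotation demo)."""
    layout = layout or default_layout({"mix": {}})
    b = ProtocolBuilder(layout)
    ds = []
    for i in range(n_droplets):
        d = b.dispense("mix", node=f"lane{i}")
        b.park(d)
        ds.append(d)
    b.thermocycle(ds, program, node="lane")
    for d in ds:
        b.trash(d)
    return b.protocol()


def _program_anneal(primers: Iterable[str], offset: float = 0.0) -> float:
    tms = []
    for p in primers:
        try:
            tms.append(tm_nn(p, DEFAULT_TM_CONFIG))
        except (UnsupportedBaseError, ValueError):
            continue
    t = (min(tms) if tms else 60.0) + offset
    return min(72.0, max(40.0, t))


def compile_protocol(plan: PopPlan | ConstructionPlan,
                     layout: CartridgeLayout | None = None) -> Protocol:
    """Compile an assembly plan into a timed droplet protocol."""
    if isinstance(plan, PopPlan):
        return _compile_pop(plan, layout)
    if isinstance(plan, ConstructionPlan):
        return _compile_mcad(plan, layout)
    raise TypeError(f"cannot compile {type(plan).__name__}")


def _compile_pop(plan: PopPlan, layout: CartridgeLayout | None) -> Protocol:
    if layout is None:
        reagents: dict[str, dict[str, float]] = {
            "core_template": {str(plan.core): TEMPLATE_COPIES_PER_DROPLET},
        }
        for stage in plan.stages:
            mix: dict[str, float] = {}
            for o in stage.oligos:
                mix[str(o.sequence)] = PRIMER_COPIES_PER_DROPLET
            reagents[f"stage{stage.index}_primers"] = mix
        reagents["diluent"] = {}
        layout = default_layout(reagents)

    b = ProtocolBuilder(layout)
    if not plan.stages:
        return b.protocol()
    current = b.dispense("core_template", node="core")
    b.park(current, node="core")
    kb = len(plan.target) / 1000.0
    construct_len = len(plan.core)
    for stage in plan.stages:
        tag = f"pop_stage_{stage.index}"
        if stage.index > 1:
            half, spill = b.split(current, node=tag)
            b.trash(spill, node=tag)
            steps = stage.pre_dilution_fold.bit_length() - 1
            current = b.serial_dilution(half, steps, "diluent", node=tag)
        prm = b.dispense(f"stage{stage.index}_primers", node=tag)
        current = b.merge(current, prm, node=tag)
        construct_len += stage.added_length
        program = ThermalProgram(
            anneal_c=min(72.0, max(40.0, stage.anneal_temp)),
            cycles=stage.cycles,
            product_len_kb=construct_len / 1000.0,
            activation_s=600.0 if stage.index == 1 else 0.0,
        )
        b.thermocycle([current], program, node=tag)
    b.elute(current, next(iter(layout.elution_wells)), node="final_product")
    return b.protocol()


def _mcad_reagents(plan: ConstructionPlan) -> dict[str, dict[str, float]]:
    reagents: dict[str, dict[str, float]] = {}
    for node in plan.stage_nodes("template"):
        reagents[f"tpl::{node.id}"] = {str(node.sequence): TEMPLATE_COPIES_PER_DROPLET}
    # primer-pair mixes per PCR / final node, deduplicated by pair sequences
    pair_well: dict[tuple[str, str], str] = {}
    for node in plan.stage_nodes("pcr_product") + plan.stage_nodes("final_target"):
        primers = tuple(
            str(plan.nodes[i].sequence) for i in node.inputs
            if plan.nodes[i].kind == "primer"
        )
        if primers not in pair_well:
            name = f"mix::{len(pair_well)}"
            pair_well[primers] = name
            reagents[name] = {p: PRIMER_COPIES_PER_DROPLET for p in primers}
    reagents["diluent"] = {}
    plan._pair_well = pair_well  # type: ignore[attr-defined]
    return reagents


def _compile_mcad(plan: ConstructionPlan, layout: CartridgeLayout | None) -> Protocol:
    if layout is None:
        layout = default_layout(_mcad_reagents(plan))
    pair_well: dict[tuple[str, str], str] = getattr(plan, "_pair_well")
    b = ProtocolBuilder(layout)

    reaction_nodes = [n for n in plan.stage_nodes()
                      if n.kind in ("pcr_product", "join_intermediate", "final_target")]
    demand: dict[str, int] = {}
    for node in reaction_nodes:
        for dep in node.inputs:
            if plan.nodes[dep].kind in ("pcr_product", "join_intermediate"):
                demand[dep] = demand.get(dep, 0) + 1

    bank: dict[str, list[str]] = {}

    def take(node_id: str, tag: str) -> str:
        pool = bank[node_id]
        if not pool:
            raise LayoutCapacityError(f"no droplet left for node {node_id}")
        if len(pool) == 1 and demand[node_id] > 1:
            # replicate: top up with buffer and split into two unit droplets
            d = pool.pop()
            buf = b.dispense("diluent", node=f"replicate::{node_id}")
            m = b.merge(d, buf, node=f"replicate::{node_id}")
            h1, h2 = b.split(m, node=f"replicate::{node_id}")
            b.park(h1, node=f"replicate::{node_id}")
            b.park(h2, node=f"replicate::{node_id}")
            pool.extend([h1, h2])
        demand[node_id] -= 1
        return pool.pop()

    def primers_of(node) -> tuple[str, str]:
        return tuple(str(plan.nodes[i].sequence) for i in node.inputs
                     if plan.nodes[i].kind == "primer")

    def product_bank(node, rxn: str) -> None:
        h1, h2 = b.split(rxn, node=node.id)
        b.park(h1, node=node.id)
        if demand.get(node.id, 0) >= 2:
            b.park(h2, node=node.id)
            bank[node.id] = [h1, h2]
        else:
            b.trash(h2, node=f"surplus::{node.id}")
            bank[node.id] = [h1]

    def finish_inputs(node) -> None:
        for dep in node.inputs:
            if dep in demand and demand[dep] == 0 and bank.get(dep):
                for d in bank.pop(dep):
                    b.trash(d, node=f"surplus::{dep}")

    elution_wells = list(layout.elution_wells)
    n_eluted = 0
    first_entry = True
    for node in reaction_nodes:
        tag = node.id
        kb = len(node.sequence) / 1000.0
        if node.kind == "pcr_product":
            tpl_node = next(i for i in node.inputs if plan.nodes[i].kind == "template")
            tpl = b.dispense(f"tpl::{tpl_node}", node=tag)
            b.park(tpl, node=tag)
            prm = b.dispense(pair_well[primers_of(node)], node=tag)
            rxn = b.merge(tpl, prm, node=tag)
            program = ThermalProgram(
                anneal_c=_program_anneal(primers_of(node), ANNEAL_TM_OFFSET),
                cycles=AMPLIFICATION_CYCLES, product_len_kb=kb,
                activation_s=600.0 if first_entry else 0.0)
            b.thermocycle([rxn], program, node=tag)
            product_bank(node, rxn)
        elif node.kind == "join_intermediate":
            da = take(node.inputs[0], tag)
            db = take(node.inputs[1], tag)
            rxn = b.merge(da, db, node=tag)
            program = ThermalProgram(anneal_c=62.0, cycles=JOIN_CYCLES,
                                     product_len_kb=kb)
            b.thermocycle([rxn], program, node=tag)
            product_bank(node, rxn)
        else:  # final_target
            assembly = next(i for i in node.inputs
                            if plan.nodes[i].kind in ("pcr_product", "join_intermediate"))
            d = take(assembly, tag)
            prm = b.dispense(pair_well[primers_of(node)], node=tag)
            rxn = b.merge(d, prm, node=tag)
            program = ThermalProgram(
                anneal_c=_program_anneal(primers_of(node), ANNEAL_TM_OFFSET),
                cycles=AMPLIFICATION_CYCLES, product_len_kb=kb)
            b.thermocycle([rxn], program, node=tag)
            well = elution_wells[n_eluted % len(elution_wells)]
            n_eluted += 1
            b.elute(rxn, well, node=tag)
        first_entry = False
        finish_inputs(node)

    for node_id, pool in list(bank.items()):
        for d in pool:
            b.trash(d, node=f"surplus::{node_id}")
    return b.protocol()
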