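"""Virtual execution of droplet protocols.

The simulator replays a :class:`~dmfsynth.dmf_protocol.Protocol` op by op,
tracking droplet positions, volumes and molecular composition, and enforces
the cartridge safety contracts: defined-before-use, grid-adjacent paths,
contamination spacing, minimum split volume and reservoir capacity.

Chemistry model
---------------
Composition maps DNA species (sequence strings) to molecule counts.  Values
stored as ``int`` are discrete copies (split by a seeded binomial draw —
essential at single-molecule dilutions); ``float`` values are bulk amounts
(primers, buffer) and split exactly in half.  A PCR cycle is triggered every
time a droplet completes a denature -> anneal -> extend station sequence;
each cycle amplifies primed amplicons geometrically with a per-cycle
efficiency, capped by primer availability, and fuses overlapping fragment
pairs (the overlap-extension join mechanism).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .seqcore import revcomp, MIN_ANNEAL_LEN
from .dmf_protocol import (
    CartridgeLayout,
    Protocol,
    ThermalProgram,
    Cell,
)

__all__ = [
    "SimulationFault",
    "DropletState",
    "ElutedDroplet",
    "SimReport",
    "execute",
    "pcr_update",
    "predict_amplicon",
    "volume_ledger",
    "PCR_EFFICIENCY",
    "AMPLIFIED_MIN_COPIES",
    "PRIMER_MAX_LEN",
]

#: Default per-cycle amplification efficiency.
PCR_EFFICIENCY = 0.9
#: Copies regarded as a detectable (sequencable) amplification product.
AMPLIFIED_MIN_COPIES = 1e9
#: Species up to this length can act as primers; longer ones are templates.
PRIMER_MAX_LEN = 120


class SimulationFault(RuntimeError):
    """A protocol op breached a cartridge contract."""

    def __init__(self, op_index: int, message: str):
        super().__init__(f"op {op_index}: {message}")
        self.op_index = op_index


@dataclass
class DropletState:
    id: str
    position: Cell
    volume_nl: float
    composition: dict[str, float] = field(default_factory=dict)
    temperature_c: float = 25.0
    fold_dilution: float = 1.0
    #: PCR phase machine: next expected phase (0 denature, 1 anneal, 2 extend)
    pcr_phase: int = 0


@dataclass
class ElutedDroplet:
    droplet: str
    well: str
    volume_nl: float
    composition: dict[str, float]
    dominant_product: str | None
    amplified: bool
    fold_dilution: float


@dataclass
class SimReport:
    eluted: list[ElutedDroplet]
    final_droplets: dict[str, DropletState]
    violations: list[str]
    ledger: dict[str, float]
    reservoir_use_nl: dict[str, float]
    dilution_ledger: dict[str, float]
    cycles_run: dict[str, int]

    def to_json(self) -> str:
        def enc(o):
            if isinstance(o, (DropletState, ElutedDroplet)):
                return o.__dict__
            raise TypeError(type(o))
        return json.dumps(self.__dict__, default=enc, sort_keys=True)


def _chebyshev(a: Cell, b: Cell) -> int:
    return max(abs(a[0] - b[0]), abs(a[1] - b[1]))


@lru_cache(maxsize=16384)
def predict_amplicon(template: str, fwd: str, rev: str,
                     min_anneal: int = MIN_ANNEAL_LEN) -> str | None:
    """In-silico PCR: product of a primer pair on a template, or None.

    The longest 3' suffix of each primer with an exact match on the template
    (top strand for the forward primer, bottom strand for the reverse)
    defines the amplicon; primer tails (including substitution edits) are
    incorporated into the product ends.
    """
    p = la = -1
    for n in range(min(len(fwd), len(template)), min_anneal - 1, -1):
        p = template.find(fwd[-n:])
        if p >= 0:
            la = n
            break
    if p < 0:
        return None
    trc = revcomp(template)
    q = lr = -1
    for n in range(min(len(rev), len(template)), min_anneal - 1, -1):
        q = trc.find(rev[-n:])
        if q >= 0:
            lr = n
            break
    if q < 0:
        return None
    s = len(template) - q - lr  # top-strand start of the reverse anneal site
    if s < p + la:
        return None
    return fwd + template[p + la: s] + revcomp(rev)


@lru_cache(maxsize=16384)
def _overlap(left: str, right: str, min_anneal: int = MIN_ANNEAL_LEN) -> int:
    limit = min(len(left), len(right), PRIMER_MAX_LEN)
    for n in range(limit, min_anneal - 1, -1):
        if left[-n:] == right[:n]:
            return n
    return 0


def pcr_update(composition: dict[str, float], program: ThermalProgram | None = None,
               efficiency: float = PCR_EFFICIENCY, cycles: int | None = None,
               min_anneal: int = MIN_ANNEAL_LEN) -> dict[str, float]:
    """Apply thermocycles to a droplet composition; returns a new dict.

    Per cycle, for every primer pair with an exact amplicon on a present
    template, product copies grow by ``efficiency x (template + product)``,
    consuming one molecule of each primer per new product (so totals cap out
    at the available primer amount).  Species pairs whose ends overlap fuse
    into join products, consuming the fragments.  Zero-copy species never
    amplify.
    """
    if not 0 < efficiency <= 1:
        raise ValueError("efficiency must be in (0, 1]")
    n_cycles = cycles if cycles is not None else (program.cycles if program else 1)
    comp = dict(composition)
    for _ in range(n_cycles):
        # synchronous update: every reaction seeds from the cycle-entry counts
        start = dict(comp)
        primers = [s for s, c in start.items() if len(s) <= PRIMER_MAX_LEN and c > 0]
        templates = [s for s, c in start.items() if len(s) > PRIMER_MAX_LEN and c > 0]
        for fwd in primers:
            for rev in primers:
                for tpl in templates:
                    product = predict_amplicon(tpl, fwd, rev, min_anneal)
                    if product is None:
                        continue
                    new = efficiency * start[tpl]
                    cost = 2.0 if fwd == rev else 1.0
                    # primer cap: one molecule of each primer per new product
                    new = min(new, max(comp.get(fwd, 0), 0) / cost,
                              max(comp.get(rev, 0), 0) / cost)
                    if new <= 0:
                        continue
                    comp[product] = comp.get(product, 0) + new
                    comp[fwd] = comp.get(fwd, 0) - new * (2.0 if fwd == rev else 1.0)
                    if rev != fwd:
                        comp[rev] = comp.get(rev, 0) - new
        # overlap-extension fusion of fragment pairs (binary joins)
        for i, a in enumerate(templates):
            for bz in templates[i + 1:]:
                for left, right in ((a, bz), (bz, a)):
                    k = _overlap(left, right, min_anneal)
                    if k:
                        fused = left + right[k:]
                        new = efficiency * min(start[left], start[right],
                                               max(comp.get(left, 0), 0),
                                               max(comp.get(right, 0), 0))
                        if new <= 0:
                            continue
                        comp[fused] = comp.get(fused, 0) + new
                        comp[left] = comp.get(left, 0) - new
                        comp[right] = comp.get(right, 0) - new
                        break
    return comp


def dominant_product(composition: dict[str, float]) -> str | None:
    """The template-length species with the most copies (deterministic)."""
    cands = [(c, s) for s, c in composition.items()
             if len(s) > PRIMER_MAX_LEN and c > 0]
    if not cands:
        return None
    cands.sort(key=lambda cs: (-cs[0], cs[1]))
    return cands[0][1]


def _split_composition(comp: dict[str, float], rng: np.random.Generator
                       ) -> tuple[dict[str, float], dict[str, float]]:
    a: dict[str, float] = {}
    b: dict[str, float] = {}
    for s, c in comp.items():
        if isinstance(c, (int, np.integer)):
            ca = int(rng.binomial(int(c), 0.5))
            a[s], b[s] = ca, int(c) - ca
        else:
            a[s] = b[s] = c / 2.0
    return a, b


def execute(protocol: Protocol, layout: CartridgeLayout | None = None,
            seed: int = 0, *, efficiency: float = PCR_EFFICIENCY,
            strict: bool = True, stochastic_split: bool = True) -> SimReport:
    """Execute a protocol on the virtual cartridge.

    Deterministic given ``seed``.  With ``strict`` (default) any contract
    breach raises :class:`SimulationFault` naming the op; otherwise breaches
    are recorded in the report's violation list.  ``stochastic_split=False``
    forces exact halving of discrete copies too (ideal bulk partitioning).
    """
    layout = layout or protocol.layout
    rng = np.random.default_rng(seed)
    droplets: dict[str, DropletState] = {}
    violations: list[str] = []
    reservoir_use: dict[str, float] = {r: 0.0 for r in layout.reservoirs}
    dispensed = trashed = eluted_vol = 0.0
    eluted: list[ElutedDroplet] = []
    dilution_ledger: dict[str, float] = {}
    cycles_run: dict[str, int] = {}
    station_temp = {s.name: s.temp_c for s in layout.pcr_stations}

    def fault(i: int, msg: str) -> None:
        if strict:
            raise SimulationFault(i, msg)
        violations.append(f"op {i}: {msg}")

    def need(i: int, d: str) -> DropletState:
        if d not in droplets:
            raise SimulationFault(i, f"unknown droplet {d!r}")
        return droplets[d]

    ops = sorted(enumerate(protocol.ops), key=lambda iv: (iv[1].t, iv[0]))
    for i, op in ops:
        if op.kind == "DISPENSE":
            res = layout.reservoirs.get(op.reservoir)
            if res is None:
                raise SimulationFault(i, f"unknown reservoir {op.reservoir!r}")
            vol = op.volume_nl or layout.unit_volume_nl
            reservoir_use[op.reservoir] += vol
            if reservoir_use[op.reservoir] > res.usable_nl + 1e-9:
                fault(i, f"reservoir {op.reservoir!r} over-drawn "
                         f"({reservoir_use[op.reservoir]:.0f} nl > "
                         f"{res.usable_nl:.0f} nl usable)")
            scale = vol / layout.unit_volume_nl
            comp: dict[str, float] = {}
            for s, c in res.contents.items():
                comp[s] = int(round(c * scale)) if isinstance(c, int) else c * scale
            for other in droplets.values():
                if _chebyshev(other.position, res.port) <= 1:
                    fault(i, f"dispense at {res.port} within contamination "
                             f"spacing of droplet {other.id}")
            droplets[op.droplet] = DropletState(op.droplet, res.port, vol, comp)
            dispensed += vol
        elif op.kind == "MOVE":
            d = need(i, op.droplet)
            path = op.path
            if path[0] != d.position:
                fault(i, f"path starts at {path[0]}, droplet at {d.position}")
            for a, b in zip(path, path[1:]):
                if abs(a[0] - b[0]) + abs(a[1] - b[1]) != 1:
                    fault(i, f"path step {a} -> {b} not grid-adjacent")
                if not layout.in_grid(b):
                    fault(i, f"path leaves the grid at {b}")
            for cell in path[1:]:
                for other in droplets.values():
                    if other.id in (op.droplet, op.merge_exempt):
                        continue
                    if _chebyshev(cell, other.position) <= 1:
                        fault(i, f"droplet {op.droplet} at {cell} within one "
                                 f"electrode of droplet {other.id}")
            d.position = path[-1]
        elif op.kind == "MERGE":
            da, db = need(i, op.src[0]), need(i, op.src[1])
            if _chebyshev(da.position, db.position) > 1:
                fault(i, f"merge partners at {da.position} / {db.position} not in contact")
            comp = dict(da.composition)
            for s, c in db.composition.items():
                comp[s] = comp.get(s, 0) + c
            fold = da.fold_dilution
            if op.diluent_merge:
                fold *= (da.volume_nl + db.volume_nl) / da.volume_nl
            droplets[op.out] = DropletState(
                op.out, da.position, da.volume_nl + db.volume_nl, comp,
                fold_dilution=fold, pcr_phase=da.pcr_phase)
            dilution_ledger[op.out] = fold
            del droplets[op.src[0]], droplets[op.src[1]]
        elif op.kind == "SPLIT":
            d = need(i, op.droplet)
            if d.volume_nl < 2 * layout.unit_volume_nl - 1e-9:
                fault(i, f"cannot split {d.volume_nl:.0f} nl: below two unit volumes")
            if stochastic_split:
                ca, cb = _split_composition(d.composition, rng)
            else:
                ca, cb = {}, {}
                for s, c in d.composition.items():
                    ca[s] = cb[s] = c / 2.0
            p1, p2 = op.positions
            half = d.volume_nl / 2.0
            for out, comp_h, pos in ((op.outs[0], ca, p1), (op.outs[1], cb, p2)):
                droplets[out] = DropletState(out, pos, half, comp_h,
                                             fold_dilution=d.fold_dilution,
                                             pcr_phase=d.pcr_phase)
                dilution_ledger[out] = d.fold_dilution
            del droplets[op.droplet]
        elif op.kind == "HOLD":
            d = need(i, op.droplet)
            temp = station_temp.get(op.zone, None) if op.zone in station_temp else None
            if temp is not None:
                d.temperature_c = temp
                phase = {95.0: 0, 62.0: 1, 72.0: 2}.get(temp)
                if phase == d.pcr_phase:
                    d.pcr_phase += 1
                    if d.pcr_phase == 3:
                        d.pcr_phase = 0
                        d.composition = pcr_update(
                            d.composition, efficiency=efficiency, cycles=1)
                        cycles_run[d.id] = cycles_run.get(d.id, 0) + 1
        elif op.kind == "TRASH":
            d = need(i, op.droplet)
            trashed += d.volume_nl
            del droplets[op.droplet]
        elif op.kind == "ELUTE":
            d = need(i, op.droplet)
            dom = dominant_product(d.composition)
            eluted.append(ElutedDroplet(
                d.id, op.well, d.volume_nl, dict(d.composition), dom,
                bool(dom and d.composition[dom] >= AMPLIFIED_MIN_COPIES),
                d.fold_dilution))
            eluted_vol += d.volume_nl
            del droplets[op.droplet]
        else:
            raise SimulationFault(i, f"unknown op kind {op.kind!r}")

    live = sum(d.volume_nl for d in droplets.values())
    ledger = {
        "dispensed_nl": dispensed,
        "live_nl": live,
        "trashed_nl": trashed,
        "eluted_nl": eluted_vol,
        "balance_nl": dispensed - (live + trashed + eluted_vol),
    }
    return SimReport(eluted=eluted, final_droplets=droplets,
                     violations=violations, ledger=ledger,
                     reservoir_use_nl=reservoir_use,
                     dilution_ledger=dilution_ledger, cycles_run=cycles_run)


def volume_ledger(report: SimReport, tol_nl: float = 1e-9) -> dict:
    """Conservation check: dispensed = live + trashed + eluted."""
    balanced = abs(report.ledger["balance_nl"]) <= tol_nl
    return {"balanced": balanced, **report.ledger}
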