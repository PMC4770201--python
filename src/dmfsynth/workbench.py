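"""Fixtures, document I/O and serialization.

The worked examples in this package run on seeded synthetic fixtures that
emulate the shape of the two demonstration libraries: a ~780 nt reporter-like
target with a randomized 14-N ribosome-binding-site window, assembled
inside-out from a 140 nt core in four stages (nine building blocks), and an
Azurin-like combinatorial library of 3 positions x 3 variants (27-combination
space, 24 selected targets, 12 deduplicated building-block PCRs, 4 fragments
per target).  Fixture sequences are random at ~50% GC with anneal windows
pre-screened against the 60 C rule, so plans are satisfiable by
construction; they are byte-identical for identical (kind, seed, params).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .seqcore import NucSequence
from .pop_planner import PopConstraints, PopPlan, plan_pop
from .mcad_planner import (
    FragmentSpec,
    LibrarySpec,
    PositionSpec,
    VariantSpec,
)

__all__ = [
    "PopFixture",
    "make_pop_fixture",
    "make_azurin_fixture",
    "read_fasta",
    "write_fasta",
    "read_genbank_sequence",
    "plan_document",
    "load_plan_document",
    "oligo_order_sheet",
    "SCHEMA_VERSION",
]

SCHEMA_VERSION = "1"

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _random_seq(rng: np.random.Generator, n: int) -> NucSequence:
    return NucSequence("".join(_BASES[rng.integers(0, 4, size=n)].astype("U1")))


@dataclass(frozen=True)
class PopFixture:
    target: NucSequence
    core_interval: tuple[int, int]
    barcode_interval: tuple[int, int]
    constraints: PopConstraints
    seed: int

    def plan(self) -> PopPlan:
        return plan_pop(self.target, self.core_interval, self.constraints)


def make_pop_fixture(seed: int = 1, target_len: int = 780, core_len: int = 140,
                     barcode_len: int = 14) -> PopFixture:
    """A reporter-like inside-out assembly target.

    ``target_len`` nt total with a centered ``core_len`` nt core holding the
    randomized barcode window (``N`` x ``barcode_len``) at its middle, so no
    extension oligo ever anneals over undetermined bases.  Flanks of 320 nt
    per side with the default 160 nt stage budget give exactly 4 two-sided
    stages = 9 building blocks.  Candidate sequences whose anneal windows
    cannot reach 60 C inside the oligo budget are rejected and redrawn, so
    the fixture is deterministic per seed.
    """
    constraints = PopConstraints()
    ss = np.random.SeedSequence([seed, 0x70B])
    for attempt in range(64):
        rng = np.random.default_rng(ss.spawn(1)[0])
        seq = list(_random_seq(rng, target_len))
        a = (target_len - core_len) // 2
        core_interval = (a, a + core_len)
        mid = target_len // 2 - barcode_len // 2
        seq[mid: mid + barcode_len] = "N" * barcode_len
        target = NucSequence("".join(seq))
        try:
            plan = plan_pop(target, core_interval, constraints)
        except Exception:
            continue
        expected_stages = -(-(a) // (constraints.stage_extension_budget // 2))
        if len(plan.stages) == expected_stages and plan.building_blocks == 1 + 2 * expected_stages:
            return PopFixture(target, core_interval, (mid, mid + barcode_len),
                              constraints, seed)
    raise RuntimeError(f"no viable target found for seed {seed}")  # pragma: no cover


def make_azurin_fixture(seed: int = 1) -> LibrarySpec:
    """An Azurin-like combinatorial library specification.

    Three positions, three variants each (27-combination space); the outer
    positions are single PCR fragments, the middle position is split into
    sub-fragments a + b, so each target is assembled from 4 fragments and
    the deduplicated stage-1 building blocks number 3 x 4 = 12.  Variants
    come from three template sequences that differ only inside interior
    variant windows; junction overlap windows (30 nt) are shared by all
    templates, mirroring fragment reuse across targets.  24 of the 27
    combinations are selected, as in a rationally designed subset.
    """
    ss = np.random.SeedSequence([seed, 0xA2])
    length = 660
    # fragment intervals on the construct: P1, P2a, P2b, P3 with 30 nt overlaps
    ivals = [(0, 200), (170, 350), (320, 490), (460, 660)]
    overlaps = [(170, 200), (320, 350), (460, 490)]
    marks = [(80, 90), (230, 240), (400, 410), (560, 570)]  # interior windows
    for attempt in range(64):
        rng = np.random.default_rng(ss.spawn(1)[0])
        backbone = _random_seq(rng, length)
        if not _junctions_ok(backbone, overlaps):
            continue
        templates: dict[str, NucSequence] = {}
        for t in range(3):
            seq = list(backbone)
            for (m0, m1) in marks:
                window = _random_seq(rng, m1 - m0)
                seq[m0:m1] = window
            templates[f"pT{t}"] = NucSequence("".join(seq))
        # variant windows must be distinct across templates
        if any(
            templates[f"pT{i}"][m0:m1] == templates[f"pT{j}"][m0:m1]
            for (m0, m1) in marks for i in range(3) for j in range(i + 1, 3)
        ):
            continue
        positions = [
            PositionSpec("P1", tuple(
                VariantSpec(f"p1v{t}", (FragmentSpec(f"pT{t}", ivals[0]),))
                for t in range(3))),
            PositionSpec("P2", tuple(
                VariantSpec(f"p2v{t}", (FragmentSpec(f"pT{t}", ivals[1]),
                                        FragmentSpec(f"pT{t}", ivals[2])))
                for t in range(3))),
            PositionSpec("P3", tuple(
                VariantSpec(f"p3v{t}", (FragmentSpec(f"pT{t}", ivals[3]),))
                for t in range(3))),
        ]
        import itertools
        space = list(itertools.product(range(3), repeat=3))
        selected = [c for c in space if len(set(c)) != 1][:24]
        ext_f = NucSequence(backbone[:25])
        from .seqcore import revcomp
        ext_r = revcomp(backbone[length - 25:])
        return LibrarySpec(positions=positions, templates=templates,
                           selected_targets=selected,
                           external_primers=(ext_f, ext_r))
    raise RuntimeError(f"no viable library fixture for seed {seed}")  # pragma: no cover


def _junctions_ok(backbone: NucSequence, overlaps) -> bool:
    from .seqcore import tm_nn, MIN_ANNEAL_TM
    try:
        return all(tm_nn(backbone[a:b]) >= MIN_ANNEAL_TM for a, b in overlaps)
    except ValueError:  # pragma: no cover
        return False


# ---------------------------------------------------------------------------
# Sequence and document I/O


def read_fasta(path) -> dict[str, NucSequence]:
    return {rec.id: NucSequence(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, seqs: dict[str, str]) -> None:
    records = [SeqRecord(Seq(str(s)), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_genbank_sequence(path) -> dict[str, NucSequence]:
    """Extract sequences from GenBank records (features are ignored)."""
    out = {}
    for rec in SeqIO.parse(str(path), "genbank"):
        if rec.features:
            import logging
            logging.getLogger(__name__).info(
                "record %s: %d features ignored (sequence-only import)",
                rec.id, len(rec.features))
        out[rec.id] = NucSequence(str(rec.seq))
    return out


def oligo_order_sheet(plan: PopPlan) -> dict[str, str]:
    """Oligo set of a plan as a name -> sequence mapping (FASTA-ready)."""
    sheet = {"core_template": str(plan.core)}
    for oligo in plan.oligos:
        sheet[oligo.id] = str(oligo.sequence)
    return sheet


def plan_document(plan: PopPlan, provenance: dict | None = None) -> dict:
    """Serializable plan document (schema-versioned)."""
    return {
        "schema_version": SCHEMA_VERSION,
        "kind": "pop",
        "target": str(plan.target),
        "core_interval": list(plan.core_interval),
        "constraints": {
            "max_oligo_len": plan.constraints.max_oligo_len,
            "min_anneal_tm": plan.constraints.min_anneal_tm,
            "min_anneal_len": plan.constraints.min_anneal_len,
            "stage_extension_budget": plan.constraints.stage_extension_budget,
        },
        "stages": [
            {
                "index": s.index,
                "anneal_temp": s.anneal_temp,
                "cycles": s.cycles,
                "pre_dilution_fold": s.pre_dilution_fold,
                "oligos": [
                    {
                        "id": o.id,
                        "sequence": str(o.sequence),
                        "role": o.role.value,
                        "anneal_interval": list(o.anneal_interval),
                        "tail_length": o.tail_length,
                    }
                    for o in s.oligos
                ],
            }
            for s in plan.stages
        ],
        "provenance": provenance or {},
    }


def load_plan_document(doc: dict | str) -> PopPlan:
    """Rebuild a plan from its document; schema-validated."""
    if isinstance(doc, str):
        try:
            doc = json.loads(doc)
        except json.JSONDecodeError as exc:
            raise ValueError(f"malformed plan document: {exc}") from exc
    for key in ("schema_version", "kind", "target", "core_interval"):
        if key not in doc:
            raise ValueError(f"plan document missing field {key!r}")
    if doc["schema_version"] != SCHEMA_VERSION:
        raise ValueError(
            f"unsupported schema version {doc['schema_version']!r} "
            f"(expected {SCHEMA_VERSION!r})")
    if doc["kind"] != "pop":
        raise ValueError(f"cannot load plan of kind {doc['kind']!r}")
    plan = plan_pop(
        NucSequence(doc["target"]),
        tuple(doc["core_interval"]),
        PopConstraints(**doc.get("constraints", {})),
    )
    return plan
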