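"""Combinatorial DNA library construction planning.

A library is specified position-by-position: each position offers several
variants, each variant is copied out of a source template as one or more PCR
fragments whose primers may carry substitution edits.  Planning turns the
selected combinations into a staged DAG of reactions:

* stage 1 - building-block PCRs, deduplicated so a fragment shared by many
  targets is amplified once;
* middle stages - binary overlap-extension joins, ordered greedily so the
  join shared by the most remaining targets is scheduled first;
* final stage - per-target amplification with the external primer pair.

Every node carries its in-silico product sequence, so the plan doubles as a
sequence-level prediction of the whole construction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx

from .seqcore import MIN_ANNEAL_LEN, NucSequence, revcomp

__all__ = [
    "FragmentSpec",
    "VariantSpec",
    "PositionSpec",
    "LibrarySpec",
    "ConstructionNode",
    "ConstructionPlan",
    "SpecError",
    "enumerate_combinations",
    "plan_library",
    "count_reactions",
    "reuse_savings",
    "assemble_fragments",
]

#: Reaction-recipe defaults: binary joins run few cycles, the final
#: external-primer amplification runs a full program.  Building-block PCRs
#: use the final-amplification cycle count.
JOIN_CYCLES = 10
AMPLIFICATION_CYCLES = 30
#: Annealing temperature convention for library reactions: Tm of primers - 5.
ANNEAL_TM_OFFSET = -5.0

PRIMER_SPAN = 25  # nt copied into each fragment-end primer


class SpecError(ValueError):
    """The library specification is malformed or unplannable."""


@dataclass(frozen=True)
class FragmentSpec:
    """One PCR fragment: an interval on a source template plus primer edits.

    ``edits`` are (offset, base) substitutions relative to the fragment
    start; they must fall inside the terminal primer spans, mirroring
    site-directed mutagenesis via primer tails.
    """

    template_id: str
    interval: tuple[int, int]
    edits: tuple[tuple[int, str], ...] = ()

    def sequence(self, templates: dict[str, NucSequence]) -> NucSequence:
        a, b = self.interval
        tpl = templates[self.template_id]
        if not (0 <= a < b <= len(tpl)):
            raise SpecError(f"interval [{a}, {b}) outside template {self.template_id!r}")
        frag = list(tpl[a:b])
        for off, base in self.edits:
            if not (off < PRIMER_SPAN or off >= (b - a) - PRIMER_SPAN):
                raise SpecError(
                    f"edit at offset {off} lies outside the terminal primer spans"
                )
            frag[off] = base
        return NucSequence("".join(frag))


@dataclass(frozen=True)
class VariantSpec:
    id: str
    fragments: tuple[FragmentSpec, ...]


@dataclass(frozen=True)
class PositionSpec:
    name: str
    variants: tuple[VariantSpec, ...]


@dataclass
class LibrarySpec:
    positions: list[PositionSpec]
    templates: dict[str, NucSequence]
    #: Combinations (one variant index per position) actually built.
    selected_targets: list[tuple[int, ...]]
    external_primers: tuple[NucSequence, NucSequence]
    min_overlap: int = MIN_ANNEAL_LEN

    def __post_init__(self) -> None:
        if not self.positions:
            raise SpecError("library needs at least one position")
        for pos in self.positions:
            if not pos.variants:
                raise SpecError(f"position {pos.name!r} has no variants")
        space = {c for c in itertools.product(*(range(len(p.variants)) for p in self.positions))}
        for combo in self.selected_targets:
            if tuple(combo) not in space:
                raise SpecError(f"selected target {combo} outside the combination space")

    def target_id(self, combo: tuple[int, ...]) -> str:
        return "t_" + "_".join(
            pos.variants[i].id for pos, i in zip(self.positions, combo)
        )

    def target_fragments(self, combo: tuple[int, ...]) -> list[FragmentSpec]:
        frags: list[FragmentSpec] = []
        for pos, i in zip(self.positions, combo):
            frags.extend(pos.variants[i].fragments)
        return frags


def enumerate_combinations(spec: LibrarySpec) -> list[tuple[int, ...]]:
    """The full combination space, lexicographically ordered."""
    return list(itertools.product(*(range(len(p.variants)) for p in spec.positions)))


def _merge_overlap(left: str, right: str, min_overlap: int) -> NucSequence:
    """Fuse two fragments over their shared end window, counted once."""
    limit = min(len(left), len(right))
    for n in range(limit, min_overlap - 1, -1):
        if left[-n:] == right[:n]:
            return NucSequence(left + right[n:])
    raise SpecError(
        f"no overlap window of >= {min_overlap} nt at junction "
        f"...{left[-12:]} | {right[:12]}..."
    )


def assemble_fragments(frag_seqs: list[str], min_overlap: int = MIN_ANNEAL_LEN) -> NucSequence:
    """Merge an ordered fragment chain into one sequence (overlaps merged once)."""
    if not frag_seqs:
        raise SpecError("no fragments to assemble")
    out = NucSequence(frag_seqs[0])
    for nxt in frag_seqs[1:]:
        out = _merge_overlap(out, nxt, min_overlap)
    return out


@dataclass(frozen=True)
class ConstructionNode:
    id: str
    kind: str  # template | primer | pcr_product | join_intermediate | final_target
    sequence: NucSequence
    inputs: tuple[str, ...]
    stage: int

    def recipe(self) -> dict:
        cycles = {"pcr_product": AMPLIFICATION_CYCLES,
                  "join_intermediate": JOIN_CYCLES,
                  "final_target": AMPLIFICATION_CYCLES}.get(self.kind, 0)
        return {"id": self.id, "kind": self.kind, "stage": self.stage,
                "cycles": cycles, "inputs": list(self.inputs)}


@dataclass
class ConstructionPlan:
    spec: LibrarySpec
    nodes: dict[str, ConstructionNode]
    #: Map from selected combination -> final_target node id.
    targets: dict[tuple[int, ...], str]

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for node in self.nodes.values():
            g.add_node(node.id, kind=node.kind, stage=node.stage)
            for dep in node.inputs:
                g.add_edge(dep, node.id)
        return g

    def stage_nodes(self, kind: str | None = None) -> list[ConstructionNode]:
        out = [n for n in self.nodes.values() if kind is None or n.kind == kind]
        return sorted(out, key=lambda n: (n.stage, n.id))


def _fragment_primers(seq: NucSequence) -> tuple[NucSequence, NucSequence]:
    """Terminal primers of a building-block PCR (they carry any edits)."""
    return NucSequence(seq[:PRIMER_SPAN]), revcomp(seq[len(seq) - PRIMER_SPAN:])


def plan_library(spec: LibrarySpec, *, dedup: bool = True) -> ConstructionPlan:
    """Build the staged construction DAG for the selected targets.

    With ``dedup`` (the default) identical non-primer products are planned
    once and shared; disabling it models naive per-target construction and
    exists only for bookkeeping comparisons.
    """
    templates = spec.templates
    nodes: dict[str, ConstructionNode] = {}
    seq_index: dict[tuple[str, str], str] = {}  # (kind, sequence) -> node id

    def add_node(kind: str, sequence: NucSequence, inputs: tuple[str, ...],
                 stage: int, hint: str) -> str:
        key = (kind, str(sequence))
        if dedup and kind != "primer" and key in seq_index:
            return seq_index[key]
        node_id = f"{hint}"
        if node_id in nodes:
            node_id = f"{hint}#{len(nodes)}"
        nodes[node_id] = ConstructionNode(node_id, kind, sequence, inputs, stage)
        seq_index.setdefault(key, node_id)
        return node_id

    for tid, tseq in sorted(templates.items()):
        add_node("template", tseq, (), 0, f"tpl_{tid}")

    # Stage 1: deduplicated building-block PCRs, with their primers.
    chains: dict[tuple[int, ...], list[str]] = {}
    node_seq: dict[str, NucSequence] = {n.id: n.sequence for n in nodes.values()}
    for combo in spec.selected_targets:
        chain: list[str] = []
        for k, frag in enumerate(spec.target_fragments(tuple(combo))):
            fseq = frag.sequence(templates)
            fwd, rev = _fragment_primers(fseq)
            tpl_node = seq_index[("template", str(templates[frag.template_id]))]
            pf = add_node("primer", fwd, (), 0, f"prm_f_{frag.template_id}_{frag.interval[0]}")
            pr = add_node("primer", rev, (), 0, f"prm_r_{frag.template_id}_{frag.interval[1]}")
            nid = add_node("pcr_product", fseq, (tpl_node, pf, pr), 1,
                           f"pcr_{frag.template_id}_{frag.interval[0]}_{frag.interval[1]}")
            node_seq[nid] = fseq
            chain.append(nid)
        chains[tuple(combo)] = chain

    # Join stages: greedily fuse the adjacent pair shared by most targets.
    while any(len(c) > 1 for c in chains.values()):
        pair_targets: dict[tuple[str, str], list[tuple[int, ...]]] = {}
        for combo, chain in chains.items():
            for a, b in zip(chain, chain[1:]):
                pair_targets.setdefault((a, b), []).append(combo)
        # Most shared first; ties toward the left-most (earlier) junction for
        # determinism, which yields left-deep join trees on uniform sharing.
        def rank(item: tuple[tuple[str, str], list]) -> tuple:
            (a, b), combos = item
            positions = [chains[c].index(a) for c in combos]
            return (-len(combos), min(positions), a, b)

        (a, b), combos = min(pair_targets.items(), key=rank)
        joined = _merge_overlap(node_seq[a], node_seq[b], spec.min_overlap)
        stage = max(nodes[a].stage, nodes[b].stage) + 1
        nid = add_node("join_intermediate", joined, (a, b), stage, f"join_{a}+{b}")
        node_seq[nid] = joined
        for combo in combos:
            chain = chains[combo]
            i = chain.index(a)
            chains[combo] = chain[:i] + [nid] + chain[i + 2:]

    # Final stage: per-target amplification with the external primers.
    ext_f, ext_r = spec.external_primers
    pf = add_node("primer", ext_f, (), 0, "prm_ext_f")
    pr = add_node("primer", ext_r, (), 0, "prm_ext_r")
    targets: dict[tuple[int, ...], str] = {}
    max_stage = max((n.stage for n in nodes.values()), default=0)
    for combo, chain in chains.items():
        (assembly,) = chain
        nid = f"final_{spec.target_id(combo)}"
        nodes[nid] = ConstructionNode(
            nid, "final_target", node_seq[assembly], (assembly, pf, pr), max_stage + 1
        )
        targets[combo] = nid
    return ConstructionPlan(spec=spec, nodes=nodes, targets=targets)


def count_reactions(plan: ConstructionPlan) -> dict:
    """Per-stage reaction counts (PCRs, joins, final amplifications)."""
    per_stage: dict[int, int] = {}
    kinds = {"pcr_product": 0, "join_intermediate": 0, "final_target": 0}
    for node in plan.nodes.values():
        if node.kind in kinds:
            kinds[node.kind] += 1
            per_stage[node.stage] = per_stage.get(node.stage, 0) + 1
    return {
        "per_stage": dict(sorted(per_stage.items())),
        "pcr_products": kinds["pcr_product"],
        "joins": kinds["join_intermediate"],
        "final_amplifications": kinds["final_target"],
        "total": sum(kinds.values()),
    }


def _binary_tree_ranges(n: int) -> list[frozenset[tuple[int, int]]]:
    """All binary join-tree shapes over an n-fragment chain, as the sets of
    internal contiguous ranges they create (the full range included)."""
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def shapes(a: int, b: int) -> list[frozenset[tuple[int, int]]]:
        if b - a == 1:
            return [frozenset()]
        out = []
        for cut in range(a + 1, b):
            for ls in shapes(a, cut):
                for rs in shapes(cut, b):
                    out.append(ls | rs | {(a, b)})
        return out

    return shapes(0, n)


def reuse_savings(spec: LibrarySpec, *, brute_force: bool = False) -> dict:
    """Reaction totals with and without shared-intermediate reuse.

    ``brute_force`` additionally computes the true minimum join count by
    exhausting every per-target binary join-tree shape; it is only allowed
    on small specs (<= 3 positions and <= 8 selected targets).
    """
    dedup = count_reactions(plan_library(spec, dedup=True))
    naive = count_reactions(plan_library(spec, dedup=False))
    out = {"dedup_total": dedup["total"], "naive_total": naive["total"],
           "dedup": dedup, "naive": naive}
    if brute_force:
        if len(spec.positions) > 3 or len(spec.selected_targets) > 8:
            raise SpecError("brute-force minimum only enumerable on <= 3 positions / <= 8 targets")
        chains = {
            tuple(c): [f.sequence(spec.templates) for f in spec.target_fragments(tuple(c))]
            for c in spec.selected_targets
        }
        best = None
        per_target_shapes = [
            (combo, _binary_tree_ranges(len(frags))) for combo, frags in chains.items()
        ]
        for assignment in itertools.product(*(s for _, s in per_target_shapes)):
            joins: set[str] = set()
            for (combo, _), ranges in zip(per_target_shapes, assignment):
                frags = chains[combo]
                for (a, b) in ranges:
                    joins.add(str(assemble_fragments(frags[a:b], spec.min_overlap)))
            if best is None or len(joins) < best:
                best = len(joins)
        stage1 = {str(s) for frags in chains.values() for s in frags}
        out["brute_force_minimum"] = len(stage1) + (best or 0) + len(chains)
    return out
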