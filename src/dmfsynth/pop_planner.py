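"""Inside-out gene assembly planning by ordered overlap-extension stages.

A construct is grown outward from a central core template.  Each stage uses
one forward and one reverse extension oligo; the 3' part of each oligo
anneals to the current construct end (the tail laid down by the previous
stage) and its 5' tail appends new target sequence.  Planning is greedy:
every stage uses as much of its extension budget as the flanks allow, and a
plan is only returned if replaying it through the in-silico overlap-extension
oracle reproduces the target exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .seqcore import (
    MAX_OLIGO_LEN,
    MIN_ANNEAL_LEN,
    MIN_ANNEAL_TM,
    DEFAULT_TM_CONFIG,
    NucSequence,
    OligoRole,
    OligoSpec,
    TmConfig,
    anneal_tm,
    revcomp,
    validate_oligo,
)

__all__ = [
    "PopConstraints",
    "PopStage",
    "PopPlan",
    "PlanningError",
    "MisHybridizationError",
    "VerifyReport",
    "plan_pop",
    "simulate_overlap_extension",
    "verify_pop_plan",
    "find_anneal_length",
]

#: Thermal-cycling defaults of an assembly stage.
POP_CYCLES_PER_STAGE = 4
#: Fold dilution applied before every stage after the first (washes out the
#: previous stage's primers without a purification step).
POP_PRE_DILUTION_FOLD = 64


class PlanningError(ValueError):
    """A flank cannot be decomposed under the design constraints."""


class MisHybridizationError(ValueError):
    """An oligo's 3' end does not anneal exactly where required."""


@dataclass(frozen=True)
class PopConstraints:
    max_oligo_len: int = MAX_OLIGO_LEN
    min_anneal_tm: float = MIN_ANNEAL_TM
    min_anneal_len: int = MIN_ANNEAL_LEN
    #: Approximate total nt of new sequence added per stage (both ends).
    stage_extension_budget: int = 160
    tm_config: TmConfig = DEFAULT_TM_CONFIG


@dataclass(frozen=True)
class PopStage:
    """One elongation stage: a forward/reverse extension-oligo pair.

    Either oligo may be absent when the corresponding flank is already
    complete (a one-sided stage).
    """

    index: int  # 1-based
    fwd: OligoSpec | None
    rev: OligoSpec | None
    anneal_temp: float
    cycles: int = POP_CYCLES_PER_STAGE
    pre_dilution_fold: int = POP_PRE_DILUTION_FOLD

    @property
    def added_length(self) -> int:
        n = 0
        if self.fwd is not None:
            n += self.fwd.tail_length
        if self.rev is not None:
            n += self.rev.tail_length
        return n

    @property
    def oligos(self) -> list[OligoSpec]:
        return [o for o in (self.fwd, self.rev) if o is not None]


@dataclass
class PopPlan:
    target: NucSequence
    core_interval: tuple[int, int]
    stages: list[PopStage]
    constraints: PopConstraints = field(default_factory=PopConstraints)

    @property
    def core(self) -> NucSequence:
        a, b = self.core_interval
        return NucSequence(self.target[a:b])

    @property
    def building_blocks(self) -> int:
        """Total building blocks: the core template plus every oligo."""
        return 1 + sum(len(s.oligos) for s in self.stages)

    @property
    def oligos(self) -> list[OligoSpec]:
        return [o for s in self.stages for o in s.oligos]


def find_anneal_length(
    end_seq: str,
    constraints: PopConstraints,
    *,
    from_right: bool,
) -> int:
    """Shortest anneal length reaching the Tm minimum, floored at 15 nt.

    ``end_seq`` is the construct region adjacent to the extension point:
    its prefix is used for forward oligos (``from_right=False`` means the
    window grows from the left end rightwards) and its suffix for reverse
    oligos.  Raises :class:`PlanningError` when no window within the oligo
    length budget reaches the minimum.
    """
    limit = min(len(end_seq), constraints.max_oligo_len - 1)
    for n in range(constraints.min_anneal_len, limit + 1):
        window = end_seq[-n:] if from_right else end_seq[:n]
        if "N" in window:
            continue
        if anneal_tm(window, constraints.tm_config) >= constraints.min_anneal_tm:
            return n
    raise PlanningError(
        f"no anneal window of <= {limit} nt reaches "
        f"{constraints.min_anneal_tm:.0f} C at this construct end"
    )


def plan_pop(
    target: str,
    core_interval: tuple[int, int],
    constraints: PopConstraints | None = None,
) -> PopPlan:
    """Plan an inside-out assembly of ``target`` from the core interval.

    Greedy outward extension: each stage adds up to
    ``stage_extension_budget`` nt split evenly between the two ends (all of
    it to one end once the other flank is exhausted), subject to the oligo
    length cap.  The returned plan round-trips through
    :func:`verify_pop_plan`.
    """
    constraints = constraints or PopConstraints()
    target = NucSequence(target)
    a, b = core_interval
    if not (0 <= a < b <= len(target)):
        raise ValueError(f"core interval [{a}, {b}) invalid for target of {len(target)} nt")

    stages: list[PopStage] = []
    left, right = a, b  # current construct spans target[left:right]
    index = 0
    while left > 0 or right < len(target):
        index += 1
        construct = target[left:right]
        two_sided = left > 0 and right < len(target)
        per_side = constraints.stage_extension_budget // 2

        fwd = rev = None
        tm_f = tm_r = None
        if left > 0:
            n_anneal = find_anneal_length(construct, constraints, from_right=False)
            cap = constraints.max_oligo_len - n_anneal
            if cap <= 0:
                raise PlanningError(
                    f"anneal region of {n_anneal} nt at coordinate {left} leaves no tail budget"
                )
            budget = per_side if two_sided else min(constraints.stage_extension_budget, cap)
            tail_len = min(left, budget, cap)
            new_left = left - tail_len
            seq = NucSequence(target[new_left:left] + construct[:n_anneal])
            fwd = OligoSpec(
                id=f"pop_s{index}_fwd",
                sequence=seq,
                role=OligoRole.EXTENSION_FWD,
                stage=index,
                anneal_interval=(0, n_anneal),
                tail_length=tail_len,
            )
            tm_f = anneal_tm(construct[:n_anneal], constraints.tm_config)
            left = new_left
        if right < len(target):
            n_anneal = find_anneal_length(construct, constraints, from_right=True)
            cap = constraints.max_oligo_len - n_anneal
            if cap <= 0:
                raise PlanningError(
                    f"anneal region of {n_anneal} nt at coordinate {right} leaves no tail budget"
                )
            budget = per_side if two_sided else min(constraints.stage_extension_budget, cap)
            tail_len = min(len(target) - right, budget, cap)
            new_right = right + tail_len
            anneal_top = construct[len(construct) - n_anneal :]
            seq = revcomp(anneal_top + target[right:new_right])
            rev = OligoSpec(
                id=f"pop_s{index}_rev",
                sequence=seq,
                role=OligoRole.EXTENSION_REV,
                stage=index,
                anneal_interval=(len(construct) - n_anneal, len(construct)),
                tail_length=tail_len,
            )
            tm_r = anneal_tm(anneal_top, constraints.tm_config)
            right = new_right

        tms = [t for t in (tm_f, tm_r) if t is not None]
        stage = PopStage(index=index, fwd=fwd, rev=rev, anneal_temp=min(tms))
        for oligo in stage.oligos:
            rep = validate_oligo(oligo, construct, constraints.tm_config)
            if not rep.ok:  # pragma: no cover - guarded by construction
                raise PlanningError(f"stage {index} oligo {oligo.id} invalid: {rep.violations}")
        stages.append(stage)

    plan = PopPlan(target=target, core_interval=core_interval, stages=stages,
                   constraints=constraints)
    report = verify_pop_plan(plan)
    if not report.ok:  # pragma: no cover - greedy construction is exact
        raise PlanningError(f"planned stages do not reconstruct the target: {report.detail}")
    return plan


def _match_suffix(oligo_seq: str, reference: str, min_anneal: int) -> int:
    """Length of the longest 3' suffix of ``oligo_seq`` matching a prefix of
    ``reference``; raises if shorter than ``min_anneal``."""
    best = 0
    limit = min(len(oligo_seq), len(reference))
    for n in range(limit, 0, -1):
        if oligo_seq[-n:] == reference[:n]:
            best = n
            break
    if best < min_anneal:
        raise MisHybridizationError(
            f"3' end anneals over only {best} nt (< {min_anneal} required)"
        )
    return best


def simulate_overlap_extension(
    construct: str,
    fwd: OligoSpec | None,
    rev: OligoSpec | None,
    min_anneal: int = MIN_ANNEAL_LEN,
) -> NucSequence:
    """In-silico oracle for one overlap-extension stage.

    Requires the forward oligo's 3' suffix to match the construct prefix
    exactly (and symmetrically for the reverse oligo on the bottom strand);
    returns tail(fwd) + construct + revcomp(tail(rev)).  Any mismatch is a
    mis-hybridization (the off-track assembly failure mode), not a partial
    product.
    """
    construct = NucSequence(construct)
    prefix = suffix = NucSequence("")
    if fwd is not None:
        n = _match_suffix(fwd.sequence, construct, min_anneal)
        prefix = NucSequence(fwd.sequence[: len(fwd.sequence) - n])
    if rev is not None:
        n = _match_suffix(rev.sequence, revcomp(construct), min_anneal)
        suffix = revcomp(rev.sequence[: len(rev.sequence) - n])
    return NucSequence(prefix + construct + suffix)


@dataclass
class VerifyReport:
    ok: bool
    stage_lengths: list[int]
    detail: str = ""


def verify_pop_plan(plan: PopPlan) -> VerifyReport:
    """Replay a plan through the overlap-extension oracle.

    Passes iff folding every stage over the core reconstructs the target
    exactly.  The per-stage intermediate lengths are the in-silico analog of
    monitoring each assembly step on a gel.
    """
    construct = plan.core
    lengths: list[int] = []
    for stage in plan.stages:
        try:
            construct = simulate_overlap_extension(
                construct, stage.fwd, stage.rev, plan.constraints.min_anneal_len
            )
        except MisHybridizationError as exc:
            return VerifyReport(False, lengths, f"stage {stage.index}: {exc}")
        lengths.append(len(construct))
    if construct != plan.target:
        return VerifyReport(False, lengths, "final sequence differs from target")
    return VerifyReport(True, lengths)
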