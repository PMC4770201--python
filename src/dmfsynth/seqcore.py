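"""DNA sequence primitives, melting-temperature models and oligo design rules.

The assembly planners treat DNA as plain top-strand text over ``A C G T N``
(``N`` only for fully randomized windows such as cloning barcodes).  Two
melting-temperature models are provided: the nearest-neighbor model used for
all design decisions, and the Wallace 2+4 rule kept as an independent sanity
oracle for short oligos.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from Bio.SeqUtils import MeltingTemp as _mt

__all__ = [
    "NucSequence",
    "OligoRole",
    "OligoSpec",
    "TmConfig",
    "AlphabetError",
    "UnsupportedBaseError",
    "ValidationReport",
    "revcomp",
    "gc_fraction",
    "tm_wallace",
    "tm_nn",
    "validate_oligo",
    "MAX_OLIGO_LEN",
    "MIN_ANNEAL_TM",
    "MIN_ANNEAL_LEN",
]

#: Hard upper length for extension-role oligos (long synthetic oligos do not
#: prime reliably beyond this length).
MAX_OLIGO_LEN = 120
#: Minimal acceptable melting temperature of any anneal region, in deg C.
MIN_ANNEAL_TM = 60.0
#: Floor on anneal-region length in nt, independent of Tm.
MIN_ANNEAL_LEN = 15

_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class AlphabetError(ValueError):
    """A sequence contains a character outside {A, C, G, T, N}."""


class UnsupportedBaseError(ValueError):
    """An operation met a base (typically N) it cannot score."""


class NucSequence(str):
    """An uppercase DNA string over {A,C,G,T,N}, validated at construction.

    Behaves as a plain ``str`` (slicing returns ``str``); wrap results back
    into :class:`NucSequence` when the invariant matters downstream.
    """

    def __new__(cls, bases: str) -> "NucSequence":
        s = str(bases).upper()
        for i, ch in enumerate(s):
            if ch not in _ALPHABET:
                raise AlphabetError(
                    f"invalid base {ch!r} at position {i}; expected one of ACGTN"
                )
        return super().__new__(cls, s)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"NucSequence({str.__repr__(self)})"


def revcomp(seq: str) -> NucSequence:
    """Reverse complement; an involution. ``N`` maps to ``N``."""
    s = seq if isinstance(seq, NucSequence) else NucSequence(seq)
    return NucSequence(s.translate(_COMPLEMENT)[::-1])


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


class OligoRole(str, enum.Enum):
    CORE_TEMPLATE = "core_template"
    EXTENSION_FWD = "extension_fwd"
    EXTENSION_REV = "extension_rev"
    AMPLIFICATION_FWD = "amplification_fwd"
    AMPLIFICATION_REV = "amplification_rev"
    MUTAGENIC = "mutagenic"


#: Roles whose oligos are length-capped at MAX_OLIGO_LEN.
EXTENSION_ROLES = frozenset({OligoRole.EXTENSION_FWD, OligoRole.EXTENSION_REV})


@dataclass(frozen=True)
class TmConfig:
    """Conditions for melting-temperature evaluation.

    ``oligo_conc`` defaults to 0.1 pmol in a 0.3 ul droplet (~3.33e-7 M), the
    working primer concentration of the droplet reaction recipes.
    """

    method: str = "nearest_neighbor"
    monovalent_salt: float = 0.05  # mol/L
    oligo_conc: float = 3.33e-7  # mol/L

    def __post_init__(self) -> None:
        if self.monovalent_salt <= 0 or self.oligo_conc <= 0:
            raise ValueError("concentrations must be > 0")
        if self.method not in ("nearest_neighbor", "wallace"):
            raise ValueError(f"unknown Tm method {self.method!r}")


DEFAULT_TM_CONFIG = TmConfig()


@dataclass(frozen=True)
class OligoSpec:
    """A synthetic oligo with its role on the growing construct.

    ``anneal_interval`` is a 0-based half-open interval on the top strand of
    the construct the oligo hybridizes to at its design stage.  Reverse-role
    oligos are stored 5'->3', i.e. as the reverse complement of that
    top-strand window plus any 5' tail of new sequence.
    """

    id: str
    sequence: NucSequence
    role: OligoRole
    stage: int = 0
    anneal_interval: tuple[int, int] = (0, 0)
    tail_length: int = 0

    def __post_init__(self) -> None:
        if self.stage < 0:
            raise ValueError("stage must be >= 0")
        a, b = self.anneal_interval
        if a < 0 or b < a:
            raise ValueError(f"malformed anneal interval {self.anneal_interval}")

    @property
    def anneal_length(self) -> int:
        a, b = self.anneal_interval
        return b - a

    @property
    def anneal_region(self) -> NucSequence:
        """The annealing 3' part of the oligo, 5'->3' as stored."""
        n = self.anneal_length
        return NucSequence(self.sequence[len(self.sequence) - n :])

    @property
    def tail(self) -> NucSequence:
        """The 5' tail of new sequence ahead of the anneal region."""
        return NucSequence(self.sequence[: len(self.sequence) - self.anneal_length])


def tm_wallace(seq: str) -> float:
    """Wallace 2+4 rule: 2*(A+T) + 4*(G+C), in deg C.

    Only meaningful for short oligos; used here as an independent oracle for
    the nearest-neighbor model.
    """
    s = NucSequence(seq)
    if len(s) < 2:
        raise ValueError("sequence too short for a Tm estimate (need >= 2 nt)")
    if "N" in s:
        raise UnsupportedBaseError("cannot score N bases")
    at = s.count("A") + s.count("T")
    gc = s.count("G") + s.count("C")
    return 2.0 * at + 4.0 * gc


def tm_nn(seq: str, cfg: TmConfig = DEFAULT_TM_CONFIG) -> float:
    """Nearest-neighbor duplex Tm (unified parameter set, salt-corrected).

    Monovalent salt and the excess-primer concentration come from ``cfg``.
    Deterministic; for a fixed length and salt it is monotone non-decreasing
    in GC content.
    """
    s = NucSequence(seq)
    if len(s) < 8:
        raise ValueError(f"sequence of {len(s)} nt too short for the NN model (need >= 8)")
    if "N" in s:
        raise UnsupportedBaseError("cannot score N bases")
    return float(
        _mt.Tm_NN(
            str(s),
            dnac1=cfg.oligo_conc * 1e9,  # nM
            dnac2=0.0,
            Na=cfg.monovalent_salt * 1e3,  # mM
            saltcorr=5,
        )
    )


def anneal_tm(seq: str, cfg: TmConfig = DEFAULT_TM_CONFIG) -> float:
    """Tm of an anneal region under the configured model."""
    if cfg.method == "wallace":
        return tm_wallace(seq)
    return tm_nn(seq, cfg)


@dataclass
class ValidationReport:
    """Outcome of oligo design-rule checking."""

    oligo_id: str
    ok: bool = True
    violations: list[str] = field(default_factory=list)

    def fail(self, rule: str, message: str) -> None:
        self.ok = False
        self.violations.append(f"{rule}: {message}")


def validate_oligo(
    oligo: OligoSpec,
    construct: str,
    cfg: TmConfig = DEFAULT_TM_CONFIG,
) -> ValidationReport:
    """Check an oligo against the design rules on a given construct.

    Rules: extension-role oligos are <= 120 nt; the anneal region reaches
    60 deg C; and the anneal region matches the construct exactly at
    ``anneal_interval`` (orientation-aware for reverse-role oligos).
    """
    report = ValidationReport(oligo.id)
    a, b = oligo.anneal_interval
    if b > len(construct):
        raise IndexError(
            f"anneal interval [{a}, {b}) out of bounds for construct of {len(construct)} nt"
        )

    if oligo.role in EXTENSION_ROLES and len(oligo.sequence) > MAX_OLIGO_LEN:
        report.fail(
            "length",
            f"{len(oligo.sequence)} nt exceeds the {MAX_OLIGO_LEN} nt limit",
        )

    region = oligo.anneal_region
    try:
        tm = anneal_tm(region, cfg)
    except (UnsupportedBaseError, ValueError) as exc:
        report.fail("tm", f"anneal region not scoreable: {exc}")
    else:
        if tm < MIN_ANNEAL_TM:
            report.fail(
                "tm", f"anneal Tm {tm:.1f} C below the {MIN_ANNEAL_TM:.0f} C minimum"
            )

    window = NucSequence(construct[a:b])
    expected = window if oligo.role != OligoRole.EXTENSION_REV and oligo.role != OligoRole.AMPLIFICATION_REV else revcomp(window)
    if region != expected:
        report.fail("anneal_match", f"anneal region does not match construct at [{a}, {b})")
    return report
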