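"""Cell-free cloning by limiting dilution and single-molecule PCR (smPCR).

An assembly product is serially diluted 2-fold on cartridge until droplets
hold on average well under one template molecule; droplets that amplify then
usually derive from a single founder.  Occupancy follows a Poisson law, and
clonality is certified by a fully randomized barcode window (14 N bases by
default, a space of 4^14 sequences): a clonal amplification shows one base
per position, a multi-founder one shows heterogeneous positions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "DilutionPlan",
    "SmPcrOutcome",
    "BarcodeCall",
    "poisson_occupancy",
    "clonal_fraction",
    "plan_limiting_dilution",
    "simulate_smpcr",
    "call_clonality",
    "barcode_collision_prob",
    "barcode_space",
    "BARCODE_LEN",
    "DEFAULT_TARGET_LAMBDA",
    "PURITY_THRESHOLD",
]

#: Length of the fully randomized barcode window.
BARCODE_LEN = 14
#: Default target occupancy, molecules/droplet ("well under 1").
DEFAULT_TARGET_LAMBDA = 0.5
#: Majority-base fraction required at every position to call clonal.
PURITY_THRESHOLD = 0.9

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def barcode_space(length: int = BARCODE_LEN) -> int:
    """Number of possible barcode sequences, 4**length."""
    return 4 ** length


@dataclass(frozen=True)
class DilutionPlan:
    initial: float  # molecules/droplet before dilution
    target_lambda: float
    steps: int  # count of 2-fold dilutions
    achieved_lambda: float


@dataclass(frozen=True)
class SmPcrOutcome:
    molecules: int
    amplified: bool
    clonal: bool
    founder_barcodes: tuple[str, ...]


@dataclass(frozen=True)
class BarcodeCall:
    call: str  # clonal | mixed | empty
    base_fractions: np.ndarray | None  # positions x 4 (A,C,G,T)


def poisson_occupancy(lam: float, k: int) -> float:
    """P(droplet holds exactly k molecules) at occupancy ``lam``."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if lam == 0:
        return 1.0 if k == 0 else 0.0
    return float(stats.poisson.pmf(k, lam))


def clonal_fraction(lam: float) -> tuple[float, float]:
    """(P(exactly one molecule), P(one molecule | amplified)).

    The first component, lam*exp(-lam), is maximized at lam = 1; the second,
    lam*exp(-lam)/(1 - exp(-lam)), rises towards 1 as lam -> 0 (at the price
    of mostly-empty droplets).
    """
    if lam <= 0:
        raise ValueError("lambda must be > 0")
    p1 = lam * math.exp(-lam)
    return p1, p1 / (1.0 - math.exp(-lam))


def plan_limiting_dilution(initial: float, target_lambda: float = DEFAULT_TARGET_LAMBDA
                           ) -> DilutionPlan:
    """Number of on-cartridge 2-fold dilution steps to reach the target
    occupancy: k = ceil(log2(initial / target))."""
    if initial <= 0:
        raise ValueError("initial concentration must be > 0")
    if not 0 < target_lambda <= initial:
        raise ValueError("target occupancy must be in (0, initial]")
    ratio = initial / target_lambda
    k = max(0, math.ceil(math.log2(ratio) - 1e-12))
    return DilutionPlan(initial, target_lambda, k, initial / 2 ** k)


def _random_barcode(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)].astype("U1"))


def simulate_smpcr(n_droplets: int, lam: float, barcode_len: int = BARCODE_LEN,
                   seed: int = 0) -> list[SmPcrOutcome]:
    """Seeded smPCR outcomes: Poisson molecule counts per droplet, one
    uniform random barcode per founder molecule.  A droplet amplifies iff it
    received at least one molecule and is clonal iff exactly one."""
    if n_droplets < 1:
        raise ValueError("need at least one droplet")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(lam, size=n_droplets)
    out = []
    for c in counts:
        barcodes = tuple(_random_barcode(rng, barcode_len) for _ in range(int(c)))
        out.append(SmPcrOutcome(int(c), c >= 1, c == 1, barcodes))
    return out


def call_clonality(reads, purity_threshold: float = PURITY_THRESHOLD) -> BarcodeCall:
    """Call a barcode window clonal, mixed or empty.

    ``reads`` is either a sequence of equal-length barcode reads or a
    positions x 4 base-fraction matrix (A,C,G,T columns).  Clonal iff the
    majority-base fraction at every position reaches the threshold.
    """
    if isinstance(reads, np.ndarray) and reads.ndim == 2:
        frac = np.asarray(reads, dtype=float)
        if frac.size and not np.allclose(frac.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("base-fraction rows must sum to 1")
    else:
        reads = list(reads)
        if not reads:
            return BarcodeCall("empty", None)
        length = len(reads[0])
        if any(len(r) != length for r in reads):
            raise ValueError("all barcode reads must have the same length")
        arr = np.frombuffer("".join(reads).encode(), dtype="S1").reshape(len(reads), length)
        counts = np.stack([(arr == base).sum(axis=0)
                           for base in (b"A", b"C", b"G", b"T")], axis=1)
        frac = counts / len(reads)
    if frac.size == 0:
        return BarcodeCall("empty", None)
    call = "clonal" if bool((frac.max(axis=1) >= purity_threshold).all()) else "mixed"
    return BarcodeCall(call, frac)


def barcode_collision_prob(n_founders: int, barcode_len: int = BARCODE_LEN) -> float:
    """P(any two of n founders share a barcode): the birthday bound in exact
    product form, 1 - prod_{i=1..n-1}(1 - i/4^len)."""
    if n_founders < 2:
        raise ValueError("need at least two founders")
    space = float(barcode_space(barcode_len))
    i = np.arange(1, n_founders)
    log_no_collision = np.log1p(-i / space).sum()
    return float(-np.expm1(log_no_collision))
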