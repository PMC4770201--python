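"""Construction-fidelity statistics.

Error rates are estimated by dividing total sequencing errors by total
sequenced bases (substitutions only — the error spectrum of proof-reading
polymerase assembly).  Under independent per-base errors the probability of
an error-free clone decays exponentially with length, p = (1 - eps)^L, which
drives the expected number of clones one must sequence to find a correct
instance, 1/p per variant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ErrorModel",
    "ErrorRateReport",
    "error_rate_from_counts",
    "total_sequenced_bp",
    "p_error_free",
    "expected_clones",
    "simulate_clone_screen",
    "hamming_matrix",
]


@dataclass(frozen=True)
class ErrorModel:
    """Per-base substitution rate and clone length."""

    epsilon: float  # errors/bp
    length: int  # bp

    def __post_init__(self) -> None:
        if not 0 <= self.epsilon < 1:
            raise ValueError("epsilon must be in [0, 1)")
        if self.length < 0:
            raise ValueError("length must be >= 0")


@dataclass(frozen=True)
class ErrorRateReport:
    rate: float  # errors/bp
    errors_per_10kb: float  # truncated to one decimal
    bp_per_error_floor: float  # floor(bases/errors); inf when error-free


def total_sequenced_bp(n_clones: int, bp_per_clone: int) -> int:
    """Total bases read across a clone set (n_clones x bp_per_clone)."""
    if n_clones < 0 or bp_per_clone < 0:
        raise ValueError("counts must be >= 0")
    return n_clones * bp_per_clone


def error_rate_from_counts(errors: int, bases: int) -> ErrorRateReport:
    """Substitution rate from sequencing tallies.

    ``errors_per_10kb`` is truncated (not rounded) to one decimal;
    ``bp_per_error_floor`` is the integer part of bases/errors, the
    conventional "1 error per N bp" figure.
    """
    if bases <= 0:
        raise ValueError("bases must be > 0")
    if errors < 0:
        raise ValueError("errors must be >= 0")
    rate = errors / bases
    per_10kb = math.floor(rate * 1e4 * 10) / 10
    floor = math.inf if errors == 0 else bases // errors
    return ErrorRateReport(rate, per_10kb, floor)


def p_error_free(length: int, epsilon: float) -> float:
    """P(clone of ``length`` bp has zero errors) = (1 - eps)^L."""
    ErrorModel(epsilon, length)  # validates
    return (1.0 - epsilon) ** length


def expected_clones(length: int, epsilon: float) -> float:
    """Expected clones to sequence per variant until one is error-free."""
    return 1.0 / p_error_free(length, epsilon)


def simulate_clone_screen(n_variants: int, length: int, epsilon: float,
                          seed: int = 0, replicates: int = 1) -> np.ndarray:
    """Total clones sequenced until every variant has an error-free clone.

    Per variant the number of clones needed is geometric with success
    probability (1 - eps)^L; the screen total is their sum.  Returns one
    total per replicate; the mean converges to n_variants / p.
    """
    if n_variants < 1:
        raise ValueError("need at least one variant")
    rng = np.random.default_rng(seed)
    p = p_error_free(length, epsilon)
    if p == 1.0:
        return np.full(replicates, n_variants, dtype=np.int64)
    draws = rng.geometric(p, size=(replicates, n_variants))
    return draws.sum(axis=1)


def hamming_matrix(seqs: list[str]) -> tuple[np.ndarray, bool]:
    """Pairwise Hamming distances of equal-length sequences.

    Returns the symmetric zero-diagonal matrix and a flag that is true iff
    every pair differs in at least one position (the library-diversity
    check: all clones distinct).
    """
    if not seqs:
        return np.zeros((0, 0), dtype=np.int64), True
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("sequences must all have the same length")
    arr = np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(len(seqs), length)
    diff = arr[:, None, :] != arr[None, :, :]
    mat = diff.sum(axis=2).astype(np.int64)
    n = len(seqs)
    off_diag = mat[~np.eye(n, dtype=bool)]
    return mat, bool((off_diag >= 1).all()) if n > 1 else True
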