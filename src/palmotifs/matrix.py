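"""Core motif matrix types and mathematics.

A motif recognised by a dimeric helix-turn-helix regulator is represented
throughout this package as a position frequency matrix (PFM / PWM): per
position, the probability of each of the four bases in the fixed order
A, C, G, T.  This module provides the matrix containers plus the handful
of operations everything downstream is built from: count-to-probability
conversion with pseudocounts, per-position information content (bits,
uniform background), reverse complementation, a palindromicity score, and
IUPAC degenerate consensus strings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical base order for every matrix in the package.
BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
#: Row permutation implementing complementation (A<->T, C<->G).
COMPLEMENT_ROWS = np.array([3, 2, 1, 0])

_IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C",
    frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AC"): "M", frozenset("AG"): "R", frozenset("AT"): "W",
    frozenset("CG"): "S", frozenset("CT"): "Y", frozenset("GT"): "K",
    frozenset("ACG"): "V", frozenset("ACT"): "H",
    frozenset("AGT"): "D", frozenset("CGT"): "B",
    frozenset("ACGT"): "N",
}

COLUMN_SUM_TOL = 1e-9


class DegenerateMatrixError(ValueError):
    """Raised when a count matrix cannot be normalised (zero column, no pseudocount)."""


@dataclass(frozen=True)
class CountMatrix:
    """4 x W base counts from an alignment of binding sites.

    Every column sums to ``nsites``, the number of sites contributing.
    """

    counts: np.ndarray
    nsites: int

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape[0] != 4:
            raise ValueError(f"counts must be 4 x W, got shape {counts.shape}")
        if counts.shape[1] < 1:
            raise ValueError("motif width must be >= 1")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        sums = counts.sum(axis=0)
        if not np.allclose(sums, self.nsites):
            raise ValueError(
                f"every column must sum to nsites={self.nsites}; got sums {sums}"
            )

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @classmethod
    def from_sites(cls, sites: list[str]) -> "CountMatrix":
        """Build counts from equal-length site strings (A/C/G/T only)."""
        if not sites:
            raise ValueError("need at least one site")
        w = len(sites[0])
        counts = np.zeros((4, w))
        for s in sites:
            if len(s) != w:
                raise ValueError("sites must all have the same length")
            for j, ch in enumerate(s.upper()):
                counts[BASE_INDEX[ch], j] += 1
        return cls(counts=counts, nsites=len(sites))


@dataclass(frozen=True)
class FrequencyMatrix:
    """4 x W base probabilities; each column sums to 1.

    ``pseudocount`` records the per-cell pseudocount used at construction
    (purely provenance; the probabilities are already smoothed).
    """

    probs: np.ndarray
    pseudocount: float = 0.0

    def __post_init__(self):
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", probs)
        if probs.ndim != 2 or probs.shape[0] != 4:
            raise ValueError(f"probs must be 4 x W, got shape {probs.shape}")
        if probs.shape[1] < 1:
            raise ValueError("motif width must be >= 1")
        if (probs < -COLUMN_SUM_TOL).any():
            raise ValueError("probabilities must be non-negative")
        sums = probs.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError(f"columns must sum to 1; got {sums}")

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    def __eq__(self, other) -> bool:  # value equality, used heavily in tests
        if not isinstance(other, FrequencyMatrix):
            return NotImplemented
        return self.probs.shape == other.probs.shape and np.allclose(
            self.probs, other.probs, atol=COLUMN_SUM_TOL
        )


@dataclass(frozen=True)
class ConservationProfile:
    """Per-position information content in bits, each value in [0, 2]."""

    values: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1:
            raise ValueError("profile must be one-dimensional")
        if (values < -1e-9).any() or (values > 2 + 1e-9).any():
            raise ValueError("information content must lie in [0, 2] bits")

    @property
    def width(self) -> int:
        return self.values.shape[0]

    def mean(self) -> float:
        return float(self.values.mean())


@dataclass
class MotifRecord:
    """A discovered motif: its matrix plus site bookkeeping.

    ``nsites`` and ``coverage`` (fraction of input sequences carrying at
    least one site) are the two quantities the downstream filter acts on.
    ``sites`` holds (sequence id, 0-based start, strand) triples.
    """

    id: str
    matrix: FrequencyMatrix
    nsites: int
    coverage: float
    source_set: str = ""
    count_matrix: CountMatrix | None = None
    sites: list[tuple[str, int, str]] = field(default_factory=list)

    def __post_init__(self):
        if self.sites and self.nsites != len(self.sites):
            raise ValueError(
                f"nsites={self.nsites} but {len(self.sites)} sites recorded"
            )
        if not 0.0 <= self.coverage <= 1.0:
            raise ValueError("coverage must lie in [0, 1]")

    @property
    def width(self) -> int:
        return self.matrix.width


def counts_to_pwm(counts: CountMatrix, pseudocount: float = 0.5) -> FrequencyMatrix:
    """Convert counts to probabilities with a per-cell pseudocount.

    probs[b, j] = (counts[b, j] + pseudocount) / (nsites + 4 * pseudocount)
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if pseudocount == 0 and (counts.counts.sum(axis=0) == 0).any():
        raise DegenerateMatrixError(
            "zero-count column with zero pseudocount cannot be normalised"
        )
    probs = (counts.counts + pseudocount) / (counts.nsites + 4.0 * pseudocount)
    return FrequencyMatrix(probs=probs, pseudocount=pseudocount)


def information_content(pwm: FrequencyMatrix) -> ConservationProfile:
    """Per-column information content, 2 + sum_b p log2 p, uniform background.

    0 bits for a uniform column, 2 bits for a fully conserved one.
    """
    p = pwm.probs
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    values = 2.0 + plogp.sum(axis=0)
    return ConservationProfile(values=np.clip(values, 0.0, 2.0))


def reverse_complement(pwm: FrequencyMatrix) -> FrequencyMatrix:
    """Reverse the columns and swap complementary bases (involution)."""
    return FrequencyMatrix(
        probs=pwm.probs[COMPLEMENT_ROWS][:, ::-1], pseudocount=pwm.pseudocount
    )


def palindromicity(pwm: FrequencyMatrix) -> float:
    """How close a PWM is to its own reverse complement, in [0, 1].

    1 - mean over columns of the total-variation distance between the PWM
    and its reverse complement.  Exactly 1 iff pwm == rc(pwm); invariant
    under reverse complementation.  A dimer-bound operator site should
    score near 1.
    """
    rc = reverse_complement(pwm).probs
    tv = 0.5 * np.abs(pwm.probs - rc).sum(axis=0)
    return float(1.0 - tv.mean())


def is_palindromic(pwm: FrequencyMatrix, tol: float = COLUMN_SUM_TOL) -> bool:
    return bool(np.abs(pwm.probs - reverse_complement(pwm).probs).max() <= tol)


def consensus_iupac(pwm: FrequencyMatrix, include_thresh: float = 0.25) -> str:
    """Degenerate consensus: at each position, the IUPAC code for all bases
    with probability >= ``include_thresh`` (falling back to the single
    max-probability base if none qualify).
    """
    if not 0 < include_thresh <= 0.5:
        raise ValueError("include_thresh must lie in (0, 0.5]")
    out = []
    for j in range(pwm.width):
        col = pwm.probs[:, j]
        chosen = {BASES[b] for b in range(4) if col[b] >= include_thresh}
        if not chosen:
            chosen = {BASES[int(col.argmax())]}
        out.append(_IUPAC[frozenset(chosen)])
    return "".join(out)


def total_variation_columns(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-column total-variation distance between two 4 x W blocks."""
    return 0.5 * np.abs(a - b).sum(axis=0)
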