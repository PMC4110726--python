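"""Distance functions over fixed-length nucleotide strings.

A metric-space index is only exact if its distance obeys the metric axioms
(non-negativity, symmetry, triangle inequality, identity of indiscernibles).
This module provides the two distances commonly used for DNA — Hamming and
banded Needleman–Wunsch — plus the combinatorial size of a Hamming ball and
an empirical axiom checker used to validate custom weight schemes.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._encoding import ALPHABET, encode_strict

__all__ = [
    "DistanceFn",
    "HammingDistance",
    "BandedNWDistance",
    "WeightScheme",
    "AxiomReport",
    "hamming",
    "banded_nw",
    "query_ball_size",
    "check_metric_axioms",
]

#: biologically standard transition pairs (purine<->purine, pyrimidine<->pyrimidine)
TRANSITIONS_BIOLOGICAL = (("a", "g"), ("c", "t"))


@dataclass(frozen=True)
class WeightScheme:
    """Per-substitution costs distinguishing transitions from transversions.

    Both costs must be positive so that identity of indiscernibles holds, and
    the induced 4x4 cost matrix must satisfy the triangle inequality per
    position; otherwise position-wise summation is not a metric and index
    results would silently lose exactness. Violations raise at construction.

    The transition pairing is configurable; the default is the biological one
    (a<->g, c<->t).
    """

    transition_cost: float = 1.0
    transversion_cost: float = 1.0
    transitions: tuple[tuple[str, str], ...] = TRANSITIONS_BIOLOGICAL

    def __post_init__(self) -> None:
        if self.transition_cost <= 0 or self.transversion_cost <= 0:
            raise ValueError("substitution costs must be > 0")
        m = self.matrix()
        for x, y, z in itertools.product(range(4), repeat=3):
            if m[x, z] > m[x, y] + m[y, z] + 1e-12:
                raise ValueError(
                    "weight scheme violates the triangle inequality over the "
                    f"nucleotide alphabet: d({ALPHABET[x]},{ALPHABET[z]}) > "
                    f"d({ALPHABET[x]},{ALPHABET[y]}) + d({ALPHABET[y]},{ALPHABET[z]})"
                )

    def matrix(self) -> np.ndarray:
        """4x4 cost matrix indexed by the 2-bit nucleotide code."""
        m = np.full((4, 4), float(self.transversion_cost))
        np.fill_diagonal(m, 0.0)
        for a, b in self.transitions:
            i, j = ALPHABET.index(a), ALPHABET.index(b)
            m[i, j] = m[j, i] = float(self.transition_cost)
        return m


class DistanceFn:
    """A distance over equal-length nucleotide strings.

    Subclasses implement :meth:`evaluate` (pairwise, on strings) and
    :meth:`batch` (one encoded query row against a matrix of encoded points);
    the index uses the batch form exclusively.
    """

    name: str = "abstract"
    alphabet_size: int = 4

    def evaluate(self, a: str, b: str) -> float:
        raise NotImplementedError

    def batch(self, mat: np.ndarray, row: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, a: str, b: str) -> float:
        return self.evaluate(a, b)


class HammingDistance(DistanceFn):
    """Count (or weighted sum) of mismatching positions."""

    def __init__(self, weights: WeightScheme | None = None):
        self.weights = weights
        self.name = "hamming" if weights is None else "weighted_hamming"
        self._cost = None if weights is None else weights.matrix()

    def evaluate(self, a: str, b: str) -> float:
        return hamming(a, b, self.weights)

    def batch(self, mat: np.ndarray, row: np.ndarray) -> np.ndarray:
        if self._cost is None:
            return np.count_nonzero(mat != row, axis=1)
        return self._cost[mat, row].sum(axis=1)


def hamming(a: str, b: str, weights: WeightScheme | None = None) -> float:
    """Hamming distance between two equal-length nucleotide strings.

    Unweighted (default) it is the integer count of mismatching positions;
    with a :class:`WeightScheme` it is the sum of per-position substitution
    costs. Raises on unequal lengths or non-ACGT characters.
    """
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    ea, eb = encode_strict(a), encode_strict(b)
    if weights is None:
        return int(np.count_nonzero(ea != eb))
    return float(weights.matrix()[ea, eb].sum())


class BandedNWDistance(DistanceFn):
    """Banded global edit distance (see :func:`banded_nw`).

    Whether a given cost scheme preserves the triangle inequality under
    banding is not guaranteed in general; :func:`check_metric_axioms` can
    probe it empirically, and a warning is emitted at construction.
    """

    def __init__(self, band: int, match: float = 0.0, mismatch: float = 1.0,
                 gap: float = 1.0):
        self.band, self.match, self.mismatch, self.gap = band, match, mismatch, gap
        self.name = f"banded_nw(band={band})"
        warnings.warn(
            "banded Needleman-Wunsch is not guaranteed to satisfy the triangle "
            "inequality for every cost scheme; validate with check_metric_axioms "
            "before indexing",
            stacklevel=2,
        )

    def evaluate(self, a: str, b: str) -> float:
        return banded_nw(a, b, self.band, self.match, self.mismatch, self.gap)

    def batch(self, mat: np.ndarray, row: np.ndarray) -> np.ndarray:
        from ._encoding import decode

        q = decode(row)
        return np.array([self.evaluate(decode(r), q) for r in mat])


def banded_nw(a: str, b: str, band: int, match: float = 0.0,
              mismatch: float = 1.0, gap: float = 1.0) -> float:
    """Global alignment cost restricted to a diagonal band.

    Minimum edit cost over alignments whose path stays within ``band`` cells
    of the main diagonal, i.e. at most ``band`` unbalanced gaps. With unit
    costs and ``band >= max(len(a), len(b))`` this equals the Levenshtein
    distance. ``band=0`` forces a substitution-only (Hamming) alignment.

    Raises if the band cannot absorb the length difference.
    """
    if band < 0:
        raise ValueError("band must be >= 0")
    if abs(len(a) - len(b)) > band:
        raise ValueError(
            f"band {band} infeasible for length difference {abs(len(a) - len(b))}"
        )
    ea, eb = encode_strict(a), encode_strict(b)
    n, m = len(ea), len(eb)
    inf = math.inf
    # dp over rows of a; columns restricted to |j - i| <= band
    prev = {0: 0.0}
    for j in range(1, min(m, band) + 1):
        prev[j] = j * gap
    for i in range(1, n + 1):
        cur: dict[int, float] = {}
        lo, hi = max(0, i - band), min(m, i + band)
        for j in range(lo, hi + 1):
            best = inf
            if j > 0 and (j - 1) in prev:
                best = min(best, prev[j - 1]
                           + (match if ea[i - 1] == eb[j - 1] else mismatch))
            if j in prev:
                best = min(best, prev[j] + gap)
            if (j - 1) in cur:
                best = min(best, cur[j - 1] + gap)
            cur[j] = best
        prev = cur
    return prev[m]


def query_ball_size(k: int, r: int, n: int = 4) -> int:
    """Number of distinct strings at Hamming distance 1..r from a fixed k-mer.

    B(k, r) = sum_{i=1}^{r} C(k, i) * (n - 1)^i for an alphabet of n symbols.
    The query itself (distance 0) is not counted, so B(k, 0) = 0 and
    B(k, k) = n^k - 1.
    """
    if n < 2:
        raise ValueError("alphabet size must be >= 2")
    if not 0 <= r <= k:
        raise ValueError(f"radius {r} outside [0, {k}]")
    return sum(math.comb(k, i) * (n - 1) ** i for i in range(1, r + 1))


@dataclass
class AxiomReport:
    """Outcome of an empirical metric-axiom check."""

    n_strings: int
    violations: list[tuple[str, tuple]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def check_metric_axioms(fn: DistanceFn, sample: list[str]) -> AxiomReport:
    """Check the four metric axioms on every pair/triple of ``sample``.

    Returns a report listing each violated axiom with a witness tuple.
    Unweighted Hamming passes on any sample; this exists to vet custom
    weight schemes and banded-alignment cost choices before they back an
    index whose exactness depends on the triangle inequality.
    """
    if not sample:
        raise ValueError("sample must be non-empty")
    strings = list(sample)
    report = AxiomReport(n_strings=len(strings))
    d = {}
    for x, y in itertools.product(strings, repeat=2):
        d[x, y] = fn.evaluate(x, y)
    for x in strings:
        if d[x, x] != 0:
            report.violations.append(("identity", (x, d[x, x])))
    for x, y in itertools.combinations(strings, 2):
        if d[x, y] < 0:
            report.violations.append(("non-negativity", (x, y, d[x, y])))
        if d[x, y] != d[y, x]:
            report.violations.append(("symmetry", (x, y, d[x, y], d[y, x])))
        if x != y and d[x, y] == 0:
            report.violations.append(("identity-of-indiscernibles", (x, y)))
    for x, y, z in itertools.permutations(strings, 3):
        if d[x, z] > d[x, y] + d[y, z] + 1e-9:
            report.violations.append(("triangle", (x, y, z, d[x, z], d[x, y], d[y, z])))
    return report
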