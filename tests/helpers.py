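"""Shared construction helpers for the test suite."""

import numpy as np

from adam._encoding import decode
from adam.apf import KmerPoints


def random_kmer_points(n: int, k: int, seed: int) -> KmerPoints:
    """Uniform random k-mers with distinct synthetic origins."""
    rng = np.random.default_rng(seed)
    return KmerPoints(rng.integers(0, 4, (n, k)).astype(np.uint8),
                      np.zeros(n), np.arange(n), np.zeros(n), ["chr1"])


def line_points(distances: list[int], k: int = 16) -> KmerPoints:
    """Points on a Hamming 'line': point at d differs from the base k-mer in
    its first d positions, so pairwise distances are |d_i - d_j|."""
    assert max(distances) <= k
    seqs = []
    for d in distances:
        row = np.zeros(k, dtype=np.uint8)
        row[:d] = 1  # 'c'
        seqs.append(row)
    n = len(distances)
    return KmerPoints(np.vstack(seqs), np.zeros(n), np.arange(n),
                      np.zeros(n), ["chr1"])


def random_kmer(k: int, rng: np.random.Generator) -> str:
    return decode(rng.integers(0, 4, k).astype(np.uint8))
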