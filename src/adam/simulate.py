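"""Synthetic genomes, reads with a position-dependent error profile, and
mapping-accuracy evaluation.

The generator stands in for a real reference plus a read simulator: a
uniform-random DNA background with optional planted diverged duplications
(the feature that makes mapping hard — a read whose errors push it closer
to a repeat copy than to its own origin can never be placed correctly by
*any* method). Reads are fixed-length substrings from known positions and
strands with substitution errors whose per-base probability rises along the
read, Illumina-style; the whole profile scales by a 1x/2x/10x multiplier.
Every read carries a truth record, so the evaluator can distinguish merely
*incorrect* mappings (the origin is still globally optimal and an exact
mapper recovers it) from *unrecoverable* ones (some other location is
strictly closer).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._encoding import decode, encode, revcomp_encoded
from .mapper import MappingResult

__all__ = [
    "SyntheticGenome",
    "ErrorProfile",
    "TruthRecord",
    "AccuracyReport",
    "simulate_genome",
    "simulate_reads",
    "write_fastq",
    "sliding_min_hamming",
    "classify_error",
    "evaluate",
]


@dataclass
class SyntheticGenome:
    """Named sequences plus the repeats planted in them."""

    sequences: dict[str, str]
    planted_repeats: list[tuple[int, int, int, float]] = field(default_factory=list)
    # (source_start, length, copy_start, divergence) per planted duplication


@dataclass(frozen=True)
class ErrorProfile:
    """Per-position substitution probability for a read.

    A linear ramp from ``rate_start`` at the first base to ``rate_end`` at
    position ``ramp_len`` (later positions stay at ``rate_end``), scaled by
    ``multiplier`` and capped at ``cap``. Defaults emulate a typical
    Illumina profile for 80-bp reads: 0.1% at the read start rising to 1%
    at the end; multipliers 2 and 10 model progressively noisier runs.
    """

    rate_start: float = 0.001
    rate_end: float = 0.01
    ramp_len: int = 80
    multiplier: float = 1.0
    cap: float = 0.75

    def probs(self, read_len: int) -> np.ndarray:
        base = np.interp(np.arange(read_len), [0, self.ramp_len - 1],
                         [self.rate_start, self.rate_end])
        return np.clip(base * self.multiplier, 0.0, self.cap)


@dataclass(frozen=True)
class TruthRecord:
    read_id: str
    chrom: str
    true_pos: int  # 0-based leftmost position on the reference
    strand: str
    n_errors_planted: int


@dataclass
class AccuracyReport:
    """Mapping accuracy with the incorrect-vs-unrecoverable breakdown.

    ``accuracy`` counts unmapped/skipped reads as errors (percent correct of
    all reads); ``accuracy_mapped`` restricts the denominator to mapped
    reads. ``*_potential_accuracy`` is, within the skipped and wrong
    subsets, the percentage whose true origin is still globally optimal —
    i.e. the share an exact mapper could still place correctly.
    """

    n_reads: int
    n_correct: int
    n_incorrect: int
    n_skipped: int
    n_unrecoverable: int
    accuracy: float
    accuracy_mapped: float
    skipped_total: int = 0
    skipped_potential_accuracy: float = float("nan")
    wrong_total: int = 0
    wrong_potential_accuracy: float = float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, n).astype(np.uint8)


def _diverge(enc: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    out = enc.copy()
    hit = np.flatnonzero(rng.random(len(enc)) < rate)
    # substitute to one of the three other bases
    out[hit] = (out[hit] + rng.integers(1, 4, len(hit))) % 4
    return out


def simulate_genome(length: int,
                    repeat_spec: list[tuple[int, int, int, float]] | None = None,
                    seed: int = 0, name: str = "chr1") -> SyntheticGenome:
    """Uniform-random genome with optional planted diverged duplications.

    ``repeat_spec`` entries are (source_start, length, copy_start,
    divergence): the source interval is copied over the copy interval with
    each base substituted independently at the divergence rate. Seeded and
    deterministic.
    """
    if length < 1000:
        raise ValueError("genome length must be >= 1000")
    rng = np.random.default_rng(seed)
    enc = _random_seq(rng, length)
    planted = []
    for src, rep_len, dst, div in repeat_spec or []:
        if not (0 <= src and src + rep_len <= length
                and 0 <= dst and dst + rep_len <= length):
            raise ValueError(f"repeat interval out of range: {(src, rep_len, dst)}")
        enc[dst:dst + rep_len] = _diverge(enc[src:src + rep_len], div, rng)
        planted.append((src, rep_len, dst, div))
    return SyntheticGenome(sequences={name: decode(enc)},
                           planted_repeats=planted)


def simulate_reads(genome: SyntheticGenome, n_reads: int, read_len: int = 80,
                   profile: ErrorProfile | None = None, seed: int = 0
                   ) -> tuple[dict[str, str], list[TruthRecord]]:
    """Draw reads from uniform positions/strands with profile-driven errors.

    Returns (reads, truth): reads as an ordered id -> sequence dict, truth
    as one record per read with the planted error count. Deterministic for
    a fixed seed. Each read uses its own RNG substream keyed by (seed, i),
    so for a fixed seed the read origins are identical across error
    multipliers and the planted error positions are nested as the
    multiplier grows — error batteries at 1x/2x/10x are paired read for
    read.
    """
    profile = profile or ErrorProfile()
    names = list(genome.sequences)
    encs = {n: encode(genome.sequences[n].lower()) for n in names}
    lens = np.array([len(encs[n]) for n in names])
    if (lens < read_len).any():
        raise ValueError("read_len exceeds a sequence length")
    probs = profile.probs(read_len)
    weights = lens / lens.sum()
    reads: dict[str, str] = {}
    truth: list[TruthRecord] = []
    pad = len(str(max(n_reads - 1, 1)))
    for i in range(n_reads):
        rng = np.random.default_rng([seed, i])
        ci = int(rng.choice(len(names), p=weights))
        name = names[ci]
        pos = int(rng.integers(0, lens[ci] - read_len + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        frag = encs[name][pos:pos + read_len].copy()
        if strand == "-":
            frag = revcomp_encoded(frag)
        hit = np.flatnonzero(rng.random(read_len) < probs)
        frag[hit] = (frag[hit] + rng.integers(1, 4, len(hit))) % 4
        rid = f"r{i:0{pad}d}"
        reads[rid] = decode(frag)
        truth.append(TruthRecord(rid, name, pos, strand, len(hit)))
    return reads, truth


def write_fastq(reads: dict[str, str], path: str,
                profile: ErrorProfile | None = None,
                read_len: int | None = None) -> None:
    """Write reads as FASTQ; qualities encode the error profile per position."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    profile = profile or ErrorProfile()
    records = []
    for rid, seq in reads.items():
        p = profile.probs(len(seq))
        quals = np.clip(np.round(-10 * np.log10(np.maximum(p, 1e-4))), 2, 40)
        rec = SeqRecord(Seq(seq.upper()), id=rid, description="")
        rec.letter_annotations["phred_quality"] = [int(q) for q in quals]
        records.append(rec)
    SeqIO.write(records, path, "fastq")


def truth_frame(truth: list[TruthRecord]) -> pd.DataFrame:
    return pd.DataFrame([t.__dict__ for t in truth])


def sliding_min_hamming(read: str, genome: SyntheticGenome | dict[str, str]
                        ) -> tuple[int, list[tuple[str, int, str]]]:
    """Exhaustive scan: minimum full-read Hamming distance over every
    position and strand, with all locations achieving it.

    This is the genome-wide brute-force oracle used both to validate
    map_read and to decide recoverability.
    """
    seqs = genome.sequences if isinstance(genome, SyntheticGenome) else genome
    renc = encode(read.lower())
    rrc = revcomp_encoded(renc)
    L = len(renc)
    best = L + 1
    where: list[tuple[str, int, str]] = []
    for name, s in seqs.items():
        enc = encode(s.lower())
        if len(enc) < L:
            continue
        wins = np.lib.stride_tricks.sliding_window_view(enc, L)
        for strand, q in (("+", renc), ("-", rrc)):
            d = np.count_nonzero(wins != q, axis=1)
            m = int(d.min())
            if m < best:
                best = m
                where = [(name, int(p), strand) for p in np.flatnonzero(d == m)]
            elif m == best:
                where += [(name, int(p), strand) for p in np.flatnonzero(d == m)]
    return best, where


def classify_error(mapping: MappingResult | None, truth: TruthRecord,
                   genome: SyntheticGenome, read: str | None = None,
                   tolerance: int = 0) -> tuple[str, bool]:
    """Label one read's mapping and decide whether it was recoverable.

    Labels: ``correct`` (same chrom/strand, position within ``tolerance``),
    ``skipped`` (no mapping reported), else ``incorrect``. A read is
    *recoverable* iff the full-read distance at its true origin is no worse
    than at the best location genome-wide (brute-force scan; requires the
    read sequence) — the defining property that an exact mapper can still
    return the origin. A read whose errors made another location strictly
    closer is unrecoverable: no exact method can place it correctly.
    """
    correct = (mapping is not None and mapping.status != "unmapped"
               and mapping.chrom == truth.chrom
               and mapping.strand == truth.strand
               and abs(mapping.pos - truth.true_pos) <= tolerance)
    if correct:
        return "correct", True
    label = "skipped" if mapping is None or mapping.status == "unmapped" \
        else "incorrect"
    if read is None:
        return label, True
    best, _ = sliding_min_hamming(read, genome)
    origin = _distance_at(read, truth.chrom, truth.true_pos, truth.strand, genome)
    return label, origin <= best


def _distance_at(read: str, chrom: str, pos: int, strand: str,
                 genome: SyntheticGenome) -> int:
    enc = encode(genome.sequences[chrom].lower())
    renc = encode(read.lower())
    if strand == "-":
        renc = revcomp_encoded(renc)
    ref = enc[pos:pos + len(renc)]
    return int(np.count_nonzero(ref != renc))


def evaluate(mappings: dict[str, MappingResult], truth: list[TruthRecord],
             genome: SyntheticGenome, reads: dict[str, str] | None = None,
             tolerance: int = 0, recoverability: bool = True) -> AccuracyReport:
    """Score mappings against truth; optionally break down skipped/wrong.

    ``accuracy`` is the percent of all reads mapped to their true origin
    (skipped reads count as errors); ``accuracy_mapped`` uses only mapped
    reads as denominator. With ``recoverability`` on (requires ``reads``),
    each skipped or wrong read is brute-force checked genome-wide, giving
    the potential-accuracy breakdown: the share of each subset an exact
    mapper could still place correctly.
    """
    ids = [t.read_id for t in truth]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate read ids in truth")
    extra = set(mappings) - set(ids)
    if extra:
        raise ValueError(f"mappings for unknown read ids: {sorted(extra)[:5]}")

    n_correct = n_incorrect = n_skipped = n_unrec = 0
    skipped_rec = wrong_rec = 0
    skipped_tot = wrong_tot = 0
    for t in truth:
        m = mappings.get(t.read_id)
        correct = (m is not None and m.status != "unmapped"
                   and m.chrom == t.chrom and m.strand == t.strand
                   and abs(m.pos - t.true_pos) <= tolerance)
        if correct:
            n_correct += 1
            continue
        label = "skipped" if m is None or m.status == "unmapped" else "incorrect"
        if label == "skipped":
            n_skipped += 1
            skipped_tot += 1
        else:
            n_incorrect += 1
            wrong_tot += 1
        if recoverability:
            if reads is None:
                raise ValueError("recoverability check requires read sequences")
            read = reads[t.read_id]
            best, _ = sliding_min_hamming(read, genome)
            origin = _distance_at(read, t.chrom, t.true_pos, t.strand, genome)
            recoverable = origin <= best
            if not recoverable:
                n_unrec += 1
            elif label == "skipped":
                skipped_rec += 1
            else:
                wrong_rec += 1

    n = len(truth)
    n_mapped = n - n_skipped
    report = AccuracyReport(
        n_reads=n, n_correct=n_correct, n_incorrect=n_incorrect,
        n_skipped=n_skipped, n_unrecoverable=n_unrec,
        accuracy=100.0 * n_correct / n if n else float("nan"),
        accuracy_mapped=(100.0 * n_correct / n_mapped if n_mapped
                         else float("nan")),
        skipped_total=skipped_tot, wrong_total=wrong_tot)
    if recoverability:
        if skipped_tot:
            report.skipped_potential_accuracy = 100.0 * skipped_rec / skipped_tot
        if wrong_tot:
            report.wrong_potential_accuracy = 100.0 * wrong_rec / wrong_tot
    return report
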