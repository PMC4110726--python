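"""Seed-and-extend read mapping on the APF, and the two-stage rescue ensemble.

The forest indexes fixed-length reference k-mers; to map a longer read it is
split into seeds, each seed is range-queried, every hit is projected to the
full-read reference location it implies, and candidates are scored by
full-read Hamming distance. Because seed queries are exact, a pigeonhole
argument carries the guarantee up to the read level: a read within ``r``
mismatches of some location has at least one of its ``n`` disjoint seeds
within ``floor(r / n)`` mismatches of the corresponding reference k-mer, so
querying every seed at that radius can never miss the optimal location.

The ensemble stage reproduces the two-step pipeline: a fast heuristic
aligner handles confident reads, and any read it left unmapped or placed
with MAPQ below a cutoff (default 14) is re-mapped exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pysam

from ._encoding import INVALID, encode, encode_strict, revcomp_encoded
from .apf import APForest, BuildParams, KmerPoints, build_forest
from .distance import DistanceFn, HammingDistance
from .search import RangeQuery, range_query_forest

__all__ = [
    "ReferenceIndex",
    "load_reference_index",
    "MappingResult",
    "EnsembleParams",
    "extract_kmers",
    "map_read",
    "rescue_pipeline",
    "heuristic_stub_align",
    "write_sam",
    "read_sam_mappings",
]


def extract_kmers(genome: dict[str, str], k: int, stride: int = 1,
                  both_strands: bool = True) -> KmerPoints:
    """All k-mer points of a genome, on one or both strands.

    Windows containing non-ACGT characters (N runs etc.) are skipped. A
    minus-strand point at ``start`` stores the reverse complement of the
    forward window at the same coordinates. For stride 1 on one strand of an
    N-free sequence of length L this yields L - k + 1 points.
    """
    if k < 4:
        raise ValueError("k must be >= 4")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    names = list(genome)
    seqs, cids, starts, strands = [], [], [], []
    for ci, name in enumerate(names):
        enc = encode(genome[name].lower())
        if len(enc) < k:
            import warnings

            warnings.warn(f"sequence {name!r} shorter than k={k}; skipped")
            continue
        wins = np.lib.stride_tricks.sliding_window_view(enc, k)[::stride]
        pos = np.arange(0, len(enc) - k + 1, stride)
        ok = (wins != INVALID).all(axis=1)
        wins, pos = np.ascontiguousarray(wins[ok]), pos[ok]
        if len(wins) == 0:
            continue
        seqs.append(wins)
        cids.append(np.full(len(wins), ci))
        starts.append(pos)
        strands.append(np.zeros(len(wins), dtype=np.int8))
        if both_strands:
            rc = 3 - wins[:, ::-1]
            seqs.append(rc)
            cids.append(np.full(len(wins), ci))
            starts.append(pos)
            strands.append(np.ones(len(wins), dtype=np.int8))
    if not seqs:
        return KmerPoints(np.zeros((0, k), dtype=np.uint8), np.zeros(0),
                          np.zeros(0), np.zeros(0), names)
    return KmerPoints(np.vstack(seqs), np.concatenate(cids),
                      np.concatenate(starts), np.concatenate(strands), names)


class ReferenceIndex:
    """A genome plus the APF built over its k-mers."""

    def __init__(self, genome: dict[str, str], forest: APForest, stride: int = 1):
        self.genome = {n: s.lower() for n, s in genome.items()}
        self.forest = forest
        self.stride = stride
        self._enc = {n: encode(s) for n, s in self.genome.items()}

    @classmethod
    def build(cls, genome: dict[str, str], k: int = 16, stride: int = 1,
              params: BuildParams | None = None,
              distance: DistanceFn | None = None,
              both_strands: bool = True) -> "ReferenceIndex":
        points = extract_kmers(genome, k, stride, both_strands)
        forest = build_forest(points, params or BuildParams(),
                              distance or HammingDistance())
        return cls(genome, forest, stride)

    @property
    def k(self) -> int:
        return self.forest.k

    def encoded(self, chrom: str) -> np.ndarray:
        return self._enc[chrom]

    def save(self, path: str) -> None:
        from .apf import save_forest

        save_forest(self.forest, path, genome=self.genome)


def load_reference_index(path: str) -> ReferenceIndex:
    """Load an index archive written with an embedded reference genome."""
    import json

    from ._encoding import decode
    from .apf import load_forest

    forest = load_forest(path)
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        names = meta.get("genome_names") or []
        if not names:
            raise ValueError(f"{path} has no embedded reference genome")
        flat, off = z["genome_flat"], z["genome_off"]
        genome = {n: decode(flat[off[i]:off[i + 1]])
                  for i, n in enumerate(names)}
    return ReferenceIndex(genome, forest)


@dataclass
class MappingResult:
    """A read's reported location, full-read distance and uniqueness."""

    read_id: str
    chrom: str | None
    pos: int | None  # 0-based leftmost reference position of the read
    strand: str | None
    distance: float | None
    n_candidates: int
    status: str  # unique | tied_random | unmapped
    mapq: int = 0
    reason: str | None = None


@dataclass(frozen=True)
class EnsembleParams:
    """Mapping and rescue parameters.

    ``radius`` is the full-read Hamming budget r; ``seed_radius`` the
    per-seed query radius r', derived as ``floor(r / n_disjoint_seeds)``
    when left None (the pigeonhole-sound choice). ``mapq_cutoff`` is the
    first-stage confidence threshold: records with MAPQ strictly below it
    (or unmapped) are re-mapped exactly.
    """

    mapq_cutoff: int = 14
    radius: int = 6
    seed_radius: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.mapq_cutoff < 0 or self.radius < 0:
            raise ValueError("mapq_cutoff and radius must be >= 0")


def read_rng(seed: int, read_id: str) -> np.random.Generator:
    """Per-read RNG substream keyed by (seed, crc32 of the read id).

    Tie-breaking then depends only on the seed and the read itself, not on
    how many other reads were processed first — batteries that share read
    ids (e.g. the same reads at different error rates) break ties
    identically.
    """
    import zlib

    return np.random.default_rng([seed, zlib.crc32(read_id.encode())])


def _rescued_mapq(best: float, second: float, radius: int) -> int:
    """Monotone confidence from the margin between best and runner-up.

    gap = second_best - best (runner-up taken as radius + 1 when the best
    location is the only candidate); MAPQ = min(42, 6 * gap).
    """
    gap = max(0.0, (second if second is not None else radius + 1) - best)
    return int(min(42, round(6 * gap)))


def map_read(read_id: str, seq: str, index: ReferenceIndex,
             params: EnsembleParams | None = None,
             rng: np.random.Generator | None = None) -> MappingResult:
    """Map one read by exact seed queries plus full-read Hamming extension.

    The read is split into ``floor(L / k)`` non-overlapping seeds (plus, when
    k does not divide L, a final seed covering the last k bases); each seed
    is queried at the per-seed radius, hits are projected to implied
    full-read locations, and the minimum-distance location within the radius
    budget is reported. Ties are broken by a seeded uniform draw and
    flagged; MAPQ is then 0.
    """
    params = params or EnsembleParams()
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    L, k = len(seq), index.k
    if L < k:
        return MappingResult(read_id, None, None, None, None, 0, "unmapped",
                             reason=f"read shorter than seed length {k}")
    seq = seq.lower()
    n_disjoint = L // k
    offsets = [i * k for i in range(n_disjoint)]
    if L % k:
        offsets.append(L - k)
    r_seed = params.seed_radius if params.seed_radius is not None \
        else params.radius // n_disjoint

    renc = encode(seq)
    renc_rc = revcomp_encoded(renc) if not (renc == INVALID).any() else None

    candidates: set[tuple[str, int, str]] = set()
    for off in offsets:
        sub = seq[off:off + k]
        try:
            encode_strict(sub)
        except ValueError:
            continue  # seed contains N etc.; other seeds still cover the read
        res = range_query_forest(index.forest, RangeQuery(sub, r_seed))
        pts = index.forest.points
        for i in res.hit_idx:
            chrom = pts.chrom_names[pts.chrom_ids[i]]
            start = int(pts.starts[i])
            if pts.strands[i] == 0:
                pos, strand = start - off, "+"
            else:
                pos, strand = start - (L - k - off), "-"
            if 0 <= pos and pos + L <= len(index.genome[chrom]):
                candidates.add((chrom, pos, strand))

    if not candidates:
        return MappingResult(read_id, None, None, None, None, 0, "unmapped",
                             reason="no seed hit within radius")

    scored = []
    for chrom, pos, strand in sorted(candidates):
        ref = index.encoded(chrom)[pos:pos + L]
        query = renc if strand == "+" else renc_rc
        if query is None:
            query = renc  # read with ambiguous bases: forward compare only
        d = int(np.count_nonzero(ref != query))
        scored.append((d, chrom, pos, strand))
    scored.sort()
    best = scored[0][0]
    if best > params.radius:
        return MappingResult(read_id, None, None, None, None, len(scored),
                             "unmapped", reason="best candidate beyond radius")
    ties = [s for s in scored if s[0] == best]
    second = scored[len(ties)][0] if len(scored) > len(ties) else None
    if len(ties) > 1:
        d, chrom, pos, strand = ties[int(rng.integers(len(ties)))]
        return MappingResult(read_id, chrom, pos, strand, d, len(ties),
                             "tied_random", mapq=0)
    d, chrom, pos, strand = ties[0]
    return MappingResult(read_id, chrom, pos, strand, d, 1, "unique",
                         mapq=_rescued_mapq(d, second, params.radius))


# ---------------------------------------------------------------------------
# SAM plumbing (pysam-backed)

def _sam_header(genome: dict[str, str], program: str, cl: str,
                seed: int | None = None,
                config_hash: str | None = None) -> pysam.AlignmentHeader:
    head = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": n, "LN": len(s)} for n, s in genome.items()],
        "PG": [{"ID": program, "PN": program, "CL": cl}],
    }
    if seed is not None or config_hash is not None:
        head["CO"] = [f"adam seed={seed} config_hash={config_hash}"]
    return pysam.AlignmentHeader.from_dict(head)


def _to_segment(m: MappingResult, seq: str, header: pysam.AlignmentHeader,
                program: str) -> pysam.AlignedSegment:
    a = pysam.AlignedSegment(header)
    a.query_name = m.read_id
    seq = seq.lower()
    if m.status == "unmapped" or m.chrom is None:
        a.flag = 4
        a.query_sequence = seq.upper()
        a.mapping_quality = 0
        a.set_tag("PG", "adam-rescue" if m.reason == "rescued" else program)
        return a
    a.flag = 16 if m.strand == "-" else 0
    a.reference_id = header.get_tid(m.chrom)
    a.reference_start = m.pos
    a.mapping_quality = int(m.mapq)
    a.cigartuples = [(0, len(seq))]  # Hamming-only alignments: all-match CIGAR
    from ._encoding import revcomp

    a.query_sequence = (revcomp(seq) if m.strand == "-" else seq).upper()
    a.set_tag("NM", int(m.distance))
    # rescued records carry their own program tag so the two stages stay
    # distinguishable in the merged output
    a.set_tag("PG", "adam-rescue" if m.reason == "rescued" else program)
    return a


def write_sam(results: list[MappingResult], reads: dict[str, str],
              genome: dict[str, str], path: str, program: str = "adam",
              cl: str = "adam", seed: int | None = None,
              config_hash: str | None = None) -> None:
    """Write mapping results as a SAM file (one primary record per read)."""
    header = _sam_header(genome, program, cl, seed, config_hash)
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for m in results:
            out.write(_to_segment(m, reads[m.read_id], header, program))


def read_sam_mappings(path: str) -> dict[str, MappingResult]:
    """Parse primary SAM records into MappingResults (unmapped included)."""
    out: dict[str, MappingResult] = {}
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_secondary or rec.is_supplementary:
                continue
            if rec.query_name in out:
                raise ValueError(f"duplicate primary record {rec.query_name!r}")
            if rec.is_unmapped:
                out[rec.query_name] = MappingResult(
                    rec.query_name, None, None, None, None, 0, "unmapped",
                    mapq=0)
            else:
                out[rec.query_name] = MappingResult(
                    rec.query_name, rec.reference_name, rec.reference_start,
                    "-" if rec.is_reverse else "+",
                    rec.get_tag("NM") if rec.has_tag("NM") else None,
                    1, "unique", mapq=rec.mapping_quality)
    return out


def heuristic_stub_align(reads: dict[str, str], genome: dict[str, str],
                         seed_len: int = 22) -> list[MappingResult]:
    """A deliberately error-prone first-stage aligner.

    Exact hashing of the read's leading ``seed_len`` bases against a
    first-hit table of genome k-mers (both strands via the reverse
    complement of the read). Any error inside the leading seed loses the
    read; repeats resolve to whichever copy was hashed first. MAPQ is
    ``max(0, 40 - 5 * mismatches)``, so poor extensions surface as
    low-confidence records — exactly the reads the rescue stage re-maps.
    """
    table: dict[bytes, tuple[str, int]] = {}
    enc_cache = {}
    for name, s in genome.items():
        enc = encode(s.lower())
        enc_cache[name] = enc
        wins = np.lib.stride_tricks.sliding_window_view(enc, seed_len)
        ok = (wins != INVALID).all(axis=1)
        for p in np.flatnonzero(ok):
            key = wins[p].tobytes()
            if key not in table:
                table[key] = (name, int(p))

    out = []
    for rid, seq in reads.items():
        seq = seq.lower()
        L = len(seq)
        renc = encode(seq)
        m = MappingResult(rid, None, None, None, None, 0, "unmapped", mapq=0,
                          reason="no exact seed hit")
        if L >= seed_len and not (renc == INVALID).any():
            rc = revcomp_encoded(renc)
            for strand, q in (("+", renc), ("-", rc)):
                hit = table.get(q[:seed_len].tobytes())
                if hit is None:
                    continue
                chrom, pos = hit
                if pos + L > len(genome[chrom]):
                    continue
                d = int(np.count_nonzero(enc_cache[chrom][pos:pos + L] != q))
                m = MappingResult(rid, chrom, pos, strand, d, 1, "unique",
                                  mapq=max(0, 40 - 5 * d))
                break
        out.append(m)
    return out


def rescue_pipeline(sam_in: str, reads: dict[str, str], index: ReferenceIndex,
                    params: EnsembleParams | None = None) -> list[MappingResult]:
    """Two-stage ensemble: keep confident first-stage records, re-map the rest.

    Reads whose primary record has MAPQ >= the cutoff pass through
    untouched; the uncertain set R' (MAPQ strictly below the cutoff, or
    unmapped) is re-mapped with :func:`map_read`. Read ids present in the
    SAM but absent from ``reads`` raise; every read appears exactly once in
    the output.
    """
    params = params or EnsembleParams()
    first = read_sam_mappings(sam_in)
    missing = set(first) - set(reads)
    if missing:
        raise ValueError(f"SAM read ids absent from reads: {sorted(missing)[:5]}")
    out: list[MappingResult] = []
    for rid in reads:
        rec = first.get(rid)
        if rec is None or rec.status == "unmapped" or rec.mapq < params.mapq_cutoff:
            remapped = map_read(rid, reads[rid], index, params,
                                read_rng(params.seed, rid))
            remapped.reason = "rescued"
            out.append(remapped)
        else:
            out.append(rec)
    return out
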