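# Methods

## The problem

Heuristic short-read mappers trade accuracy for speed: a read whose errors
defeat the seeding heuristic is reported at the wrong locus or not at all,
even when its true origin is still the globally best-scoring location. This
package implements the opposite trade — an *exact* range query over genomic
k-mers — and uses it where it pays: as a second stage that re-maps only the
reads a fast first-stage aligner handled badly.

## The index: an Adaptive Projection Forest

The APF is an excluded-middle, multi-pivot vantage-point forest over the set
of k-mers of a reference genome (both strands, minus-strand k-mers stored as
reverse complements at the same coordinates).

**Node construction.** At each node, pivots p_0..p_{d-1} are chosen one at a
time (see pivot strategies below) and removed from the point set. For each
pivot, the *upper median* dm(p_j) of the remaining points' distances — the
element at index ⌊n/2⌋ of the sorted distance multiset — is the partition
boundary. A band of half-width τ around each median is *excluded*: a point
with dm(p_j) − τ ≤ d(x, p_j) < dm(p_j) + τ for **some** pivot j is withheld
from every child and deferred. Points that survive exclusion are routed to
one of 2^d children by a bit label: bit j is 0 iff d(x, p_j) < dm(p_j), 1
otherwise. Recursion stops when a set has at most `leaf_size` points
(default 32), when all remaining points are identical, or when the band
swallowed everything (the node is then rejected and kept whole as a leaf).
The half-open band convention makes τ = 0 degenerate cleanly into a plain
median split with empty exclusion.

**Forest formation.** All exclusion sets produced anywhere in a tree are
pooled and become the input of the next tree; the process repeats until the
pool is empty. Every input point is therefore stored exactly once, either
as a pivot of an internal node or inside a leaf — a conservation invariant
the tests recheck on every build.

**Union vs intersection exclusion.** The per-pivot band combined by union
is the convention under which band-aware traversal (below) is exact; it is
the default. An `exclusion_mode="intersection"` variant (excluded only when
inside *every* pivot's band) is also provided; adding pivots then shrinks
the excluded set, at the price of a conservative traversal that splits at
the median and ignores the band. A consequence of the union convention is
that adding pivots can only grow the excluded set, so the pivot-addition
loop ("add a pivot while the exclusion fraction exceeds m, up to D") acts
as a branching-factor control rather than an exclusion reducer: a node ends
with one pivot if the first already satisfies m, and with D pivots
otherwise. The invariant "exclusion fraction ≤ m or d = D" holds at every
internal node either way.

**Parameters.**

| parameter | meaning | default |
|---|---|---|
| τ | exclusion half-width, distance units; `"auto"` derives per node the largest integer keeping the exclusion fraction ≤ m | 2 |
| m | ceiling on the excluded fraction of a node's points | 0.1 |
| D | max pivots per node (2^d children) | 4 |
| leaf_size | recursion stop | 32 |
| pivot_strategy | optimal / random / poor | optimal |
| seed | build RNG (first pivots, random strategy) | 0 |

**Pivot strategies.** `optimal` takes the next pivot at the (upper) median
distance from the previous one — on distance distributions concentrated
around their median this imitates choosing a direction of high variance
without a PCA-scale computation; `random` draws uniformly; `poor`
deliberately takes the closest point to the previous pivot (near-duplicate
pivots carry almost no information, the worst case). The first pivot is
always a seeded uniform draw. Ties in optimal/poor are broken by the lowest
(chrom, start, strand) triple for determinism. On a fixed random 8-mer
dataset the mean distance calls per query order as optimal ≤ random ≤ poor
(a seeded regression property; the margin between optimal and random is
small on uniform data, the margin to poor is large).

## Distances

The default distance is unweighted Hamming (integer-valued); the mapper
supports only Hamming alignments. A `WeightScheme` (transition vs
transversion costs, pairing configurable, biological a↔g / c↔t by default)
is validated at construction against the metric axioms over the 4-letter
alphabet — index exactness rests on the triangle inequality, so
non-metric weights are rejected outright. A banded Needleman–Wunsch
distance (DP restricted to ±band of the diagonal) is provided for
completeness; whether a given banded cost scheme keeps the triangle
inequality is not guaranteed, so constructing it warns and
`check_metric_axioms` can probe a sample empirically.

The expected Hamming ball B(k, r) = Σ_{i=1..r} C(k,i)·(n−1)^i counts the
distinct strings within radius r of a k-mer over an n-letter alphabet;
B(k, k) = n^k − 1.

## Querying

For query q and radius r, each tree is traversed top-down. At a node the d
query–pivot distances are computed once; per pivot, the low child side is
needed iff d(q,p_j) − r < dm − τ and the high side iff d(q,p_j) + r ≥
dm + τ; the visited children are the Cartesian product of needed sides. A
query interval falling entirely inside a band needs, strictly, no side —
the matching points were excluded into a later tree — but one side (the
exact-query side) is still descended, which costs a little and can never
lose a hit. Pivots are real index points and are tested for membership at
their own node from the already-computed distances. Leaves are scanned
with one vectorised comparison. Results from all trees are unioned; a
skip-marker for later trees is deliberately not implemented (exclusion
pools from the whole build are combined, so the skip condition essentially
never triggers).

The exactness contract — hits are exactly {t : d(q,t) ≤ r}, for any r,
including r > τ — is exercised against a brute-force scan over randomized
builds spanning τ ∈ {0,1,2}, D ∈ {1,2,4}, r ∈ {0..6} (>1000 build/query
instances). Every result carries the number of distance evaluations
performed, the standard cost measure for metric indexes, verified in tests
with a counting wrapper.

## Read mapping and the rescue ensemble

Reads are mapped seed-and-extend: split into ⌊L/k⌋ non-overlapping k-long
seeds (plus, when k ∤ L, a final seed over the last k bases so every base is
covered), each seed range-queried at radius r′ = ⌊r / ⌊L/k⌋⌋, every hit
projected to the full-read location it implies, and candidates scored by
full-read Hamming distance against the reference. By pigeonhole, a read
within r mismatches of some location has at least one disjoint seed within
r′ of the corresponding reference k-mer, so the optimal location within the
budget is never missed. Defaults k = 16, r = 6 for 80-bp reads give r′ = 1.
Co-optimal locations are broken by a seeded uniform draw (flagged, MAPQ 0,
count recorded); the per-read RNG is keyed by (seed, crc32(read id)) so tie
decisions depend only on the seed and the read, not on batch order. Unique
hits get MAPQ = min(42, 6·gap) where gap is the margin to the runner-up
(radius + 1 when there is none) — a simple documented monotone confidence.

The ensemble stage reads any first-stage SAM: records with MAPQ ≥ a cutoff
(default 14) pass through untouched; unmapped or low-confidence reads are
re-mapped exactly and tagged `adam-rescue`. For end-to-end testing without
external binaries, `heuristic_stub_align` is a deliberately fragile
first-stage aligner: exact hashing of the read's leading 22 bases with
first-hit reporting, MAPQ = max(0, 40 − 5·mismatches). Any error in the
leading seed loses the read and repeats resolve to whichever copy was
hashed first — the two first-stage failure modes the rescue is meant to
repair.

## The simulator

`simulate_genome` draws a uniform ACGT background and plants duplications
(source interval copied elsewhere with per-base divergence) — repeats are
the feature that creates ties and unrecoverable reads. `simulate_reads`
draws uniform positions and strands and substitutes bases with a
position-dependent probability: a linear ramp from 0.001 (read start) to
0.01 (position 80), scaled by a multiplier (1x/2x/10x) and capped at 0.75.
Each read uses an RNG substream keyed by (seed, read index), so for a fixed
seed the batteries at different multipliers are paired read-for-read with
nested error sets. Only substitutions are simulated, matching the
Hamming-only mapper.

What the generator does *not* emulate: real base-composition bias, indels,
quality-score miscalibration, coverage bias, and chromosome-scale repeat
structure. Passing tests therefore demonstrate the algorithmic guarantees
(exactness, the pigeonhole seed bound, the rescue direction) on controlled
data, not calibrated accuracy on real libraries.

`evaluate` scores mappings against truth: correct requires same chromosome,
strand and position (tolerance 0 by default, configurable); unmapped reads
count as errors in `accuracy` and are excluded in `accuracy_mapped` (both
conventions are reported). A wrong or skipped read is *recoverable* iff a
brute-force genome-wide scan confirms its true origin is still no worse
than the best alternative — the share of recoverable reads in each subset
is the "potential accuracy" an exact mapper can realise; a read whose
errors made another locus strictly closer is unrecoverable by any exact
method.

## Why combined-pipeline accuracy is not asserted monotone between 1x and 2x

With paired batteries the first-stage accuracy is structurally
non-increasing in the multiplier: a read it loses at 1x it also loses at
2x. The combined pipeline has no such guarantee: a first-stage record that
is confidently wrong (repeat-copy placement with MAPQ above the cutoff)
passes through at a low error rate, while at a higher rate the same read's
extra errors can push its MAPQ under the cutoff, sending it to the exact
stage which corrects it — more noise can mean more rescue. In a measured
battery this produced a ~0.2-point inversion between 1x and 2x. The tests
therefore assert first-stage monotonicity, the strict 10x rescue gain, and
the combined direction against 10x, where error-driven loss dominates.

## Problem sizes and numerical choices

Scaled-down batteries (the package's own choices): a 1 Mb genome / 200
error-free reads for the read-level guarantee; 60 kb / 200 reads at 10x for
the sliding-window oracle comparison; 150 kb with one exact 1.5 kb and one
2%-diverged 2 kb duplication / 1200 reads per multiplier for the ensemble;
400-point 8-mer sets for the exactness battery; 1000 16-mers (D = 1) for
the τ–forest-size direction; 4000 8-mers, 150 queries, three builds per
strategy for the pivot ordering. Degenerate inputs: all-identical point
sets and fully-excluded nodes collapse to leaves; duplicate (chrom, start,
strand) origins are rejected at build; identical sequences at distinct loci
are allowed and retrieved independently. All randomness flows from explicit
seeds; builds and mapping runs are byte-reproducible.

## Limitations

Gapped alignment, paired-end reads, and base-quality-aware scoring are out
of scope. The index is held in memory (a 1 Mb genome, both strands, k = 16
is ~2M points); building is vectorised but single-threaded — the forest's
tree list is the natural unit of parallelism, but scheduling is not
implemented. MAPQ from the exact stage is a documented heuristic, not a
calibrated error probability.
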