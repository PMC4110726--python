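"""The Adaptive Projection Forest: an exact metric-space index over k-mers.

An AP-tree generalises the excluded-middle vantage-point tree. Each internal
node holds up to ``D`` pivots; for each pivot the median distance ``dm`` of
the node's points splits the space, and a band of half-width ``tau`` around
each median is *excluded* — withheld from every child and deferred to the
next tree of the forest. Points surviving exclusion are routed to one of
``2^d`` children by a bit label (bit ``j`` set iff the point lies at or above
the median of pivot ``j``). Building trees from successive exclusion pools
yields an ordered forest in which every input point is stored exactly once,
either as a pivot of an internal node or inside a leaf.

Excluding the middle is what makes range queries cheap: a query ball of
radius ``r <= tau`` can never straddle a median without falling entirely
inside an excluded band, so at most one child per pivot needs visiting.
Exactness does not depend on ``r <= tau`` — wider queries simply descend
into more children (see :mod:`adam.search`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from ._encoding import decode, encode_strict
from .distance import DistanceFn, HammingDistance, WeightScheme

__all__ = [
    "KmerPoint",
    "KmerPoints",
    "BuildParams",
    "APNode",
    "APTree",
    "APForest",
    "ForestStats",
    "select_pivot",
    "partition_node",
    "child_label",
    "build_tree",
    "build_forest",
    "forest_stats",
    "save_forest",
    "load_forest",
]


@dataclass(frozen=True, order=True)
class KmerPoint:
    """An indexed k-mer and its genomic origin."""

    chrom: str
    start: int
    strand: str  # '+' or '-'
    seq: str

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


class KmerPoints:
    """Column-oriented store for a set of equal-length k-mers.

    Sequences live in one ``(N, k)`` uint8 matrix so that node construction
    and leaf scans are single vectorised comparisons; genomic origins are
    parallel arrays. Individual :class:`KmerPoint` views are materialised on
    demand.
    """

    def __init__(self, seqs: np.ndarray, chrom_ids: np.ndarray,
                 starts: np.ndarray, strands: np.ndarray,
                 chrom_names: list[str]):
        if seqs.ndim != 2:
            raise ValueError("seqs must be a 2-D matrix of encoded k-mers")
        self.seqs = np.ascontiguousarray(seqs, dtype=np.uint8)
        self.chrom_ids = np.asarray(chrom_ids, dtype=np.int32)
        self.starts = np.asarray(starts, dtype=np.int64)
        self.strands = np.asarray(strands, dtype=np.int8)  # 0 = '+', 1 = '-'
        self.chrom_names = list(chrom_names)

    @classmethod
    def from_records(cls, records: list[KmerPoint]) -> "KmerPoints":
        if not records:
            raise ValueError("empty point set")
        k = len(records[0].seq)
        if any(len(r.seq) != k for r in records):
            raise ValueError("all k-mers must have the same length")
        names: list[str] = []
        name_id: dict[str, int] = {}
        rows, cids, starts, strands = [], [], [], []
        for r in records:
            if r.chrom not in name_id:
                name_id[r.chrom] = len(names)
                names.append(r.chrom)
            rows.append(encode_strict(r.seq))
            cids.append(name_id[r.chrom])
            starts.append(r.start)
            strands.append(0 if r.strand == "+" else 1)
        return cls(np.vstack(rows), np.array(cids), np.array(starts),
                   np.array(strands), names)

    @property
    def k(self) -> int:
        return self.seqs.shape[1]

    def __len__(self) -> int:
        return self.seqs.shape[0]

    def point(self, i: int) -> KmerPoint:
        return KmerPoint(
            chrom=self.chrom_names[self.chrom_ids[i]],
            start=int(self.starts[i]),
            strand="+" if self.strands[i] == 0 else "-",
            seq=decode(self.seqs[i]),
        )

    def origin_key(self) -> np.ndarray:
        """One int64 per point encoding (chrom, start, strand), for dedup."""
        return (self.chrom_ids.astype(np.int64) << 42) | \
               (self.starts.astype(np.int64) << 1) | self.strands.astype(np.int64)


@dataclass(frozen=True)
class BuildParams:
    """Index construction parameters.

    tau
        Half-width of the exclusion band, in distance units, or ``"auto"``
        to derive per node the largest integer whose exclusion fraction
        stays within ``m``.
    m
        Ceiling on the fraction of a node's points falling in the exclusion
        region; when exceeded additional pivots are added, up to ``D``.
    D
        Maximum pivots per node (an internal node with d pivots has 2^d
        children).
    leaf_size
        Recursion stops once a point set has at most this many points.
    pivot_strategy
        ``optimal`` (next pivot at the median distance from the previous),
        ``random``, or ``poor`` (closest point to the previous pivot).
    exclusion_mode
        ``union`` (a point is excluded if it falls in *any* pivot's band;
        the default, under which band-aware traversal is exact) or
        ``intersection`` (excluded only if within every pivot's band;
        traversal then conservatively splits at the median, ignoring tau).
    """

    tau: int | str = 2
    m: float = 0.1
    D: int = 4
    leaf_size: int = 32
    pivot_strategy: str = "optimal"
    seed: int = 0
    exclusion_mode: str = "union"

    def __post_init__(self):
        if self.tau != "auto":
            if int(self.tau) < 0:
                raise ValueError("tau must be >= 0 or 'auto'")
        if not 0.0 <= float(self.m) < 1.0:
            raise ValueError("m must be in [0, 1)")
        if self.D < 1 or self.leaf_size < 1:
            raise ValueError("D and leaf_size must be >= 1")
        if self.pivot_strategy not in ("optimal", "random", "poor"):
            raise ValueError(f"unknown pivot strategy {self.pivot_strategy!r}")
        if self.exclusion_mode not in ("union", "intersection"):
            raise ValueError(f"unknown exclusion mode {self.exclusion_mode!r}")


@dataclass
class APNode:
    """One node of an AP-tree (internal multi-pivot node or leaf)."""

    is_leaf: bool
    leaf_idx: np.ndarray | None = None          # leaves: global point indices
    pivot_idx: np.ndarray | None = None          # internal: global indices, p_0..p_{d-1}
    medians: np.ndarray | None = None            # per-pivot median distance dm(p_j)
    tau_node: int = 0                            # exclusion half-width applied here
    m_node: float = 0.0                          # realised exclusion fraction
    children: list["APNode | None"] | None = None  # 2^d slots, Example-1 ordering

    @property
    def d(self) -> int:
        return 0 if self.is_leaf else len(self.pivot_idx)


@dataclass
class APTree:
    root: APNode
    size: int  # points stored in this tree (node pivots + leaf points)


@dataclass
class APForest:
    """Ordered list of AP-trees; tree i+1 indexes the exclusion pool of tree i."""

    trees: list[APTree]
    points: KmerPoints
    distance: DistanceFn
    params: BuildParams
    total: int

    @property
    def k(self) -> int:
        return self.points.k


def child_label(point_distances, medians) -> int:
    """Child index for a point from its per-pivot distances.

    Bit ``j`` of the label is 0 iff the distance to pivot ``p_j`` is strictly
    below that pivot's median, and 1 otherwise (>= goes high). With 4 pivots,
    child 13 therefore reads 1101 as the digit string p3 p2 p1 p0.
    """
    if len(point_distances) != len(medians):
        raise ValueError("need one distance per pivot")
    label = 0
    for j, (dist, dm) in enumerate(zip(point_distances, medians)):
        if dist >= dm:
            label |= 1 << j
    return label


def _upper_median(values: np.ndarray):
    return np.sort(values)[len(values) // 2]


def _lowest_origin(points: KmerPoints, candidates: np.ndarray) -> int:
    """Deterministic tie-break: lowest (chrom, start, strand) triple."""
    order = np.lexsort((points.strands[candidates],
                        points.starts[candidates],
                        points.chrom_ids[candidates]))
    return int(candidates[order[0]])


def _select_pos(points: KmerPoints, rem: np.ndarray, dist_prev: np.ndarray | None,
                strategy: str, rng: np.random.Generator) -> int:
    """Position within ``rem`` of the next pivot."""
    if strategy == "random" or dist_prev is None:
        return int(rng.integers(len(rem)))
    if strategy == "optimal":
        target = _upper_median(dist_prev)
        cand = np.flatnonzero(dist_prev == target)
    else:  # poor: closest to the previous pivot, excluding distance-0 twins
        nz = dist_prev[dist_prev > 0]
        if len(nz) == 0:
            cand = np.arange(len(rem))
        else:
            cand = np.flatnonzero(dist_prev == nz.min())
    best = _lowest_origin(points, rem[cand])
    return int(np.flatnonzero(rem == best)[0])


def select_pivot(points: KmerPoints, strategy: str,
                 prev_pivot: KmerPoint | None = None,
                 rng: np.random.Generator | None = None,
                 distance: DistanceFn | None = None) -> KmerPoint:
    """Select the next pivot from a point set.

    ``optimal`` picks a point at the (upper) median distance from
    ``prev_pivot``, ``random`` draws uniformly, ``poor`` picks the closest
    point to ``prev_pivot``. The first pivot (no ``prev_pivot``) is a random
    draw for every strategy.
    """
    if len(points) == 0:
        raise ValueError("cannot select a pivot from an empty point set")
    rng = rng if rng is not None else np.random.default_rng()
    distance = distance if distance is not None else HammingDistance()
    rem = np.arange(len(points))
    dist_prev = None
    if prev_pivot is not None and strategy != "random":
        dist_prev = distance.batch(points.seqs, encode_strict(prev_pivot.seq))
    pos = _select_pos(points, rem, dist_prev, strategy, rng)
    return points.point(pos)


def _exclusion_mask(drows: list[np.ndarray], medians: list, tau: int,
                    mode: str) -> np.ndarray:
    """Band membership dm - tau <= d < dm + tau, combined across pivots."""
    masks = [(r >= dm - tau) & (r < dm + tau) for r, dm in zip(drows, medians)]
    out = masks[0]
    for m_ in masks[1:]:
        out = (out | m_) if mode == "union" else (out & m_)
    return out


def _derive_tau(drows, medians, m: float, mode: str, k: int) -> int:
    """Largest integer tau whose exclusion fraction stays within m."""
    n = len(drows[0])
    tau = 0
    while tau < k:
        frac = _exclusion_mask(drows, medians, tau + 1, mode).sum() / n
        if frac > m:
            break
        tau += 1
    return tau


def _partition(points: KmerPoints, idx: np.ndarray, params: BuildParams,
               distance: DistanceFn, rng: np.random.Generator):
    """Partition one node's point set.

    Returns ``(node, child_index_arrays, excluded_idx)``; ``node`` may come
    back as a leaf when the set is degenerate (all points identical, or the
    exclusion band swallowed everything — the node is then rejected and its
    points kept together).
    """
    rem = idx.copy()
    drows: list[np.ndarray] = []
    pivot_idx: list[int] = []
    medians: list = []
    tau_node = 0
    m_node = 0.0
    excl = np.zeros(0, dtype=bool)

    while True:
        if not pivot_idx or params.pivot_strategy == "random":
            ppos = int(rng.integers(len(rem)))
        else:
            ppos = _select_pos(points, rem, drows[-1], params.pivot_strategy, rng)
        pglob = int(rem[ppos])
        pivot_idx.append(pglob)
        rem = np.delete(rem, ppos)
        drows = [np.delete(r, ppos) for r in drows]
        if len(rem) < 2:
            # not enough points left to split meaningfully
            return APNode(is_leaf=True, leaf_idx=idx), None, None
        drows.append(distance.batch(points.seqs[rem], points.seqs[pglob]))
        if len(pivot_idx) == 1 and drows[0].max() == 0:
            # all remaining points identical to the pivot
            return APNode(is_leaf=True, leaf_idx=idx), None, None
        medians = [_upper_median(r) for r in drows]
        if params.tau == "auto":
            tau_node = _derive_tau(drows, medians, params.m,
                                   params.exclusion_mode, points.k)
        else:
            tau_node = int(params.tau)
        excl = _exclusion_mask(drows, medians, tau_node, params.exclusion_mode)
        m_node = excl.sum() / len(rem)
        if m_node <= params.m or len(pivot_idx) == params.D:
            break

    if m_node >= 1.0:
        # every point fell in the exclusion band: reject the node
        return APNode(is_leaf=True, leaf_idx=idx), None, None

    d = len(pivot_idx)
    keep = ~excl
    labels = np.zeros(len(rem), dtype=np.int64)
    for j, (row, dm) in enumerate(zip(drows, medians)):
        labels |= (row >= dm).astype(np.int64) << j
    children_idx = [rem[keep & (labels == c)] for c in range(2 ** d)]
    node = APNode(is_leaf=False,
                  pivot_idx=np.array(pivot_idx, dtype=np.int64),
                  medians=np.array(medians),
                  tau_node=tau_node, m_node=float(m_node),
                  children=[None] * (2 ** d))
    return node, children_idx, rem[excl]


def partition_node(points: KmerPoints, params: BuildParams,
                   distance: DistanceFn | None = None,
                   rng: np.random.Generator | None = None,
                   idx: np.ndarray | None = None):
    """Single-node partition (exposed for inspection; see :func:`build_tree`).

    Returns ``(node, excluded_idx)`` where ``excluded_idx`` are the global
    indices withheld from all children.
    """
    distance = distance if distance is not None else HammingDistance()
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    idx = idx if idx is not None else np.arange(len(points))
    node, children_idx, excl = _partition(points, idx, params, distance, rng)
    if node.is_leaf:
        return node, np.zeros(0, dtype=np.int64)
    for c, cidx in enumerate(children_idx):
        if len(cidx):
            node.children[c] = APNode(is_leaf=True, leaf_idx=cidx)
    return node, excl


def build_tree(points: KmerPoints, params: BuildParams,
               distance: DistanceFn | None = None,
               rng: np.random.Generator | None = None,
               idx: np.ndarray | None = None):
    """Build one AP-tree; returns ``(tree, exclusion_pool)``.

    The pool is the union of every exclusion set produced anywhere in the
    tree, in build order; it seeds the next tree of the forest.
    """
    distance = distance if distance is not None else HammingDistance()
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    idx = idx if idx is not None else np.arange(len(points))
    if len(idx) == 0:
        raise ValueError("cannot build a tree from an empty point set")

    pools: list[np.ndarray] = []
    root = _build_node(points, idx, params, distance, rng, pools)
    pool = np.concatenate(pools) if pools else np.zeros(0, dtype=np.int64)
    return APTree(root=root, size=len(idx) - len(pool)), pool


def _build_node(points, idx, params, distance, rng, pools) -> APNode:
    # explicit stack: (parent, slot, idx); avoids recursion-depth limits on
    # adversarially unbalanced inputs
    sentinel = APNode(is_leaf=False, pivot_idx=np.zeros(0, dtype=np.int64),
                      medians=np.zeros(0), children=[None])
    stack = [(sentinel, 0, idx)]
    while stack:
        parent, slot, sub = stack.pop()
        if len(sub) <= params.leaf_size:
            parent.children[slot] = APNode(is_leaf=True, leaf_idx=sub)
            continue
        node, children_idx, excl = _partition(points, sub, params, distance, rng)
        parent.children[slot] = node
        if node.is_leaf:
            continue
        if len(excl):
            pools.append(excl)
        for c, cidx in enumerate(children_idx):
            if len(cidx):
                stack.append((node, c, cidx))
    return sentinel.children[0]


def build_forest(points: KmerPoints, params: BuildParams | None = None,
                 distance: DistanceFn | None = None) -> APForest:
    """Build the full forest: successive trees over successive exclusion pools.

    Deterministic for a fixed ``params.seed``. Duplicate (chrom, start,
    strand) origins are rejected; identical sequences at different loci are
    allowed and retrieved independently.
    """
    params = params if params is not None else BuildParams()
    distance = distance if distance is not None else HammingDistance()
    if len(points) == 0:
        raise ValueError("cannot index an empty point set")
    keys = points.origin_key()
    if len(np.unique(keys)) != len(keys):
        raise ValueError("duplicate (chrom, start, strand) points in input")

    rng = np.random.default_rng(params.seed)
    trees: list[APTree] = []
    pool = np.arange(len(points), dtype=np.int64)
    while len(pool):
        tree, pool = build_tree(points, params, distance, rng, idx=pool)
        trees.append(tree)
    return APForest(trees=trees, points=points, distance=distance,
                    params=params, total=len(points))


@dataclass
class ForestStats:
    trees: int
    nodes: int
    pivots: int
    leaf_points: int
    total: int
    depth: int
    tree_sizes: list[int] = field(default_factory=list)
    node_exclusions: list[tuple[int, int, float]] = field(default_factory=list)
    # (n_pivots, tau_node, realised m) per internal node


def forest_stats(forest: APForest) -> ForestStats:
    """Structural summary; recomputed from the stored nodes."""
    stats = ForestStats(trees=len(forest.trees), nodes=0, pivots=0,
                        leaf_points=0, total=forest.total, depth=0,
                        tree_sizes=[t.size for t in forest.trees])
    for tree in forest.trees:
        stack = [(tree.root, 0)]
        while stack:
            node, depth = stack.pop()
            stats.nodes += 1
            stats.depth = max(stats.depth, depth)
            if node.is_leaf:
                stats.leaf_points += len(node.leaf_idx)
            else:
                stats.pivots += node.d
                stats.node_exclusions.append(
                    (node.d, node.tau_node, node.m_node))
                for child in node.children:
                    if child is not None:
                        stack.append((child, depth + 1))
    return stats


# ---------------------------------------------------------------------------
# serialization: a single .npz archive holding the point table, flattened
# node records, and a JSON metadata blob; round-trip reproduces identical
# query results.

def _distance_info(distance: DistanceFn) -> dict:
    from .distance import BandedNWDistance

    if isinstance(distance, HammingDistance):
        if distance.weights is None:
            return {"type": "hamming"}
        w = distance.weights
        return {"type": "weighted_hamming", "transition": w.transition_cost,
                "transversion": w.transversion_cost,
                "transitions": [list(p) for p in w.transitions]}
    if isinstance(distance, BandedNWDistance):
        return {"type": "banded_nw", "band": distance.band,
                "match": distance.match, "mismatch": distance.mismatch,
                "gap": distance.gap}
    raise ValueError(f"cannot serialise distance {distance.name!r}")


def _distance_from_info(info: dict) -> DistanceFn:
    import warnings

    from .distance import BandedNWDistance

    if info["type"] == "hamming":
        return HammingDistance()
    if info["type"] == "weighted_hamming":
        return HammingDistance(WeightScheme(
            info["transition"], info["transversion"],
            tuple(tuple(p) for p in info["transitions"])))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return BandedNWDistance(info["band"], info["match"], info["mismatch"],
                                info["gap"])


def save_forest(forest: APForest, path: str,
                genome: dict[str, str] | None = None) -> None:
    """Write the forest to a single compressed ``.npz`` archive.

    ``genome`` optionally embeds the reference sequences so a mapper can be
    reconstituted from the archive alone (see ``mapper.load_reference_index``).
    """
    nodes: list[APNode] = []
    node_tree: list[int] = []
    # iterative preorder flatten (tolerates arbitrarily deep trees)
    ids: dict[int, int] = {}
    for t_i, tree in enumerate(forest.trees):
        stack = [tree.root]
        while stack:
            node = stack.pop()
            ids[id(node)] = len(nodes)
            nodes.append(node)
            node_tree.append(t_i)
            if not node.is_leaf:
                stack.extend(c for c in reversed(node.children) if c is not None)

    is_leaf = np.array([n.is_leaf for n in nodes], dtype=bool)
    tau = np.array([n.tau_node for n in nodes], dtype=np.int64)
    m_node = np.array([n.m_node for n in nodes], dtype=np.float64)
    pivot_flat, pivot_off = [], [0]
    median_flat = []
    child_flat, child_off = [], [0]
    leaf_flat, leaf_off = [], [0]
    for n in nodes:
        if n.is_leaf:
            leaf_flat.append(n.leaf_idx)
        else:
            pivot_flat.append(n.pivot_idx)
            median_flat.append(np.asarray(n.medians, dtype=np.float64))
            child_flat.append(np.array(
                [-1 if c is None else ids[id(c)] for c in n.children],
                dtype=np.int64))
        pivot_off.append(pivot_off[-1] + (0 if n.is_leaf else n.d))
        child_off.append(child_off[-1] + (0 if n.is_leaf else len(n.children)))
        leaf_off.append(leaf_off[-1] + (len(n.leaf_idx) if n.is_leaf else 0))

    meta = {
        "format": "adam-apf-index",
        "version": 1,
        "k": forest.k,
        "total": forest.total,
        "chrom_names": forest.points.chrom_names,
        "params": {**forest.params.__dict__},
        "distance": _distance_info(forest.distance),
        "tree_sizes": [t.size for t in forest.trees],
        "genome_names": list(genome) if genome else [],
    }
    extra = {}
    if genome:
        from ._encoding import encode

        encs = [encode(genome[n].lower()) for n in genome]
        extra["genome_flat"] = np.concatenate(encs)
        extra["genome_off"] = np.cumsum([0] + [len(e) for e in encs])
    np.savez_compressed(
        path,
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        seqs=forest.points.seqs,
        chrom_ids=forest.points.chrom_ids,
        starts=forest.points.starts,
        strands=forest.points.strands,
        node_tree=np.array(node_tree, dtype=np.int64),
        is_leaf=is_leaf, tau=tau, m_node=m_node,
        pivot_flat=(np.concatenate(pivot_flat) if pivot_flat
                    else np.zeros(0, dtype=np.int64)),
        median_flat=(np.concatenate(median_flat) if median_flat
                     else np.zeros(0)),
        pivot_off=np.array(pivot_off, dtype=np.int64),
        child_flat=(np.concatenate(child_flat) if child_flat
                    else np.zeros(0, dtype=np.int64)),
        child_off=np.array(child_off, dtype=np.int64),
        leaf_flat=(np.concatenate(leaf_flat) if leaf_flat
                   else np.zeros(0, dtype=np.int64)),
        leaf_off=np.array(leaf_off, dtype=np.int64),
        **extra,
    )


def load_forest(path: str) -> APForest:
    """Load a forest written by :func:`save_forest`."""
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        if meta.get("format") != "adam-apf-index":
            raise ValueError(f"{path} is not an APF index archive")
        points = KmerPoints(z["seqs"], z["chrom_ids"], z["starts"],
                            z["strands"], meta["chrom_names"])
        params = BuildParams(**meta["params"])
        distance = _distance_from_info(meta["distance"])

        n_nodes = len(z["is_leaf"])
        is_leaf, tau, m_node = z["is_leaf"], z["tau"], z["m_node"]
        pivot_off, child_off, leaf_off = z["pivot_off"], z["child_off"], z["leaf_off"]
        pivot_flat, median_flat = z["pivot_flat"], z["median_flat"]
        child_flat, leaf_flat = z["child_flat"], z["leaf_flat"]
        node_tree = z["node_tree"]

        nodes: list[APNode] = [None] * n_nodes  # type: ignore[list-item]
        for i in range(n_nodes - 1, -1, -1):
            if is_leaf[i]:
                nodes[i] = APNode(is_leaf=True,
                                  leaf_idx=leaf_flat[leaf_off[i]:leaf_off[i + 1]])
            else:
                kids = child_flat[child_off[i]:child_off[i + 1]]
                nodes[i] = APNode(
                    is_leaf=False,
                    pivot_idx=pivot_flat[pivot_off[i]:pivot_off[i + 1]],
                    medians=median_flat[pivot_off[i]:pivot_off[i + 1]],
                    tau_node=int(tau[i]), m_node=float(m_node[i]),
                    children=[None if c < 0 else nodes[c] for c in kids])
        trees = []
        for t_i, size in enumerate(meta["tree_sizes"]):
            root_id = int(np.flatnonzero(node_tree == t_i)[0])
            trees.append(APTree(root=nodes[root_id], size=size))
    return APForest(trees=trees, points=points, distance=distance,
                    params=params, total=meta["total"])
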