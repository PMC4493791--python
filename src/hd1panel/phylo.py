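"""Distance-based phylogenetics for allele panels.

Kimura two-parameter (K2P) distances with indel/ambiguity columns ignored,
Saitou & Nei Neighbor-Joining, nonparametric bootstrap supports, outgroup
rooting, and the two-clade locus partition used to separate the functional
locus from its pseudogenized duplicate.

The K2P distance separates transition (P) and transversion (Q) fractions:

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

Neighbor-Joining is exact on additive distance matrices: path lengths on the
returned (unrooted) tree reproduce the input distances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}
_SKIP = {"-", "N"}


class SaturationError(ValueError):
    """K2P distance undefined: substitution fractions beyond the formula's domain."""


# ---------------------------------------------------------------------------
# distances


def k2p_distance(seq_a: str, seq_b: str) -> float:
    """Kimura two-parameter distance between two aligned sequences.

    Columns where either sequence has a gap or N are dropped (pairwise
    deletion, i.e. indels are ignored).  Raises ``SaturationError`` when the
    observed divergence exceeds the domain of the correction.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned to equal length")
    retained = transitions = transversions = 0
    for a, b in zip(seq_a.upper(), seq_b.upper()):
        if a in _SKIP or b in _SKIP:
            continue
        retained += 1
        if a == b:
            continue
        if (a in _PURINES) == (b in _PURINES):
            transitions += 1
        else:
            transversions += 1
    if retained == 0:
        raise ValueError("no retained columns after discarding gaps/Ns")
    return _k2p_from_fractions(transitions / retained, transversions / retained)


def _k2p_from_fractions(p: float, q: float) -> float:
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(f"saturated: P={p:.4f}, Q={q:.4f}")
    return -0.5 * np.log(w1 * np.sqrt(w2))


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(self.d < 0) or not np.all(np.isfinite(self.d)):
            raise ValueError("distances must be finite and non-negative")


_BASE_CODE = {"A": 0, "G": 1, "C": 2, "T": 3}


def encode_alignment(seqs: list[str]) -> np.ndarray:
    """Integer-encode aligned sequences: A/G/C/T -> 0..3, gap/N/other -> -1."""
    lut = np.full(256, -1, dtype=np.int8)
    for b, c in _BASE_CODE.items():
        lut[ord(b)] = c
        lut[ord(b.lower())] = c
    arr = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    return lut[arr].reshape(len(seqs), -1)


def _pair_masks(enc: np.ndarray):
    """Per-pair boolean masks (valid, transition, transversion) x columns."""
    n = enc.shape[0]
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    valid = np.empty((len(pairs), enc.shape[1]), dtype=bool)
    ts = np.empty_like(valid)
    tv = np.empty_like(valid)
    purine = enc <= 1
    ok = enc >= 0
    for k, (i, j) in enumerate(pairs):
        v = ok[i] & ok[j]
        diff = v & (enc[i] != enc[j])
        same_class = purine[i] == purine[j]
        valid[k] = v
        ts[k] = diff & same_class
        tv[k] = diff & ~same_class
    return pairs, valid, ts, tv


def k2p_matrix(labels: list[str], seqs: list[str]) -> DistanceMatrix:
    """Pairwise K2P distance matrix (pairwise deletion of gap/N columns)."""
    enc = encode_alignment(seqs)
    pairs, valid, ts, tv = _pair_masks(enc)
    n = len(labels)
    d = np.zeros((n, n))
    for k, (i, j) in enumerate(pairs):
        r = int(valid[k].sum())
        if r == 0:
            raise ValueError(f"no retained columns for pair {labels[i]}, {labels[j]}")
        d[i, j] = d[j, i] = _k2p_from_fractions(ts[k].sum() / r, tv[k].sum() / r)
    return DistanceMatrix(labels=labels, d=d)


# ---------------------------------------------------------------------------
# trees


@dataclass
class Clade:
    name: str | None = None
    branch_length: float | None = None
    support: float | None = None
    children: list["Clade"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Clade"]:
        if self.is_leaf:
            return [self]
        return [lf for c in self.children for lf in c.leaves()]

    def _newick(self, fmt: str, min_support: float | None) -> str:
        if self.is_leaf:
            if not self.name:
                raise ValueError("unnamed leaf cannot be serialised")
            label = self.name
        else:
            inner = ",".join(c._newick(fmt, min_support) for c in self.children)
            label = f"({inner})"
            if self.support is not None and (
                min_support is None or self.support > min_support
            ):
                label += f"{self.support:{fmt}}"
        if self.branch_length is not None:
            label += f":{self.branch_length:{fmt}}"
        return label


@dataclass
class PhyloTree:
    root: Clade
    rooted: bool = False

    def leaves(self) -> list[Clade]:
        return self.root.leaves()

    def leaf_names(self) -> list[str]:
        names = [lf.name for lf in self.leaves()]
        if len(set(names)) != len(names):
            raise ValueError("leaf labels must be unique")
        return names  # type: ignore[return-value]

    def to_newick(self, fmt: str = "g", min_support: float | None = None) -> str:
        return self.root._newick(fmt, min_support) + ";"

    def bipartitions(self) -> set[frozenset[frozenset[str]]]:
        """Non-trivial bipartitions of the leaf set induced by internal edges."""
        all_leaves = frozenset(self.leaf_names())
        parts: set[frozenset[frozenset[str]]] = set()

        def walk(node: Clade) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.name])  # type: ignore[list-item]
            below = frozenset().union(*(walk(c) for c in node.children))
            if 1 < len(below) < len(all_leaves) - 1:
                parts.add(frozenset([below, all_leaves - below]))
            return below

        for child in self.root.children:
            walk(child)
        return parts


# ---------------------------------------------------------------------------
# Neighbor-Joining


def nj_tree(matrix: DistanceMatrix) -> PhyloTree:
    """Saitou & Nei Neighbor-Joining agglomeration.

    Returns an unrooted tree (trifurcating root node).  Ties in the Q matrix
    break on the lowest index pair; negative branch estimates are clamped to
    zero with the deficit moved to the sister edge.
    """
    n = len(matrix.labels)
    if n < 3:
        raise ValueError("Neighbor-Joining requires at least 3 labels")
    D = matrix.d.copy()
    nodes: list[Clade] = [Clade(name=lb) for lb in matrix.labels]
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # row-major argmin -> lowest (i, j) index pair on ties
        i_loc, j_loc = np.unravel_index(int(np.argmin(Q)), Q.shape)
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        i, j = active[i_loc], active[j_loc]
        dij = D[i, j]
        li = 0.5 * dij + (r[i_loc] - r[j_loc]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0.0:
            li, lj = 0.0, dij
        elif lj < 0.0:
            li, lj = dij, 0.0
        ni, nj_ = nodes[i], nodes[j]
        ni.branch_length, nj_.branch_length = li, lj
        parent = Clade(children=[ni, nj_])
        # reduce: distances from the new node
        for k in active:
            if k in (i, j):
                continue
            D[i, k] = D[k, i] = 0.5 * (D[i, k] + D[j, k] - dij)
        nodes[i] = parent
        active.remove(j)

    # join the final three at an unrooted central node
    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    for node, length in ((nodes[a], la), (nodes[b], lb), (nodes[c], lc)):
        node.branch_length = max(length, 0.0)
    root = Clade(children=[nodes[a], nodes[b], nodes[c]])
    return PhyloTree(root=root, rooted=False)


# ---------------------------------------------------------------------------
# bootstrap


def bootstrap_support(
    labels: list[str],
    seqs: list[str],
    replicates: int = 1000,
    seed: int | None = None,
) -> PhyloTree:
    """NJ tree with bootstrap supports on internal edges.

    Alignment columns are resampled with replacement ``replicates`` times;
    the support of each internal bipartition of the full-data tree is the
    percentage of replicates whose NJ tree contains it.  Replicates in which
    the K2P distance saturates are skipped (with a warning) but still count
    in the denominator.
    """
    if len(labels) < 4:
        raise ValueError("bootstrap requires at least 4 sequences")
    full = nj_tree(k2p_matrix(labels, seqs))
    target = {bp: 0 for bp in full.bipartitions()}

    enc = encode_alignment(seqs)
    pairs, valid, ts, tv = _pair_masks(enc)
    valid_f = valid.astype(np.float32)
    ts_f = ts.astype(np.float32)
    tv_f = tv.astype(np.float32)
    ncols = enc.shape[1]
    rng = np.random.default_rng(seed)
    n = len(labels)
    skipped = 0
    for _ in range(replicates):
        idx = rng.integers(0, ncols, size=ncols)
        w = np.bincount(idx, minlength=ncols).astype(np.float32)
        rv = valid_f @ w
        rts = ts_f @ w
        rtv = tv_f @ w
        d = np.zeros((n, n))
        try:
            for k, (i, j) in enumerate(pairs):
                if rv[k] == 0:
                    raise SaturationError("pair with no retained columns")
                d[i, j] = d[j, i] = _k2p_from_fractions(
                    float(rts[k] / rv[k]), float(rtv[k] / rv[k])
                )
        except SaturationError as exc:
            skipped += 1
            logger.warning("bootstrap replicate skipped: %s", exc)
            continue
        rep = nj_tree(DistanceMatrix(labels=labels, d=d))
        for bp in rep.bipartitions():
            if bp in target:
                target[bp] += 1
    if skipped:
        logger.warning("%d of %d bootstrap replicates skipped", skipped, replicates)

    support = {bp: 100.0 * c / replicates for bp, c in target.items()}
    _annotate_supports(full, support)
    return full


def _annotate_supports(tree: PhyloTree, support: dict) -> None:
    all_leaves = frozenset(tree.leaf_names())

    def walk(node: Clade) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.name])  # type: ignore[list-item]
        below = frozenset().union(*(walk(c) for c in node.children))
        key = frozenset([below, all_leaves - below])
        if key in support:
            node.support = support[key]
        return below

    for child in tree.root.children:
        walk(child)


# ---------------------------------------------------------------------------
# rooting and locus partition


def root_with_outgroup(tree: PhyloTree, outgroup_label: str) -> PhyloTree:
    """Root the tree at the midpoint of the outgroup's pendant edge.

    Branch lengths and the support attached to each edge are preserved;
    rooting twice on the same leaf is idempotent.
    """
    # flatten to an undirected edge graph; edge attributes (length, support)
    # belong to the edge regardless of orientation
    adjacency: dict[int, list[tuple[int, float | None, float | None]]] = {}
    payload: dict[int, Clade] = {}

    def register(node: Clade) -> int:
        nid = id(node)
        payload[nid] = node
        adjacency.setdefault(nid, [])
        for child in node.children:
            cid = register(child)
            adjacency[nid].append((cid, child.branch_length, child.support))
            adjacency[cid].append((nid, child.branch_length, child.support))
        return nid

    register(tree.root)
    # suppress degree-2 internal nodes (an old root): merge their two edges so
    # rooting twice on the same leaf is idempotent
    for nid in list(adjacency):
        if not payload[nid].is_leaf and len(adjacency[nid]) == 2:
            (a, la, sa), (b, lb, sb) = adjacency[nid]
            merged_len = None if la is None and lb is None else (la or 0.0) + (lb or 0.0)
            merged_sup = sa if sa is not None else sb
            adjacency[a] = [
                (b, merged_len, merged_sup) if t == nid else (t, ln, sp)
                for t, ln, sp in adjacency[a]
            ]
            adjacency[b] = [
                (a, merged_len, merged_sup) if t == nid else (t, ln, sp)
                for t, ln, sp in adjacency[b]
            ]
            del adjacency[nid], payload[nid]
    outgroup_id = None
    for nid, node in payload.items():
        if node.is_leaf and node.name == outgroup_label:
            outgroup_id = nid
    if outgroup_id is None:
        raise ValueError(f"outgroup label {outgroup_label!r} not found")
    if len(adjacency[outgroup_id]) != 1:
        raise ValueError(f"{outgroup_label!r} is not a leaf")
    attach_id, pendant, _sup = adjacency[outgroup_id][0]
    pendant = pendant if pendant is not None else 0.0

    def build(nid: int, parent: int | None, length, support) -> Clade:
        src = payload[nid]
        kids = [
            build(cid, nid, ln, sp)
            for cid, ln, sp in adjacency[nid]
            if cid != parent
        ]
        node = Clade(
            name=src.name if src.is_leaf else None,
            branch_length=length,
            support=None if not kids else support,
            children=kids,
        )
        if kids and len(kids) == 1:
            # degenerate pass-through (the old root seen from the new one)
            only = kids[0]
            if length is not None or only.branch_length is not None:
                only.branch_length = (length or 0.0) + (only.branch_length or 0.0)
            if only.support is None:
                only.support = support
            return only
        return node

    out_leaf = Clade(name=outgroup_label, branch_length=pendant / 2.0)
    ingroup = build(attach_id, outgroup_id, pendant / 2.0, None)
    return PhyloTree(root=Clade(children=[out_leaf, ingroup]), rooted=True)


def partition_loci(
    rooted_tree: PhyloTree, marker_ids: set[str] | None = None
) -> tuple[frozenset[str], frozenset[str], float | None]:
    """Split the ingroup at its deepest split into two candidate locus clades.

    The rooted tree must have the outgroup as one child of the root; the two
    children of the ingroup subtree root are returned as leaf sets.  When
    ``marker_ids`` (alleles carrying the diagnostic pseudogene-locus insertion)
    are given, the third return value is the concordance: the largest fraction
    of marker-bearing leaves falling into a single clade.
    """
    if not rooted_tree.rooted or len(rooted_tree.root.children) != 2:
        raise ValueError("expected a rooted tree with the outgroup split at the root")
    out_child, in_child = rooted_tree.root.children
    if not out_child.is_leaf:
        out_child, in_child = in_child, out_child
    if not out_child.is_leaf:
        raise ValueError("neither root child is a single outgroup leaf")
    ingroup_leaves = [lf.name for lf in in_child.leaves()]
    if len(ingroup_leaves) < 2:
        raise ValueError("ingroup too small to partition")
    if in_child.is_leaf or len(in_child.children) < 2:
        raise ValueError("no ingroup split present (star topology)")
    if len(ingroup_leaves) == 2:
        a = frozenset([ingroup_leaves[0]])
        b = frozenset([ingroup_leaves[1]])
    else:
        kids = in_child.children
        a = frozenset(lf.name for lf in kids[0].leaves())
        b = frozenset(n for k in kids[1:] for n in (lf.name for lf in k.leaves()))
    concordance = None
    if marker_ids:
        present = {m for m in marker_ids if m in a | b}
        if present:
            in_a = len(present & a)
            concordance = max(in_a, len(present) - in_a) / len(present)
    return a, b, concordance
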