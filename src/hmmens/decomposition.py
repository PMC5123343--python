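"""Guide-tree decomposition of a seed alignment into nested taxon subsets.

The family's guide tree is recursively split on its *centroid edge* (the
edge whose removal yields the most balanced bipartition of the leaves).
A subset is split further only while it is larger than a hard floor and
has not yet reached the stopping condition: size at most X% of the initial
seed size AND mean pairwise identity at least Y%. With Y=0 the rule
degenerates to a pure size-based decomposition; with X=100, Y=0 the root
is never split (single-model mode).

Pairwise identity between two aligned rows is the fraction of columns in
which both rows carry the same canonical residue, among columns where both
are non-gap; pairs with no shared non-gap column score 0, and ambiguity
codes (B, Z, X, U, O) never count as matches.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import dendropy
import numpy as np

from .io_formats import AMINO_ACIDS, Alignment, Sequence, induced_alignment

_CODE = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_GAP_CODE = -1
_AMBIG_CODE = 20

#: Subsets at or below this size are never split further.
HARD_FLOOR = 10

#: Above this many rows, mean identity is estimated from a seeded sample.
_EXACT_PAIR_LIMIT = 100
_N_SAMPLED_PAIRS = 1000


def encode_alignment(aln: Alignment) -> np.ndarray:
    """Encode rows as int8 codes: 0-19 canonical, 20 ambiguous, -1 gap."""
    mat = np.empty((aln.n_rows, aln.length), dtype=np.int8)
    for i, row in enumerate(aln.rows):
        mat[i] = [
            _GAP_CODE if c in "-." else _CODE.get(c, _AMBIG_CODE)
            for c in row.residues
        ]
    return mat


def _identity_from_codes(a: np.ndarray, b: np.ndarray) -> float:
    both = (a != _GAP_CODE) & (b != _GAP_CODE)
    n_shared = int(both.sum())
    if n_shared == 0:
        return 0.0
    match = both & (a == b) & (a != _AMBIG_CODE)
    return int(match.sum()) / n_shared


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of mutually non-gap columns with identical canonical residues."""
    if len(a) != len(b):
        raise ValueError(f"aligned length mismatch: {len(a)} vs {len(b)}")
    enc = encode_alignment(
        Alignment([Sequence("a", a.upper()), Sequence("b", b.upper())])
    )
    return _identity_from_codes(enc[0], enc[1])


def mean_pairwise_identity(
    aln: Alignment, rng: np.random.Generator | None = None
) -> float:
    """Mean pairwise identity over rows.

    Exact over all unordered pairs for up to 100 rows; above that, the mean
    of 1,000 pairs sampled without replacement with ``rng``. A single-row
    alignment returns 1.0 by convention.
    """
    n = aln.n_rows
    if n < 2:
        return 1.0
    mat = encode_alignment(aln)
    n_pairs = n * (n - 1) // 2
    if n <= _EXACT_PAIR_LIMIT:
        pairs = ((i, j) for i in range(n - 1) for j in range(i + 1, n))
        return float(np.mean([_identity_from_codes(mat[i], mat[j]) for i, j in pairs]))
    if rng is None:
        rng = np.random.default_rng(0)
    chosen = rng.choice(n_pairs, size=min(_N_SAMPLED_PAIRS, n_pairs), replace=False)
    vals = []
    for flat in chosen:
        # decode the flat index of an unordered pair (i < j)
        i = int(n - 2 - np.floor((np.sqrt(8 * (n_pairs - 1 - flat) + 1) - 1) / 2))
        j = int(flat - i * (2 * n - i - 1) // 2 + i + 1)
        vals.append(_identity_from_codes(mat[i], mat[j]))
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# Guide trees (dendropy-backed)
# ---------------------------------------------------------------------------

GuideTree = dendropy.Tree


def tree_from_newick(newick: str) -> GuideTree:
    tree = dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True
    )
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
    return tree


def load_tree(path: str | Path, expected_ids: set[str] | None = None) -> GuideTree:
    tree = tree_from_newick(Path(path).read_text())
    if expected_ids is not None:
        labels = leaf_labels(tree)
        if labels != set(expected_ids):
            raise ValueError(
                "guide-tree leaves do not match alignment ids: "
                f"tree-only={sorted(labels - set(expected_ids))[:5]}, "
                f"alignment-only={sorted(set(expected_ids) - labels)[:5]}"
            )
    return tree


def leaf_labels(tree: GuideTree) -> set[str]:
    return {leaf.taxon.label for leaf in tree.leaf_node_iter()}


def _bipartitions(tree: GuideTree) -> list[tuple[dendropy.Node, frozenset[str]]]:
    """All edges as (head node, leaf labels below the edge), excluding trivial
    edges whose 'below' side is the full leaf set."""
    all_labels = leaf_labels(tree)
    out = []
    below: dict[int, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[id(node)] = frozenset([node.taxon.label])
        else:
            acc: frozenset[str] = frozenset()
            for child in node.child_nodes():
                acc |= below[id(child)]
            below[id(node)] = acc
        if node.parent_node is not None and below[id(node)] != all_labels:
            out.append((node, below[id(node)]))
    return out


def _split_key(side_a: frozenset[str], side_b: frozenset[str]):
    """Deterministic ranking key for a candidate centroid edge."""
    if len(side_a) < len(side_b):
        smaller = side_a
    elif len(side_b) < len(side_a):
        smaller = side_b
    else:
        smaller = min(side_a, side_b, key=lambda s: min(s))
    return (abs(len(side_a) - len(side_b)), min(smaller), len(smaller))


def centroid_edge(tree: GuideTree) -> dendropy.Node:
    """The edge (returned as its head node) giving a maximally balanced split.

    Ties are broken by the lexicographically smallest minimum leaf label on
    the smaller side, then by smaller side size — deterministic across runs.
    """
    all_labels = leaf_labels(tree)
    if len(all_labels) < 2:
        raise ValueError("centroid edge requires a tree with >= 2 leaves")
    candidates = _bipartitions(tree)
    best = min(
        candidates,
        key=lambda item: _split_key(item[1], frozenset(all_labels - item[1])),
    )
    return best[0]


def split_on_edge(
    tree: GuideTree, edge_head: dendropy.Node
) -> tuple[GuideTree, GuideTree]:
    """Delete an edge, returning the two leaf-induced subtrees."""
    all_labels = leaf_labels(tree)
    below: set[str] = {leaf.taxon.label for leaf in edge_head.leaf_iter()}
    if not below or below == all_labels:
        raise ValueError("edge does not induce a proper bipartition of the tree")
    other = all_labels - below
    t1 = tree.extract_tree_with_taxa_labels(labels=below)
    t2 = tree.extract_tree_with_taxa_labels(labels=other)
    return t1, t2


def estimate_guide_tree(
    aln: Alignment, external_tree_path: str | Path | None = None
) -> GuideTree:
    """Accept an external newick tree, or build a neighbor-joining fallback.

    The NJ fallback uses the p-distance matrix d(a,b) = 1 - identity(a,b);
    negative NJ branch lengths are clamped to 0. An external tree must have
    exactly the alignment's row ids as leaf labels.
    """
    if external_tree_path is not None:
        return load_tree(external_tree_path, expected_ids=set(aln.ids))
    n = aln.n_rows
    if n < 2:
        raise ValueError("guide-tree estimation requires >= 2 rows")
    ids = aln.ids
    if n == 2:
        mat = encode_alignment(aln)
        d = 1.0 - _identity_from_codes(mat[0], mat[1])
        return tree_from_newick(f"({_q(ids[0])}:{d / 2:.6f},{_q(ids[1])}:{d / 2:.6f});")
    mat = encode_alignment(aln)
    dm = np.zeros((n, n))
    for i in range(n - 1):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = 1.0 - _identity_from_codes(mat[i], mat[j])
    from skbio import DistanceMatrix
    from skbio.tree import nj

    tree = nj(DistanceMatrix(dm, ids))
    return tree_from_newick(str(tree))


def _q(label: str) -> str:
    return label if label.replace("_", "").isalnum() else f"'{label}'"


# ---------------------------------------------------------------------------
# Recursive decomposition
# ---------------------------------------------------------------------------


@dataclass
class DecompositionParams:
    """Stopping-rule parameters for the recursive decomposition.

    ``max_size_pct`` (X) and ``min_identity_pct`` (Y) are percentages; a
    subset stops decomposing once its size is at most X% of the initial
    seed size and its mean pairwise identity is at least Y%. Subsets of at
    most ``hard_floor`` sequences are never split.
    """

    max_size_pct: float = 10.0
    min_identity_pct: float = 40.0
    hard_floor: int = HARD_FLOOR
    n: int | None = None  # initial seed size, set at decomposition time

    def __post_init__(self) -> None:
        if not (0 < self.max_size_pct <= 100):
            raise ValueError("max_size_pct must be in (0, 100]")
        if not (0 <= self.min_identity_pct < 100):
            raise ValueError("min_identity_pct must be in [0, 100)")

    def should_split(self, size: int, mean_identity: float) -> bool:
        assert self.n is not None, "params.n must be set before use"
        if size <= self.hard_floor:
            return False
        stopped = (
            size <= self.max_size_pct / 100.0 * self.n
            and mean_identity >= self.min_identity_pct / 100.0
        )
        return not stopped


SINGLE_MODEL_PARAMS = dict(max_size_pct=100.0, min_identity_pct=0.0)


@dataclass
class SubsetNode:
    """One node of the decomposition: a taxon subset and its statistics."""

    taxon_ids: frozenset[str]
    mean_identity: float
    depth: int
    children: tuple["SubsetNode", "SubsetNode"] | None = None

    @property
    def size(self) -> int:
        return len(self.taxon_ids)

    def iter_preorder(self) -> Iterator["SubsetNode"]:
        yield self
        if self.children:
            for child in self.children:
                yield from child.iter_preorder()


@dataclass
class DecompositionTree:
    root: SubsetNode

    @property
    def node_count(self) -> int:
        return sum(1 for _ in self.root.iter_preorder())

    def nodes(self) -> list[SubsetNode]:
        return list(self.root.iter_preorder())

    def to_json(self) -> str:
        records = []
        index: dict[int, int] = {}
        parent: dict[int, int | None] = {id(self.root): None}
        for node in self.root.iter_preorder():
            idx = len(records)
            index[id(node)] = idx
            if node.children:
                for child in node.children:
                    parent[id(child)] = idx
            records.append(
                {
                    "node": idx,
                    "parent": parent[id(node)],
                    "size": node.size,
                    "mean_identity": round(node.mean_identity, 6),
                    "depth": node.depth,
                    "taxon_ids": sorted(node.taxon_ids),
                }
            )
        return json.dumps(records, indent=1)


def decompose(
    aln: Alignment,
    tree: GuideTree,
    params: DecompositionParams,
    rng: np.random.Generator | None = None,
) -> DecompositionTree:
    """Recursively split the guide tree into the nested subset hierarchy."""
    labels = leaf_labels(tree)
    if labels != set(aln.ids):
        raise ValueError("guide-tree leaves do not match alignment row ids")
    import dataclasses

    params = dataclasses.replace(params, n=aln.n_rows)

    def build(subtree: GuideTree, subset: frozenset[str], depth: int) -> SubsetNode:
        sub_aln = induced_alignment(aln, subset)
        mi = mean_pairwise_identity(sub_aln, rng)
        node = SubsetNode(taxon_ids=subset, mean_identity=mi, depth=depth)
        if params.should_split(len(subset), mi):
            head = centroid_edge(subtree)
            t1, t2 = split_on_edge(subtree, head)
            s1, s2 = frozenset(leaf_labels(t1)), frozenset(leaf_labels(t2))
            node.children = (build(t1, s1, depth + 1), build(t2, s2, depth + 1))
        return node

    root = build(tree, frozenset(aln.ids), 0)
    return DecompositionTree(root)
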