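"""Synthetic protein-family generator.

Emulates a Pfam-like input: a collection of families, each defined by a
random phylogeny and sequences evolved along it with substitutions and
tracked indels, so the "true" seed alignment is known by construction and
never re-estimated. Realism is not the goal — statistical control is: the
tree-height parameter tunes the expected within-family mean pairwise
identity, the quantity the stopping rule and the subgroup reports key on.

The substitution model is uniform replacement over the 20 residues (a
Jukes-Cantor analogue): along a branch of length ``b`` each site changes
with probability ``1 - exp(-rate*b)`` to a uniformly chosen different
residue. Indel events occur per site at rate ``indel_rate`` (split evenly
between insertions and deletions) with geometric lengths.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .decomposition import GuideTree, tree_from_newick
from .io_formats import (
    AMINO_ACIDS,
    Alignment,
    FamilyDatabase,
    FamilyRecord,
    Sequence,
    induced_alignment,
    write_alignment,
    write_manifest,
    write_sequences,
)

#: Tree heights calibrated (height -> achieved identity, measured across
#: seeds) to hit the two regimes of interest: high within-family identity
#: (~0.7) and low within-family identity (~0.35).
EASY_TREE_HEIGHT = 0.030
LOW_IDENTITY_TREE_HEIGHT = 0.110


@dataclass
class SimParams:
    """Study conditions for a synthetic benchmark."""

    seed: int
    n_families: int = 20
    family_size: tuple[int, int] = (40, 40)  # inclusive range
    root_length: tuple[int, int] = (80, 120)  # inclusive range
    tree_height: float = EASY_TREE_HEIGHT  # exponential branch-length scale
    sub_rate: float = 1.0  # substitutions per site per unit branch length
    indel_rate: float = 0.05  # indel events per site per unit branch length
    indel_mean_len: float = 2.0
    test_fraction: float = 0.25  # held-out queries per family
    fragment_fractions: tuple[float, ...] = (0.5, 0.25)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("tree_height", "sub_rate", "indel_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 < self.test_fraction < 1):
            raise ValueError("test_fraction must be in (0, 1)")


def sample_tree(
    n_leaves: int,
    rng: np.random.Generator | int,
    height: float = EASY_TREE_HEIGHT,
    labels: list[str] | None = None,
) -> GuideTree:
    """Random binary topology by sequential random leaf attachment, with
    exponential branch lengths of scale ``height``."""
    if n_leaves < 2:
        raise ValueError("a tree needs at least 2 leaves")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if labels is None:
        labels = [f"t{i + 1:03d}" for i in range(n_leaves)]
    if len(labels) != n_leaves:
        raise ValueError("labels length must equal n_leaves")
    counter = itertools.count(n_leaves)
    children: dict[int, list[int]] = {}
    root = next(counter)
    children[root] = [0, 1]
    edges: list[tuple[int, int]] = [(root, 0), (root, 1)]
    for leaf in range(2, n_leaves):
        p, c = edges[int(rng.integers(len(edges)))]
        mid = next(counter)
        children[p][children[p].index(c)] = mid
        children[mid] = [c, leaf]
        edges.remove((p, c))
        edges.extend([(mid, c), (mid, leaf), (p, mid)])
    lengths = {e: float(rng.exponential(height)) if height > 0 else 0.0 for e in _all_edges(children, root)}

    def newick(node: int) -> str:
        if node < n_leaves:
            return labels[node]
        parts = ",".join(
            f"{newick(c)}:{lengths[(node, c)]:.8f}" for c in children[node]
        )
        return f"({parts})"

    tree = tree_from_newick(newick(root) + ";")
    tree.deroot()
    return tree


def _all_edges(children: dict[int, list[int]], root: int) -> list[tuple[int, int]]:
    out = []
    stack = [root]
    while stack:
        node = stack.pop()
        for c in children.get(node, []):
            out.append((node, c))
            stack.append(c)
    return out


def evolve_family(
    tree: GuideTree, params: SimParams, rng: np.random.Generator
) -> Alignment:
    """Evolve a root sequence down the tree, tracking indels as alignment
    events so the emitted Alignment is the true alignment by construction."""
    lo, hi = params.root_length
    root_len = int(rng.integers(lo, hi + 1))
    col_counter = itertools.count()
    order: list[int] = [next(col_counter) for _ in range(root_len)]
    root_state = list(
        zip(order, rng.integers(0, 20, size=root_len).tolist())
    )  # (column id, residue code)

    leaf_rows: dict[str, dict[int, int]] = {}

    def evolve_branch(state: list[tuple[int, int]], b: float) -> list[tuple[int, int]]:
        if b <= 0 or not state:
            return list(state)
        p_sub = 1.0 - np.exp(-params.sub_rate * b)
        p_indel = 1.0 - np.exp(-0.5 * params.indel_rate * b)  # each of ins, del
        out: list[tuple[int, int]] = []
        pending_del = 0
        for col, res in state:
            if pending_del > 0:
                pending_del -= 1
                continue
            if rng.random() < p_indel:  # deletion event starting here
                pending_del = int(rng.geometric(1.0 / params.indel_mean_len)) - 1
                continue
            if rng.random() < p_sub:
                res = (res + 1 + int(rng.integers(19))) % 20
            out.append((col, res))
            if rng.random() < p_indel:  # insertion event after this site
                n_ins = int(rng.geometric(1.0 / params.indel_mean_len))
                anchor = order.index(col)
                for j in range(n_ins):
                    new_col = next(col_counter)
                    order.insert(anchor + 1 + j, new_col)
                    out.append((new_col, int(rng.integers(20))))
        return out

    def walk(node: dendropy.Node, state: list[tuple[int, int]]) -> None:
        for child in node.child_nodes():
            b = child.edge.length or 0.0
            child_state = evolve_branch(state, b)
            if child.is_leaf():
                leaf_rows[child.taxon.label] = dict(child_state)
            else:
                walk(child, child_state)

    walk(tree.seed_node, root_state)

    present = [c for c in order if any(c in row for row in leaf_rows.values())]
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    rows = [
        Sequence(
            label,
            "".join(
                AMINO_ACIDS[leaf_rows[label][c]] if c in leaf_rows[label] else "-"
                for c in present
            ),
        )
        for label in labels
    ]
    return Alignment(rows)


@dataclass
class Benchmark:
    """A synthetic family database with held-out queries and ground truth."""

    database: FamilyDatabase
    queries: list[Sequence]  # full-length held-out queries
    fragments: dict[float, list[Sequence]]  # fraction -> fragment queries
    truth: dict[str, str]  # query id -> true family id
    full_alignments: dict[str, Alignment] = field(default_factory=dict)
    params: SimParams | None = None


def make_benchmark(params: SimParams) -> Benchmark:
    """Generate families, split 75/25 into seed and queries, cut fragments."""
    from .evaluation import make_fragment

    rng = np.random.default_rng(params.seed)
    families: list[FamilyRecord] = []
    queries: list[Sequence] = []
    fragments: dict[float, list[Sequence]] = {f: [] for f in params.fragment_fractions}
    truth: dict[str, str] = {}
    full_alignments: dict[str, Alignment] = {}
    lo, hi = params.family_size
    for i in range(params.n_families):
        fid = f"F{i + 1:03d}"
        n = int(rng.integers(lo, hi + 1))
        labels = [f"{fid}_s{j + 1:03d}" for j in range(n)]
        tree = sample_tree(n, rng, height=params.tree_height, labels=labels)
        aln = evolve_family(tree, params, rng)
        full_alignments[fid] = aln
        perm = rng.permutation(n)
        n_test = max(1, int(np.floor(params.test_fraction * n)))
        test_ids = [labels[j] for j in perm[:n_test]]
        seed_ids = [labels[j] for j in perm[n_test:]]
        if len(seed_ids) < 10:
            raise ValueError(
                f"family {fid}: only {len(seed_ids)} seed sequences after the "
                "75/25 split; increase family_size"
            )
        seed_aln = induced_alignment(aln, seed_ids)
        families.append(FamilyRecord(fid, seed_aln, threshold=0.0))
        for qid in sorted(test_ids):
            full = Sequence(qid, aln.row(qid).ungapped)
            queries.append(full)
            truth[qid] = fid
            for frac in params.fragment_fractions:
                frag = make_fragment(full, frac, rng)
                frag = Sequence(f"{qid}|f{int(round(frac * 100))}", frag.residues)
                fragments[frac].append(frag)
                truth[frag.id] = fid
    return Benchmark(
        database=FamilyDatabase(families),
        queries=queries,
        fragments=fragments,
        truth=truth,
        full_alignments=full_alignments,
        params=params,
    )


def write_benchmark(bench: Benchmark, out_dir: str | Path) -> Path:
    """Write manifest + per-family FASTA + query/fragment FASTA + truth TSV."""
    out_dir = Path(out_dir)
    fam_dir = out_dir / "families"
    fam_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for fam in bench.database:
        rel = f"families/{fam.family_id}.fasta"
        write_alignment(fam.seed, out_dir / rel, "fasta")
        entries.append((fam.family_id, rel, None, fam.threshold))
    write_manifest(entries, out_dir / "manifest.tsv")
    write_sequences(bench.queries, out_dir / "queries_full.fasta")
    for frac, frags in bench.fragments.items():
        write_sequences(frags, out_dir / f"queries_f{int(round(frac * 100))}.fasta")
    with open(out_dir / "truth.tsv", "w") as fh:
        for qid in sorted(bench.truth):
            fh.write(f"{qid}\t{bench.truth[qid]}\n")
    return out_dir
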