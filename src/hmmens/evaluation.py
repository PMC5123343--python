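"""Performance-study machinery.

Cross-validation folds (per-family 75/25 with exactly-once test
membership), fragmentary query generation, precision/recall at swept
inclusion thresholds (globally and within family subgroups defined by
seed size and mean pairwise identity), and the confusable-family graph
used to select a small, mutually confusable parameter-selection set.

Conventions: recall is n_correct / n_queries over *all* queries, so
unassigned queries count against recall but not against precision
(n_correct / n_assigned, undefined when nothing is assigned).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence as TypingSequence

import networkx as nx
import numpy as np
import pandas as pd

from .classification import (
    UNASSIGNED,
    ThresholdPolicy,
    assign_from_scores,
    score_all,
)
from .decomposition import DecompositionParams
from .ensemble_build import build_database
from .hmm_backend import BackendConfig, build_profile, score_sequences
from .io_formats import (
    FamilyDatabase,
    FamilyRecord,
    Sequence,
    induced_alignment,
)

logger = logging.getLogger(__name__)

#: Default gathering-cutoff scale grid: yields 5-7 distinct sweep points.
DEFAULT_GRID = (0.0, 0.25, 0.5, 0.75, 0.9, 1.0)

MIN_FAMILY_SIZE = 10


@dataclass(frozen=True)
class FoldSplit:
    """One cross-validation fold: per-family train (~75%) and test (~25%) ids."""

    fold_index: int
    train: dict[str, list[str]]
    test: dict[str, list[str]]


def make_folds(
    db: FamilyDatabase, n_folds: int = 4, seed: int = 0
) -> list[FoldSplit]:
    """Per family, shuffle once and deal sequences into near-equal groups.

    Fold f's test set is group f; its training set is the remaining
    groups, so each sequence appears in exactly one test set and
    ``n_folds - 1`` training sets.
    """
    small = [f.family_id for f in db if f.seed.n_rows < MIN_FAMILY_SIZE]
    if small:
        raise ValueError(
            f"families smaller than {MIN_FAMILY_SIZE} sequences must be filtered "
            f"out before folding: {small[:5]}"
        )
    rng = np.random.default_rng(seed)
    groups: dict[str, list[list[str]]] = {}
    for fam in db:
        ids = list(fam.seed.ids)
        perm = rng.permutation(len(ids))
        shuffled = [ids[i] for i in perm]
        groups[fam.family_id] = [shuffled[g::n_folds] for g in range(n_folds)]
    folds = []
    for f in range(n_folds):
        test = {fid: sorted(g[f]) for fid, g in groups.items()}
        train = {
            fid: sorted(x for g2 in range(n_folds) if g2 != f for x in g[g2])
            for fid, g in groups.items()
        }
        folds.append(FoldSplit(f + 1, train, test))
    return folds


def make_fragment(
    seq: Sequence, fraction: float, rng: np.random.Generator
) -> Sequence:
    """A uniformly placed contiguous substring of the de-gapped sequence.

    Length is ``max(1, floor(fraction * L))``; fraction 1 returns the
    (de-gapped) sequence itself.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    full = seq.ungapped
    L = len(full)
    if L < 1:
        raise ValueError(f"query {seq.id!r} has no residues")
    if fraction == 1:
        return Sequence(seq.id, full)
    length = max(1, int(np.floor(fraction * L)))
    start = int(rng.integers(0, L - length + 1))
    return Sequence(seq.id, full[start : start + length])


# ---------------------------------------------------------------------------
# Precision / recall
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PRPoint:
    """Precision/recall at one inclusion-threshold setting."""

    threshold_scale: float
    precision: float | None  # None when nothing was assigned
    recall: float
    n_queries: int
    n_assigned: int
    n_correct: int
    subgroup: str | None = None


def size_bin(size: int) -> str:
    return "0-100" if size <= 100 else ">100"


def identity_bin(identity: float) -> str:
    if identity < 0.20:
        return "0-20%"
    if identity < 0.30:
        return "20-30%"
    return ">30%"


def subgroup_key(size: int, identity: float) -> str:
    return f"size {size_bin(size)} | identity {identity_bin(identity)}"


def precision_recall(
    assignments: pd.DataFrame,
    truth: Mapping[str, str],
    threshold_scale: float = 1.0,
    subgroup: str | None = None,
) -> PRPoint:
    """Best-hit precision and recall of an assignment table against truth."""
    missing = [q for q in assignments["query_id"] if q not in truth]
    if missing:
        raise KeyError(f"queries missing from truth: {missing[:5]}")
    n_queries = len(assignments)
    assigned = assignments[assignments["family_id"] != UNASSIGNED]
    n_assigned = len(assigned)
    n_correct = int(
        sum(row.family_id == truth[row.query_id] for row in assigned.itertuples())
    )
    return PRPoint(
        threshold_scale=threshold_scale,
        precision=(n_correct / n_assigned) if n_assigned else None,
        recall=(n_correct / n_queries) if n_queries else 0.0,
        n_queries=n_queries,
        n_assigned=n_assigned,
        n_correct=n_correct,
        subgroup=subgroup,
    )


def pr_curve(
    score_table: pd.DataFrame,
    truth: Mapping[str, str],
    thresholds: Mapping[str, float],
    grid: TypingSequence[float] = DEFAULT_GRID,
    family_meta: Mapping[str, dict] | None = None,
    query_ids: TypingSequence[str] | None = None,
) -> list[PRPoint]:
    """Sweep the gathering-cutoff scale, re-gating (never re-scoring).

    Emits one global point per grid value and, when ``family_meta`` maps
    family ids to ``{"size", "mean_identity"}``, one point per subgroup of
    the queries' *true* families.
    """
    if len(grid) == 0:
        raise ValueError("threshold grid must be nonempty")
    if query_ids is None:
        query_ids = sorted(set(score_table["query_id"]))
    points: list[PRPoint] = []
    for scale in grid:
        policy = ThresholdPolicy(mode="gathering-cutoff", scale=float(scale))
        assignments = assign_from_scores(
            score_table, thresholds, policy, query_ids=query_ids
        )
        points.append(precision_recall(assignments, truth, float(scale)))
        if family_meta is not None:
            key_of = {
                fid: subgroup_key(meta["size"], meta["mean_identity"])
                for fid, meta in family_meta.items()
            }
            by_group = assignments.groupby(
                assignments["query_id"].map(lambda q: key_of[truth[q]])
            )
            for group_key, sub in by_group:
                points.append(
                    precision_recall(sub, truth, float(scale), subgroup=group_key)
                )
    return points


def pr_points_to_frame(points: list[PRPoint]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(p) for p in points])


# ---------------------------------------------------------------------------
# Confusable-family selection graph
# ---------------------------------------------------------------------------


def confusable_family_graph(
    db: FamilyDatabase,
    cfg: BackendConfig | None = None,
    bit_cutoff: float = 25.0,
    degree_cutoff: int = 5,
    n_probe: int = 10,
    seed: int = 0,
) -> tuple[list[str], nx.Graph]:
    """Select mutually confusable families via cross-family probe scores.

    ``n_probe`` random sequences per family are scored against every other
    family's single full-seed profile; when the mean bit score (no-hit
    probes contribute 0) strictly exceeds ``bit_cutoff`` in either
    direction an undirected edge joins the two families. The selection is
    every family of degree >= ``degree_cutoff`` plus all its neighbors.
    """
    cfg = cfg or BackendConfig()
    rng = np.random.default_rng(seed)
    profiles = {}
    probes: dict[str, list[Sequence]] = {}
    for fam in db:
        profiles[fam.family_id] = build_profile(
            fam.seed, cfg, model_id=f"{fam.family_id}.root", family_id=fam.family_id
        )
        ids = list(fam.seed.ids)
        if len(ids) < n_probe:
            logger.info(
                "family %s has %d < %d sequences; using all as probes",
                fam.family_id,
                len(ids),
                n_probe,
            )
            chosen = ids
        else:
            chosen = [ids[i] for i in rng.choice(len(ids), n_probe, replace=False)]
        probes[fam.family_id] = [
            Sequence(sid, fam.seed.row(sid).ungapped) for sid in sorted(chosen)
        ]
    graph = nx.Graph()
    graph.add_nodes_from(fam.family_id for fam in db)
    fids = [fam.family_id for fam in db]
    for i, fid_i in enumerate(fids):
        for fid_j in fids:
            if fid_j == fid_i:
                continue
            records = score_sequences(profiles[fid_j], probes[fid_i], cfg)
            scored = {r.query_id: r.bit_score for r in records}
            mean = float(
                np.mean([scored.get(p.id, 0.0) for p in probes[fid_i]])
            )
            if mean > bit_cutoff:
                graph.add_edge(fid_i, fid_j)
    selected: set[str] = set()
    for node in graph.nodes:
        if graph.degree[node] >= degree_cutoff:
            selected.add(node)
            selected.update(graph.neighbors(node))
    return sorted(selected), graph


# ---------------------------------------------------------------------------
# Cross-validation driver
# ---------------------------------------------------------------------------


def train_database(db: FamilyDatabase, fold: FoldSplit) -> FamilyDatabase:
    """The family database induced on a fold's training sequences."""
    families = [
        FamilyRecord(
            fam.family_id,
            induced_alignment(fam.seed, fold.train[fam.family_id]),
            threshold=fam.threshold,
            guide_tree_path=None,  # trees must be re-estimated on the subset
        )
        for fam in db
    ]
    return FamilyDatabase(families)


def fold_queries(
    db: FamilyDatabase,
    fold: FoldSplit,
    fractions: TypingSequence[float],
    rng: np.random.Generator,
) -> tuple[dict[float, list[Sequence]], dict[str, str]]:
    """Held-out queries (full-length and fragments) and their truth table."""
    queries: dict[float, list[Sequence]] = {f: [] for f in fractions}
    truth: dict[str, str] = {}
    for fam in db:
        for sid in fold.test[fam.family_id]:
            full = Sequence(sid, fam.seed.row(sid).ungapped)
            truth[sid] = fam.family_id
            for frac in fractions:
                queries[frac].append(make_fragment(full, frac, rng))
    return queries, truth


def cross_validate(
    db: FamilyDatabase,
    params: DecompositionParams | None = None,
    cfg: BackendConfig | None = None,
    n_folds: int = 4,
    fractions: TypingSequence[float] = (1.0, 0.5, 0.25),
    grid: TypingSequence[float] = DEFAULT_GRID,
    seed: int = 0,
    single_hmm: bool = False,
    folds_to_run: TypingSequence[int] | None = None,
) -> dict:
    """Run the full cross-validation study on one family database.

    Returns, per fold and query-length fraction, the raw score table, the
    assignments at the full gathering cutoff, and the PR sweep (global and
    per subgroup).
    """
    params = params or DecompositionParams()
    cfg = cfg or BackendConfig()
    folds = make_folds(db, n_folds=n_folds, seed=seed)
    if folds_to_run is not None:
        folds = [f for f in folds if f.fold_index in set(folds_to_run)]
    results: dict = {"folds": []}
    for fold in folds:
        train_db = train_database(db, fold)
        edb = build_database(train_db, params, cfg, seed=seed, single_hmm=single_hmm)
        rng = np.random.default_rng([seed % (2**31), fold.fold_index])
        queries, truth = fold_queries(db, fold, fractions, rng)
        fold_out = {"fold": fold.fold_index, "fractions": {}}
        meta = edb.family_meta()
        for frac in fractions:
            table = score_all(queries[frac], edb, cfg)
            qids = [q.id for q in queries[frac]]
            assignments = assign_from_scores(
                table, edb.thresholds(), ThresholdPolicy(), query_ids=qids
            )
            points = pr_curve(
                table, truth, edb.thresholds(), grid, family_meta=meta, query_ids=qids
            )
            fold_out["fractions"][frac] = {
                "score_table": table,
                "assignments": assignments,
                "pr_points": points,
            }
        results["folds"].append(fold_out)
    return results


def write_results(results: dict, out_dir: str | Path) -> Path:
    """Write per-fold assignment/score TSVs, the PR table, and a summary."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    all_points = []
    summary: dict = {"folds": []}
    for fold_out in results["folds"]:
        f = fold_out["fold"]
        fold_summary = {"fold": f, "fractions": {}}
        for frac, data in fold_out["fractions"].items():
            tag = f"fold{f}_len{int(round(frac * 100))}"
            data["score_table"].to_csv(out_dir / f"scores_{tag}.tsv", sep="\t", index=False)
            data["assignments"].to_csv(
                out_dir / f"assignments_{tag}.tsv", sep="\t", index=False
            )
            frame = pr_points_to_frame(data["pr_points"])
            frame.insert(0, "fold", f)
            frame.insert(1, "fraction", frac)
            all_points.append(frame)
            full = next(
                p
                for p in data["pr_points"]
                if p.subgroup is None and p.threshold_scale == 1.0
            )
            fold_summary["fractions"][str(frac)] = {
                "precision": full.precision,
                "recall": full.recall,
                "n_queries": full.n_queries,
            }
        summary["folds"].append(fold_summary)
    pd.concat(all_points, ignore_index=True).to_csv(
        out_dir / "pr_points.tsv", sep="\t", index=False
    )
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=1))
    return out_dir
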