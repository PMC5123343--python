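"""Query classification against an ensemble database.

A query is scored against every profile in every family's ensemble; each
family's candidate score is the maximum bit score among its profiles that
pass the family's inclusion threshold, and the query is assigned to the
family with the best candidate score, or left unassigned when every
family's candidate set is empty. Because the threshold is constant within
a family, gating each profile before the maximum and gating the family
maximum are equivalent.

Thresholds follow the gathering-cutoff convention: the inclusion
threshold of family *i* is ``scale * g_i`` with ``scale`` in [0, 1]. An
effective threshold of 0 (``scale == 0``, ``g_i == 0``, or mode "none")
means *no minimum* — any finite score passes, so a query is unassigned
only when no profile reported a hit at all. Ties on the best score break
to the lexicographically smallest family id.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence as TypingSequence

import pandas as pd

from .ensemble_build import EnsembleDatabase
from .hmm_backend import BackendConfig, score_sequences
from .io_formats import Sequence

UNASSIGNED = "UNASSIGNED"

#: Column schema of a score table (one row per query x family with a hit).
SCORE_COLUMNS = ["query_id", "family_id", "bit_score", "model_id"]
ASSIGN_COLUMNS = [
    "query_id",
    "family_id",
    "bit_score",
    "model_id",
    "runner_up",
    "runner_up_score",
]


@dataclass(frozen=True)
class ThresholdPolicy:
    """Inclusion-threshold policy: gathering-cutoff scaling or none."""

    mode: str = "gathering-cutoff"
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in {"gathering-cutoff", "none"}:
            raise ValueError(f"unknown threshold mode {self.mode!r}")
        if not (0.0 <= self.scale <= 1.0):
            raise ValueError("scale must be in [0, 1]")

    def effective_threshold(self, g: float) -> float:
        return 0.0 if self.mode == "none" else self.scale * g

    def passes(self, bit_score: float, g: float) -> bool:
        t = self.effective_threshold(g)
        return t <= 0.0 or bit_score > t


@dataclass(frozen=True)
class Assignment:
    query_id: str
    family_id: str  # UNASSIGNED when no family passes its threshold
    bit_score: float  # NaN when unassigned
    model_id: str
    runner_up: str | None = None
    runner_up_score: float = float("nan")

    @property
    def assigned(self) -> bool:
        return self.family_id != UNASSIGNED


def score_all(
    queries: TypingSequence[Sequence],
    edb: EnsembleDatabase,
    cfg: BackendConfig | None = None,
) -> pd.DataFrame:
    """Score every query against every profile; keep each family's best.

    Returns a score table (query_id, family_id, bit_score, model_id) with
    one row per query/family pair for which some profile reported a hit.
    Raw scores are kept un-gated so threshold sweeps re-gate without
    re-scoring.
    """
    if edb.k == 0:
        raise ValueError("empty ensemble database")
    ids = [q.id for q in queries]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate query ids")
    best: dict[tuple[str, str], tuple[float, str]] = {}
    for model in edb.iter_models():
        for rec in score_sequences(model, queries, cfg):
            key = (rec.query_id, rec.family_id)
            cur = best.get(key)
            if cur is None or rec.bit_score > cur[0]:
                best[key] = (rec.bit_score, rec.model_id)
    rows = [
        {"query_id": q, "family_id": f, "bit_score": s, "model_id": m}
        for (q, f), (s, m) in best.items()
    ]
    table = pd.DataFrame(rows, columns=SCORE_COLUMNS)
    return table.sort_values(["query_id", "family_id"], ignore_index=True)


def assign_from_scores(
    score_table: pd.DataFrame,
    thresholds: Mapping[str, float],
    policy: ThresholdPolicy,
    query_ids: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Re-gate a score table at a policy without re-scoring.

    ``query_ids``, when given, forces a row (possibly UNASSIGNED) for
    queries absent from the table (no hit anywhere).
    """
    out: dict[str, Assignment] = {}
    for qid, group in score_table.groupby("query_id", sort=True):
        candidates = []
        for row in group.itertuples(index=False):
            g = thresholds.get(row.family_id, 0.0)
            if policy.passes(row.bit_score, g):
                candidates.append((-row.bit_score, row.family_id, row.model_id))
        if not candidates:
            out[qid] = Assignment(qid, UNASSIGNED, float("nan"), "")
            continue
        candidates.sort()
        neg_s, fid, mid = candidates[0]
        runner_up, runner_score = None, float("nan")
        if len(candidates) > 1:
            runner_up, runner_score = candidates[1][1], -candidates[1][0]
        out[qid] = Assignment(qid, fid, -neg_s, mid, runner_up, runner_score)
    if query_ids is not None:
        for qid in query_ids:
            if qid not in out:
                out[qid] = Assignment(qid, UNASSIGNED, float("nan"), "")
    return pd.DataFrame(
        [
            {
                "query_id": a.query_id,
                "family_id": a.family_id,
                "bit_score": a.bit_score,
                "model_id": a.model_id,
                "runner_up": a.runner_up,
                "runner_up_score": a.runner_up_score,
            }
            for a in sorted(out.values(), key=lambda a: a.query_id)
        ],
        columns=ASSIGN_COLUMNS,
    )


def classify_batch(
    queries: TypingSequence[Sequence],
    edb: EnsembleDatabase,
    policy: ThresholdPolicy | None = None,
    cfg: BackendConfig | None = None,
    return_scores: bool = False,
):
    """Classify a batch of queries; one assignment row per query."""
    policy = policy or ThresholdPolicy()
    table = score_all(queries, edb, cfg)
    assignments = assign_from_scores(
        table, edb.thresholds(), policy, query_ids=[q.id for q in queries]
    )
    if return_scores:
        return assignments, table
    return assignments


def classify(
    q: Sequence,
    edb: EnsembleDatabase,
    policy: ThresholdPolicy | None = None,
    cfg: BackendConfig | None = None,
) -> Assignment:
    """Classify a single query sequence."""
    row = classify_batch([q], edb, policy, cfg).iloc[0]
    return Assignment(
        query_id=row.query_id,
        family_id=row.family_id,
        bit_score=float(row.bit_score),
        model_id=row.model_id,
        runner_up=None if pd.isna(row.runner_up) else row.runner_up,
        runner_up_score=float(row.runner_up_score),
    )
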