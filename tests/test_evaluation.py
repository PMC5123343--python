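from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from hmmens import evaluation
from hmmens.classification import UNASSIGNED
from hmmens.evaluation import (
    DEFAULT_GRID,
    confusable_family_graph,
    cross_validate,
    make_folds,
    make_fragment,
    pr_curve,
    precision_recall,
    subgroup_key,
    write_results,
)
from hmmens.hmm_backend import ScoreRecord
from hmmens.io_formats import Alignment, FamilyDatabase, FamilyRecord, Sequence


def _dummy_db(sizes, seed=0):
    fams = []
    for i, n in enumerate(sizes):
        rows = [Sequence(f"F{i}_s{j}", "A") for j in range(n)]
        fams.append(FamilyRecord(f"F{i}", Alignment(rows)))
    return FamilyDatabase(fams)


class TestFolds:
    def test_family_of_twelve(self):
        folds = make_folds(_dummy_db([12]), seed=1)
        assert [len(f.test["F0"]) for f in folds] == [3, 3, 3, 3]

    def test_family_of_ten_near_equal(self):
        folds = make_folds(_dummy_db([10]), seed=1)
        assert sorted(len(f.test["F0"]) for f in folds) == [2, 2, 3, 3]

    def test_small_family_rejected(self):
        with pytest.raises(ValueError, match="filter"):
            make_folds(_dummy_db([9, 12]))

    @pytest.mark.parametrize("chunk", range(10))
    def test_partition_invariants(self, chunk):
        """Each sequence is in exactly one test set and n-1 training sets."""
        rng = np.random.default_rng(chunk)
        for _ in range(10):
            sizes = rng.integers(10, 200, size=int(rng.integers(1, 5)))
            db = _dummy_db(sizes.tolist(), seed=chunk)
            folds = make_folds(db, seed=int(rng.integers(1000)))
            for fam in db:
                ids = set(fam.seed.ids)
                test_sets = [set(f.test[fam.family_id]) for f in folds]
                assert set().union(*test_sets) == ids
                assert sum(len(t) for t in test_sets) == len(ids)  # disjoint
                for f in folds:
                    assert set(f.train[fam.family_id]) == ids - set(
                        f.test[fam.family_id]
                    )


class TestFragments:
    def test_half_length(self):
        rng = np.random.default_rng(0)
        seq = Sequence("q", "".join("ACDW"[i % 4] for i in range(100)))
        frag = make_fragment(seq, 0.5, rng)
        assert len(frag.residues) == 50
        assert frag.residues in seq.residues

    def test_fraction_one_identity(self):
        seq = Sequence("q", "ACDWACDW")
        frag = make_fragment(seq, 1.0, np.random.default_rng(0))
        assert frag.residues == seq.residues

    def test_minimum_length_one(self):
        frag = make_fragment(Sequence("q", "ACDWACD"), 0.25, np.random.default_rng(0))
        assert len(frag.residues) == 1

    def test_bad_fraction_error(self):
        for bad in (0.0, 1.5, -0.1):
            with pytest.raises(ValueError):
                make_fragment(Sequence("q", "ACD"), bad, np.random.default_rng(0))

    @pytest.mark.parametrize("fraction", [0.25, 0.5, 0.9])
    def test_exact_length_and_containment(self, fraction):
        rng = np.random.default_rng(42)
        for trial in range(50):
            L = int(rng.integers(1, 120))
            residues = "".join(
                "ACDEFGHIKLMNPQRSTVWY"[int(rng.integers(20))] for _ in range(L)
            )
            frag = make_fragment(Sequence("q", residues), fraction, rng)
            assert len(frag.residues) == max(1, int(np.floor(fraction * L)))
            assert frag.residues in residues


def _assignments(rows):
    return pd.DataFrame(
        rows, columns=["query_id", "family_id", "bit_score", "model_id"]
    )


class TestPrecisionRecall:
    def test_perfect(self):
        out = _assignments([("q1", "F1", 9.0, "m"), ("q2", "F2", 9.0, "m")])
        pr = precision_recall(out, {"q1": "F1", "q2": "F2"})
        assert (pr.precision, pr.recall) == (1.0, 1.0)

    def test_mixed_counts(self):
        rows = [(f"q{i}", "F1" if i < 8 else UNASSIGNED, 1.0, "m") for i in range(10)]
        truth = {f"q{i}": "F1" if i < 6 else "F2" for i in range(10)}
        pr = precision_recall(_assignments(rows), truth)
        assert pr.precision == pytest.approx(0.75)
        assert pr.recall == pytest.approx(0.60)
        # integer-exact identities
        assert pr.precision * pr.n_assigned == pr.n_correct
        assert pr.recall * pr.n_queries == pr.n_correct

    def test_nothing_assigned(self):
        rows = [("q1", UNASSIGNED, float("nan"), "")]
        pr = precision_recall(_assignments(rows), {"q1": "F1"})
        assert pr.precision is None and pr.recall == 0.0

    def test_missing_truth_error(self):
        with pytest.raises(KeyError):
            precision_recall(_assignments([("q", "F1", 1.0, "m")]), {})


class TestPRCurve:
    def _inputs(self, seed=0):
        rng = np.random.default_rng(seed)
        fams = [f"F{i}" for i in range(4)]
        rows = []
        truth = {}
        for j in range(30):
            qid = f"q{j:02d}"
            truth[qid] = fams[j % 4]
            for f in fams:
                mean = 40 if f == truth[qid] else 12
                rows.append((qid, f, float(rng.normal(mean, 10)), "m"))
        thresholds = {f: 20.0 for f in fams}
        meta = {
            f: {"size": 50 if i < 2 else 150, "mean_identity": 0.15 + 0.12 * i}
            for i, f in enumerate(fams)
        }
        table = pd.DataFrame(
            rows, columns=["query_id", "family_id", "bit_score", "model_id"]
        )
        return table, truth, thresholds, meta

    def test_monotone_gating_along_grid(self):
        table, truth, thresholds, _ = self._inputs()
        points = pr_curve(table, truth, thresholds)
        global_points = [p for p in points if p.subgroup is None]
        assert len(global_points) == len(DEFAULT_GRID)
        n_assigned = [p.n_assigned for p in global_points]
        assert n_assigned == sorted(n_assigned, reverse=True)
        recalls = [p.recall for p in global_points]
        assert recalls[0] == max(recalls)  # scale 0 has maximal recall

    def test_subgroup_counts_sum_to_global(self):
        table, truth, thresholds, meta = self._inputs()
        points = pr_curve(table, truth, thresholds, family_meta=meta)
        for scale in DEFAULT_GRID:
            at_scale = [p for p in points if p.threshold_scale == scale]
            global_point = next(p for p in at_scale if p.subgroup is None)
            subs = [p for p in at_scale if p.subgroup is not None]
            assert sum(p.n_queries for p in subs) == global_point.n_queries
            assert sum(p.n_assigned for p in subs) == global_point.n_assigned
            assert sum(p.n_correct for p in subs) == global_point.n_correct

    def test_empty_grid_error(self):
        table, truth, thresholds, _ = self._inputs()
        with pytest.raises(ValueError):
            pr_curve(table, truth, thresholds, grid=())


class TestSubgroups:
    @pytest.mark.parametrize(
        "size,identity,expected",
        [
            (100, 0.19, "size 0-100 | identity 0-20%"),
            (101, 0.20, "size >100 | identity 20-30%"),
            (50, 0.299, "size 0-100 | identity 20-30%"),
            (500, 0.30, "size >100 | identity >30%"),
        ],
    )
    def test_bin_edges(self, size, identity, expected):
        assert subgroup_key(size, identity) == expected


class TestConfusableGraph:
    def test_edge_rule_strict_inequality(self, monkeypatch):
        """Mean probe score > 25 draws an edge; exactly 25 does not."""
        db = _real_db(sizes=(12, 12, 12))
        means = {
            ("F1", "F2"): 26.0,  # edge
            ("F2", "F1"): 10.0,  # (either direction suffices)
            ("F1", "F3"): 25.0,  # exactly the cutoff: no edge
            ("F3", "F1"): 25.0,
            ("F2", "F3"): 0.0,
            ("F3", "F2"): 0.0,
        }

        def fake_scores(model, probes, cfg=None):
            src = probes[0].id.split("_")[0]
            return [
                ScoreRecord(p.id, model.model_id, model.family_id,
                            means[(src, model.family_id)])
                for p in probes
            ]

        monkeypatch.setattr(evaluation, "score_sequences", fake_scores)
        selected, graph = confusable_family_graph(db, degree_cutoff=1)
        assert set(graph.edges) == {("F1", "F2")}
        assert selected == ["F1", "F2"]

    def test_hub_selection_includes_neighbors(self, monkeypatch):
        db = _real_db(sizes=(12,) * 7)
        hub = "F1"

        def fake_scores(model, probes, cfg=None):
            src = probes[0].id.split("_")[0]
            score = 30.0 if hub in (src, model.family_id) and model.family_id != "F7" and src != "F7" else 0.0
            return [
                ScoreRecord(p.id, model.model_id, model.family_id, score)
                for p in probes
            ]

        monkeypatch.setattr(evaluation, "score_sequences", fake_scores)
        selected, graph = confusable_family_graph(db, degree_cutoff=5)
        assert graph.degree["F1"] == 5
        assert selected == ["F1", "F2", "F3", "F4", "F5", "F6"]

    def test_no_confusion_empty_selection(self, tiny_database):
        # well-separated synthetic families: no cross-family mean above 25
        selected, graph = confusable_family_graph(tiny_database, seed=1)
        assert selected == []
        assert graph.number_of_edges() == 0

    def test_small_family_uses_all_probes(self, tiny_database):
        selected, graph = confusable_family_graph(tiny_database, n_probe=50, seed=1)
        assert graph.number_of_nodes() == tiny_database.k


def _real_db(sizes, seed=0):
    from conftest import block_alignment

    fams = []
    for i, n in enumerate(sizes):
        fid = f"F{i + 1}"
        fams.append(
            FamilyRecord(
                fid,
                block_alignment(n, 20, seed=seed + i, block_noise=0.1,
                                prefix=f"{fid}_s"),
            )
        )
    return FamilyDatabase(fams)


class TestCrossValidate:
    def test_small_study_end_to_end(self, tmp_path, tiny_database):
        results = cross_validate(
            tiny_database,
            fractions=(1.0, 0.25),
            grid=(0.0, 1.0),
            seed=3,
            folds_to_run=(1, 2),
        )
        assert [f["fold"] for f in results["folds"]] == [1, 2]
        for fold_out in results["folds"]:
            for frac, data in fold_out["fractions"].items():
                n_test = sum(
                    len(fam.seed.ids) // 4 + (len(fam.seed.ids) % 4 > 0)
                    for fam in tiny_database
                )
                assert len(data["assignments"]) >= 1
                global_points = [
                    p for p in data["pr_points"] if p.subgroup is None
                ]
                assert len(global_points) == 2
        out = write_results(results, tmp_path / "eval")
        assert (out / "pr_points.tsv").exists()
        assert (out / "summary.json").exists()
        assert (out / "assignments_fold1_len100.tsv").exists()
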