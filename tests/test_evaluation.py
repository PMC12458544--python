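"""Evaluation orchestration: folds, metric records, aggregation, contrasts."""

import numpy as np
import pandas as pd
import pytest

import tcrbench as tb
from tcrbench.evaluation import CLASSIFICATION_METRICS, EvaluationError, records_to_frame


class TestClassificationEval:
    def test_oracle_is_perfect_on_every_fold(self, small_dataset):
        _, truth, repertoire, tasks = small_dataset
        spec = tb.SamplingSpec(n_folds=10, seed=2)
        records = tb.run_classification_eval(tb.OracleScorer(truth), tasks, repertoire, spec)
        rocs = [r.value for r in records if r.metric == "roc_auc"]
        assert rocs and all(v == pytest.approx(1.0, abs=1e-12) for v in rocs)

    def test_record_completeness(self, small_dataset):
        _, truth, repertoire, tasks = small_dataset
        spec = tb.SamplingSpec(n_folds=4, seed=0)
        records = tb.run_classification_eval(tb.OracleScorer(truth), tasks, repertoire, spec)
        groups_present = {t.group for t in tasks}
        assert len(records) == 4 * len(groups_present) * len(CLASSIFICATION_METRICS)
        assert len({r.key() for r in records}) == len(records)

    def test_random_scorer_near_half_auc(self, small_dataset):
        # positives keep their (hash-derived) scores across folds, so the
        # fold mean must also be averaged over scorer seeds to approach 1/2
        _, _, repertoire, tasks = small_dataset
        rocs = []
        for scorer_seed in range(6):
            spec = tb.SamplingSpec(n_folds=10, seed=5 + scorer_seed)
            records = tb.run_classification_eval(
                tb.RandomScorer(seed=scorer_seed), tasks, repertoire, spec
            )
            rocs += [r.value for r in records if r.metric == "roc_auc"]
        assert abs(np.mean(rocs) - 0.5) < 0.05

    def test_memorization_gap_direction(self, small_dataset):
        records, _, repertoire, tasks = small_dataset
        binders = {r.tcr for r in records if r.is_binder}
        memo = tb.MemorizationScorer(binders)

        def run(strategy, rep):
            spec = tb.SamplingSpec(strategy=strategy, n_folds=5, seed=4)
            out = tb.run_classification_eval(memo, tasks, rep, spec)
            frame = records_to_frame(out)
            roc = frame[frame.metric == "roc_auc"].value.mean()
            fp = frame[frame.metric == "fp"].value.sum()
            tn = frame[frame.metric == "tn"].value.sum()
            return roc, fp / (fp + tn)

        roc_bg, fpr_bg = run(tb.BACKGROUND_DRAWING, repertoire)
        roc_rs, fpr_rs = run(tb.RESHUFFLING, None)
        assert fpr_rs > fpr_bg
        assert roc_rs < roc_bg


class TestScreeningEval:
    def test_oracle_reaches_bedroc_ceiling(self, small_dataset):
        _, truth, repertoire, tasks = small_dataset
        results = tb.run_screening_eval(tb.OracleScorer(truth), tasks, repertoire)
        N = len(repertoire) + sum(t.n_binders for t in tasks)
        by_group = {}
        for t in tasks:
            by_group.setdefault(t.group, []).append(t)
        for rec in results.records:
            if rec.metric != "bedroc":
                continue
            expected = np.mean(
                [tb.max_bedroc(t.n_binders, N) for t in by_group[rec.group]]
            )
            assert rec.value == pytest.approx(expected, abs=1e-9)

    def test_missing_group_is_skipped(self, small_dataset):
        _, truth, repertoire, tasks = small_dataset
        no_zero = [t for t in tasks if t.group != tb.ZEROSHOT]
        results = tb.run_screening_eval(tb.OracleScorer(truth), no_zero, repertoire)
        assert not any(r.group == tb.ZEROSHOT for r in results.records)

    def test_pooled_group_bedroc_runs(self, small_dataset):
        _, truth, repertoire, tasks = small_dataset
        results = tb.run_screening_eval(
            tb.OracleScorer(truth), tasks, repertoire, group_bedroc="pooled"
        )
        beds = [r.value for r in results.records if r.metric == "bedroc"]
        assert beds and all(v > 1 for v in beds)

    def test_curves_persisted_per_peptide(self, small_dataset):
        _, truth, repertoire, tasks = small_dataset
        results = tb.run_screening_eval(tb.OracleScorer(truth), tasks[:2], repertoire)
        assert set(results.curves) == {t.peptide for t in tasks[:2]}
        for pts in results.curves.values():
            assert pts[-1][1] == 1.0


class TestPeptideFolds:
    def test_balanced_ten_fold_split(self):
        peptides = [f"PEP{i:04d}" for i in range(1880)]
        split = tb.make_peptide_folds(peptides, 10, seed=0)
        sizes = [len(split.fold_members(f)) for f in range(10)]
        assert sizes == [188] * 10

    def test_one_peptide_per_fold(self):
        split = tb.make_peptide_folds([f"P{i}" for i in range(10)], 10, seed=1)
        assert sorted(split.assignment.values()) == list(range(10))

    def test_uneven_sizes_differ_by_at_most_one(self):
        split = tb.make_peptide_folds([f"P{i}" for i in range(17)], 5, seed=2)
        sizes = [len(split.fold_members(f)) for f in range(5)]
        assert max(sizes) - min(sizes) <= 1 and sum(sizes) == 17

    def test_seeded_determinism(self):
        peps = [f"P{i}" for i in range(50)]
        assert tb.make_peptide_folds(peps, 7, seed=3) == tb.make_peptide_folds(peps, 7, seed=3)
        assert tb.make_peptide_folds(peps, 7, seed=3) != tb.make_peptide_folds(peps, 7, seed=4)

    def test_more_folds_than_peptides_raises(self):
        with pytest.raises(EvaluationError):
            tb.make_peptide_folds(["P1", "P2"], 3, seed=0)


def _records(values, scorer="s", metric="roc_auc"):
    return [
        tb.MetricRecord(metric, v, fold_id=i, group="all", strategy="background_drawing",
                        scorer=scorer)
        for i, v in enumerate(values)
    ]


class TestAggregate:
    def test_constant_values_have_zero_sd(self):
        df = tb.aggregate(_records([0.8, 0.8, 0.8]))
        assert df.loc[0, "sd"] == 0.0
        assert df.loc[0, "mean"] == pytest.approx(0.8)
        assert df.loc[0, "n_folds"] == 3

    def test_duplicate_context_rejected(self):
        rec = _records([0.5])[0]
        with pytest.raises(EvaluationError):
            tb.aggregate([rec, rec])

    def test_fold_order_does_not_change_aggregates(self):
        rng = np.random.default_rng(0)
        records = _records(rng.random(20).tolist())
        shuffled = [records[i] for i in rng.permutation(20)]
        pd.testing.assert_frame_equal(tb.aggregate(records), tb.aggregate(shuffled))


class TestCompareScorers:
    def test_identical_records_give_p_near_one(self):
        records = _records([0.7] * 10, "a") + _records([0.7] * 10, "b")
        p = tb.compare_scorers(records, "roc_auc", "a", "b",
                               group="all", strategy="background_drawing")
        assert p > 0.9

    def test_injected_gap_detected(self):
        rng = np.random.default_rng(6)
        a = _records((0.8 + 0.01 * rng.standard_normal(100)).tolist(), "a")
        b = _records((0.6 + 0.01 * rng.standard_normal(100)).tolist(), "b")
        p = tb.compare_scorers(a + b, "roc_auc", "a", "b",
                               group="all", strategy="background_drawing", seed=1)
        assert p < 0.001

    def test_disjoint_folds_raise(self):
        a = _records([0.5], "a")
        b = [
            tb.MetricRecord("roc_auc", 0.5, fold_id=9, group="all",
                            strategy="background_drawing", scorer="b")
        ]
        with pytest.raises(EvaluationError):
            tb.compare_scorers(a + b, "roc_auc", "a", "b",
                               group="all", strategy="background_drawing")
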