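"""Evaluation protocols: balanced multi-fold classification, virtual-screening
evaluation per group, peptide-level fold splits, and aggregation.

Classification evaluation scores each balanced fold (fixed positives, fresh
seeded negatives) and reports per-group ROC-AUC, PR-AUC and confusion counts
at a fixed 0.5 threshold, with scores min-max normalized per fold when a
scorer's outputs leave [0, 1].  Screening evaluation ranks the full library
per peptide and reports group-level BEDROC (mean over per-peptide screens by
default; a pooled variant is available), hit rates and success rates over a
top-k grid, plus per-peptide enrichment curves.

Aggregation summarizes metric records as mean / sd / min / max / fold count
per (metric, group, strategy, scorer) — both the spread and the standard
deviation are reported, since fold-to-fold variability is itself a finding of
interest when negatives are resampled.  Scorer contrasts on shared folds use
a paired two-sided sign-flip resampling test.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import BINDER, GROUPS, PeptideTask, Repertoire, TcrbenchError
from .metrics import (
    DEFAULT_K_GRID,
    BedrocParams,
    RankedScreen,
    bedroc,
    bedroc_from_ranks,
    confusion_at,
    enrichment_curve,
    hit_rate,
    pr_auc,
    roc_auc,
    success_rate,
)
from .sampling import EvalFold, SamplingSpec, make_balanced_folds
from .screening import ChunkPlan, Scorer, screen_all

logger = logging.getLogger("tcrbench.evaluation")

ALL_GROUPS = "all"
SCREENING = "screening"

#: metrics emitted per fold and group by classification evaluation
CLASSIFICATION_METRICS = ("roc_auc", "pr_auc", "tp", "fp", "tn", "fn")


class EvaluationError(TcrbenchError):
    pass


@dataclass(frozen=True)
class MetricRecord:
    """One (metric, value) result row with its full evaluation context."""

    metric: str
    value: float
    fold_id: int
    group: str
    strategy: str
    scorer: str

    def key(self) -> tuple:
        return (self.metric, self.fold_id, self.group, self.strategy, self.scorer)


@dataclass(frozen=True)
class PeptideFoldSplit:
    """Size-balanced partition of peptides into folds (no peptide spans two)."""

    n_folds: int
    assignment: Mapping[str, int]

    def fold_members(self, fold: int) -> list[str]:
        return sorted(p for p, f in self.assignment.items() if f == fold)


def records_to_frame(records: Sequence[MetricRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "metric": r.metric,
                "value": r.value,
                "fold_id": r.fold_id,
                "group": r.group,
                "strategy": r.strategy,
                "scorer": r.scorer,
            }
            for r in records
        ]
    )


def _normalize_scores(scores: np.ndarray) -> np.ndarray:
    """Min-max normalize to [0, 1] when scores fall outside the unit interval."""
    lo, hi = float(scores.min()), float(scores.max())
    if lo >= 0.0 and hi <= 1.0:
        return scores
    if hi == lo:
        return np.full_like(scores, 0.5)
    return (scores - lo) / (hi - lo)


def _score_fold(scorer: Scorer, fold: EvalFold) -> np.ndarray:
    """Score a fold's pairs, batching per peptide."""
    by_pep: dict[str, list[int]] = defaultdict(list)
    for i, (pep, _, _) in enumerate(fold.pairs):
        by_pep[pep].append(i)
    scores = np.empty(len(fold.pairs))
    for pep, idx in by_pep.items():
        tcrs = [fold.pairs[i][1] for i in idx]
        got = np.asarray(scorer.score_batch(pep, tcrs), dtype=float)
        if got.shape != (len(idx),):
            raise EvaluationError(
                f"scorer {scorer.name!r} returned wrong-length batch for {pep}"
            )
        scores[idx] = got
    return scores


def run_classification_eval(
    scorer: Scorer,
    tasks: Sequence[PeptideTask],
    repertoire: Repertoire | None,
    spec: SamplingSpec,
    threshold: float = 0.5,
) -> list[MetricRecord]:
    """Balanced multi-fold classification evaluation under one sampling strategy.

    Emits, for every fold and every group present, ROC-AUC, PR-AUC and the
    confusion counts at ``threshold``.  Exactly
    ``n_folds * groups_present * len(CLASSIFICATION_METRICS)`` records are
    produced.
    """
    folds = make_balanced_folds(tasks, repertoire, spec)
    group_of = {t.peptide: t.group for t in tasks}
    groups_present = [g for g in GROUPS if any(t.group == g for t in tasks)]
    records: list[MetricRecord] = []
    for fold in folds:
        scores = _normalize_scores(_score_fold(scorer, fold))
        labels = fold.labels()
        pep_arr = np.array([p for p, _, _ in fold.pairs])
        for group in groups_present:
            mask = np.fromiter(
                (group_of[p] == group for p in pep_arr), dtype=bool, count=len(pep_arr)
            )
            y, s = labels[mask], scores[mask]
            cm = confusion_at(y, s, threshold)
            values = {
                "roc_auc": roc_auc(y, s),
                "pr_auc": pr_auc(y, s),
                "tp": cm.tp,
                "fp": cm.fp,
                "tn": cm.tn,
                "fn": cm.fn,
            }
            records.extend(
                MetricRecord(
                    metric=m,
                    value=float(values[m]),
                    fold_id=fold.fold_id,
                    group=group,
                    strategy=spec.strategy,
                    scorer=scorer.name,
                )
                for m in CLASSIFICATION_METRICS
            )
    return records


@dataclass(frozen=True)
class ScreeningResults:
    """Screening evaluation output: metric records plus per-peptide curves."""

    records: tuple[MetricRecord, ...]
    screens: tuple[RankedScreen, ...]
    curves: Mapping[str, tuple[tuple[float, float], ...]]


def run_screening_eval(
    scorer: Scorer,
    tasks: Sequence[PeptideTask],
    library: Repertoire,
    bedroc_params: BedrocParams | None = None,
    k_grid: Sequence[float] = DEFAULT_K_GRID,
    plan: ChunkPlan | None = None,
    curve_grid: Sequence[float] | None = None,
    group_bedroc: str = "mean",
    include_binders: bool = True,
) -> ScreeningResults:
    """Virtual-screening evaluation: rank the library per peptide, score groups.

    The screening universe is the background library plus every task's known
    binders (``include_binders=False`` to screen the library as given) — the
    true binders must be present among the candidates for their ranks to be
    defined.  Per group: BEDROC (mean of per-peptide screens, or
    ``group_bedroc="pooled"`` to pool normalized binder ranks across the
    group's screens), hit rate and success rate at each fraction of
    ``k_grid``.  Groups with no successfully screened peptide are skipped.
    """
    bedroc_params = bedroc_params or BedrocParams()
    if curve_grid is None:
        curve_grid = [i / 100 for i in range(1, 101)]
    if include_binders:
        library = Repertoire.from_iterable(
            list(library.sequences) + [b for t in tasks for b in t.binders],
            chain=library.chain,
        )
    screens, failures = screen_all(scorer, tasks, library, plan)
    if failures:
        logger.warning("%d peptide(s) failed screening", len(failures))
    group_of = {t.peptide: t.group for t in tasks}
    by_group: dict[str, list[RankedScreen]] = defaultdict(list)
    for s in screens:
        by_group[group_of[s.peptide]].append(s)
    N = len(library)
    records: list[MetricRecord] = []
    curves: dict[str, tuple[tuple[float, float], ...]] = {}
    for s in screens:
        curves[s.peptide] = tuple(enrichment_curve(s, curve_grid))
    for group in GROUPS:
        gscreens = by_group.get(group)
        if not gscreens:
            continue
        if group_bedroc == "pooled":
            pooled = np.concatenate(
                [
                    1.0 + (np.asarray(s.binder_ranks) - 1.0) / (s.total - 1.0) * (N - 1.0)
                    for s in gscreens
                ]
            )
            bed = bedroc_from_ranks(pooled, N, bedroc_params)
        else:
            bed = float(np.mean([bedroc(s, bedroc_params) for s in gscreens]))
        rows: list[tuple[str, float]] = [("bedroc", bed)]
        for f in k_grid:
            k = max(1, math.ceil(f * N))
            rows.append(
                (f"hit_rate@{f:g}", float(np.mean([hit_rate(s, k) for s in gscreens])))
            )
            rows.append((f"success_rate@{f:g}", success_rate(gscreens, k)))
        records.extend(
            MetricRecord(
                metric=m,
                value=v,
                fold_id=0,
                group=group,
                strategy=SCREENING,
                scorer=scorer.name,
            )
            for m, v in rows
        )
    return ScreeningResults(
        records=tuple(records), screens=tuple(screens), curves=curves
    )


def make_peptide_folds(
    peptides: Sequence[str],
    n_folds: int,
    seed: int,
) -> PeptideFoldSplit:
    """Seeded size-balanced peptide-level fold split (sizes differ by <= 1)."""
    peptides = list(dict.fromkeys(peptides))
    if n_folds < 1:
        raise EvaluationError("n_folds must be >= 1")
    if n_folds > len(peptides):
        raise EvaluationError(
            f"cannot split {len(peptides)} peptides into {n_folds} folds"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(peptides))
    assignment = {peptides[j]: i % n_folds for i, j in enumerate(order)}
    return PeptideFoldSplit(n_folds=n_folds, assignment=assignment)


def aggregate(records: Sequence[MetricRecord]) -> pd.DataFrame:
    """Summary table: mean, sd, min, max and fold count per metric context."""
    if not records:
        raise EvaluationError("no metric records to aggregate")
    keys = [r.key() for r in records]
    if len(set(keys)) != len(keys):
        raise EvaluationError("duplicate (metric, fold, group, strategy, scorer) rows")
    df = records_to_frame(records)
    out = (
        df.groupby(["metric", "group", "strategy", "scorer"], sort=True)["value"]
        .agg(mean="mean", sd="std", min="min", max="max", n_folds="count")
        .reset_index()
    )
    out["sd"] = out["sd"].fillna(0.0)
    return out


def compare_scorers(
    records: Sequence[MetricRecord],
    metric: str,
    scorer_a: str,
    scorer_b: str,
    group: str,
    strategy: str,
    n_resamples: int = 10_000,
    seed: int = 0,
) -> float:
    """Paired two-sided sign-flip resampling p-value on shared folds.

    The observed statistic is the mean fold-wise difference (A minus B); its
    null distribution is generated by randomly flipping the sign of each
    paired difference.  With identical records the p-value is 1.
    """

    def fold_values(name: str) -> dict[int, float]:
        return {
            r.fold_id: r.value
            for r in records
            if r.metric == metric
            and r.scorer == name
            and r.group == group
            and r.strategy == strategy
        }

    va, vb = fold_values(scorer_a), fold_values(scorer_b)
    shared = sorted(set(va) & set(vb))
    if not shared:
        raise EvaluationError(
            f"no shared folds for {scorer_a!r} vs {scorer_b!r} on {metric!r}"
        )
    diffs = np.array([va[f] - vb[f] for f in shared])
    obs = abs(diffs.mean())
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_resamples, diffs.size))
    null = np.abs((signs * diffs).mean(axis=1))
    return float((1 + np.count_nonzero(null >= obs - 1e-15)) / (n_resamples + 1))
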