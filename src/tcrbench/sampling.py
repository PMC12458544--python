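"""Negative-pair construction and balanced evaluation folds.

Two strategies for manufacturing non-binding (negative) peptide-TCR pairs are
supported:

* **background-drawing** — negatives are TCRs sampled uniformly without
  replacement from a large background repertoire, excluding the peptide's own
  known binders.  Negatives are easy (antigen-irrelevant), which can
  overestimate classifier performance.
* **reshuffling** — negatives are formed by permuting the TCR column across the
  known positive pairs, excluding any permuted pair that is itself a known
  positive.  Negatives are hard (every negative TCR binds *some* peptide),
  which exposes TCR-memorizing models.

Balanced evaluation repeats the negative draw: positives are held fixed across
folds while each fold draws an independent seeded negative set, giving broader
coverage of the negative space than any single balanced subset.  Fold ``i``
uses seed ``spec.seed XOR i`` (masked to 31 bits).

Neither strategy can exclude unknown cross-reactive binders; background draws
exclude only the peptide's *known* positives (a documented bias, not a solved
one).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .core import BINDER, NON_BINDER, PeptideTask, Repertoire, TcrbenchError

logger = logging.getLogger("tcrbench.sampling")

BACKGROUND_DRAWING = "background_drawing"
RESHUFFLING = "reshuffling"
STRATEGIES = (BACKGROUND_DRAWING, RESHUFFLING)

#: (peptide, tcr, label) triple
Pair = tuple[str, str, str]


class SamplingError(TcrbenchError):
    pass


@dataclass(frozen=True)
class SamplingSpec:
    """Configuration for negative sampling and fold construction."""

    strategy: str = BACKGROUND_DRAWING
    ratio: int = 1
    seed: int = 0
    n_folds: int = 100

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise SamplingError(f"unknown strategy {self.strategy!r}")
        if self.ratio < 1:
            raise SamplingError("ratio must be >= 1")
        if self.n_folds < 1:
            raise SamplingError("n_folds must be >= 1")


@dataclass(frozen=True)
class EvalFold:
    """One balanced evaluation fold: fixed positives plus one negative draw."""

    fold_id: int
    pairs: tuple[Pair, ...]
    strategy: str

    def labels(self) -> np.ndarray:
        return np.array([1 if lab == BINDER else 0 for _, _, lab in self.pairs])


def fold_seed(base_seed: int, fold_id: int) -> int:
    """Per-fold seed: base XOR fold index, masked to a positive 31-bit int."""
    return (base_seed ^ fold_id) & 0x7FFFFFFF


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def draw_background_negatives(
    task: PeptideTask,
    repertoire: Repertoire,
    ratio: int = 1,
    seed: int | np.random.Generator = 0,
    exclude_binders: bool = True,
    pool: Sequence[str] | None = None,
) -> list[Pair]:
    """Sample ``ratio * n_binders`` negatives for one peptide from the repertoire.

    Sampling is uniform without replacement over the repertoire minus the
    peptide's known binders (exclusion switchable via ``exclude_binders``).
    ``pool`` lets callers pass a precomputed exclusion-filtered candidate list
    when drawing repeatedly for the same task.
    """
    if pool is None:
        if exclude_binders:
            known = set(task.binders)
            pool = [s for s in repertoire.sequences if s not in known]
        else:
            pool = repertoire.sequences
    need = ratio * task.n_binders
    if need > len(pool):
        raise SamplingError(
            f"peptide {task.peptide}: need {need} negatives but only "
            f"{len(pool)} candidate sequences are available"
        )
    rng = _rng(seed)
    idx = rng.choice(len(pool), size=need, replace=False)
    return [(task.peptide, pool[i], NON_BINDER) for i in idx]


def _permute_with_repair(
    rng: np.random.Generator,
    peptides: list[str],
    tcrs: list[str],
    forbidden: set[tuple[str, str]],
) -> list[str] | None:
    """One permutation round: shuffle TCRs, then repair collisions by swapping.

    A position collides when its (peptide, permuted TCR) pair is forbidden
    (a known positive or a duplicate within the draw).  Returns the assigned
    TCR list, or None if repair failed.
    """
    n = len(tcrs)
    order = rng.permutation(n)
    assigned = [tcrs[j] for j in order]

    def pair_set() -> set[tuple[str, str]]:
        return {(peptides[i], assigned[i]) for i in range(n)}

    def bad_indices() -> list[int]:
        used: dict[tuple[str, str], int] = {}
        bad = []
        for i in range(n):
            key = (peptides[i], assigned[i])
            if key in forbidden or key in used:
                bad.append(i)
            else:
                used[key] = i
        return bad

    for _ in range(4):  # a few repair sweeps are plenty in practice
        bad = bad_indices()
        if not bad:
            return assigned
        current = pair_set()
        progressed = False
        for i in bad:
            for j in rng.permutation(n):
                if i == j:
                    continue
                pi, pj = (peptides[i], assigned[j]), (peptides[j], assigned[i])
                if pi in forbidden or pj in forbidden:
                    continue
                if pi in current or pj in current:
                    continue
                assigned[i], assigned[j] = assigned[j], assigned[i]
                current = pair_set()
                progressed = True
                break
        if not progressed:
            return None
    return assigned if not bad_indices() else None


def reshuffle_negatives(
    records: Iterable[BindingRecord] | Sequence[tuple[str, str]],
    seed: int | np.random.Generator = 0,
    ratio: int = 1,
    max_retries: int = 20,
) -> list[Pair]:
    """Form negatives by permuting TCRs across the known positive pairs.

    Accepts BindingRecords (binder rows are used) or raw (peptide, tcr)
    tuples.  Produces ``ratio`` negatives per positive, none of which is a
    known positive pair and none duplicated within the draw.  Permutations
    that cannot be repaired are retried up to ``max_retries`` times.

    Raises :class:`SamplingError` when fewer than two distinct peptides are
    present (every permuted pair would be a known positive).
    """
    from .core import BindingRecord  # local to avoid import cycle in type check

    positives: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    for item in records:
        if isinstance(item, BindingRecord):
            if not item.is_binder:
                continue
            key = (item.peptide, item.tcr)
        else:
            key = (item[0], item[1])
        if key not in seen:
            seen.add(key)
            positives.append(key)
    peptides = [p for p, _ in positives]
    tcrs = [t for _, t in positives]
    if len(set(peptides)) < 2:
        raise SamplingError(
            "reshuffling undefined: needs positives from at least two distinct peptides"
        )
    rng = _rng(seed)
    out: list[Pair] = []
    forbidden = set(positives)
    for _ in range(ratio):
        assigned = None
        for _attempt in range(max_retries):
            assigned = _permute_with_repair(rng, peptides, tcrs, forbidden)
            if assigned is not None:
                break
        if assigned is None:
            raise SamplingError(
                f"reshuffling failed to find a collision-free permutation in "
                f"{max_retries} attempts"
            )
        round_pairs = list(zip(peptides, assigned))
        forbidden |= set(round_pairs)  # no duplicates across ratio rounds
        out.extend((p, t, NON_BINDER) for p, t in round_pairs)
    return out


def make_balanced_folds(
    tasks: Sequence[PeptideTask],
    repertoire: Repertoire | None,
    spec: SamplingSpec,
) -> list[EvalFold]:
    """Build ``spec.n_folds`` balanced folds with fixed positives.

    Positives (every task's binders) are identical in all folds; each fold
    draws an independent negative set with seed ``fold_seed(spec.seed, i)``.
    Under background-drawing each task samples from the repertoire minus its
    own binders (pool precomputed once per task); under reshuffling the TCR
    column of the pooled positives is permuted per fold.
    """
    if not tasks:
        raise SamplingError("no tasks to build folds from")
    if spec.strategy == BACKGROUND_DRAWING and repertoire is None:
        raise SamplingError("background_drawing requires a repertoire")

    positives: list[Pair] = [
        (t.peptide, b, BINDER) for t in tasks for b in t.binders
    ]
    pos_tuples = [(p, t) for p, t, _ in positives]

    pools: list[list[str]] = []
    if spec.strategy == BACKGROUND_DRAWING:
        assert repertoire is not None
        for task in tasks:
            known = set(task.binders)
            pools.append([s for s in repertoire.sequences if s not in known])

    folds: list[EvalFold] = []
    for fid in range(spec.n_folds):
        fseed = fold_seed(spec.seed, fid)
        try:
            if spec.strategy == BACKGROUND_DRAWING:
                rng = np.random.default_rng(fseed)
                negatives: list[Pair] = []
                for task, pool in zip(tasks, pools):
                    negatives.extend(
                        draw_background_negatives(
                            task, repertoire, ratio=spec.ratio, seed=rng, pool=pool
                        )
                    )
            else:
                negatives = reshuffle_negatives(pos_tuples, seed=fseed, ratio=spec.ratio)
        except SamplingError as exc:
            raise SamplingError(f"fold {fid}: {exc}") from exc
        folds.append(
            EvalFold(fold_id=fid, pairs=tuple(positives + negatives), strategy=spec.strategy)
        )
    logger.info(
        "built %d %s fold(s): %d positives each", len(folds), spec.strategy, len(positives)
    )
    return folds


def check_balanced(fold: EvalFold, ratio: int = 1) -> bool:
    """True when every peptide has exactly ``ratio`` negatives per positive."""
    from collections import Counter

    pos = Counter(p for p, _, lab in fold.pairs if lab == BINDER)
    neg = Counter(p for p, _, lab in fold.pairs if lab == NON_BINDER)
    return set(pos) == set(neg) and all(neg[p] == ratio * pos[p] for p in pos)
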