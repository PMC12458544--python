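"""Classification and early-enrichment metrics.

Virtual-screening evaluation ranks an entire TCR library against one peptide
by predicted binding score and asks how early the true binders appear.  With
``N`` the library size, ``n`` the number of true binders and ``r_i`` their
1-based positions in the score-sorted list, the normalized rank is
``R_i = (r_i - 1) / (N - 1)`` and the default BEDROC variant is

    BEDROC_alpha = alpha / (1 - exp(-alpha)) * (1/n) * sum_i exp(-alpha * R_i)

with ``alpha = 20`` by default.  This form is a *relative* enrichment score:
its expectation under uniform-random ranking is 1 (because
``E[exp(-alpha R)] = (1 - exp(-alpha)) / alpha`` for uniform ``R``) and its
maximum approaches ``alpha / (1 - exp(-alpha))`` (~20 for alpha=20) when all
binders sit at the very top.  The conventional Truchon-Bayly BEDROC, bounded
to [0, 1], is available as variant ``"truchon_bayly"`` for comparability with
the cheminformatics literature; it is never silently substituted for the
default.

Classification metrics (ROC-AUC, PR-AUC) are computed through scikit-learn;
ROC-AUC equals the pairwise-concordance (rank-sum) statistic with ties
counted 1/2, and PR-AUC is step-wise average precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .core import TcrbenchError

RELATIVE = "relative"
TRUCHON_BAYLY = "truchon_bayly"

#: default top-k grid as fractions of the library: 0.01%, 0.1%, 1%, 5%, 10%
DEFAULT_K_GRID = (0.0001, 0.001, 0.01, 0.05, 0.1)


class MetricError(TcrbenchError):
    pass


@dataclass(frozen=True)
class RankedScreen:
    """Ranking outcome of one peptide against a library of size ``total``.

    ``binder_ranks`` holds the 1-based positions of the true binders in the
    score-sorted candidate list, strictly increasing.
    """

    peptide: str
    total: int
    binder_ranks: tuple[int, ...]

    def __post_init__(self) -> None:
        N = self.total
        ranks = self.binder_ranks
        if N < 1:
            raise MetricError("library size must be >= 1")
        if len(ranks) > N:
            raise MetricError("more binders than library entries")
        if any(not 1 <= r <= N for r in ranks):
            raise MetricError(f"ranks must lie in [1, {N}]")
        if any(b <= a for a, b in zip(ranks, ranks[1:])):
            raise MetricError("binder ranks must be strictly increasing")

    @property
    def n(self) -> int:
        return len(self.binder_ranks)


@dataclass(frozen=True)
class BedrocParams:
    """Early-enrichment weighting: ``alpha`` controls top-rank emphasis."""

    alpha: float = 20.0
    variant: str = RELATIVE

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise MetricError("alpha must be positive")
        if self.variant not in (RELATIVE, TRUCHON_BAYLY):
            raise MetricError(f"unknown BEDROC variant {self.variant!r}")


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int
    threshold: float

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def fpr(self) -> float:
        return self.fp / (self.fp + self.tn) if (self.fp + self.tn) else math.nan

    @property
    def tpr(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else math.nan


# ---------------------------------------------------------------------------
# rank extraction

def rank_screen(
    peptide: str,
    scores: np.ndarray,
    is_binder: np.ndarray,
    tie: str = "stable",
) -> RankedScreen:
    """Extract binder ranks from raw library scores.

    Candidates are ordered by descending score; ties are broken by library
    index (``tie="stable"``), keeping rankings deterministic.  For a mid-rank
    tie policy use :func:`midrank_binder_ranks` with :func:`bedroc_from_ranks`.
    """
    scores = np.asarray(scores, dtype=float)
    is_binder = np.asarray(is_binder, dtype=bool)
    if scores.shape != is_binder.shape:
        raise MetricError("scores and binder mask must have equal length")
    if tie != "stable":
        raise MetricError("rank_screen supports only the stable tie policy")
    order = np.argsort(-scores, kind="stable")
    ranks = np.nonzero(is_binder[order])[0] + 1
    return RankedScreen(peptide=peptide, total=scores.size, binder_ranks=tuple(ranks.tolist()))


def midrank_binder_ranks(scores: np.ndarray, is_binder: np.ndarray) -> np.ndarray:
    """Binder ranks with tied scores assigned their mid (average) rank."""
    from scipy.stats import rankdata

    scores = np.asarray(scores, dtype=float)
    is_binder = np.asarray(is_binder, dtype=bool)
    ranks = rankdata(-scores, method="average")
    return np.sort(ranks[is_binder])


# ---------------------------------------------------------------------------
# BEDROC

def bedroc_from_ranks(
    ranks: Sequence[float] | np.ndarray,
    total: int,
    params: BedrocParams | None = None,
) -> float:
    """BEDROC from (possibly fractional, mid-rank) binder ranks."""
    params = params or BedrocParams()
    r = np.asarray(ranks, dtype=float)
    n, N, a = r.size, total, params.alpha
    if n == 0:
        raise MetricError("BEDROC undefined with zero binders")
    if N < 2:
        raise MetricError("BEDROC requires a library of at least 2 candidates")
    if params.variant == RELATIVE:
        R = (r - 1.0) / (N - 1.0)
        return float(a / (1.0 - math.exp(-a)) * np.mean(np.exp(-a * R)))
    # Truchon-Bayly bounded form
    ra = n / N
    rie_num = float(np.sum(np.exp(-a * r / N))) / n
    rie_den = (1.0 / N) * (1.0 - math.exp(-a)) / (math.exp(a / N) - 1.0)
    rie = rie_num / rie_den
    factor = ra * math.sinh(a / 2.0) / (math.cosh(a / 2.0) - math.cosh(a / 2.0 - a * ra))
    return float(rie * factor + 1.0 / (1.0 - math.exp(a * (1.0 - ra))))


def bedroc(screen: RankedScreen, params: BedrocParams | None = None) -> float:
    """Early-enrichment BEDROC of one ranked screen (see module docstring)."""
    return bedroc_from_ranks(screen.binder_ranks, screen.total, params)


def max_bedroc(n: int, total: int, params: BedrocParams | None = None) -> float:
    """BEDROC attained when the ``n`` binders occupy ranks 1..n (the ceiling)."""
    return bedroc_from_ranks(np.arange(1, n + 1), total, params)


# ---------------------------------------------------------------------------
# enrichment curve, hit rate, success rate

def enrichment_curve(
    screen: RankedScreen,
    grid: Sequence[float],
) -> list[tuple[float, float]]:
    """Cumulative fraction of binders recovered vs fraction of list examined.

    For each grid fraction ``f`` in (0, 1], the examined prefix has
    ``ceil(f * N)`` entries and the recovered fraction is the share of binder
    ranks inside it.  The curve is non-decreasing and reaches 1 at ``f = 1``.
    """
    if len(grid) == 0:
        raise MetricError("enrichment grid is empty")
    if any(not 0.0 < f <= 1.0 for f in grid):
        raise MetricError("grid fractions must lie in (0, 1]")
    if screen.n == 0:
        raise MetricError("enrichment undefined with zero binders")
    ranks = np.asarray(screen.binder_ranks)
    out = []
    for f in grid:
        k = math.ceil(f * screen.total)
        out.append((f, float(np.count_nonzero(ranks <= k)) / screen.n))
    return out


def hit_rate(screen: RankedScreen, k: int) -> float:
    """Fraction of true binders retrieved within the top-``k`` predictions."""
    if not 1 <= k <= screen.total:
        raise MetricError(f"k={k} outside [1, {screen.total}]")
    if screen.n == 0:
        raise MetricError("hit rate undefined with zero binders")
    ranks = np.asarray(screen.binder_ranks)
    return float(np.count_nonzero(ranks <= k)) / screen.n


def success_rate(screens: Sequence[RankedScreen], k: int) -> float:
    """Fraction of peptides with at least one binder in their top-``k``.

    This is the virtual-screening convention for per-query success; k is
    clipped per screen to its library size.
    """
    if not screens:
        raise MetricError("success rate needs at least one screen")
    if k < 1:
        raise MetricError("k must be >= 1")
    hits = sum(
        1 for s in screens if s.binder_ranks and s.binder_ranks[0] <= min(k, s.total)
    )
    return hits / len(screens)


# ---------------------------------------------------------------------------
# classification metrics

def _as_arrays(labels: Sequence[int], scores: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise MetricError("labels and scores must have equal length")
    return y, s


def roc_auc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """ROC-AUC: concordant-pair statistic with ties counted 1/2."""
    y, s = _as_arrays(labels, scores)
    if len(np.unique(y)) < 2:
        raise MetricError("ROC-AUC needs both classes present")
    return float(roc_auc_score(y, s))


def pr_auc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """PR-AUC as step-wise average precision over descending-score prefixes."""
    y, s = _as_arrays(labels, scores)
    if int(y.sum()) == 0:
        raise MetricError("PR-AUC needs at least one positive")
    return float(average_precision_score(y, s))


def confusion_at(
    labels: Sequence[int],
    scores: Sequence[float],
    threshold: float,
) -> ConfusionMatrix:
    """Confusion counts with ``score >= threshold`` predicting binder."""
    y, s = _as_arrays(labels, scores)
    pred = s >= threshold
    pos = y == 1
    return ConfusionMatrix(
        tp=int(np.count_nonzero(pred & pos)),
        fp=int(np.count_nonzero(pred & ~pos)),
        tn=int(np.count_nonzero(~pred & ~pos)),
        fn=int(np.count_nonzero(~pred & pos)),
        threshold=threshold,
    )
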