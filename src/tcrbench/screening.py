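"""Repertoire-scale virtual screening.

A scorer is any object satisfying :class:`Scorer`: it maps one peptide plus a
batch of TCR sequences to real-valued binding scores, higher meaning more
likely to bind.  Screening scores the *entire* library for each peptide in
fixed-size chunks, materializes the score vector for that one peptide, reduces
it to a ranking, and discards it before moving on — so peak retained state is
one score vector plus the binder ranks, never a peptides-by-library matrix.
Chunking is purely an execution detail: concatenated chunk scores are
bit-equal regardless of chunk size, which requires scorers to be pure
functions of (peptide, TCR) identity.

External predictors plug in without code coupling through
:class:`TableScorer`, which reads a pre-computed ``peptide <tab> tcr <tab>
score`` table.
"""

from __future__ import annotations

import logging
from abc import ABC, abstractmethod
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import PeptideTask, Repertoire, TcrbenchError
from .metrics import RankedScreen, rank_screen

logger = logging.getLogger("tcrbench.screening")


class ScorerError(TcrbenchError):
    pass


class Scorer(ABC):
    """Contract for pluggable peptide-TCR scorers.

    ``chains`` declares which CDR3 chain(s) the scorer expects
    (``alpha``/``beta``/``alphabeta``); paired sequences are passed as
    ``"<alpha>|<beta>"`` strings.  Scores must be deterministic: the same
    (peptide, TCR) input yields the same output, with any stochasticity
    carried by the scorer's own fixed seed.
    """

    name: str = "scorer"
    chains: str = "beta"

    @abstractmethod
    def score_batch(self, peptide: str, tcrs: Sequence[str]) -> np.ndarray:
        """Return one score per TCR, aligned with the input order."""


class TableScorer(Scorer):
    """Offline scorer backed by a pre-computed (peptide, tcr, score) table."""

    def __init__(self, table, name: str = "table", chains: str = "beta"):
        import pandas as pd

        if not isinstance(table, pd.DataFrame):
            table = pd.read_csv(table, sep="\t", dtype={"peptide": str, "tcr": str})
        missing = {"peptide", "tcr", "score"} - set(table.columns)
        if missing:
            raise ScorerError(f"score table missing columns {sorted(missing)}")
        self._scores = {
            (p, t): float(s)
            for p, t, s in zip(table["peptide"], table["tcr"], table["score"])
        }
        self.name = name
        self.chains = chains

    def score_batch(self, peptide: str, tcrs: Sequence[str]) -> np.ndarray:
        out = np.empty(len(tcrs))
        for i, t in enumerate(tcrs):
            try:
                out[i] = self._scores[(peptide, t)]
            except KeyError:
                raise ScorerError(
                    f"score table has no entry for peptide {peptide!r}, TCR {t!r}"
                ) from None
        return out


@dataclass(frozen=True)
class ChunkPlan:
    """Chunked execution layout for scoring a library of ``total`` sequences."""

    chunk_size: int = 10_000
    total: int = 0

    def __post_init__(self) -> None:
        if self.chunk_size < 1:
            raise ScorerError("chunk_size must be >= 1")


@dataclass(frozen=True)
class ScreenResult:
    """One peptide's screen: binder ranks plus the full ranked library order."""

    screen: RankedScreen
    order: np.ndarray  # library indices sorted best-first

    @property
    def peptide(self) -> str:
        return self.screen.peptide


@dataclass
class FailureReport:
    """Per-peptide failures collected during a multi-peptide screening run."""

    failures: list[tuple[str, str]] = field(default_factory=list)

    def add(self, peptide: str, error: Exception) -> None:
        self.failures.append((peptide, str(error)))

    def __len__(self) -> int:
        return len(self.failures)


def score_library(
    scorer: Scorer,
    peptide: str,
    library: Repertoire,
    plan: ChunkPlan | None = None,
) -> np.ndarray:
    """Score every library sequence for one peptide, chunk by chunk."""
    plan = plan or ChunkPlan()
    N = len(library)
    seqs = library.sequences
    scores = np.empty(N, dtype=float)
    for start in range(0, N, plan.chunk_size):
        chunk = seqs[start : start + plan.chunk_size]
        got = np.asarray(scorer.score_batch(peptide, chunk), dtype=float)
        if got.shape != (len(chunk),):
            raise ScorerError(
                f"scorer {scorer.name!r} returned {got.shape} scores for a "
                f"chunk of {len(chunk)}"
            )
        scores[start : start + len(chunk)] = got
    return scores


def screen_peptide(
    scorer: Scorer,
    peptide: str,
    library: Repertoire,
    truth_tcrs: Sequence[str] | set[str],
    plan: ChunkPlan | None = None,
) -> ScreenResult:
    """Rank the whole library for one peptide and locate its true binders.

    Truth binders are matched by exact sequence identity against the library.
    Ties in score are broken by library index (stable), matching the metrics
    module's default tie policy.
    """
    if len(library) == 0:
        raise ScorerError("library is empty")
    scores = score_library(scorer, peptide, library, plan)
    truth = set(truth_tcrs)
    is_binder = np.fromiter(
        (s in truth for s in library.sequences), dtype=bool, count=len(library)
    )
    order = np.argsort(-scores, kind="stable")
    screen = rank_screen(peptide, scores, is_binder)
    return ScreenResult(screen=screen, order=order)


def screen_all(
    scorer: Scorer,
    tasks: Sequence[PeptideTask],
    library: Repertoire,
    plan: ChunkPlan | None = None,
) -> tuple[list[RankedScreen], FailureReport]:
    """Screen every task's peptide against the library, in task order.

    Per-peptide failures are collected into the report and the run continues;
    only binder ranks are retained across peptides (scores are released after
    each reduction).
    """
    screens: list[RankedScreen] = []
    report = FailureReport()
    for i, task in enumerate(tasks):
        try:
            result = screen_peptide(scorer, task.peptide, library, task.binders, plan)
            screens.append(result.screen)
        except TcrbenchError as exc:
            logger.warning("screening failed for peptide %s: %s", task.peptide, exc)
            report.add(task.peptide, exc)
        if (i + 1) % 10 == 0 or i + 1 == len(tasks):
            logger.info("screened %d/%d peptides", i + 1, len(tasks))
    return screens, report


def fuse_alpha_beta(
    score_alpha: Sequence[float] | np.ndarray,
    score_beta: Sequence[float] | np.ndarray,
) -> np.ndarray:
    """Element-wise arithmetic mean of alpha- and beta-chain scores.

    Combining independent single-chain predictors by averaging their scores is
    the standard recipe for paired-receptor prediction when no paired-trained
    model exists.
    """
    a = np.asarray(score_alpha, dtype=float)
    b = np.asarray(score_beta, dtype=float)
    if a.shape != b.shape:
        raise ScorerError(f"score length mismatch: {a.shape} vs {b.shape}")
    return (a + b) / 2.0


class FusedScorer(Scorer):
    """Average of an alpha-chain and a beta-chain scorer on paired receptors.

    Expects paired ``"<alpha>|<beta>"`` TCR keys; each component scorer sees
    only its own chain.
    """

    def __init__(self, alpha_scorer: Scorer, beta_scorer: Scorer, name: str = "fused"):
        self.alpha_scorer = alpha_scorer
        self.beta_scorer = beta_scorer
        self.name = name
        self.chains = "alphabeta"

    def score_batch(self, peptide: str, tcrs: Sequence[str]) -> np.ndarray:
        from .core import CHAIN_SEP

        alphas, betas = [], []
        for t in tcrs:
            if CHAIN_SEP not in t:
                raise ScorerError(f"paired scorer got unpaired TCR {t!r}")
            a, b = t.split(CHAIN_SEP, 1)
            alphas.append(a)
            betas.append(b)
        return fuse_alpha_beta(
            self.alpha_scorer.score_batch(peptide, alphas),
            self.beta_scorer.score_batch(peptide, betas),
        )
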