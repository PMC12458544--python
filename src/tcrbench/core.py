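"""Domain model for peptide-TCR binding benchmarks.

A benchmark instance is a table of peptide-TCR binding observations
(:class:`BindingRecord`), a background library of TCR sequences
(:class:`Repertoire`) that serves as the screening universe, and a set of
per-peptide evaluation tasks (:class:`PeptideTask`) stratified by how many
binders each peptide has.  Stratification follows the three-regime convention
used throughout few-shot TCR-specificity work: *majority* peptides with at
least 100 known binders, *few-shot* peptides with 5-100, and *zero-shot*
peptides with fewer than 5.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger("tcrbench.core")

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")
AA_LETTERS = "ACDEFGHIKLMNPQRSTVWY"

BINDER = "binder"
NON_BINDER = "non-binder"

#: groups, in canonical reporting order
MAJORITY = "majority"
FEWSHOT = "fewshot"
ZEROSHOT = "zeroshot"
GROUPS = (MAJORITY, FEWSHOT, ZEROSHOT)

#: separator joining the alpha and beta CDR3 of a paired receptor into one
#: library key; '|' is outside the amino-acid alphabet so the key is unambiguous
CHAIN_SEP = "|"


class TcrbenchError(Exception):
    """Base class for all package errors."""


class ValidationError(TcrbenchError):
    pass


@dataclass(frozen=True)
class BindingRecord:
    """One peptide-TCR observation: the pair, its binary label, and provenance.

    At least one CDR3 chain must be present.  ``label`` is either
    ``"binder"`` or ``"non-binder"``.
    """

    peptide: str
    cdr3_beta: str | None = None
    cdr3_alpha: str | None = None
    label: str = BINDER
    source: str = ""

    @property
    def tcr(self) -> str:
        """Canonical TCR identity used for grouping, dedup and screening.

        Paired alpha/beta receptors are keyed as ``"<alpha>|<beta>"``;
        single-chain records use the chain that is present.
        """
        if self.cdr3_alpha and self.cdr3_beta:
            return f"{self.cdr3_alpha}{CHAIN_SEP}{self.cdr3_beta}"
        return self.cdr3_beta or self.cdr3_alpha or ""

    @property
    def is_binder(self) -> bool:
        return self.label == BINDER


@dataclass(frozen=True)
class Repertoire:
    """Deduplicated background library of TCR sequences (the screening universe).

    ``chain`` records which CDR3 chain the sequences represent; paired
    ``alphabeta`` libraries store ``"<alpha>|<beta>"`` keys.  Iteration order is
    the (first-occurrence) order of the input, so a repertoire loaded twice from
    the same file is identical.
    """

    sequences: tuple[str, ...]
    chain: str = "beta"

    def __post_init__(self) -> None:
        if len(self.sequences) < 1:
            raise ValidationError("repertoire must contain at least one sequence")
        if len(set(self.sequences)) != len(self.sequences):
            raise ValidationError("repertoire contains duplicate sequences")
        if self.chain not in ("alpha", "beta", "alphabeta"):
            raise ValidationError(f"unknown chain {self.chain!r}")

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self):
        return iter(self.sequences)

    @classmethod
    def from_iterable(cls, sequences: Iterable[str], chain: str = "beta") -> "Repertoire":
        """Build a repertoire, dropping duplicates while preserving first-seen order."""
        return cls(tuple(dict.fromkeys(sequences)), chain=chain)


@dataclass(frozen=True)
class GroupThresholds:
    """Binder-count boundaries separating majority / few-shot / zero-shot peptides.

    Defaults implement: count >= 100 -> majority, 5 <= count <= 100 -> few-shot,
    count < 5 -> zero-shot.  The 100-binder boundary is assigned to the majority
    group; set ``majority_min=101`` to adopt the strict "more than 100" reading
    instead.
    """

    majority_min: int = 100
    fewshot_min: int = 5
    fewshot_max: int = 100
    zeroshot_max_exclusive: int = 5

    def __post_init__(self) -> None:
        if not (
            self.zeroshot_max_exclusive <= self.fewshot_min
            <= self.fewshot_max
            and self.fewshot_min <= self.majority_min
        ):
            raise ValidationError(f"inconsistent group thresholds: {self}")

    def classify(self, n_binders: int) -> str:
        if n_binders >= self.majority_min:
            return MAJORITY
        if n_binders >= self.fewshot_min:
            return FEWSHOT
        return ZEROSHOT


@dataclass(frozen=True)
class PeptideTask:
    """One peptide with its known binders and group assignment.

    ``support`` is the subset of binders reserved for task adaptation (may be
    empty); ``query`` holds the remaining binders used for evaluation.
    ``support`` and ``query`` partition ``binders``.
    """

    peptide: str
    binders: tuple[str, ...]
    group: str
    support: tuple[str, ...] = ()
    query: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.query and not self.support:
            object.__setattr__(self, "query", self.binders)
        sup, qry = set(self.support), set(self.query)
        if sup & qry:
            raise ValidationError(f"support and query overlap for {self.peptide}")
        if sup | qry != set(self.binders):
            raise ValidationError(f"support+query must cover binders for {self.peptide}")

    @property
    def n_binders(self) -> int:
        return len(self.binders)


@dataclass(frozen=True)
class SplitReport:
    """Partition of test records by TCR membership in a reference set."""

    seen_subset: tuple[BindingRecord, ...]
    unseen_subset: tuple[BindingRecord, ...]
    reference_tcrs: int
    novel_tcrs: int


@dataclass(frozen=True)
class ValidationRules:
    """Sequence-validity bounds.  Length windows are inclusive."""

    peptide_len: tuple[int, int] = (8, 15)
    cdr3_len: tuple[int, int] = (6, 30)


def _check_chain(seq: str, lo: int, hi: int) -> str | None:
    """Return a rejection reason for one chain sequence, or None if valid."""
    if not seq:
        return "empty sequence"
    if not set(seq) <= AA_ALPHABET:
        bad = sorted(set(seq) - AA_ALPHABET)
        return f"invalid characters {bad}"
    if not lo <= len(seq) <= hi:
        return f"length {len(seq)} outside [{lo}, {hi}]"
    return None


def validate_records(
    records: Iterable[BindingRecord],
    rules: ValidationRules | None = None,
) -> list[BindingRecord]:
    """Keep records whose sequences pass alphabet and length validation.

    Rejection counts are logged per reason.  Raises :class:`ValidationError`
    if no record survives.
    """
    rules = rules or ValidationRules()
    kept: list[BindingRecord] = []
    reasons: dict[str, int] = defaultdict(int)
    n_in = 0
    for rec in records:
        n_in += 1
        why = None
        if not rec.peptide:
            why = "peptide: empty sequence"
        else:
            r = _check_chain(rec.peptide, *rules.peptide_len)
            if r:
                why = f"peptide: {r}"
        if why is None and not rec.cdr3_beta and not rec.cdr3_alpha:
            why = "no CDR3 chain present"
        if why is None:
            for name, seq in (("cdr3_beta", rec.cdr3_beta), ("cdr3_alpha", rec.cdr3_alpha)):
                if seq is not None:
                    r = _check_chain(seq, *rules.cdr3_len)
                    if r:
                        why = f"{name}: {r}"
                        break
        if why is None and rec.label not in (BINDER, NON_BINDER):
            why = f"label: {rec.label!r} not in {{binder, non-binder}}"
        if why is None:
            kept.append(rec)
        else:
            reasons[why] += 1
    for why, n in sorted(reasons.items()):
        logger.warning("rejected %d record(s): %s", n, why)
    if n_in and not kept:
        raise ValidationError("no valid records after validation")
    return kept


def dedupe_records(records: Iterable[BindingRecord]) -> list[BindingRecord]:
    """Collapse duplicate (peptide, TCR, label) rows; drop label-conflicting pairs.

    A (peptide, TCR) pair observed with both labels has no resolution rule, so
    both rows are dropped with a warning (conservative).
    """
    labels: dict[tuple[str, str], set[str]] = defaultdict(set)
    ordered: list[BindingRecord] = []
    seen: set[tuple[str, str, str]] = set()
    for rec in records:
        key = (rec.peptide, rec.tcr, rec.label)
        labels[(rec.peptide, rec.tcr)].add(rec.label)
        if key not in seen:
            seen.add(key)
            ordered.append(rec)
    conflicted = {k for k, v in labels.items() if len(v) > 1}
    if conflicted:
        logger.warning(
            "dropping %d (peptide, TCR) pair(s) with conflicting labels", len(conflicted)
        )
    return [r for r in ordered if (r.peptide, r.tcr) not in conflicted]


def stratify_peptides(
    records: Iterable[BindingRecord],
    thresholds: GroupThresholds | None = None,
) -> list[PeptideTask]:
    """Group records by peptide and assign each peptide to a binder-count group.

    Each distinct peptide with at least one binder yields exactly one
    :class:`PeptideTask`; peptides with zero binders cannot form a task and are
    skipped with a warning.  Group assignment is a pure function of the number
    of distinct binder TCRs under ``thresholds``.  Duplicate and
    label-conflicting rows are resolved by :func:`dedupe_records` first, so the
    result is invariant to record order and duplication.
    """
    thresholds = thresholds or GroupThresholds()
    by_pep: dict[str, list[BindingRecord]] = defaultdict(list)
    for rec in dedupe_records(records):
        by_pep[rec.peptide].append(rec)
    tasks: list[PeptideTask] = []
    for pep in sorted(by_pep):
        binders = tuple(sorted({r.tcr for r in by_pep[pep] if r.is_binder}))
        if not binders:
            logger.warning("peptide %s has no binders; cannot form a task", pep)
            continue
        tasks.append(
            PeptideTask(peptide=pep, binders=binders, group=thresholds.classify(len(binders)))
        )
    return tasks


def split_support_query(task: PeptideTask, support_size: int, seed: int) -> PeptideTask:
    """Reserve a seeded random subset of binders as the adaptation support set."""
    import numpy as np

    if support_size >= task.n_binders:
        raise ValidationError(
            f"support_size {support_size} must leave at least one query binder "
            f"(peptide {task.peptide} has {task.n_binders})"
        )
    rng = np.random.default_rng(seed)
    idx = set(rng.choice(task.n_binders, size=support_size, replace=False).tolist())
    support = tuple(b for i, b in enumerate(task.binders) if i in idx)
    query = tuple(b for i, b in enumerate(task.binders) if i not in idx)
    return replace(task, support=support, query=query)


def split_seen_unseen(
    test_records: Sequence[BindingRecord],
    reference_tcrs: Iterable[str],
) -> SplitReport:
    """Partition test records by exact TCR membership in a reference TCR set.

    Records whose TCR occurs in the reference set form the *seen* subset;
    the rest pair unseen peptides with novel TCRs (the stricter
    unknown-unknown generalization test).
    """
    ref = set(reference_tcrs)
    if not ref:
        raise ValidationError("reference TCR set is empty")
    seen = tuple(r for r in test_records if r.tcr in ref)
    unseen = tuple(r for r in test_records if r.tcr not in ref)
    novel = {r.tcr for r in unseen}
    return SplitReport(
        seen_subset=seen,
        unseen_subset=unseen,
        reference_tcrs=len(ref),
        novel_tcrs=len(novel),
    )
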