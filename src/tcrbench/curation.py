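"""Dataset-construction logic for independent benchmarks.

Multi-source binding tables (e.g. exports from IEDB, VDJdb, McPAS) are merged
under a per-source column mapping, passed through configurable conjunctive
quality filters, deduplicated against a reference dataset (typically a
model's original training/evaluation data), and reduced to peptides with
enough binders to form tasks.  The exact quality-control criteria used by
published pipelines are rarely enumerated, so filters here are explicit,
configurable rules — the shipped defaults (valid alphabet, length bounds) are
a reconstruction, and every report header says so.

All steps operate on local tables only; no database clients are included.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core import (
    AA_ALPHABET,
    BINDER,
    NON_BINDER,
    BindingRecord,
    TcrbenchError,
)

logger = logging.getLogger("tcrbench.curation")

RECONSTRUCTION_NOTE = (
    "filter defaults are a reconstruction (valid alphabet + length bounds), "
    "not a published criteria list"
)


class CurationError(TcrbenchError):
    pass


@dataclass(frozen=True)
class FilterRule:
    """One conjunctive quality filter: (field, relation, value).

    Supported relations: ``min_len``, ``max_len``, ``alphabet`` (value
    ignored), ``equals``, ``not_equals``, ``in``.  Field ``cdr3`` applies to
    every chain present on the record.  Rules are order-independent.
    """

    name: str
    field: str
    relation: str
    value: object = None
    enabled: bool = True

    def _check_one(self, seq: str) -> bool:
        if self.relation == "min_len":
            return len(seq) >= int(self.value)  # type: ignore[arg-type]
        if self.relation == "max_len":
            return len(seq) <= int(self.value)  # type: ignore[arg-type]
        if self.relation == "alphabet":
            return set(seq) <= AA_ALPHABET
        if self.relation == "equals":
            return seq == self.value
        if self.relation == "not_equals":
            return seq != self.value
        if self.relation == "in":
            return seq in self.value  # type: ignore[operator]
        raise CurationError(f"unknown relation {self.relation!r}")

    def passes(self, rec: BindingRecord) -> bool:
        if self.field == "cdr3":
            chains = [c for c in (rec.cdr3_beta, rec.cdr3_alpha) if c]
            return all(self._check_one(c) for c in chains)
        value = getattr(rec, self.field, None)
        if value is None:
            return True  # absent field: rule does not apply
        return self._check_one(value)


DEFAULT_FILTERS = (
    FilterRule("peptide_alphabet", "peptide", "alphabet"),
    FilterRule("cdr3_alphabet", "cdr3", "alphabet"),
    FilterRule("peptide_min_len", "peptide", "min_len", 8),
    FilterRule("peptide_max_len", "peptide", "max_len", 15),
    FilterRule("cdr3_min_len", "cdr3", "min_len", 6),
    FilterRule("cdr3_max_len", "cdr3", "max_len", 30),
)

_CANONICAL_LABELS = {
    "1": BINDER, "binder": BINDER, "true": BINDER, "positive": BINDER,
    "0": NON_BINDER, "non-binder": NON_BINDER, "nonbinder": NON_BINDER,
    "false": NON_BINDER, "negative": NON_BINDER,
}


def normalize_label(value: object) -> str:
    key = str(value).strip().lower()
    if key not in _CANONICAL_LABELS:
        raise CurationError(f"unrecognized label value {value!r}")
    return _CANONICAL_LABELS[key]


def merge_sources(
    tables: Sequence[pd.DataFrame],
    column_maps: Sequence[Mapping[str, str] | None] | None = None,
) -> list[BindingRecord]:
    """Concatenate source tables into one deduplicated record list.

    ``column_maps[i]`` maps table ``i``'s header names onto the canonical
    schema fields (peptide, cdr3b, cdr3a, label, source); None means the
    table already uses canonical headers.  Exact duplicate rows (same
    peptide, chains, label) are collapsed with their source tags joined by
    ``;``.  Empty tables are skipped with a warning; a table missing the
    peptide or label column, or both chain columns, raises.
    """
    if column_maps is None:
        column_maps = [None] * len(tables)
    merged: dict[tuple, BindingRecord] = {}
    for i, (table, cmap) in enumerate(zip(tables, column_maps)):
        if table.empty:
            logger.warning("source table %d is empty; skipped", i)
            continue
        df = table.rename(columns=dict(cmap)) if cmap else table
        cols = set(df.columns)
        missing = {"peptide", "label"} - cols
        if missing or not ({"cdr3b", "cdr3a"} & cols):
            need = sorted(missing | ({"cdr3b|cdr3a"} if not ({"cdr3b", "cdr3a"} & cols) else set()))
            raise CurationError(f"source table {i} missing columns {need}")
        for row in df.itertuples(index=False):
            d = row._asdict()
            rec = BindingRecord(
                peptide=str(d["peptide"]),
                cdr3_beta=_opt(d.get("cdr3b")),
                cdr3_alpha=_opt(d.get("cdr3a")),
                label=normalize_label(d["label"]),
                source=str(d.get("source", "") or ""),
            )
            key = (rec.peptide, rec.cdr3_beta, rec.cdr3_alpha, rec.label)
            if key in merged:
                prev = merged[key]
                tags = [t for t in prev.source.split(";") if t]
                if rec.source and rec.source not in tags:
                    tags.append(rec.source)
                merged[key] = BindingRecord(
                    rec.peptide, rec.cdr3_beta, rec.cdr3_alpha, rec.label, ";".join(tags)
                )
            else:
                merged[key] = rec
    return list(merged.values())


def _opt(value: object) -> str | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    return s or None


def apply_filters(
    records: Iterable[BindingRecord],
    rules: Sequence[FilterRule] = DEFAULT_FILTERS,
) -> tuple[list[BindingRecord], dict[str, int]]:
    """Apply the conjunction of enabled rules; report per-rule removal counts.

    Counts are computed independently per rule over the *input* records, so
    the report is order-independent (a record failing two rules is counted
    under both).
    """
    records = list(records)
    active = [r for r in rules if r.enabled]
    report = {r.name: sum(0 if r.passes(rec) else 1 for rec in records) for r in active}
    kept = [rec for rec in records if all(r.passes(rec) for r in active)]
    logger.info(
        "filters kept %d/%d records (%s)", len(kept), len(records), RECONSTRUCTION_NOTE
    )
    return kept, report


def exclude_reference(
    records: Iterable[BindingRecord],
    reference: Iterable[BindingRecord],
    mode: str = "pair",
) -> list[BindingRecord]:
    """Remove records overlapping a reference dataset.

    ``mode`` sets the granularity: ``pair`` (exact peptide+TCR match, the
    default), ``peptide`` (any record of a reference peptide), or ``tcr``
    (any record carrying a reference TCR).
    """
    ref = list(reference)
    if mode == "pair":
        ref_keys = {(r.peptide, r.tcr) for r in ref}
        return [r for r in records if (r.peptide, r.tcr) not in ref_keys]
    if mode == "peptide":
        ref_peps = {r.peptide for r in ref}
        return [r for r in records if r.peptide not in ref_peps]
    if mode == "tcr":
        ref_tcrs = {r.tcr for r in ref}
        return [r for r in records if r.tcr not in ref_tcrs]
    raise CurationError(f"unknown exclusion mode {mode!r}")


def min_binder_filter(
    records: Iterable[BindingRecord],
    min_binders: int,
) -> list[BindingRecord]:
    """Drop every record of peptides with fewer than ``min_binders`` binders.

    Mirrors meta-training eligibility rules that exclude peptides whose
    support/query requirements cannot be met (e.g. fewer than three binders).
    """
    if min_binders < 1:
        raise CurationError("min_binders must be >= 1")
    records = list(records)
    counts: dict[str, set[str]] = defaultdict(set)
    for r in records:
        if r.is_binder:
            counts[r.peptide].add(r.tcr)
    keep = {p for p, tcrs in counts.items() if len(tcrs) >= min_binders}
    return [r for r in records if r.peptide in keep]
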