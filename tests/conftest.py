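"""Shared fixtures: small synthetic benchmarks generated at session scope."""

import pytest

import tcrbench as tb


@pytest.fixture(scope="session")
def small_dataset():
    """10 peptides (2 majority / 4 few-shot / 4 zero-shot), 2,000-sequence background."""
    config = tb.SyntheticConfig(
        n_peptides=10, repertoire_size=2000, group_sizes=(2, 4, 4), seed=7
    )
    records, truth, repertoire = tb.generate_dataset(config)
    tasks = tb.stratify_peptides(records)
    return records, truth, repertoire, tasks


@pytest.fixture(scope="session")
def small_alphabeta_dataset():
    """Paired-chain benchmark: each peptide's motif is split across alpha and beta."""
    config = tb.SyntheticConfig(
        n_peptides=6,
        repertoire_size=1500,
        group_sizes=(1, 3, 2),
        motif_length=6,
        chain="alphabeta",
        seed=11,
    )
    records, truth, repertoire = tb.generate_dataset(config)
    tasks = tb.stratify_peptides(records)
    return records, truth, repertoire, tasks


def make_binder_records(pairs):
    """(peptide, tcr) tuples -> binder BindingRecords (beta chain)."""
    return [tb.BindingRecord(p, cdr3_beta=t, label=tb.BINDER) for p, t in pairs]
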