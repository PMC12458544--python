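"""Synthetic peptide/TCR benchmark data with known ground truth.

The generator emulates the structure of a curated multi-peptide binding table:
a handful of immunodominant peptides with hundreds of known binders
(majority), a broad middle of 5-100 binders (few-shot), and a long tail with
fewer than 5 (zero-shot), plus a large disjoint background repertoire to
screen against.

Binding is driven by a hidden per-peptide sequence motif: a TCR binds a
peptide iff its CDR3 carries (a close-enough copy of) that peptide's motif.
Affinity of a pair is the best ungapped window identity between the motif and
the CDR3, in [0, 1]; a pair is a binder iff affinity >= ``binder_threshold``.
Binder CDR3s are generated by implanting the motif; background sequences (and
binders of *other* peptides) are rejected if they reach the threshold for any
peptide, so emitted labels regenerate exactly from affinity + threshold.

This transparent construction makes downstream properties checkable
(a truth-oracle scorer ranks all binders first; a memorizing scorer inflates
false positives under reshuffled negatives), at the cost of biophysical
realism: real CDR3s have V/J-templated ends, position-dependent composition
and many-to-many cross-reactivity, none of which is modelled here.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import norm

from .core import AA_LETTERS, BINDER, CHAIN_SEP, BindingRecord, Repertoire, TcrbenchError
from .screening import Scorer, ScorerError

logger = logging.getLogger("tcrbench.synthetic")

_AA = np.frombuffer(AA_LETTERS.encode(), dtype=np.uint8)


class SyntheticError(TcrbenchError):
    pass


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic benchmark.

    ``group_sizes`` fixes how many peptides fall in the (majority, few-shot,
    zero-shot) groups; when None, peptides are split roughly 20% / 50% / 30%
    with at least one peptide per group.  Binder counts are drawn uniformly
    from ``count_ranges`` per group.  The default fixture is 20 peptides over
    a 100,000-sequence background repertoire.
    """

    n_peptides: int = 20
    repertoire_size: int = 100_000
    group_sizes: tuple[int, int, int] | None = None
    count_ranges: tuple[tuple[int, int], tuple[int, int], tuple[int, int]] = (
        (100, 150),
        (5, 100),
        (1, 4),
    )
    peptide_length_range: tuple[int, int] = (8, 12)
    cdr3_length_range: tuple[int, int] = (10, 18)
    motif_length: int = 4
    binder_threshold: float = 1.0
    noise_sd: float = 0.05
    chain: str = "beta"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_peptides < 3 and self.group_sizes is None:
            raise SyntheticError("need n_peptides >= 3 to populate all three groups")
        if self.chain not in ("beta", "alphabeta"):
            raise SyntheticError(f"unsupported chain {self.chain!r}")
        if self.noise_sd < 0:
            raise SyntheticError("noise_sd must be non-negative")

    def resolved_group_sizes(self) -> tuple[int, int, int]:
        if self.group_sizes is not None:
            if sum(self.group_sizes) != self.n_peptides:
                raise SyntheticError("group_sizes must sum to n_peptides")
            return self.group_sizes
        n = self.n_peptides
        n_maj = max(1, round(0.2 * n))
        n_zero = max(1, round(0.3 * n))
        n_few = n - n_maj - n_zero
        if n_few < 1:
            raise SyntheticError("n_peptides too small to populate all groups")
        return (n_maj, n_few, n_zero)


@dataclass(frozen=True)
class GroundTruth:
    """Hidden generative model: per-peptide motifs plus the binder threshold.

    ``affinity(peptide, tcr)`` is defined for any pair, so the truth acts as
    an oracle scorer over arbitrary libraries; ``label`` is binder iff
    affinity >= ``binder_threshold``.
    """

    motifs: Mapping[str, str]
    binder_threshold: float = 1.0
    chain: str = "beta"

    def affinity(self, peptide: str, tcr: str) -> float:
        motif = self.motifs[peptide]
        if self.chain == "alphabeta" and CHAIN_SEP in tcr:
            a, b = tcr.split(CHAIN_SEP, 1)
            h = len(motif) // 2
            return 0.5 * (_match_fraction(motif[:h], a) + _match_fraction(motif[h:], b))
        return _match_fraction(motif, tcr)

    def affinity_batch(self, peptide: str, tcrs: Sequence[str]) -> np.ndarray:
        motif = self.motifs[peptide]
        if self.chain == "alphabeta":
            h = len(motif) // 2
            alphas, betas = zip(*(t.split(CHAIN_SEP, 1) for t in tcrs))
            return 0.5 * (
                _match_fraction_batch(motif[:h], alphas)
                + _match_fraction_batch(motif[h:], betas)
            )
        return _match_fraction_batch(motif, tcrs)

    def label(self, peptide: str, tcr: str) -> str:
        from .core import NON_BINDER

        return BINDER if self.affinity(peptide, tcr) >= self.binder_threshold else NON_BINDER

    def binder_tcrs(self, records: Sequence[BindingRecord]) -> frozenset[str]:
        return frozenset(r.tcr for r in records if r.is_binder)


# ---------------------------------------------------------------------------
# motif matching

def _match_fraction(motif: str, seq: str) -> float:
    """Best ungapped window identity of ``motif`` within ``seq``, in [0, 1]."""
    m = len(motif)
    if len(seq) < m:
        return 0.0
    if motif in seq:
        return 1.0
    best = 0
    for i in range(len(seq) - m + 1):
        window = seq[i : i + m]
        score = sum(a == b for a, b in zip(motif, window))
        if score > best:
            best = score
    return best / m


def _match_fraction_batch(motif: str, seqs: Sequence[str]) -> np.ndarray:
    """Vectorized :func:`_match_fraction` over a batch of sequences."""
    m = len(motif)
    n = len(seqs)
    lengths = np.fromiter((len(s) for s in seqs), dtype=int, count=n)
    maxlen = int(lengths.max(initial=0))
    if maxlen < m:
        return np.zeros(n)
    arr = np.zeros((n, maxlen), dtype=np.uint8)
    for i, s in enumerate(seqs):
        arr[i, : len(s)] = np.frombuffer(s.encode(), dtype=np.uint8)
    mot = np.frombuffer(motif.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(arr, m, axis=1)
    matches = (windows == mot).sum(axis=2)  # (n, maxlen - m + 1)
    # windows running past a sequence's end are invalid
    n_windows = np.clip(lengths - m + 1, 0, None)
    col = np.arange(matches.shape[1])
    matches = np.where(col[None, :] < n_windows[:, None], matches, 0)
    return matches.max(axis=1) / m


# ---------------------------------------------------------------------------
# sequence generation

def _random_cdr3(rng: np.random.Generator, lo: int, hi: int) -> str:
    """CDR3-like string: canonical C...F frame around a random core."""
    length = int(rng.integers(lo, hi + 1))
    core = rng.choice(_AA, size=length - 2)
    return "C" + core.tobytes().decode() + "F"


def _random_peptide(rng: np.random.Generator, lo: int, hi: int) -> str:
    length = int(rng.integers(lo, hi + 1))
    return rng.choice(_AA, size=length).tobytes().decode()


def _hits_any_motif(seq: str, motifs: Sequence[str], threshold: float) -> bool:
    if threshold >= 1.0:
        return any(m in seq for m in motifs)
    return any(_match_fraction(m, seq) >= threshold for m in motifs)


def generate_repertoire(
    size: int,
    config: SyntheticConfig | None = None,
    forbidden_motifs: Sequence[str] = (),
    rng: np.random.Generator | None = None,
) -> Repertoire:
    """Generate ``size`` unique CDR3-like sequences, seeded by the config.

    Sequences reaching the binder threshold for any forbidden motif are
    rejected, keeping the background disjoint from binder-generating signal.
    """
    config = config or SyntheticConfig()
    if size < 1:
        raise SyntheticError("repertoire size must be >= 1")
    lo, hi = config.cdr3_length_range
    if 20 ** (hi - 2) < size:
        raise SyntheticError("requested size exceeds sequence-space capacity")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    threshold = config.binder_threshold
    out: dict[str, None] = {}
    attempts = 0
    limit = 200 * size + 1000
    while len(out) < size:
        attempts += 1
        if attempts > limit:
            raise SyntheticError("could not generate enough unique sequences")
        if config.chain == "alphabeta":
            a = _random_cdr3(rng, lo, hi)
            b = _random_cdr3(rng, lo, hi)
            seq = a + CHAIN_SEP + b
            if forbidden_motifs and any(
                _hits_pair(seq, m, threshold) for m in forbidden_motifs
            ):
                continue
        else:
            seq = _random_cdr3(rng, lo, hi)
            if forbidden_motifs and _hits_any_motif(seq, forbidden_motifs, threshold):
                continue
        out.setdefault(seq)
    return Repertoire(tuple(out), chain=config.chain)


def _hits_pair(pair_seq: str, motif: str, threshold: float) -> bool:
    a, b = pair_seq.split(CHAIN_SEP, 1)
    h = len(motif) // 2
    return 0.5 * (_match_fraction(motif[:h], a) + _match_fraction(motif[h:], b)) >= threshold


def _implant(rng: np.random.Generator, motif: str, lo: int, hi: int) -> str:
    """Random CDR3 with ``motif`` implanted inside the core region."""
    length = int(rng.integers(max(lo, len(motif) + 2), hi + 1))
    seq = _random_cdr3(rng, length, length)
    pos = int(rng.integers(1, len(seq) - len(motif)))
    return seq[:pos] + motif + seq[pos + len(motif) :]


def generate_dataset(
    config: SyntheticConfig | None = None,
) -> tuple[list[BindingRecord], GroundTruth, Repertoire]:
    """Generate a full benchmark: binder records, ground truth, background.

    Each peptide carries a hidden motif; its binders are unique CDR3s with the
    motif implanted (for paired alpha/beta data the motif is split across the
    two chains so both carry signal).  Binder counts per peptide follow the
    configured per-group ranges, and the background repertoire is disjoint
    from every motif, so stratifying the emitted records recovers the planted
    group sizes exactly.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    lo, hi = config.cdr3_length_range
    n_maj, n_few, n_zero = config.resolved_group_sizes()
    group_of_index = [0] * n_maj + [1] * n_few + [2] * n_zero

    # unique peptides
    peptides: dict[str, None] = {}
    while len(peptides) < config.n_peptides:
        peptides.setdefault(_random_peptide(rng, *config.peptide_length_range))
    pep_list = list(peptides)

    # distinct motifs (distinctness keeps cross-peptide affinity honest)
    motifs: dict[str, str] = {}
    used: set[str] = set()
    for pep in pep_list:
        while True:
            m = rng.choice(_AA, size=config.motif_length).tobytes().decode()
            if m not in used:
                used.add(m)
                motifs[pep] = m
                break
    truth = GroundTruth(
        motifs=motifs, binder_threshold=config.binder_threshold, chain=config.chain
    )

    records: list[BindingRecord] = []
    all_binders: set[str] = set()
    motif_list = list(motifs.values())
    for gi, pep in zip(group_of_index, pep_list):
        cr = config.count_ranges[gi]
        count = int(rng.integers(cr[0], cr[1] + 1))
        made = 0
        guard = 0
        while made < count:
            guard += 1
            if guard > 500 * count + 1000:
                raise SyntheticError("binder generation stalled")
            others = [m for p2, m in motifs.items() if p2 != pep]
            if config.chain == "alphabeta":
                m = motifs[pep]
                h = len(m) // 2
                a = _implant(rng, m[:h], lo, hi)
                b = _implant(rng, m[h:], lo, hi)
                tcr = a + CHAIN_SEP + b
                if tcr in all_binders or any(
                    _hits_pair(tcr, om, config.binder_threshold) for om in others
                ):
                    continue
                if truth.affinity(pep, tcr) < config.binder_threshold:
                    continue
                records.append(
                    BindingRecord(pep, cdr3_beta=b, cdr3_alpha=a, label=BINDER, source="synthetic")
                )
            else:
                tcr = _implant(rng, motifs[pep], lo, hi)
                if tcr in all_binders or _hits_any_motif(
                    tcr, others, config.binder_threshold
                ):
                    continue
                records.append(
                    BindingRecord(pep, cdr3_beta=tcr, label=BINDER, source="synthetic")
                )
            all_binders.add(tcr)
            made += 1

    repertoire = generate_repertoire(
        config.repertoire_size, config, forbidden_motifs=motif_list, rng=rng
    )
    logger.info(
        "generated %d peptides (%d/%d/%d per group), %d binder pairs, %d background sequences",
        config.n_peptides, n_maj, n_few, n_zero, len(records), len(repertoire),
    )
    return records, truth, repertoire


# ---------------------------------------------------------------------------
# synthetic scorers

def _pair_uniforms(seed: int, tag: str, peptide: str, tcrs: Sequence[str]) -> np.ndarray:
    """Deterministic U(0,1) per (seed, peptide, TCR identity).

    Hash-derived rather than drawn from a stream so that scores do not depend
    on batch composition or order — required for chunk-invariant screening.
    """
    out = np.empty(len(tcrs))
    prefix = f"{tag}|{seed}|{peptide}|".encode()
    for i, t in enumerate(tcrs):
        h = hashlib.blake2b(prefix + t.encode(), digest_size=8).digest()
        out[i] = (int.from_bytes(h, "little") + 0.5) / 2.0**64
    return out


class OracleScorer(Scorer):
    """Scores with the true generative affinity; the performance ceiling."""

    def __init__(self, truth: GroundTruth, name: str = "oracle"):
        self.truth = truth
        self.name = name
        self.chains = truth.chain

    def score_batch(self, peptide: str, tcrs: Sequence[str]) -> np.ndarray:
        return self.truth.affinity_batch(peptide, tcrs)


class NoisyOracleScorer(Scorer):
    """True affinity plus deterministic per-pair Gaussian noise of sd ``sd``."""

    def __init__(self, truth: GroundTruth, sd: float, seed: int = 0, name: str = "noisy_oracle"):
        if sd < 0:
            raise ScorerError("noise sd must be non-negative")
        self.truth = truth
        self.sd = sd
        self.seed = seed
        self.name = name
        self.chains = truth.chain

    def score_batch(self, peptide: str, tcrs: Sequence[str]) -> np.ndarray:
        base = self.truth.affinity_batch(peptide, tcrs)
        if self.sd == 0:
            return base
        u = _pair_uniforms(self.seed, "noisy", peptide, tcrs)
        return base + self.sd * norm.ppf(u)


class RandomScorer(Scorer):
    """Seeded uniform scores, independent across peptides and TCRs."""

    def __init__(self, seed: int = 0, name: str = "random", chains: str = "beta"):
        self.seed = seed
        self.name = name
        self.chains = chains

    def score_batch(self, peptide: str, tcrs: Sequence[str]) -> np.ndarray:
        return _pair_uniforms(self.seed, "random", peptide, tcrs)


class MemorizationScorer(Scorer):
    """Scores by TCR identity alone: high iff the TCR binds *any* peptide.

    Operationalizes the over-memorization failure mode: a model that has
    memorized positive-labelled TCRs scores them high regardless of the query
    peptide, so reshuffled negatives (which reuse binder TCRs) come back as
    false positives while background negatives do not.
    """

    def __init__(self, binder_tcrs: frozenset[str] | set[str], seed: int = 0,
                 name: str = "memorization", chains: str = "beta"):
        self.binder_tcrs = frozenset(binder_tcrs)
        self.seed = seed
        self.name = name
        self.chains = chains

    def score_batch(self, peptide: str, tcrs: Sequence[str]) -> np.ndarray:
        u = _pair_uniforms(self.seed, "memo", peptide, tcrs)
        memorized = np.fromiter(
            (t in self.binder_tcrs for t in tcrs), dtype=bool, count=len(tcrs)
        )
        return np.where(memorized, 0.8 + 0.2 * u, 0.2 * u)


SCORER_KINDS = ("oracle", "noisy_oracle", "random", "tcr_memorization")


def make_scorer(
    kind: str,
    truth: GroundTruth | None = None,
    seed: int = 0,
    sd: float | None = None,
    binder_tcrs: Sequence[str] | None = None,
) -> Scorer:
    """Factory for the built-in synthetic scorers.

    ``oracle`` and ``noisy_oracle`` require ``truth``; ``tcr_memorization``
    requires either ``binder_tcrs`` or a ``truth``-consistent binder set
    passed explicitly.
    """
    if kind == "oracle":
        if truth is None:
            raise ScorerError("oracle scorer requires ground truth")
        return OracleScorer(truth)
    if kind == "noisy_oracle":
        if truth is None:
            raise ScorerError("noisy_oracle scorer requires ground truth")
        return NoisyOracleScorer(truth, sd=0.05 if sd is None else sd, seed=seed)
    if kind == "random":
        return RandomScorer(seed=seed)
    if kind == "tcr_memorization":
        if binder_tcrs is None:
            raise ScorerError("tcr_memorization scorer requires the binder TCR set")
        return MemorizationScorer(frozenset(binder_tcrs), seed=seed)
    raise ScorerError(f"unknown scorer kind {kind!r}; expected one of {SCORER_KINDS}")
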