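"""Enrichment and classification metrics against independent oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tcrbench as tb
from tcrbench.metrics import (
    RELATIVE,
    TRUCHON_BAYLY,
    MetricError,
    midrank_binder_ranks,
)


def bedroc_direct(ranks, total, alpha):
    """Independent direct-summation oracle for the default BEDROC variant.

    Written from the definition with plain python floats: prefactor
    alpha/(1-e^-alpha) times the mean of e^(-alpha * (r-1)/(N-1)).
    """
    terms = [math.exp(-alpha * (r - 1) / (total - 1)) for r in ranks]
    return alpha / (1 - math.exp(-alpha)) * sum(terms) / len(terms)


def random_screen(rng, total=None, n=None):
    total = total or int(rng.integers(2, 5000))
    n = n or int(rng.integers(1, min(total, 100) + 1))
    ranks = np.sort(rng.choice(total, size=n, replace=False) + 1)
    return tb.RankedScreen("PEP", total, tuple(int(r) for r in ranks))


class TestBedroc:
    def test_top_ranked_single_binder_hits_prefactor(self):
        # R = 0 forces the sum term to 1, leaving alpha/(1-e^-alpha)
        for total in (2, 10, 10_000):
            screen = tb.RankedScreen("PEP", total, (1,))
            expected = 20.0 / (1.0 - math.exp(-20.0))
            assert tb.bedroc(screen) == pytest.approx(expected, abs=1e-12)

    def test_two_binder_closed_form(self):
        # ranks {1, N}: (alpha/(1-e^-alpha)) * (1 + e^-alpha) / 2
        screen = tb.RankedScreen("PEP", 10, (1, 10))
        expected = 20.0 / (1.0 - math.exp(-20.0)) * (1.0 + math.exp(-20.0)) / 2.0
        assert tb.bedroc(screen) == pytest.approx(expected, abs=1e-12)

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(300):
            s = random_screen(rng)
            assert tb.bedroc(s) == pytest.approx(
                bedroc_direct(s.binder_ranks, s.total, 20.0), abs=1e-9
            )

    def test_alpha_is_respected(self):
        rng = np.random.default_rng(1)
        s = random_screen(rng)
        for alpha in (2.0, 20.0, 100.0):
            got = tb.bedroc(s, tb.BedrocParams(alpha=alpha))
            assert got == pytest.approx(bedroc_direct(s.binder_ranks, s.total, alpha), abs=1e-9)

    def test_truchon_bayly_matches_rdkit(self):
        from rdkit.ML.Scoring.Scoring import CalcBEDROC

        rng = np.random.default_rng(8)
        for _ in range(50):
            s = random_screen(rng, total=int(rng.integers(20, 500)))
            ranked = [[0.0, 1 if (i + 1) in set(s.binder_ranks) else 0]
                      for i in range(s.total)]
            expected = CalcBEDROC(ranked, 1, 20.0)
            got = tb.bedroc(s, tb.BedrocParams(variant=TRUCHON_BAYLY))
            assert got == pytest.approx(expected, abs=1e-9)
            assert 0.0 <= got <= 1.0

    @settings(max_examples=50, deadline=None)
    @given(st.integers(min_value=0, max_value=2**32 - 1))
    def test_earlier_rank_strictly_increases_bedroc(self, seed):
        rng = np.random.default_rng(seed)
        s = random_screen(rng)
        ranks = list(s.binder_ranks)
        movable = [i for i, r in enumerate(ranks)
                   if r - 1 >= 1 and (i == 0 or ranks[i - 1] < r - 1)]
        if not movable:
            return
        i = movable[int(rng.integers(len(movable)))]
        improved = sorted(ranks[:i] + [ranks[i] - 1] + ranks[i + 1:])
        better = tb.RankedScreen("PEP", s.total, tuple(improved))
        assert tb.bedroc(better) > tb.bedroc(s)
        grid = (0.01, 0.1, 0.5, 1.0)
        for (_, a), (_, b) in zip(tb.enrichment_curve(s, grid),
                                  tb.enrichment_curve(better, grid)):
            assert b >= a

    def test_degenerate_inputs_raise(self):
        with pytest.raises(MetricError):
            tb.bedroc(tb.RankedScreen("PEP", 5, ()))
        with pytest.raises(MetricError):
            tb.bedroc(tb.RankedScreen("PEP", 1, (1,)))
        with pytest.raises(MetricError):
            tb.BedrocParams(alpha=0)
        with pytest.raises(MetricError):
            tb.BedrocParams(variant="other")

    def test_max_bedroc_is_front_loaded_ceiling(self):
        assert tb.max_bedroc(5, 1000) == pytest.approx(
            bedroc_direct(range(1, 6), 1000, 20.0), abs=1e-12
        )


class TestRankedScreenValidation:
    @pytest.mark.parametrize(
        "total, ranks",
        [(10, (0, 3)), (10, (3, 11)), (10, (4, 4)), (10, (5, 3)), (3, (1, 2, 3, 3))],
    )
    def test_bad_ranks_rejected(self, total, ranks):
        with pytest.raises(MetricError):
            tb.RankedScreen("PEP", total, ranks)


class TestEnrichmentCurve:
    def test_all_binders_in_top_percent(self):
        screen = tb.RankedScreen("PEP", 1000, (1, 4, 9))
        assert tb.enrichment_curve(screen, (0.01,)) == [(0.01, 1.0)]

    def test_counting_example(self):
        screen = tb.RankedScreen("PEP", 100, (1, 2, 50, 100))
        ((_, at_half),) = tb.enrichment_curve(screen, (0.5,))
        assert at_half == 0.75

    def test_curve_ends_at_one_and_is_monotone(self):
        rng = np.random.default_rng(3)
        s = random_screen(rng)
        pts = tb.enrichment_curve(s, tuple(np.linspace(0.01, 1.0, 25)))
        ys = [y for _, y in pts]
        assert ys[-1] == 1.0
        assert all(b >= a for a, b in zip(ys, ys[1:]))

    def test_uniform_ranks_track_diagonal(self):
        rng = np.random.default_rng(4)
        grid = (0.1, 0.25, 0.5, 0.75)
        acc = np.zeros(len(grid))
        reps = 300
        for _ in range(reps):
            s = random_screen(rng, total=2000, n=40)
            acc += [y for _, y in tb.enrichment_curve(s, grid)]
        np.testing.assert_allclose(acc / reps, grid, atol=0.02)

    def test_empty_or_invalid_grid_raises(self):
        s = tb.RankedScreen("PEP", 10, (1,))
        with pytest.raises(MetricError):
            tb.enrichment_curve(s, ())
        with pytest.raises(MetricError):
            tb.enrichment_curve(s, (0.0, 0.5))


class TestHitAndSuccessRates:
    def test_hit_rate_definitional(self):
        s = tb.RankedScreen("PEP", 100, (1, 2, 50, 100))
        assert tb.hit_rate(s, 100) == 1.0
        assert tb.hit_rate(s, 2) == 0.5
        with pytest.raises(MetricError):
            tb.hit_rate(s, 0)
        with pytest.raises(MetricError):
            tb.hit_rate(s, 101)

    def test_hit_rate_random_expectation(self):
        # hypergeometric mean: E[hits in top k] = n * k / N
        rng = np.random.default_rng(6)
        k, total, n = 100, 2000, 40
        mean = np.mean([tb.hit_rate(random_screen(rng, total, n), k) for _ in range(400)])
        assert mean == pytest.approx(k / total, abs=0.01)

    def test_success_rate_fraction_of_peptides(self):
        screens = [
            tb.RankedScreen("P1", 100, (3,)),
            tb.RankedScreen("P2", 100, (40,)),
            tb.RankedScreen("P3", 100, (90,)),
        ]
        assert tb.success_rate(screens, 10) == pytest.approx(1 / 3)
        assert tb.success_rate(screens, 100) == 1.0
        with pytest.raises(MetricError):
            tb.success_rate([], 10)

    def test_success_rate_single_binder_expectation(self):
        rng = np.random.default_rng(7)
        k, total = 50, 1000
        screens = [random_screen(rng, total, 1) for _ in range(800)]
        assert tb.success_rate(screens, k) == pytest.approx(k / total, abs=0.03)


class TestClassificationMetrics:
    def test_roc_examples(self):
        assert tb.roc_auc([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1]) == 1.0
        assert tb.roc_auc([1, 1, 0, 0], [0.9, 0.4, 0.8, 0.3]) == 0.75
        assert tb.roc_auc([1, 0, 1, 0], [0.5, 0.5, 0.5, 0.5]) == 0.5
        with pytest.raises(MetricError):
            tb.roc_auc([1, 1], [0.5, 0.6])

    def test_roc_equals_pairwise_concordance(self):
        rng = np.random.default_rng(10)
        for _ in range(30):
            n = int(rng.integers(4, 120))
            y = rng.integers(0, 2, size=n)
            if len(np.unique(y)) < 2:
                continue
            s = np.round(rng.random(n), 2)  # coarse scores force ties
            conc = sum(
                1.0 if sp > sn else 0.5 if sp == sn else 0.0
                for sp in s[y == 1]
                for sn in s[y == 0]
            )
            expected = conc / (np.sum(y == 1) * np.sum(y == 0))
            assert tb.roc_auc(y, s) == pytest.approx(expected, abs=1e-12)

    def test_pr_examples(self):
        assert tb.pr_auc([1, 0], [0.9, 0.1]) == 1.0
        assert tb.pr_auc([1, 0], [0.1, 0.9]) == 0.5
        with pytest.raises(MetricError):
            tb.pr_auc([0, 0], [0.1, 0.9])

    def test_confusion_counts_partition_input(self):
        cm = tb.confusion_at([1, 0], [0.9, 0.2], 0.5)
        assert (cm.tp, cm.fp, cm.tn, cm.fn) == (1, 0, 1, 0)
        cm = tb.confusion_at([1, 0, 1], [0.1, 0.2, 0.3], 0.9)
        assert cm.tp == 0 and cm.fp == 0 and cm.total == 3

    def test_fpr_property(self):
        cm = tb.confusion_at([0, 0, 0, 1], [0.9, 0.9, 0.1, 0.9], 0.5)
        assert cm.fpr == pytest.approx(2 / 3)


class TestTiePolicy:
    def test_stable_rank_breaks_ties_by_library_index(self):
        scores = np.array([0.5, 0.9, 0.5, 0.1])
        mask = np.array([True, False, True, False])
        screen = tb.rank_screen("PEP", scores, mask)
        assert screen.binder_ranks == (2, 3)  # first 0.5 before second 0.5

    def test_midrank_assigns_average_rank(self):
        scores = np.array([0.5, 0.9, 0.5, 0.1])
        mask = np.array([True, False, True, False])
        np.testing.assert_allclose(midrank_binder_ranks(scores, mask), [2.5, 2.5])
        val = tb.bedroc_from_ranks(midrank_binder_ranks(scores, mask), 4)
        assert val > 0
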