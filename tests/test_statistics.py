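"""Aggregate indexing, histogram accumulation, reliability filter, favored
clusters and effective charge."""

import numpy as np
import pytest

from dendrisurf.clusters import AggregateRecord, MicelleRecord
from dendrisurf.statistics import (
    EnsembleStats,
    accumulate,
    aggregate_index,
    effective_charge,
    favored_clusters,
    index_conditioned_means,
    index_to_sd,
)
from dendrisurf.topology import DendrimerSpec, build_dendrimer


def agg(s_masses, dends, n_s, kinds=None, n_dc=0, n_sc=0, N_t=16):
    """Build an AggregateRecord by hand for bookkeeping tests."""
    kinds = kinds or (
        ["free"] * len(s_masses)
        if not dends
        else ["corona"] * len(s_masses)
    )
    mics = [
        MicelleRecord(
            frozenset(range(100 * i, 100 * i + m)), frozenset(dends), kinds[i]
        )
        for i, m in enumerate(s_masses)
    ]
    s = sum(s_masses)
    record = AggregateRecord(
        micelles=mics,
        dendrimer_ids=frozenset(dends),
        index=aggregate_index(s, len(dends), n_s),
        n_dc=n_dc,
        n_sc=n_sc,
    )
    record.ch = effective_charge(s, len(dends), N_t, n_sc, n_dc)
    return record


class TestIndexBijection:
    def test_free_dendrimer_maps_to_zero(self):
        assert aggregate_index(0, 1, 600) == 0
        assert index_to_sd(0, 600) == (0, 1)

    def test_formula_and_inverse(self):
        assert aggregate_index(600, 1, 600) == 1200
        assert index_to_sd(1200, 600) == (600, 1)

    def test_exhaustive_round_trip_d_up_to_2(self):
        n_s = 600
        pairs = [(0, 1)] + [
            (s, d) for d in (0, 1, 2) for s in range(1, n_s + 1)
        ]
        seen = set()
        for s, d in pairs:
            n = aggregate_index(s, d, n_s)
            assert index_to_sd(n, n_s) == (s, d)
            assert n not in seen  # injectivity
            seen.add(n)

    def test_inadmissible_pairs_rejected(self):
        for s, d in [(0, 0), (0, 2), (-1, 1), (601, 1)]:
            with pytest.raises(ValueError):
                aggregate_index(s, d, 600)


class TestEffectiveCharge:
    def test_free_dendrimer_keeps_intrinsic_charge(self):
        assert effective_charge(0, 1, 16) == 16

    def test_free_micelle_carries_minus_s(self):
        assert effective_charge(40, 0, 16) == -40

    def test_g3_two_dendrimer_cluster(self):
        n_t = build_dendrimer(DendrimerSpec(3, 4)).N_t  # topology oracle
        assert effective_charge(40, 2, n_t) == -8

    def test_condensed_counterions_shift_the_charge(self):
        assert effective_charge(10, 1, 16, n_sc=3, n_dc=5) == 16 - 10 + 3 - 5


class TestAccumulation:
    def test_bookkeeping_on_identical_frames(self):
        n_s = 60
        frames = [
            [agg([5], [0], n_s), agg([1], [], n_s)]
            for _ in range(10)
        ]
        stats = accumulate(frames, n_s=n_s, n_d=1, N_t=16)
        assert stats.H_index == {aggregate_index(5, 1, n_s): 10, 1: 10}
        assert stats.H_nmixc == {1: 10}
        assert stats.H_nfmic == {1: 10}
        assert stats.H_nfuni == {1: 10}
        assert stats.H_s == {5: 10}
        assert stats.H_mfmic == {1: 10}
        assert stats.H_mcor == {5: 10}

    def test_fraction_of_absorbed_surfactants(self):
        n_s = 6
        frames = [[agg([3], [0], n_s), agg([3], [], n_s)] for _ in range(7)]
        stats = accumulate(frames, n_s=n_s, n_d=1, N_t=4)
        assert stats.f_s == pytest.approx(0.5)

    def test_condensed_fractions(self):
        n_s = 10
        frames = [[agg([10], [0], n_s, n_dc=2, n_sc=5, N_t=4)] for _ in range(3)]
        stats = accumulate(frames, n_s=n_s, n_d=1, N_t=4)
        assert stats.f_dc == pytest.approx(2 / 4)
        assert stats.f_sc == pytest.approx(5 / 10)

    def test_histograms_sum_to_frames_and_observations(self):
        n_s = 20
        rng = np.random.default_rng(0)
        frames = []
        for _ in range(25):
            k = int(rng.integers(1, 4))
            frames.append([agg([int(rng.integers(1, 5))], [], n_s) for _ in range(k)])
        stats = accumulate(frames, n_s=n_s, n_d=1, N_t=4)
        assert sum(stats.H_nfmic.values()) == 25
        assert sum(stats.H_mfmic.values()) == sum(
            len(f) for f in frames
        )
        probs = stats.index_probabilities()
        assert sum(probs.values()) == pytest.approx(1.0)


class TestReliabilityFilter:
    def _stats_with_occurrences(self, occ: int) -> EnsembleStats:
        n_s = 30
        frames = [[agg([4], [0], n_s)] for _ in range(occ)]
        return accumulate(frames, n_s=n_s, n_d=1, N_t=16)

    def test_ten_occurrences_excluded(self):
        means = index_conditioned_means(self._stats_with_occurrences(10))
        assert aggregate_index(4, 1, 30) not in means

    def test_eleven_occurrences_included(self):
        idx = aggregate_index(4, 1, 30)
        means = index_conditioned_means(self._stats_with_occurrences(11))
        assert idx in means
        assert means[idx].occurrence == 11
        assert means[idx].n_cor == pytest.approx(1.0)
        assert means[idx].m_cor == pytest.approx(4.0)

    def test_planted_compositions_recovered_exactly(self):
        n_s = 50
        frames = [
            [agg([10, 4], [0, 1], n_s, kinds=["bridge", "corona"], n_dc=1, n_sc=2)]
            for _ in range(12)
        ]
        stats = accumulate(frames, n_s=n_s, n_d=2, N_t=16)
        means = index_conditioned_means(stats)
        m = means[aggregate_index(14, 2, n_s)]
        assert (m.n_br, m.m_br, m.n_cor, m.m_cor) == (1.0, 10.0, 1.0, 4.0)
        assert (m.n_dc, m.n_sc) == (1.0, 2.0)
        assert m.ch == pytest.approx(2 * 16 - 14 + 2 - 1)


class TestFavoredClusters:
    def _stats_from_hist(self, hist: dict, n_s: int = 600) -> EnsembleStats:
        stats = EnsembleStats(n_s=n_s, n_d=2, N_t=16)
        stats.H_index.update(hist)
        return stats

    def test_unimodal_peak(self):
        hist = {660 + k: 10 - abs(k - 6) for k in range(13)}
        fav = favored_clusters(self._stats_from_hist(hist), d=1)
        assert fav.index == 666 and fav.s_f == 66 and fav.d == 1

    def test_empty_range_is_absent(self):
        hist = {666: 30}  # only d = 1 content
        assert favored_clusters(self._stats_from_hist(hist), d=2) is None

    def test_bimodal_takes_higher_peak(self):
        hist = {610: 5, 611: 8, 612: 5, 700: 5, 701: 12, 702: 5}
        fav = favored_clusters(self._stats_from_hist(hist), d=1)
        assert fav.index == 701

    def test_tie_resolves_to_lower_index_with_warning(self):
        hist = {610: 2, 611: 9, 612: 2, 700: 2, 701: 9, 702: 2}
        with pytest.warns(UserWarning, match="tie"):
            fav = favored_clusters(self._stats_from_hist(hist), d=1)
        assert fav.index == 611

    def test_zero_count_gaps_are_merged(self):
        # 650 and 652 are neighbors once the empty 651 bin is skipped
        hist = {650: 4, 652: 9, 654: 3}
        fav = favored_clusters(self._stats_from_hist(hist), d=1)
        assert fav.index == 652


class TestEnsembleInvariants:
    def test_index_histogram_mass_balance(self):
        """Sum over mixed-cluster indices of H(n) * s(n) equals the total
        absorbed surfactant count over frames."""
        rng = np.random.default_rng(3)
        n_s = 40
        frames = []
        for _ in range(30):
            f = []
            left = n_s
            for dend in range(2):
                s = int(rng.integers(0, left // 2 + 1))
                if s > 0:
                    f.append(agg([s], [dend], n_s))
                    left -= s
            if rng.random() < 0.7 and left:
                f.append(agg([1], [], n_s))
            frames.append(f)
        stats = accumulate(frames, n_s=n_s, n_d=2, N_t=16)
        total = 0
        for n, c in stats.H_index.items():
            s, d = index_to_sd(n, n_s)
            if d >= 1 and s > 0:
                total += c * s
        assert total == sum(k * v for k, v in stats.H_s.items())

    def test_unimers_never_exceed_free_micelles(self):
        rng = np.random.default_rng(4)
        n_s = 30
        frames = []
        for _ in range(20):
            masses = [int(rng.integers(1, 4)) for _ in range(rng.integers(1, 5))]
            frames.append([agg([m], [], n_s) for m in masses])
        stats = accumulate(frames, n_s=n_s, n_d=1, N_t=4)
        assert stats.mean_n_funi <= stats.mean_n_fmic
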