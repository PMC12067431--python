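"""Ensemble statistics over analyzed frames.

Aggregates of ``s`` surfactant chains and ``d`` dendrimers are indexed by a
single integer ``n_{s,d} = d*n_s + s`` (``s > 0``), with the free-dendrimer
pair ``(0, 1)`` mapped to 0.  For ``n > 0`` the inverse is
``d = (n - 1) div n_s`` and ``s = n - d*n_s``; the mapping is a bijection
over admissible pairs.  Histograms are unit-width integer-bin counters;
index-conditioned means are only reported for indices observed more than
``min_occurrence`` times (default 10), mirroring the reliability filter
used when averaging over cluster realizations.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "aggregate_index",
    "index_to_sd",
    "effective_charge",
    "EnsembleStats",
    "IndexMeans",
    "accumulate",
    "index_conditioned_means",
    "favored_clusters",
    "FavoredCluster",
]


def aggregate_index(s: int, d: int, n_s: int) -> int:
    """Map an admissible composition (s, d) to its integer index n_{s,d}."""
    if s < 0 or d < 0:
        raise ValueError(f"negative composition ({s}, {d})")
    if s == 0:
        if d != 1:
            raise ValueError(f"(s=0, d={d}) is not an admissible aggregate")
        return 0
    if s > n_s:
        raise ValueError(f"s={s} exceeds n_s={n_s}")
    return d * n_s + s


def index_to_sd(n: int, n_s: int) -> tuple[int, int]:
    """Inverse of :func:`aggregate_index`: n -> (s, d)."""
    if n < 0:
        raise ValueError(f"negative index {n}")
    if n == 0:
        return 0, 1
    d = (n - 1) // n_s
    s = n - d * n_s
    return s, d


def effective_charge(s: int, d: int, N_t: int, n_sc: int = 0, n_dc: int = 0) -> int:
    """Effective aggregate charge ``d*N_t - s + n_sc - n_dc`` in units of e.

    ``d*N_t`` is the intrinsic dendrimer charge, ``-s`` the surfactant-head
    charge, and the condensed surfactant/dendrimer counterions contribute
    ``+n_sc`` and ``-n_dc``.  A free dendrimer keeps +N_t; a free micelle
    keeps -s (absent condensation).
    """
    return d * N_t - s + n_sc - n_dc


@dataclass
class _IndexAccumulator:
    occurrence: int = 0
    n_br_sum: float = 0.0
    n_cor_sum: float = 0.0
    m_br_sum: float = 0.0  # total bridge mass over occurrences
    m_br_count: int = 0  # total bridge micelles over occurrences
    m_cor_sum: float = 0.0
    m_cor_count: int = 0
    n_dc_sum: float = 0.0
    n_sc_sum: float = 0.0
    ch_sum: float = 0.0


@dataclass(frozen=True)
class IndexMeans:
    """Index-conditioned means over aggregates of one n_{s,d}."""

    index: int
    occurrence: int
    n_br: float
    m_br: float  # mean bridge micelle mass (nan if no bridges observed)
    n_cor: float
    m_cor: float
    n_dc: float
    n_sc: float
    ch: float


@dataclass
class EnsembleStats:
    """Histograms and per-index accumulators over analyzed frames."""

    n_s: int
    n_d: int
    N_t: int
    n_frames: int = 0
    H_s: Counter = field(default_factory=Counter)  # absorbed surfactants per frame
    H_nfmic: Counter = field(default_factory=Counter)  # free micelles per frame
    H_nfuni: Counter = field(default_factory=Counter)  # free unimers per frame
    H_nfdend: Counter = field(default_factory=Counter)  # free dendrimers per frame
    H_nmixc: Counter = field(default_factory=Counter)  # mixed clusters per frame
    H_mfmic: Counter = field(default_factory=Counter)  # free micelle mass
    H_mbr: Counter = field(default_factory=Counter)  # bridge micelle mass
    H_mcor: Counter = field(default_factory=Counter)  # corona micelle mass
    H_index: Counter = field(default_factory=Counter)  # aggregate index n_{s,d}
    _per_index: dict = field(default_factory=dict)
    _s_total: int = 0
    _ndc_total: int = 0
    _nsc_total: int = 0

    def add_frame(self, aggregates) -> None:
        """Accumulate one frame's list of aggregate records."""
        self.n_frames += 1
        s_frame = 0
        n_fmic = n_funi = n_fdend = n_mixc = 0
        for agg in aggregates:
            s, d = agg.s, agg.d
            idx = agg.index
            self.H_index[idx] += 1
            acc = self._per_index.setdefault(idx, _IndexAccumulator())
            acc.occurrence += 1
            acc.n_br_sum += agg.n_br
            acc.n_cor_sum += agg.n_cor
            for m in agg.bridge_micelles:
                acc.m_br_sum += m.mass
                acc.m_br_count += 1
                self.H_mbr[m.mass] += 1
            for m in agg.corona_micelles:
                acc.m_cor_sum += m.mass
                acc.m_cor_count += 1
                self.H_mcor[m.mass] += 1
            acc.n_dc_sum += agg.n_dc
            acc.n_sc_sum += agg.n_sc
            acc.ch_sum += agg.ch
            self._ndc_total += agg.n_dc
            self._nsc_total += agg.n_sc
            if d == 0:
                n_fmic += 1
                self.H_mfmic[s] += 1
                if s == 1:
                    n_funi += 1
            elif s == 0:
                n_fdend += 1
            else:
                n_mixc += 1
                s_frame += s
        self._s_total += s_frame
        self.H_s[s_frame] += 1
        self.H_nfmic[n_fmic] += 1
        self.H_nfuni[n_funi] += 1
        self.H_nfdend[n_fdend] += 1
        self.H_nmixc[n_mixc] += 1

    # -- ensemble means and fractions ------------------------------------

    @property
    def f_s(self) -> float:
        """Mean fraction of absorbed surfactants <s>/n_s."""
        return self._s_total / (self.n_frames * self.n_s)

    @property
    def f_dc(self) -> float:
        """Mean condensed fraction of dendrimer counterions."""
        return self._ndc_total / (self.n_frames * self.n_d * self.N_t)

    @property
    def f_sc(self) -> float:
        """Mean condensed fraction of surfactant counterions."""
        return self._nsc_total / (self.n_frames * self.n_s)

    @property
    def mean_n_fmic(self) -> float:
        return _counter_mean(self.H_nfmic)

    @property
    def mean_n_funi(self) -> float:
        return _counter_mean(self.H_nfuni)

    @property
    def mean_m_fmic(self) -> float:
        return _counter_mean(self.H_mfmic)

    @property
    def mean_m_br(self) -> float:
        return _counter_mean(self.H_mbr)

    @property
    def mean_m_cor(self) -> float:
        return _counter_mean(self.H_mcor)

    def occurrence(self, index: int) -> int:
        acc = self._per_index.get(index)
        return acc.occurrence if acc else 0

    def index_probabilities(self) -> dict[int, float]:
        """H_index normalized by the total number of aggregate observations."""
        total = sum(self.H_index.values())
        return {n: c / total for n, c in self.H_index.items()}


def _counter_mean(counter: Counter) -> float:
    total = sum(counter.values())
    if total == 0:
        return float("nan")
    return sum(k * v for k, v in counter.items()) / total


def accumulate(frames_aggregates, n_s: int, n_d: int, N_t: int) -> EnsembleStats:
    """Build :class:`EnsembleStats` from an iterable of per-frame aggregate
    record lists."""
    stats = EnsembleStats(n_s=n_s, n_d=n_d, N_t=N_t)
    for aggregates in frames_aggregates:
        stats.add_frame(aggregates)
    return stats


def index_conditioned_means(
    stats: EnsembleStats, min_occurrence: int = 10
) -> dict[int, IndexMeans]:
    """Per-index means, restricted to indices seen strictly more than
    ``min_occurrence`` times (the statistical-reliability filter)."""
    out: dict[int, IndexMeans] = {}
    for idx, acc in sorted(stats._per_index.items()):
        if acc.occurrence <= min_occurrence:
            continue
        occ = acc.occurrence
        out[idx] = IndexMeans(
            index=idx,
            occurrence=occ,
            n_br=acc.n_br_sum / occ,
            m_br=(acc.m_br_sum / acc.m_br_count) if acc.m_br_count else float("nan"),
            n_cor=acc.n_cor_sum / occ,
            m_cor=(acc.m_cor_sum / acc.m_cor_count) if acc.m_cor_count else float("nan"),
            n_dc=acc.n_dc_sum / occ,
            n_sc=acc.n_sc_sum / occ,
            ch=acc.ch_sum / occ,
        )
    return out


@dataclass(frozen=True)
class FavoredCluster:
    """The statistically favored aggregate within one d-range."""

    index: int
    d: int
    s_f: int
    count: int

    @property
    def s_per_dendrimer(self) -> float:
        return self.s_f / self.d


def favored_clusters(
    stats: EnsembleStats, d: int, smooth: bool = False
) -> FavoredCluster | None:
    """Highest local maximum of H(n_{s,d}) within the d-range of mixed
    clusters (d*n_s < n <= (d+1)*n_s).

    A bin counts as a local maximum if its count strictly exceeds those of
    the nearest nonzero-count neighbors (zero-count gaps are merged away).
    Ties between equal maxima resolve to the lower index with a warning.
    ``smooth`` applies a window-3 moving average on the dense histogram
    first.  Returns ``None`` when the d-range is empty (no such clusters
    observed, e.g. two-dendrimer clusters at weak hydrophobicity).
    """
    if d < 1:
        raise ValueError("favored clusters are defined for mixed clusters (d >= 1)")
    n_s = stats.n_s
    lo, hi = d * n_s, (d + 1) * n_s
    entries = sorted(
        (n, c) for n, c in stats.H_index.items() if lo < n <= hi and c > 0
    )
    if not entries:
        return None
    if smooth:
        dense = np.zeros(hi - lo, dtype=float)
        for n, c in entries:
            dense[n - lo - 1] = c
        kernel = np.ones(3) / 3.0
        sm = np.convolve(dense, kernel, mode="same")
        entries = [
            (lo + 1 + i, sm[i]) for i in range(len(sm)) if dense[i] > 0
        ]
    # local maxima over the sequence of nonzero bins
    maxima = []
    for k, (n, c) in enumerate(entries):
        left = entries[k - 1][1] if k > 0 else 0.0
        right = entries[k + 1][1] if k + 1 < len(entries) else 0.0
        if c > left and c > right:
            maxima.append((n, c))
    if not maxima:  # plateau-only histogram: fall back to the global max
        best_c = max(c for _, c in entries)
        cands = [(n, c) for n, c in entries if c == best_c]
    else:
        best_c = max(c for _, c in maxima)
        cands = [(n, c) for n, c in maxima if c == best_c]
    if len(cands) > 1:
        warnings.warn(
            f"tie between favored-cluster candidates {[n for n, _ in cands]} "
            f"in d={d} range; choosing the lowest index",
            stacklevel=2,
        )
    n_best = min(n for n, _ in cands)
    s_f, _ = index_to_sd(n_best, n_s)
    return FavoredCluster(
        index=n_best, d=d, s_f=s_f, count=stats.H_index[n_best]
    )
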