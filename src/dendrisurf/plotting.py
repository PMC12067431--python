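"""Optional matplotlib helpers mirroring the standard presentation of the
aggregate statistics (log-linear histograms, d-range separators).

matplotlib is an optional dependency; importing this module without it
raises ImportError.
"""

from __future__ import annotations

import matplotlib.pyplot as plt

from .statistics import EnsembleStats

__all__ = ["plot_index_histogram", "plot_mass_histogram"]


def plot_index_histogram(stats: EnsembleStats, ax=None, probability=True):
    """H(n_{s,d}) on a log-linear scale with vertical separators between
    the d = 0, 1, 2, ... ranges and a dashed line at the ten-occurrence
    reliability level."""
    if ax is None:
        _, ax = plt.subplots()
    data = stats.index_probabilities() if probability else dict(stats.H_index)
    xs = sorted(data)
    ax.semilogy([x for x in xs if x > 0], [data[x] for x in xs if x > 0],
                "o", ms=3, label="aggregates")
    if 0 in data:
        ax.semilogy([0], [data[0]], "s", color="k", label="free dendrimers")
    for d in range(1, stats.n_d + 1):
        ax.axvline(d * stats.n_s + 0.5, color="k", lw=1)
    total = sum(stats.H_index.values())
    if probability and total:
        ax.axhline(10 / total, color="gray", ls="--", lw=1)
    ax.set_xlabel(r"$n_{s,d}$")
    ax.set_ylabel("probability" if probability else "count")
    return ax


def plot_mass_histogram(stats: EnsembleStats, which: str = "H_mfmic", ax=None):
    """Micelle-mass histogram (free/bridge/corona) on a log-linear scale."""
    if ax is None:
        _, ax = plt.subplots()
    counter = getattr(stats, which)
    xs = sorted(counter)
    ax.semilogy(xs, [counter[x] for x in xs], "o-", ms=3)
    ax.set_xlabel({"H_mfmic": r"$m_{fmic}$", "H_mbr": r"$m_{br}$",
                   "H_mcor": r"$m_{cor}$"}.get(which, "mass"))
    ax.set_ylabel("count")
    return ax
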