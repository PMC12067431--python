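"""Independent O(N^2) reference implementations of the cluster criteria.

These deliberately avoid KD-trees, sparse graphs and library
connected-component routines: distances come from full minimum-image
distance matrices and components from a hand-written breadth-first search.
They exist to cross-validate :mod:`dendrisurf.clusters` on small systems
and are not meant to be fast.
"""

from __future__ import annotations

import numpy as np

from .clusters import AggregateRecord, CutoffParams, MicelleRecord
from .statistics import aggregate_index, effective_charge
from .topology import Frame, MolecularSystem, Species, minimum_image

__all__ = [
    "bf_find_micelles",
    "bf_bind_micelles",
    "bf_find_mixed_clusters",
    "bf_assign_condensed",
    "bf_analyze_frame",
    "canonical_form",
]


def _dist2(a: np.ndarray, b: np.ndarray, L: float) -> np.ndarray:
    dr = minimum_image(a[:, None, :] - b[None, :, :], L)
    return np.einsum("ijk,ijk->ij", dr, dr)


def _bfs_components(n: int, adj: dict[int, set[int]]) -> list[list[int]]:
    seen = [False] * n
    comps = []
    for start in range(n):
        if seen[start]:
            continue
        comp, queue = [], [start]
        seen[start] = True
        while queue:
            u = queue.pop()
            comp.append(u)
            for w in adj.get(u, ()):
                if not seen[w]:
                    seen[w] = True
                    queue.append(w)
        comps.append(sorted(comp))
    return comps


def bf_find_micelles(
    frame: Frame, system: MolecularSystem, cutoffs: CutoffParams = CutoffParams()
) -> list[MicelleRecord]:
    n_s = system.n_s
    if n_s == 0:
        return []
    L = frame.box_L
    r2 = cutoffs.r_star**2
    tails = system.tail_indices  # (n_s, 3)
    adj: dict[int, set[int]] = {c: set() for c in range(n_s)}
    for a in range(n_s):
        pa = frame.positions[tails[a]]
        for b in range(a + 1, n_s):
            if (_dist2(pa, frame.positions[tails[b]], L) < r2).any():
                adj[a].add(b)
                adj[b].add(a)
    return [
        MicelleRecord(frozenset(comp)) for comp in _bfs_components(n_s, adj)
    ]


def bf_bind_micelles(
    micelles: list[MicelleRecord],
    frame: Frame,
    system: MolecularSystem,
    cutoffs: CutoffParams = CutoffParams(),
) -> list[MicelleRecord]:
    L = frame.box_L
    r2 = cutoffs.r_star**2
    for m in micelles:
        bound = set()
        for dend in range(system.n_d):
            tpos = frame.positions[system.terminal_indices(dend)]
            for chain in m.chain_ids:
                hpos = frame.positions[system.head_indices[chain]][None, :]
                if len(tpos) and (_dist2(hpos, tpos, L) < r2).any():
                    bound.add(dend)
                    break
        m.bound_dendrimers = frozenset(bound)
        m.classify()
    return micelles


def bf_find_mixed_clusters(
    micelles: list[MicelleRecord], system: MolecularSystem
) -> list[AggregateRecord]:
    n_mic = len(micelles)
    n = n_mic + system.n_d
    adj: dict[int, set[int]] = {i: set() for i in range(n)}
    for mi, m in enumerate(micelles):
        for dend in m.bound_dendrimers:
            adj[mi].add(n_mic + dend)
            adj[n_mic + dend].add(mi)
    aggregates = []
    for comp in _bfs_components(n, adj):
        mics = [micelles[i] for i in comp if i < n_mic]
        dends = frozenset(i - n_mic for i in comp if i >= n_mic)
        s = sum(m.mass for m in mics)
        aggregates.append(
            AggregateRecord(
                micelles=mics,
                dendrimer_ids=dends,
                index=aggregate_index(s, len(dends), system.n_s),
            )
        )
    return aggregates


def bf_assign_condensed(
    aggregates: list[AggregateRecord],
    frame: Frame,
    system: MolecularSystem,
    cutoffs: CutoffParams = CutoffParams(),
) -> tuple[int, int]:
    """Exclusive nearest-bead condensation by full distance matrices."""
    L = frame.box_L
    beads_of = []
    for agg in aggregates:
        idx = []
        for dend in agg.dendrimer_ids:
            idx.extend(system.dendrimer_beads(dend).tolist())
        for m in agg.micelles:
            for chain in m.chain_ids:
                idx.extend(system.chain_beads[chain].tolist())
        beads_of.append(np.array(idx, dtype=np.int64))
        agg.n_dc = 0
        agg.n_sc = 0
    ions = system.counterion_indices
    n_free_dc = int(np.sum(system.species[ions] == Species.DENDRIMER_COUNTERION))
    n_free_sc = int(np.sum(system.species[ions] == Species.SURFACTANT_COUNTERION))
    for ion in ions:
        best_d2, best_agg = np.inf, -1
        p = frame.positions[ion][None, :]
        for ai, beads in enumerate(beads_of):
            if len(beads) == 0:
                continue
            d2 = _dist2(p, frame.positions[beads], L).min()
            if d2 < best_d2:
                best_d2, best_agg = d2, ai
        if best_agg >= 0 and best_d2 < cutoffs.r_star**2:
            if system.species[ion] == Species.DENDRIMER_COUNTERION:
                aggregates[best_agg].n_dc += 1
                n_free_dc -= 1
            else:
                aggregates[best_agg].n_sc += 1
                n_free_sc -= 1
    return n_free_dc, n_free_sc


def bf_analyze_frame(
    frame: Frame,
    system: MolecularSystem,
    cutoffs: CutoffParams = CutoffParams(),
) -> tuple[list[AggregateRecord], int, int]:
    micelles = bf_bind_micelles(
        bf_find_micelles(frame, system, cutoffs), frame, system, cutoffs
    )
    aggregates = bf_find_mixed_clusters(micelles, system)
    n_free_dc, n_free_sc = bf_assign_condensed(aggregates, frame, system, cutoffs)
    for agg in aggregates:
        agg.ch = effective_charge(agg.s, agg.d, system.N_t, agg.n_sc, agg.n_dc)
    return aggregates, n_free_dc, n_free_sc


def canonical_form(aggregates: list[AggregateRecord]):
    """Order-independent representation for equality checks between
    implementations: per aggregate, its micelle partition with kinds and
    bindings, dendrimer set, condensation counts and charge."""
    out = []
    for agg in aggregates:
        mics = tuple(
            sorted(
                (tuple(sorted(m.chain_ids)), m.kind, tuple(sorted(m.bound_dendrimers)))
                for m in agg.micelles
            )
        )
        out.append(
            (
                agg.s,
                agg.d,
                agg.index,
                tuple(sorted(agg.dendrimer_ids)),
                mics,
                agg.n_dc,
                agg.n_sc,
                agg.ch,
            )
        )
    return tuple(sorted(out))
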