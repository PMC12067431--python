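"""Planted test configurations with exact ground-truth aggregate structure.

A :class:`PlantSpec` states a complete aggregate decomposition — micelle
masses, which dendrimers each micelle is attached to, and which counterions
are condensed on which entity — and :func:`plant_frame` realizes it
geometrically so that every intended contact sits well below the r* = 1.5
criterion and every unintended pair sits well above it, separated by a
stated safety margin.  Analysis of a planted frame must therefore recover
the planted labels exactly; that fixed-point property is what the cluster
and statistics modules are validated against.

Geometry is intentionally unphysical (blocks on a coarse grid, heads
teleported next to terminal beads): planted frames validate classification
logic, not thermodynamics.  Micelle tails are packed into tight columns
(a cartoon of the dense hydrophobic core), heads sit above them, and
binding is realized by placing a head and a terminal 1.2 sigma apart on a
"porch" beside the dendrimer block.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .clusters import AggregateRecord, MicelleRecord
from .statistics import aggregate_index, effective_charge
from .topology import (
    DendrimerSpec,
    Frame,
    MolecularSystem,
    PackingError,
    Species,
    compose_topology,
)

__all__ = [
    "PlantSpec",
    "GroundTruth",
    "plant_frame",
    "plant_trajectory",
    "random_plant_spec",
]

_R_STAR = 1.5


@dataclass(frozen=True)
class PlantSpec:
    """A stated aggregate decomposition to be realized geometrically.

    ``attachments[j]`` is the set of dendrimer ids micelle ``j`` is bound
    to (empty = free, one = corona, two or more = bridge).  ``condensed_dc``
    and ``condensed_sc`` list the target entity of each condensed
    counterion as ``("micelle", j)`` or ``("dendrimer", i)``; all remaining
    counterions are planted free.  ``n_s`` is the sum of the micelle
    masses (every chain belongs to exactly one planted micelle).
    """

    micelle_masses: tuple[int, ...]
    attachments: tuple[frozenset[int], ...]
    n_d: int = 0
    dendrimer: DendrimerSpec = DendrimerSpec(3, 4)
    condensed_dc: tuple[tuple[str, int], ...] = ()
    condensed_sc: tuple[tuple[str, int], ...] = ()
    margin: float = 0.2
    box_L: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.micelle_masses) != len(self.attachments):
            raise ValueError("attachments must match micelle_masses")
        if any(m < 1 for m in self.micelle_masses):
            raise ValueError("micelle masses must be >= 1")
        for att in self.attachments:
            if any(i < 0 or i >= self.n_d for i in att):
                raise ValueError("attachment references an unknown dendrimer")
        if not (0 < self.margin <= 0.45):
            raise ValueError("margin must lie in (0, 0.45]")
        for kind, i in self.condensed_dc + self.condensed_sc:
            if kind == "micelle":
                if i < 0 or i >= len(self.micelle_masses):
                    raise ValueError(f"condensed target micelle {i} does not exist")
            elif kind == "dendrimer":
                if i < 0 or i >= self.n_d:
                    raise ValueError(f"condensed target dendrimer {i} does not exist")
            else:
                raise ValueError(f"unknown condensed target kind {kind!r}")

    @property
    def n_s(self) -> int:
        return int(sum(self.micelle_masses))

    def build_system(self) -> MolecularSystem:
        return compose_topology(
            self.n_d, self.n_s, self.dendrimer if self.n_d else None
        )


@dataclass
class GroundTruth:
    """Planted labels in the same record types the analysis produces."""

    micelles: list[MicelleRecord]
    aggregates: list[AggregateRecord]
    n_free_dc: int
    n_free_sc: int

    @property
    def absorbed(self) -> int:
        return sum(a.s for a in self.aggregates if a.is_mixed)


def _components(n_mic: int, n_d: int, attachments) -> list[tuple[list[int], set[int]]]:
    """Connected components of the planted micelle-dendrimer graph, via
    union-find (independent of the analysis code)."""
    parent = list(range(n_mic + n_d))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    for j, att in enumerate(attachments):
        for i in att:
            union(j, n_mic + i)
    comps: dict[int, tuple[list[int], set[int]]] = {}
    for j in range(n_mic):
        comps.setdefault(find(j), ([], set()))[0].append(j)
    for i in range(n_d):
        comps.setdefault(find(n_mic + i), ([], set()))[1].add(i)
    return list(comps.values())


def _ground_truth(spec: PlantSpec, system: MolecularSystem) -> GroundTruth:
    masses = spec.micelle_masses
    chain_of_micelle: list[list[int]] = []
    c = 0
    for m in masses:
        chain_of_micelle.append(list(range(c, c + m)))
        c += m
    micelles = [
        MicelleRecord(frozenset(chain_of_micelle[j]), frozenset(att)).classify()
        for j, att in enumerate(spec.attachments)
    ]
    agg_of_entity: dict[tuple[str, int], int] = {}
    aggregates = []
    for mics, dends in _components(len(masses), spec.n_d, spec.attachments):
        s = sum(masses[j] for j in mics)
        agg = AggregateRecord(
            micelles=[micelles[j] for j in mics],
            dendrimer_ids=frozenset(dends),
            index=aggregate_index(s, len(dends), spec.n_s),
        )
        for j in mics:
            agg_of_entity[("micelle", j)] = len(aggregates)
        for i in dends:
            agg_of_entity[("dendrimer", i)] = len(aggregates)
        aggregates.append(agg)
    for target in spec.condensed_dc:
        aggregates[agg_of_entity[target]].n_dc += 1
    for target in spec.condensed_sc:
        aggregates[agg_of_entity[target]].n_sc += 1
    for agg in aggregates:
        agg.ch = effective_charge(agg.s, agg.d, system.N_t, agg.n_sc, agg.n_dc)
    n_free_dc = spec.n_d * system.N_t - len(spec.condensed_dc)
    n_free_sc = spec.n_s - len(spec.condensed_sc)
    if n_free_dc < 0 or n_free_sc < 0:
        raise ValueError("more condensed counterions than exist in the system")
    return GroundTruth(micelles, aggregates, n_free_dc, n_free_sc)


def plant_frame(
    spec: PlantSpec, system: MolecularSystem | None = None
) -> tuple[MolecularSystem, Frame, GroundTruth]:
    """Realize a planted spec as coordinates with unambiguous margins.

    Intended contacts are placed at ``<= r* - margin`` and unintended pairs
    at ``>= r* + margin`` (grid construction guarantees at least 2.2 sigma
    between distinct blocks).  Raises :class:`PackingError` when the stated
    box cannot hold the required layout.
    """
    if system is None:
        system = spec.build_system()
    if system.n_s != spec.n_s or system.n_d != spec.n_d:
        raise ValueError("system topology does not match the plant spec")
    truth = _ground_truth(spec, system)
    rng = np.random.default_rng(spec.seed)
    jitter = 0.02
    bound_d = min(1.2, _R_STAR - spec.margin - 0.08)
    touch_d = 0.7  # condensed-ion anchor distance

    masses = spec.micelle_masses
    n_mic = len(masses)
    n_d = spec.n_d

    # --- block extents
    def dend_extent() -> float:
        side = max(1, math.ceil(system.N_d ** (1.0 / 3.0)))
        return (side - 1) * 1.0

    def mic_extent(m: int) -> float:
        cols = max(1, math.ceil(math.sqrt(m)))
        return max((cols - 1) * 1.2, 2.0)

    extents = [dend_extent()] * n_d + [mic_extent(m) for m in masses]
    bonds_per_dend = [0] * n_d
    for att in spec.attachments:
        for i in att:
            bonds_per_dend[i] += 1
    b_max = max(bonds_per_dend, default=0)
    site_rows = max(1, math.ceil(math.sqrt(max(b_max, 1))))
    e_core = max(extents, default=1.0)
    pitch = max(e_core + 7.0, 3.4 + 3.0 * (site_rows - 1) + 2.4)

    n_free_ions = truth.n_free_dc + truth.n_free_sc
    cap = max(1, int(pitch - 2.4)) ** 3
    n_ion_cells = math.ceil(n_free_ions / cap) if n_free_ions else 0
    n_blocks = n_d + n_mic + n_ion_cells
    if n_blocks == 0:
        L = spec.box_L if spec.box_L else 10.0
        return system, Frame(np.empty((0, 3)), L, 0), truth

    k_grid = math.ceil(n_blocks ** (1.0 / 3.0))
    L = spec.box_L if spec.box_L is not None else k_grid * pitch + 1.0
    if k_grid * pitch > L:
        raise PackingError(
            f"box L={L} cannot hold {n_blocks} blocks of pitch {pitch:.1f} "
            f"(needs L >= {k_grid * pitch:.1f})"
        )

    cells = [
        np.array([i, j, k], dtype=float) * pitch + 1.0
        for i in range(k_grid)
        for j in range(k_grid)
        for k in range(k_grid)
    ]
    order = rng.permutation(len(cells))
    pos = np.zeros((system.n_beads, 3))

    def snake(n: int, spacing: float) -> np.ndarray:
        side = max(1, math.ceil(n ** (1.0 / 3.0)))
        pts = []
        for a in range(side):
            for b in range(side):
                for c in range(side):
                    pts.append((a, b, c))
                    if len(pts) == n:
                        return np.array(pts, dtype=float) * spacing
        return np.array(pts[:n], dtype=float) * spacing

    block = 0
    dend_origin = []
    for i in range(n_d):
        origin = cells[order[block]]
        block += 1
        dend_origin.append(origin)
        beads = system.dendrimer_beads(i)
        pos[beads] = origin + snake(len(beads), 1.0) + rng.uniform(
            -jitter, jitter, (len(beads), 3)
        )

    chain_of_micelle: list[list[int]] = []
    c = 0
    for m in masses:
        chain_of_micelle.append(list(range(c, c + m)))
        c += m

    mic_anchor_tails: list[list[int]] = []  # tail beads usable as ion anchors
    for j, m in enumerate(masses):
        origin = cells[order[block]]
        block += 1
        cols = max(1, math.ceil(math.sqrt(m)))
        anchors = []
        for k, chain in enumerate(chain_of_micelle[j]):
            cx, cy = divmod(k, cols)
            base = origin + np.array([cx * 1.2, cy * 1.2, 0.0])
            tails = system.tail_indices[chain]
            for t, bead in enumerate(tails):
                pos[bead] = base + np.array([0.0, 0.0, 0.6 * t]) + rng.uniform(
                    -jitter, jitter, 3
                )
            pos[system.head_indices[chain]] = base + np.array([0.0, 0.0, 2.0])
            anchors.append(int(tails[0]))
        mic_anchor_tails.append(anchors)

    # --- binding sites on dendrimer porches
    site_counter = [0] * n_d
    term_counter = [0] * n_d
    terminals = [list(system.terminal_indices(i)) for i in range(n_d)]

    def next_site(i: int) -> np.ndarray:
        k = site_counter[i]
        site_counter[i] += 1
        row, col = divmod(k, site_rows)
        return dend_origin[i] + np.array(
            [extents[i] + 2.0, 1.0 + 3.0 * row, 1.0 + 3.0 * col]
        )

    def next_terminal(i: int) -> int:
        if term_counter[i] >= len(terminals[i]):
            raise PackingError(
                f"dendrimer {i} has only {len(terminals[i])} terminals for "
                f"{bonds_per_dend[i]} planted bonds"
            )
        t = terminals[i][term_counter[i]]
        term_counter[i] += 1
        return int(t)

    axes = np.array(
        [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
        dtype=float,
    )
    for j, att in enumerate(spec.attachments):
        dends = sorted(att)
        chains = chain_of_micelle[j]
        if len(dends) <= len(chains):
            for k, i in enumerate(dends):
                p = next_site(i)
                pos[next_terminal(i)] = p
                pos[system.head_indices[chains[k]]] = p + np.array([bound_d, 0, 0])
        else:
            if len(dends) > 6:
                raise PackingError(
                    "a single chain cannot bridge more than 6 dendrimers"
                )
            p = next_site(dends[0])
            head = system.head_indices[chains[0]]
            pos[head] = p
            for k, i in enumerate(dends):
                pos[next_terminal(i)] = p + bound_d * axes[k]

    # --- counterions
    dci = np.flatnonzero(system.species == Species.DENDRIMER_COUNTERION)
    sci = np.flatnonzero(system.species == Species.SURFACTANT_COUNTERION)
    dend_anchor_ptr = [0] * n_d
    mic_anchor_ptr = [0] * n_mic
    offset = touch_d * np.array([1.0, 1.0, 1.0]) / math.sqrt(3.0)

    def anchor_bead(target: tuple[str, int]) -> int:
        kind, i = target
        if kind == "dendrimer":
            beads = system.dendrimer_beads(i)
            # interior beads only: terminals may have been moved to a porch
            interior = [
                int(b) for b in beads if system.species[b] != Species.DENDRIMER_TERMINAL
            ]
            ptr = dend_anchor_ptr[i] % len(interior)
            dend_anchor_ptr[i] += 1
            return interior[ptr]
        ptr = mic_anchor_ptr[i] % len(mic_anchor_tails[i])
        mic_anchor_ptr[i] += 1
        return mic_anchor_tails[i][ptr]

    for ion, target in zip(dci, spec.condensed_dc):
        pos[ion] = pos[anchor_bead(target)] + offset
    for ion, target in zip(sci, spec.condensed_sc):
        pos[ion] = pos[anchor_bead(target)] + offset

    free_ions = list(dci[len(spec.condensed_dc):]) + list(sci[len(spec.condensed_sc):])
    placed = 0
    for _ in range(n_ion_cells):
        origin = cells[order[block]]
        block += 1
        take = free_ions[placed : placed + cap]
        pos[take] = origin + snake(len(take), 1.0)
        placed += len(take)

    return system, Frame(np.mod(pos, L), L, 0), truth


def plant_trajectory(
    specs: list[PlantSpec],
    dump_path=None,
    labels_path=None,
) -> tuple[MolecularSystem, list[Frame], list[GroundTruth]]:
    """Realize a sequence of planted specs sharing one topology.

    All specs must agree on ``n_d``, dendrimer architecture and total chain
    count.  Optionally writes the frames as a LAMMPS dump trajectory and
    the labels as a tab-separated sidecar (see :mod:`dendrisurf.lammpsio`).
    """
    if not specs:
        raise ValueError("need at least one frame spec")
    first = specs[0]
    for sp in specs[1:]:
        if (
            sp.n_d != first.n_d
            or sp.dendrimer != first.dendrimer
            or sp.n_s != first.n_s
        ):
            raise ValueError("all frame specs must share one topology")
    system = first.build_system()
    frames, truths = [], []
    for step, sp in enumerate(specs):
        _, frame, truth = plant_frame(sp, system)
        frame.step = step
        frames.append(frame)
        truths.append(truth)
    box_L = max(f.box_L for f in frames)
    for f in frames:
        f.box_L = box_L  # one consistent box across the trajectory
    if dump_path is not None:
        from .lammpsio import write_dump

        write_dump(dump_path, frames, system)
    if labels_path is not None:
        from .lammpsio import write_labels

        write_labels(labels_path, truths)
    return system, frames, truths


def random_plant_spec(
    rng: np.random.Generator,
    max_beads: int = 500,
    n_d_choices: tuple[int, ...] = (0, 1, 2, 2, 3),
    dendrimer: DendrimerSpec = DendrimerSpec(2, 2),
    seed: int | None = None,
) -> PlantSpec:
    """Draw a fuzzed planted spec under a bead budget (for oracle tests)."""
    n_d = int(rng.choice(n_d_choices))
    sys_probe = compose_topology(n_d, 0, dendrimer if n_d else None)
    budget = max_beads - n_d * (sys_probe.N_d + sys_probe.N_t)
    if budget < 5:
        n_d, budget = 0, max_beads
    masses = []
    while budget >= 5 and len(masses) < 12:
        m = int(rng.integers(1, min(9, budget // 5) + 1))
        masses.append(m)
        budget -= 5 * m  # 4 beads + 1 counterion per chain
        if rng.random() < 0.25:
            break
    if not masses and n_d == 0:
        masses = [1]
    attachments = []
    for m in masses:
        if n_d == 0 or rng.random() < 0.4:
            attachments.append(frozenset())
        else:
            k = min(int(rng.integers(1, n_d + 1)), 6)
            ids = rng.choice(n_d, size=k, replace=False)
            attachments.append(frozenset(int(i) for i in ids))
    # keep planted bonds within each dendrimer's terminal budget
    sysN = compose_topology(n_d, sum(masses), dendrimer if n_d else None)
    loads = [0] * max(n_d, 1)
    pruned = []
    for att in attachments:
        keep = set()
        for i in sorted(att):
            if loads[i] < sysN.N_t:
                keep.add(i)
                loads[i] += 1
        pruned.append(frozenset(keep))
    attachments = pruned
    entities = [("micelle", j) for j in range(len(masses))] + [
        ("dendrimer", i) for i in range(n_d)
    ]
    n_dci = n_d * sysN.N_t
    n_sci = sum(masses)
    condensed_dc = tuple(
        entities[int(rng.integers(len(entities)))]
        for _ in range(int(rng.integers(0, min(n_dci, 6) + 1)))
    )
    condensed_sc = tuple(
        entities[int(rng.integers(len(entities)))]
        for _ in range(int(rng.integers(0, min(n_sci, 6) + 1)))
    )
    return PlantSpec(
        micelle_masses=tuple(masses),
        attachments=tuple(attachments),
        n_d=n_d,
        dendrimer=dendrimer,
        condensed_dc=condensed_dc,
        condensed_sc=condensed_sc,
        seed=int(rng.integers(2**31)) if seed is None else seed,
    )
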