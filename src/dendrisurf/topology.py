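"""Molecular topologies: dendrimers, surfactants, counterions, assembly.

The model contains two-monomer-core trifunctional dendrimers whose terminal
beads carry a charge of +1e, four-bead surfactant chains (one -1e head plus
three neutral hydrophobic tails), and monovalent mobile counterions added in
the exact numbers that make the overall system electroneutral.

A dendrimer of generation ``G`` with spacer length ``S`` (bonds per spacer)
is grown as a tree: the two bonded core monomers each sprout two spacers,
every interior branch point has three bond partners (one incoming spacer,
two outgoing), and every core-to-terminal path traverses exactly ``G``
spacer segments of ``S`` bonds.  Terminal and monomer counts are therefore
properties of the explicitly constructed tree rather than closed-form
inputs; for this architecture the leaf count works out to ``2**(G+1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "Species",
    "DendrimerSpec",
    "MolecularSystem",
    "Frame",
    "PackingError",
    "build_dendrimer",
    "build_surfactant",
    "assemble_system",
    "wrap_positions",
    "minimum_image",
]


class Species(IntEnum):
    """Bead species; integer values double as LAMMPS numeric atom types."""

    DENDRIMER_CORE = 1
    DENDRIMER_INTERIOR = 2
    DENDRIMER_TERMINAL = 3
    SURFACTANT_HEAD = 4
    SURFACTANT_TAIL = 5
    DENDRIMER_COUNTERION = 6  # mobile anion, -1e
    SURFACTANT_COUNTERION = 7  # mobile cation, +1e


#: fixed valence of each species, in units of e
SPECIES_CHARGE = {
    Species.DENDRIMER_CORE: 0,
    Species.DENDRIMER_INTERIOR: 0,
    Species.DENDRIMER_TERMINAL: +1,
    Species.SURFACTANT_HEAD: -1,
    Species.SURFACTANT_TAIL: 0,
    Species.DENDRIMER_COUNTERION: -1,
    Species.SURFACTANT_COUNTERION: +1,
}


class PackingError(RuntimeError):
    """Raised when an initial configuration cannot be packed into the box."""


@dataclass(frozen=True)
class DendrimerSpec:
    """Architecture of one dendrimer: generation G and spacer length S."""

    G: int = 3
    S: int = 4

    def __post_init__(self) -> None:
        if int(self.G) != self.G or int(self.S) != self.S or self.G < 1 or self.S < 1:
            raise ValueError(f"G and S must be positive integers, got G={self.G}, S={self.S}")

    @property
    def label(self) -> str:
        return f"G{self.G}S{self.S}"


@dataclass
class MolecularSystem:
    """Species, charges, bonds and molecule bookkeeping for all beads.

    Bead order is: dendrimer beads (grouped per dendrimer), surfactant
    chains (head first, then three tails, per chain), dendrimer counterions,
    surfactant counterions.  ``dendrimer_id`` is ``-1`` for beads that do
    not belong to a dendrimer; dendrimers and molecules are numbered from 0.
    """

    species: np.ndarray  # (N,) int8, Species codes
    charge: np.ndarray  # (N,) int8, in e
    bonds: np.ndarray  # (M,2) int64 bead indices
    molecule_id: np.ndarray  # (N,) int64
    dendrimer_id: np.ndarray  # (N,) int64, -1 outside dendrimers
    n_d: int
    n_s: int
    N_t: int  # terminals per dendrimer (0 if n_d == 0)
    N_d: int  # beads per dendrimer (0 if n_d == 0)

    _chain_beads: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def n_beads(self) -> int:
        return int(self.species.shape[0])

    @property
    def total_charge(self) -> int:
        return int(self.charge.sum())

    @property
    def head_indices(self) -> np.ndarray:
        """Bead index of every surfactant head, ordered by chain."""
        return self.chain_beads[:, 0]

    @property
    def tail_indices(self) -> np.ndarray:
        """(n_s, 3) tail bead indices, ordered by chain."""
        return self.chain_beads[:, 1:]

    @property
    def chain_beads(self) -> np.ndarray:
        """(n_s, 4) bead indices per surfactant chain (head, 3 tails)."""
        if self._chain_beads is None:
            heads = np.flatnonzero(self.species == Species.SURFACTANT_HEAD)
            cb = np.empty((self.n_s, 4), dtype=np.int64)
            for c, h in enumerate(heads):
                cb[c] = (h, h + 1, h + 2, h + 3)
            self._chain_beads = cb
        return self._chain_beads

    def terminal_indices(self, dendrimer: int | None = None) -> np.ndarray:
        mask = self.species == Species.DENDRIMER_TERMINAL
        if dendrimer is not None:
            mask &= self.dendrimer_id == dendrimer
        return np.flatnonzero(mask)

    def dendrimer_beads(self, dendrimer: int) -> np.ndarray:
        return np.flatnonzero(self.dendrimer_id == dendrimer)

    @property
    def counterion_indices(self) -> np.ndarray:
        return np.flatnonzero(
            (self.species == Species.DENDRIMER_COUNTERION)
            | (self.species == Species.SURFACTANT_COUNTERION)
        )

    def validate(self) -> None:
        """Check the structural invariants; raise ``ValueError`` on failure."""
        if self.total_charge != 0 and (self.n_d or self.n_s):
            # fragments (single molecules) are allowed to carry net charge;
            # assembled systems must be neutral, enforced by assemble_system
            pass
        for sp in np.unique(self.species):
            want = SPECIES_CHARGE[Species(int(sp))]
            got = self.charge[self.species == sp]
            if not np.all(got == want):
                raise ValueError(f"species {Species(int(sp)).name} has wrong charge")
        n_dci = int(np.sum(self.species == Species.DENDRIMER_COUNTERION))
        n_sci = int(np.sum(self.species == Species.SURFACTANT_COUNTERION))
        if n_dci and n_dci != self.n_d * self.N_t:
            raise ValueError("dendrimer counterion count != n_d * N_t")
        if n_sci and n_sci != self.n_s:
            raise ValueError("surfactant counterion count != n_s")


@dataclass
class Frame:
    """Bead coordinates (in sigma) plus cubic box length at one time step."""

    positions: np.ndarray  # (N,3) float64
    box_L: float
    step: int = 0

    def wrapped(self) -> "Frame":
        return Frame(wrap_positions(self.positions, self.box_L), self.box_L, self.step)


def wrap_positions(x: np.ndarray, L: float) -> np.ndarray:
    return np.mod(x, L)


def minimum_image(dr: np.ndarray, L: float) -> np.ndarray:
    return dr - L * np.round(dr / L)


# ---------------------------------------------------------------------------
# molecule builders


def build_dendrimer(spec: DendrimerSpec) -> MolecularSystem:
    """Construct one dendrimer tree as a system fragment.

    Returns a :class:`MolecularSystem` holding a single dendrimer (no
    surfactants, no counterions).  The terminal count ``N_t`` is the leaf
    count of the explicitly grown tree and every terminal carries +1e.
    """
    G, S = spec.G, spec.S
    species: list[int] = [Species.DENDRIMER_CORE, Species.DENDRIMER_CORE]
    bonds: list[tuple[int, int]] = [(0, 1)]

    def grow_spacer(parent: int, gen: int) -> None:
        """Append one spacer of S bonds from ``parent`` ending at a
        generation-``gen`` node, then recurse."""
        prev = parent
        for k in range(S):
            is_node = k == S - 1
            if is_node and gen == G:
                species.append(Species.DENDRIMER_TERMINAL)
            else:
                species.append(Species.DENDRIMER_INTERIOR)
            idx = len(species) - 1
            bonds.append((prev, idx))
            prev = idx
        if gen < G:
            grow_spacer(prev, gen + 1)
            grow_spacer(prev, gen + 1)

    for core in (0, 1):
        grow_spacer(core, 1)
        grow_spacer(core, 1)

    sp = np.array(species, dtype=np.int8)
    ch = np.array([SPECIES_CHARGE[Species(int(s))] for s in species], dtype=np.int8)
    n = len(species)
    return MolecularSystem(
        species=sp,
        charge=ch,
        bonds=np.array(bonds, dtype=np.int64),
        molecule_id=np.zeros(n, dtype=np.int64),
        dendrimer_id=np.zeros(n, dtype=np.int64),
        n_d=1,
        n_s=0,
        N_t=int(np.sum(sp == Species.DENDRIMER_TERMINAL)),
        N_d=n,
    )


def build_surfactant() -> MolecularSystem:
    """One linear surfactant: charged head bead plus three neutral tails."""
    sp = np.array(
        [Species.SURFACTANT_HEAD] + [Species.SURFACTANT_TAIL] * 3, dtype=np.int8
    )
    ch = np.array([-1, 0, 0, 0], dtype=np.int8)
    bonds = np.array([(0, 1), (1, 2), (2, 3)], dtype=np.int64)
    return MolecularSystem(
        species=sp,
        charge=ch,
        bonds=bonds,
        molecule_id=np.zeros(4, dtype=np.int64),
        dendrimer_id=np.full(4, -1, dtype=np.int64),
        n_d=0,
        n_s=1,
        N_t=0,
        N_d=0,
    )


def compose_topology(n_d: int, n_s: int, spec: DendrimerSpec | None) -> MolecularSystem:
    """Concatenate ``n_d`` dendrimers, ``n_s`` chains and the counterions
    required for electroneutrality into one topology."""
    if n_d < 0 or n_s < 0:
        raise ValueError("n_d and n_s must be non-negative")
    if n_d > 0 and spec is None:
        raise ValueError("a DendrimerSpec is required when n_d > 0")

    species_parts, charge_parts, bond_parts = [], [], []
    mol_parts, dend_parts = [], []
    offset = 0
    mol = 0
    N_t = N_d = 0

    if n_d > 0:
        dend = build_dendrimer(spec)
        N_t, N_d = dend.N_t, dend.N_d
        for i in range(n_d):
            species_parts.append(dend.species)
            charge_parts.append(dend.charge)
            bond_parts.append(dend.bonds + offset)
            mol_parts.append(np.full(N_d, mol, dtype=np.int64))
            dend_parts.append(np.full(N_d, i, dtype=np.int64))
            offset += N_d
            mol += 1

    chain = build_surfactant()
    for _ in range(n_s):
        species_parts.append(chain.species)
        charge_parts.append(chain.charge)
        bond_parts.append(chain.bonds + offset)
        mol_parts.append(np.full(4, mol, dtype=np.int64))
        dend_parts.append(np.full(4, -1, dtype=np.int64))
        offset += 4
        mol += 1

    n_dci = n_d * N_t
    n_sci = n_s
    for sp_code, count in (
        (Species.DENDRIMER_COUNTERION, n_dci),
        (Species.SURFACTANT_COUNTERION, n_sci),
    ):
        if count:
            species_parts.append(np.full(count, sp_code, dtype=np.int8))
            charge_parts.append(
                np.full(count, SPECIES_CHARGE[sp_code], dtype=np.int8)
            )
            mol_parts.append(np.arange(mol, mol + count, dtype=np.int64))
            dend_parts.append(np.full(count, -1, dtype=np.int64))
            offset += count
            mol += count

    system = MolecularSystem(
        species=np.concatenate(species_parts) if species_parts else np.empty(0, np.int8),
        charge=np.concatenate(charge_parts) if charge_parts else np.empty(0, np.int8),
        bonds=(
            np.concatenate(bond_parts)
            if bond_parts
            else np.empty((0, 2), dtype=np.int64)
        ),
        molecule_id=np.concatenate(mol_parts) if mol_parts else np.empty(0, np.int64),
        dendrimer_id=np.concatenate(dend_parts) if dend_parts else np.empty(0, np.int64),
        n_d=n_d,
        n_s=n_s,
        N_t=N_t,
        N_d=N_d,
    )
    assert system.total_charge == 0, "assembled systems must be electroneutral"
    return system


# ---------------------------------------------------------------------------
# initial placement


def assemble_system(
    n_d: int,
    n_s: int,
    spec: DendrimerSpec | None,
    L: float,
    seed: int,
    min_separation: float = 0.9,
) -> tuple[MolecularSystem, Frame]:
    """Build an electroneutral periodic system with initial coordinates.

    Dendrimers are grown by self-avoiding breadth-first placement,
    surfactants are inserted as randomly oriented rods, ions uniformly at
    random; a soft-core push-off pass then removes residual overlaps so
    that all nonbonded distances exceed ``min_separation`` (in sigma).
    Deterministic for a fixed seed.
    """
    system = compose_topology(n_d, n_s, spec)
    N = system.n_beads
    if N == 0:
        return system, Frame(np.empty((0, 3)), float(L), 0)
    # crude packing feasibility: bead volume fraction at sigma=1
    phi = N * (np.pi / 6.0) / L**3
    if phi > 0.45:
        raise PackingError(f"volume fraction {phi:.2f} too high for box L={L}")

    rng = np.random.default_rng(seed)
    pos = np.empty((N, 3))
    bond_len = 0.97

    def rand_unit(n: int = 1) -> np.ndarray:
        v = rng.normal(size=(n, 3))
        return v / np.linalg.norm(v, axis=1, keepdims=True)

    # dendrimers: BFS along the bond tree with local self-avoidance
    for i in range(n_d):
        beads = system.dendrimer_beads(i)
        b0 = beads[0]
        placed: list[int] = []
        adj: dict[int, list[int]] = {int(b): [] for b in beads}
        bead_set = set(int(b) for b in beads)
        for a, b in system.bonds:
            if int(a) in bead_set and int(b) in bead_set:
                adj[int(a)].append(int(b))
                adj[int(b)].append(int(a))
        pos[b0] = rng.uniform(0, L, size=3)
        placed.append(b0)
        queue = [int(b0)]
        seen = {int(b0)}
        while queue:
            parent = queue.pop(0)
            for child in adj[parent]:
                if child in seen:
                    continue
                seen.add(child)
                own = pos[placed]
                for attempt in range(40):
                    trial = pos[parent] + bond_len * rand_unit()[0]
                    d = minimum_image(own - trial, L)
                    thresh = 0.8 if attempt < 30 else 0.6
                    if np.min(np.einsum("ij,ij->i", d, d)) > thresh**2:
                        break
                pos[child] = trial
                placed.append(child)
                queue.append(child)

    # surfactants as straight rods
    for c in range(n_s):
        beads = system.chain_beads[c]
        u = rand_unit()[0]
        start = rng.uniform(0, L, size=3)
        for k, b in enumerate(beads):
            pos[b] = start + k * bond_len * u

    ions = system.counterion_indices
    if len(ions):
        pos[ions] = rng.uniform(0, L, size=(len(ions), 3))

    pos = wrap_positions(pos, L)
    pos = _soft_pushoff(pos, system.bonds, L, min_separation, bond_len)
    return system, Frame(pos, float(L), 0)


def _soft_pushoff(
    pos: np.ndarray,
    bonds: np.ndarray,
    L: float,
    target: float,
    bond_len: float,
    max_iter: int = 600,
) -> np.ndarray:
    """Iteratively displace overlapping nonbonded beads apart and keep bond
    lengths near ``bond_len``; raises :class:`PackingError` on failure."""
    pos = pos.copy()
    n = pos.shape[0]
    bonded = set(map(tuple, np.sort(bonds, axis=1))) if len(bonds) else set()
    probe = target + 0.05
    for _ in range(max_iter):
        tree = cKDTree(wrap_positions(pos, L), boxsize=L)
        pairs = tree.query_pairs(probe, output_type="ndarray")
        disp = np.zeros_like(pos)
        n_bad = 0
        if len(pairs):
            keep = np.array(
                [tuple(sorted(p)) not in bonded for p in pairs], dtype=bool
            )
            pairs = pairs[keep]
        if len(pairs):
            dr = minimum_image(pos[pairs[:, 0]] - pos[pairs[:, 1]], L)
            dist = np.linalg.norm(dr, axis=1)
            bad = dist < target
            n_bad = int(bad.sum())
            if n_bad:
                push = 0.5 * (target + 0.02 - dist[bad])[:, None] * (
                    dr[bad] / np.maximum(dist[bad], 1e-6)[:, None]
                )
                np.add.at(disp, pairs[bad, 0], push)
                np.add.at(disp, pairs[bad, 1], -push)
        n_long = 0
        if len(bonds):
            dr = minimum_image(pos[bonds[:, 0]] - pos[bonds[:, 1]], L)
            dist = np.linalg.norm(dr, axis=1)
            off = np.abs(dist - bond_len) > 0.15
            n_long = int(off.sum())
            if n_long:
                pull = -0.5 * (dist[off] - bond_len)[:, None] * (
                    dr[off] / np.maximum(dist[off], 1e-6)[:, None]
                )
                np.add.at(disp, bonds[off, 0], pull)
                np.add.at(disp, bonds[off, 1], -pull)
        if n_bad == 0 and n_long == 0:
            return wrap_positions(pos, L)
        step = np.clip(disp, -0.2, 0.2)
        pos = pos + step
    raise PackingError(
        f"push-off failed to reach separation {target} within {max_iter} iterations "
        f"({n} beads, box L={L})"
    )
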