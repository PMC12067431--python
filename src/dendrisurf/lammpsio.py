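"""Text file formats: LAMMPS data (atom_style full), LAMMPS dump
trajectories, aggregate tables and planted-label sidecars.

The data format stores id, molecule, numeric type, charge and coordinates
plus a Bonds section; the numeric type codes are the :class:`Species`
values and are recorded in the header comment.  Coordinates are stored
wrapped; readers re-wrap, so dialect differences in dump wrapping are
neutralized on read.
"""

from __future__ import annotations

import numpy as np

from .topology import Frame, MolecularSystem, Species, wrap_positions

__all__ = [
    "ParseError",
    "write_data",
    "read_data",
    "write_dump",
    "read_dump",
    "write_aggregate_table",
    "write_labels",
]


class ParseError(ValueError):
    """Malformed file content; the message carries the line number."""


_TYPE_COMMENT = "; ".join(f"{s.value}={s.name.lower().replace('_', '-')}" for s in Species)


def write_data(path, system: MolecularSystem, frame: Frame) -> None:
    """Write a LAMMPS data file (atom_style full) for a system + frame."""
    pos = wrap_positions(frame.positions, frame.box_L)
    lines = [
        f"# dendrisurf data file; atom types: {_TYPE_COMMENT}",
        "",
        f"{system.n_beads} atoms",
        f"{len(system.bonds)} bonds",
        f"{len(Species)} atom types",
        "1 bond types",
        "",
        f"0.0 {frame.box_L:.10g} xlo xhi",
        f"0.0 {frame.box_L:.10g} ylo yhi",
        f"0.0 {frame.box_L:.10g} zlo zhi",
        "",
        "Masses",
        "",
    ]
    lines += [f"{s.value} 1.0" for s in Species]
    lines += ["", "Atoms # full", ""]
    for i in range(system.n_beads):
        x, y, z = pos[i]
        lines.append(
            f"{i + 1} {system.molecule_id[i] + 1} {int(system.species[i])} "
            f"{int(system.charge[i])} {x:.10g} {y:.10g} {z:.10g}"
        )
    if len(system.bonds):
        lines += ["", "Bonds", ""]
        for b, (i, j) in enumerate(system.bonds):
            lines.append(f"{b + 1} 1 {i + 1} {j + 1}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_data(path) -> tuple[MolecularSystem, Frame]:
    """Read a LAMMPS data file written in atom_style full.

    Reconstructs species, charges, bonds, molecule and dendrimer ids; the
    round trip through :func:`write_data` is lossless.
    """
    with open(path) as fh:
        raw = fh.readlines()
    n_atoms = n_bonds = None
    box = {}
    atoms: dict[int, tuple] = {}
    bonds = []
    section = None
    for ln, line in enumerate(raw, start=1):
        stripped = line.split("#")[0].strip()
        if not stripped:
            continue
        tokens = stripped.split()
        if stripped.endswith("atoms"):
            n_atoms = int(tokens[0])
            continue
        if stripped.endswith(" bonds"):
            n_bonds = int(tokens[0])
            continue
        if stripped.endswith("types"):
            continue
        if len(tokens) == 4 and tokens[2] in ("xlo", "ylo", "zlo"):
            box[tokens[2]] = (float(tokens[0]), float(tokens[1]))
            continue
        if tokens[0] in ("Masses", "Atoms", "Bonds", "Velocities", "Pair", "Bond"):
            section = tokens[0]
            continue
        if section == "Atoms":
            if len(tokens) < 7:
                raise ParseError(f"line {ln}: atom line needs 7 fields, got {len(tokens)}")
            try:
                aid = int(tokens[0])
                mol = int(tokens[1])
                typ = int(tokens[2])
                q = float(tokens[3])
                xyz = tuple(float(t) for t in tokens[4:7])
            except ValueError as exc:
                raise ParseError(f"line {ln}: {exc}") from exc
            if typ not in Species._value2member_map_:
                raise ParseError(f"line {ln}: unknown atom type {typ}")
            if q not in (-1.0, 0.0, 1.0):
                raise ParseError(f"line {ln}: charge must be -1, 0 or +1, got {q}")
            atoms[aid] = (mol, typ, int(q), xyz)
        elif section == "Bonds":
            if len(tokens) < 4:
                raise ParseError(f"line {ln}: bond line needs 4 fields")
            try:
                bonds.append((int(tokens[2]) - 1, int(tokens[3]) - 1))
            except ValueError as exc:
                raise ParseError(f"line {ln}: {exc}") from exc
    if n_atoms is None or len(atoms) != n_atoms:
        raise ParseError(f"expected {n_atoms} atoms, found {len(atoms)}")
    if n_bonds and len(bonds) != n_bonds:
        raise ParseError(
            f"expected {n_bonds} bonds, found {len(bonds)} (missing Bonds section?)"
        )
    if set(box) != {"xlo", "ylo", "zlo"}:
        raise ParseError("missing box bounds")
    spans = [hi - lo for lo, hi in box.values()]
    if max(spans) - min(spans) > 1e-9:
        raise ParseError("box must be cubic")
    L = box["xlo"][1] - box["xlo"][0]

    order = sorted(atoms)
    if order != list(range(1, n_atoms + 1)):
        raise ParseError("atom ids must be 1..N")
    species = np.array([atoms[i][1] for i in order], dtype=np.int8)
    charge = np.array([atoms[i][2] for i in order], dtype=np.int8)
    mol = np.array([atoms[i][0] - 1 for i in order], dtype=np.int64)
    pos = np.array([atoms[i][3] for i in order], dtype=np.float64)
    pos -= np.array([box["xlo"][0], box["ylo"][0], box["zlo"][0]])

    # reconstruct dendrimer ids from molecule grouping of dendrimer species
    dend_species = (
        (species == Species.DENDRIMER_CORE)
        | (species == Species.DENDRIMER_INTERIOR)
        | (species == Species.DENDRIMER_TERMINAL)
    )
    dendrimer_id = np.full(n_atoms, -1, dtype=np.int64)
    dend_mols = sorted(set(mol[dend_species].tolist()))
    for k, dm in enumerate(dend_mols):
        dendrimer_id[(mol == dm) & dend_species] = k
    n_d = len(dend_mols)
    n_s = int(np.sum(species == Species.SURFACTANT_HEAD))
    N_t = int(np.sum((species == Species.DENDRIMER_TERMINAL) & (dendrimer_id == 0)))
    N_d = int(np.sum(dendrimer_id == 0))
    system = MolecularSystem(
        species=species,
        charge=charge,
        bonds=np.array(bonds, dtype=np.int64).reshape(-1, 2),
        molecule_id=mol,
        dendrimer_id=dendrimer_id,
        n_d=n_d,
        n_s=n_s,
        N_t=N_t,
        N_d=N_d,
    )
    system.validate()
    return system, Frame(wrap_positions(pos, L), L, 0)


def write_dump(path, frames: list[Frame], system: MolecularSystem) -> None:
    """Write a LAMMPS text dump (id type x y z, periodic box bounds)."""
    with open(path, "w") as fh:
        for frame in frames:
            pos = wrap_positions(frame.positions, frame.box_L)
            fh.write("ITEM: TIMESTEP\n")
            fh.write(f"{frame.step}\n")
            fh.write("ITEM: NUMBER OF ATOMS\n")
            fh.write(f"{len(pos)}\n")
            fh.write("ITEM: BOX BOUNDS pp pp pp\n")
            for _ in range(3):
                fh.write(f"0.0 {frame.box_L:.10g}\n")
            fh.write("ITEM: ATOMS id type x y z\n")
            for i, (x, y, z) in enumerate(pos):
                fh.write(f"{i + 1} {int(system.species[i])} {x:.10g} {y:.10g} {z:.10g}\n")


def read_dump(path, system: MolecularSystem | None = None, stride: int = 1):
    """Iterate frames from a LAMMPS text dump.

    Yields every ``stride``-th frame starting from the first.  If a
    topology is given, atom count and per-id species are reconciled against
    it and a mismatch raises :class:`ParseError` naming the frame.
    Coordinates are wrapped into the primary cell on read.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    n_frame = 0
    while i < len(lines):
        if not lines[i].startswith("ITEM: TIMESTEP"):
            raise ParseError(f"line {i + 1}: expected ITEM: TIMESTEP")
        step = int(lines[i + 1])
        if not lines[i + 2].startswith("ITEM: NUMBER OF ATOMS"):
            raise ParseError(f"line {i + 3}: expected ITEM: NUMBER OF ATOMS")
        n = int(lines[i + 3])
        if not lines[i + 4].startswith("ITEM: BOX BOUNDS"):
            raise ParseError(f"line {i + 5}: expected ITEM: BOX BOUNDS")
        lo, hi = (float(t) for t in lines[i + 5].split()[:2])
        L = hi - lo
        header = lines[i + 8].split()
        if header[:2] != ["ITEM:", "ATOMS"]:
            raise ParseError(f"line {i + 9}: expected ITEM: ATOMS")
        cols = header[2:]
        try:
            c_id = cols.index("id")
            c_type = cols.index("type")
            c_xyz = [cols.index(a) for a in ("x", "y", "z")]
        except ValueError as exc:
            raise ParseError(f"line {i + 9}: dump needs id type x y z") from exc
        if system is not None and n != system.n_beads:
            raise ParseError(
                f"frame {n_frame} (step {step}): {n} atoms but topology has "
                f"{system.n_beads}"
            )
        pos = np.empty((n, 3))
        for k in range(n):
            tokens = lines[i + 9 + k].split()
            aid = int(tokens[c_id]) - 1
            typ = int(tokens[c_type])
            if system is not None and typ != int(system.species[aid]):
                raise ParseError(
                    f"frame {n_frame} (step {step}): atom id {aid + 1} has type "
                    f"{typ}, topology says {int(system.species[aid])}"
                )
            pos[aid] = [float(tokens[c]) - lo for c in c_xyz]
        if n_frame % stride == 0:
            yield Frame(wrap_positions(pos, L), L, step)
        n_frame += 1
        i += 9 + n


_AGG_HEADER = "frame\tindex\ts\td\tn_br\tn_cor\tn_dc\tn_sc\tch"


def write_aggregate_table(path, per_frame_aggregates) -> None:
    """Tab-separated aggregate table, one row per aggregate per frame."""
    with open(path, "w") as fh:
        fh.write(_AGG_HEADER + "\n")
        for f, aggregates in enumerate(per_frame_aggregates):
            for a in aggregates:
                fh.write(
                    f"{f}\t{a.index}\t{a.s}\t{a.d}\t{a.n_br}\t{a.n_cor}\t"
                    f"{a.n_dc}\t{a.n_sc}\t{a.ch}\n"
                )


def write_labels(path, truths) -> None:
    """Planted ground-truth sidecar: aggregate rows plus per-frame free-ion
    counts (rows with index == 'free')."""
    with open(path, "w") as fh:
        fh.write(_AGG_HEADER + "\n")
        for f, truth in enumerate(truths):
            for a in truth.aggregates:
                fh.write(
                    f"{f}\t{a.index}\t{a.s}\t{a.d}\t{a.n_br}\t{a.n_cor}\t"
                    f"{a.n_dc}\t{a.n_sc}\t{a.ch}\n"
                )
            fh.write(f"{f}\tfree\t{truth.n_free_dc}\t{truth.n_free_sc}\t\t\t\t\t\n")
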