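"""Interaction potentials in reduced units: LJ 12-6 truncated-shifted,
FENE bonds, and Coulomb pair interactions.

Three interactions act between beads:

* a truncated-and-shifted 12-6 Lennard-Jones potential.  Tail-tail pairs
  use strength ``eps_tt`` (the hydrophobicity dial) with cutoff 2.5 sigma;
  every other pair uses strength 1 with cutoff 2^(1/6) sigma, i.e. the
  purely repulsive WCA form that mimics good-solvent conditions;
* FENE springs (k* = 30, R0* = 1.5) along all bonds, the standard
  bead-spring parameterization.  Bonded pairs keep their LJ interaction;
* Coulomb ``lambda_B* z_i z_j / r`` between charged beads, in thermal
  units, truncated at ``rc_coul``.  With the length unit equal to the
  Bjerrum length, lambda_B* = 1.

Pair interactions are evaluated over Verlet neighbor lists built by an
O(N^2) minimum-image pass (at desk scale this outperforms cell lists); the
engine reuses lists across steps with a skin and rebuilds them when bead
displacements approach half the skin.  ``compute_forces`` is the one-shot
zero-skin path used by tests and analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from numba import njit

__all__ = [
    "ForceFieldParams",
    "lj_ts_energy",
    "fene_energy",
    "coulomb_energy",
    "compute_forces",
    "PairLists",
    "build_pair_lists",
    "evaluate",
    "BondOverstretchError",
]

RC_WCA = 2.0 ** (1.0 / 6.0)


class BondOverstretchError(RuntimeError):
    """A FENE bond reached its maximum extension R0."""


@dataclass(frozen=True)
class ForceFieldParams:
    """Force-field and integrator parameters, all in reduced units."""

    eps_tt: float = 1.0  # tail-tail LJ strength (hydrophobicity)
    eps_other: float = 1.0
    rc_lj_tt: float = 2.5
    rc_lj_other: float = RC_WCA
    k_fene: float = 30.0
    R0: float = 1.5
    lambda_B_star: float = 1.0
    rc_coul: float = 10.0
    coul_tolerance: float = 1e-4
    sigma: float = 1.0
    mass: float = 1.0
    T_star: float = 1.0
    gamma_star: float = 1.0
    dt_star: float = 0.005

    @classmethod
    def paper(cls, eps_tt: float = 1.5) -> "ForceFieldParams":
        """The published parameter set; only the tail-tail strength varies
        (1.25, 1.5 or 1.6)."""
        return cls(eps_tt=eps_tt)

    def with_(self, **kw) -> "ForceFieldParams":
        return replace(self, **kw)


def lj_ts_energy(r: float, eps: float, rc: float) -> float:
    """Truncated-and-shifted 12-6 LJ energy (sigma = 1), zero for r >= rc."""
    if r <= 0:
        raise ValueError("LJ potential diverges at r = 0")
    if r >= rc:
        return 0.0
    u = 4.0 * eps * (r**-12 - r**-6)
    u_rc = 4.0 * eps * (rc**-12 - rc**-6)
    return u - u_rc


def fene_energy(r: float, k: float = 30.0, R0: float = 1.5) -> float:
    """FENE bond energy -0.5 k R0^2 ln(1 - (r/R0)^2); diverges at r = R0."""
    if r < 0:
        raise ValueError("bond length must be non-negative")
    if r >= R0:
        raise BondOverstretchError(f"bond length {r} >= R0 = {R0}")
    return -0.5 * k * R0**2 * math.log(1.0 - (r / R0) ** 2)


def coulomb_energy(r: float, z_i: int, z_j: int, lambda_B_star: float = 1.0) -> float:
    """Coulomb pair energy lambda_B* z_i z_j / r, in units of k_B T."""
    if r <= 0:
        raise ValueError("Coulomb potential diverges at r = 0")
    return lambda_B_star * z_i * z_j / r


@njit(cache=True)
def _build_all_pairs(pos, L, cutoff):  # pragma: no cover - via build_pair_lists
    n = pos.shape[0]
    invL = 1.0 / L
    c2 = cutoff * cutoff
    count = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            dx -= L * round(dx * invL)
            dy -= L * round(dy * invL)
            dz -= L * round(dz * invL)
            if dx * dx + dy * dy + dz * dz < c2:
                count += 1
    out = np.empty((count, 2), np.int64)
    k = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            dx -= L * round(dx * invL)
            dy -= L * round(dy * invL)
            dz -= L * round(dz * invL)
            if dx * dx + dy * dy + dz * dz < c2:
                out[k, 0] = i
                out[k, 1] = j
                k += 1
    return out


@njit(cache=True)
def _build_subset_pairs(pos, L, idx, cutoff):  # pragma: no cover
    m = idx.shape[0]
    invL = 1.0 / L
    c2 = cutoff * cutoff
    count = 0
    for a in range(m - 1):
        i = idx[a]
        for b in range(a + 1, m):
            j = idx[b]
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            dx -= L * round(dx * invL)
            dy -= L * round(dy * invL)
            dz -= L * round(dz * invL)
            if dx * dx + dy * dy + dz * dz < c2:
                count += 1
    out = np.empty((count, 2), np.int64)
    k = 0
    for a in range(m - 1):
        i = idx[a]
        for b in range(a + 1, m):
            j = idx[b]
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            dx -= L * round(dx * invL)
            dy -= L * round(dy * invL)
            dz -= L * round(dz * invL)
            if dx * dx + dy * dy + dz * dz < c2:
                out[k, 0] = i
                out[k, 1] = j
                k += 1
    return out


@njit(cache=True)
def _eval_kernel(
    pos,
    L,
    is_tail,
    charge,
    lj_pairs,
    coul_pairs,
    eps_tt,
    eps_other,
    rc_tt,
    rc_other,
    bonds,
    k_fene,
    R0,
    lamB,
    rc_coul,
):  # pragma: no cover - exercised via evaluate()
    n = pos.shape[0]
    invL = 1.0 / L
    forces = np.zeros((n, 3))
    energy = 0.0
    status = 0

    rc_tt2 = rc_tt * rc_tt
    rc_other2 = rc_other * rc_other
    rc_coul2 = rc_coul * rc_coul
    sr6 = 1.0 / rc_tt**6
    shift_tt = 4.0 * eps_tt * (sr6 * sr6 - sr6)
    sr6 = 1.0 / rc_other**6
    shift_other = 4.0 * eps_other * (sr6 * sr6 - sr6)

    for p in range(lj_pairs.shape[0]):
        i = lj_pairs[p, 0]
        j = lj_pairs[p, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= L * round(dx * invL)
        dy -= L * round(dy * invL)
        dz -= L * round(dz * invL)
        r2 = dx * dx + dy * dy + dz * dz
        if is_tail[i] == 1 and is_tail[j] == 1:
            eps = eps_tt
            rc2 = rc_tt2
            shift = shift_tt
        else:
            eps = eps_other
            rc2 = rc_other2
            shift = shift_other
        if r2 < rc2:
            inv2 = 1.0 / r2
            inv6 = inv2 * inv2 * inv2
            energy += 4.0 * eps * (inv6 * inv6 - inv6) - shift
            fr = 24.0 * eps * inv6 * (2.0 * inv6 - 1.0) * inv2
            forces[i, 0] += fr * dx
            forces[i, 1] += fr * dy
            forces[i, 2] += fr * dz
            forces[j, 0] -= fr * dx
            forces[j, 1] -= fr * dy
            forces[j, 2] -= fr * dz

    for p in range(coul_pairs.shape[0]):
        i = coul_pairs[p, 0]
        j = coul_pairs[p, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= L * round(dx * invL)
        dy -= L * round(dy * invL)
        dz -= L * round(dz * invL)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < rc_coul2:
            qq = charge[i] * charge[j]
            r = math.sqrt(r2)
            energy += lamB * qq / r
            fr = lamB * qq / (r2 * r)
            forces[i, 0] += fr * dx
            forces[i, 1] += fr * dy
            forces[i, 2] += fr * dz
            forces[j, 0] -= fr * dx
            forces[j, 1] -= fr * dy
            forces[j, 2] -= fr * dz

    R02 = R0 * R0
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= L * round(dx * invL)
        dy -= L * round(dy * invL)
        dz -= L * round(dz * invL)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= R02:
            status = 1
            continue
        energy += -0.5 * k_fene * R02 * math.log(1.0 - r2 / R02)
        fr = -k_fene / (1.0 - r2 / R02)
        forces[i, 0] += fr * dx
        forces[i, 1] += fr * dy
        forces[i, 2] += fr * dz
        forces[j, 0] -= fr * dx
        forces[j, 1] -= fr * dy
        forces[j, 2] -= fr * dz

    return energy, forces, status


@dataclass
class PairLists:
    """Verlet neighbor lists with a skin, plus the build-time positions."""

    lj_pairs: np.ndarray
    coul_pairs: np.ndarray
    skin: float
    built_at: np.ndarray  # positions when the lists were built


def build_pair_lists(
    positions: np.ndarray,
    box_L: float,
    charge: np.ndarray,
    params: ForceFieldParams,
    skin: float = 0.0,
) -> PairLists:
    pos = np.ascontiguousarray(positions, dtype=np.float64)
    rc_lj = max(params.rc_lj_tt, params.rc_lj_other)
    lj = _build_all_pairs(pos, float(box_L), rc_lj + skin)
    charged = np.flatnonzero(np.asarray(charge) != 0).astype(np.int64)
    coul = _build_subset_pairs(pos, float(box_L), charged, params.rc_coul + skin)
    return PairLists(lj, coul, skin, pos.copy())


def evaluate(
    positions: np.ndarray,
    box_L: float,
    is_tail: np.ndarray,
    charge: np.ndarray,
    bonds: np.ndarray,
    params: ForceFieldParams,
    lists: PairLists,
) -> tuple[float, np.ndarray]:
    """Energy and forces over prebuilt pair lists (exact cutoffs applied)."""
    energy, forces, status = _eval_kernel(
        np.ascontiguousarray(positions, dtype=np.float64),
        float(box_L),
        np.ascontiguousarray(is_tail, dtype=np.uint8),
        np.ascontiguousarray(charge, dtype=np.float64),
        lists.lj_pairs,
        lists.coul_pairs,
        params.eps_tt,
        params.eps_other,
        params.rc_lj_tt,
        params.rc_lj_other,
        np.ascontiguousarray(bonds, dtype=np.int64).reshape(-1, 2),
        params.k_fene,
        params.R0,
        params.lambda_B_star,
        params.rc_coul,
    )
    if status != 0:
        raise BondOverstretchError(
            "a FENE bond reached R0; reduce dt_star or re-relax the configuration"
        )
    return float(energy), forces


def compute_forces(
    positions: np.ndarray,
    box_L: float,
    is_tail: np.ndarray,
    charge: np.ndarray,
    bonds: np.ndarray,
    params: ForceFieldParams,
) -> tuple[float, np.ndarray]:
    """One-shot total potential energy and per-bead forces (minimum image).

    Builds zero-skin pair lists for the given configuration; raises
    :class:`BondOverstretchError` if any FENE bond reaches R0.
    """
    lists = build_pair_lists(positions, box_L, charge, params, skin=0.0)
    return evaluate(positions, box_L, is_tail, charge, bonds, params, lists)
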