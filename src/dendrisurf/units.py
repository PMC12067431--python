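"""Reduced Lennard-Jones unit system anchored to aqueous electrostatics.

The model is nondimensionalized so that the energy unit is the thermal
energy at room temperature, ``epsilon_u = k_B * T_r``, and the length unit
is the Bjerrum length of the solvent, ``sigma_u = lambda_B(eps_r, T_r)``.
With this choice the reduced Bjerrum length is exactly 1 and the Coulomb
pair energy between valences ``z_i, z_j`` at reduced separation ``r*`` is
simply ``z_i * z_j / r*`` in units of ``k_B T``.

For water at room temperature (``eps_r = 81``, ``T_r = 298 K``) the length
unit is approximately 7 Angstrom, the reduced elementary charge is
``e* = sqrt(eps_r) = 9``, and with a bead mass of 30 g/mol the intrinsic
time unit is approximately 2.4 ps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy import constants as _const

__all__ = [
    "bjerrum_length",
    "reduced_elementary_charge",
    "UnitSystem",
]


def bjerrum_length(eps_r: float, T: float) -> float:
    """Bjerrum length ``e^2 / (4 pi eps_0 eps_r k_B T)`` in Angstrom.

    Parameters
    ----------
    eps_r : float
        Relative permittivity of the solvent (dimensionless, > 0).
    T : float
        Absolute temperature in kelvin (> 0).

    Returns
    -------
    float
        The distance at which two elementary charges in the solvent have a
        Coulomb energy of ``k_B T``, in Angstrom.
    """
    if eps_r <= 0 or T <= 0:
        raise ValueError(f"eps_r and T must be positive, got {eps_r=}, {T=}")
    lam_m = _const.e**2 / (4.0 * math.pi * _const.epsilon_0 * eps_r * _const.k * T)
    return lam_m * 1e10


def reduced_elementary_charge(eps_r: float) -> float:
    """Reduced elementary charge ``e* = sqrt(eps_r)``.

    With the length unit equal to the Bjerrum length, the reduced Coulomb
    energy ``e*^2 z_i z_j / (eps_r r*)`` must reduce to ``z_i z_j / r*``
    (thermal units), which fixes ``e* = sqrt(eps_r)``.  For water
    (``eps_r = 81``) this gives ``e* = 9``.
    """
    if eps_r <= 0:
        raise ValueError(f"eps_r must be positive, got {eps_r}")
    return math.sqrt(eps_r)


@dataclass(frozen=True)
class UnitSystem:
    """Mapping between reduced simulation units and SI units.

    Attributes
    ----------
    eps_r : relative permittivity of the implicit solvent.
    T_r : reference temperature in kelvin; sets ``epsilon_u = k_B T_r``.
    m_u_g_mol : real mass assigned to one bead, in g/mol.
    """

    eps_r: float = 81.0
    T_r: float = 298.0
    m_u_g_mol: float = 30.0

    lambda_B_angstrom: float = field(init=False)
    epsilon_u_joule: float = field(init=False)
    sigma_u_meter: float = field(init=False)
    m_u_kg: float = field(init=False)
    t_u_ps: float = field(init=False)
    e_star: float = field(init=False)

    def __post_init__(self) -> None:
        lam = bjerrum_length(self.eps_r, self.T_r)
        eps_u = _const.k * self.T_r
        sig = lam * 1e-10
        m_u = self.m_u_g_mol * 1e-3 / _const.N_A
        object.__setattr__(self, "lambda_B_angstrom", lam)
        object.__setattr__(self, "epsilon_u_joule", eps_u)
        object.__setattr__(self, "sigma_u_meter", sig)
        object.__setattr__(self, "m_u_kg", m_u)
        # LJ time unit t_u = sigma_u * sqrt(m_u / epsilon_u)
        object.__setattr__(self, "t_u_ps", sig * math.sqrt(m_u / eps_u) * 1e12)
        object.__setattr__(self, "e_star", reduced_elementary_charge(self.eps_r))
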