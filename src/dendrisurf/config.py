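"""Run configuration: one flat key-value record covering architecture,
force field, run lengths and analysis settings.

``RunConfig.paper(eps_tt=...)`` reproduces the published parameter set
exactly: two dendrimers, 600 surfactants, box L* = 70, k* = 30, R0* = 1.5,
tail-tail cutoff 2.5, WCA cutoff elsewhere, Coulomb cutoff 10 with force
tolerance 1e-4, gamma* = 1, dt* = 0.005, T* = 1, contact distance
r* = 1.5 and the more-than-ten-occurrences reliability filter.  Desk-scale
presets shrink the system for test runs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .forcefield import ForceFieldParams
from .topology import DendrimerSpec

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # architecture / composition
    G: int = 3
    S: int = 4
    n_d: int = 2
    n_s: int = 600
    L_star: float = 70.0
    # force field & integrator
    forcefield: ForceFieldParams = field(default_factory=ForceFieldParams)
    # run control
    seed: int = 1
    steps_equil: int = 1_000_000
    steps_prod: int = 10_000_000
    dump_stride: int = 10_000
    # analysis
    r_star: float = 1.5
    min_occurrence: int = 10

    @classmethod
    def paper(cls, G: int = 5, eps_tt: float = 1.5) -> "RunConfig":
        """Full-scale published parameter set (long-running)."""
        return cls(G=G, forcefield=ForceFieldParams.paper(eps_tt=eps_tt))

    @classmethod
    def desk(cls, eps_tt: float = 1.5, seed: int = 1) -> "RunConfig":
        """Reduced system for desk-scale runs: one G3S4 dendrimer, 60
        surfactant chains and matching counterions in an L* = 30 box."""
        return cls(
            G=3,
            n_d=1,
            n_s=60,
            L_star=30.0,
            forcefield=ForceFieldParams.paper(eps_tt=eps_tt),
            seed=seed,
            steps_equil=50_000,
            steps_prod=150_000,
            dump_stride=2_000,
        )

    @property
    def dendrimer_spec(self) -> DendrimerSpec:
        return DendrimerSpec(self.G, self.S)

    def to_flat_dict(self) -> dict:
        d = asdict(self)
        ff = d.pop("forcefield")
        d.update(ff)
        return d

    @classmethod
    def from_flat_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        ff_fields = ForceFieldParams.__dataclass_fields__
        ff = {k: d.pop(k) for k in list(d) if k in ff_fields}
        return cls(forcefield=ForceFieldParams(**ff), **d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_flat_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_flat_dict(yaml.safe_load(fh))
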