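"""pH-dependent stochastic net charge of messenger proteins.

A protein's isoelectric point (IEP) is the pH at which its net charge is
zero.  Below its IEP a protein has an increasing chance of protonating
(+1 e); above it, of deprotonating (-1 e).  The two-state speciation
probability is a linear ramp in |IEP - pH| with slope 1/2 per pH unit,
calibrated so a protein of IEP 6.7 at pH 6.5 has a 10% chance of being
protonated and 90% of staying neutral.  Each phosphate group carries one
or two negative elementary charges with equal probability.  Charges are
resampled every time step at the particle's current local pH.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .constants import PROTEIN_MASS

__all__ = [
    "ProteinSpecies",
    "ChargeState",
    "RAF",
    "MEK",
    "ERK",
    "KSR1",
    "protonation_probability",
    "sample_iep_charge",
    "sample_iep_charges",
    "sample_phosphate_charges",
    "phosphate_charge_totals",
    "complex_iep",
    "net_charge",
]

#: Slope of the speciation ramp: full ionisation 2 pH units away from the IEP.
RAMP_HALF_WIDTH = 2.0


@dataclass(frozen=True)
class ProteinSpecies:
    """A protein class: IEP, hydrodynamic size and phosphorylation capacity."""

    name: str
    iep: float
    stokes_radius_nm: float = 5.0
    n_phospho_sites: int = 2
    role: str = "generic"
    mass_kg: float = PROTEIN_MASS

    def __post_init__(self) -> None:
        if not 0.0 < self.iep < 14.0:
            raise ValueError("iep must lie strictly inside (0, 14)")
        if self.stokes_radius_nm <= 0:
            raise ValueError("stokes_radius_nm must be > 0")
        if self.n_phospho_sites < 0:
            raise ValueError("n_phospho_sites must be >= 0")
        if self.role not in ("RAF", "MEK", "ERK", "KSR1", "generic"):
            raise ValueError(f"unknown role {self.role!r}")


#: MAPK cascade species with their literature isoelectric points.
RAF = ProteinSpecies("RAF", iep=9.2, role="RAF")
MEK = ProteinSpecies("MEK", iep=6.1, role="MEK")
ERK = ProteinSpecies("ERK", iep=6.2, role="ERK")
KSR1 = ProteinSpecies("KSR1", iep=9.1, role="KSR1", n_phospho_sites=0)


@dataclass
class ChargeState:
    """One sampled charge configuration, in elementary charges."""

    iep_charge: int = 0
    phosphate_charges: list = field(default_factory=list)

    @property
    def net_charge(self) -> int:
        return self.iep_charge + sum(self.phosphate_charges)


def protonation_probability(iep: float, ph: float) -> float:
    """Probability of carrying the non-neutral charge state at ``ph``.

    For pH below the IEP this is P(+1 e); above, P(-1 e); exactly at the
    IEP the protein is always neutral.  Linear ramp clipped to [0, 1].
    """
    for v, nm in ((iep, "iep"), (ph, "ph")):
        if not 0.0 <= v <= 14.0:
            raise ValueError(f"{nm}={v} outside [0, 14]")
    return float(np.clip(abs(iep - ph) / RAMP_HALF_WIDTH, 0.0, 1.0))


def sample_iep_charge(
    species: ProteinSpecies, ph: float, rng: np.random.Generator
) -> int:
    """Draw the IEP-derived charge (+1, 0 or -1 e) at local ``ph``."""
    p = protonation_probability(species.iep, ph)
    if rng.uniform() >= p:
        return 0
    return 1 if ph < species.iep else -1


def sample_iep_charges(
    iep: np.ndarray, ph: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Vectorised :func:`sample_iep_charge` over particle arrays."""
    iep = np.asarray(iep, dtype=float)
    ph = np.asarray(ph, dtype=float)
    p = np.clip(np.abs(iep - ph) / RAMP_HALF_WIDTH, 0.0, 1.0)
    charged = rng.uniform(size=iep.shape) < p
    sign = np.where(ph < iep, 1, -1)
    return np.where(charged, sign, 0).astype(np.int64)


def sample_phosphate_charges(
    n_phosphates: int, rng: np.random.Generator
) -> list[int]:
    """Each phosphate carries -1 or -2 e with probability 1/2 each."""
    if n_phosphates < 0:
        raise ValueError("n_phosphates must be >= 0")
    if n_phosphates == 0:
        return []
    return list(-1 - rng.integers(0, 2, size=n_phosphates))


def phosphate_charge_totals(
    n_phosphates: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Vectorised total phosphate charge: -(n + Binomial(n, 1/2)) per particle."""
    n = np.asarray(n_phosphates, dtype=np.int64)
    extra = rng.binomial(np.maximum(n, 0), 0.5)
    return -(n + extra)


def complex_iep(components: Sequence[ProteinSpecies] | Iterable[float]) -> float:
    """Effective IEP of a bound complex: the mean of its components' IEPs.

    A KSR1(9.1)+MEK(6.1) complex takes IEP 7.6, which sits above the
    cytosolic pH range and moves the bound pair peripherally, away from
    the nucleus, relative to free MEK.
    """
    ieps = [c.iep if isinstance(c, ProteinSpecies) else float(c) for c in components]
    if not ieps:
        raise ValueError("complex_iep requires at least one component")
    return float(np.mean(ieps))


def net_charge(
    species: ProteinSpecies,
    n_phosphates: int,
    ph: float,
    rng: np.random.Generator,
) -> ChargeState:
    """Sample the total charge: IEP speciation plus phosphate charges."""
    if n_phosphates > species.n_phospho_sites:
        raise ValueError("n_phosphates exceeds the species' phospho sites")
    return ChargeState(
        iep_charge=sample_iep_charge(species, ph, rng),
        phosphate_charges=sample_phosphate_charges(n_phosphates, rng),
    )
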