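"""Readouts: RMS-displacement validation, arrival statistics, projection
fidelity (signal-to-noise of CM-to-NM spatial information), and radial
density profiles of the protein species.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import SimState
from .geometry import CellGeometry, radial_projection

__all__ = [
    "ArrivalSummary",
    "RadialProfile",
    "rms_displacement",
    "theoretical_rms",
    "arrival_statistics",
    "projection_fidelity",
    "uniform_cap_snr",
    "radial_density",
]


@dataclass
class ArrivalSummary:
    """First-passage statistics over particles absorbed at the NM.

    Unabsorbed particles are right-censored: counted in ``n_released``
    but excluded from the time statistics.
    """

    n_released: int
    n_absorbed: int
    arrival_times: np.ndarray
    arrival_points: np.ndarray
    mean_time: float = np.nan
    max_time: float = np.nan
    min_time: float = np.nan

    def __post_init__(self) -> None:
        if self.n_absorbed > self.n_released:
            raise ValueError("n_absorbed cannot exceed n_released")
        if len(self.arrival_times):
            self.mean_time = float(np.mean(self.arrival_times))
            self.max_time = float(np.max(self.arrival_times))
            self.min_time = float(np.min(self.arrival_times))

    @property
    def censored_fraction(self) -> float:
        if self.n_released == 0:
            return 0.0
        return 1.0 - self.n_absorbed / self.n_released

    def to_dict(self) -> dict:
        return {
            "n_released": self.n_released,
            "n_absorbed": self.n_absorbed,
            "censored_fraction": self.censored_fraction,
            "mean_time_s": None if np.isnan(self.mean_time) else self.mean_time,
            "max_time_s": None if np.isnan(self.max_time) else self.max_time,
            "min_time_s": None if np.isnan(self.min_time) else self.min_time,
        }


@dataclass
class RadialProfile:
    """Shell-volume-normalised radial histogram per (species, phospho state)."""

    bin_edges: np.ndarray
    counts: dict = field(default_factory=dict)
    density: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        lo, hi = self.bin_edges[:-1], self.bin_edges[1:]
        for (species, st), cnt in self.counts.items():
            dens = self.density[(species, st)]
            for i in range(len(cnt)):
                rows.append(
                    {
                        "bin_lo_um": lo[i],
                        "bin_hi_um": hi[i],
                        "species": species,
                        "state": st,
                        "count": int(cnt[i]),
                        "density": dens[i],
                    }
                )
        return pd.DataFrame(rows)


def rms_displacement(displacements: np.ndarray) -> np.ndarray:
    """RMS of displacement magnitudes, one value per row of checkpoints.

    ``displacements`` has shape (n_times, n_walkers) holding |x(t)-x(0)|.
    """
    d = np.asarray(displacements, dtype=float)
    return np.sqrt(np.mean(d * d, axis=-1))


def theoretical_rms(D: float, times: np.ndarray) -> np.ndarray:
    """Wiener-process law sqrt(6 D t) for unconfined 3-D diffusion."""
    return np.sqrt(6.0 * D * np.asarray(times, dtype=float))


def arrival_statistics(state: SimState, n_released: int | None = None) -> ArrivalSummary:
    """Summarise NM arrivals recorded in a simulation state."""
    done = np.isfinite(state.arrival_time)
    if n_released is None:
        n_released = state.n
    return ArrivalSummary(
        n_released=int(n_released),
        n_absorbed=int(done.sum()),
        arrival_times=state.arrival_time[done].copy(),
        arrival_points=state.arrival_point[done].copy(),
    )


def projection_fidelity(
    arrival_points_um: np.ndarray,
    geometry: CellGeometry,
    origin_point_um: np.ndarray,
    cap_angle_deg: float = 30.0,
) -> tuple[float, np.ndarray]:
    """Signal-to-noise of the CM-to-NM spatial projection.

    The expected landing site is the radial projection of the release
    point onto the NM.  The angular error of each arrival is the angle
    subtended at the cell centre; SNR is (# arrivals within the cap) /
    (# outside).  Returns ``inf`` when every arrival is inside the cap.
    """
    pts = np.atleast_2d(np.asarray(arrival_points_um, dtype=float))
    if len(pts) == 0:
        raise ValueError("projection fidelity requires at least one arrival")
    expected = radial_projection(geometry, origin_point_um) - geometry.center
    expected = expected / np.linalg.norm(expected)
    v = pts - geometry.center
    v = v / np.linalg.norm(v, axis=1, keepdims=True)
    cosang = np.clip(v @ expected, -1.0, 1.0)
    errors = np.rad2deg(np.arccos(cosang))
    n_in = int(np.sum(errors <= cap_angle_deg))
    n_out = len(errors) - n_in
    snr = float("inf") if n_out == 0 else n_in / n_out
    return snr, errors


def uniform_cap_snr(cap_angle_deg: float = 30.0) -> float:
    """Closed-form SNR for arrivals uniform over the sphere.

    The cap of half-angle theta covers a fraction f = (1 - cos theta)/2
    of the sphere, giving SNR = f / (1 - f).
    """
    f = 0.5 * (1.0 - np.cos(np.deg2rad(cap_angle_deg)))
    return f / (1.0 - f)


def radial_density(
    state: SimState, geometry: CellGeometry, n_bins: int = 20
) -> RadialProfile:
    """Radial histogram of free particles, split by species and phospho state.

    Density is count per shell volume (um^-3); counts sum exactly to the
    number of free particles.
    """
    edges = np.linspace(geometry.r_nucleus, geometry.r_outer, n_bins + 1)
    vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    profile = RadialProfile(bin_edges=edges)
    free = state.free
    r = state.radii_um(geometry)
    roles_or_names = np.array([s.name for s in state.species])[state.species_idx]
    phospho = np.where(state.n_phosphates > 0, "phospho", "unphospho")
    for species in np.unique(roles_or_names):
        for st in ("unphospho", "phospho"):
            sel = free & (roles_or_names == species) & (phospho == st)
            if not sel.any():
                continue
            cnt, _ = np.histogram(np.clip(r[sel], edges[0], edges[-1]), bins=edges)
            profile.counts[(species, st)] = cnt
            profile.density[(species, st)] = cnt / vol
    return profile
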