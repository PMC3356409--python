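"""Particle dynamics: Brownian motion, Coulomb forces, Stokes drag, boundaries.

Each messenger protein is a particle advanced at a fixed time step dt.
Per step, in order: (a) its charge is resampled from the local pH and
phosphorylation state, (b) the total Coulomb force is summed over the
nuclear point charge and every other free particle (full interaction),
(c) velocity is updated by Newton's second law and capped at the Stokes
terminal velocity v_t = |F|/b, (d) the position is advanced, (e) a
fixed-length Brownian step of length sqrt(6 D dt) in a uniformly random
direction is added, and (f) boundaries are applied: the cell membrane
reflects, the nuclear membrane absorbs (policy-dependent).

The speed cap makes the dynamics effectively overdamped: at the forces
reached here the Newtonian velocity exceeds v_t by ~10 orders of
magnitude, so capped-Newtonian and plain overdamped (v = F/b) modes give
statistically indistinguishable transport.

The particle state is stored as a structure of arrays (:class:`SimState`)
so a step is a handful of vectorised numpy operations regardless of
particle count; :class:`Particle` provides a per-particle record view.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .charge_model import (
    ChargeState,
    ProteinSpecies,
    phosphate_charge_totals,
    sample_iep_charges,
)
from .constants import (
    DT,
    E_CHARGE,
    EPSILON_R,
    ETA_CYTOPLASM,
    K_BOLTZMANN,
    K_COULOMB,
    TEMPERATURE,
    UM,
)
from .geometry import CellGeometry, NuclearField, PHField, apply_boundaries_arrays, ph_at_radius

__all__ = [
    "DynamicsParams",
    "Particle",
    "SimState",
    "einstein_stokes_D",
    "drag_constant",
    "terminal_velocity",
    "brownian_step",
    "pair_coulomb_force",
    "total_force",
    "velocity_update",
    "integrate_step",
    "drift_transit_time",
    "random_unit_vectors",
    "random_positions_in_shell",
    "random_positions_on_cap",
    "sample_diffusion_first_passage",
    "simulate_free_walkers",
    "simulate_confined_walkers",
]


def drag_constant(eta: float, stokes_radius: float) -> float:
    """Stokes drag b = 6 pi eta r (kg/s) for a low-Reynolds-number sphere."""
    if eta <= 0 or stokes_radius <= 0:
        raise ValueError("eta and stokes_radius must be > 0")
    return 6.0 * np.pi * eta * stokes_radius


@dataclass(frozen=True)
class DynamicsParams:
    """Integration and medium parameters (SI units)."""

    dt: float = DT
    eta: float = ETA_CYTOPLASM
    temperature: float = TEMPERATURE
    k_coulomb: float = K_COULOMB
    epsilon_r: float = EPSILON_R
    #: "capped_newtonian" integrates Newton's law then caps at v_t;
    #: "overdamped" sets v = F/b directly.
    mode: str = "capped_newtonian"

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.eta <= 0:
            raise ValueError("eta must be > 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.mode not in ("capped_newtonian", "overdamped"):
            raise ValueError(f"unknown mode {self.mode!r}")

    def drag_b(self, stokes_radius: float) -> float:
        return drag_constant(self.eta, stokes_radius)


def einstein_stokes_D(params: DynamicsParams, stokes_radius: float) -> float:
    """Einstein-Stokes diffusion coefficient D = k_B T / (6 pi eta r)."""
    if stokes_radius <= 0:
        raise ValueError("stokes_radius must be > 0")
    return K_BOLTZMANN * params.temperature / params.drag_b(stokes_radius)


def terminal_velocity(force_mag: float, b: float) -> float:
    """Speed at which the Coulomb force balances Stokes drag: v_t = |F| / b."""
    if b <= 0:
        raise ValueError("drag constant must be > 0")
    return force_mag / b


def random_unit_vectors(n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniformly distributed directions on the unit sphere, shape (n, 3)."""
    v = rng.standard_normal((n, 3))
    norm = np.linalg.norm(v, axis=1, keepdims=True)
    # A zero draw has probability 0; guard anyway.
    small = norm[:, 0] < 1e-300
    if small.any():
        v[small] = (1.0, 0.0, 0.0)
        norm[small] = 1.0
    return v / norm


def brownian_step(
    position: np.ndarray, D: float, dt: float, rng: np.random.Generator
) -> np.ndarray:
    """Fixed-length Brownian step: length sqrt(6 D dt), random direction."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if D < 0:
        raise ValueError("D must be >= 0")
    if D == 0.0:
        return np.asarray(position, dtype=float).copy()
    step = np.sqrt(6.0 * D * dt) * random_unit_vectors(1, rng)[0]
    return np.asarray(position, dtype=float) + step


def pair_coulomb_force(
    q1: float,
    q2: float,
    pos1: np.ndarray,
    pos2: np.ndarray,
    params: DynamicsParams,
    min_separation: float = 0.0,
) -> np.ndarray:
    """Coulomb force on particle 1 from particle 2 (N); charges in e.

    F = k q1 q2 / (eps_r r^2) along the unit vector from 2 to 1, so a
    positive product is repulsive.  ``min_separation`` clamps r to soften
    near-coincident pairs.
    """
    d = np.asarray(pos1, dtype=float) - np.asarray(pos2, dtype=float)
    r = np.linalg.norm(d)
    if r == 0.0 and min_separation <= 0.0:
        raise ValueError("coincident particles require a min_separation clamp")
    r_eff = max(r, min_separation)
    mag = params.k_coulomb * (q1 * E_CHARGE) * (q2 * E_CHARGE) / (
        params.epsilon_r * r_eff * r_eff
    )
    unit = d / r if r > 0 else np.array([1.0, 0.0, 0.0])
    return mag * unit


# ---------------------------------------------------------------------------
# Particle records and the array-backed simulation state
# ---------------------------------------------------------------------------


@dataclass
class Particle:
    """Per-particle record (positions and velocities in SI metres)."""

    id: int
    species: ProteinSpecies
    position: np.ndarray
    velocity: np.ndarray
    charge_state: ChargeState
    n_phosphates: int = 0
    phospho_clock: float = 0.0
    bound_to: Optional[int] = None
    absorbed: bool = False
    arrival_time: Optional[float] = None
    arrival_point: Optional[np.ndarray] = None


class SimState:
    """Structure-of-arrays state for all particles in a run.

    Positions/velocities are SI (m, m/s); charges in elementary charges.
    ``eff_iep`` and ``eff_n_phosphates`` are the values used for charge
    sampling — they differ from the species values only for scaffold
    complexes, whose members pool their IEPs and phosphates.
    """

    NM_POLICIES = ("absorb_all", "absorb_phosphorylated", "reflect_all")

    def __init__(
        self,
        species: Sequence[ProteinSpecies],
        species_idx: np.ndarray,
        positions_m: np.ndarray,
        nm_policy: str = "absorb_all",
    ):
        if nm_policy not in self.NM_POLICIES:
            raise ValueError(f"unknown nm_policy {nm_policy!r}")
        self.species = list(species)
        self.species_idx = np.asarray(species_idx, dtype=np.int64)
        n = len(self.species_idx)
        self.pos = np.array(positions_m, dtype=float).reshape(n, 3)
        self.vel = np.zeros((n, 3))
        self.nm_policy = nm_policy

        iep = np.array([s.iep for s in self.species])
        rad = np.array([s.stokes_radius_nm for s in self.species]) * 1e-9
        mass = np.array([s.mass_kg for s in self.species])
        self.iep = iep[self.species_idx]
        self.radius_m = rad[self.species_idx]
        self.mass = mass[self.species_idx]

        self.eff_iep = self.iep.copy()
        self.n_phosphates = np.zeros(n, dtype=np.int64)
        self.eff_n_phosphates = np.zeros(n, dtype=np.int64)
        self.phospho_clock = np.zeros(n)
        self.charge = np.zeros(n, dtype=np.int64)
        #: Override for calibration scenarios: NaN means "sample from pH".
        self.fixed_charge = np.full(n, np.nan)
        self.bound_to = np.full(n, -1, dtype=np.int64)
        self.pinned = np.zeros(n, dtype=bool)
        self.arrival_time = np.full(n, np.nan)
        self.arrival_point = np.full((n, 3), np.nan)
        #: scaffold book-keeping (pathway module)
        self.mek_slot = np.full(n, -1, dtype=np.int64)
        self.erk_slot = np.full(n, -1, dtype=np.int64)
        self.perk_blocked = np.zeros(n, dtype=bool)
        self.t = 0.0
        self.n_phospho_events = 0
        #: per-role phosphorylation event tally (audit ledger)
        self.phospho_counters: dict[str, int] = {}
        self._roles = np.array([s.role for s in self.species])[self.species_idx]

    # -- derived -----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.species_idx)

    @property
    def n(self) -> int:
        return len(self.species_idx)

    def drag_b(self, params: DynamicsParams) -> np.ndarray:
        return 6.0 * np.pi * params.eta * self.radius_m

    def diffusion_D(self, params: DynamicsParams) -> np.ndarray:
        return K_BOLTZMANN * params.temperature / self.drag_b(params)

    @property
    def free(self) -> np.ndarray:
        """Particles that move and exert forces: not pinned, not slaved."""
        return ~self.pinned & (self.bound_to < 0)

    def roles(self) -> np.ndarray:
        return self._roles

    def radii_um(self, geometry: CellGeometry) -> np.ndarray:
        """Centre distance of every particle (um)."""
        return np.linalg.norm(self.pos / UM - geometry.center, axis=1)

    def particle(self, i: int) -> Particle:
        """Materialise particle ``i`` as a record (copy, not a view)."""
        cs = ChargeState(iep_charge=int(self.charge[i]), phosphate_charges=[])
        return Particle(
            id=i,
            species=self.species[self.species_idx[i]],
            position=self.pos[i].copy(),
            velocity=self.vel[i].copy(),
            charge_state=cs,
            n_phosphates=int(self.n_phosphates[i]),
            phospho_clock=float(self.phospho_clock[i]),
            bound_to=int(self.bound_to[i]) if self.bound_to[i] >= 0 else None,
            absorbed=bool(self.pinned[i]),
            arrival_time=float(self.arrival_time[i])
            if np.isfinite(self.arrival_time[i])
            else None,
            arrival_point=self.arrival_point[i].copy()
            if np.isfinite(self.arrival_point[i]).all()
            else None,
        )

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_counts(
        cls,
        species_counts: Sequence[tuple[ProteinSpecies, int]],
        geometry: CellGeometry,
        rng: np.random.Generator,
        nm_policy: str = "absorb_all",
    ) -> "SimState":
        """Particles placed uniformly in the cytoplasm, grouped by species."""
        species = [s for s, _ in species_counts]
        idx = np.concatenate(
            [np.full(c, i, dtype=np.int64) for i, (_, c) in enumerate(species_counts)]
        ) if species_counts else np.zeros(0, dtype=np.int64)
        pos_um = random_positions_in_shell(geometry, len(idx), rng)
        return cls(species, idx, pos_um * UM, nm_policy=nm_policy)


def random_positions_in_shell(
    geometry: CellGeometry, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform random positions in the cytoplasm (um), rejection-sampled."""
    out = np.empty((n, 3))
    half = geometry.r_outer
    got = 0
    while got < n:
        cand = rng.uniform(-half, half, size=(max(2 * (n - got), 16), 3))
        r = np.linalg.norm(cand, axis=1)
        ok = r >= geometry.r_nucleus
        if geometry.shape == "sphere":
            ok &= r <= geometry.r_cell
        cand = cand[ok]
        take = min(len(cand), n - got)
        out[got : got + take] = cand[:take]
        got += take
    return out + geometry.center


def random_positions_on_cap(
    geometry: CellGeometry,
    direction: np.ndarray,
    half_angle_deg: float,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Random points (um) on the CM within a spherical cap around ``direction``."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    cos_max = np.cos(np.deg2rad(half_angle_deg))
    # Uniform over the cap: cos(theta) uniform in [cos_max, 1].
    c = rng.uniform(cos_max, 1.0, size=n)
    s = np.sqrt(1.0 - c * c)
    phi = rng.uniform(0.0, 2.0 * np.pi, size=n)
    # Orthonormal frame around d.
    a = np.array([1.0, 0.0, 0.0])
    if abs(d @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    pts = (
        c[:, None] * d
        + (s * np.cos(phi))[:, None] * e1
        + (s * np.sin(phi))[:, None] * e2
    )
    if geometry.shape == "sphere":
        r = geometry.r_cell
    else:
        # Scale each direction to the cube surface.
        half = geometry.cube_side / 2.0
        scale = half / np.max(np.abs(pts), axis=1)
        return geometry.center + pts * scale[:, None]
    return geometry.center + r * pts


# ---------------------------------------------------------------------------
# Forces and integration
# ---------------------------------------------------------------------------


def _nuclear_forces(
    pos_m: np.ndarray,
    charge_e: np.ndarray,
    nucleus: NuclearField,
    center_m: np.ndarray,
    params: DynamicsParams,
) -> np.ndarray:
    d = pos_m - center_m
    r2 = np.einsum("ij,ij->i", d, d)
    r = np.sqrt(r2)
    mag = (
        params.k_coulomb
        * nucleus.q_nucleus
        * (charge_e * E_CHARGE)
        / (params.epsilon_r * np.maximum(r2, 1e-30))
    )
    return (mag / np.maximum(r, 1e-15))[:, None] * d


def _pairwise_forces(
    pos_m: np.ndarray,
    charge_e: np.ndarray,
    radius_m: np.ndarray,
    params: DynamicsParams,
) -> np.ndarray:
    """Full-interaction O(n^2) Coulomb sum among the given particles."""
    n = len(charge_e)
    out = np.zeros((n, 3))
    charged = np.flatnonzero(charge_e != 0)
    if len(charged) < 2:
        return out
    p = pos_m[charged]
    q = charge_e[charged].astype(float)
    rad = radius_m[charged]
    # Squared separations via the Gram matrix (BLAS) instead of an
    # (n, n, 3) difference tensor.
    sq = np.einsum("ij,ij->i", p, p)
    r2 = sq[:, None] + sq[None, :] - 2.0 * (p @ p.T)
    np.maximum(r2, 0.0, out=r2)
    r = np.sqrt(r2)
    # Softening: clamp the separation at the sum of Stokes radii.
    rmin = rad[:, None] + rad[None, :]
    r_eff = np.maximum(r, rmin)
    # c_ij = k q_i q_j e^2 / (eps_r r_eff^2 r): F_i = sum_j c_ij (p_i - p_j).
    c = (params.k_coulomb * E_CHARGE * E_CHARGE / params.epsilon_r) * (
        q[:, None] * q[None, :]
    ) / (r_eff * r_eff * np.maximum(r, rmin * 0.5))
    np.fill_diagonal(c, 0.0)
    out[charged] = p * c.sum(axis=1)[:, None] - c @ p
    return out


def total_force(
    particle: Particle,
    all_particles: Sequence[Particle],
    nucleus: NuclearField,
    geometry: CellGeometry,
    params: DynamicsParams,
) -> np.ndarray:
    """Total Coulomb force (N) on one particle: nucleus plus every free peer."""
    if particle.absorbed:
        raise ValueError("absorbed particles exert and feel no forces")
    center_m = np.asarray(geometry.center, dtype=float) * UM
    q = particle.charge_state.net_charge
    f = _nuclear_forces(
        particle.position[None, :], np.array([q]), nucleus, center_m, params
    )[0]
    r_self = particle.species.stokes_radius_nm * 1e-9
    for other in all_particles:
        if other.id == particle.id or other.absorbed:
            continue
        qo = other.charge_state.net_charge
        if qo == 0 or q == 0:
            continue
        r_other = other.species.stokes_radius_nm * 1e-9
        f = f + pair_coulomb_force(
            q, qo, particle.position, other.position, params,
            min_separation=r_self + r_other,
        )
    return f


def _velocity_update_arrays(
    vel: np.ndarray,
    force: np.ndarray,
    mass: np.ndarray,
    b: np.ndarray,
    params: DynamicsParams,
) -> np.ndarray:
    fmag = np.linalg.norm(force, axis=1)
    vt = fmag / b
    if params.mode == "overdamped":
        return force / b[:, None]
    v_new = vel + force / mass[:, None] * params.dt
    speed = np.linalg.norm(v_new, axis=1)
    over = speed > vt
    scale = np.ones_like(speed)
    nz = over & (speed > 0)
    scale[nz] = vt[nz] / speed[nz]
    scale[over & (speed == 0)] = 0.0
    # Zero-force particles have vt = 0: they stop rather than coast.
    return v_new * scale[:, None]


def velocity_update(
    particle: Particle, force: np.ndarray, params: DynamicsParams
) -> np.ndarray:
    """Newton's-law velocity update capped at the terminal velocity."""
    if particle.species.mass_kg <= 0:
        raise ValueError("particle mass must be > 0")
    b = params.drag_b(particle.species.stokes_radius_nm * 1e-9)
    return _velocity_update_arrays(
        particle.velocity[None, :],
        np.asarray(force, dtype=float)[None, :],
        np.array([particle.species.mass_kg]),
        np.array([b]),
        params,
    )[0]


def _resample_charges(state: SimState, geometry, ph_field, rng) -> None:
    act = np.flatnonzero(state.free)
    if len(act) == 0:
        return
    r_um = np.linalg.norm(state.pos[act] / UM - geometry.center, axis=1)
    ph = ph_at_radius(geometry, ph_field, r_um)
    iepq = sample_iep_charges(state.eff_iep[act], ph, rng)
    phosq = phosphate_charge_totals(state.eff_n_phosphates[act], rng)
    q = iepq + phosq
    fixed = np.isfinite(state.fixed_charge[act])
    if fixed.any():
        q = np.where(
            fixed, np.nan_to_num(state.fixed_charge[act]).astype(np.int64), q
        )
    state.charge[act] = q
    # Pinned/slaved particles exert no forces.
    state.charge[~state.free] = 0


def integrate_step(
    state: SimState,
    geometry: CellGeometry,
    ph_field: PHField,
    nucleus: NuclearField,
    params: DynamicsParams,
    rng: np.random.Generator,
) -> SimState:
    """Advance every free particle by one time step dt (in place)."""
    act = np.flatnonzero(state.free)
    state.phospho_clock[state.n_phosphates > 0] += params.dt
    state.t += params.dt
    if len(act) == 0:
        return state

    _resample_charges(state, geometry, ph_field, rng)

    center_m = np.asarray(geometry.center, dtype=float) * UM
    pos = state.pos[act]
    force = _nuclear_forces(pos, state.charge[act].astype(float), nucleus, center_m, params)
    force += _pairwise_forces(
        pos, state.charge[act].astype(float), state.radius_m[act], params
    )

    b = state.drag_b(params)[act]
    state.vel[act] = _velocity_update_arrays(
        state.vel[act], force, state.mass[act], b, params
    )
    new = pos + state.vel[act] * params.dt

    D = state.diffusion_D(params)[act]
    step_len = np.sqrt(6.0 * D * params.dt)
    new = new + step_len[:, None] * random_unit_vectors(len(act), rng)

    if state.nm_policy == "absorb_all":
        may_absorb = np.ones(len(act), dtype=bool)
    elif state.nm_policy == "absorb_phosphorylated":
        may_absorb = state.eff_n_phosphates[act] > 0
    else:
        may_absorb = np.zeros(len(act), dtype=bool)

    pos_um, absorbed, hit_um = apply_boundaries_arrays(
        geometry, pos / UM, new / UM, absorb=may_absorb
    )
    state.pos[act] = pos_um * UM
    if absorbed.any():
        ids = act[absorbed]
        state.pinned[ids] = True
        state.vel[ids] = 0.0
        state.arrival_time[ids] = state.t
        state.arrival_point[ids] = hit_um[absorbed] * UM
        state.charge[ids] = 0

    # Slaved scaffold members ride on their scaffold.
    slaved = np.flatnonzero(state.bound_to >= 0)
    if len(slaved):
        state.pos[slaved] = state.pos[state.bound_to[slaved]]
    return state


def drift_transit_time(
    r_start: float,
    r_end: float,
    q: float,
    nucleus: NuclearField,
    b: float,
    params: DynamicsParams | None = None,
) -> float:
    """Closed-form Brownian-free radial transit time under the nuclear field.

    With terminal-velocity (overdamped) radial motion dr/dt = -sign A / r^2,
    A = k Q_N |q| e / (eps_r b), the transit from r_start to r_end takes
    t = |r_start^3 - r_end^3| / (3 A).  Inward transits require attraction
    (q < 0 with a positive nucleus); outward transits require repulsion.
    """
    if params is None:
        params = DynamicsParams()
    if r_start <= 0 or r_end <= 0:
        raise ValueError("radii must be > 0")
    if r_start == r_end:
        return 0.0
    inward = r_start > r_end
    if inward and q >= 0:
        raise ValueError("inward transit requires an attractive (negative) charge")
    if not inward and q <= 0:
        raise ValueError("outward transit requires a repulsive (positive) charge")
    if b <= 0:
        raise ValueError("drag constant must be > 0")
    A = params.k_coulomb * nucleus.q_nucleus * abs(q) * E_CHARGE / (params.epsilon_r * b)
    return abs(r_start**3 - r_end**3) / (3.0 * A)


# ---------------------------------------------------------------------------
# Fast special-purpose kernels (diffusion-only walkers)
# ---------------------------------------------------------------------------


def sample_diffusion_first_passage(
    geometry: CellGeometry,
    D: float,
    dt: float,
    n_walkers: int,
    rng: np.random.Generator,
    t_max: float = 300.0,
    start_r: float | None = None,
    start_positions_um: np.ndarray | None = None,
) -> tuple[np.ndarray, int, np.ndarray]:
    """First-passage times of pure-diffusion walkers to the absorbing NM.

    Walkers start at radius ``start_r`` (default: on the CM; or at the
    explicit ``start_positions_um``), reflect off the CM and are absorbed
    at the NM.  Returns ``(arrival_times, n_censored, arrival_points_um)``;
    censored walkers have not arrived by ``t_max``.

    The reflecting wall uses a radial fold, which agrees with specular
    reflection to first order at the ~10 nm step lengths used here.
    """
    if geometry.shape != "sphere":
        raise ValueError("first-passage sampler requires sphere geometry")
    a, R = geometry.r_nucleus, geometry.r_cell
    ell = np.sqrt(6.0 * D * dt) / UM  # step length in um
    n_steps = int(np.ceil(t_max / dt))
    if start_positions_um is not None:
        pos = np.array(start_positions_um, dtype=float).reshape(n_walkers, 3)
        pos = pos - geometry.center
    else:
        pos = (R if start_r is None else start_r) * random_unit_vectors(n_walkers, rng)
    alive = np.arange(n_walkers)
    times = np.full(n_walkers, np.nan)
    points = np.full((n_walkers, 3), np.nan)
    for k in range(1, n_steps + 1):
        m = len(alive)
        if m == 0:
            break
        pos += ell * random_unit_vectors(m, rng)
        r = np.linalg.norm(pos, axis=1)
        out = r > R
        if out.any():
            pos[out] *= ((2.0 * R - r[out]) / r[out])[:, None]
        hit = r <= a
        if hit.any():
            ids = alive[hit]
            times[ids] = k * dt
            ph = pos[hit]
            points[ids] = (
                ph / np.linalg.norm(ph, axis=1, keepdims=True) * a + geometry.center
            )
            keep = ~hit
            pos = pos[keep]
            alive = alive[keep]
    done = np.isfinite(times)
    return times[done], int(len(alive)), points[done]


def simulate_free_walkers(
    n_walkers: int,
    D: float,
    dt: float,
    record_times: Sequence[float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Unconfined fixed-step walkers; displacement magnitudes at checkpoints.

    Returns an array of shape (len(record_times), n_walkers) of |x(t)-x(0)|
    in metres.
    """
    ell = np.sqrt(6.0 * D * dt)
    record_steps = np.rint(np.asarray(record_times, dtype=float) / dt).astype(int)
    pos = np.zeros((n_walkers, 3))
    out = np.empty((len(record_steps), n_walkers))
    order = np.argsort(record_steps)
    k = 0
    for j in order:
        target = record_steps[j]
        while k < target:
            pos += ell * random_unit_vectors(n_walkers, rng)
            k += 1
        out[j] = np.linalg.norm(pos, axis=1)
    return out


def simulate_confined_walkers(
    n_walkers: int,
    D: float,
    dt: float,
    record_times: Sequence[float],
    rng: np.random.Generator,
    r_confine_um: float,
) -> np.ndarray:
    """Walkers confined inside a reflecting sphere of radius ``r_confine_um``.

    Starts at the centre; returns |x(t)-x(0)| in metres at the checkpoints,
    shape (len(record_times), n_walkers).
    """
    R = r_confine_um
    ell = np.sqrt(6.0 * D * dt) / UM
    record_steps = np.rint(np.asarray(record_times, dtype=float) / dt).astype(int)
    pos = np.zeros((n_walkers, 3))
    out = np.empty((len(record_steps), n_walkers))
    order = np.argsort(record_steps)
    k = 0
    for j in order:
        target = record_steps[j]
        while k < target:
            pos += ell * random_unit_vectors(n_walkers, rng)
            r = np.linalg.norm(pos, axis=1)
            bad = r > R
            if bad.any():
                pos[bad] *= ((2.0 * R - r[bad]) / r[bad])[:, None]
            k += 1
        out[j] = np.linalg.norm(pos, axis=1) * UM
    return out
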