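"""MAPK reaction layer on top of the particle dynamics.

Rules implemented per time step:

* membrane phosphorylation — ligand binding at a cell-membrane patch
  activates RAF (RAF near the patch becomes pRAF while the ligand window
  is open; in steady mode the window never closes);
* contact phospho-transfer — pRAF + MEK -> pMEK, pMEK + ERK -> pERK
  whenever the pair is within the reaction radius (cascade order is
  strict; a single pRAF acts catalytically and can phosphorylate many
  MEK, which is the amplification step);
* phosphatase timers — every phosphorylated particle loses all its
  phosphates 30 s after phosphorylation, reverts to its IEP-only charge,
  and, if it was pinned at the nuclear membrane, is released;
* KSR1 scaffolding — free MEK (and ERK) bind a KSR1 scaffold on contact;
  the complex moves as one unit with the mean IEP of its members and
  their pooled phosphates; the cascade fires on the scaffold; newly
  formed pERK unbinds, and free pERK may rebind a separate KSR1 site,
  blocking further pRAF interaction with that scaffold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .charge_model import complex_iep
from .constants import UM
from .dynamics import SimState
from .geometry import CellGeometry

__all__ = [
    "ReactionRules",
    "ScaffoldState",
    "membrane_phosphorylation",
    "contact_reactions",
    "dephosphorylation_timer",
    "ksr1_binding",
    "refresh_effective",
    "scaffold_states",
]


@dataclass(frozen=True)
class ReactionRules:
    """Kinetic-free reaction parameters.

    Reactions fire deterministically on first approach within
    ``reaction_radius_um``; with ~10-20 nm steps this approximates
    diffusion-limited contact without missed crossings.
    """

    reaction_radius_um: float = 0.1
    phosphatase_delay_s: float = 30.0
    ligand_window_s: float = 30.0
    ligand_direction: tuple = (0.0, 0.0, 1.0)
    cap_half_angle_deg: float = 15.0
    ksr1_enabled: bool = False
    #: phosphates added to RAF on membrane activation (net ~ -2 e with the
    #: IEP contribution at cytosolic pH)
    raf_phosphates: int = 2

    def __post_init__(self) -> None:
        if self.reaction_radius_um <= 0:
            raise ValueError("reaction_radius_um must be > 0")
        if self.phosphatase_delay_s < 0 or self.ligand_window_s < 0:
            raise ValueError("delays must be >= 0")


@dataclass
class ScaffoldState:
    """Read-only snapshot of one KSR1 scaffold's occupancy."""

    ksr1_id: int
    mek_slot: int | None = None
    erk_slot: int | None = None
    perk_blocked: bool = False
    members: list = field(default_factory=list)


def scaffold_states(state: SimState) -> list[ScaffoldState]:
    out = []
    for i in np.flatnonzero(state.roles() == "KSR1"):
        mek = int(state.mek_slot[i])
        erk = int(state.erk_slot[i])
        members = [m for m in (mek, erk) if m >= 0]
        out.append(
            ScaffoldState(
                ksr1_id=int(i),
                mek_slot=mek if mek >= 0 else None,
                erk_slot=erk if erk >= 0 else None,
                perk_blocked=bool(state.perk_blocked[i]),
                members=members,
            )
        )
    return out


def refresh_effective(state: SimState) -> None:
    """Recompute complex IEPs and pooled phosphate counts after any event."""
    state.eff_iep[:] = state.iep
    state.eff_n_phosphates[:] = state.n_phosphates
    for i in np.flatnonzero((state.mek_slot >= 0) | (state.erk_slot >= 0)):
        members = [int(i)]
        for slot in (state.mek_slot[i], state.erk_slot[i]):
            if slot >= 0:
                members.append(int(slot))
        state.eff_iep[i] = complex_iep([state.iep[m] for m in members])
        state.eff_n_phosphates[i] = sum(int(state.n_phosphates[m]) for m in members)


def _phosphorylate(state: SimState, ids: np.ndarray, n: int, role_key: str) -> None:
    if len(ids) == 0:
        return
    state.n_phosphates[ids] = n
    state.phospho_clock[ids] = 0.0
    state.n_phospho_events += len(ids)
    state.phospho_counters[role_key] = state.phospho_counters.get(role_key, 0) + len(ids)


def _in_ligand_patch(
    state: SimState, geometry: CellGeometry, rules: ReactionRules, ids: np.ndarray
) -> np.ndarray:
    """Boolean mask over ``ids``: within the CM ligand cap and near the CM."""
    if len(ids) == 0:
        return np.zeros(0, dtype=bool)
    p = state.pos[ids] / UM - geometry.center
    r = np.linalg.norm(p, axis=1)
    d = np.asarray(rules.ligand_direction, dtype=float)
    d = d / np.linalg.norm(d)
    with np.errstate(invalid="ignore"):
        cosang = (p @ d) / np.maximum(r, 1e-12)
    in_cap = cosang >= np.cos(np.deg2rad(rules.cap_half_angle_deg))
    near_cm = r >= geometry.r_outer - rules.reaction_radius_um
    return in_cap & near_cm


def membrane_phosphorylation(
    state: SimState,
    rules: ReactionRules,
    geometry: CellGeometry,
    t: float,
    rng: np.random.Generator | None = None,
    steady: bool = False,
) -> SimState:
    """Activate RAF at the ligand patch while the ligand window is open."""
    if not steady and t >= rules.ligand_window_s:
        return state
    roles = state.roles()
    cand = np.flatnonzero(
        (roles == "RAF") & (state.n_phosphates == 0) & state.free
    )
    hit = cand[_in_ligand_patch(state, geometry, rules, cand)]
    _phosphorylate(state, hit, rules.raf_phosphates, "RAF")
    if len(hit):
        refresh_effective(state)
    return state


def _targets_within(
    state: SimState, sources: np.ndarray, targets: np.ndarray, radius_um: float
) -> np.ndarray:
    """Subset of ``targets`` within ``radius_um`` of any source."""
    if len(sources) == 0 or len(targets) == 0:
        return np.zeros(0, dtype=np.int64)
    sp = state.pos[sources] / UM
    tp = state.pos[targets] / UM
    d2 = np.sum((tp[:, None, :] - sp[None, :, :]) ** 2, axis=2)
    hit = (d2 <= radius_um * radius_um).any(axis=1)
    return targets[hit]


def contact_reactions(
    state: SimState, rules: ReactionRules, rng: np.random.Generator | None = None
) -> SimState:
    """Fire pRAF+MEK -> pMEK and pMEK+ERK -> pERK for pairs in contact.

    Pinned particles still react (a pRAF pinned at the NM phosphorylates
    MEK passing within the contact radius).  MEK bound to a pERK-blocked
    scaffold is shielded from pRAF.
    """
    roles = state.roles()
    changed = False

    praf = np.flatnonzero((roles == "RAF") & (state.n_phosphates > 0))
    mek_t = np.flatnonzero((roles == "MEK") & (state.n_phosphates == 0))
    if len(mek_t):
        sc = state.bound_to[mek_t]
        blocked = (sc >= 0) & state.perk_blocked[np.maximum(sc, 0)]
        mek_t = mek_t[~blocked]
    hit = _targets_within(state, praf, mek_t, rules.reaction_radius_um)
    if len(hit):
        _phosphorylate(state, hit, 1, "MEK")
        changed = True

    pmek = np.flatnonzero((roles == "MEK") & (state.n_phosphates > 0))
    erk_t = np.flatnonzero((roles == "ERK") & (state.n_phosphates == 0))
    hit = _targets_within(state, pmek, erk_t, rules.reaction_radius_um)
    if len(hit):
        _phosphorylate(state, hit, 1, "ERK")
        changed = True
        # Newly formed pERK releases from its scaffold and moves freely.
        for i in hit:
            sc = state.bound_to[i]
            if sc >= 0:
                state.bound_to[i] = -1
                if state.erk_slot[sc] == i:
                    state.erk_slot[sc] = -1

    if changed:
        refresh_effective(state)
    return state


def dephosphorylation_timer(
    state: SimState, rules: ReactionRules, t: float | None = None
) -> SimState:
    """Strip phosphates once a particle's phospho clock passes the delay.

    A dephosphorylated particle pinned at the NM is released and resumes
    moving; with its IEP-only (typically positive) charge restored, RAF
    is then pushed back out to the CM.
    """
    done = np.flatnonzero(
        (state.n_phosphates > 0) & (state.phospho_clock > rules.phosphatase_delay_s)
    )
    if len(done) == 0:
        return state
    state.n_phosphates[done] = 0
    state.phospho_clock[done] = 0.0
    release = done[state.pinned[done]]
    if len(release):
        state.pinned[release] = False
        state.arrival_time[release] = np.nan
        state.arrival_point[release] = np.nan
    refresh_effective(state)
    return state


def _bind(state: SimState, scaffold: int, member: int, slot: str) -> None:
    getattr(state, slot)[scaffold] = member
    state.bound_to[member] = scaffold
    state.pos[member] = state.pos[scaffold]
    state.vel[member] = 0.0
    state.charge[member] = 0


def ksr1_binding(
    state: SimState, rules: ReactionRules, rng: np.random.Generator | None = None
) -> SimState:
    """Bind free MEK/ERK to KSR1 scaffolds on contact; handle pERK rebinding.

    First-come occupancy: a second candidate for an occupied slot is
    ignored.  Free pERK within the contact radius of a scaffold occupies
    the ERK slot and sets ``perk_blocked``, shielding that scaffold's MEK
    from further pRAF encounters.
    """
    if not rules.ksr1_enabled:
        return state
    roles = state.roles()
    scaffolds = np.flatnonzero(roles == "KSR1")
    if len(scaffolds) == 0:
        return state
    changed = False
    r2 = rules.reaction_radius_um**2
    sp = state.pos[scaffolds] / UM

    def nearby(cands: np.ndarray) -> list[tuple[int, int]]:
        """(candidate, scaffold) contact pairs, nearest scaffold first."""
        if len(cands) == 0:
            return []
        cp = state.pos[cands] / UM
        d2 = np.sum((cp[:, None, :] - sp[None, :, :]) ** 2, axis=2)
        in_range = d2 <= r2
        if not in_range.any():
            return []
        pairs = []
        for ci in np.flatnonzero(in_range.any(axis=1)):
            order = np.argsort(d2[ci])
            for sj in order:
                if d2[ci, sj] > r2:
                    break
                pairs.append((int(cands[ci]), int(scaffolds[sj])))
        return pairs

    free_mek = np.flatnonzero(
        (roles == "MEK") & (state.bound_to < 0) & ~state.pinned
    )
    for m, s in nearby(free_mek):
        if state.mek_slot[s] < 0 and state.bound_to[m] < 0:
            _bind(state, s, m, "mek_slot")
            changed = True

    free_erk = np.flatnonzero(
        (roles == "ERK") & (state.bound_to < 0) & ~state.pinned
    )
    for e, s in nearby(free_erk):
        if state.erk_slot[s] >= 0 or state.bound_to[e] >= 0:
            continue
        if state.n_phosphates[e] > 0:
            # pERK rebinds a separate site and blocks the scaffold.
            _bind(state, s, e, "erk_slot")
            state.perk_blocked[s] = True
        else:
            _bind(state, s, e, "erk_slot")
        changed = True

    if changed:
        refresh_effective(state)
    return state
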