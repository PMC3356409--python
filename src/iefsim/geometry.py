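"""Cell geometry, boundary handling, the radial pH field and the nuclear charge.

The cell is a spherical shell (or a cube with a spherical nucleus): the
outer cell membrane (CM) reflects particles specularly, the nuclear
membrane (NM) absorbs them, pinning each arrival at its collision point.
All lengths here are micrometres; the dynamics engine converts to metres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import EPSILON_R, PH_CM, PH_NM, Q_NUCLEUS, R_CELL_UM, R_NUCLEUS_UM

__all__ = [
    "CellGeometry",
    "PHField",
    "NuclearField",
    "local_ph",
    "ph_at_radius",
    "apply_boundaries",
    "apply_boundaries_arrays",
    "shortest_transit_distance",
    "radial_projection",
]

_TOL = 1e-9


@dataclass(frozen=True)
class CellGeometry:
    """Spatial domain of the cell.

    ``sphere``: cytoplasm is the shell between the nuclear radius and the
    cell radius.  ``cube``: cytoplasm is the cube interior minus the
    nuclear sphere; the cube is centred on the nucleus.
    """

    shape: str = "sphere"
    r_nucleus: float = R_NUCLEUS_UM
    r_cell: float = R_CELL_UM
    cube_side: float = 10.0
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        if self.shape not in ("sphere", "cube"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.r_nucleus <= 0:
            raise ValueError("r_nucleus must be > 0")
        if self.shape == "sphere":
            if not self.r_nucleus < self.r_cell:
                raise ValueError("r_nucleus must be < r_cell")
        else:
            if self.cube_side <= 2 * self.r_nucleus:
                raise ValueError("nucleus sphere must fit inside the cube")

    @property
    def r_outer(self) -> float:
        """Largest centre distance still inside the domain (um)."""
        return self.r_cell if self.shape == "sphere" else self.cube_side / 2.0

    def contains(self, position: np.ndarray, tol: float = _TOL) -> bool:
        """True if ``position`` (um) lies in the cytoplasm (boundaries included)."""
        p = np.asarray(position, dtype=float) - self.center
        r = float(np.linalg.norm(p))
        if r < self.r_nucleus - tol:
            return False
        if self.shape == "sphere":
            return r <= self.r_cell + tol
        return bool(np.all(np.abs(p) <= self.cube_side / 2.0 + tol))


@dataclass(frozen=True)
class PHField:
    """Radial cytosolic pH profile.

    ``uniform`` returns a constant; ``linear_radial`` interpolates from
    ``ph_nm`` at the nuclear membrane to ``ph_cm`` at the cell membrane;
    ``double_acidic`` is piecewise linear with both membranes relatively
    acidic and ``ph_mid`` at mid-cytoplasm.
    """

    profile: str = "linear_radial"
    ph_nm: float = PH_NM
    ph_cm: float = PH_CM
    ph_mid: float | None = None

    def __post_init__(self) -> None:
        if self.profile not in ("uniform", "linear_radial", "double_acidic"):
            raise ValueError(f"unknown pH profile {self.profile!r}")
        for v in (self.ph_nm, self.ph_cm):
            if not 0.0 <= v <= 14.0:
                raise ValueError("pH values must lie in [0, 14]")
        if self.profile == "double_acidic":
            if self.ph_mid is None:
                raise ValueError("double_acidic profile requires ph_mid")
            if not 0.0 <= self.ph_mid <= 14.0:
                raise ValueError("pH values must lie in [0, 14]")
            if self.ph_mid < max(self.ph_nm, self.ph_cm):
                raise ValueError("ph_mid must be >= both membrane anchors")

    @classmethod
    def uniform(cls, ph: float) -> "PHField":
        return cls(profile="uniform", ph_nm=ph, ph_cm=ph)

    @classmethod
    def linear(cls, ph_nm: float = PH_NM, ph_cm: float = PH_CM) -> "PHField":
        return cls(profile="linear_radial", ph_nm=ph_nm, ph_cm=ph_cm)

    @classmethod
    def double_acidic(
        cls, ph_nm: float = 7.2, ph_mid: float = 7.4, ph_cm: float = 7.2
    ) -> "PHField":
        return cls(profile="double_acidic", ph_nm=ph_nm, ph_cm=ph_cm, ph_mid=ph_mid)


@dataclass(frozen=True)
class NuclearField:
    """Nuclear membrane charge collapsed to a point charge at the centre.

    By Gauss's law a uniformly charged nuclear membrane acts on the
    cytoplasm like a point charge at the nuclear centre.
    """

    q_nucleus: float = Q_NUCLEUS
    epsilon_r: float = EPSILON_R

    def __post_init__(self) -> None:
        if self.q_nucleus < 0:
            raise ValueError("q_nucleus must be >= 0 (cytoplasm-facing positive)")
        if self.epsilon_r <= 0:
            raise ValueError("epsilon_r must be > 0")


def ph_at_radius(geometry: CellGeometry, ph: PHField, r: np.ndarray) -> np.ndarray:
    """pH at centre distance ``r`` (um); vectorised, clipped to the shell."""
    r = np.asarray(r, dtype=float)
    a, b = geometry.r_nucleus, geometry.r_outer
    if ph.profile == "uniform":
        return np.full_like(r, ph.ph_nm)
    rc = np.clip(r, a, b)
    if ph.profile == "linear_radial":
        return ph.ph_nm + (ph.ph_cm - ph.ph_nm) * (rc - a) / (b - a)
    mid = 0.5 * (a + b)
    inner = ph.ph_nm + (ph.ph_mid - ph.ph_nm) * (rc - a) / (mid - a)
    outer = ph.ph_mid + (ph.ph_cm - ph.ph_mid) * (rc - mid) / (b - mid)
    return np.where(rc <= mid, inner, outer)


def local_ph(geometry: CellGeometry, ph: PHField, position: np.ndarray) -> float:
    """pH at a cytoplasmic ``position`` (um).

    Raises ``ValueError`` if the position is outside the cytoplasm.
    """
    position = np.asarray(position, dtype=float)
    if not geometry.contains(position, tol=1e-6):
        raise ValueError(f"position {position} is outside the cytoplasm")
    r = np.linalg.norm(position - geometry.center)
    return float(ph_at_radius(geometry, ph, r))


def shortest_transit_distance(geometry: CellGeometry) -> float:
    """Shortest CM-to-NM travel distance (um): the radial gap of the shell."""
    if geometry.shape != "sphere":
        raise ValueError("shortest_transit_distance is defined for spheres")
    return geometry.r_cell - geometry.r_nucleus

def radial_projection(geometry: CellGeometry, cm_point: np.ndarray) -> np.ndarray:
    """Project a CM surface point onto the NM along the ray through the centre.

    This is the arrival point a purely field-driven particle released at
    ``cm_point`` would reach, and serves as the "expected" landing site
    for projection-fidelity metrics.
    """
    p = np.asarray(cm_point, dtype=float) - geometry.center
    n = np.linalg.norm(p)
    if n < _TOL:
        raise ValueError("cm_point coincides with the cell centre")
    return geometry.center + geometry.r_nucleus * p / n


# ---------------------------------------------------------------------------
# Boundary handling
# ---------------------------------------------------------------------------


def _sphere_hit_t(old: np.ndarray, d: np.ndarray, radius: float) -> np.ndarray:
    """Smallest t in [0, 1] where |old + t d| = radius, else +inf.  Vectorised."""
    a = np.einsum("ij,ij->i", d, d)
    b = 2.0 * np.einsum("ij,ij->i", old, d)
    c = np.einsum("ij,ij->i", old, old) - radius * radius
    disc = b * b - 4.0 * a * c
    ok = (disc >= 0.0) & (a > 0.0)
    sq = np.sqrt(np.where(ok, disc, 0.0))
    denom = np.where(a > 0.0, 2.0 * a, 1.0)
    t1 = (-b - sq) / denom
    t2 = (-b + sq) / denom
    # a > 0 implies t1 <= t2: prefer the earlier crossing.
    in1 = ok & (t1 >= -_TOL) & (t1 <= 1.0)
    in2 = ok & (t2 >= -_TOL) & (t2 <= 1.0)
    t = np.where(in1, t1, np.where(in2, t2, np.inf))
    return np.clip(t, 0.0, None)


def _reflect_sphere(pos: np.ndarray, old: np.ndarray, radius: float, outer: bool) -> None:
    """Specularly reflect, in place, segments old->pos that cross the sphere.

    ``outer=True`` keeps particles inside the sphere (CM); ``outer=False``
    keeps them outside (non-absorbing NM).  Repeats until interior.
    """
    for _ in range(8):
        r = np.sqrt(np.einsum("ij,ij->i", pos, pos))
        bad = (r > radius + _TOL) if outer else (r < radius - _TOL)
        if not bad.any():
            return
        o, p = old[bad], pos[bad]
        d = p - o
        t = _sphere_hit_t(o, d, radius)
        # Fallback for numerically tangent cases: radial fold about the sphere.
        no_hit = ~np.isfinite(t)
        t = np.where(no_hit, 0.0, t)
        hit = o + t[:, None] * d
        nrm = hit / np.maximum(np.linalg.norm(hit, axis=1, keepdims=True), _TOL)
        rem = (1.0 - t)[:, None] * d
        rem -= 2.0 * np.einsum("ij,ij->i", rem, nrm)[:, None] * nrm
        newp = hit + rem
        if no_hit.any():
            # Radial fold: r -> 2*radius - r along the same ray.
            pb = p[no_hit]
            rb = np.maximum(np.linalg.norm(pb, axis=1, keepdims=True), _TOL)
            newp[no_hit] = pb / rb * (2.0 * radius - rb)
        pos[bad] = newp
        old[bad] = hit
    # Last resort: clamp radially onto the boundary.
    r = np.linalg.norm(pos, axis=1)
    bad = (r > radius) if outer else (r < radius)
    if bad.any():
        rb = np.maximum(r[bad], _TOL)[:, None]
        pos[bad] = pos[bad] / rb * radius


def _reflect_cube(pos: np.ndarray, half: float) -> None:
    """Fold coordinates back into [-half, half] (specular face reflection)."""
    for _ in range(16):
        over = pos > half
        under = pos < -half
        if not (over.any() or under.any()):
            return
        pos[over] = 2.0 * half - pos[over]
        pos[under] = -2.0 * half - pos[under]
    np.clip(pos, -half, half, out=pos)


def apply_boundaries_arrays(
    geometry: CellGeometry,
    old: np.ndarray,
    new: np.ndarray,
    absorb: np.ndarray | bool = True,
):
    """Apply NM absorption and CM reflection to a batch of steps.

    Parameters
    ----------
    old, new : (n, 3) arrays, um, relative to any origin (centre subtracted
        internally).
    absorb : bool or (n,) bool array — whether each particle may be absorbed
        at the NM this step; non-absorbing particles reflect off the NM.

    Returns
    -------
    pos : (n, 3) corrected positions (um)
    absorbed : (n,) bool
    hit : (n, 3) NM collision points (NaN where not absorbed)
    """
    old = np.asarray(old, dtype=float) - geometry.center
    pos = np.asarray(new, dtype=float) - geometry.center
    n = old.shape[0]
    absorb = np.broadcast_to(np.asarray(absorb, dtype=bool), (n,)).copy()
    absorbed = np.zeros(n, dtype=bool)
    hit = np.full((n, 3), np.nan)

    d = pos - old
    dlen = np.sqrt(np.einsum("ij,ij->i", d, d))
    r_new = np.sqrt(np.einsum("ij,ij->i", pos, pos))

    # Only particles within one step of the NM can interact with it.
    cand = np.flatnonzero(r_new <= geometry.r_nucleus + dlen + _TOL)
    if len(cand):
        oc, dc = old[cand], d[cand]
        t = _sphere_hit_t(oc, dc, geometry.r_nucleus)
        crossed = np.isfinite(t)
        # Degenerate: already exactly on the NM with zero-length step.
        on_nm = (
            np.abs(np.sqrt(np.einsum("ij,ij->i", oc, oc)) - geometry.r_nucleus)
            <= _TOL
        )
        crossed |= on_nm & (dlen[cand] == 0.0)
        take = crossed & absorb[cand]
        if take.any():
            ids = cand[take]
            tp = np.where(np.isfinite(t), t, 0.0)
            pts = oc[take] + tp[take, None] * dc[take]
            # Pin exactly onto the NM sphere.
            nr = np.maximum(np.linalg.norm(pts, axis=1, keepdims=True), _TOL)
            pts = pts / nr * geometry.r_nucleus
            pos[ids] = pts
            hit[ids] = pts + geometry.center
            absorbed[ids] = True

    # CM reflection (and NM reflection for non-absorbing particles).
    # Steps are far smaller than the shell, so only endpoints outside the
    # domain (or within one step of the NM) need the exact treatment.
    if geometry.shape == "sphere":
        out_cm = np.flatnonzero(~absorbed & (r_new > geometry.r_cell + _TOL))
        if len(out_cm):
            o, p = old[out_cm].copy(), pos[out_cm]
            _reflect_sphere(p, o, geometry.r_cell, outer=True)
            pos[out_cm] = p
    else:
        half = geometry.cube_side / 2.0
        out_cm = np.flatnonzero(
            ~absorbed & (np.abs(pos) > half + _TOL).any(axis=1)
        )
        if len(out_cm):
            p = pos[out_cm]
            _reflect_cube(p, half)
            pos[out_cm] = p

    r_new = np.sqrt(np.einsum("ij,ij->i", pos, pos))
    in_nm = np.flatnonzero(~absorbed & (r_new < geometry.r_nucleus - _TOL))
    if len(in_nm):
        o, p = old[in_nm].copy(), pos[in_nm]
        _reflect_sphere(p, o, geometry.r_nucleus, outer=False)
        pos[in_nm] = p

    return pos + geometry.center, absorbed, hit


def apply_boundaries(
    geometry: CellGeometry, old_position: np.ndarray, new_position: np.ndarray
):
    """Scalar boundary step: absorb at the NM, reflect at the CM.

    Returns ``(position, absorbed, absorption_point_or_None)``.
    """
    old = np.atleast_2d(np.asarray(old_position, dtype=float))
    if not geometry.contains(old[0], tol=1e-6):
        raise ValueError("old_position must lie inside the cytoplasm")
    new = np.atleast_2d(np.asarray(new_position, dtype=float))
    pos, absorbed, hit = apply_boundaries_arrays(geometry, old, new, absorb=True)
    if absorbed[0]:
        return pos[0], True, hit[0]
    return pos[0], False, None
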