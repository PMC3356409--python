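"""Run configuration: TOML/JSON loading, validation and defaults.

Omitted geometry/dynamics fields fall back to the reference cytoplasm
parameter set (3/5 um spherical shell, dt = 1e-4 s, eta = 0.3 Pa s,
T = 310 K, eps_r = 80, calibrated nuclear charge).
"""

from __future__ import annotations

import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

from . import constants
from .charge_model import ProteinSpecies
from .dynamics import DynamicsParams
from .geometry import CellGeometry, NuclearField, PHField
from .pathway import ReactionRules

__all__ = [
    "ConfigError",
    "ConfigParseError",
    "ConfigValidationError",
    "SpeciesConfig",
    "ScenarioConfig",
    "OutputConfig",
    "RunConfig",
    "load_config",
    "config_from_dict",
]

SCENARIO_MODES = ("diffusion_only", "pulse", "transient", "steady")


class ConfigError(Exception):
    """Base class for configuration problems."""


class ConfigParseError(ConfigError):
    """The file could not be parsed as TOML or JSON."""


class ConfigValidationError(ConfigError):
    """A parsed config violates an invariant; names the offending key."""


@dataclass(frozen=True)
class SpeciesConfig:
    name: str
    iep: float
    stokes_radius_nm: float = 5.0
    n_phospho_sites: int = 2
    role: str = "generic"
    count: int = 0

    def to_species(self) -> ProteinSpecies:
        return ProteinSpecies(
            name=self.name,
            iep=self.iep,
            stokes_radius_nm=self.stokes_radius_nm,
            n_phospho_sites=self.n_phospho_sites,
            role=self.role,
        )


@dataclass(frozen=True)
class ScenarioConfig:
    mode: str
    count: int = 100
    ligand_direction: tuple = (0.0, 0.0, 1.0)
    cap_half_angle_deg: float = 15.0
    #: pulse/diffusion: fixed net charge (e); None samples from pH instead
    fixed_charge_e: Optional[float] = -2.0
    n_phosphates: int = 2
    reaction_radius_um: float = 0.1
    phosphatase_delay_s: float = 30.0
    ligand_window_s: float = 30.0
    ksr1_enabled: bool = False
    t_end_s: float = 1.0
    nm_policy: Optional[str] = None
    #: run the reaction layer every this many steps; at dt = 1e-4 s a
    #: contact pair stays within the reaction radius for ~5 steps, so a
    #: small stride misses no encounters while cutting bookkeeping cost
    reaction_stride: int = 1

    def default_nm_policy(self) -> str:
        if self.nm_policy is not None:
            return self.nm_policy
        return "absorb_all" if self.mode in ("diffusion_only", "pulse") else "absorb_phosphorylated"

    def rules(self) -> ReactionRules:
        return ReactionRules(
            reaction_radius_um=self.reaction_radius_um,
            phosphatase_delay_s=self.phosphatase_delay_s,
            ligand_window_s=self.ligand_window_s,
            ligand_direction=tuple(self.ligand_direction),
            cap_half_angle_deg=self.cap_half_angle_deg,
            ksr1_enabled=self.ksr1_enabled,
        )


@dataclass(frozen=True)
class OutputConfig:
    trajectory_csv: Optional[str] = None
    summary_json: Optional[str] = None
    profile_csv: Optional[str] = None
    xyz: Optional[str] = None
    stride: int = 100


@dataclass(frozen=True)
class RunConfig:
    geometry: CellGeometry
    ph: PHField
    nucleus: NuclearField
    dynamics: DynamicsParams
    species: tuple
    scenario: ScenarioConfig
    output: OutputConfig = field(default_factory=OutputConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        g, p, s = self.geometry, self.ph, self.scenario
        return {
            "geometry": {
                "shape": g.shape,
                "r_nucleus_um": g.r_nucleus,
                "r_cell_um": g.r_cell,
                "cube_side_um": g.cube_side,
            },
            "ph": {
                "profile": p.profile,
                "ph_nm": p.ph_nm,
                "ph_cm": p.ph_cm,
                **({"ph_mid": p.ph_mid} if p.ph_mid is not None else {}),
            },
            "nucleus": {
                "q_nucleus_c": self.nucleus.q_nucleus,
                "epsilon_r": self.nucleus.epsilon_r,
            },
            "dynamics": {
                "dt_s": self.dynamics.dt,
                "eta_pa_s": self.dynamics.eta,
                "temperature_k": self.dynamics.temperature,
                "mode": self.dynamics.mode,
            },
            "species": [
                {
                    "name": sp.name,
                    "iep": sp.iep,
                    "stokes_radius_nm": sp.stokes_radius_nm,
                    "n_phospho_sites": sp.n_phospho_sites,
                    "role": sp.role,
                    "count": sp.count,
                }
                for sp in self.species
            ],
            "scenario": {
                "mode": s.mode,
                "count": s.count,
                "ligand_direction": list(s.ligand_direction),
                "cap_half_angle_deg": s.cap_half_angle_deg,
                "fixed_charge_e": s.fixed_charge_e,
                "n_phosphates": s.n_phosphates,
                "reaction_radius_um": s.reaction_radius_um,
                "phosphatase_delay_s": s.phosphatase_delay_s,
                "ligand_window_s": s.ligand_window_s,
                "ksr1_enabled": s.ksr1_enabled,
                "t_end_s": s.t_end_s,
                "nm_policy": s.nm_policy,
                "reaction_stride": s.reaction_stride,
            },
            "output": {
                "trajectory_csv": self.output.trajectory_csv,
                "summary_json": self.output.summary_json,
                "profile_csv": self.output.profile_csv,
                "xyz": self.output.xyz,
                "stride": self.output.stride,
            },
            "seed": self.seed,
        }


def _require(cond: bool, key: str, msg: str) -> None:
    if not cond:
        raise ConfigValidationError(f"{key}: {msg}")


def config_from_dict(raw: dict[str, Any]) -> RunConfig:
    """Build and validate a :class:`RunConfig` from a parsed mapping."""
    if not isinstance(raw, dict):
        raise ConfigValidationError("config: top level must be a table/object")

    g = raw.get("geometry", {})
    try:
        geometry = CellGeometry(
            shape=g.get("shape", "sphere"),
            r_nucleus=g.get("r_nucleus_um", constants.R_NUCLEUS_UM),
            r_cell=g.get("r_cell_um", constants.R_CELL_UM),
            cube_side=g.get("cube_side_um", 10.0),
        )
    except ValueError as e:
        raise ConfigValidationError(f"geometry: {e}") from e

    p = raw.get("ph", {})
    try:
        ph = PHField(
            profile=p.get("profile", "linear_radial"),
            ph_nm=p.get("ph_nm", constants.PH_NM),
            ph_cm=p.get("ph_cm", constants.PH_CM),
            ph_mid=p.get("ph_mid"),
        )
    except ValueError as e:
        raise ConfigValidationError(f"ph: {e}") from e

    nb = raw.get("nucleus", {})
    try:
        nucleus = NuclearField(
            q_nucleus=nb.get("q_nucleus_c", constants.Q_NUCLEUS),
            epsilon_r=nb.get("epsilon_r", constants.EPSILON_R),
        )
    except ValueError as e:
        raise ConfigValidationError(f"nucleus: {e}") from e

    d = raw.get("dynamics", {})
    try:
        dynamics = DynamicsParams(
            dt=d.get("dt_s", constants.DT),
            eta=d.get("eta_pa_s", constants.ETA_CYTOPLASM),
            temperature=d.get("temperature_k", constants.TEMPERATURE),
            epsilon_r=nb.get("epsilon_r", constants.EPSILON_R),
            mode=d.get("mode", "capped_newtonian"),
        )
    except ValueError as e:
        raise ConfigValidationError(f"dynamics: {e}") from e

    species = []
    for i, sp in enumerate(raw.get("species", [])):
        key = f"species[{i}]"
        _require("name" in sp, f"{key}.name", "is required")
        _require("iep" in sp, f"{key}.iep", "is required")
        try:
            sc = SpeciesConfig(
                name=sp["name"],
                iep=sp["iep"],
                stokes_radius_nm=sp.get("stokes_radius_nm", 5.0),
                n_phospho_sites=sp.get("n_phospho_sites", 2),
                role=sp.get("role", "generic"),
                count=sp.get("count", 0),
            )
            sc.to_species()
        except ValueError as e:
            raise ConfigValidationError(f"{key}: {e}") from e
        _require(sc.count >= 0, f"{key}.count", "must be >= 0")
        species.append(sc)

    sb = raw.get("scenario", {})
    _require(bool(sb.get("mode")), "scenario.mode", "is required")
    _require(sb["mode"] in SCENARIO_MODES, "scenario.mode", f"must be one of {SCENARIO_MODES}")
    scenario = ScenarioConfig(
        mode=sb["mode"],
        count=sb.get("count", 100),
        ligand_direction=tuple(sb.get("ligand_direction", (0.0, 0.0, 1.0))),
        cap_half_angle_deg=sb.get("cap_half_angle_deg", 15.0),
        fixed_charge_e=sb.get("fixed_charge_e", -2.0 if sb["mode"] == "pulse" else None),
        n_phosphates=sb.get("n_phosphates", 2),
        reaction_radius_um=sb.get("reaction_radius_um", 0.1),
        phosphatase_delay_s=sb.get("phosphatase_delay_s", 30.0),
        ligand_window_s=sb.get("ligand_window_s", 30.0),
        ksr1_enabled=sb.get("ksr1_enabled", False),
        t_end_s=sb.get("t_end_s", 1.0),
        nm_policy=sb.get("nm_policy"),
        reaction_stride=sb.get("reaction_stride", 1),
    )
    _require(scenario.reaction_stride >= 1, "scenario.reaction_stride", "must be >= 1")
    _require(scenario.t_end_s > 0, "scenario.t_end_s", "must be > 0")
    _require(scenario.count > 0 or scenario.mode in ("transient", "steady"),
             "scenario.count", "must be > 0 for pulse/diffusion scenarios")
    _require(scenario.reaction_radius_um > 0, "scenario.reaction_radius_um", "must be > 0")
    if scenario.nm_policy is not None:
        _require(
            scenario.nm_policy in ("absorb_all", "absorb_phosphorylated", "reflect_all"),
            "scenario.nm_policy",
            "must be absorb_all | absorb_phosphorylated | reflect_all",
        )
    if scenario.mode in ("transient", "steady"):
        _require(
            any(sp.count > 0 for sp in species),
            "species",
            "transient/steady scenarios need at least one species with count > 0",
        )

    ob = raw.get("output", {})
    output = OutputConfig(
        trajectory_csv=ob.get("trajectory_csv"),
        summary_json=ob.get("summary_json"),
        profile_csv=ob.get("profile_csv"),
        xyz=ob.get("xyz"),
        stride=ob.get("stride", 100),
    )
    _require(output.stride >= 1, "output.stride", "must be >= 1")

    seed = raw.get("seed", 0)
    _require(isinstance(seed, int), "seed", "must be an integer")

    return RunConfig(
        geometry=geometry,
        ph=ph,
        nucleus=nucleus,
        dynamics=dynamics,
        species=tuple(species),
        scenario=scenario,
        output=output,
        seed=seed,
    )


def load_config(path: str | Path) -> RunConfig:
    """Load a TOML (``.toml``) or JSON (``.json``) run configuration."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        if path.suffix.lower() == ".json":
            raw = json.loads(path.read_text())
        else:
            with open(path, "rb") as fh:
                raw = tomllib.load(fh)
    except (json.JSONDecodeError, tomllib.TOMLDecodeError) as e:
        raise ConfigParseError(f"{path}: {e}") from e
    return config_from_dict(raw)
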