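"""Configuration, scenario assembly, output writers and the command line.

The configuration mirrors the default TC-PMN scenario: a 60 x 32 x 42 um
domain, tumor cell centroid at (20, 10, 21) um, PMN centroid at (30, 2.5, 21)
um and 100 timesteps, with molecule densities and kinetic constants from the
published parameter tables. Config files are TOML; lengths are given in
micrometres (and other conveniences noted in field names) and converted to SI
on load so the core modules never mix units.

Every CSV written here carries a header block with the config hash, seed,
code version and a reminder that hydrodynamic loads come from the analytic
near-wall surrogate rather than a CFD solution.
"""

from __future__ import annotations

import dataclasses
import hashlib
import io
import logging
import sys
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .adhesion import (
    BondTypeParams,
    KineticEnvironment,
    MoleculeLedger,
    MoleculeSpecies,
)
from .dynamics import FlowEnvironment, RigidBodyState
from .geometry import (
    Load,
    SurfaceMesh,
    cap_for_max_edge,
    face_properties,
    gated_face_pairs,
    icosphere_for_max_edge,
    load_obj,
    write_off,
    write_vtk_polydata,
)
from .repulsion import RepulsionParams

logger = logging.getLogger(__name__)

UM = 1.0e-6

SURROGATE_NOTE = (
    "hydrodynamic loads from analytic near-wall shear surrogate (no CFD solution)"
)


class ConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Configuration dataclasses (convenience units; converted to SI on assembly)
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class TCConfig:
    radius_um: float = 4.0  # assumption (not tabulated)
    centroid_um: tuple = (20.0, 10.0, 21.0)  # tabulated scenario value
    max_element_um: float = 1.0  # assumption
    density_kg_m3: float = 1050.0  # assumption
    mesh_file: str | None = None


@dataclasses.dataclass
class PMNConfig:
    base_radius_um: float = 5.0  # assumption
    height_um: float = 5.0  # assumption
    centroid_um: tuple = (30.0, 2.5, 21.0)  # tabulated; y is informational,
    # the cap always rests on the substrate so x,z are used for placement
    max_element_um: float = 1.0  # assumption
    mesh_file: str | None = None


@dataclasses.dataclass
class SpeciesConfig:
    name: str
    body: str
    density_per_um2: float


@dataclasses.dataclass
class BondTypeConfig:
    tc_species: str
    pmn_species: str
    kon0_per_s: float = 3000.0  # tabulated (printed unit 1/Ms read as 1/s per molecule)
    koff0_per_s: float = 0.3  # tabulated
    spring_n_per_m: float = 2.0e-3  # tabulated
    transition_spring_n_per_m: float = 1.0e-3  # tabulated
    eq_length_um: float = 0.05  # tabulated


@dataclasses.dataclass
class EnvironmentConfig:
    temperature_k: float = 310.15  # assumption
    timestep_s: float = 1.0e-3  # assumption (only the step count is tabulated)
    repulsion_a_n_per_m: float = -110.0e-6  # tabulated
    repulsion_b_n_per_m3: float = 600.0e6  # tabulated
    repulsion_eps_um: float = 1.2  # tabulated
    microvilli_um: float = 1.2  # standoff = repulsion critical distance
    shear_rate_per_s: float = 100.0  # assumption
    viscosity_pa_s: float = 1.0e-3  # assumption
    fluid_density_kg_m3: float = 1000.0  # assumption


@dataclasses.dataclass
class RunConfig:
    n_steps: int = 100  # tabulated
    seed: int = 0
    out_dir: str | None = None
    repulsion: bool = True
    adhesion: bool = True
    forced_probability: float | None = None
    repulsion_mode: str = "clamped"
    dynamics_mode: str = "overdamped"
    ext_force_n: tuple = (0.0, 0.0, 0.0)
    write_meshes: bool = False


def _default_species() -> list[SpeciesConfig]:
    return [
        SpeciesConfig("ICAM-1", "tc", 13.0),
        SpeciesConfig("LFA-1", "pmn", 45.0),
        SpeciesConfig("Mac-1", "pmn", 5.0),
    ]


def _default_bond_types() -> list[BondTypeConfig]:
    return [
        BondTypeConfig("ICAM-1", "LFA-1", koff0_per_s=0.3),
        BondTypeConfig("ICAM-1", "Mac-1", koff0_per_s=0.29),
    ]


@dataclasses.dataclass
class SimulationConfig:
    domain_um: tuple = (60.0, 32.0, 42.0)  # tabulated
    tc: TCConfig = dataclasses.field(default_factory=TCConfig)
    pmn: PMNConfig = dataclasses.field(default_factory=PMNConfig)
    species: list = dataclasses.field(default_factory=_default_species)
    bond_types: list = dataclasses.field(default_factory=_default_bond_types)
    environment: EnvironmentConfig = dataclasses.field(default_factory=EnvironmentConfig)
    run: RunConfig = dataclasses.field(default_factory=RunConfig)

    def __post_init__(self):
        self.domain_um = tuple(float(v) for v in self.domain_um)
        self.tc.centroid_um = tuple(float(v) for v in self.tc.centroid_um)
        self.pmn.centroid_um = tuple(float(v) for v in self.pmn.centroid_um)
        self.run.ext_force_n = tuple(float(v) for v in self.run.ext_force_n)

    def validate(self) -> None:
        for name, value in (
            ("domain_um", min(self.domain_um)),
            ("tc.radius_um", self.tc.radius_um),
            ("tc.max_element_um", self.tc.max_element_um),
            ("tc.density_kg_m3", self.tc.density_kg_m3),
            ("pmn.base_radius_um", self.pmn.base_radius_um),
            ("pmn.height_um", self.pmn.height_um),
            ("pmn.max_element_um", self.pmn.max_element_um),
            ("environment.temperature_k", self.environment.temperature_k),
            ("environment.timestep_s", self.environment.timestep_s),
            ("environment.repulsion_b_n_per_m3", self.environment.repulsion_b_n_per_m3),
            ("environment.repulsion_eps_um", self.environment.repulsion_eps_um),
            ("environment.viscosity_pa_s", self.environment.viscosity_pa_s),
        ):
            if not value > 0.0:
                raise ConfigError(f"{name} must be positive (got {value!r})")
        if self.environment.microvilli_um < 0.0:
            raise ConfigError("environment.microvilli_um must be >= 0")
        if self.run.n_steps < 0:
            raise ConfigError("run.n_steps must be >= 0")
        if self.run.repulsion_mode not in ("clamped", "signed"):
            raise ConfigError("run.repulsion_mode must be 'clamped' or 'signed'")
        if self.run.dynamics_mode not in ("overdamped", "newtonian"):
            raise ConfigError("run.dynamics_mode must be 'overdamped' or 'newtonian'")
        if self.run.forced_probability is not None and not (
            0.0 <= self.run.forced_probability <= 1.0
        ):
            raise ConfigError("run.forced_probability must lie in [0, 1]")
        names = {sp.name for sp in self.species}
        if len(names) != len(self.species):
            raise ConfigError("species names must be unique")
        for sp in self.species:
            if sp.body not in ("tc", "pmn"):
                raise ConfigError(f"species {sp.name}: body must be 'tc' or 'pmn'")
            if sp.density_per_um2 < 0.0:
                raise ConfigError(f"species {sp.name}: density must be >= 0")
        for bt in self.bond_types:
            for side, body in ((bt.tc_species, "tc"), (bt.pmn_species, "pmn")):
                match = [sp for sp in self.species if sp.name == side]
                if not match or match[0].body != body:
                    raise ConfigError(
                        f"bond type {bt.pmn_species}-{bt.tc_species}: "
                        f"no {body} species named {side!r}"
                    )
            for field in ("kon0_per_s", "koff0_per_s", "spring_n_per_m",
                          "transition_spring_n_per_m", "eq_length_um"):
                if not getattr(bt, field) > 0.0:
                    raise ConfigError(
                        f"bond type {bt.pmn_species}-{bt.tc_species}: "
                        f"{field} must be positive"
                    )
        _check_bodies_disjoint(self)

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "domain_um": list(self.domain_um),
            "tc": _clean(dataclasses.asdict(self.tc)),
            "pmn": _clean(dataclasses.asdict(self.pmn)),
            "species": [dataclasses.asdict(sp) for sp in self.species],
            "bond_types": [dataclasses.asdict(bt) for bt in self.bond_types],
            "environment": dataclasses.asdict(self.environment),
            "run": _clean(dataclasses.asdict(self.run)),
        }
        d["tc"]["centroid_um"] = list(self.tc.centroid_um)
        d["pmn"]["centroid_um"] = list(self.pmn.centroid_um)
        d["run"]["ext_force_n"] = list(self.run.ext_force_n)
        return d

    @staticmethod
    def from_dict(data: dict) -> "SimulationConfig":
        data = dict(data)
        _reject_unknown(data, {"domain_um", "tc", "pmn", "species", "bond_types",
                               "environment", "run"}, "top level")
        kwargs = {}
        if "domain_um" in data:
            kwargs["domain_um"] = tuple(data["domain_um"])
        for key, cls in (("tc", TCConfig), ("pmn", PMNConfig),
                         ("environment", EnvironmentConfig), ("run", RunConfig)):
            if key in data:
                kwargs[key] = _build(cls, data[key], key)
        if "species" in data:
            kwargs["species"] = [_build(SpeciesConfig, s, "species") for s in data["species"]]
        if "bond_types" in data:
            kwargs["bond_types"] = [
                _build(BondTypeConfig, b, "bond_types") for b in data["bond_types"]
            ]
        return SimulationConfig(**kwargs)

    def hash(self) -> str:
        """Digest of the physical scenario (output location excluded)."""
        d = self.to_dict()
        d["run"].pop("out_dir", None)
        return hashlib.sha256(repr(sorted_items(d)).encode()).hexdigest()[:16]


def sorted_items(obj):
    """Canonical nested representation for hashing."""
    if isinstance(obj, dict):
        return tuple(sorted((k, sorted_items(v)) for k, v in obj.items()))
    if isinstance(obj, (list, tuple)):
        return tuple(sorted_items(v) for v in obj)
    return obj


def _clean(d: dict) -> dict:
    return {k: v for k, v in d.items() if v is not None}


def _reject_unknown(data: dict, allowed: set, where: str) -> None:
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {sorted(unknown)}")


def _build(cls, data: dict, where: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    _reject_unknown(dict(data), fields, where)
    try:
        obj = cls(**data)
    except TypeError as exc:
        raise ConfigError(f"invalid {where} section: {exc}") from exc
    for f in dataclasses.fields(cls):
        if getattr(obj, f.name) is dataclasses.MISSING:  # pragma: no cover
            raise ConfigError(f"missing required key {where}.{f.name}")
    return obj


def load_config(path) -> SimulationConfig:
    """Read, validate and return a configuration; an empty file yields the
    full default scenario. Unknown keys are rejected by name."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    cfg = SimulationConfig.from_dict(data)
    cfg.validate()
    _log_provenance(cfg)
    return cfg


def save_config(cfg: SimulationConfig, path) -> None:
    Path(path).write_text(dumps_toml(cfg.to_dict()))


def dumps_toml(data: dict) -> str:
    """Minimal TOML emitter for the configuration schema (scalars, lists of
    scalars, tables, and arrays of tables)."""
    out = []

    def fmt(v):
        if isinstance(v, bool):
            return "true" if v else "false"
        if isinstance(v, (int, float)):
            return repr(v)
        if isinstance(v, str):
            return '"' + v.replace("\\", "\\\\").replace('"', '\\"') + '"'
        if isinstance(v, (list, tuple)):
            return "[" + ", ".join(fmt(x) for x in v) + "]"
        raise ConfigError(f"cannot serialise {type(v).__name__} to TOML")

    scalars = {k: v for k, v in data.items() if not isinstance(v, (dict, list))
               or (isinstance(v, list) and not any(isinstance(x, dict) for x in v))}
    for k, v in scalars.items():
        out.append(f"{k} = {fmt(v)}")
    for k, v in data.items():
        if isinstance(v, dict):
            out.append(f"\n[{k}]")
            for kk, vv in v.items():
                out.append(f"{kk} = {fmt(vv)}")
    for k, v in data.items():
        if isinstance(v, list) and any(isinstance(x, dict) for x in v):
            for item in v:
                out.append(f"\n[[{k}]]")
                for kk, vv in item.items():
                    out.append(f"{kk} = {fmt(vv)}")
    return "\n".join(out) + "\n"


def _log_provenance(cfg: SimulationConfig) -> None:
    tabulated = {
        "domain_um": cfg.domain_um,
        "tc.centroid_um": cfg.tc.centroid_um,
        "pmn.centroid_um (x,z)": cfg.pmn.centroid_um,
        "run.n_steps": cfg.run.n_steps,
        "environment.repulsion_a_n_per_m": cfg.environment.repulsion_a_n_per_m,
        "environment.repulsion_b_n_per_m3": cfg.environment.repulsion_b_n_per_m3,
        "environment.repulsion_eps_um": cfg.environment.repulsion_eps_um,
        "species densities": [(s.name, s.density_per_um2) for s in cfg.species],
        "bond kinetics": [(b.pmn_species, b.kon0_per_s, b.koff0_per_s) for b in cfg.bond_types],
    }
    assumed = {
        "tc.radius_um": cfg.tc.radius_um,
        "pmn.base_radius_um/height_um": (cfg.pmn.base_radius_um, cfg.pmn.height_um),
        "environment.temperature_k": cfg.environment.temperature_k,
        "environment.timestep_s": cfg.environment.timestep_s,
        "environment.shear_rate_per_s": cfg.environment.shear_rate_per_s,
        "environment.viscosity_pa_s": cfg.environment.viscosity_pa_s,
    }
    for k, v in tabulated.items():
        logger.info("config %s = %r [tabulated scenario value]", k, v)
    for k, v in assumed.items():
        logger.info("config %s = %r [assumption, configurable]", k, v)


# ---------------------------------------------------------------------------
# Scenario assembly (SI units from here on)
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class Scenario:
    domain: np.ndarray
    tc_mesh: SurfaceMesh
    pmn_mesh: SurfaceMesh
    tc_state: RigidBodyState
    pmn_state: RigidBodyState
    tc_ledger: MoleculeLedger
    pmn_ledger: MoleculeLedger
    bond_types: list
    kin_env: KineticEnvironment
    rep_params: RepulsionParams
    flow_env: FlowEnvironment
    tc_radius: float
    external_load: Load


def species_params(cfg: SimulationConfig) -> list[MoleculeSpecies]:
    return [
        MoleculeSpecies(sp.name, sp.density_per_um2 / UM ** 2, sp.body)
        for sp in cfg.species
    ]


def bond_type_params(cfg: SimulationConfig) -> list[BondTypeParams]:
    return [
        BondTypeParams(
            tc_species=bt.tc_species,
            pmn_species=bt.pmn_species,
            kon0=bt.kon0_per_s,
            koff0=bt.koff0_per_s,
            spring=bt.spring_n_per_m,
            transition_spring=bt.transition_spring_n_per_m,
            eq_length=bt.eq_length_um * UM,
        )
        for bt in cfg.bond_types
    ]


def build_scenario(cfg: SimulationConfig) -> Scenario:
    cfg.validate()
    env = cfg.environment
    tc_mesh = _tc_mesh(cfg)
    pmn_mesh_raw = _pmn_mesh_raw(cfg)
    pmn_com = pmn_mesh_raw.volume_centroid()
    pmn_mesh = pmn_mesh_raw.recentred()
    pmn_pos = np.array(
        [cfg.pmn.centroid_um[0] * UM, pmn_com[1], cfg.pmn.centroid_um[2] * UM]
    )

    tc_state = RigidBodyState.sphere(
        np.asarray(cfg.tc.centroid_um) * UM, cfg.tc.radius_um * UM, cfg.tc.density_kg_m3
    )
    pmn_state = RigidBodyState.fixed_body(pmn_pos)

    species = species_params(cfg)
    tc_faces = face_properties(tc_mesh, tc_state.pose, body_id="tc")
    pmn_faces = face_properties(pmn_mesh, pmn_state.pose, body_id="pmn")
    tc_ledger = MoleculeLedger.from_faces(tc_faces, [s for s in species if s.body == "tc"])
    pmn_ledger = MoleculeLedger.from_faces(pmn_faces, [s for s in species if s.body == "pmn"])

    ext = np.asarray(cfg.run.ext_force_n, dtype=float)
    return Scenario(
        domain=np.asarray(cfg.domain_um) * UM,
        tc_mesh=tc_mesh,
        pmn_mesh=pmn_mesh,
        tc_state=tc_state,
        pmn_state=pmn_state,
        tc_ledger=tc_ledger,
        pmn_ledger=pmn_ledger,
        bond_types=bond_type_params(cfg),
        kin_env=KineticEnvironment(
            temperature=env.temperature_k,
            dt=env.timestep_s,
            eps_mv=env.microvilli_um * UM,
        ),
        rep_params=RepulsionParams(
            a=env.repulsion_a_n_per_m,
            b=env.repulsion_b_n_per_m3,
            eps=env.repulsion_eps_um * UM,
            mode=cfg.run.repulsion_mode,
        ),
        flow_env=FlowEnvironment(
            shear_rate=env.shear_rate_per_s,
            viscosity=env.viscosity_pa_s,
            fluid_density=env.fluid_density_kg_m3,
        ),
        tc_radius=cfg.tc.radius_um * UM,
        external_load=Load(ext, np.zeros(3)),
    )


def _tc_mesh(cfg: SimulationConfig) -> SurfaceMesh:
    if cfg.tc.mesh_file:
        return load_obj(cfg.tc.mesh_file).recentred()
    return icosphere_for_max_edge(cfg.tc.radius_um * UM, cfg.tc.max_element_um * UM)


def _pmn_mesh_raw(cfg: SimulationConfig) -> SurfaceMesh:
    if cfg.pmn.mesh_file:
        return load_obj(cfg.pmn.mesh_file)
    return cap_for_max_edge(
        cfg.pmn.base_radius_um * UM, cfg.pmn.height_um * UM, cfg.pmn.max_element_um * UM
    )


def _check_bodies_disjoint(cfg: SimulationConfig) -> None:
    """Reject initially overlapping bodies.

    Default shapes are analytic (sphere TC, half-ellipsoid cap PMN), so the
    check samples the cap surface densely and tests whether the TC sphere
    reaches it; imported meshes fall back to a face-distance screen.
    """
    tc_c = np.asarray(cfg.tc.centroid_um, dtype=float)
    r_tc = cfg.tc.radius_um
    if tc_c[1] <= r_tc:
        raise ConfigError(
            f"tc.centroid_um: sphere of radius {r_tc} um at height {tc_c[1]} um "
            "touches the substrate"
        )
    if cfg.tc.mesh_file or cfg.pmn.mesh_file:
        scn_tc = _tc_mesh(cfg)
        scn_pmn = _pmn_mesh_raw(cfg)
        from .geometry import Pose
        from scipy.spatial.distance import cdist

        com = scn_pmn.volume_centroid()
        tc_faces = face_properties(scn_tc, Pose.identity(tc_c * UM), "tc")
        pmn_faces = face_properties(
            scn_pmn.recentred(),
            Pose.identity(np.array(
                [cfg.pmn.centroid_um[0] * UM, com[1], cfg.pmn.centroid_um[2] * UM]
            )),
            "pmn",
        )
        if cdist(tc_faces.centroids, pmn_faces.centroids).min() <= 0.0:
            raise ConfigError("bodies overlap (imported-mesh face screen)")
        return

    a = cfg.pmn.base_radius_um
    h = cfg.pmn.height_um
    base = np.array([cfg.pmn.centroid_um[0], 0.0, cfg.pmn.centroid_um[2]])
    rel = tc_c - base
    inside = rel[1] >= 0.0 and (rel[0] / a) ** 2 + (rel[1] / h) ** 2 + (rel[2] / a) ** 2 <= 1.0
    theta = np.linspace(0.0, 0.5 * np.pi, 80)
    phi = np.linspace(0.0, 2.0 * np.pi, 160, endpoint=False)
    T, P = np.meshgrid(theta, phi)
    shell = np.stack(
        [base[0] + a * np.sin(T) * np.cos(P),
         h * np.cos(T),
         base[2] + a * np.sin(T) * np.sin(P)], axis=-1,
    ).reshape(-1, 3)
    rho = np.linspace(0.0, a, 40)
    R2, P2 = np.meshgrid(rho, phi)
    disk = np.stack(
        [base[0] + R2 * np.cos(P2), np.zeros_like(R2), base[2] + R2 * np.sin(P2)],
        axis=-1,
    ).reshape(-1, 3)
    min_d = np.linalg.norm(np.vstack([shell, disk]) - tc_c, axis=1).min()
    if inside or min_d < r_tc:
        raise ConfigError(
            "tc.centroid_um / pmn.centroid_um: bodies overlap "
            f"(TC centre {min_d:.3g} um from the PMN surface, radius {r_tc} um)"
        )


# ---------------------------------------------------------------------------
# Results and writers
# ---------------------------------------------------------------------------

def trajectory_record(step, t, state, loads, n_bonds, min_sep, n_pairs_gated) -> dict:
    rec = {"step": step, "time_s": t}
    for name, vec in (
        ("x", state.position), ("v", state.velocity), ("w", state.angular_velocity),
    ):
        for ax, val in zip("xyz", vec):
            rec[f"{name}{ax}" if name != "x" else f"{ax}_m"] = float(val)
    for ax, val in zip("xyzw", state.quaternion):
        rec[f"q{ax}"] = float(val)
    for src, load in (
        ("fluid", loads.fluid), ("bonds", loads.bonds),
        ("rep", loads.repulsion), ("ext", loads.external),
    ):
        for ax, val in zip("xyz", load.force):
            rec[f"F_{src}_{ax}_N"] = float(val)
    for ax, val in zip("xyz", loads.repulsion.torque):
        rec[f"T_rep_{ax}_Nm"] = float(val)
    for ax, f_val, t_val in zip("xyz", loads.force, loads.torque):
        rec[f"F_total_{ax}_N"] = float(f_val)
        rec[f"T_total_{ax}_Nm"] = float(t_val)
    rec["n_bonds"] = n_bonds
    rec["min_separation_m"] = min_sep
    rec["n_pairs_gated"] = n_pairs_gated
    return rec


@dataclasses.dataclass
class SimResult:
    config: SimulationConfig
    status: str
    tc_state: RigidBodyState
    pmn_state: RigidBodyState
    bonds: list
    records: list
    bond_events: list
    scenario: Scenario

    def trajectory_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def bonds_frame(self) -> pd.DataFrame:
        cols = ["step", "time_s", "event", "tc_face", "pmn_face", "bond_type",
                "d_face_m", "d_kin_m", "force_N"]
        return pd.DataFrame(self.bond_events, columns=cols)

    def header_block(self) -> str:
        return (
            f"# adhesim {__version__}\n"
            f"# config_sha256: {self.config.hash()}\n"
            f"# seed: {self.config.run.seed}\n"
            f"# status: {self.status}\n"
            f"# note: {SURROGATE_NOTE}\n"
        )

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_csv(out / "trajectory.csv", self.trajectory_frame(), self.header_block())
        _write_csv(out / "bonds.csv", self.bonds_frame(), self.header_block())
        save_config(self.config, out / "config.toml")
        if self.config.run.write_meshes:
            from .geometry import Pose

            write_off(self.scenario.pmn_mesh, out / "pmn.off", self.pmn_state.pose)
            write_vtk_polydata(self.scenario.pmn_mesh, out / "pmn.vtk", self.pmn_state.pose)
            meshes = out / "meshes"
            meshes.mkdir(exist_ok=True)
            for rec in self.records:  # per-step TC snapshots from logged poses
                pose = Pose(
                    np.array([rec["x_m"], rec["y_m"], rec["z_m"]]),
                    np.array([rec["qx"], rec["qy"], rec["qz"], rec["qw"]]),
                )
                step = rec["step"]
                write_off(self.scenario.tc_mesh, meshes / f"tc_{step:05d}.off", pose)
                write_vtk_polydata(self.scenario.tc_mesh, meshes / f"tc_{step:05d}.vtk", pose)


def _write_csv(path, frame: pd.DataFrame, header: str) -> None:
    buf = io.StringIO()
    frame.to_csv(buf, index=False)
    Path(path).write_text(header + buf.getvalue())


# ---------------------------------------------------------------------------
# Command line
# ---------------------------------------------------------------------------

def run_cli(argv=None) -> int:
    import argparse

    parser = argparse.ArgumentParser(
        prog="adhesim",
        description="Adhesive-dynamics simulation of a melanoma cell meeting a "
        "substrate-adherent neutrophil (stochastic bonds + repulsion + 6DOF).",
    )
    sub = parser.add_subparsers(dest="command", required=True)

    p_run = sub.add_parser("run", help="run a full simulation")
    p_run.add_argument("--config", help="TOML configuration (omit for the default scenario)")
    p_run.add_argument("--seed", type=int)
    p_run.add_argument("--steps", type=int)
    p_run.add_argument("--out", help="output directory")
    p_run.add_argument("--no-repulsion", action="store_true")
    p_run.add_argument("--no-adhesion", action="store_true")
    p_run.add_argument("--force-bonds", action="store_true",
                       help="force bond formation probability to 1 (verification)")

    p_fix = sub.add_parser("fixture", help="planar verification fixture (forced bonding)")
    p_fix.add_argument("--n-faces", type=int, default=8)
    p_fix.add_argument("--face-area-um2", type=float, default=1.0)
    p_fix.add_argument("--gap-um", type=float, default=0.06)
    p_fix.add_argument("--tc-per-face", type=float, default=3.0)
    p_fix.add_argument("--pmn-per-face", type=float, default=1000.0)
    p_fix.add_argument("--seed", type=int, default=0)

    p_cmp = sub.add_parser("compare-meshes", help="coarse vs fine bond-count experiment")
    p_cmp.add_argument("--seeds", type=int, default=60)
    p_cmp.add_argument("--coarse-um", type=float, default=1.5)
    p_cmp.add_argument("--fine-um", type=float, default=0.5)
    p_cmp.add_argument("--seed", type=int, default=0)
    p_cmp.add_argument("--out", help="CSV file for the summary table")

    p_app = sub.add_parser("approach", help="driven approach with and without repulsion")
    p_app.add_argument("--steps", type=int, default=900)
    p_app.add_argument("--load-n", type=float, default=1.0e-11)
    p_app.add_argument("--seed", type=int, default=0)
    p_app.add_argument("--out", help="output directory")

    try:
        args = parser.parse_args(argv)
    except SystemExit as exc:
        return int(exc.code or 0)

    if args.command == "run":
        return _cmd_run(args)
    if args.command == "fixture":
        return _cmd_fixture(args)
    if args.command == "compare-meshes":
        return _cmd_compare(args)
    return _cmd_approach(args)


def _cmd_run(args) -> int:
    from .dynamics import simulate

    if args.config:
        path = Path(args.config)
        if not path.exists():
            print(f"error: config file not found: {path}", file=sys.stderr)
            return 1
        try:
            cfg = load_config(path)
        except (ConfigError, tomllib.TOMLDecodeError) as exc:
            print(f"error: invalid config: {exc}", file=sys.stderr)
            return 1
    else:
        cfg = SimulationConfig()
    if args.seed is not None:
        cfg.run.seed = args.seed
    if args.steps is not None:
        cfg.run.n_steps = args.steps
    if args.out is not None:
        cfg.run.out_dir = args.out
    if args.no_repulsion:
        cfg.run.repulsion = False
    if args.no_adhesion:
        cfg.run.adhesion = False
    if args.force_bonds:
        cfg.run.forced_probability = 1.0
    cfg.validate()
    result = simulate(cfg)
    last = result.records[-1] if result.records else {}
    print(
        f"status={result.status} steps={len(result.records)} "
        f"n_bonds={last.get('n_bonds', 0)} "
        f"min_separation_um={last.get('min_separation_m', float('nan')) / UM:.4g}"
    )
    if cfg.run.out_dir:
        result.write(cfg.run.out_dir)
        print(f"wrote {cfg.run.out_dir}/trajectory.csv and bonds.csv")
    return 0


def _cmd_fixture(args) -> int:
    from . import fixtures

    count, bonds = fixtures.planar_forced_bonding(
        n_faces=args.n_faces,
        face_area=args.face_area_um2 * UM ** 2,
        gap=args.gap_um * UM,
        tc_per_face=args.tc_per_face,
        pmn_per_face=args.pmn_per_face,
        seed=args.seed,
    )
    print(f"planar fixture: {args.n_faces} opposing face pairs, forced P=1")
    print(f"bonds formed: {count}")
    return 0


def _cmd_compare(args) -> int:
    from . import fixtures

    table = fixtures.mesh_independence_experiment(
        n_seeds=args.seeds,
        coarse_max_element=args.coarse_um * UM,
        fine_max_element=args.fine_um * UM,
        seed=args.seed,
    )
    print(table.to_string(index=False))
    diff = abs(table["mean_bonds"].iloc[0] - table["mean_bonds"].iloc[1])
    two_se = 2.0 * float(np.hypot(*table["se_bonds"]))
    print(f"difference of means: {diff:.3f} (2 x combined SE = {two_se:.3f})")
    if args.out:
        Path(args.out).parent.mkdir(parents=True, exist_ok=True)
        _write_csv(args.out, table, _experiment_header(args.seed))
    return 0


def _cmd_approach(args) -> int:
    from . import fixtures

    rows = []
    for repulsion in (True, False):
        res = fixtures.driven_approach(
            load=args.load_n, repulsion=repulsion, n_steps=args.steps, seed=args.seed
        )
        rows.append(res)
        tag = "with" if repulsion else "without"
        print(
            f"{tag} repulsion: min face separation "
            f"{res['min_separation_m'] / UM:.4g} um, "
            f"min axial surface gap {res['min_axial_gap_m'] / UM:.4g} um, "
            f"interpenetrated={res['interpenetrated']}"
        )
        if args.out:
            out = Path(args.out)
            out.mkdir(parents=True, exist_ok=True)
            _write_csv(
                out / f"approach_{'rep' if repulsion else 'norep'}.csv",
                pd.DataFrame(res["trajectory"]),
                _experiment_header(args.seed),
            )
    return 0


def _experiment_header(seed) -> str:
    return (
        f"# adhesim {__version__}\n"
        f"# seed: {seed}\n"
        f"# note: {SURROGATE_NOTE}\n"
    )


def main() -> None:  # console entry point
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(name)s: %(message)s")
    sys.exit(run_cli(sys.argv[1:]))
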