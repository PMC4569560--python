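"""Rigid-body dynamics, load aggregation, and the analytic flow-load surrogate.

The tumor cell is a rigid, uniform-density sphere moving with six degrees of
freedom; the neutrophil is rigid and fixed to the substrate (its net load is
defined to be zero). Forces and torques from three sources — fluid, bonds and
repulsion (plus an optional external driving load for controlled
experiments) — are aggregated at the body centroid and fed to the integrator.

Flow surrogate
--------------
Instead of solving the Navier-Stokes equations and integrating surface
stresses, hydrodynamic loads on the spherical TC come from an analytic
near-wall linear-shear model: Stokes drag toward the local fluid velocity
``u_x(y) = G*y`` and a shear-induced torque toward the local half-vorticity
rotation rate, each amplified by a wall-proximity correction factor
interpolated from a built-in monotone table in ``h/r`` (>= 1, tending to 1
far from the wall). This is a deliberate, clearly-stamped surrogate: the
biochemical model is solver-agnostic, and the surrogate supplies physically
reasonable quasi-steady loads at desk scale.

Integration
-----------
Default mode is overdamped (quasi-steady): at cell scale the inertial
relaxation time (~m / 6 pi mu r ~ microseconds) is far below any usable
timestep, so velocities are set by instantaneous force balance between drag
and the other loads, then positions advance by dt. A semi-implicit Euler
"newtonian" mode integrates Newton's second law directly for fidelity to the
printed equations of motion.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy.spatial.transform import Rotation

from .geometry import Load, Pose

logger = logging.getLogger(__name__)


class DynamicsError(RuntimeError):
    pass


class WallContactError(DynamicsError):
    """Sphere centre at or below one radius above the substrate."""


@dataclasses.dataclass
class RigidBodyState:
    """Pose, velocities and inertial properties of one rigid body."""

    position: np.ndarray  # centroid [m]
    quaternion: np.ndarray  # scalar-last unit quaternion
    velocity: np.ndarray  # [m/s]
    angular_velocity: np.ndarray  # [rad/s]
    mass: float  # [kg]
    inertia: float  # principal moment, sphere: (2/5) m r^2 [kg m^2]
    fixed: bool = False

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        self.quaternion = np.asarray(self.quaternion, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        self.angular_velocity = np.asarray(self.angular_velocity, dtype=float)
        self.renormalize()

    @staticmethod
    def sphere(position, radius: float, density: float, fixed: bool = False) -> "RigidBodyState":
        mass = density * 4.0 / 3.0 * np.pi * radius ** 3
        return RigidBodyState(
            position=np.asarray(position, dtype=float),
            quaternion=np.array([0.0, 0.0, 0.0, 1.0]),
            velocity=np.zeros(3),
            angular_velocity=np.zeros(3),
            mass=mass,
            inertia=0.4 * mass * radius ** 2,
            fixed=fixed,
        )

    @staticmethod
    def fixed_body(position) -> "RigidBodyState":
        return RigidBodyState(
            position=np.asarray(position, dtype=float),
            quaternion=np.array([0.0, 0.0, 0.0, 1.0]),
            velocity=np.zeros(3),
            angular_velocity=np.zeros(3),
            mass=np.inf,
            inertia=np.inf,
            fixed=True,
        )

    def renormalize(self) -> None:
        n = np.linalg.norm(self.quaternion)
        if not np.isfinite(n) or n == 0.0:
            raise DynamicsError("non-finite quaternion")
        self.quaternion = self.quaternion / n

    @property
    def pose(self) -> Pose:
        return Pose(self.position, self.quaternion)

    def copy(self) -> "RigidBodyState":
        return dataclasses.replace(
            self,
            position=self.position.copy(),
            quaternion=self.quaternion.copy(),
            velocity=self.velocity.copy(),
            angular_velocity=self.angular_velocity.copy(),
        )


@dataclasses.dataclass
class LoadSet:
    """Per-source loads at the body centroid; totals are the exact
    componentwise sums (fluid + bonds + repulsion + external)."""

    fluid: Load
    bonds: Load
    repulsion: Load
    external: Load = dataclasses.field(default_factory=Load.zero)

    @property
    def force(self) -> np.ndarray:
        return self.fluid.force + self.bonds.force + self.repulsion.force + self.external.force

    @property
    def torque(self) -> np.ndarray:
        return (
            self.fluid.torque + self.bonds.torque + self.repulsion.torque + self.external.torque
        )

    @property
    def non_fluid_force(self) -> np.ndarray:
        return self.bonds.force + self.repulsion.force + self.external.force

    @property
    def non_fluid_torque(self) -> np.ndarray:
        return self.bonds.torque + self.repulsion.torque + self.external.torque


@dataclasses.dataclass(frozen=True)
class FlowEnvironment:
    """Linear near-wall shear flow: u_x(y) = G*y, substrate at y = 0."""

    shear_rate: float = 100.0  # G [1/s]
    viscosity: float = 1.0e-3  # mu [Pa s]
    fluid_density: float = 1000.0  # [kg/m^3]
    wall_axis: int = 1  # y

    def __post_init__(self):
        if not self.viscosity > 0.0:
            raise ValueError("viscosity must be positive")
        if self.wall_axis != 1:
            raise ValueError("only a y-normal substrate is supported")

    def fluid_velocity(self, position: np.ndarray) -> np.ndarray:
        return np.array([self.shear_rate * position[1], 0.0, 0.0])

    def half_vorticity(self) -> np.ndarray:
        """Local rigid rotation rate of the shear flow: -G/2 about z."""
        return np.array([0.0, 0.0, -0.5 * self.shear_rate])


# Near-wall amplification of Stokes drag (translation) and rotational
# resistance for a sphere at height h above a plane wall, tabulated against
# h/r. Monotone decreasing toward 1; constant extrapolation at the ends.
_HR_TABLE = np.array([1.05, 1.1, 1.2, 1.5, 2.0, 3.0, 5.0, 10.0])
_CT_TABLE = np.array([2.30, 2.00, 1.76, 1.43, 1.27, 1.14, 1.06, 1.02])
_CR_TABLE = np.array([1.30, 1.25, 1.19, 1.10, 1.05, 1.02, 1.01, 1.00])


def wall_correction_translation(h_over_r: float) -> float:
    return float(np.interp(h_over_r, _HR_TABLE, _CT_TABLE))


def wall_correction_rotation(h_over_r: float) -> float:
    return float(np.interp(h_over_r, _HR_TABLE, _CR_TABLE))


def drag_coefficients(
    state: RigidBodyState, env: FlowEnvironment, radius: float
) -> tuple[float, float]:
    """(translational, rotational) drag coefficients [N s/m, N m s] for the
    sphere at its current height, wall corrections included."""
    h = float(state.position[env.wall_axis])
    if h <= radius:
        raise WallContactError(f"sphere centre height {h:g} m <= radius {radius:g} m")
    c_t = wall_correction_translation(h / radius)
    c_r = wall_correction_rotation(h / radius)
    return 6.0 * np.pi * env.viscosity * radius * c_t, 8.0 * np.pi * env.viscosity * radius ** 3 * c_r


def flow_loads(state: RigidBodyState, env: FlowEnvironment, radius: float) -> Load:
    """Surrogate hydrodynamic load on the spherical TC.

    Drag toward the local fluid velocity and torque toward the local
    half-vorticity spin; both vanish when the sphere advects and rotates with
    the flow.
    """
    gamma_t, gamma_r = drag_coefficients(state, env, radius)
    u = env.fluid_velocity(state.position)
    force = gamma_t * (u - state.velocity)
    torque = gamma_r * (env.half_vorticity() - state.angular_velocity)
    return Load(force, torque)


def total_loads(
    flow: Load, bonds: Load, rep: Load, external: Load | None = None
) -> LoadSet:
    """Assemble the per-source loads; totals are exact componentwise sums."""
    return LoadSet(
        fluid=flow,
        bonds=bonds,
        repulsion=rep,
        external=external if external is not None else Load.zero(),
    )


def step_6dof(
    state: RigidBodyState,
    loads: LoadSet,
    dt: float,
    mode: str = "overdamped",
    env: FlowEnvironment | None = None,
    radius: float | None = None,
) -> RigidBodyState:
    """Advance one rigid body by one timestep.

    overdamped (default): translational and angular velocities are set so the
    surrogate drag balances the non-fluid loads (quasi-steady force balance),
    then the pose advances by dt. Requires ``env`` and ``radius``.

    newtonian: semi-implicit Euler on Newton's second law using the total
    loads as given (including whatever fluid load the caller computed).
    """
    if not dt > 0.0:
        raise DynamicsError("dt must be positive")
    if state.fixed:
        raise DynamicsError("cannot step a fixed body")
    if not (np.all(np.isfinite(loads.force)) and np.all(np.isfinite(loads.torque))):
        raise DynamicsError(
            f"non-finite loads: F={loads.force}, T={loads.torque}, "
            f"position={state.position}"
        )
    new = state.copy()
    if mode == "overdamped":
        if env is None or radius is None:
            raise DynamicsError("overdamped mode needs a FlowEnvironment and radius")
        gamma_t, gamma_r = drag_coefficients(state, env, radius)
        new.velocity = env.fluid_velocity(state.position) + loads.non_fluid_force / gamma_t
        new.angular_velocity = env.half_vorticity() + loads.non_fluid_torque / gamma_r
    elif mode == "newtonian":
        new.velocity = state.velocity + loads.force / state.mass * dt
        new.angular_velocity = state.angular_velocity + loads.torque / state.inertia * dt
    else:
        raise DynamicsError("mode must be 'overdamped' or 'newtonian'")
    new.position = state.position + new.velocity * dt
    rot = Rotation.from_rotvec(new.angular_velocity * dt) * Rotation.from_quat(state.quaternion)
    new.quaternion = rot.as_quat()
    new.renormalize()
    return new


def simulate(config, rng: np.random.Generator | None = None):
    """Run the full coupled simulation described by a SimulationConfig.

    Per step: update world-frame geometry, compute repulsion loads, test
    existing bonds for breakage, attempt new bond formation, compute bond
    loads, compute flow loads, aggregate, and advance the TC 6DOF state.
    Deterministic for a fixed config and seed. Returns a SimResult.
    """
    from .sim_io import build_scenario, SimResult, trajectory_record  # lazy: avoid cycle

    scn = build_scenario(config)
    if rng is None:
        rng = np.random.default_rng(config.run.seed)
    tc_state = scn.tc_state
    bonds: list = []
    records: list[dict] = []
    bond_events: list[dict] = []
    status = "completed"

    from . import adhesion as adh
    from . import repulsion as rep
    from .geometry import face_properties, gated_face_pairs

    pmn_faces = face_properties(scn.pmn_mesh, scn.pmn_state.pose, body_id="pmn")
    gate_cut = max((bt.gate for bt in scn.bond_types), default=0.0) + scn.kin_env.eps_mv

    for step in range(config.run.n_steps):
        t = step * scn.kin_env.dt
        tc_faces = face_properties(scn.tc_mesh, tc_state.pose, body_id="tc")
        rep_pairs = gated_face_pairs(tc_faces, pmn_faces, scn.rep_params.eps)
        adh_pairs = (
            rep_pairs
            if gate_cut <= scn.rep_params.eps
            else gated_face_pairs(tc_faces, pmn_faces, gate_cut)
        )

        if config.run.repulsion:
            rep_load, _ = rep.repulsion_loads(rep_pairs, tc_faces, pmn_faces, scn.rep_params)
        else:
            rep_load = Load.zero()

        if config.run.adhesion:
            tc_pos = {int(f): tc_faces.centroids[k] for k, f in enumerate(tc_faces.face_ids)}
            pmn_pos = {int(f): pmn_faces.centroids[k] for k, f in enumerate(pmn_faces.face_ids)}
            bonds, broken = adh.breakage_step(
                bonds, tc_faces, pmn_faces, scn.tc_ledger, scn.pmn_ledger,
                scn.bond_types, scn.kin_env, rng,
            )
            for b in broken:
                bond_events.append(_bond_event(step, t, "break", b, tc_pos, pmn_pos, scn))
            for b in bonds:
                bond_events.append(_bond_event(step, t, "survive", b, tc_pos, pmn_pos, scn))
            d_centroid = float(np.linalg.norm(scn.pmn_state.position - tc_state.position))
            new_bonds = adh.formation_step(
                adh_pairs, scn.tc_ledger, scn.pmn_ledger, scn.bond_types, scn.kin_env,
                rng, time=t, forced_probability=config.run.forced_probability,
                d_centroid=d_centroid,
            )
            for b in new_bonds:
                bond_events.append(_bond_event(step, t, "form", b, tc_pos, pmn_pos, scn))
            bonds = bonds + new_bonds
            bond_load, _ = adh.bond_loads(bonds, tc_faces, pmn_faces, scn.bond_types, scn.kin_env)
        else:
            bond_load = Load.zero()

        fluid_load = (
            flow_loads(tc_state, scn.flow_env, scn.tc_radius)
            if config.run.dynamics_mode == "newtonian"
            else Load.zero()
        )
        loads = total_loads(fluid_load, bond_load, rep_load, external=scn.external_load)

        min_sep = float(rep_pairs.distance.min()) if len(rep_pairs) else np.inf
        records.append(
            trajectory_record(step, t, tc_state, loads, len(bonds), min_sep, len(rep_pairs))
        )
        logger.info(
            "step %d: n_bonds=%d min_sep=%.3g m |F|=%.3g N",
            step, len(bonds), min_sep, float(np.linalg.norm(loads.force)),
        )

        tc_state = step_6dof(
            tc_state, loads, scn.kin_env.dt, mode=config.run.dynamics_mode,
            env=scn.flow_env, radius=scn.tc_radius,
        )
        if not _inside_domain(tc_state.position, scn.domain):
            status = "exited_domain"
            logger.info("TC centroid left the domain at step %d; terminating", step)
            break

    return SimResult(
        config=config,
        status=status,
        tc_state=tc_state,
        pmn_state=scn.pmn_state,
        bonds=bonds,
        records=records,
        bond_events=bond_events,
        scenario=scn,
    )


def _inside_domain(position: np.ndarray, domain: np.ndarray) -> bool:
    return bool(np.all(position >= 0.0) and np.all(position <= domain))


def _bond_event(step, t, event, bond, tc_pos, pmn_pos, scn) -> dict:
    from . import adhesion as adh

    d_face = float(np.linalg.norm(pmn_pos[bond.pmn_face_id] - tc_pos[bond.tc_face_id]))
    bt = next(b for b in scn.bond_types if b.name == bond.bond_type)
    return {
        "step": step,
        "time_s": t,
        "event": event,
        "tc_face": bond.tc_face_id,
        "pmn_face": bond.pmn_face_id,
        "bond_type": bond.bond_type,
        "d_face_m": d_face,
        "d_kin_m": adh.bond_coordinate(d_face, scn.kin_env),
        "force_N": adh.bond_force_scalar(d_face, bt, scn.kin_env),
    }
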