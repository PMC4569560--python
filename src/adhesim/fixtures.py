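"""Verification fixtures and scripted experiments.

These isolate the biochemical machinery from meshing and flow, in the spirit
of prototyping the adhesion routine on a bare list of face centroids before
wiring it into a solver: a pair of parallel planar face grids exercises
distance gating, molecule allocation and availability-limited bonding with
the formation probability forced to 1; the mesh-independence experiment
re-runs single-instant bond formation on the same two-cell geometry at a
coarse (1.5 um) and fine (0.5 um) maximum element size; the driven-approach
experiment pushes the tumor cell onto the fixed PMN with a constant load to
measure the separation floor the repulsion model maintains.

Fixture face sets use a zero microvilli standoff so the raw gap distances
feed the kinetics directly.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from . import adhesion as adh
from . import repulsion as rep
from .dynamics import FlowEnvironment, RigidBodyState, step_6dof, total_loads
from .geometry import (
    FaceSet,
    Load,
    cap_for_max_edge,
    face_properties,
    gated_face_pairs,
    make_icosphere,
)

UM = 1.0e-6


# ---------------------------------------------------------------------------
# Planar fixture
# ---------------------------------------------------------------------------

def make_parallel_planes(
    n_faces_per_side: int, face_area: float, gap: float
) -> tuple[FaceSet, FaceSet]:
    """Two co-registered rows of square planar faces separated by ``gap``.

    TC faces sit at ``y = gap`` facing down, PMN faces at ``y = 0`` facing up,
    centroids spaced by the face edge length along x, so directly opposing
    pairs are exactly ``gap`` apart and the full pair-distance matrix is
    n x n.
    """
    if n_faces_per_side < 1:
        raise ValueError("need at least one face per side")
    if not (face_area > 0.0 and gap > 0.0):
        raise ValueError("face_area and gap must be positive")
    w = math.sqrt(face_area)
    x = w * np.arange(n_faces_per_side)
    n = n_faces_per_side

    def plane(y: float, normal_y: float, body_id: str) -> FaceSet:
        centroids = np.stack([x, np.full(n, y), np.zeros(n)], axis=1)
        body_centroid = centroids.mean(axis=0)
        return FaceSet(
            body_id=body_id,
            face_ids=np.arange(n),
            centroids=centroids,
            areas=np.full(n, face_area),
            normals=np.tile([0.0, normal_y, 0.0], (n, 1)),
            lever_arms=centroids - body_centroid,
            body_centroid=body_centroid,
        )

    return plane(gap, -1.0, "tc"), plane(0.0, +1.0, "pmn")


def fixture_environment(dt: float = 1.0e-3) -> adh.KineticEnvironment:
    """Kinetic environment with zero microvilli standoff (raw gap distances)."""
    return adh.KineticEnvironment(dt=dt, eps_mv=0.0)


def default_bond_types() -> list[adh.BondTypeParams]:
    """The tabulated LFA-1/ICAM-1 and Mac-1/ICAM-1 parameter sets."""
    return [
        adh.BondTypeParams("ICAM-1", "LFA-1", kon0=3000.0, koff0=0.3,
                           spring=2.0e-3, transition_spring=1.0e-3,
                           eq_length=0.05 * UM),
        adh.BondTypeParams("ICAM-1", "Mac-1", kon0=3000.0, koff0=0.29,
                           spring=2.0e-3, transition_spring=1.0e-3,
                           eq_length=0.05 * UM),
    ]


def uniform_ledger(faces: FaceSet, species: list[str], per_face: float) -> adh.MoleculeLedger:
    counts = np.full((faces.n_faces, len(species)), per_face, dtype=float)
    return adh.MoleculeLedger(faces.face_ids, species, counts)


def forced_bonding_run(
    tc_faces: FaceSet,
    pmn_faces: FaceSet,
    tc_ledger: adh.MoleculeLedger,
    pmn_ledger: adh.MoleculeLedger,
    bond_types: list[adh.BondTypeParams],
    env: adh.KineticEnvironment | None = None,
    seed: int = 0,
    probability: float = 1.0,
    cutoff: float | None = None,
) -> tuple[int, list[adh.Bond]]:
    """Deterministic availability-limited bonding sweep with forced P.

    With integer molecule counts and P = 1 the outcome is fully determined by
    availability on both sides; a molecule engaged by one bond type is not
    available to the next (the double-counting fix).
    """
    env = env or fixture_environment()
    if cutoff is None:
        cutoff = env.eps_mv + max(bt.gate for bt in bond_types)
    pairs = gated_face_pairs(tc_faces, pmn_faces, cutoff)
    rng = np.random.default_rng(seed)
    bonds = adh.formation_step(
        pairs, tc_ledger, pmn_ledger, bond_types, env, rng,
        forced_probability=probability,
    )
    return len(bonds), bonds


def planar_forced_bonding(
    n_faces: int = 8,
    face_area: float = 1.0 * UM ** 2,
    gap: float = 0.06 * UM,
    tc_per_face: float = 3.0,
    pmn_per_face: float = 1000.0,
    seed: int = 0,
) -> tuple[int, list[adh.Bond]]:
    """The eight-face planar verification scenario with forced P = 1."""
    tc_faces, pmn_faces = make_parallel_planes(n_faces, face_area, gap)
    bond_types = default_bond_types()[:1]
    tc_ledger = uniform_ledger(tc_faces, ["ICAM-1"], tc_per_face)
    pmn_ledger = uniform_ledger(pmn_faces, ["LFA-1"], pmn_per_face)
    return forced_bonding_run(
        tc_faces, pmn_faces, tc_ledger, pmn_ledger, bond_types, seed=seed
    )


# ---------------------------------------------------------------------------
# Mesh-independence experiment
# ---------------------------------------------------------------------------

_TABLE3_DENSITIES = {"ICAM-1": 13.0e12, "LFA-1": 45.0e12, "Mac-1": 5.0e12}


def _crop_to_contact(
    tc_faces: FaceSet, pmn_faces: FaceSet, cutoff: float
) -> tuple[FaceSet, FaceSet]:
    """Drop faces that cannot possibly pair within ``cutoff``.

    A pair at distance < cutoff has wall-normal offset < cutoff, so keeping
    TC faces below (max PMN height + cutoff) and PMN faces above (min TC
    height - cutoff) leaves the gated pair set — and the minimum pair
    distance, when it is below cutoff — exactly unchanged.
    """
    def subset(fs: FaceSet, mask: np.ndarray) -> FaceSet:
        return FaceSet(
            body_id=fs.body_id,
            face_ids=fs.face_ids[mask],
            centroids=fs.centroids[mask],
            areas=fs.areas[mask],
            normals=fs.normals[mask],
            lever_arms=fs.lever_arms[mask],
            body_centroid=fs.body_centroid,
        )

    tc_mask = tc_faces.centroids[:, 1] < pmn_faces.centroids[:, 1].max() + cutoff
    tc_crop = subset(tc_faces, tc_mask)
    lo = tc_crop.centroids[:, 1].min() if tc_crop.n_faces else np.inf
    pmn_crop = subset(pmn_faces, pmn_faces.centroids[:, 1] > lo - cutoff)
    return tc_crop, pmn_crop


def make_parallel_plane_grids(
    side_length: float, max_element: float, gap: float
) -> tuple[FaceSet, FaceSet]:
    """Two opposed square n x n grids of square faces covering the same
    ``side_length`` x ``side_length`` contact patch, meshed so the element
    edge is the largest value <= ``max_element`` that tiles the patch exactly.

    The physical geometry (patch size and gap) is identical at every
    resolution; only the discretization changes — the setting for the
    mesh-dependency experiment.
    """
    if not (side_length > 0.0 and max_element > 0.0 and gap > 0.0):
        raise ValueError("side_length, max_element and gap must be positive")
    n = max(1, int(math.ceil(side_length / max_element - 1e-9)))
    w = side_length / n
    face_area = w * w
    coords = (np.arange(n) + 0.5) * w
    xx, zz = np.meshgrid(coords, coords, indexing="ij")
    m = n * n

    def plane(y: float, normal_y: float, body_id: str) -> FaceSet:
        centroids = np.stack(
            [xx.ravel(), np.full(m, y), zz.ravel()], axis=1
        )
        body_centroid = centroids.mean(axis=0)
        return FaceSet(
            body_id=body_id,
            face_ids=np.arange(m),
            centroids=centroids,
            areas=np.full(m, face_area),
            normals=np.tile([0.0, normal_y, 0.0], (m, 1)),
            lever_arms=centroids - body_centroid,
            body_centroid=body_centroid,
        )

    return plane(gap, -1.0, "tc"), plane(0.0, +1.0, "pmn")


def single_instant_bond_count(
    tc_faces: FaceSet,
    pmn_faces: FaceSet,
    env: adh.KineticEnvironment,
    rng: np.random.Generator,
    *,
    bond_types: list[adh.BondTypeParams] | None = None,
    forced_probability: float | None = None,
) -> int:
    """One formation sweep over a fresh ledger pair; returns the bond count.

    Densities are the tabulated surface expressions (ICAM-1 on the TC side,
    LFA-1 and Mac-1 on the PMN side); the correction factor is applied with
    the body-centroid distance, as in a production step.
    """
    bond_types = bond_types or default_bond_types()
    tc_ledger = adh.MoleculeLedger.from_faces(
        tc_faces, [adh.MoleculeSpecies("ICAM-1", _TABLE3_DENSITIES["ICAM-1"], "tc")]
    )
    pmn_ledger = adh.MoleculeLedger.from_faces(
        pmn_faces,
        [
            adh.MoleculeSpecies("LFA-1", _TABLE3_DENSITIES["LFA-1"], "pmn"),
            adh.MoleculeSpecies("Mac-1", _TABLE3_DENSITIES["Mac-1"], "pmn"),
        ],
    )
    cutoff = env.eps_mv + max(bt.gate for bt in bond_types)
    pairs = gated_face_pairs(tc_faces, pmn_faces, cutoff)
    d_centroid = float(np.linalg.norm(tc_faces.body_centroid - pmn_faces.body_centroid))
    bonds = adh.formation_step(
        pairs, tc_ledger, pmn_ledger, bond_types, env, rng,
        forced_probability=forced_probability, d_centroid=d_centroid,
    )
    return len(bonds)


def mesh_independence_experiment(
    n_seeds: int = 60,
    coarse_max_element: float = 1.5 * UM,
    fine_max_element: float = 0.5 * UM,
    side_length: float = 6.0 * UM,
    gap: float = 0.05 * UM,
    dt: float = 1.0e-8,
    seed: int = 0,
    forced_probability: float | None = None,
) -> pd.DataFrame:
    """Mean single-instant bond count on the same contact patch at a coarse
    (1.5 um) and a fine (0.5 um) element size.

    The geometry is the planar contact fixture: a 6 x 6 um patch pair at the
    equilibrium bond length, where the whole-contact-area formation rate is
    well defined and the discretization correction (global / average local
    k_on) provably removes the element-size dependence of the expected count.
    The tabulated densities and kinetic constants are used as-is; the
    verification timestep is chosen short enough that every single-draw
    probability is small, the regime the one-draw-per-molecule Bernoulli
    scheme is built for. Reports mean +- SE per resolution over ``n_seeds``
    independent sweeps; resolution independence holds when the means agree
    within two combined standard errors.
    """
    if n_seeds < 2:
        raise ValueError("need at least 2 seeds for a standard error")
    env = fixture_environment(dt=dt)
    rows = []
    for label, max_el in (("coarse", coarse_max_element), ("fine", fine_max_element)):
        tc_faces, pmn_faces = make_parallel_plane_grids(side_length, max_el, gap)
        counts = np.empty(n_seeds)
        for i in range(n_seeds):
            rng = np.random.default_rng(np.random.SeedSequence([seed, i]))
            counts[i] = single_instant_bond_count(
                tc_faces, pmn_faces, env, rng, forced_probability=forced_probability
            )
        rows.append(
            {
                "resolution": label,
                "max_element_um": max_el / UM,
                "n_tc_faces": tc_faces.n_faces,
                "n_pmn_faces": pmn_faces.n_faces,
                "n_seeds": n_seeds,
                "mean_bonds": counts.mean(),
                "se_bonds": counts.std(ddof=1) / math.sqrt(n_seeds),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Driven-approach experiment
# ---------------------------------------------------------------------------

def driven_approach(
    load: float = 1.0e-11,
    initial_gap: float = 2.0 * UM,
    repulsion: bool = True,
    repulsion_params: rep.RepulsionParams | None = None,
    n_steps: int = 900,
    dt: float = 3.0e-5,  # keeps mobility * contact stiffness * dt < 1 (no limit cycle)
    tc_radius: float = 4.0 * UM,
    tc_subdivisions: int = 3,
    cap_base: float = 5.0 * UM,
    cap_height: float = 5.0 * UM,
    cap_max_element: float = 1.0 * UM,
    seed: int = 0,
) -> dict:
    """Push the tumor sphere onto the fixed PMN cap with a constant wall-ward
    load, adhesion off, and record the separation history.

    Overdamped integration in a quiescent fluid (shear rate 0): each step the
    velocity balances the external load plus repulsion against the surrogate
    drag. Returns the minimum over time of the smallest face-pair separation,
    the minimum axial surface gap (negative = interpenetration), and the
    per-step trajectory.
    """
    params = repulsion_params or rep.RepulsionParams()
    tc_mesh = make_icosphere(tc_radius, tc_subdivisions)
    cap_raw = cap_for_max_edge(cap_base, cap_height, cap_max_element)
    com = cap_raw.volume_centroid()
    pmn_mesh = cap_raw.recentred()
    pmn_state = RigidBodyState.fixed_body(np.array([0.0, com[1], 0.0]))
    pmn_faces = face_properties(pmn_mesh, pmn_state.pose, "pmn")

    start_y = cap_height + initial_gap + tc_radius
    tc_state = RigidBodyState.sphere(np.array([0.0, start_y, 0.0]), tc_radius, 1050.0)
    flow_env = FlowEnvironment(shear_rate=0.0)
    external = Load(np.array([0.0, -load, 0.0]), np.zeros(3))

    min_sep = np.inf
    min_axial = np.inf
    trajectory = []
    for step in range(n_steps):
        tc_faces = face_properties(tc_mesh, tc_state.pose, "tc")
        tc_near, pmn_near = _crop_to_contact(tc_faces, pmn_faces, 4.0 * UM)
        if tc_near.n_faces and pmn_near.n_faces:
            step_min = float(cdist(tc_near.centroids, pmn_near.centroids).min())
        else:
            step_min = np.inf
        step_min = min(step_min, 4.0 * UM)  # crop bound: larger gaps saturate
        axial_gap = float(tc_state.position[1] - tc_radius - cap_height)
        min_sep = min(min_sep, step_min)
        min_axial = min(min_axial, axial_gap)
        if repulsion and tc_near.n_faces and pmn_near.n_faces:
            pairs = gated_face_pairs(tc_near, pmn_near, params.eps)
            rep_load, _ = rep.repulsion_loads(pairs, tc_near, pmn_near, params)
        else:
            rep_load = Load.zero()
        loads = total_loads(Load.zero(), Load.zero(), rep_load, external=external)
        trajectory.append(
            {
                "step": step,
                "time_s": step * dt,
                "y_m": float(tc_state.position[1]),
                "min_separation_m": step_min,
                "axial_gap_m": axial_gap,
                "F_rep_y_N": float(rep_load.force[1]),
            }
        )
        if axial_gap < -1.0 * UM:  # deep interpenetration: nothing more to learn
            break
        tc_state = step_6dof(tc_state, loads, dt, mode="overdamped",
                             env=flow_env, radius=tc_radius)
    settled = (
        len(trajectory) >= 2
        and abs(trajectory[-1]["y_m"] - trajectory[-2]["y_m"]) < 1.0e-12
    )
    return {
        "min_separation_m": min_sep,
        "min_axial_gap_m": min_axial,
        "final_separation_m": trajectory[-1]["min_separation_m"] if trajectory else np.inf,
        "interpenetrated": min_axial < 0.05 * UM,
        "settled": settled,
        "n_steps_run": len(trajectory),
        "trajectory": trajectory,
    }
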