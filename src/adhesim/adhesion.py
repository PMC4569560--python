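"""Localized stochastic receptor-ligand bond kinetics.

The melanoma cell (TC) expresses ICAM-1; the neutrophil (PMN) expresses the
beta-2 integrins LFA-1 and Mac-1. Molecules are distributed uniformly over
each cell surface, so a mesh face of area ``A_L`` carries ``n_density * A_L``
molecules — deliberately *not* rounded, since rounding would bias the surface
distribution; the fractional remainder takes part in bonding with a
proportionally reduced probability.

Per gated face pair the formation rate follows the Bell/Dembo form

    k_on  = k_on0 * (available partner molecules) * exp(-s_ts (d-lambda)^2 / 2 k_b T)
    k_off = k_off0 * exp((s - s_ts)(d-lambda)^2 / 2 k_b T)

where ``d`` is the bond coordinate: the face-centroid separation minus a
microvilli standoff, because adhesion molecules are taken to sit at the tips
of fully extended microvilli. Each candidate bond is tested once per step
against ``P = 1 - exp(-rate * dt)`` with a uniform random draw; a per-face,
per-species availability ledger prevents a molecule from being double-booked
across bond types in the same step and is conserved exactly as bonds form and
break.

Because per-face rates on a discretized surface are systematically smaller
than the single whole-contact-area rate, local rates are rescaled by a
correction factor (global k_on / mean local k_on) so that the gated-face mean
of corrected rates matches the global value — this is what makes bond counts
mesh-resolution independent.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Sequence

import numpy as np

from .geometry import FacePairs, FaceSet, Load

logger = logging.getLogger(__name__)

BOLTZMANN = 1.380649e-23  # J/K


class LedgerError(RuntimeError):
    """Molecule bookkeeping was driven into an inconsistent state."""


@dataclasses.dataclass(frozen=True)
class MoleculeSpecies:
    """One adhesion molecule type on one body."""

    name: str
    density: float  # surface density [molecules / m^2]
    body: str  # "tc" or "pmn"

    def __post_init__(self):
        if self.density < 0.0:
            raise ValueError("molecule surface density must be >= 0")
        if self.body not in ("tc", "pmn"):
            raise ValueError("species body must be 'tc' or 'pmn'")


@dataclasses.dataclass(frozen=True)
class BondTypeParams:
    """Kinetic and spring constants for one TC-species/PMN-species pair.

    ``kon0`` is treated as a rate per available partner molecule [1/s]; the
    formation rate is ``kon0`` times the partner face's available count.
    ``spring`` (s) > ``transition_spring`` (s_ts) gives slip-bond behaviour:
    strained bonds dissociate faster.
    """

    tc_species: str
    pmn_species: str
    kon0: float  # [1/s per available molecule]
    koff0: float  # [1/s]
    spring: float  # s [N/m]
    transition_spring: float  # s_ts [N/m]
    eq_length: float  # lambda [m]

    def __post_init__(self):
        for field in ("kon0", "koff0", "spring", "transition_spring", "eq_length"):
            if not getattr(self, field) > 0.0:
                raise ValueError(f"bond parameter {field} must be positive")

    @property
    def name(self) -> str:
        return f"{self.pmn_species}-{self.tc_species}"

    @property
    def gate(self) -> float:
        """Formation gate width: bond coordinate must lie in (0, 2*lambda)."""
        return 2.0 * self.eq_length


@dataclasses.dataclass(frozen=True)
class KineticEnvironment:
    """Thermal/temporal context shared by all kinetic evaluations."""

    temperature: float = 310.15  # [K]
    dt: float = 1.0e-3  # timestep [s]
    eps_mv: float = 1.2e-6  # microvilli standoff subtracted from face distances [m]
    k_b: float = BOLTZMANN  # [J/K]

    def __post_init__(self):
        if not self.temperature > 0.0:
            raise ValueError("temperature must be positive")
        if not self.dt > 0.0:
            raise ValueError("timestep must be positive")
        if self.eps_mv < 0.0:
            raise ValueError("microvilli standoff must be >= 0")


@dataclasses.dataclass
class Bond:
    """A formed receptor-ligand bond, persistent until a breakage draw.

    ``tc_consumed``/``pmn_consumed`` record how much availability the bond
    removed from each face (1.0 for a whole molecule; the remaining fraction
    when the face's last, fractional molecule bonded), so conservation of
    ``available + consumed-by-live-bonds`` is exact.
    """

    tc_face_id: int
    pmn_face_id: int
    bond_type: str
    t_formed: float  # [s]
    tc_consumed: float = 1.0
    pmn_consumed: float = 1.0


class MoleculeLedger:
    """Per-face x per-species available molecule counts for one body.

    Counts are non-negative reals (fractional molecules allowed). Indexed by
    stable face id and species name.
    """

    def __init__(self, face_ids: np.ndarray, species: Sequence[str], counts: np.ndarray):
        self.face_ids = np.asarray(face_ids, dtype=np.int64)
        self.species = list(species)
        counts = np.asarray(counts, dtype=float)
        if counts.shape != (len(self.face_ids), len(self.species)):
            raise LedgerError("ledger shape must be (n_faces, n_species)")
        if np.any(counts < 0.0):
            raise LedgerError("initial molecule counts must be >= 0")
        self._row = {int(fid): k for k, fid in enumerate(self.face_ids)}
        self._col = {name: k for k, name in enumerate(self.species)}
        self.available = counts.copy()
        self.initial = counts.copy()

    @staticmethod
    def from_faces(faces: FaceSet, species: Sequence[MoleculeSpecies]) -> "MoleculeLedger":
        counts = np.stack([molecules_per_face(sp, faces) for sp in species], axis=1) \
            if species else np.zeros((faces.n_faces, 0))
        return MoleculeLedger(faces.face_ids, [sp.name for sp in species], counts)

    def get(self, face_id: int, species: str) -> float:
        return float(self.available[self._row[face_id], self._col[species]])

    def column(self, species: str) -> np.ndarray:
        return self.available[:, self._col[species]]

    def total(self, species: str) -> float:
        return float(self.column(species).sum())

    def take(self, face_id: int, species: str, amount: float) -> None:
        r, c = self._row[face_id], self._col[species]
        if self.available[r, c] + 1e-12 < amount:
            raise LedgerError(
                f"ledger underflow: face {face_id} species {species} "
                f"has {self.available[r, c]:.6g}, tried to take {amount:.6g}"
            )
        self.available[r, c] = max(0.0, self.available[r, c] - amount)

    def put(self, face_id: int, species: str, amount: float) -> None:
        self.available[self._row[face_id], self._col[species]] += amount


# ---------------------------------------------------------------------------
# Elementary kinetic evaluations
# ---------------------------------------------------------------------------

def molecules_per_face(species: MoleculeSpecies, faces: FaceSet) -> np.ndarray:
    """Fractional molecule count per face: ``density * area`` (not rounded)."""
    return species.density * faces.areas


def bond_coordinate(d_face: float, env: KineticEnvironment) -> float:
    """Signed kinetic bond coordinate: face separation minus the microvilli
    standoff. Negative values mean the surfaces are closer than the microvilli
    tips; the formation gate excludes them."""
    return d_face - env.eps_mv


def local_kon(
    d_kin: float, n_avail: float, p: BondTypeParams, env: KineticEnvironment
) -> float:
    """Per-face-pair formation rate [1/s].

    Zero outside the gate ``0 < d_kin < 2*lambda`` (beyond twice the
    equilibrium length the rate is astronomically small anyway; the gate just
    skips the work).
    """
    if n_avail < 0.0:
        raise LedgerError("negative available molecule count")
    if not (0.0 < d_kin < p.gate):
        return 0.0
    strain = d_kin - p.eq_length
    expo = -p.transition_spring * strain * strain / (2.0 * env.k_b * env.temperature)
    return p.kon0 * n_avail * math.exp(expo)


def koff(d_kin: float, p: BondTypeParams, env: KineticEnvironment) -> float:
    """Dissociation rate [1/s]; equals ``koff0`` at ``d_kin = lambda`` and,
    for s > s_ts, grows with strain in either direction (slip bond)."""
    strain = d_kin - p.eq_length
    expo = (p.spring - p.transition_spring) * strain * strain / (
        2.0 * env.k_b * env.temperature
    )
    # far-stretched bonds: rate is astronomically large and the breakage
    # draw is certain either way; clamp to keep exp() finite
    return p.koff0 * math.exp(min(expo, 700.0))


def event_probability(rate: float, dt: float) -> float:
    """Probability that a Poisson event with the given rate fires within dt."""
    if rate < 0.0:
        raise ValueError("rate must be >= 0")
    if not dt > 0.0:
        raise ValueError("dt must be positive")
    return 1.0 - math.exp(-rate * dt)


def correction_factor(
    local_kons: np.ndarray,
    total_partner_molecules: float,
    d_centroid_kin: float,
    p: BondTypeParams,
    env: KineticEnvironment,
) -> float:
    """Discretization correction: global k_on / mean nonzero local k_on.

    The global rate uses the whole-surface molecule total and the cell
    centroid-to-centroid coordinate. After multiplying every local rate by
    the factor, the mean corrected rate over gated faces equals the global
    rate. When the centroid separation is so large that the global exponential
    underflows (the usual case for whole cells micrometres apart), or no local
    rate is nonzero, the factor is forced to 1 and a warning is logged —
    rescaling by a denormal quotient would be noise, not physics.
    """
    local_kons = np.asarray(local_kons, dtype=float)
    nonzero = local_kons[local_kons > 0.0]
    strain = d_centroid_kin - p.eq_length
    expo = -p.transition_spring * strain * strain / (2.0 * env.k_b * env.temperature)
    kon_global = total_partner_molecules * p.kon0 * math.exp(expo)
    if nonzero.size == 0 or kon_global <= 0.0 or not np.isfinite(kon_global):
        logger.warning(
            "k_on correction factor forced to 1 (global=%.3g, gated pairs=%d)",
            kon_global,
            nonzero.size,
        )
        return 1.0
    kon_average = float(nonzero.mean())
    if kon_average <= 0.0:
        logger.warning("k_on correction factor forced to 1 (zero local average)")
        return 1.0
    return kon_global / kon_average


# ---------------------------------------------------------------------------
# Stochastic formation / breakage sweeps
# ---------------------------------------------------------------------------

def formation_step(
    pairs: FacePairs,
    tc_ledger: MoleculeLedger,
    pmn_ledger: MoleculeLedger,
    bond_types: Sequence[BondTypeParams],
    env: KineticEnvironment,
    rng: np.random.Generator,
    *,
    time: float = 0.0,
    forced_probability: float | None = None,
    d_centroid: float | None = None,
    apply_correction: bool = True,
) -> list[Bond]:
    """One stochastic bond-formation sweep over the gated face pairs.

    Structure: two nested species loops (every TC species, then every PMN
    species), so that a molecule engaged by one bond type is unavailable to
    the next within the same step. For each gated pair, the current TC-face
    availability ``c`` yields ``floor(c)`` draws at probability ``P`` plus one
    draw at ``frac(c) * P`` (the fractional-molecule rule). Each formed bond
    consumes availability on both faces and the PMN side caps formation: a
    draw against an exhausted partner face is skipped, and a partner face down
    to its last fractional molecule contributes that fraction (it enters the
    rate through the availability count, and in forced-probability mode scales
    the probability), so no face ever goes negative.

    ``forced_probability`` replaces the rate-derived ``P`` for verification
    runs (e.g. P = 1 availability-limit checks). Ledgers are updated in place;
    the new bonds are returned.
    """
    if forced_probability is not None and not (0.0 <= forced_probability <= 1.0):
        raise ValueError("forced_probability must lie in [0, 1]")
    new_bonds: list[Bond] = []
    d_kin = pairs.distance - env.eps_mv

    for tc_sp in tc_ledger.species:
        for pmn_sp in pmn_ledger.species:
            bt = _lookup(bond_types, tc_sp, pmn_sp)
            if bt is None:
                continue
            factor = 1.0
            if forced_probability is None and apply_correction and d_centroid is not None:
                snapshot = np.array(
                    [
                        local_kon(d_kin[k], pmn_ledger.get(int(pairs.pmn_ids[k]), pmn_sp), bt, env)
                        for k in range(len(pairs))
                    ]
                )
                factor = correction_factor(
                    snapshot,
                    pmn_ledger.total(pmn_sp),
                    bond_coordinate(d_centroid, env),
                    bt,
                    env,
                )
            for k in range(len(pairs)):
                if forced_probability is None and not (0.0 < d_kin[k] < bt.gate):
                    continue
                tc_id = int(pairs.tc_ids[k])
                pmn_id = int(pairs.pmn_ids[k])
                c = tc_ledger.get(tc_id, tc_sp)
                if c <= 0.0:
                    continue
                n_full = int(math.floor(c))
                frac = c - n_full
                for draw in range(n_full + (1 if frac > 1e-12 else 0)):
                    avail_pmn = pmn_ledger.get(pmn_id, pmn_sp)
                    if avail_pmn <= 1e-12:
                        break  # partner availability caps formation
                    w_pmn = min(1.0, avail_pmn)
                    if forced_probability is not None:
                        prob = forced_probability * w_pmn
                    else:
                        # availability (incl. a last fractional partner
                        # molecule) enters through the rate itself
                        rate = factor * local_kon(d_kin[k], avail_pmn, bt, env)
                        prob = event_probability(rate, env.dt)
                    is_fractional = draw == n_full
                    if is_fractional:
                        prob *= frac
                    if rng.random() < prob:
                        w_tc = frac if is_fractional else 1.0
                        tc_ledger.take(tc_id, tc_sp, w_tc)
                        pmn_ledger.take(pmn_id, pmn_sp, w_pmn)
                        new_bonds.append(
                            Bond(
                                tc_id, pmn_id, bt.name, time,
                                tc_consumed=w_tc, pmn_consumed=w_pmn,
                            )
                        )
    return new_bonds


def breakage_step(
    bonds: Sequence[Bond],
    tc_faces: FaceSet,
    pmn_faces: FaceSet,
    tc_ledger: MoleculeLedger,
    pmn_ledger: MoleculeLedger,
    bond_types: Sequence[BondTypeParams],
    env: KineticEnvironment,
    rng: np.random.Generator,
) -> tuple[list[Bond], list[Bond]]:
    """Test every live bond for breakage at the current face positions.

    Each bond is an independent, memoryless event with
    ``P = 1 - exp(-k_off dt)``. Broken bonds return their consumed
    availability to both faces. Returns (survivors, broken).
    """
    by_name = {bt.name: bt for bt in bond_types}
    tc_pos = _centroid_lookup(tc_faces)
    pmn_pos = _centroid_lookup(pmn_faces)
    survivors: list[Bond] = []
    broken: list[Bond] = []
    for bond in bonds:
        bt = by_name[bond.bond_type]
        d_face = _bond_distance(bond, tc_pos, pmn_pos)
        d_kin = bond_coordinate(d_face, env)
        prob = event_probability(koff(d_kin, bt, env), env.dt)
        if rng.random() < prob:
            sp_tc, sp_pmn = bt.tc_species, bt.pmn_species
            tc_ledger.put(bond.tc_face_id, sp_tc, bond.tc_consumed)
            pmn_ledger.put(bond.pmn_face_id, sp_pmn, bond.pmn_consumed)
            broken.append(bond)
        else:
            survivors.append(bond)
    return survivors, broken


def bond_loads(
    bonds: Sequence[Bond],
    tc_faces: FaceSet,
    pmn_faces: FaceSet,
    bond_types: Sequence[BondTypeParams],
    env: KineticEnvironment,
) -> tuple[Load, Load]:
    """Hookean spring loads from all live bonds, aggregated at each body
    centroid. A stretched bond (d_kin > lambda) pulls the bodies together;
    a compressed one pushes them apart. Returns (load on TC, load on PMN)."""
    by_name = {bt.name: bt for bt in bond_types}
    tc_pos = _centroid_lookup(tc_faces)
    pmn_pos = _centroid_lookup(pmn_faces)
    tc_lever = _lever_lookup(tc_faces)
    pmn_lever = _lever_lookup(pmn_faces)
    F_tc = np.zeros(3)
    T_tc = np.zeros(3)
    F_pmn = np.zeros(3)
    T_pmn = np.zeros(3)
    for bond in bonds:
        bt = by_name[bond.bond_type]
        x_tc = tc_pos[bond.tc_face_id]
        x_pmn = pmn_pos[bond.pmn_face_id]
        sep = x_pmn - x_tc
        d_face = float(np.linalg.norm(sep))
        if d_face <= 0.0:
            continue
        e_hat = sep / d_face
        f_scalar = bt.spring * (bond_coordinate(d_face, env) - bt.eq_length)
        f_tc = f_scalar * e_hat  # tensile: toward the PMN
        F_tc += f_tc
        T_tc += np.cross(tc_lever[bond.tc_face_id], f_tc)
        F_pmn += -f_tc
        T_pmn += np.cross(pmn_lever[bond.pmn_face_id], -f_tc)
    return Load(F_tc, T_tc), Load(F_pmn, T_pmn)


def bond_force_scalar(d_face: float, p: BondTypeParams, env: KineticEnvironment) -> float:
    """Signed spring force magnitude s*(d_kin - lambda) for one bond [N]."""
    return p.spring * (bond_coordinate(d_face, env) - p.eq_length)


def expected_new_bonds(
    pairs: FacePairs,
    tc_ledger: MoleculeLedger,
    pmn_ledger: MoleculeLedger,
    bond_types: Sequence[BondTypeParams],
    env: KineticEnvironment,
    *,
    forced_probability: float | None = None,
) -> float:
    """Closed-form expectation of the one-step new-bond count, Sum n*P with
    the fractional-molecule terms, ignoring within-step depletion (valid when
    partner availability is ample). Companion oracle for Monte Carlo checks."""
    total = 0.0
    for tc_sp in tc_ledger.species:
        for pmn_sp in pmn_ledger.species:
            bt = _lookup(bond_types, tc_sp, pmn_sp)
            if bt is None:
                continue
            for k in range(len(pairs)):
                c = tc_ledger.get(int(pairs.tc_ids[k]), tc_sp)
                if forced_probability is not None:
                    prob = forced_probability
                else:
                    d_kin = bond_coordinate(float(pairs.distance[k]), env)
                    rate = local_kon(d_kin, pmn_ledger.get(int(pairs.pmn_ids[k]), pmn_sp), bt, env)
                    prob = event_probability(rate, env.dt)
                total += c * prob
    return total


def conservation_violation(
    tc_ledger: MoleculeLedger,
    pmn_ledger: MoleculeLedger,
    bonds: Sequence[Bond],
    bond_types: Sequence[BondTypeParams],
) -> float:
    """Largest absolute per-face/per-species violation of
    ``available + consumed-by-live-bonds = initial`` across both ledgers."""
    by_name = {bt.name: bt for bt in bond_types}
    worst = 0.0
    for ledger, side in ((tc_ledger, "tc"), (pmn_ledger, "pmn")):
        bound = np.zeros_like(ledger.available)
        for bond in bonds:
            bt = by_name[bond.bond_type]
            if side == "tc":
                r = ledger._row[bond.tc_face_id]
                c = ledger._col[bt.tc_species]
                bound[r, c] += bond.tc_consumed
            else:
                r = ledger._row[bond.pmn_face_id]
                c = ledger._col[bt.pmn_species]
                bound[r, c] += bond.pmn_consumed
        worst = max(worst, float(np.abs(ledger.available + bound - ledger.initial).max()))
    return worst


def _lookup(
    bond_types: Sequence[BondTypeParams], tc_sp: str, pmn_sp: str
) -> BondTypeParams | None:
    for bt in bond_types:
        if bt.tc_species == tc_sp and bt.pmn_species == pmn_sp:
            return bt
    return None


def _centroid_lookup(faces: FaceSet) -> dict[int, np.ndarray]:
    return {int(fid): faces.centroids[k] for k, fid in enumerate(faces.face_ids)}


def _lever_lookup(faces: FaceSet) -> dict[int, np.ndarray]:
    return {int(fid): faces.lever_arms[k] for k, fid in enumerate(faces.face_ids)}


def _bond_distance(bond: Bond, tc_pos, pmn_pos) -> float:
    try:
        return float(np.linalg.norm(pmn_pos[bond.pmn_face_id] - tc_pos[bond.tc_face_id]))
    except KeyError as exc:  # pragma: no cover - state corruption guard
        raise LedgerError(f"bond references unknown face: {exc}") from exc
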