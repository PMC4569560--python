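# Methods

## Scope and modelling stance

`adhesim` simulates the biochemical contact between one rigid melanoma tumor
cell (TC) and one rigid, substrate-fixed neutrophil (PMN) at the level of
individual mesh faces. The contribution it implements is the *localized*
adhesive-dynamics bookkeeping: distance-gated per-face-pair kinetics, a
discretization correction that ties local rates to the whole-contact-area
rate, a per-face/per-species molecule-availability ledger, and the coupling
of the resulting bond and repulsion loads into 6DOF rigid-body motion. What
it deliberately does not implement is a flow solution: hydrodynamic loads
come from an analytic near-wall surrogate (below). Cell deformation,
selectin kinetics, the endothelium, and lateral diffusion of membrane
molecules are out of scope; molecules are fixed in the membrane and
expression levels are constant over the simulated timescales.

## Geometry

Cells are closed triangulated surfaces in a body-fixed frame, mapped to the
world by a pose (translation + unit quaternion); meshes are never
regenerated, so face ids are stable and bonds can be keyed to them across
steps. The TC is an icosphere (radius 4 µm by default); the PMN is a
parametric half-ellipsoid cap (base radius 5 µm, height 5 µm) resting on the
substrate plane y = 0 — a stand-in for the flattened adherent neutrophil
shape. Mesh resolution is specified as a maximum element size; the generator
picks the smallest refinement whose longest edge fits. The coordinate frame
is right-handed with x streamwise and y wall-normal. All internal units are
SI; the configuration layer accepts micrometre conveniences and converts on
load.

Default TC radius and cap dimensions are package choices, not tabulated
values: the source scenario lists only domain size, body centroids (TC at
y = 10 µm, PMN at y = 2.5 µm) and a step count. The 5×5 µm cap places its
volume centroid at 3h/8 ≈ 1.9 µm, near the listed PMN centroid height; the
cap always rests on the substrate, so the configured PMN centroid fixes x
and z only. Both shapes are configurable, and arbitrary OBJ meshes can be
imported.

## Bond kinetics

For a face pair at separation `d_face`, the kinetic coordinate is
`d_kin = d_face − ε_mv`, with the microvilli standoff `ε_mv` defaulting to
the repulsion critical distance (1.2 µm): adhesion molecules are treated as
sitting at the tips of fully extended microvilli, otherwise repulsion would
hold the surfaces ~24 bond lengths apart and no bond could ever form. The
standoff is a modelling device, not measured biophysics; fixture mode sets
`ε_mv = 0` so raw gap distances feed the kinetics. Formation is gated to
`0 < d_kin < 2λ`; beyond twice the equilibrium length the Boltzmann factor
is negligible anyway and the gate only skips work.

Rates follow the Bell/Dembo forms (README). Two unit choices deserve
mention. First, the tabulated `k_on0 = 3000` is treated as a rate per second
per available partner molecule, so `k_on = k_on0 · (available count)`; the
count is re-read from the ledger as the step proceeds, so depletion within a
step lowers subsequent rates. Second, temperature is not tabulated; the
default is body temperature, 310.15 K, with `k_B = 1.380649×10⁻²³ J/K`.

The discretization correction multiplies every local `k_on` by
`k_on,global / k_on,average`, where the global value uses the whole-surface
molecule total and the cell centroid-to-centroid coordinate and the average
runs over gated (nonzero) pairs only. After correction the gated mean equals
the global rate exactly — the identity the tests enforce to 1e-12. When the
centroid separation makes the global exponential underflow (the usual case
for whole cells micrometres apart), the factor is forced to 1 and a warning
is logged; rescaling by a denormal quotient would inject noise, not physics.

## Stochastic formation and breakage

Each step first tests existing bonds for breakage — each an independent,
memoryless event with `P = 1 − exp(−k_off Δt)`; expected bond lifetimes
emerge from repeated draws, not from per-bond age — then sweeps gated pairs
for formation inside two nested species loops (every TC species × every PMN
species). A face with `c` available molecules gets `⌊c⌋` draws at `P` plus
one draw at `frac(c)·P`: allocating `n_L·A_L` molecules per face without
rounding preserves the uniform surface density exactly, and the fractional
draw keeps the expected count equal to `Σ n·P` including the fraction.

Ledger rules, chosen to make conservation exact and resolution-safe:

* A formed bond consumes availability on **both** faces — 1.0 for a whole
  molecule, the remaining fraction when a face's last fractional molecule
  binds — and records what it consumed; breakage returns exactly that.
  The invariant `available + consumed-by-live-bonds = initial` holds to
  1e-9 over thousands of sweeps (it is checked in the suite).
* A molecule engaged by one bond type within a step is immediately
  unavailable to the next (the ledger decrements inline), so ICAM-1 bound by
  LFA-1 cannot also bind Mac-1 in the same sweep.
* The partner (PMN) side caps formation: a draw against an exhausted face is
  skipped, and a face holding only a fraction of a molecule contributes that
  fraction through the rate (or scales a forced probability). Without this,
  fine meshes of a low-density species could never bond at all — at
  5 molecules/µm², a 0.5 µm face carries ~0.5 molecules.
* Gated pairs are processed in ascending (TC face id, PMN face id) order and
  a single seeded generator drives the whole simulation, so runs are
  bit-identical for a fixed config and seed.

Bond loads treat each live bond as a Hookean spring along the line joining
the bonded face centroids, tensile when stretched past λ; forces and torques
(lever arms from face centroid to body centroid) are summed per source.
A fractional-molecule bond exerts the full spring force — the fraction lives
only in the availability accounting.

## Repulsion

The cubic `F(d) = a d + b d³` with the printed constants is, taken literally
along the repulsive direction, *attractive* for `d < d* = √(−a/b) ≈ 0.43 µm`
and repulsive beyond — inverted relative to its stated purpose of preventing
contact. The default convention therefore applies the clamped push
`max(0, −(a d + b d³))`: monotone repulsive below `d*`, zero at and beyond
it, continuous everywhere, zero past the gate `ε = 1.2 µm`. The literal
signed form is retained as `mode="signed"` for fidelity experiments. Under a
constant 1×10⁻¹¹ N approach load the clamped model settles where push
balances load — ≈ 0.37 µm for a single pair (the root-finding oracle in the
tests), ≈ 0.42 µm minimum face separation for the full sphere-on-cap
geometry since many pairs share the load — consistent with the ~0.3 µm
separation the constants were calibrated to maintain.

## Flow surrogate and rigid-body integration

In place of surface integrals of pressure and viscous stress over a solved
flow field, the TC (a uniform-density sphere, `I = 2/5 m r²`) receives
Stokes drag toward the local linear-shear velocity `u_x = G y` and a torque
toward the local half-vorticity spin `−G/2 ẑ`, each amplified by a
wall-proximity factor interpolated piecewise-linearly in `h/r` from a small
built-in monotone table (≥ 1, → 1 far from the wall, constant beyond the
tabulated range; the values are a smooth surrogate of classical
sphere-near-wall corrections, not a data import). The surrogate is exact in
the free-advection limit and linear in viscosity; it is the package's
largest deliberate departure from a CFD-coupled formulation and is stamped
into every output header. Shear rate (default 100 s⁻¹), viscosity (10⁻³
Pa·s) and fluid density (1000 kg/m³) are configurable assumptions.

Two integration modes advance the TC: the default overdamped mode sets
velocities by instantaneous balance between surrogate drag and the other
loads — at cell scale the inertial relaxation time (~10⁻⁶ s) is far below
any useful timestep, so the quasi-steady balance is the physically honest
integrator — and a semi-implicit Euler Newtonian mode integrates the second
law directly. The quaternion is renormalized every step. The PMN is fixed:
its net load is defined to be zero and its state never changes. A TC leaving
the domain terminates the run cleanly with status `exited_domain`. The
timestep is configurable (default 10⁻³ s; only the step count, 100, is
tabulated in the source scenario). The driven-approach experiment uses
3×10⁻⁵ s so that mobility × contact stiffness × Δt stays below 1 and the
settling is monotone rather than a discrete-step limit cycle.

## Verification fixtures and experiments

The planar fixture reproduces the bare-list verification setup: two
co-registered rows (or grids) of planar faces at a controlled gap, zero
microvilli standoff. Forcing `P = 1` makes bonding deterministic and
availability-limited, which is how the partner cap and the double-booking
fix are validated against a pure-python oracle.

The mesh-dependency experiment runs single-instant bond formation on a
6×6 µm planar contact patch at the equilibrium bond length, meshed at 1.5 µm
vs 0.5 µm elements, with the tabulated densities and kinetics and the
correction factor active. On this geometry the corrected per-pair rate
equals the whole-contact rate on *any* mesh (the suite asserts this to
1e-9), so the expected count is provably resolution-free and the 2-SE
comparison of means over ≥ 50 seeded replicates tests the stochastic
machinery, not the quadrature. The verification timestep (10⁻⁸ s) keeps
every single-draw probability small — the regime the one-draw-per-molecule
Bernoulli scheme approximates a Poisson process in.

Two design notes on this experiment. A *constant* forced probability is not
suitable for cross-resolution comparison: each TC molecule receives one draw
per gated partner face, and the partner count scales with resolution, so
only area-proportional (rate-derived) probabilities compare like with like.
And the experiment is planar on purpose: on the curved sphere-on-cap
geometry the formation gate is a 0.1 µm-wide spherical band which a 1.5 µm
mesh cannot resolve — facet-area deficit (~2%) and face-centroid depth
(~60–70 nm against a 100 nm window) leave a systematic ~10% undercount that
no amount of seeding removes. That quadrature limit is a real property of
coarse meshes under this model, documented here rather than averaged away;
the resolution-independence claim the correction factor supports is the
planar-contact one.

## What the synthetic scenarios do and do not show

All inputs are generated programmatically (icosphere, cap, planar grids);
there is no measured geometry or kinetics beyond the tabulated constants.
The experiments therefore validate internal consistency — conservation,
normalization identities, oracle equivalence, calibrated separation floors,
resolution independence on resolvable geometry — not agreement with cell
experiments. Real neutrophils deform, redistribute receptors, and present
shear-dependent shapes; none of that is modelled, and parameters like
`a`, `b`, `ε` and `k_on0` remain calibration targets awaiting empirical
data. Passing tests show the bookkeeping and coupling are right, not that a
melanoma cell behaves this way.

## Numerical choices

* Exponentials: the breakage exponent is clamped at 700 before `exp` — a
  far-stretched bond's rate is astronomically large either way and the draw
  is certain; formation exponent underflow is benign (rate 0).
* Degenerate pairs at zero distance get a zero direction vector instead of
  NaN; they can only occur with repulsion disabled.
* Pair gating uses a full distance matrix (`scipy.spatial.distance.cdist`);
  its output contract is exact equality with the brute-force O(N²) filter,
  which the suite checks on random instances. Experiments pre-crop face sets
  by a wall-normal bound that provably cannot change the gated set.
* The configuration hash that stamps outputs covers the physical scenario
  and seed but not the output directory.
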