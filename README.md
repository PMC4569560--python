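# adhesim

Adhesive-dynamics simulation of a circulating melanoma tumor cell (TC)
interacting with a substrate-adherent polymorphonuclear neutrophil (PMN) in
near-wall shear flow. Melanoma cells hijack neutrophils during extravasation:
ICAM-1 on the tumor cell binds the β2 integrins LFA-1 (initial tethering) and
Mac-1 (adhesion stabilization) on the neutrophil. `adhesim` models that
contact at the resolution of individual mesh faces: stochastic formation and
breakage of discrete receptor–ligand bonds, a nonlinear-spring repulsion
standing in for microvilli pushing / electrostatic / steric effects, and full
six-degree-of-freedom rigid-body motion of the tumor cell. It is a desk-scale
tool for people studying leukocyte-assisted tumor cell arrest who want the
localized bond bookkeeping without running a CFD solver.

## Model

Both cell surfaces are closed triangulated meshes. Each face of area
`A_L` carries `n_L · A_L` adhesion molecules (fractional counts allowed — the
fractional remainder participates in bonding with proportionally reduced
probability). For every pair of faces within the gated range, Bell/Dembo
kinetics give the formation and breakage rates

    k_on  = k_on0 · n_L A_L · exp( −s_ts (d − λ)² / 2 k_B T )
    k_off = k_off0 · exp( (s − s_ts)(d − λ)² / 2 k_B T )

with spring constant `s = 2×10⁻³ N/m`, transition-state spring constant
`s_ts = 1×10⁻³ N/m`, equilibrium bond length `λ = 0.05 µm`, and
`k_off0 = 0.3 s⁻¹` (LFA-1·ICAM-1) or `0.29 s⁻¹` (Mac-1·ICAM-1). `d` is the
bond coordinate: the face separation minus a microvilli standoff (molecules
sit at the tips of extended microvilli). Because per-face rates on a
discretized surface are systematically below the whole-contact-area rate,
local rates are rescaled by `k_on,global / k_on,average` so that their gated
mean equals the global value — this correction is what makes bond counts
independent of mesh resolution. Each candidate bond is tested once per step
against `P = 1 − exp(−k Δt)` with a uniform draw; a per-face, per-species
availability ledger guarantees a molecule is never double-booked across bond
types and is conserved exactly as bonds form and break. Live bonds are
Hookean springs `f = s (d − λ)` acting along the line between the bonded
faces.

Below a critical separation `ε = 1.2 µm` every close face pair also feels the
cell–cell repulsion `F = a d + b d³` with `a = −110×10⁻⁶ N/m`,
`b = 600×10⁶ N/m³`, applied (by default) in a clamped, purely repulsive
convention that holds the surfaces roughly 0.3 µm apart.

Forces and torques from bonds, repulsion and the fluid are summed at the TC
centroid (`F = F_fluid + F_bonds + F_rep`, likewise torques) and drive rigid
6DOF motion — by default an overdamped quasi-steady balance, optionally
explicit Newtonian integration. Hydrodynamic loads come from an analytic
near-wall surrogate (Stokes drag plus shear-induced torque with tabulated
wall-proximity corrections), not a flow solution; every output file carries
that disclaimer in its header.

## Worked example

The repulsion experiment: drive the 4 µm tumor sphere onto the fixed PMN cap
with a constant 1×10⁻¹¹ N wall-ward load, with and without repulsion:

```sh
$ adhesim approach --steps 900
with repulsion: min face separation 0.4234 um, min axial surface gap 0.3554 um, interpenetrated=False
without repulsion: min face separation 0.01021 um, min axial surface gap -0.9318 um, interpenetrated=True
```

With the clamped cubic spring active the surfaces settle where the repulsive
push balances the driving load (face-pair floor ≈ 0.42 µm, above the 0.3 µm
calibration target); with repulsion disabled the sphere ploughs straight into
the neutrophil (negative axial gap = interpenetration).

The mesh-dependency experiment repeats single-instant bond formation on the
same contact patch meshed at a coarse (1.5 µm) and fine (0.5 µm) maximum
element size:

```sh
$ adhesim compare-meshes --seeds 60
resolution  max_element_um  n_tc_faces  n_pmn_faces  n_seeds  mean_bonds  se_bonds
    coarse             1.5          16           16       60   24.466667  0.720352
      fine             0.5         144          144       60   24.250000  0.587355
difference of means: 0.217 (2 x combined SE = 1.859)
```

Nine times more faces, statistically identical bond counts: the subgrid
correction absorbs the discretization. A forced-bonding verification fixture
(`adhesim fixture`) and the full coupled run (`adhesim run --config ...`,
which writes `trajectory.csv` and `bonds.csv`) are also available; default
parameters reproduce the standard scenario (60×32×42 µm domain, TC at
(20, 10, 21) µm, PMN at x,z = (30, 21) µm, 100 steps).

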