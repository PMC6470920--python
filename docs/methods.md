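# Methods

`chiroscan` models the discrimination of enantiomers by a macrocyclic host
— the physics behind chiral chromatography with cyclodextrin-type
selectors — with classical molecular mechanics and rigid-body molecular
dynamics. This note records the model, the numerical choices and what the
synthetic fixtures do and do not establish.

## Energy model

The potential is an AMBER-type sum,

    E_total = E_inter + E_intra

with the intermolecular part summed over all host x guest atom pairs:

    E_inter = Σ_{i<j} [ A_ij/R_ij^12 − B_ij/R_ij^6 + κ q_i q_j / (ε R_ij) ]
              + Σ_{H-bonds} [ C_ij/R_ij^12 − D_ij/R_ij^10 ]

and the intramolecular part over the bonded topology:

    E_intra = Σ_bonds k_r (r − r_eq)^2 + Σ_angles k_θ (θ − θ_eq)^2
              + Σ_dihedrals V_n/2 [1 + cos(n φ − γ)]

Conventions and choices:

* **Units.** kcal/mol, Å, ps, amu, elementary charges, radians. The
  Coulomb constant is κ = 332.0522 kcal·Å/(mol·e²) (the AMBER value);
  kB = 0.0019872 kcal/mol/K. The conversion kcal/mol → amu·Å²/ps² is
  exactly 418.4.
* **12-10 hydrogen bond.** For atom pairs flagged (donor-H, acceptor) the
  12-10 term *replaces* the 12-6 term, the classic AMBER-1984 handling;
  this is why the hydrogen-bond energy is a separate column of the energy
  breakdown rather than folded into the van der Waals column.
* **No intramolecular non-bonded terms.** E_intra carries only the bonded
  columns (bond, angle, torsion). With rigid bodies it is a constant per
  conformer anyway.
* **No cutoffs, no periodicity.** Systems are small and aperiodic; all
  pairs are summed.
* **Solvent.** Implicit only: a dielectric constant ε ≥ 1 screening the
  Coulomb term, combined with the guest charge variant (neutral NP or
  zwitterionic P) that the solvent polarity selects. ε = 1 with the NP
  guest is the vacuum reference.
* **Forces.** The gradient is analytic: per-pair dE/dR assembled into a
  net force on the rigid guest and a torque about its centre of mass.
  It is validated against central finite differences (step 1e-5 Å /
  1e-5 rad) at relative 1e-5 over random dispositions; configurations
  with a pair distance under 0.5 Å are excluded from that comparison
  because the 1/R^13 curvature there makes the *finite-difference* stencil
  itself inaccurate, not the analytic gradient.

## Grid x orientation scanning

The host is fixed with its COM at the origin and the cavity axis along Z.
The guest COM is stepped over a Cartesian grid (default bounds ±5 Å,
spacing 0.1 Å at full resolution) and at each point the energy is
minimized over a regular ZYZ Euler grid of orientations (full resolution
36 x 18 x 36 = 23,328 orientations, enumerated uniformly in the Euler
angles, not uniformly on SO(3)). Because that resolution is
compute-heavy, the working default is a `coarse` preset (0.5 Å,
12 x 6 x 12 = 864 orientations); the full-resolution `full` preset sits behind a
flag. Desk-scale tests use still smaller grids; the acceptance script
states the sizes it uses in its output (`n` per quantity).

Products per scan:

* per-point minimum energy and argmin orientation; ties broken toward the
  lowest (Z, Y, X, orientation-index) — deterministic outputs;
* per-point Boltzmann-average energy ⟨E⟩ = Σ E e^(−E/kT) / Σ e^(−E/kT)
  at the process temperature (293 K default), computed streamingly with
  the running minimum shifted out of the exponent so repulsive points
  underflow harmlessly; coincident-atom geometries score +∞ and drop out
  of minima and weights;
* the global minimum E_min with its disposition and full per-term
  breakdown;
* the penetration potential W(Z): the minimum intermolecular energy over
  each plane Z = const (computed from an `inter`-mode scan; `total` mode
  only shifts every point by the constant rigid-conformer E_intra);
* enantioselectivity maps: signed differences of the L and D Boltzmann
  surfaces above a threshold, with XY/XZ projections.

"Inside the cavity" is operationalized as a cylinder (radius r_c,
half-height h_c about the host origin); the fixture derives r_c = ring
radius − 1.5 Å and h_c = ring half-height + 1 Å from its own geometry.
A guest disposition is an inclusion complex if all atoms are inside,
partial if some are.

## Rigid-body constant-temperature MD

Only the guest moves; both molecules are rigid (the equations of motion
are purely translational + rotational, so the intramolecular energy is an
additive constant and the recorded energy samples W_i are the
intermolecular energy; constants cancel in enantiomer *differences*).
Orientations are unit quaternions — the Euler-angle equations are
singular at β = 0, π — updated by the exponential map with the body-frame
angular velocity and renormalized every step.

The integrator is a velocity-Verlet-form leap-frog: half-kick, drift,
force recomputation, half-kick. The angular half-kicks solve
ω' = ω + (h/2) I⁻¹(τ_b − ω' × Iω'); the opening kick evaluates the
gyroscopic term explicitly (one fixed-point iteration), the closing kick
implicitly (six iterations), which makes the pair time-symmetric: over a
toy run, total energy drifts by < 1e-3 of the initial kinetic energy in
2 x 10^4 steps at 1 fs, torque-free angular momentum is conserved to
better than 1e-6 relative over 10^4 steps, and reversing the velocities
returns the initial state to ~1e-12 Å.

Constant temperature is the Brown–Clarke kinetic-energy constraint: after
every step the translational and rotational velocities are *separately*
rescaled so each kinetic energy equals (3/2) kB T exactly. Initial speeds
are likewise set exactly to the targets (the thermostat would pin them
there anyway) with directions drawn uniformly from the seeded generator;
a degenerate inertia axis (linear molecule, point mass) is excluded and
the rotational target scaled to the active axes.

Protocol defaults: dt = 1 fs, T = 293 K,
recording every 100 steps, trajectories started in front of both rims.
The desk-scale simulation time is 50 ps per trajectory (5 ns is
`t_s=5000` away, just slow). A trajectory ends at t_s or by the escape
rule: guest COM farther than R_esc = 15 Å from the host with interaction
energy above −0.5 kcal/mol for 10 consecutive recorded frames —
"outside, and not attracted strongly enough to return".

**Matched initial conditions.** To keep artificial asymmetries out of the
L/D comparison, each L starting disposition is paired with the D
disposition (same COM, orientation searched over a pool that always
contains the mirrored L orientation) minimizing a weighted sum of the
mean per-atom distance between the two initial configurations and the
difference of their host-interaction energies; D initial velocities are
the exact mirror images of L's (linear velocity as a vector, body-frame
angular velocity as a pseudovector).

**Exact mirror arithmetic.** Energies and forces are reduced over host
atoms two-at-a-time in storage order, and the fixture host stores
reflection-partner atoms adjacently (on-plane atoms last). IEEE addition
is commutative and every kernel operation is a fixed sign-symmetric
formula (including an explicit adjugate 3x3 inverse for the inertia
tensor — no LAPACK call inside the dynamics), so a mirrored run on an
achiral host produces *bitwise* mirrored trajectories: identical W_i
series and ΔF = 0 exactly, not merely to rounding. This turns the
mirror-null test into an exact oracle.

## Binding free energy and elution order

Per trajectory, F = −kB T ln Σ_i exp(−W_i/kB T) over the recorded
samples, evaluated with log-sum-exp. As written this is a log-*sum*: it
decreases as low-energy samples accumulate, satisfies F ≤ min W_i, and
collapses to min W_i as T → 0. It is computed verbatim per trajectory and
averaged across trajectories to F_mean; a log-mean-exp variant
(`normalize=True`) is available for sensitivity analysis. Only
trajectories that were at least partially inside the cavity at some frame
("included") enter F_mean and t_mean; external trajectories are counted
but excluded, and the all-trajectory mean residence time is reported
alongside.

Residence time is the *longest contiguous* inside span times the frame
spacing — the lifetime of the stable complex — not the total inside time.
Elution: ΔF = F_L − F_D; ΔF > 0 means D is more tightly bound and L
elutes first; |ΔF| < 1e-6 kcal/mol is a tie.

Occupancy analysis: the COM histogram over grid voxels normalized to
probability 1 (out-of-grid frames counted separately), and the
most-probable configuration as the modal voxel's quaternion mean (largest
eigenvector of Σ qqᵀ with sign alignment) at the mean COM of its frames;
density ties return all modes.

## The synthetic fixtures

The fixtures emulate the *structure* of a host–guest chiral separation
problem, not any particular molecule:

* **Host**: two stacked rings of 7 LJ sites (narrow rim radius 4.5 Å with
  H-bond-acceptor sites, wide rim 5.5 Å, ring planes at z = ±2 Å),
  exactly mirror-symmetric about the xz plane by construction. Site-pair
  LJ wells of ~0.1–0.4 kcal/mol give a smooth cavity well of roughly
  −16 kcal/mol at the centre — deep enough that included guests stay for
  the whole desk-scale trajectory, as in the strongly bound vacuum case.
  Ring charges follow a dipolar pattern 0.3·cos θ (net zero).
* **Chiral decoration**: a counter-twisted quadrupolar charge term,
  +0.6 sin 2θ on the wide ring and −0.6 sin 2θ on the narrow ring. The
  opposite phases cannot be rotated away, so the charge distribution is
  chiral while the site geometry stays achiral. The amplitude is chosen
  so the enantioselective energy split exceeds desk-scale sampling noise:
  F is an extreme-value statistic of ~500 samples per trajectory, and
  weaker decorations (or geometric ripples, which introduce a competing
  channel of opposite handedness) leave sign(ΔF) at the mercy of seeds.
  With this host the sign of ΔF is negative (F_L < F_D: the L guest binds
  more tightly, so D elutes first) for the large majority of master seeds
  at desk scale; the per-seed-set flip probability is small but nonzero, and
  the acceptance script reports the observed sign-consistency fraction
  rather than asserting unanimity. The sign itself is a property of this
  fixture, not of any real system.
* **Guest**: a single-stereocenter amino-acid-like molecule (10 atoms):
  central carbon with H, an amine, a carboxyl and a two-carbon chain;
  built at its force-field equilibrium bond lengths/angles (torsional
  strain ~2 kcal/mol). D is the exact xz-mirror of L, index-aligned. NP
  and P variants share the skeleton; they differ in charges (group sums
  0/0 vs +1/−1) and in one hydrogen that sits on the carboxyl oxygen in
  NP and on the nitrogen in the zwitterion. All torsion phases are
  γ ∈ {0, π}, so E_intra is mirror-invariant and cancels exactly.
* **Force field**: hand-assigned, AMBER-magnitude constants; the 12-10
  well has depth 0.5 kcal/mol at 2.0 Å (a typical H-bond).

What passing tests show — and do not show. The fixtures establish that
the machinery is correct: exact mirror nulls, conservation laws,
closed-form values, oracle agreement, and that a chiral environment
produces a seed-stable elution signal through this pipeline. They do not
validate any real host's selectivity: real cyclodextrin work needs
literature coordinates and charges (accepted as ordinary PDB/XYZ +
parameter inputs) plus far longer sampling than the desk-scale protocol.

## Numerical details and limitations

* Scans and MD inner loops are numba-compiled, without fastmath
  (determinism and sign symmetry take precedence over vectorization).
* Scan tie-breaks, orientation ordering and all randomness are
  deterministic; one master seed expands to per-trajectory streams.
* Degenerate inputs: coincident atoms raise a singularity error in direct
  energy calls and score +∞ inside scans; zero-inertia axes are excluded
  from velocity sampling and rotational response; β at the gimbal points
  folds the full Z-rotation into α when converting back to Euler angles.
* PDB round-trips are limited to the format's 3 decimals; XYZ files carry
  full precision (1e-6 Å round-trip guarantee). Charges, masses, types
  and topology travel in a YAML sidecar; a bare PDB falls back to
  distance-rule topology inference and is flagged.
* The rigid-body approximation means conformational relaxation of host
  and guest is absent; the intramolecular terms exist for per-conformer
  energetics (breakdowns, mirror checks), not for dynamics.
* Desk-scale trajectory statistics (10 x 50 ps) resolve the fixture's
  engineered discrimination; they would not resolve the ~0.5 kcal/mol
  splits typical of weakly selective real systems.
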