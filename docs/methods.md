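# Methods

This note records the models `bfekit` implements, the parameters that
matter, the numerical choices made where the design was genuinely open, and
what the synthetic study systems do and do not establish.

## Force field and units

The toy force field uses AMBER functional forms: bonds `k(r−r0)²` and
angles `k(θ−θ0)²` (the force constant absorbs the conventional ½), cosine
dihedrals `(V_n/2)(1 + cos(nφ − γ))`, Coulomb `332.0637 q_i q_j/(ε_in r)`
and Lennard-Jones in the Rmin/ε convention with Lorentz–Berthelot
combination (`Rmin = Rmin/2_i + Rmin/2_j`, `ε = √(ε_i ε_j)`).  1-2 and 1-3
pairs are excluded, 1-4 pairs scaled by 1/1.2 (electrostatics) and 1/2
(Lennard-Jones); the toy topology format can override these per pair.
Nonbonded sums run over **all** pairs — end-point post-processing
conventionally applies no cutoff; any cutoff belongs to the sampling
engine, which is out of scope.  Units: Å, kcal/mol, elementary charges, K;
k_B = 0.0019872041 kcal/(mol·K).

## End-point binding free energies

Single-trajectory protocol: for every frame the complex, the receptor
alone, and the ligand alone are evaluated on the same coordinates and
differenced.  The bonded difference is computed as the sum of bonded terms
that *span* the ligand/receptor partition, which is the exact algebraic
difference — when no term spans (the normal case), the cancellation is
exact by construction rather than exact up to floating-point noise.

**Polar solvation.**
* *GB.*  OBC variant 1: intrinsic radii ρ with a 0.09 Å offset, pairwise
  HCT descreening integrals scaled by per-atom screening factors, and the
  tanh rescaling `1/R = 1/ρ̃ − tanh(αΨ − βΨ² + γΨ³)/ρ` with α = 0.8, β = 0,
  γ = 2.909125 (the cited model names these constants; they are the
  standard "variant 1" set).  Energy by the Still pairwise form
  `f_GB = √(r² + R_i R_j e^{−r²/(4R_iR_j)})`, self terms included, so a
  single ion reduces exactly to the Born equation.
* *PB.*  Linearized, zero ionic strength, on a cubic 7-point-stencil grid:
  harmonic-mean face dielectrics over a one-cell smoothed (inverse-ε
  interpolated) boundary, trilinear charge spreading, Debye–Hückel
  (Coulomb/ε_out) boundary on a coarse grid at 4× spacing focused onto the
  fine grid, conjugate-gradient solve to a 1e-6 relative residual.  The
  reaction-field energy subtracts a uniform-ε_in reference solved on the
  identical grid with the identical charge spreading, so the grid
  self-energy cancels.  On the Born ion (q = 1 e, a = 2 Å) the error is
  10.3 % at 1.0 Å spacing, 2.3 % at 0.5 Å, and 0.5 % at 0.25 Å.  The cited
  PB radius set is not reproduced here; the dielectric envelope uses the
  system's GB intrinsic radii (falling back to LJ Rmin/2), and this
  divergence is deliberate and documented.
* Grid padding must be ≥ 8 Å; spacings above 1 Å are rejected.

**Nonpolar solvation.**  `γ·SASA + b` with γ = 0.0072 kcal/(mol·Å²), b = 0,
probe 1.4 Å.  SASA comes from the LCPO four-term pairwise-overlap formula
with the published parameter rows keyed by element and bonded-heavy-neighbor
count.  Two caveats worth knowing:
* An atom with zero bonded neighbors gets the exact isolated-sphere row
  (P1 = 1), which is the correct free-ion limit.
* The published carbon rows describe CH3/CH2 groups and absorb the surface
  their implicit hydrogens add; against a hydrogen-free numeric reference
  they overestimate bare-bead chains by ~8–12 %, while near-hydrogen-free
  oxygen-type chains agree to a few percent.  The accuracy checks therefore
  compare like with like (oxygen-type chains, realistic tetrahedral
  geometry); elements without rows fall back to the carbon series with a
  warning.

**Per-residue decomposition.**  Gas-phase cross pair energies split
half/half between the two residues of each pair; the GB matrix of the
complex minus the embedded part matrices is decomposed the same way
(diagonal self terms belong to their atom); nonpolar per-atom ΔSASA·γ is
summed per residue.  Residue sums reconstruct the totals to < 1e-6 kcal/mol
by construction.  Finite-difference PB is not pairwise-decomposable, so
with the PB model the decomposition's polar column is still the pairwise GB
split while PB supplies the totals — a standard, prominently logged
approximation.

**Entropy.**  Residues with any heavy atom within 9 Å of any ligand heavy
atom are kept whole (hydrogens never participate in the distance test);
chain breaks of the truncated fragment are recorded as metadata (charged
COO⁻/NH₃⁺ termini are noted, not chemically rebuilt — bead systems need no
caps).  The truncated species are minimized (steepest descent with
backtracking, then conjugate gradient, default cap 10,000 steps) to an RMS
gradient ≤ 1e-4 kcal/(mol·Å); the mass-weighted Hessian is built by central
differences of the gradient (δ = 1e-4 Å) and symmetrized.  External modes
are removed by smallest absolute eigenvalue: 6 for nonlinear systems, 5 for
linear ones (detected from the inertia tensor), 3 for single atoms; genuine
negative curvature beyond them raises an error.  Vibrational entropy by the
harmonic-oscillator formula, plus rigid-rotor (σ = 1) and ideal-gas
(1 atm) translational terms, standard atomic masses.  The diatomic
pipeline reproduces the closed-form oscillator entropy to ~1e-14 kcal/mol
at 300 K.  Binding entropy defaults to 5 equally spaced frames (the
reference protocol's every-Nth-frame extraction, scaled to desk size).

**ΔΔG convention.**  `ΔΔG = ΔG_mut − ΔG_wt`; positive = resistance.

## Thermodynamic integration

Linear coupling `U(λ) = U0 + λΔU`; the estimator is the trapezoidal rule
over per-window sample means on a sorted λ grid that must include both
endpoints (duplicates rejected).  The bundled schedule is the 14-point grid
0, 0.0001, 0.001, 0.01, 0.1, 0.2, …, 1.0 — dense near λ = 0 where ∂U/∂λ
varies fastest for decoupling transforms.  Replica results are averaged
with a sample (n−1) standard deviation; a single replica reports NaN SD
rather than a fabricated zero.  An optional equilibration-discard fraction
defaults to 0 (the emulated protocol states no discard).  Only the
trapezoidal estimator is provided; Gaussian-quadrature and
acceptance-ratio estimators are out of scope, as is softcore sampling
itself (inputs are post-processed ∂U/∂λ series).

## Umbrella sampling and WHAM

Bias `w_i(ξ) = (K/2)(ξ − ξ_ref)²`.  The standard self-consistent WHAM
iteration runs on window free-energy offsets until the largest change is
below 1e-6 kcal/mol (cap 100,000 iterations; non-convergence raises with
the last offsets).  Bin width defaults to 0.1 Å — five bins per 0.5 Å
window balances resolution against per-bin counts.  The unbiased
probability is normalized before the log transform; empty bins report NaN;
profiles are anchored to min = 0.  Round averaging takes the per-bin mean
of the last *n* (default 10) anchored profiles.  ΔG extraction is
`mean(bulk region) − min(bound region)`, so vertical anchoring cancels in
ΔΔG.  The window layout emulated by the generator places ξ_ref on
12.5–32.5 Å every 0.5 Å (41 windows, K = 5 kcal/(mol·Å²), 300 K) — the
"restraint in the middle of each window" reading of a span-based layout.
The reaction coordinate is a generic scalar; its structural definition
lives in the generator, not the estimator.

## Contact network analysis

Nodes are residues (Cα or first-atom anchors; the ligand can join as one
node).  Correlations: frames are superposed (one refinement pass onto the
mean structure), and `C_ij = ⟨Δr_i·Δr_j⟩ / √(⟨Δr_i²⟩⟨Δr_j²⟩)`.  Edges
require persistent contact — by default any-heavy-atom residue–residue
distance ≤ 4.5 Å in ≥ 75 % of frames (the standard dynamical-network
convention; a literal node-atom criterion is available as
`calpha_strict`).  Edge weight `d_ij = −ln |C_ij|` (natural log; |C|
floored at 1e-12; negative correlations enter by magnitude and keep their
sign on the edge attribute).

Community detection is divisive Girvan–Newman with the partition of
maximal modularity over the dendrogram and deterministic tie-breaking by
sorted edge ids.  Edge removal uses **topological** (unweighted) edge
betweenness, as in the original algorithm: Dijkstra betweenness on the
d_ij weights funnels all traffic between two blocks through the single
cheapest of several parallel bridges and can split inside a block before
the bridges — observed directly on the planted lattice benchmarks.  The
d_ij weights drive shortest-path (transmission-chain) extraction, where
they belong.

Hydrogen bonds: donor-heavy–acceptor distance ≤ 3.0 Å and donor–H···acceptor
angle ≥ 135°, matching common analysis-tool defaults; donors must have a
bonded hydrogen.

## Synthetic study systems

The generators are pure functions of (seed, parameters) and return planted
ground truth alongside the data.

* *Toy complexes*: a ring of two-bead residues (pocket radius 6 Å) around a
  short-chain ligand; charges |q| ≤ 0.3 e, bond constants 150–500
  kcal/(mol·Å²) — narrow physical ranges that keep normal-mode analysis
  well-conditioned.  The "mutation" flips the contact residue's inward bead
  charge, planting an electrostatic repulsion against the ligand's anchor
  charge (the bead-scale analogue of an in-pocket aromatic/nitrile clash).
* *Correlated trajectories*: residues in staggered grid blocks (3.8 Å
  spacing) joined by single 4.0 Å bridges; each block shares one latent
  Gaussian displacement per frame (σ_latent = 0.15 Å) plus independent
  noise (σ_noise = 0.015 Å), giving intra-block |C| ≈ 0.99 and guaranteed
  contacts.
* *Umbrella datasets*: vectorized Metropolis chains per window, step size
  auto-tuned to 30–50 % acceptance during a 10 % burn-in that is
  discarded; default truth 0.5·(ξ−20)², 1000 samples/window.  Early-round
  drift (a Gaussian bump decaying as e^{−r/τ}) emulates slow convergence,
  so last-10-round averaging measurably beats first-10.
* *TI datasets*: Gaussian samples about a chosen ∂U/∂λ curve (default a
  smooth cubic); truth by dense quadrature.
* *Benchmark pairs*: bivariate normal with chosen population correlation.

What passing tests show — and don't: the pipeline recovers planted truths
on bead-scale systems with idealized noise.  Real protein trajectories add
anharmonicity, slow conformational exchange, force-field error, and
solvent degrees of freedom that no bead system emulates; agreement here
validates the estimators' correctness, not their accuracy on laboratory
systems.

## Problem sizes and determinism

Defaults are sized so the full test suite runs in well under a minute of
numerics per stage: complexes of 8 residues + 5 ligand atoms, 200-frame
trajectories, 41 × 1000 umbrella samples, 14 λ × 1000 samples × 5
replicas, 20-atom SASA toys.  All randomness flows through
`numpy.random.default_rng(seed)`; identical seeds give bit-identical
datasets, and the command-line pipeline writes byte-identical tables across
repeated runs.

## Known limitations

* No periodic boundary conditions, Ewald electrostatics, or explicit
  solvent anywhere (post-processing scope).
* The PB solver is linearized and salt-free; no nonlinear term, no
  molecular-surface (SES) construction beyond the smoothed vdW envelope.
* LCPO accuracy is tied to the published radius/parameter semantics (see
  caveats above); arbitrary radii give larger errors.
* NMA entropy assumes a true minimum of the toy potential; shallow or
  anharmonic wells on larger toys can stall the minimizer, which raises
  rather than silently continuing.
* The Girvan–Newman stopping rule (max modularity) and the unweighted
  betweenness choice are documented conventions, not uniquely determined
  by the emulated protocol.
* Three-trajectory end-point protocols, quasi-harmonic/interaction
  entropies, MBAR/BAR estimators, and 2-D PMFs are out of scope.
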