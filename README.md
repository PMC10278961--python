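# bfekit

Binding free energies and drug-resistance mechanism analysis for
receptor–ligand systems, at desk scale.

When a kinase acquires a resistance mutation, the binding free energy of an
ATP-competitive inhibitor shifts by a ΔΔG = ΔG_mut − ΔG_wt of a few
kcal/mol — positive values mean weakened binding.  Attributing that shift to
a mechanism (a direct in-pocket clash, or an allosteric chain of residue
interactions transmitting a distant mutation's effect into the pocket) takes
a stack of trajectory post-processing methods that are usually scattered
across several simulation packages.  `bfekit` implements that stack as one
tested Python library:

* **End-point binding free energies (MM/PB(GB)SA).**  Under the
  single-trajectory protocol, per frame,
  `ΔG_bind = ΔH − TΔS`, `ΔH = ΔE_ele + ΔE_vdW + ΔG_polar + ΔG_SA`,
  with the bonded terms cancelling exactly.  The polar term comes from
  either a generalized Born model (OBC variant 1: pairwise-descreening
  effective radii with tanh rescaling, α = 0.8, β = 0, γ = 2.909125) or a
  focused finite-difference linearized Poisson–Boltzmann solve
  (ε_in ∈ {1, 2, 4}, ε_out = 80); the nonpolar term is γ·SASA + b with
  γ = 0.0072 kcal/(mol·Å²), b = 0, and LCPO surface areas.  Per-residue
  decomposition splits every cross pair half/half and reconstructs the
  totals exactly; `−TΔS` comes from truncated (9 Å, whole residues)
  normal-mode analysis after minimization.
* **Thermodynamic integration.**  `ΔG = ∫₀¹ ⟨∂U/∂λ⟩ dλ` by the trapezoidal
  rule on the 14-point λ schedule (0, 0.0001, 0.001, 0.01, 0.1, …, 1.0),
  with replica averaging and the double-decoupling
  `ΔΔG = ΔG_holo − ΔG_apo` cycle.
* **Umbrella sampling → WHAM.**  Harmonic window biases
  `w_i(ξ) = (K/2)(ξ − ξ_ref)²`, self-consistent WHAM unbiasing to a PMF
  anchored at zero, round-averaged profiles (last-*n* rounds), and
  bulk-minus-bound ΔG extraction.
* **Contact network analysis.**  Residue nodes, edges where residues stay
  within 4.5 Å in ≥ 75 % of frames, weighted by `d_ij = −ln |C_ij|` with
  `C_ij` the normalized displacement cross-correlation; Girvan–Newman
  communities at maximal modularity; shortest-path transmission chains;
  hydrogen-bond occupancy scanning.
* **Synthetic study systems.**  Seeded generators for bead-scale
  receptor/ligand complexes (with plantable in-pocket "mutations"),
  trajectories with planted motion communities, Metropolis umbrella samples
  from a known analytic PMF under the 41-window / 0.5 Å / K = 5 kcal/(mol·Å²)
  layout, ∂U/∂λ samples with known integrals, and benchmark ΔΔG pairs with
  chosen correlation — so every stage is testable closed-loop, offline.

Units are AMBER-compatible throughout: Å, kcal/mol, elementary charges,
Coulomb constant 332.0637 kcal·Å/(mol·e²), k_B = 0.0019872041 kcal/(mol·K).

## Worked example

```python
import numpy as np
from bfekit import (make_umbrella_dataset, wham, pmf_delta,
                    make_ti_dataset, replica_statistics,
                    make_toy_complex, Trajectory, endpoint_bfe)

# umbrella sampling from a known harmonic PMF, unbiased by WHAM
rounds, truth = make_umbrella_dataset(seed=42, n_samples=1000)
profile = wham(rounds[0], bin_width=0.1, T=300.0)
dg = pmf_delta(profile, bound_region=(18.0, 22.0), bulk_region=(28.0, 32.0))

# 5-replica trapezoidal TI on noisy dU/dlambda samples
replicas, ti_truth = make_ti_dataset(seed=42, noise=1.0,
                                     n_samples=1000, n_replicas=5)
res = replica_statistics(replicas)

# one-frame MM/GBSA on a toy complex
system, frame, _ = make_toy_complex(seed=42)
r = endpoint_bfe(system, Trajectory(frame[None]))
```

This prints (numbers produced by the code above):

```
WHAM recovery RMSD over the central 15 A: 0.191 kcal/mol
bulk-minus-bound dG from the PMF:        47.05 kcal/mol
TI dG = 1.006 +- 0.022 kcal/mol (truth 1.000)
endpoint dH = -2.257 kcal/mol  (ele 6.590, vdW -1.413, polar -6.142, SA -1.292)
```

The WHAM profile reproduces the planted PMF to 0.19 kcal/mol RMSD; the PMF
ΔG is large because the planted well is steep (0.5·(ξ−20)² over a 20 Å
range).  The TI mean lands within one standard deviation of the exact
integral.  The endpoint ΔH decomposes into a repulsive gas-phase
electrostatic term screened by polar solvation, plus favorable van der Waals
and surface-area burial — the typical anatomy of a toy pocket complex.

The same pipelines are scriptable from the shell:

```sh
bfekit simulate --scenario umbrella --seed 42 --out us/
bfekit wham --windows us/ --out pmf.tsv --last-rounds 1
bfekit simulate --scenario complex --seed 1 --out cx/
bfekit endpoint --topology cx/system.top --trajectory cx/system.pdb --out ep/
bfekit cna --topology ct/system.top --trajectory ct/trajectory.pdb --out cna/
```

Subcommands: `simulate`, `endpoint`, `ti`, `wham`, `cna`, `hbond`, `bench`.
Each run writes a `run.log` with the resolved configuration and seed.

## Layout

| module | contents |
| --- | --- |
| `bfekit.core` | atoms, systems, trajectories, selection grammar, superposition |
| `bfekit.io` | PDB, toy topology format, xyz/series tables |
| `bfekit.mm` | bonded, Coulomb, Lennard-Jones, interaction energies |
| `bfekit.solvation` / `bfekit.pb` | GB(OBC1), LCPO SASA, nonpolar term, FD-PB |
| `bfekit.endpoint` / `bfekit.nma` | MM/PB(GB)SA assembly, decomposition, truncation, NMA entropy |
| `bfekit.ti` | trapezoidal TI, replicas, ΔΔG cycles |
| `bfekit.wham` | umbrella windows, WHAM, round averaging, PMF ΔG |
| `bfekit.network` | correlations, contacts, communities, paths, H-bonds |
| `bfekit.synth` | seeded generators with planted ground truth |
| `bfekit.bench` / `bfekit.cli` | Pearson/MUE reports, command line |

See `docs/methods.md` for the models, assumptions, numerical choices, and
known limitations.
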