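# fepath

A desk-scale toolkit for the free-energy and electrostatics machinery used
to characterise enzyme catalysis and conformational change:

* **adaptive string method** in collective-variable (CV) space — evolve a
  chain of nodes toward the minimum free energy path (MFEP) under
  restrained sampling with equidistant reparameterization and
  neighbour-node replica exchange;
* **path-CV umbrella sampling and WHAM** — a scalar reaction coordinate
  *s* ∈ [0, 1] measuring progress along the frozen string, umbrella
  windows with on-the-fly force-constant calibration, the weighted
  histogram analysis method, and block-bootstrap uncertainty bands;
* **thermodynamic integration (TI)** over an alchemical coupling λ, with
  thermodynamic-cycle algebra and the pKa ↔ ΔG relation for titratable
  residues;
* **CV selection by distribution overlap** — rank candidate distances and
  torsions by the overlap coefficient of their marginal distributions in
  two end-state ensembles;
* **bond-probe electric fields** — the environment's Coulomb field at the
  midpoint of a carbonyl bond, projected on the O→C unit vector and
  decomposed per residue and per structural motif (MV·cm⁻¹, solvent
  cutoff, |E| > 2 MV·cm⁻¹ reporting);
* **per-residue interaction-energy decomposition** — Coulomb +
  Lennard-Jones ligand–environment energies with full (not even-split)
  assignment to each environment residue and 10-block error estimation.

The analyses run on synthetic systems shipped with the package: analytic
multi-basin potentials (Müller–Brown, bistable wells), a seeded overdamped
Langevin sampler standing in for MD, λ-coupled toy Hamiltonians with known
ΔF, two-state CV ensembles with a planted discriminating coordinate, and
ligand-in-pocket point-charge assemblies read and written as PQR.

## The core quantities

With K string nodes z₁…z_K in CV space, each iteration samples around
every node under a harmonic restraint k; the restrained mean is displaced
from the node by ≈ −∇A/k, so

    zᵢ ← zᵢ + η·(⟨z⟩ᵢ − zᵢ),   then reparameterize to equal arc length,

which converges to the MFEP. Along the frozen path, umbrella windows at
s₀ with bias ½k(s−s₀)² are combined by WHAM:

    p_j ∝ Σ_i n_ij / Σ_i N_i e^{f_i} e^{−b_ij/kT},   A(s) = −kT ln p(s).

For a λ-coupled Hamiltonian H(λ) = (1−λ)H₀ + λH₁,

    ΔF = ∫₀¹ ⟨∂H/∂λ⟩_λ dλ   (trapezoidal quadrature),

cycles combine as ΔΔG = Σᵢ signᵢ·ΔGᵢ with quadrature errors, and
pKa = pH + ΔG_deprot/(k_B T ln 10). Projected fields use
E = k_e q r̂/r² with k_e = 332.0637 kcal·Å·mol⁻¹·e⁻² and
1 kcal·mol⁻¹·e⁻¹·Å⁻¹ = 4.3364 MV·cm⁻¹.

## Worked example

```python
import numpy as np
from fepath import combine_cycle, deprotonation_pka
from fepath.alchemical_ti import CycleLeg, analytic_ti_leg, ti_integrate

kt = 0.61603  # kcal/mol at 310 K

# Acylation stage: covalent-intermediate state plus ammonia release
stage, err = combine_cycle([
    CycleLeg("acyl-enzyme + NH3 (site)", 3.9, 0.3),
    CycleLeg("NH3 release to bulk", -4.2, 0.7),
])
print(f"acylation stage: {stage:+.1f} +/- {err:.2f} kcal/mol")

# Lysine pKa from its deprotonation cost at pH 7.5, 310 K
print(f"pKa = {deprotonation_pka(3.7, 7.5, 310.0):.2f}")

# TI of a harmonic spring transformation k: 1 -> 4 (exact (kT/2) ln 4)
leg = analytic_ti_leg(lambda lam: 3 * kt / (2 * (1 + 3 * lam)))
dF, _ = ti_integrate(leg)
print(f"TI dF = {dF:.3f} kcal/mol")
```

prints

```
acylation stage: -0.3 +/- 0.76 kcal/mol
pKa = 10.11
TI dF = 0.428 kcal/mol
```

i.e. the acylation stage is mildly exergonic once ammonia release is
included, the active-site lysine stays protonated at physiological pH
(pKa ≈ 10.1), and the 21-point trapezoid reproduces the closed-form
(kT/2)·ln 4 = 0.427 kcal/mol to quadrature accuracy.

The same stages are scriptable from the shell via the `fepath` command
(`simulate`, `cvselect`, `string`, `umbrella`, `wham`, `ti`, `cycle`,
`field`, `decompose`); every artifact carries a provenance header with
the tool version, seed and config hash.

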