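# Methods

This note documents the models, numerical choices and known limitations
of the toolkit, module by module, including what the synthetic systems do
and do not emulate about real enzyme simulations.

## Units and constants

Energies are kcal·mol⁻¹, lengths Å, charges e, temperatures K, dihedrals
degrees in [−180, 180), fields MV·cm⁻¹. The Boltzmann constant is fixed
at 0.0019872041 kcal·mol⁻¹·K⁻¹ (kT = 0.61603 at 310 K), the Coulomb
constant at k_e = 332.0637 kcal·Å·mol⁻¹·e⁻², and the field conversion at
4.3364 MV·cm⁻¹ per kcal·mol⁻¹·e⁻¹·Å⁻¹. The latter two are re-derived in
the test suite from CODATA constants (via `scipy.constants`) and agree to
five significant figures. Constants are frozen in `fepath.constants`
rather than read from scipy at run time so that numeric output cannot
drift with library versions.

## Synthetic systems (`toy_systems`)

The generators supply inputs with the *statistical structure* the
analyses assume, at a scale where every result can be checked against a
closed form or an exhaustive computation:

* **Potentials.** The Müller–Brown four-Gaussian surface (canonical
  parameters; deepest minima near (−0.558, 1.442) and (0.623, 0.028)) is
  the standard MFEP benchmark; `double_well_1d(h)` = h(x²−1)² gives a
  bistable profile with a known barrier; `harmonic_nd` provides the
  Gaussian closed forms used by sampler and TI tests. All gradients are
  analytic and held to central finite differences at 1e−5 relative.
* **Sampler.** Overdamped Langevin dynamics with the Euler–Maruyama
  update x ← x − dt·∇V + √(2 kT dt)·ξ replaces molecular dynamics. Its
  stationary law is Boltzmann up to O(dt) discretisation bias, it needs
  no force field, and at kT = 0 it degenerates to gradient descent —
  which makes limits testable. Temperature enters directly as the thermal
  energy kT in kcal·mol⁻¹ rather than as a kelvin value, since no
  particle masses or friction coefficients exist in this model.
  Randomness comes from a counter-based Philox stream keyed on the user
  seed and split per replica/iteration, so every run is bit-reproducible
  and independent of scheduling. Trajectories diverging beyond |x| > 1e6
  raise an error naming the step.
* **Toy complexes.** A ligand residue at the origin carries a
  carbonyl-like probe bond (O and C 1.23 Å apart, ∓0.55 e); protein
  residues sit on a 7 Å shell with random partial charges (optionally
  zero-summed per residue); single-atom waters are scattered between 3
  and 25 Å so a 15 Å solvent cutoff has visible effect; two placeholder
  motifs partition the protein residues. What is *not* emulated:
  connectivity, sterics, polarisation, periodic images, and realistic
  charge distributions — so passing field/decomposition tests
  demonstrates correct electrostatic bookkeeping, not chemical realism.
* **Two-state ensembles.** n CV columns sharing all marginals except one,
  displaced by a chosen shift; linear coordinates are Gaussian (σ = 1 by
  default), dihedral-like ones wrapped Gaussians (σ = 15°) on
  [−180, 180). A 3σ shift between equal-variance normals has overlap
  coefficient 2Φ(−1.5) ≈ 0.134, the closed form the selection tests use.

## Collective variables and CV selection

Distances and proper dihedrals (IUPAC sign convention; planar trans
reported as −180) carry amu^1/2 metric weights (default 1). To compare
strings of mixed CVs with one RMSD, dihedral differences are wrapped to
(−180, 180] and converted to length at **1° ≡ 0.02 Å**, a declared fixed
conversion — the mixed-unit metric used in practice is not recoverable
from published descriptions, so this package states its own.

CV selection replaces a by-eye judgement of "clearly non-overlapping
distributions" with the histogram overlap coefficient
Σ_bins min(p̂_A, p̂_B) on a common binning (Freedman–Diaconis by default,
clipped to [10, 200] bins; full-circle binning for dihedrals). A CV
discriminates the end states when its overlap falls below 0.25 — chosen
once as a scale-free surrogate for "clearly not overlapping"; at 3σ
separation the true overlap (0.134) is well below it and at 1σ (0.617)
well above.

## Adaptive string method

The update rule moves each node a fraction η (default 0.1) toward its
restrained-sampling mean: under a harmonic restraint k the stationary
mean is displaced from the node by ≈ −∇A/k, so this is preconditioned
free-energy-gradient descent without explicit gradient estimation.
Endpoints are free by default (a flag pins them). After each update,
nodes are resampled to equally spaced arc-length positions *on the
current polyline* (dihedrals unwrapped along the path first): along-path
spacing is exactly equal, endpoints unchanged, total arc length
preserved. Convergence is declared when the inter-iteration weighted
RMSD stays at or below a threshold (default 0.1 amu^1/2·Å) for a window
of iterations (default 20). Defaults elsewhere: K = 24 nodes, restraint
100 kcal·mol⁻¹ per squared CV unit. No smoothing is applied.

Restraint stiffness must dominate the surface curvature for the
restrained mean to track −∇A/k; on the Müller–Brown benchmark (Hessian
eigenvalues of order 10³ near the saddles, energies of order 10²) the
benchmark runs therefore use k = 2000, dt = 5·10⁻⁵, 400 steps per node,
kT = 1 and a 0.002 convergence threshold. The converged 24-node string
lies within a mean nearest-distance of ≈ 0.02 units of the
steepest-descent reference path.

The reference (`mfep_reference`) is deliberately independent machinery:
saddles from Nelder–Mead minimisation of |∇V|², a step off each saddle
along the negative-curvature eigenvector, then discrete lowest-neighbour
descent on a 1000×1000 grid.

Sampled string iterations are implemented for linear CVs (the analytic
surrogates); circular CVs are supported throughout initialisation,
reparameterization and the path coordinate, where the shorter-arc
convention applies.

The path coordinate s is the exact geometric projection onto the
piecewise-linear string under the weighted metric (arc position of the
nearest-segment projection, normalised; ties to the lower segment index;
clamped to [0, 1]) rather than the exponentially weighted form — the
projection has closed-form anchors (node k ↦ k/(K−1) on an equidistant
string) and the difference is negligible for well-resolved strings.

Neighbour-node replica exchange uses the Metropolis rule on the bias
energies; at kT = 0 a swap is accepted only if it does not raise the
total bias.

## Umbrella sampling and WHAM

Window centres are uniform on [0, 1]. Force constants are calibrated
from pilot runs by k → k·(σ_pilot/σ_target)², the exact correction for
Gaussian window distributions, clamped to [10⁻², 10⁶]; on a flat
landscape this returns kT/σ_target². WHAM is solved by direct iteration
on the window log-shift constants in log space (`logsumexp`), default
101 bins, tolerance 1e−8 on the largest shift change, 100 000 iteration
cap — robustness over speed at desk scale; exhausting the cap raises an
error carrying the residual. Bins never visited are reported as NaN gaps
with a warning, never interpolated. Profiles are anchored at min A = 0.
The solution is invariant under constant bias offsets and sample-count
scaling, and with a single (near-)unbiased window it reduces to the
histogram estimator — all asserted in tests.

Uncertainty bands are a moving-block bootstrap (blocks of 20 consecutive
samples, respecting autocorrelation) over each window's trajectory;
every replicate is re-solved and re-anchored, the band is the pointwise
standard deviation, and replicates that fail to converge are dropped
(more than 10 % dropped is an error).

Benchmark scale: 16 windows × 5000 samples on the double-well surrogate
(barrier 3 kcal·mol⁻¹, domain [−1.5, 1.5] mapped onto s) reconstructs
the direct Boltzmann integral on the same bins to ≈ 0.10 kcal·mol⁻¹
RMS; residual error is dominated by the O(dt) sampler bias, not WHAM.

## Thermodynamic integration and cycles

Linear coupling H(λ) = (1−λ)H₀ + λH₁ makes ∂H/∂λ = H₁ − H₀ exact at
every λ. Per-λ means are sampled at the mixed Hamiltonian; the error is
the 10-block rule (below). Quadrature is the trapezoid on the user's λ
grid (default 21 even points), with point errors propagated through the
trapezoid weights in quadrature — no Gaussian quadrature, keeping error
propagation transparent. A descending grid integrates the reverse
transformation (ΔF negated); non-monotonic grids are rejected. Soft-core
potentials are not needed because toy transformations never annihilate
particles. The harmonic spring transformation k₀ → k₁ has
ΔF = (kT/2)·ln(k₁/k₀); 21-point trapezoid reproduces it to < 0.002
kcal·mol⁻¹.

Cycle legs are signed; ΔΔG = Σ signᵢ·ΔGᵢ and errors combine in
quadrature under the independence assumption. Published stage
uncertainties are not always the quadrature of the printed leg errors
(e.g. ±0.3 and ±0.7 combine to ±0.76, not ±1.1); this package documents
its rule and reports it consistently rather than reverse-engineering any
other combination. pKa = pH + ΔG_deprot/(k_B T ln 10), with the exact
inverse provided.

## Electric fields

The probe sits at the midpoint of a named bond; the projection axis runs
from the first selected atom to the second (oxygen first for a carbonyl),
so a positive projected field stabilises negative charge developing at
the oxygen end. Contributions are bare Coulomb fields of point charges —
no induced polarisation, no reaction field, no periodic images (finite
clusters only). The solvent cutoff (default 15 Å, applied frame by
frame about the probe) excludes *solvent-flagged atoms only*; solute
atoms always contribute, because per-residue protein sums legitimately
include distant charged residues. The probe's own residue is excluded
from the environment by default (a self-field is not an environment
contribution); a flag includes it. Motif records sum all atoms of their
member residues — side chains and backbone alike, a declared choice.
Reports filter |E| > 2 MV·cm⁻¹ and sort by magnitude; residue labels
decorate the chain as primes (chain D → ′, B → ″, C → ‴).

## Interaction-energy decomposition

Gas-phase Coulomb + Lennard-Jones (Lorentz–Berthelot combination), no
distance cutoff. The full pair energy is assigned to the environment
residue, so per-residue energies sum *exactly* to the direct
ligand–environment total; the conventional even-split scheme, kept as a
negative control, halves that sum. Implicit-solvent (GB) terms are not
computed — the bespoke content here is the assignment scheme and the
error rule, not solvation internals — and the report schema carries an
always-empty `E_solv` column for forward compatibility.

**10-block error rule:** split the per-frame series into 10 contiguous
equal blocks (⌊n/10⌋ frames each, tail remainder dropped) and report the
(n−1)-normalised standard deviation of the block means. The same rule
supplies per-λ TI errors. Differential (two-ligand) reports filter by
the reference-state magnitude (|E_int| > 2 kcal·mol⁻¹ by default) and
combine errors in quadrature; the stabiliser report for a region treated
as the ligand uses a 15 kcal·mol⁻¹ threshold on absolute values.

## I/O and CLI

Structures are whitespace-separated PQR (chain column optional,
detected per record; waters/ions flagged solvent by a configurable name
list; numeric fields written with 17 significant digits so write→read
round trips are exact); trajectories are multi-frame XYZ. Both parsers
name the offending line on malformed input. The `fepath` CLI exposes one
subcommand per stage; artifacts are TSV with `#`-prefixed provenance
headers (version, seed, config hash) and are byte-reproducible from
config + seed. Library errors map to distinct exit codes.

## Problem sizes

Benchmarks were sized for a single CPU: 16 × 5000 umbrella samples,
24-node strings with 400 sampling steps per node per iteration, 30 000
TI steps per λ, 100-replicate CV-selection recovery at n = 10⁴. These
sizes leave comfortable statistical margins in every criterion the tests
assert.

## Known limitations

* The sampler's O(dt) discretisation bias sets the accuracy floor of
  sampled benchmarks; the analytic/closed-form paths are exact.
* Sampled string iterations require linear CVs; torsional surrogates
  must be expressed on a linear chart first.
* The overlap coefficient depends mildly on binning; the
  Freedman–Diaconis default and the 0.25 threshold are conventions, not
  derived quantities.
* No MBAR estimator (WHAM is the method implemented), no 2-D umbrella
  sampling, no absolute binding free energies, no restraint-release
  corrections.
* Toy charged structures validate bookkeeping (additivity, cutoffs,
  grouping, equivariance), not force-field realism.
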