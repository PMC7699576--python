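# Methods

This note records the models implemented by `fibriddi`, the numerical and
design choices behind them, what the synthetic study conditions emulate,
and the package's known limitations.

## Structure validation

PDB parsing is delegated to gemmi; the package keeps one atom per
(chain, author residue number, insertion code, atom name), resolving
alternate locations to the highest-occupancy conformer (ties: first
occurrence). Dihedrals follow the IUPAC sign convention in degrees on
(−180, 180], computed by the projection/atan2 formula and cross-checked in
the tests against gemmi-convention oracles and a chirality-inversion
property (mirroring coordinates negates all defined angles).

Ramachandran classification uses a shipped coarse polygonal contour table
(`data/rama_contour.json`), general case with glycine/proline lumped in:
favored boxes around the extended/β, right-handed helical, and left-handed
helical basins, nested strictly inside larger allowed boxes. The source
study does not name the contour it used, so exact reproduction of its
plot is not attempted; the table is deliberately coarse but satisfies the
invariants that matter downstream (favored ⊂ allowed, (−60, −45) favored,
(0, 0) disallowed). Site flexibility is the percentage of a site's
residues, among those with both angles defined, that fall in
favored-or-allowed regions; termini therefore never dilute it.

The deposited fibrinogen E-region crystal structure is not
redistributable with the package, so validation and tests run on a
synthetic stand-in built by an internal-coordinate (NeRF-style) backbone
builder: six chains named N, O, P, Q, R, S whose numbering covers the
three binding-site residue lists, with φ/ψ drawn from the favored helical
and extended basins (ideal bond lengths/angles, trans ω). The builder
doubles as a strong oracle: `compute_phi_psi` must recover the prescribed
torsions to 1e-6°. Passing this says the dihedral/classification pipeline
is correct; it says nothing about any particular crystal structure —
`analysis/01_validate_binding_sites.py --pdb <file>` runs the same report
on real data.

## Druggability

D_g = γ·A_nonpolar·A_druglike/S_max + C with γ = 0.024 kcal/mol and
A_druglike = 300 Å². The score is reported as a positive magnitude with
ΔG_max = −D_g exposed alongside: the defining relation equates a negative
maximum binding free energy with a positive druggability degree, and the
positive convention matches how the scores are quoted. S_max is accepted
as a caller-supplied positive normalization; no recipe is imposed. The
druggable/undruggable cutoff defaults to 0.2 (configurable), chosen once
to sit between the undruggable control regime (≈ 0.08) and the ranked-site
regime (≥ 0.39). Ranking is a stable descending sort, so tied scores keep
input order.

## Tunnel transport

Throughput T = exp(−∫₀ᴸ r(l)⁻ⁿ dl), n = 2 by default (configurable
integer ≥ 1). The cost integral uses the trapezoidal rule on a uniform
grid with at least 8 trapezoids and spacing never above 0.1 Å, the grid
rule of the upstream transport tool; the package's default target spacing
is 0.05 Å because at 0.1 Å the trapezoid error on a profile as gentle as
r(l) = 2 − l is ≈ 1.5e-3, while 0.05 Å brings smooth profiles under 1e-3
and halving the grid again moves results by < 1e-3. Radius is linearly
interpolated between profile samples.

DDI segment detection resamples both trajectories by linear interpolation
onto the union of their position grids restricted to the intersection of
supports (no resampling rule is stated upstream; the union grid loses no
sample of either input), then takes maximal runs where both ΔG < 0,
keeping runs at least `min_length` long. Boundaries land on grid points,
so their resolution equals the local sampling density. The
mutual-overlap criterion is strict: a site qualifies only when the
within-3 Å fraction strictly exceeds 0.5, so exactly half fails.
Trajectory extrema break ties toward the smallest position.

## Two-ligand MWC occupancy

The receptor is a two-state (R/T) unit with n₁ slots for ligand A and n₂
for ligand B; slot s binds with half-saturation constant K_s in R and
K_s/c_s in T (0 < c_s ≤ 1), and L_iso = [T₀]/[R₀] weighs the empty-state
equilibrium. With x_s = X/K_s the grand partition function is
Z = Π(1+x_s) + L_iso·Π(1+c_s x_s) and slot occupancy is the
Boltzmann-weighted bound fraction. The defining equation as published
mixes its notations and is not well-formed term-by-term; the
implementation is the canonical heterogeneous two-ligand generalization
of the MWC framework it cites, and reproduces every stated limit:
L_iso = 0 gives independent-site (Langmuir/Adair) binding exactly, c ≡ 1
makes δ independent of L_iso, δ ∈ [0, 1] and → 1 at saturating doses.
Correctness is pinned by brute-force enumeration of all R/T × occupancy
micro-states for n₁+n₂ ≤ 4 at < 1e-12 relative error. The 1/n mean uses
n = n₁+n₂ by default; the prefactor's n is exposed because its intended
scope is ambiguous. K values are dissociation-style (concentration at
half-saturation in R). No fitting is provided — no data exist to fit.

## Depth quasi-sequence-order descriptors

τ_d sums squared Euclidean Cα distances of residues d apart
(1-based positions, d = 1..L_max); q_ic = f_r/(Σf_r + w·Στ_d) with
normalized type frequencies (Σf_r = 1) and w = 0.1, so q is strictly
decreasing in every inter-residue distance and in w. The depth relation
with the double product over chains is not well-formed as typeset, and
depths of different chains are stated to be independent; the package
therefore exposes (a) the per-chain form D = q_ic·S_max, which satisfies
that independence, and (b) a clearly labeled noisy-OR tunnel-level
aggregate D = [1 − Π_c(1 − q_ic)]·S_max that preserves the printed
motif. Perturbation under binding is modeled by re-evaluating the
descriptors on perturbed coordinates (no closed-form correction is
given), reported as ΔD = D_before − D_after with mean and max |ΔD|.
Chain-count relevance: c ≥ 6 high, 3–5 medium (the unstated c = 5 is
grouped with medium), c ≤ 2 low.

## Energy decomposition

The five pairwise terms act on the surface distance d = center distance −
r_vdW(i) − r_vdW(j): gauss1 = exp(−(d/0.5)²), gauss2 = exp(−((d−3)/2)²),
repulsion = d² for d < 0, an H-bond ramp 1→0 on [−0.7, 0] over
donor–acceptor pairs, and a hydrophobic ramp 1→0 on [0.5, 1.5] over
hydrophobic–hydrophobic pairs, with the published empirical weights
(−0.035579, −0.005156, 0.840245, −0.587439, −0.035069; rotor weight
0.05846) and an 8 Å center-to-center cutoff, all configurable. The
torsional penalty scales the interaction sum by 1/(1 + w_rot·N_rot);
ΔG_rot is reported as the induced difference so the six-term sum equals
the scaled total exactly, keeping the additive decomposition an identity
rather than an approximation. Per-atom analysis credits each weighted
pair term to its ligand atom (scaled by the same torsional factor), so
per-atom credits sum to the ligand total to numerical precision. Atom
typing (hydrophobic/donor/acceptor) is caller-supplied or taken from a
minimal element table — no perception engine is embedded. k-occurrence
histograms bin pose affinities in bins anchored at 0 kcal/mol, tallying
docked and undocked poses separately; no pose-clustering inference is
attempted.

## Dimer configuration ranking

E_b = −(E_total − E_A − E_P) in eV (positive = stabilizing). The packaged
15-row table of drug-dimer results is ranked by |E_b| with a stable sort:
its tied rows follow neither gap nor distance consistently, so preserving
input order is the only faithful rule. E_b < 2.50 eV (strict) classifies
a configuration as non-covalent.

## Solution thermodynamics

k_S is computed by the Laplace relation 1/(ρu²) in SI with an explicit
g/cm³ → kg/m³ conversion; the printed constant-form of that equation is
dimensionally inconsistent with its stated units, so the unambiguous
Laplace relation is implemented instead. V_φ, used by K_φ but never
defined upstream, is caller-supplied or computed by the standard
definition V_φ = M/ρ − 10³(ρ−ρ₀)/(m·ρ·ρ₀).

cac detection fits a continuous two-segment (hinge) least-squares line to
velocity vs molality: candidate breakpoints are the midpoints between
interior abscissae (≥ 2 points per side), the best candidate is refined
by bounded scalar minimization, and the fit must beat a single line by an
F-ratio (default 4.0) or a no-break error is raised. The statistic is
invariant under affine rescaling of the velocity axis.

The Rubingh inversion solves X₁ ∈ (0, 1) of the regular-solution
consistency equation by bracketed root finding (tolerance 1e-10), then
β = ln(α₁·cmc_m/(X₁·cmc₁))/(1−X₁)². β = 0 iff cmc_m satisfies Clint
ideal mixing. k_BT → kcal/mol conversion defaults to 310 K
(physiological; no temperature is stated for the printed conversions,
which are in fact not both consistent with any single temperature, so
conversions are reported unrounded with the temperature attached).

## Synthetic study conditions

Each generator is deterministic given its seed and emits the ground truth
its consuming stage should recover.

* **Tunnel profiles**: Gaussian bottleneck (default 2.4 Å under a 3.5 Å
  ambient radius over 15 Å — the critical-constriction regime of the
  studied tunnel), 0.1 Å sampling, corrugation suppressed near the
  bottleneck so the minimum is exact to < 1 %.
* **Trajectory pairs**: both ligands share a smooth well inside the
  co-interaction window (default 5–10 Å, depths −7.7 / −6.5 kcal/mol, the
  observed affinity scale), correlated > 0.8; outside it the second
  ligand's affinity collapses above zero, emulating trajectories that
  become abruptly independent. Zero divergence with equal depths gives
  identical trajectories.
* **Depth chains**: random-type chains on jittered linear backbones in
  normalized coordinate units, L_max = 2 (the immediate-neighbor coupling
  the descriptor prose describes), scaled so the unbound mean depth is
  exactly 4.0 in the S_max = 100 scale and the bound-state expansion
  realizes a planted mean drop drawn from [1, 2] Å exactly per chain.
  Realistic Cα spacing (3.8 Å) with w = 0.1 would drive q (hence D)
  orders of magnitude below the few-Å depth scale, so the coordinate
  units are normalized rather than physical; the perturbation *mechanism*
  (expansion → larger τ → smaller q → shallower D) is the object under
  test, not absolute distances.
* **Pose ensembles**: hot = tight Gaussian at −7.7 kcal/mol (one dominant
  bin, the k ≈ 100 regime), cold = uniform over −7…−4 (k ≈ 10–25 per
  bin).
* **Ultrasound series**: the mixed cac follows from the planted β via
  self-consistent activity coefficients f₁ = exp(β(1−X₁)²),
  f₂ = exp(βX₁²) — the exact inverse of the Rubingh analysis, which is
  the only way to make β recovery testable without raw instrument data.
  Velocity is piecewise-linear in molality (slopes 50 / 20 m/s per unit
  molality, a clear but instrument-plausible aggregation break) with
  multiplicative Gaussian noise (default 0.1 % relative, the
  reproducibility scale of a vibrating-tube densitometer/velocimeter),
  48 points spanning twice the cac; density rises gently and linearly.

Passing on these conditions demonstrates correctness of the downstream
mathematics under the stated noise and structure; it does not certify
behavior on real instrument drift, non-ideal baselines, or real docking
ensembles.

## Problem sizes

The default test and acceptance runs use: 1,000 (tests) / 500
(acceptance script) random MWC models against brute-force enumeration;
100 seeds for noisy β recovery; 100 random toy complexes for energy
conservation; 20 trajectory pairs for window recovery; 15-row dimer
table; a ~105-residue six-chain stand-in receptor. These sizes give
stable statistics in seconds.

## Known limitations

* Pocket areas (A_nonpolar, S_max) are inputs, not computed from
  structure; the upstream pocket predictor is out of scope.
* Tunnel geometry and docking poses are consumed, never generated; the
  printed throughput values (0.90–0.96) rest on unpublished radius
  profiles and serve only as plausibility context.
* No electronic-structure computation: dimer energies are table inputs.
* The Ramachandran contour is coarse and polygonal; borderline residues
  near basin edges may classify differently than under a
  density-derived contour.
* The Rubingh solver rejects cmc_m values whose boundary limits share a
  sign; physically those correspond to strongly non-ideal double-root
  regimes outside the studied range.
* mmCIF input, hydrogen placement, and protonation are out of scope.
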