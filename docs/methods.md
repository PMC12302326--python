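# Methods

This note documents the models, conventions and design choices behind
`padock`, in the spirit of a methods appendix: what each stage assumes, which
knobs matter, and what the synthetic closed-loop tests do and do not
demonstrate.

## Units and numbering

Coordinates are in Å, energies in kJ mol⁻¹, charges in elementary charge
units, time in ps (frame spacing) and hours (kinetics). Residue numbering is
taken verbatim from input files, so positions such as F134, T267, D304 or
R330 address the same residues as in the source structure. Structures and
trajectories travel as PDB v3.3 (single- or multi-model) and concatenated
XYZ; binary MD formats are out of scope because desk-scale trajectories are
small. Nonbonded parameters are a delimited table
`residue, atom, charge, sigma, epsilon` combined with Lorentz–Berthelot
rules; the packaged table is a self-contained toy parameter set, not a
reproduction of any published force field.

## Oligomer construction

A PA 6 oligomer is a chain of 6-aminohexanoic-acid repeat units
(N, C2…C6, C7=O) with either an acetyl cap and a carboxylate terminus
(Ace–[6-AHA]ₙ–COO⁻, net −1) or an N-methylamide cap and an ammonium terminus
(NMe–[6-AHA]ₙ–NH₃⁺, net +1) — the proxies for a chain continuing into the
polymer on one side and ending on the other. Geometry is built from internal
coordinates with standard amide/alkane bond lengths and angles; the default
conformation is fully extended (all backbone torsions anti). Amide ω
dihedrals are frozen trans: amide rotation is not a meaningful degree of
freedom at this resolution. Only polar hydrogens (amide N–H, ammonium H) are
modelled; hydrogen-bond geometry needs them and aliphatic hydrogens would
only slow the nonbonded sums. Rotatable bonds are the backbone single bonds
whose rotation moves heavy atoms on both sides — terminal methyl and
ammonium rotors and amide C–N bonds are excluded.

The "attack site" — the scissile amide modelled near the catalytic
threonine — is taken to be the central backbone amide (between units 2 and 3
for a tetramer), so that both termini can occupy the pocket symmetrically.
This is a documented assumption; nothing in the workflow depends on it unless
the `constrain_attack_site` docking option is enabled, which filters final
poses by the distance of that amide nitrogen to the catalytic-site centroid
(6 Å default).

## Incremental docking

The docking engine is a deliberately transparent fragment-growth algorithm
with the population-plus-affinity ranking rule, intended for toy pockets and
method-level reasoning rather than production screening:

1. **Seeding.** The first repeat unit (with its cap) is placed rigidly:
   positions uniform in a sphere (R = 8 Å default) around the catalytic-site
   centroid, orientations uniform over rotations. Placements with any
   heavy-atom pair closer than 2.0 Å to the receptor are discarded. The
   receptor is rigid throughout; receptor flexibility is the job of the
   downstream trajectory stage.
2. **Growth.** The best-scoring seeds (top `keep_k`, 50 by default) are grown
   one unit per increment. Each new backbone torsion is sampled from
   {60°, 180°, −60°} with uniform ± 15° jitter (`n_dihedral_samples` values
   per bond); every combination is built in the world frame, clash-checked
   (receptor and intramolecular, heavy atoms beyond geminal pairs), scored,
   and the global top `keep_k` survive. Torsions chosen in earlier
   increments stay fixed.
3. **Ranking.** Complete poses are clustered by substrate heavy-atom RMSD
   (2.0 Å leader clustering, no superposition — poses share the receptor
   frame). Clusters rank by population, ties broken by mean score; the
   reported pose is the lowest-score member of the top cluster.

The score is the short-range LJ + Coulomb interaction energy with a 10 Å
cutoff and no long-range correction. The result field is named
`binding_energy_estimate` deliberately: it contains no entropic or
desolvation terms and is an affinity *proxy*, not a free energy.

Both substrate orientations (mirrored termini, e.g. Ace–[6-AHA]₄–COO⁻ vs
⁻OOC–[6-AHA]₄–Ace) are docked as independent runs with independent seed
streams derived from the master seed; at the resolution of a rigid toy
pocket, growing the mirrored chain is statistically equivalent to an
independent placement of the same chemistry, so the orientation label is a
bookkeeping device for reporting, not a different topology.

Determinism: all sampling flows from `numpy` generators seeded from the
run seed, so identical configuration and seed give bit-identical results.

## Trajectory analytics

* **Contacts.** A residue contacts the substrate in a frame when the minimum
  distance over all its atoms (hydrogens included) to any substrate atom is
  ≤ 2.5 Å, cutoff inclusive. The contact frequency is the percentage of
  frames in contact; replicas aggregate as mean ± SEM (SEM = s/√n across
  replicas). Hotspot nomination selects residues with replica-mean f ≥ 50%,
  minus an exclusion set for residues that must not be mutated (the
  catalytic nucleophile). Δf between two variants is the difference of means
  with SEMs combined in quadrature.
* **Hydrogen bonds / salt bridges.** Donor–acceptor heavy-atom distance
  ≤ 3.5 Å plus donor–H–acceptor angle ≥ 150° (hydrogen bonds, donor
  hydrogens identified from frame-0 covalent geometry), or any positively
  charged N to negatively charged O pair ≤ 4.0 Å (salt bridges, signs read
  from assigned partial charges, |q| > 0.2 e by default). These thresholds
  are standard MD-analysis values and are exposed as arguments. Occupancy is
  the percentage of frames with at least one qualifying interaction.
* **Conditional energies.** The per-frame enzyme–substrate LJ+Coulomb energy
  is split by the bond state of an interaction series; ΔE = E_bound −
  E_unbound is reported only when both states occur in ≥ 5 frames, with a
  propagated standard error √(s_b²/n_b + s_u²/n_u). The weighted state means
  reconstruct the total energy to 1e-9 relative — a conservation check the
  tests enforce.
* **Side-chain conformations.** Aromatic rings (Phe/Tyr/Trp) are classified
  per frame by the angle θ between Cβ→ring-centroid and the pocket axis
  (catalytic-site centroid → pocket-mouth centroid): θ ≤ 45° is
  "conformation 1, toward the active site", else conformation 2. An
  axis-angle rule with two parameters was preferred over χ-angle clustering
  because it is reproducible and matches the verbal vertical/horizontal
  distinction it implements; the 45° boundary is configurable.

## Variant evaluation

Specific activity divides released amine (μM, i.e. μmol per litre) by enzyme
load (mg per litre) and incubation time (h); the reaction volume cancels.
Molar enzyme concentrations convert via the molecular weight (50 nM at
38 kDa ↔ 1.90 mg L⁻¹), and the two unit paths agree within 2% by
construction. Amine quantification uses a free-intercept linear calibration
(rejected below R² = 0.98, out-of-range samples flagged); background
correction subtracts a matched blank series pointwise, flooring negative
values at zero while counting them — background can exceed signal at early
time points.

Fold-changes are ratios of means with first-order error propagation and are
reported to one decimal, half-up. The epistasis null is multiplicative:
fold-changes are ratios, so independence of substitutions means additivity in
log space; a combination is negative/positive when its fold falls
below/above the product of the single folds by more than k·σ (k = 2 default,
σ propagated from the singles). Michaelis–Menten fits use nonlinear least
squares with V₀ = max(v), K₀ = median(x), positive-parameter bounds, and a
few K₀ restarts; the conventional and inverse forms differ only in which
variable saturates (substrate loading vs enzyme concentration).

Degree of depolymerization converts a soluble-product composition to the
mass fraction of the solid released: DoD% = 100 · Σᵢ nᵢ uᵢ M_repeat / loading,
with uᵢ repeat units per product (1 for 6-AHA, 2 for the dimer and for the
PA 6,6 monomer) and M_repeat = 113.16 g mol⁻¹, the in-chain repeat mass
(condensation subtracts one water from the 131.17 g mol⁻¹ free monomer).
On this basis complete depolymerization is exactly 100%; a
`basis="free-monomer"` flag switches the accounting. The monomer fraction is
the share of released repeat mass carried by free 6-AHA.

Melting temperatures come from the maximum of the smoothed (Savitzky–Golay)
first derivative of the melt curve, refined by a two-state Boltzmann fit
whose covariance supplies the standard error; curves whose derivative peaks
at a grid boundary are rejected as having no transition in range. The
derivative-first design matches thermal-shift practice and keeps the
estimator instrument-agnostic.

## Conservation

Column information content is IC = log₂20 − H with H the Shannon entropy of
the amino-acid frequencies; gaps are excluded from the entropy but reported
as a per-column gap fraction. No small-sample correction is applied by
default (a pseudocount argument exists), so a single-sequence column scores
the full 4.32 bits. "Variable-in-conserved" positions have own IC ≤ 1.0 bit
while the mean IC of their 9-column window (centre excluded) is ≥ 3.0 bits;
all three numbers are parameters. This is the pattern expected of positions
under relaxed constraint sitting next to catalytic residues.

## Synthetic data: what it emulates and what it does not

The generators plant statistics directly rather than simulating physics,
because the object under test is the analysis code. The trajectory generator
builds a statistical complex: one pseudo-atom per enzyme residue with a
dedicated substrate partner toggled between contact and non-contact
positions by Bernoulli draws at the planted frequency; a donor/acceptor pair
realizing compliant hydrogen-bond geometry in bonded frames and leaving all
cutoffs otherwise; a fixed pure-Coulomb anchor pair whose charges are chosen
so the energy analysis *computes* the planted unbound baseline (and the
donor charges the planted ΔE) from coordinates; and an aromatic ring placed
along or across the pocket axis at the planted state fractions. The default
planted profile puts eleven residues at or above the 50% contact rule — the
always-contacting catalytic stand-in (residue 267) and the bond-donor
(residue 330, through its occupancy) among them — so the nomination step has
a realistic exclusion case. Planted contact frequencies keep a ≥ 6-point
margin from the 50% threshold so that Bernoulli sampling noise (σ ≈ 1.5
points for the 3 × 300-frame default) cannot flip the selected set.

Melt curves are two-state Boltzmann sigmoids with Gaussian noise; screening
plates apply mean-preserving lognormal noise to planted fold-changes and
include background wells; alignments are sampled column-independently from a
frequency profile; time courses integrate a saturating release plus a linear
background, so a zero-enzyme series reproduces the blank exactly.

Passing the closed-loop tests shows that the analyses recover known truth
under their own statistical model — independent frames, uncorrelated
residues, two-state bonds, column-independent evolution. Real trajectories
are autocorrelated, real plates have spatial effects, and real families have
phylogenetic structure; none of that is claimed.

Recovery tolerances in the tests are z-intervals using the *known* sampling
variance of the planted model (binomial for occupancies and contact
frequencies, Gaussian for conditional energies), i.e. two or three standard
errors of the estimator at the generated problem size — not empirical SEMs
from three replicas, whose 2-SEM t-intervals would undercover.

## Problem sizes and numerical choices

Default study sizes: 3 replicas × 300 frames for trajectory statistics;
600 rigid-body seeds, keep-k 30, 3 torsion samples per bond for the
pipeline's docking stage (a 2-unit chain in the toy channel); 500 simulated
datasets of 8 loadings at 5% noise for the Michaelis–Menten calibration; 100
melt curves at 0.5 °C grid and 1% noise for the T_m calibration; 60
sequences × 310 columns for conservation. These sizes make every stage exact
enough for its planted margins while keeping a full pipeline run around ten
seconds. Ties in pose clustering are broken by mean score; floating-point
determinism is maintained by seeding every generator from the run seed and
rounding serialized floats to six decimals.

## Known limitations

* The docking engine is a methodological reimplementation of incremental
  fragment growth, not a replication of any production workflow; its scores
  are nonbonded proxies without entropy or desolvation.
* No periodic boundaries, no solvent, no long-range electrostatics: analyses
  operate on solute atoms with a plain cutoff.
* PA 6,6 oligomer topology (hexamethylenediamine/adipate) is an extension
  point, not implemented; protonation states are fixed by the chosen
  terminus.
* Whole-residue vs side-chain-only donor selection for occupancies is the
  caller's choice of atom groups; the synthetic defaults use side chains.
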