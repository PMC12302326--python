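# padock

Computational support for directed-evolution campaigns on polyamidases —
enzymes that hydrolyze nylons such as polyamide 6 (PA 6) and PA 6,6.
Engineering these interfacial depolymerases leans on a recurring set of
computational steps: dock a flexible oligomeric substrate into the binding
pocket, analyze enzyme–substrate interactions along molecular-dynamics
trajectories to nominate positions for mutagenesis, and turn screening and
characterization measurements into fold-changes, kinetic parameters, melting
temperatures and epistasis calls. `padock` packages those steps as a tested,
reusable pipeline for desk-scale work.

It is aimed at protein engineers and structural bioinformaticians who have
structures, trajectories and plate data in hand and want reproducible
analytics — not an MD engine or a production docking code.

## What it computes

**Incremental docking.** PA 6 oligomers ([6-AHA]ₙ chains with one capped and
one charged terminus, e.g. Ace–[6-AHA]₄–COO⁻ as the carboxy-terminus proxy)
have too many rotatable bonds for rigid docking. `padock` grows the chain
unit by unit inside a rigid pocket: random rigid-body seeds of the first
unit, per-bond backbone-torsion sampling from {60°, 180°, −60°} ± jitter for
each added unit, global top-k survivor selection, then greedy leader
clustering of complete poses ranked by (population, mean score). The score is
the short-range nonbonded energy

E = Σ_{ij, r ≤ r_c} 4ε_ij[(σ_ij/r_ij)¹² − (σ_ij/r_ij)⁶] + k_e q_i q_j / r_ij

with Lorentz–Berthelot mixing, r_c = 10 Å by default.

**Trajectory analytics.** Per-residue contact frequencies f (% of frames with
any-atom distance ≤ 2.5 Å to the substrate), hotspot nomination at f ≥ 50%
with the catalytic nucleophile excluded, hydrogen-bond (d(D···A) ≤ 3.5 Å,
∠D-H-A ≥ 150°) and salt-bridge (N⁺···O⁻ ≤ 4.0 Å) occupancies, interaction
energies conditioned on the bond state (ΔE = E_bound − E_unbound),
contact-frequency differences Δf between variants, and a vertical/horizontal
classifier for aromatic side-chain conformations. Replicas aggregate as
mean ± SEM.

**Variant evaluation.** Specific activities (μmol₆₋AHAeq h⁻¹ mg_enzyme⁻¹),
fold-changes with first-order error propagation, conventional and inverse
Michaelis–Menten fits (v = V_max·x/(K_m + x), x = substrate loading or enzyme
concentration), degree of depolymerization (% w/w from product compositions),
melting temperatures from two-state melt curves, and epistasis classification
against the multiplicative null (expected fold = product of single folds).

**Conservation.** Per-column information content IC = log₂20 − H of a family
alignment, and detection of variable positions embedded in conserved patches.

**Synthetic data.** Every input the pipeline consumes can be generated with
planted ground truth (contact frequencies, bond occupancies, ΔE, fold-changes,
T_m, conservation patterns, pocket geometries), which is the backbone of the
test suite.

## Worked example

```python
from padock.kinetics import fold_change, classify_epistasis, round_fold, extract_tm
from padock.synthetic import make_melt_curve, default_trajectory_truth, make_trajectory
from padock.trajectory import (contact_frequencies, select_hotspots,
                               detect_interactions, interaction_energy_series,
                               conditional_energy, aggregate_replicas)

# fold-change with error propagation from two measured activities
fold, sem = fold_change((1026.0, 25.0), (304.0, 9.0))
print(f"PA 6,6 fold-change: {round_fold(fold)} +/- {sem:.1f}")

# epistasis of a recombined double against its singles
cls, expected, _ = classify_epistasis([(2.8, 0.1), (3.0, 0.1)], (5.3, 0.1))
print(f"F134W/D304M epistasis: {cls} (expected {round_fold(expected)}x, observed 5.3x)")

# hotspot nomination on three planted trajectory replicas
truth = default_trajectory_truth()
trajs = make_trajectory(truth, n_frames=300, n_replicas=3, seed=7)
profiles = [contact_frequencies(t) for t in trajs]
print("hotspots:", select_hotspots(profiles, threshold=50.0, exclude={267}))

# bond occupancy and the energy drop on bond formation
occs, deltas = [], []
for t in trajs:
    hb = detect_interactions(t, "donor_sidechain", "substrate_terminus", "hbond")
    ce = conditional_energy(interaction_energy_series(t), hb)
    occs.append(hb.occupancy); deltas.append(ce.delta_e)
print("occupancy %.0f%%, dE %.0f kJ/mol" %
      (aggregate_replicas(occs)[0], aggregate_replicas(deltas)[0]))

# melting temperature of a two-state melt curve
curve, _ = make_melt_curve(tm=89.9, seed=2)
print("Tm %.1f C" % extract_tm(curve)[0])
```

prints

```
PA 6,6 fold-change: 3.4 +/- 0.1
F134W/D304M epistasis: negative (expected 8.4x, observed 5.3x)
hotspots: [134, 91, 305, 137, 330, 98, 146, 144, 111, 139]
occupancy 68%, dE -98 kJ/mol
Tm 89.9 C
```

The fold-change says the variant turns over the PA 6,6 substrate 3.4× faster
than its parent. The double substitution improves activity 5.3-fold where
independent effects would predict 8.4-fold — negative epistasis. The hotspot
list contains every residue in contact with the substrate for at least half
the simulation time (the catalytic T267 is excluded from nomination); the
arginine at 330 holds the charged substrate terminus through a hydrogen bond
two-thirds of the time, and frames with that bond are ~98 kJ/mol lower in
enzyme–substrate interaction energy.

The same operations are available from the shell:

```bash
padock synth traj --seed 7 --out data/
padock traj contacts --traj data/replica0.pdb --top data/topology.pdb --out contacts.tsv
padock dock --enzyme pocket.pdb --params nb.tsv --units 4 --seed 42 --out dock.json
padock run --out results/          # full workflow on the synthetic bundle
```

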