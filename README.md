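# campsn

Dynamic protein-structure-network (PSN) analysis and binding energetics for
protein–peptide complexes, built around the workflow used to compare
wild-type and arrhythmia-associated calmodulin (CaM) variants bound to a
ryanodine-receptor (RyR2) peptide.

## What it computes

Given conformational ensembles of a complex (multi-model PDB, e.g. from MD
replicas), the pipeline:

1. **Interaction persistence** — detects hydrophobic contacts (side-chain
   centers of mass within 5.0 Å), salt bridges (oppositely charged group
   atoms within 4.5 Å) and hydrogen bonds (donor–acceptor ≤ 3.5 Å, angle
   ≥ 120°) in every frame and tabulates, per residue pair and class, the
   percentage of frames in which the interaction is present.
2. **PSN topology** — determines the persistence threshold *pT* as the
   largest threshold at which the biggest hydrophobic cluster is still
   half-maximal, filters all interaction classes at *pT*, and reports degree
   centrality, hubs (degree ≥ 4), high-degree hubs (≥ 6), and per-residue
   ΔDegree between a variant and a reference network.
3. **Communication Robustness** — for residue pairs (A, B),

       CR(A,B) = nAB · pT / l

   where *nAB* is the number of distinct shortest paths, *l* their length in
   edges, and *pT* enters as a fraction of 1. Preset queries map the
   communication among the four EF-hand Ca²⁺-coordinating glutamates
   (E31, E67, E104, E140) and from each EF-hand to the target interface.
4. **Sampling reproducibility** — Cα-covariance PCA per replica and
   concatenated, essential subspaces of the top S = 20 components, subspace
   overlap via RMSIP = √((1/S)·Σ(vₙⁱ·vₘʲ)²), and LDA of the 2-PC projections
   with replica labels (accuracy at chance ⇒ consistent sampling).
5. **Binding energetics** — 1:1 Langmuir SPR analysis (single-exponential
   dissociation → k_off; pseudo-first-order association, k_obs = k_on·C +
   k_off → k_on; mean ± SEM over injections; t½ = ln2/k_off; K_D =
   k_off/k_on) and ITC-derived thermodynamics (ΔG = RT·ln K_D = ΔH − TΔS,
   ΔΔG = ΔG_mut − ΔG_WT, fold-change ↔ ΔΔG conversion).

A synthetic-data module generates every input with known ground truth —
toy two-chain complexes, multi-replica Gaussian ensembles with planted
collective modes, Bernoulli contact streams, and noisy Langmuir
sensorgrams — so every estimator is testable for parameter recovery.

## Worked example

```python
import campsn

# 1:1 Langmuir titration at the wild-type CaM–RyR2 rates
spec = campsn.SensorgramSpec(kon=15e3, koff=7.1e-3, noise_sd=0.2, seed=1)
fits = [campsn.fit_injection(sg) for sg in campsn.simulate_sensorgram(spec)]
params = campsn.aggregate_kinetics(fits)
print(f"koff = {params.koff:.2e} s-1, t1/2 = {params.t_half:.1f} s")
# koff = 7.10e-03 s-1, t1/2 = 97.6 s

th = campsn.thermodynamics_from_itc(1.0, kd=8.6e-9, dh=-20.0)
print(f"dG = {th.dg:.1f} kcal/mol")
# dG = -11.0 kcal/mol

print(f"{campsn.fold_change_to_ddg(3.9):.2f} kcal/mol destabilization")
# 0.81 kcal/mol destabilization
```

A dissociation rate of 7.1×10⁻³ s⁻¹ corresponds to a complex half-life of
97.6 s; a K_D of 8.6 nM at 25 °C to a binding free energy of −11.0
kcal/mol; and a 3.9-fold loss of affinity to a 0.81 kcal/mol
destabilization of the complex.

The same workflow runs from the shell:

```bash
campsn simulate ensemble --config ens.json --out ens/
campsn persist --traj ens/replica-0.pdb --traj ens/replica-1.pdb --out persistence.csv
campsn psn build --persistence persistence.csv --auto-pt --out net.graphml
campsn psn hubs --net net.graphml --ref wt.graphml
campsn communicate --net net.graphml --sources preset:efhands --targets preset:interface
```

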