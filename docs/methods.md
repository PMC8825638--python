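# Methods

## Interaction detection and persistence

Residue–residue interactions are detected geometrically in every frame of a
conformational ensemble, in three classes:

* **Hydrophobic**: the mass-weighted centers of the side-chain heavy atoms
  of two hydrophobic residues (ILE, LEU, VAL, PHE, MET, ALA) lie within
  `d_hydro` (default 5.0 Å).
* **Salt bridge**: any two oppositely charged group atoms (ASP OD1/OD2,
  GLU OE1/OE2 vs LYS NZ, ARG NE/NH1/NH2, HIS ND1/NE2) lie within `d_salt`
  (default 4.5 Å).
* **Hydrogen bond**: donor–acceptor heavy-atom distance ≤ `d_hb` (default
  3.5 Å) and an angle ≥ `theta_hb` (default 120°). When the donor proton is
  present the angle is donor–H–acceptor; protonless inputs (common for
  multi-model PDB ensembles) fall back to the angle at the donor heavy atom
  between its covalent antecedent and the acceptor. A donor with neither
  proton nor resolvable antecedent is accepted on distance alone.

These cutoffs are standard residue-network practice and are fully
configurable (`DetectionConfig`, serialisable to JSON so a run records what
it used). Sequence-adjacent residues (|Δindex| ≤ 1 within a chain) are never
connected: covalent neighbours carry no network information. π-stacking,
cation–π and water-mediated interactions are out of scope.

Persistence of a (pair, class) interaction is the percentage of frames in
which it is detected. It is invariant under frame reordering, and the
persistence of concatenated replicas equals the frame-count-weighted mean of
per-replica persistences (an exact identity used as a test). Interaction
classes are tabulated separately and merged only at network-build time,
because the persistence threshold is defined on the hydrophobic subnetwork
alone.

## Persistence threshold (pT) and network construction

Transient contacts are filtered with a single complex-wide threshold chosen
by the *half-maximal hydrophobic cluster* criterion: scanning thresholds t
(default step 0.1% over 0–100%), keep hydrophobic edges with persistence
≥ t and record the node count of the largest connected component. pT is the
largest scanned threshold at which that size is still ≥ ceil(max/2), where
max is the size at the lowest scanned threshold. The crossing rule
(ceiling, ties toward the larger threshold) is our operational choice — the
criterion is usually stated without one — and errs toward stricter
networks. Residues that ever appear in a hydrophobic pair remain nodes at
every threshold, so the size floor is 1; a table whose largest cluster
never exceeds one node has no meaningful pT and is an error. The criterion
is evaluated on hydrophobic edges only; the resulting pT then filters all
three interaction classes. Parallel class edges between the same pair
collapse to one adjacency for degree and path purposes, keeping their class
annotations.

Degree centrality is the number of distinct neighbours; hubs are residues
with degree ≥ 4 and high-degree hubs ≥ 6 (both configurable — where the
field's wording wavers between "= k" and "≥ k" we use ≥). ΔDegree is
degree(variant) − degree(reference) over the shared node set, optionally
restricted to residues that are high-degree hubs in at least one of the two
networks.

## Communication Robustness

CR(A,B) = nAB · pT / l, with l the unweighted shortest-path length between
residues A and B and nAB the number of distinct geodesics. Paths are
unweighted because l is a hop count; persistence already acted at the
filtering stage. pT enters as a fraction of 1 (0.242 for 24.2%), keeping CR
in the O(0.1–0.5) range in which "robust" communication bins (0.1/0.2/0.3/
0.4) are conventionally drawn; a switch restores the percent scale.
Disconnected pairs score 0 — the absence of robust communication, not an
undefined value. nAB is counted by dynamic programming over BFS layers
(counts propagate along (dist+1) edges), which is linear in edges per
source; tests verify it against exhaustive geodesic enumeration. The
default query uses the four EF-hand bidentate glutamates as sources and the
wild-type target-interface residue list as targets; the published interface
list names position 15 twice ("E15" and "A15"), so both tokens are accepted
and whichever resolves in the network is used, with unresolvable tokens
reported and skipped.

## Essential dynamics and replica consistency

Each frame is least-squares superposed (rotation + translation, Kabsch via
`scipy`'s `Rotation.align_vectors`) onto a reference on Cα atoms; the
default reference is the first frame of the (concatenated) ensemble and is
recorded in output metadata. The 3N×3N covariance of the flattened Cα
coordinates about the ensemble mean is diagonalised; the essential subspace
keeps the top S = 20 eigenpairs (plain, not mass-weighted, coordinates).
Eigenvector signs are fixed by making the largest-magnitude component
positive, for reproducible outputs; requesting S beyond the covariance rank
truncates with a warning.

Subspaces are compared with RMSIP = √((1/S)·Σₙₘ(vₙⁱ·vₘʲ)²) ∈ [0, 1], which
is invariant under orthonormal re-mixing within either subspace. As a
qualitative consistency criterion, same-distribution replicas from the
synthetic generator at default settings give replica-vs-concatenated RMSIP
above 0.8 — asserted as a property of the generator plus pipeline, at the
desk-scale problem sizes below.

Replica distinguishability is assessed by projecting all frames onto the
first two PCs of the concatenated covariance and fitting LDA with replica
labels, reporting stratified 5-fold cross-validated accuracy (in-sample
accuracy is optimistically biased; chance is 1/n_replicas for balanced
replicas) and pairwise density overlap coefficients, Σ min(p, q), on a
shared 50×50 histogram grid. The overlap coefficient is an operational
stand-in for "substantial overlap of the density functions"; with a few
hundred frames per replica it underestimates the true distributional
overlap (sparse histograms), so the LDA accuracy is the primary
consistency readout and the overlap is reported for inspection.

## SPR kinetics

The two-step 1:1 Langmuir scheme: the dissociation phase is fitted first to
R(t) = R₀·e^(−k_off·(t−t₀)) + baseline by nonlinear least squares. The
constant baseline (default on) absorbs instrument drift; disable it to
recover rates from noiseless traces to machine precision. A non-decaying
phase (end value ≥ start value) or a non-positive rate estimate is flagged
rather than fitted. The association phase is then fitted to
R(t) = R_eq·(1 − e^(−k_obs·t)) and k_on = (k_obs − k_off)/C; injections with
k_obs ≤ k_off (the zero-concentration limit) are flagged as yielding no
k_on.

Per-injection parameters are aggregated as mean ± SEM across injections,
k_off as a plain mean. For k_on the default is an inverse-variance weighted
mean using each association fit's k_obs variance: at the lowest
concentrations k_obs − k_off is small and division by C amplifies fit noise,
so the plain mean is dominated by the least-informative injections
(single-titration error up to ~17% at 1% noise, versus ~2% weighted). This
remains a per-injection-then-average scheme, not a global k_obs-vs-C
regression; `weight_kon=False` restores the plain mean. t½ = ln2/k_off and
K_D = k_off/k_on are computed from the aggregated means; t½·k_off = ln 2
holds exactly by construction.

## ITC thermodynamics

The module consumes fitted one-set-of-sites parameters (N, K_D, ΔH at
temperature T) rather than raw injection heats. ΔG = R·T·ln K_D with K_D in
molar and R = 1.9872×10⁻³ kcal·mol⁻¹·K⁻¹, T defaulting to 298.15 K; TΔS =
ΔH − ΔG, so the closure ΔG = ΔH − TΔS holds to rounding. The sign
convention keeps ΔG negative for sub-molar K_D. ΔΔG = ΔG_mut − ΔG_WT;
an affinity fold-change f maps to a ΔΔG magnitude R·T·ln f, negative
(stabilizing) for affinity gains. Isotherms that a single-site model cannot
describe are screened by a monotonicity check on the injection-heat
magnitudes (`flag_biphasic_isotherm`): a secondary rise larger than 5% of
the heat range along the titration flags the titration as unfittable.
Full isotherm regression and mass-transport or bivalent SPR models are
out of scope.

## Synthetic data: what it emulates and what it does not

The generator stands in for microsecond MD trajectories and biosensor raw
data:

* **Toy complexes** are deterministic pseudo-helical two-chain topologies
  (chain A helix, chain B extended peptide facing it) whose residues always
  cover the hydrophobic/acidic/basic/polar classes. Geometry is plausible
  enough for contact detection, not stereochemically correct.
* **Ensembles** displace whole residues rigidly along prescribed
  orthonormal Cα modes with Gaussian amplitudes, plus i.i.d. isotropic
  noise per atom coordinate; the Cα covariance converges to
  Σ varₖ·vₖvₖᵀ + σ²I. Mode generators project out rigid-body translations
  and rotations so planted modes survive superposition. Replica r uses
  seed + r: reproducible but distinct replicas.
* **Contact streams** are independent Bernoulli draws per (pair, class),
  matching the persistence estimator's counting model exactly but ignoring
  the temporal autocorrelation of real contacts.
* **Sensorgrams** invert the 1:1 Langmuir model with i.i.d. Gaussian noise
  (the simplest model consistent with the residuals of 1:1 fits); defaults
  mirror the experimental design of the CaM–RyR2 titrations — injections of
  0.25–3 µM followed for 60 s of association and 300 s of dissociation,
  k_on = 1.5×10⁴ M⁻¹s⁻¹, k_off = 7.1×10⁻³ s⁻¹, R_max = 100 RU, 0.5 RU
  noise.

Passing recovery tests on these inputs demonstrates the estimators are
correct under their own model assumptions; it does not validate force
fields, sampling adequacy of real MD, or instrument artefacts
(mass-transport limitation, baseline drift beyond a constant, correlated
noise).

## Problem sizes and numerical choices

Tests and the acceptance script use 20+5-residue complexes, ensembles of
100–2000 frames, 4 replicas, networks of ≤ 15 residues for path-census
cross-checks, and 6-concentration titrations repeated over 20 seeds —
sizes at which every brute-force oracle (geodesic enumeration, union-find
clustering, filter-and-count) is exact and fast. pT scanning uses a 0.1%
step; eigen-decomposition uses `numpy.linalg.eigh`; fits use
`scipy.optimize.curve_fit` with analytic-free defaults and documented
initial guesses. All randomness flows through `numpy.random.default_rng`
seeds carried in the spec objects.

## Known limitations

* Interaction cutoffs are defaults of the trade, not fitted to any
  particular force field or structure-preparation protocol.
* The hydrophobic-cluster criterion is computed on hydrophobic edges only;
  pipelines that define pT on the full network will differ.
* H-bond detection without protons is necessarily approximate (antecedent
  geometry is a proxy for the proton position).
* LDA overlap coefficients depend on the histogram grid and sample size;
  compare like with like.
* The kinetic scheme assumes pseudo-first-order association and a single
  exponential dissociation; heterogeneous surfaces or rebinding produce
  biased rates that no amount of averaging repairs.
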