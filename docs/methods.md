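# Methods

This note records the models implemented in `protdyn`, the defaults and why
they were chosen, what the synthetic fixtures do and do not emulate, and the
numerical conventions that matter for reproducibility.

## Structures and mutant modelling

PDB input/output goes through gemmi. Only one model is read (default the
first); alternate locations are resolved by keeping the highest-occupancy
atom, ties broken alphabetically by altloc id. HETATM ligands and waters are
kept aside and never enter any elastic network. Common modified residues
(MSE, SEP, TPO, …) are mapped to their parent amino acid; unmappable
residues are excluded from the coarse model and reported. Author residue
numbering and insertion codes are preserved verbatim; internal site indices
are 0-based and contiguous.

Mutants are modelled by idealized side-chain replacement: backbone
(N, CA, C, O) and, where present, Cβ are kept fixed; remaining side-chain
atoms are placed by internal coordinates (NeRF) from a fixed table of ideal
bond lengths and angles with a single common rotamer (χ1 = −60° unless the
residue's geometry dictates otherwise) and no minimization. Ring closure for
Pro/His/Phe/Tyr/Trp is idealized-planar, which is geometrically approximate
but adequate for contact counting and surface burial — the only uses the
mutant structure has here. Because the backbone never moves and the builder
is deterministic, ΔΔS_vib is exactly antisymmetric under exchanging
wild-type and mutant structures. Users who prefer their own mutant models
can pass a pre-built mutant structure.

## Elastic networks

Two Cα-level force fields:

- **anm** — springs of uniform constant γ (default 1, dimensionless scale)
  between all site pairs within a cutoff (default 15 Å). Force constants set
  an overall scale only: eigenvalues are exactly linear in γ, so every
  reported difference or ratio is scale-free.
- **encom** — a sequence-dependent network with four harmonic terms:
  nearest-neighbour stretch (k = 100), three-site angle (k = 20) and
  four-site dihedral (k = 1) terms along the Cα trace, plus a long-range
  pair term k_lr·(w0 + w_ij) for pairs at sequence separation ≥ 3 within
  18 Å, where w_ij sums an element-pair weight over heavy-atom contacts
  closer than 4.5 Å. The bonded-constant ladder (stretch ≫ angle ≫
  dihedral) follows common coarse-grained Go-like practice. The element
  weights (C/N/O/S pairs, values 1.0–1.3) are this package's own defaults
  and are fully configurable; with all weights equal and bonded terms
  zeroed the builder reduces exactly to a contact-count-weighted ANM, which
  is tested.

Every bonded term is harmonic in an internal coordinate q (length, angle,
dihedral) whose rest value is taken from the input geometry. At that minimum
the Hessian contribution is exactly k·∇q∇qᵀ — the q·∇²q cross-term vanishes
— so symmetry and translational invariance hold to machine precision by
construction rather than by tolerance.

Masses default to total residue masses by type; a unit-mass scheme is
provided because much of the Cα-network literature omits masses. Results
record which scheme was used.

## Normal modes and trivial-mode classification

The mass-weighted symmetric eigenproblem is solved densely
(scipy.linalg.eigh). Trivial (rigid-body) modes are identified by
|λ| ≤ 10⁻⁸·λ_max combined with a floor of 6 (5 for collinear site sets,
detected by singular values of the centred coordinates); disconnected
networks yield more and the disconnection is recorded as a Hessian warning.
Eigenvector sign is fixed by making each column's largest-magnitude
component positive, so porcupine vectors and trajectories are reproducible
across runs. Comparisons against oracles are done eigenvalue-wise plus by
subspace projection, never vector-by-vector, to stay robust under
degeneracy.

## Derived dynamics

With displacements mapped back from mass-weighted coordinates
(u_k,i = e_k,i/√m_i):

- mean-square fluctuation: msf_i = Σ_k |u_k,i|²/λ_k over selected
  non-trivial modes (uniform k_BT scale omitted — all uses are ratios);
- cross-correlation: C_ij = cov_ij/√(cov_ii·cov_jj),
  cov_ij = Σ_k u_k,i·u_k,j/λ_k;
- deformation energy: per spring ½k(Δℓ)² along the mode displacement, split
  half to each endpoint, normalized to sum 1 per mode; identically zero for
  rigid-body displacement fields;
- porcupine vectors: the first non-trivial mode by default, scaled to a
  maximum arrow length.

Vibrational entropy uses the classical harmonic-oscillator limit
S_vib = −k_B Σ_k ln ν_k (k_B = 0.0019872 kcal/mol/K, ν_k = √λ_k), dropping
additive constants that cancel between systems with equal mode counts —
ΔΔS_vib is the only quantity ever reported. Scaling all force constants by
c shifts S_vib by −k_B·M·ln(c)/2 (M non-trivial modes), an identity used as
an analytic test. The ENM stability term is ΔΔG = −α·T·ΔΔS_vib with
T = 298.15 K: entropy gained by the folded state's vibrations is taken as
destabilizing under the ΔΔG ≥ 0 = stabilizing sign convention. α is an
exposed calibration scalar (default 1); nothing in the package depends on
its value beyond an overall scale on this one feature.

## Signatures and environment features

Pharmacophore classes (hydrophobic, positive, negative, acceptor, donor,
aromatic, sulfur, neutral) come from a fixed residue/atom lookup; atoms
missing from the table are neutral. The cutoff-scan signature counts heavy
atom pairs around a residue (environment = atoms within 10 Å of any of its
atoms), stratified by unordered class pair and cumulative distance bins
0–10 Å in 2 Å steps; multi-class atoms contribute to every applicable class
pair. Side-chain pharmacophore deltas count atoms per class, except that
formal charge is counted once per charged group (a carboxylate is one
negative, a guanidinium one positive) — the chemically meaningful unit for
a charge-swap mutation.

SASA is a deterministic Shrake–Rupley with a fixed 128-point Fibonacci
sphere per atom, probe 1.4 Å, standard van der Waals radii. RSA divides a
residue's SASA by that of the same residue type in an extended Gly-X-Gly
tripeptide computed by the same algorithm, so RSA ≤ ~1 holds by
construction. Residue depth is the mean distance of the residue's heavy
atoms to the nearest accessible van-der-Waals-surface dot (accessibility
tested on the probe-expanded sphere), so a fully exposed residue has depth
of order one atomic radius. Both computations express all coordinates in a
frame anchored on the target residue's N–CA–C backbone before sampling,
which makes them exactly invariant under rigid transforms of the input and
exactly local (distant atoms cannot perturb the frame).

Secondary structure is a three-class φ/ψ-window assignment (helix:
φ∈(−100°,−30°) ∧ ψ∈(−80°,−5°); strand: φ∈(−180°,−90°) ∧ ψ∈(90°,180°); else
coil; termini and incomplete backbones are coil). This is deliberately not a
hydrogen-bond (DSSP-style) assignment: a deterministic torsion window is
sufficient for a 3-class feature and has no geometric edge cases.

## Dataset protocol and metrics

Mutation tables are ingested with an explicit sign convention
(stabilizing-positive or destabilizing-positive) because published tables
disagree; internally ΔΔG ≥ 0 is stabilizing, and classification uses that
boundary inclusively. Reverse augmentation adds, for every forward record,
the mutant→wild-type record with negated ΔΔG (state-function argument);
forward/reverse pairs share a group key, and all splits (train/blind and
k-fold) operate on group keys so a pair never straddles a boundary. The
default group key is (PDB id, chain, residue position) — the redundancy
criterion of published blind sets is not uniquely defined, so splits here
are reproducible but not guaranteed to match any particular published
partition.

Evaluation reports Pearson r and RMSE, plus trimmed variants after removing
the worst 10 % of records by |predicted − experimental| (stable ties), and
sub-reports for forward/reverse and stabilizing/destabilizing subsets.
Method comparison uses two-sided z-tests on Fisher-transformed correlations
with the transform clamped at |r| = 1 − 10⁻¹².

## Consensus model

Features per mutation: ΔΔS_vib and ENM ΔΔG from the sequence-dependent
field, the site fluctuation ratio from the ANM, 8 pharmacophore deltas, 180
signature counts (36 class pairs × 5 bins), RSA, depth, secondary-structure
one-hot, and the direction flag; external predictor columns can be merged
with explicit present/absent flags but are never computed. Reverse
mutations are featurized against the modelled mutant structure as the
"wild type", consistent with the thermodynamic-cycle rationale for the
augmentation. The regressor is a Random Forest with 500 trees, unlimited
depth, √p features per split and a fixed seed (recorded, with the schema
hash and CV metrics, in the model metadata); these hyperparameters are
conventional defaults, exposed in config. Model archives embed a format
version and the feature-schema hash; prediction refuses mismatched schemas.

## Synthetic fixtures: what they do and do not show

`make_toy_structure` generates three deterministic fixture families:
an ideal α-helix (φ = −57°, ψ = −47°; Cα spacing 3.80 Å), an extended
β-like chain (φ = −140°, ψ = 145°), and compact cubic-lattice clusters
(5.5 Å spacing, seeded Gaussian jitter of 0.3 Å, random residue
orientations, lattice points ordered centre-outwards so low residue numbers
are buried). Synthetic mutation tables mirror the composition of the
standard curated benchmark (2648 mutations, 131 proteins, 602 stabilizing /
2046 destabilizing, ΔΔG magnitudes gamma-distributed at ~1 kcal/mol scale);
synthetic feature tables plant a linear signal (coefficients 0.8/−0.5,
noise σ = 0.2) among distractor columns.

These fixtures exercise every code path with exact or analytic expectations:
eigenproblem correctness, thermodynamic antisymmetry, feature invariances,
and the learning machinery's ability to recover a known signal (10-fold CV
r ≥ 0.9 at n = 2000) against a permuted-target null (|r| < 0.1). They do
not emulate real protein packing, rotamer statistics or experimental ΔΔG
noise structure; passing them demonstrates the correctness of the
machinery, not field performance on curated benchmarks. Running the full
protocol on real data requires the user's own mutation table and structures
(see `scripts/run_benchmark.py`); problem sizes used in the bundled checks
(30-site networks, 2000-row tables) were chosen as the smallest at which
every property is sharply testable.

## Known limitations

- The idealized single-rotamer mutant builder ignores side-chain packing
  and can create clashes; it is a documented stand-in, and user-supplied
  mutant structures are accepted.
- The ENCoM-style element-pair weights are package defaults, not fitted
  values; only their qualitative structure (contact-count modulation) is
  load-bearing, and the degenerate-parameter limit is verified exactly.
- φ/ψ secondary structure misses hydrogen-bond-defined edge cases (3₁₀
  helices, β-bulges).
- The entropy model is classical-harmonic; anharmonicity and solvent
  entropy are out of scope.
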