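# Methods

This note documents the models and procedures implemented in `allodyn`,
the defaults and why they were chosen, what the synthetic generators do and
do not emulate, and the numerical choices a maintainer should know about.

## Data model and conventions

Author (PDB) residue numbering is the public coordinate system everywhere;
internal 0-based indices never appear in reports.  Numbering gaps are
first-class: a construct in which a disordered insert was replaced by a
short linker keeps its jump (e.g. 693 → 754), and selections spanning a gap
silently select only existing residues.  Multi-model PDB is the supported
trajectory format (read/write via biotite, MODEL/ENDMDL delimited,
coordinates preserved to the format's 10⁻³ Å).  "Backbone" means
{N, CA, C, O}; fluctuation profiles use the carbon/nitrogen backbone subset
{N, CA, C}.  Centers of mass are mass-weighted by standard atomic masses,
with a geometric (unit-mass) mode available since either convention is
found in practice.

## Superposition, RMSD, RMSF

Rigid superposition is the Kabsch SVD solution constrained to proper
rotations; the batch form vectorizes the 3×3 SVDs over frames.  RMSD
series are measured against the initial frame (the convention for
monitoring conformational drift); RMSF and PCA instead fit every frame to
the *iteratively converged ensemble average* (fit → average → refit until
the average moves < 10⁻⁴ Å, ≤ 10 rounds), which removes the dependence of
fluctuations on an arbitrary single reference.  Per-residue RMSF averages
the per-atom fluctuation √⟨|x−⟨x⟩|²⟩ over each residue's selected atoms.
For isotropic Gaussian jitter of scale σ the per-atom value converges to
√3·σ, which the tests use as a closed-form check.

## Conformational clustering and the convergence criterion

The ensemble-based clustering draws a random remaining frame as a
reference and pops every frame with best-fit RMSD < r (strict; boundary
frames stay candidates), repeating until the ensemble is exhausted —
references are therefore pairwise ≥ r apart.  Assignment is
nearest-reference by RMSD with re-superposition per pair (safer than a
shared frame of reference) and lowest-index tie-breaking.  Halves are
split at ⌊n/2⌋ in stored frame order.  The criterion is

    c = 1 − mean over repeats of (N_lone / N_total)

where a reference is lone when one half contributes zero members; c = 1 is
optimal convergence, c = 0 means the halves explore disjoint basins.  The
form is written so that the optimum is 1, matching the criterion's stated
interpretation; with 5 repeats (default) the randomness of reference
picking averages out.  `best_reference_set` retains the repeat minimizing
the per-cluster normalized |first − second| imbalance, with first-in-order
tie-breaking.  Cross-model clustering concatenates all models' frames,
clusters them identically (e.g. r = 2.5 Å on an activation-loop backbone,
4 Å for a more mobile switch segment) and tabulates per-cluster member
counts per source model.

## H-bonds and secondary structure

Geometric H-bonds require D···A ≤ 3.5 Å and D–H···A ≥ 120°; both cutoffs
are **inclusive** (the convention is documented rather than universal),
with a 10⁻⁹ float guard so geometries constructed exactly at the boundary
are accepted.  Hydrogens are paired to donor heavy atoms of the same
residue within 1.25 Å; donors without hydrogens are skipped silently.  The
donor/acceptor table covers backbone N–H/C=O plus standard polar side
chains (S/T/Y hydroxyls, K/R/H/N/Q/W nitrogens, D/E/N/Q carboxyl/amide
oxygens, His ring nitrogens).  Occupancy is the fraction of sampled frames
(default stride: every 100 stored frames) in which an interaction is
present; identity is residue-level by default (any donor/acceptor atom
combination between the two residues), atom-level optionally.

Secondary structure follows Kabsch–Sander: amide H reconstructed 1 Å from
N opposite the preceding carbonyl when absent, electrostatic energy
E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol, bond when
E < −0.5.  Helices need two consecutive n-turns (n = 3, 4, 5 → G, H, I),
strands come from parallel/antiparallel bridges, ladders promote B to E,
and remaining turn residues get T.  Chain breaks (peptide C–N > 2.5 Å or a
chain-ID change) block donation across the break.  Reported classes reduce
the letters: G → 3₁₀, H/I → α, E/B → β, T → turn, everything else
(including bends) coil.  On the ideal fixtures the assignment agrees
letter-for-letter with an independent DSSP implementation (mdtraj), which
the tests assert at the ≥ 95 % level.

## Essential dynamics

PCA diagonalizes the covariance of Cartesian deviations after fitting to
the iterative average; eigenvalues are in Å² and clipped at zero.  The
80 %-of-fluctuation rule picks the mode count for the network stage.
Collectivity uses the exponential-entropy form
k = (1/n)·exp(−Σ α_i² ln α_i²) with α normalized over the domain
(Σα² = 1); its bounds 1/n and 1 are exact and tested.  The weighted
variant multiplies by λ_m/Σλ, i.e. the mode's share of the total
fluctuation.  A domain's contribution to a mode is
100·Σ_{i∈D}|v_i|²/Σ_all|v_i|², additive over disjoint domains.  The
resultant norm |Σ_{i∈D} v_i| quantifies net concerted displacement
(anti-correlated pairs cancel); it can be weighted by the mode share and
by the contribution of non-excluded residues when a segment (e.g. an
engineered linker) is masked.

## Local feature analysis and independent dynamic segments

From the retained eigenvector block V (3A × n) the subspace projection
kernel K = VVᵀ is reduced to residue level by the Euclidean norm of the
three Cartesian diagonal components of each residue block, then normalized
to unit diagonal, giving residual correlations P(i,j) ∈ [0,1] with
guaranteed diagonal dominance.  P_cut is placed between the k-th and
(k+1)-th largest off-diagonal |P| where k targets the midpoint of the
1.0–1.2 % band; the achieved fraction is stored and asserted.  Seeds are
chosen by greedy pivoted deflation of the unnormalized residue kernel
(take the largest remaining diagonal, subtract its Schur complement) —
one seed per retained mode, the natural stopping point since each seed
claims one local degree of freedom.  An IDS is a seed plus all residues
with P(seed, j) > P_cut.  Duplicated or overlapping segments are
meaningful (locally duplicated segments occur in real systems), so
merging (Jaccard > 0.5, lower seed wins) is available but off by default.

## Commute times, interactions, pathways, hubs

CT(i,j) is the variance over frames of the Cα–Cα distance (Å²), computed
by chunked accumulation and checked against a two-pass oracle at 10⁻¹⁰
relative.  CT_cut is either a fixed value (a published analysis used 0.09
for its specific systems; that constant does not transfer) or, by default,
calibrated by binary search on the sorted CT grid so the most connected
residue reaches ~20 % of residues.  Non-bonded interactions are geometric:
any heavy-atom pair ≤ 3.9 Å (a standard non-bonded contact cutoff),
sequence separation ≥ 2 so covalent/peptide neighbors never count,
persisting in ≥ 50 % of frames.  Pathways grow from every interaction edge
with CT ≤ CT_cut, extending at either end by residues that interact with
the current end and are fast (CT ≤ CT_cut) to *every* member; maximal
chains are deduplicated against reversals and contiguous sub-chains, with
deterministic ordering and a configurable enumeration cap (default 2·10⁵,
with visited-state memoization) guarding pathological dense inputs.  Every
stored pathway is re-verified against both growth constraints at graph
construction.  Length classes: 2–3 short, 4–5 intermediate, > 5 long; span
classes: end-to-end Cα distance < 10 Å local, ≥ 10 Å extended (the exact
10 Å boundary is assigned to extended; the boundary itself is otherwise
unspecified).  A residue's communication efficiency is the number of
residues it shares at least one pathway with; hubs exceed 10 % of the
residue count.  A direct-partner variant (CT ≤ CT_cut neighbors) is
provided for comparison.

## Synthetic generators: what they emulate, and what not

The Gaussian ensemble sampler draws per-residue displacements (applied
rigidly to the residue's atoms) from a factor model: independent
background of scale σ, planted blocks sharing a latent factor with
internal correlation ρ, and stiff chains sharing a factor with weight
1 − ε so that pairwise distance variance is suppressed by ~ε relative to
background.  This is the direct-sampling equivalent of an elastic-network
precision matrix — exactly Gaussian, trivially positive semi-definite, and
cheap — chosen because the analyses consume only distributional
properties, not dynamics.  The canonical planted study system
(`planted_study_spec`, 150 residues on an ideal helix) combines a quiet
scaffold (σ = 0.25 Å), three mobile loops (ρ = 0.6, σ = 1.0 Å — giving
the leading-mode structure real flexible segments provide), two concerted
blocks of 11 residues (ρ = 0.9, σ = 1.2 Å; at this size the planted
correlated pairs match the 1.0–1.2 % calibration band of a 150-residue
system), and a stiff 6-residue fiber spaced 4 apart in sequence so
consecutive members touch through the helix contact network (ε = 0.02).

Two-basin ensembles interpolate half-mixing linearly: mixing 0 gives pure
first-half/second-half basins (worst convergence), mixing 1 gives 50/50 in
both halves.  H-bond fixtures place donor, hydrogen and acceptor at exact
distance/angle; toggling is Bernoulli per frame.  Ideal helices come from
standard backbone internal coordinates (φ/ψ = −57/−47 and −49/−26); the
β-hairpin is a continuous chain of two strands (φ/ψ = −120/130) closed by
a two-residue turn (55/35, 95/10) whose geometry brings the strands into
H-bond register.

What the generators do **not** emulate: force-field energetics, solvent,
anharmonic transitions, autocorrelated dynamics (frames are i.i.d.), side
chains (poly-alanine backbone except the H-bond fixtures), or periodic
boundary artifacts.  Passing tests therefore demonstrate that each stage
recovers the statistical structure it is defined on — not that real MD
trajectories satisfy those statistics.

## Problem sizes and seeds

Validation runs were sized for quick desk-scale iteration: convergence
extremes on 100 residues × 1000 frames; calibration bands and the
commute-time study on 150 residues × 2000 frames with a 30-residue stiff
block; planted-recovery on 150 residues × 1000 frames over 20 seeds
(success requires ≥ 18).  All randomness flows through
`numpy.random.default_rng`; repeats derive seeds as `seed + repeat_index`.
Determinism is bitwise for a fixed platform and RNG stream.

## Known limitations

* Pathway enumeration is exponential in the worst case; the cap plus
  memoization makes dense graphs safe but can truncate (deterministically)
  rather than enumerate exhaustively.
* DSSP reduction folds π-helices into the α class and bends into coil by
  design; κ/α bend angles (the DSSP "S" state) are not computed.
* The LFA residue reduction (Euclidean norm of the block diagonal) is one
  of several defensible conventions; the unnormalized kernel is kept on
  the result object so alternatives can be derived without recomputation.
* Binary trajectory formats (DCD/XTC) are not read; conversion to
  multi-model PDB is assumed upstream.
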