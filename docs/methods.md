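# Methods

This note documents the models and numerical choices behind each analysis
stage, what the synthetic generators do and do not emulate, and the known
limitations of the simplified components.

## Selection statistics (NG86 dN/dS)

`nei_gojobori` implements the Nei–Gojobori (1986) counting estimator on
pairs of aligned coding sequences:

- **Site counting.** For each codon, the synonymous site count is the
  fraction of the nine possible single-nucleotide changes that preserve
  the encoded amino acid, summed per position (each position contributes
  its synonymous fraction of 1). Changes that create a stop codon count
  as non-synonymous. Site counts are averaged over the two sequences.
- **Difference counting.** For codon pairs differing at d positions, all
  d! orderings of the single-nucleotide steps are enumerated and the
  synonymous/non-synonymous step counts averaged with equal weight.
  Pathways passing through a stop codon are excluded whenever at least
  one stop-free pathway exists; if none exists, all pathways are used
  with stop-involving steps counted non-synonymous.
- **Distance correction.** Jukes–Cantor, d = −(3/4)·ln(1 − 4p/3), applied
  to both proportions. p ≥ 3/4 raises a saturation error — note this
  means very short inputs (a single codon) can be formally saturated even
  for one synonymous change. dN/dS is undefined (None) when dS = 0.
- Codon pairs containing a gap in either sequence are skipped pairwise.

The estimator is deterministic and closed-form; the test suite checks it
to 1e-12 against an independent pathway-enumeration oracle. A known
estimator property: under a purely synonymous substitution process,
codon pairs connected only through amino-acid-changing intermediates
(serine's two codon families) contribute small non-zero dN, so dN → 0
holds only in the limit of low divergence.

## Identity, ordination and trees

- `pairwise_identity` scores a global (Needleman–Wunsch) alignment —
  BLOSUM62 for protein, match +1/mismatch 0 for nucleotide, affine gaps
  open −10 / extend −0.5 — and reports matches over aligned columns
  (dual-gap columns excluded) × 100. Identity distances are stored as
  100 − identity%; this quantity is not guaranteed to be metric.
- `classical_mds` is Torgerson scaling: square the distances, double-center
  (B = −½ J D² J), eigendecompose, keep the top-k positive-eigenvalue
  axes scaled by √λ. Axis signs are fixed by making the first non-zero
  loading of each axis positive. Requesting more axes than the positive
  rank raises an error carrying the usable rank. Distances that are
  exactly Euclidean embed exactly (the tests verify Procrustes error
  < 1e-8 against generating planar points).
- `nj_tree` is Saitou–Nei neighbor joining with a deterministic
  lexicographic tie-break (pairs compared by their smallest leaf labels)
  and negative branch-length estimates clamped to zero and recorded.
  On additive matrices the generating topology and branch lengths are
  recovered exactly. The tree is unrooted; `has_split` tests whether an
  edge separates a label set from the rest (unrooted monophyly).
  Distance-based NJ was chosen over maximum-likelihood inference
  deliberately: only topology-level statements are asserted downstream,
  and NJ is deterministic with no model-fitting machinery.

## Variable positions and side-chain classes

`variable_positions` reports every alignment column with ≥ 2 distinct
non-gap residues, 1-based; for gap-free alignments these coordinates
equal sequence positions. Residues are classified into the 5-way
side-chain partition: negative (D, E), positive (R, H, K),
polar-uncharged (S, T, N, Q), hydrophobic (A, V, I, L, M, F, Y, W) and
special (C, G, P).

## Transmembrane topology

HMM/NN topology predictors are replaced by a documented hydropathy
heuristic:

- `hydropathy_profile`: sliding mean of Kyte–Doolittle values; default
  window 19 (the classic choice for membrane spans); terminal positions
  average the truncated window.
- `predict_tm_segments`: maximal runs above threshold 1.6, runs separated
  by ≤ 3 residues merged, runs shorter than 17 discarded, runs longer
  than 35 split at their interior hydropathy minimum. All parameters are
  exposed. This detects well-separated hydrophobic spans reliably but,
  unlike an HMM, has no grammar — marginal or closely spaced helices may
  merge or vanish, so exact boundary agreement with HMM predictors is not
  claimed.
- `assign_compartments`: loop sidedness strictly alternates; the
  orientation is the one placing more Arg+Lys on cytoplasmic loops (the
  positive-inside rule), ties defaulting to a cytoplasmic N-terminus.

## Secondary structure and hydrogen bonds

- Amide hydrogens are reconstructed geometrically: H sits 1.01 Å from N
  along the external bisector of the N–C(prev) and N–CA bonds.
- `assign_secondary_structure` uses the Kabsch–Sander electrostatic
  energy E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol with
  bond threshold E < −0.5. Residues covered by an i→i+4 backbone bond are
  H; residues in bonds of sequence separation ≥ 5 (not already H) are E;
  everything else C. No β-ladder bookkeeping is done, so isolated
  long-range bonds can mark single residues E.
- `detect_hbonds` uses the common visualization-tool default criterion:
  donor–acceptor heavy-atom distance ≤ 3.0 Å and donor angle (between
  D→H and D→A) ≤ 20°. When a donor's hydrogen cannot be placed
  (side-chain donors in hydrogen-free models), a distance-only rule at
  3.2 Å applies, flagged per bond. The donor-angle convention is used
  rather than the D–H…A supplement because ideal helical geometry has a
  donor angle near 10° while its D–H…A angle is ~155–160°; the former is
  the convention under which backbone helix bonds (i→i−4) are detected.
- `detect_discontinuous_helices` scans each membrane segment for
  H-run ≥ 4, a 1–6 residue non-H break, then H-run ≥ 4. The arm/break
  thresholds admit the extended-peptide breaks typical of ion-coupled
  transporter helices while rejecting single-residue kinks.

## Contact maps and structural comparison

- Contacts are unordered residue pairs (i < j) with Cα–Cα distance ≤
  cutoff (8.0 Å default, boundary inclusive). Sequence-neighbor pairs
  are retained.
- Two maps are compared after a global sequence alignment of the two
  models' sequences; contacts whose residues lack a counterpart are
  unique by definition. The partition |unique_x| + |common| = total_x is
  exact set algebra and is verified on every comparison.
- Superposition is the Kabsch SVD solution with reflection correction;
  collinear point sets are flagged degenerate but still yield a proper
  rotation. Structural clustering applies average-linkage hierarchical
  clustering to the pairwise matched-Cα RMSD matrix, cut at a requested
  k or at the largest gap between successive linkage heights.
- Interaction networks report every residue with any atom within the
  radius (5 Å default, inclusive) of the focal residue's side-chain
  atoms (Cα fallback for glycine, flagged), with minimal inter-atomic
  distances.

## Energetics (simplified single-snapshot MM-GBSA)

ΔG_bind = G_TOTAL(AB) − G_TOTAL(A) − G_TOTAL(B), evaluated on fixed
coordinates for A (focal residue), B (residues with any atom within 5 Å
of A) and their union. G_TOTAL = H_MM + G_polar + G_nonpolar.

- **H_MM** is non-bonded only: Coulomb 332.0636·q_iq_j/(ε_in·r) plus
  Lennard-Jones 12-6 (Lorentz–Berthelot combination of per-atom ε, r_min),
  excluding intra-residue pairs and peptide-bond C–N 1-2 pairs. Bonded
  terms cancel in the A/B/AB difference except across the A–B boundary
  peptide bond, which the exclusion removes — the "non-bonded
  decomposition" approximation. With solvation disabled, ΔG_bind reduces
  exactly to the inter-group pairwise sum, which the tests verify to
  1e-9.
- **G_polar** is the pairwise Still generalized-Born energy with
  f_GB = sqrt(r² + R_iR_j·exp(−r²/4R_iR_j)) and self-terms f_GB = R_i.
  Effective Born radii are the intrinsic atomic radii — no HCT/OBC
  descreening integral. This reproduces the Born formula exactly for a
  single charge but underestimates burial effects in dense packing; a
  documented limitation.
- **G_nonpolar** = γ·SASA with γ = 0.0072 kcal/mol/Å², probe 1.4 Å.
  SASA is Shrake–Rupley with a deterministic Fibonacci sphere point set
  (960 points/atom default; quadrature error < 0.5% on a single sphere).
- **Parameters** (`params/ff_simple.tsv`, version 1): per-atom backbone
  charges (N −0.30, CA +0.10, C +0.45, O −0.45) and a single united
  side-chain pseudo-atom carrying the residue's formal charge plus the
  backbone complement, so every residue sums exactly to its formal
  charge (Asp/Glu −1, Lys/Arg +1, others 0; glycine's complement moves
  to CA). LJ well depths and radii are element-typical values; the
  side-chain pseudo-atom radius grows with residue size. ε_in = 1,
  ε_out = 78.5. In full-atom models, extra side-chain heavy atoms get
  generic carbon parameters with the united charge kept on the first
  side-chain atom; hydrogens get zero charge. Absolute kcal/mol values
  from this table are not comparable to published force-field energies —
  only orderings, differences and the decomposition identity are
  meaningful, and that is all the pipeline asserts.

## Synthetic data: what it does and does not emulate

`generate_helix_bundle` builds backbones from ideal internal coordinates
(N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å, trans ω) with canonical
α-helix dihedrals φ = −60°, ψ = −47°, chosen so the construction itself
realizes i→i+4 hydrogen-bond geometry (O…N ≈ 2.94 Å); helices alternate
direction on a ring of configurable radius and loops are extended
connectors. Side chains are single pseudo-atoms at the Cβ direction with
residue-typical lengths. Consequences: secondary-structure and H-bond
detectors see genuine helical geometry; contact maps, networks and
energetics are exercised end-to-end; but there is no membrane, no
rotamer chemistry, no loop realism, and chain geometry is broken at
helix–loop junctions. Passing tests demonstrate correctness of the
*operations* on controlled geometry, not predictive accuracy on real
membrane proteins.

`simulate_codon_family` evolves each taxon independently from a root:
each accepted substitution is a proposed point mutation (uniform
position; transition bias κ, default 1.0) that never creates a stop
codon, accepted with probability 1 if synonymous and ω if
non-synonymous (roles invert for ω > 1); the accepted count per taxon is
Poisson(branch_length × n_codons). Defaults (branch 0.3
substitutions/codon, ω = 0.13, 11 taxa) place simulated families in the
strong-purifying regime typical of essential transporter genes, and the
NG86 estimator recovers the simulated ω (mean over 20 seeds within
[0.10, 0.16] at 5,000 codons). κ = 1 is the default because NG86's site
counting assumes equal rates; transition-biased simulations (κ > 1) are
available but bias the counting estimator downward, as is well known.
No insertions/deletions and no among-site rate variation are simulated.

## Determinism

All generators are pure functions of (spec, seed) using a single
`numpy.random.Generator` per call. Analyses contain no randomness except
through the generators, so identical config + seed yields byte-identical
tabular outputs. The problem sizes used by the default test suite and
the acceptance script (10–80 residue bundles, 30–5,000 codon sequences,
≤ 100 random fixtures per oracle check) were chosen so every ground
truth is recoverable exactly while a full run completes in well under a
minute; all sizes scale up through the public specs.
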