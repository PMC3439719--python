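# Methods

## Problem and scope

X-ray structures of the *same* protein sequence are routinely treated as a
gold standard, yet redeposited crystals of one sequence differ: backbones
shift, secondary structure "wobbles" between helix, sheet and coil at
equivalent sites, and the sequence alignments implied by structural
superposition are not unique. `structflex` quantifies these effects for
*structural groups* — sets of chains whose sequences are at least 99%
identical — organized into protein families:

1. **3D flexibility.** All-against-all rigid superposition within a group;
   per-group maximum RMSD and minimum TM-score.
2. **Secondary-structure wobble.** 3-state secondary structure per chain;
   an alignment column showing ≥ 2 states across a group is a wobble site,
   with ratio `Rw = Nw / Na × 100%`.
3. **Alignment variation.** Across all structure-pair alignments of a group
   pair, residue sites are *common* (same partner in every comparison),
   *gap* (gap in every comparison) or *multi* (anything else); ratios
   `Rx = Nx / Na × 100%` with `Na` the average protein length.
4. **Evolutionary distance (ED).** For an aligned pair `Sx, Sy` with `n`
   both-residue columns,
   `ED = [1 − 2·Σ M(xi,yi) / (Σ M(xi,xi) + Σ M(yi,yi))] × 100`
   under BLOSUM62. Per group pair the structurally best and worst
   comparisons are selected (min/max RMSD, or max/min TM-score) and the
   expectation `ED(best) ≤ ED(worst)` audited; exceptions are profiled by
   gap-opening/extension differences after terminal trimming.

## Superposition and structure-based alignment

Rigid superposition is the closed-form Kabsch solution (SVD with reflection
correction). TM-score uses `d0(L) = 1.24·(L−15)^⅓ − 1.8` Å, floored at
0.5 Å, normalized by the shorter chain by default ("average" is available).

Chains with near-identical sequences (identity ≥ the 0.99 grouping
threshold) take the sequence alignment as the residue correspondence, so
within-group RMSD is the plain Kabsch value over all matched C-alphas —
the dominant code path. Diverged pairs are aligned iteratively: seed from
the sequence alignment, then repeat {superpose on the current pairs;
rebuild the correspondence by global dynamic programming on the score
`1/(1 + (dij/d0)²)` with a linear gap penalty of 0.6 and free end gaps}
until the pair set is stable or 30 iterations, keeping the iterate with the
highest TM-score (the earlier iterate on ties, for determinism). This is a
deliberately simple stand-in for fragment-assembly structural aligners; it
is exact on congruent chains and recovers insertions of a few residues, but
it is not a bit-for-bit reproduction of any published aligner.

## Secondary structure

When a DSSP output file accompanies a structure it takes precedence.
Otherwise a simplified Kabsch–Sander assignment runs from backbone
coordinates: amide hydrogens imputed at 1.01 Å from N along the previous
residue's O→C direction; H-bond energy
`E = 0.084·332·(1/rON + 1/rCH − 1/rOH − 1/rCN)` kcal/mol, accepted below
−0.5 kcal/mol (distances clamped at 0.5 Å with a warning); helices from two
consecutive i→i+4 turns (3-10 and pi analogously), sheets from bridge
ladders of length ≥ 2, isolated bridges 'B', remaining turn residues 'T'.
Bends ('S') are never emitted, proline's missing amide H is not special-
cased, and the helix-termination tie rules of full DSSP are simplified —
drift of one residue at helix/strand termini relative to reference DSSP
output is expected. The 3-state reduction is fixed: H/G/I → H, E → E,
everything else → C.

## Statistics

Pearson correlation (t-distributed p, n−2 df), ordinary least squares
(optionally through the origin), and the 2×2 chi-square with Yates
continuity correction on by default — required to reproduce the published
mutation-site enrichment statistic (X² = 11.59 from the 72/412 vs
4,027/33,899 table; the published total-ratio figure of 12.00% for
4,027/33,899 is arithmetically 11.88% and is not reproduced). The
"all sites" row includes the mutation sites; excluding them does not
reproduce the published statistic. Implementations are thin wrappers over
scipy; tests cross-check against independent references.

## Design choices at genuinely open points

- **Identity definition**: matches / alignment length (gaps included),
  configurable; clustering is greedy longest-first with lexicographic id
  tie-breaks, deterministic by construction.
- **Mutation sites**: alignment columns with ≥ 2 distinct non-gap residues;
  gap-versus-residue columns are not mutations (point substitutions only).
- **Site classes form a partition**: a site mixing residue partners and
  gaps across comparisons is *multi*; per-class counts are averaged over
  the two proteins so `Rc + Rm + Rg = 100%` exactly.
- **Three-state wobble columns** increment all three type tallies
  (C⇔E, C⇔H, H⇔E); in the state-composition-by-class analysis a site's
  unit weight is split equally among its observed states (0.5/0.5 for two,
  1/3 each for three — the three-way split is this package's extension).
- **ED and gaps**: ED sums run over both-residue columns only (a gap score
  is undefined); ED is computed on the untrimmed alignment, gap counts on
  the terminally trimmed core, and both are exported. A zero ED difference
  is its own class, not an exception.
- **Wobble Single** uses as denominator the alignment columns where at
  least one of the two structures is observed.
- **Resolution binning**: 0.1 Å bins labelled by lower edge, `[x, x+0.1)`;
  every structure's state at a pairwise-wobbling site is attributed to that
  structure's bin; the correlation/fit can be restricted to well-populated
  bins (`curve_min_states`).

## Synthetic ensembles and what they do (not) show

The generator builds families from a segment layout (default: six helices
joined by coil linkers, 102 residues) with canonical backbone geometry
(N–CA 1.458, CA–C 1.525, C–N 1.329 Å; helix φ/ψ = −57°/−47°, strand
−120°/+120°, template linkers drawn once per family from an extended coil
region). Within groups, structures vary by:

- **hinge motion** — one designated coil linker's dihedrals perturbed per
  structure, Normal(0, spread/√(2·n)) per dihedral with total spread 8° by
  default, rotating the downstream domain rigidly;
- **wobble** — two designated near-terminal helices rebuilt as loops in a
  random 30% of structures; among 12 candidate loop draws the one
  minimizing the whole-chain superposed RMSD to the unflipped conformation
  is kept, standing in for the tertiary packing that keeps real secondary-
  structure changes local;
- **jitter** — chain-correlated Gaussian displacement (σ 0.08 Å for
  helix/strand, 0.2 Å for coil).

Groups within a family differ by 4 point substitutions and by 0–2 residues
of terminal truncation per end (distinct resolved spans, the source of gap
sites); 45% of groups carry one engineered point mutation in a single
member, placed inside a flexible core with probability 0.5 (mutated sites
in real datasets concentrate at functionally important, mobile regions).
Resolution is `a + b·coil_fraction + N(0, σ)` clipped to [0.8, 3.49] Å with
defaults a = 1.3 Å, b = 1.5 Å, σ = 0.15 Å, making the coil–resolution trend
a recoverable parameter. One seeded generator drives all draws; a fixed
seed yields byte-identical PDB output.

Ground-truth wobble sites are the flip-segment cores (2 boundary residues
excluded per end, where assignment drift at helix termini is expected);
the rigid core excludes the same margins. Default conditions give 3
families × 3 groups × 6 structures — large enough for every selection rule
and statistic to engage while keeping a full pipeline run near ten seconds.

Known gaps between the emulation and real data: strand segments are
assigned C unless paired (isolated strands have no ladder partner), so
default layouts use helix/coil only; whole-segment two-state flips make
Wobble Total ≈ max Wobble Single (slope ≈ 1 through the origin), whereas
redeposited crystal series show slope ≈ 1.6 — reproducing that excess
would need per-structure partial states or correlated multi-region flip
patterns the generator does not model; there is no tertiary packing,
side chains, crystal contacts or experimental noise model. Passing
recovery tests therefore demonstrates correctness of the detection
machinery under controlled conditions, not performance on deposited
crystal structures.

## Numerical notes

- Kabsch requires ≥ 3 non-collinear points; reflections are excluded by
  sign correction; RMSD/TM-score are rigid-motion invariant to 1e-6.
- The distance DP breaks ties toward the diagonal (match) move; on tiny
  inputs its optimum equals exhaustive enumeration over colinear matchings.
- Chains shorter than 5 residues get all-blank secondary structure; chains
  shorter than 10 are rejected by the structural aligner.
- 'X' (unknown residue) scores 0 against everything in BLOSUM62 lookups.
- Degenerate inputs (single comparison in a group pair, fully trimmed
  alignments, groups without mutation sites) are flagged, not errors.

## Problem sizes used in checks

The default validation conditions run the full pipeline on 54 structures
of 98–102 residues (≈ 135 within-group and ≈ 324 cross-group
superpositions), 20 seeded single-family replicates for the
resolution-slope sign check, 100 substitution-load pairs for the ED rank
correlation, and 50 random ≤ 8-point sets against a multi-start rotation-
optimization oracle for the superposition check.
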