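# Methods

## Structure model

PDB files are parsed with gemmi and mapped into a small atom / residue /
chain / assembly hierarchy.  Only the first MODEL of a multi-model file
is used for X-ray-style inputs; `parse_ensemble` loads every MODEL as a
coordinate frame for the ensemble reductions.  Waters and monoatomic
ions are excluded from chains; modified residues are kept when mappable
to a parent (MSE→Met, PSU→U, …).  Alternate locations are resolved by
keeping the highest-occupancy conformer, first-in-file on ties — crystal
structures require *some* rule and this is the conventional one.  Chains
are classified protein / rna / other by majority vote over residue
names, which makes the classification invariant to residue order.
Residues keep their author numbering; an identifier is always the triple
(chain id, residue number, insertion code), so contact sets and mobility
profiles can be joined without renumbering.

## Contact rule

A protein residue is a contact residue when any of its atoms lies within
the cutoff (default 3.5 Å) of any atom of an RNA nucleotide.  The
comparison is **inclusive** (≤); the prose convention "within 3.5 Å" does
not fix the boundary, and an explicit choice is needed for
reproducibility.  Hydrogens are used if present in the file and never
added.  The production search uses a k-d tree over the RNA atoms; an
all-pairs brute-force implementation is kept as an oracle and the two
are asserted equal on random toy complexes.  Each (residue, nucleotide)
pair records its minimum atom–atom distance; pair counts can exceed
contact-residue counts because one residue may touch several
nucleotides.

Charge bookkeeping: Lys/Arg +1, Asp/Glu −1, everything else neutral
(His neutral).  The six-way side-chain classification used for the
contact census and conservation is basic {K,R}, acidic {D,E}, histidine
{H}, aromatic {F,W,Y}, polar {S,T,N,Q,C}, nonpolar {G,A,V,L,I,P,M}.
Cys is grouped with the polar residues; no worked example constrains
its placement, so this is a documented package choice.  Tyr is counted
aromatic (it is also polar, but the partition assigns each residue to
exactly one class).  Composition percentages over several sequences are
residue-weighted (computed on the concatenation), not protein-averaged.

## Anisotropic network model

Nodes are Cα atoms; pairs within the cutoff (default 13 Å) are joined by
identical springs.  For pair (i,j) at separation vector r_ij with length
d, the off-diagonal 3×3 Hessian block is −(γ/d²)·r_ij r_ijᵀ and diagonal
blocks are minus the row sums, which enforces translational invariance
exactly.  The spring constant γ and the k_BT prefactor are omitted: the
enrichment factor and profile correlations are invariant to an overall
scale, so ANM RMSF values are reported in arbitrary units (the tests
assert the γ^(−1/2) scale law explicitly).

Modes come from a dense symmetric eigendecomposition (`scipy.linalg.eigh`),
sorted ascending with a deterministic sign convention (first
non-negligible component positive).  Modes with eigenvalue below
`zero_mode_tolerance` × (largest eigenvalue), default 1e−8, are rigid;
for a connected, genuinely three-dimensional network exactly six rigid
modes are asserted (a two-node or planar network legitimately has a
different count and is not asserted).  Per-residue mean-square
fluctuation sums λ_k⁻¹|v_k,i|² over **all** non-rigid modes; whether a
subset of modes would suffice is an open modelling question and using
all of them is the parameter-free choice.

**Tip effect.**  Coarse-grained networks exaggerate the motion of highly
extended terminal nodes.  The automatic filter excludes residues with
RMSF above median + 5·IQR, re-applied until stable, and refuses (with an
error demanding manual review) if it would remove more than 10% of the
residues.  The published exclusion lists for the T. thermophilus
structures can be supplied as manual lists, which bypass the automatic
rule entirely; manual lists are first-class precisely so that reported
analyses can be reproduced exactly.

## Enrichment statistic

EF = mean RMSF over contacting residues / mean RMSF over non-contacting
residues, excluded residues ignored on both sides.  The permutation null
draws C residues uniformly without replacement from the N usable
residues (independent draws; default 10,000) and recomputes the
analogous ratio.  The p-value counts ties as extreme and applies the
add-one correction,

    p = (1 + #{EF_null ≥ EF_obs}) / (1 + n_perm),

so p ∈ [1/(1+n_perm), 1] exactly and a degenerate constant profile
yields p = 1 rather than 0.  Counting only strictly greater null values
would report p = 0 in degenerate cases, which a resampling test cannot
support; the inclusive convention is the conservative standard
(Phipson–Smyth).  Draws are vectorized (argsort of a uniform matrix) and
bitwise reproducible given (seed, n_perm).  Calibration is checked by
simulation: over 1,000 exchangeable replicates (N=50, C=10, 499 draws)
the rejection rate at α=0.05 is 0.05 ± 0.02, and a planted two-fold
enrichment (N=100, C=20, noise sd 0.1) is detected at p ≤ 0.001 in ≥99%
of seeds.

## Ensemble reductions

Per-frame RMSD is computed after optimal superposition onto a reference
(default: the first frame), using proper-rotation Procrustes
(`Rotation.align_vectors`), so reflections are never introduced.
Per-residue RMSF uses the standard iterative scheme: superpose all
frames onto the running mean structure and recompute the mean until it
moves < 1e−6 Å; the per-residue value is the mean of its atoms' RMSF
about the converged mean.  All atoms present are included in both
reductions.  B-factors convert as B = (8/3)π²·RMSF².  Profile
correlation is Pearson's r over shared, non-excluded residue ids with
optional symmetric trimming of k terminal residues (methods often
disagree most at chain termini).

Note a small-system caveat verified in the tests: rigid-body fitting
absorbs part of a single atom's displacement, so for an m-frame ensemble
of an n-atom frame the RMSF of one jittered atom falls slightly below
the Gaussian closed form √3·σ·√((m−1)/m); with n = 100 atoms the
deficit is ≈2%.

## Conservation

Pairwise global alignment uses Needleman–Wunsch with BLOSUM62, gap open
10 and extend 0.5 (Biopython's `PairwiseAligner`; ties broken by the
aligner's deterministic enumeration order).  These are conventional
defaults — the original cross-species comparisons were made with
commercial software whose parameters are unpublished, so identity
percentages should be read with a ±5-point alignment-sensitivity margin.
Percent identity divides by the columns where both sequences have a
residue (gaps excluded); class conservation uses the six-way partition
above, so it can never be below identity.  Contact conservation is
computed per species over its own contact list (an unmatched contact
counts as non-conserved), which is why the two directions differ.
Cross-species superposition RMSD uses the sequence-aligned Cα pairs, not
a structure-guided alignment.

## Synthetic data

`make_toy_complex` builds a straight protein strand (N, CA, C per
residue, 6 Å pitch) and a parallel RNA strand (P, C1′, N9/N1 per
nucleotide, 7 Å pitch) 30 Å apart, then realizes each planted contact by
adding a pseudo side-chain atom at exactly the target distance from the
partner nucleotide's C1′ atom.  Placement directions are restricted so
the anchor is the unique nearest RNA atom, every other nucleotide stays
≥ 3.6 Å away, and planted atoms keep ≥ 2 Å steric clearance (successive
plants on one nucleotide occupy disjoint out-of-plane bands).  Target
distances must avoid the 3.5 Å decision boundary (≤ 3.4 or ≥ 3.6) so
recovery tests are immune to floating-point noise.  The geometry makes
no claim of realism — it exercises the any-atom distance logic, the
parser round trip and the pipeline plumbing, not force-field physics.

`make_anm_fixture` provides a two-body system (nonzero eigenvalue
exactly 2γ, five zero modes), a regular tetrahedron (six zero modes), a
planar square (symmetry-equivalent nodes) and reproducible random
clouds.  `make_mobility_sample` draws non-contacting residues with mean
RMSF 1.0 and contacting residues with mean equal to the effect ratio
(default 2.0, matched to the strong-enrichment regime; noise sd 0.1;
normal-truncated or mean-matched lognormal).  With effect 1 the profile
is exchangeable — exactly the permutation null.  What passing these
tests shows is that the statistics behave correctly on data satisfying
their assumptions; real mobility profiles have spatial autocorrelation
along the chain that the generator deliberately omits, so empirical
p-values on real structures should be interpreted as conditional on the
exchangeability assumption.

## Problem sizes and defaults

The test suite and the acceptance script run entirely on synthetic
inputs: 50 random toy complexes for the contact oracle comparison, 1,000
replicates × 499 draws for the type-I calibration, 100 seeds × 1,999
draws for planted-effect recovery, networks of 2–20 nodes for the
spectral checks and 400–500-frame Gaussian ensembles for the reduction
checks.  These sizes give stable statistics (binomial standard error
≈0.007 on the type-I rate) while keeping the whole suite in seconds.
Full-assembly runs (≈1,500 nucleotides, ≈20 protein chains) use the same
code paths through the k-d-tree search and per-protein dense
eigensolvers and take a few minutes; they require the user to supply the
crystal structures (`scripts/reproduce_30s.py`).

## Known limitations

* The package consumes coordinate ensembles or per-residue mobility
  tables; it does not run molecular dynamics, and MD-derived published
  values can only be checked against externally supplied profiles.
* ANM networks model each protein in isolation, as in the source
  analyses; mixed protein–RNA networks are out of scope.
* The automatic tip filter is a pragmatic outlier rule, not the
  (unpublished) criterion used in the original analyses; manual
  exclusion lists exist to bridge that gap.
* mmCIF input, symmetry expansion and structure-based alignment are not
  implemented.
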