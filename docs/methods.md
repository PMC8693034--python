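# Methods

This note records the scientific and numerical choices behind `trxgeom`:
what is computed, which parts follow established convention, which parts
are this package's own reconstruction, and what the synthetic benchmark
does and does not demonstrate.

## Geometry definition and discretization

For residues i and j the package computes the Cβ–Cβ distance
d(i,j) = ‖CB_i − CB_j‖, the dihedral ω(i,j) = (CA_i, CB_i, CB_j, CA_j),
the dihedral θ(i,j) = (N_i, CA_i, CB_i, CB_j) and the planar angle
φ(i,j) = (CA_i, CB_i, CB_j).  d and ω are symmetric; θ and φ are ordered.
Dihedral signs follow the IUPAC convention (cross-checked against biotite).
Residues without a Cβ (glycine) get a virtual Cβ from N, CA, C via the
standard ideal-geometry linear combination with coefficients
(−0.58273431, 0.56802827, −0.54067466).

Bins: distance has 37 labels — label 0 is "no contact" (d ≥ 20 Å or any
needed atom missing), labels 1–36 tile [2, 20) Å in 0.5 Å steps.  ω and θ
have 25 labels (24 × 15° over [−180°, 180°)); φ has 13 (12 × 15° over
[0°, 180°], with 180° assigned to the top bin).  The no-contact label is
keyed on d alone and shared by all four label maps: orientations are
geometrically meaningless without spatial proximity, so a far pair is
label 0 everywhere.  Angular bin edges are closed at the lower edge;
values exactly on an edge go to the higher bin, except the closed 180°
endpoint of φ.

Contacts are pairs with d ≤ 8 Å; with the grid above this equals the
summed mass of distance bins 1–12.  Precision is evaluated on pairs i < j
ranked by contact probability within a separation class (short [6, 12),
medium [12, 24), long [24, ∞); "separation ≥ 12" is medium ∪ long).  Rank
ties break by ascending (i, j) — an arbitrary but deterministic rule.

## MSA features (526 channels)

The published channel total is 526; the decomposition used here —
2 × 42 one-dimensional channels + 441 couplings + 1 APC norm — is this
package's reconstruction of the underlying recipe and is documented as
such.  Per position: 20 query one-hot channels, 21 weighted frequencies
(additive pseudocount c, default 1/N_seq: f = (f₀ + c)/(1 + 21c)), and the
positional entropy −Σ f ln f ∈ [0, ln 21].  Sequence weights follow the
usual identity-based reweighting, wₙ = 1/#{m : identity(n,m) ≥ 0.8}, with
Neff = Σ wₙ.

Couplings are the negated off-diagonal 21×21 blocks of the inverse of the
shrunken weighted covariance of the one-hot encoding (gap participates as
a 21st state; wildcards count as gap).  Shrinkage adds λ to the diagonal,
default λ = 4.5/√Neff, a common choice in sparse inverse-covariance contact
analysis; the matrix is inverted by Cholesky factorization and a failure
raises with advice to increase λ.  The scalar coupling score is the
Frobenius norm over the 20×20 non-gap sub-block with average-product
correction S_ij − S_i·S_j/S_‥ (means over off-diagonal entries), the
standard APC convention.  The exact constants used by the original
pipeline are not restated in its description, so both defaults are
config-overridable; sensitivity to them is monotone and mild (tests assert
the monotone decrease of coupling magnitude in λ).

MSA subsampling for training draws k = max(1, round(10ᵘ)) rows,
u ~ U(0, log₁₀ N_seq), always retaining the query.

## Network architecture

The basic block is a pre-activation bottleneck: instance norm → ELU →
1×1 reduce → split into s = 4 subsets → the hierarchical 3×3 stage
(y₁ = x₁; y₂ = K₂(x₂); yᵢ = Kᵢ(xᵢ + yᵢ₋₁)) → concat → norm/ELU → 1×1
expand → residual add.  Pre-activation was chosen so that a block with
zero expansion weights is an exact identity, which gives a sharp unit test
of the residual contract; the hierarchical stage is tested against a
direct evaluation of the recursion with normalization disabled.  No
pooling or strided convolution anywhere — pair maps keep their L×L shape.

Block counts and dilation schedules are not published.  Defaults: the
full profile uses 4 groups of (2, 2, 3, 3) blocks at widths
(64, 128, 256, 512) — 50 trunk convolutions counting each subset
convolution, matching the stated ~50-layer depth — with dilations cycling
(1, 2, 4) block-wise; the residual path gains a 1×1 projection when group
width changes.  These are explicit guesses, config-exposed.  A tiny
profile (2 groups × 2 blocks, width 16) exists for desk-scale training;
it keeps every structural invariant (scale 4, head sizes, frozen reuse)
at ~1/1000 of the parameter count.

The FM network maps the 526-channel tensor through the groups to four 1×1
softmax heads (37/25/25/13 bins).  The TBM network reuses the FM input
convolution and first two groups *frozen* (they are simply absent from
its parameter list, so no gradient ever reaches them — asserted bitwise
after optimizer steps), concatenates their output with the 100-channel
combined template map, and continues through four new groups and its own
heads: six groups in total.  Since d and ω are symmetric by definition,
predicted posteriors are symmetrized (averaged with their transpose) before
fusion and evaluation; θ and φ are not.

## Template encoding and attention

Each good template (probability > 60 % or E-value < 0.001; at most 10, in
search order) is encoded by computing its own binned geometry and
scattering the one-hots onto query indexing through the alignment; pairs
with an unaligned endpoint are all-zero rather than carrying a mask
channel, which preserves the printed 100-channel count.  Pair confidences
are sₖ(i,j) = [sₖ(i) + sₖ(j)]/2 with sₖ = 0 off-alignment.

The attention module's exact wiring is not published in the main text of
its source; the reconstruction here is a deliberately small single-head
design: query = 1×1 projection of the FM group-2 output, key = shared 1×1
projection of each template map, per-pair logit = scaled dot product of the
query with the key augmented by its row-mean and column-mean axial context,
softmax over the template axis.  This satisfies every documented contract —
a single template gets weight 1, identical templates share 1/N, weights are
permutation-equivariant and normalized — while staying cheap and exactly
differentiable.  Template confidences deliberately do not enter the
logits; they act only in the fusion weight, keeping the two mechanisms
separable and testable.

Fusion: w_TBM(i,j) = Σₖ wₖ(i,j)·sₖ(i,j) ∈ [0,1], w_FM = 1 − w_TBM, applied
pixel-wise as one shared map across the four heads (whether the original
uses per-head weights is unstated; sharing is the simpler reading).  With
no good templates, w_TBM ≡ 0 and the fused posterior is bit-identical to
the FM posterior.

## Training

Categorical cross-entropy summed over the four heads, averaged over valid
pairs (equal head weights; the original objective is not printed, but
softmax heads imply cross-entropy).  Optimizer Adam, lr 10⁻³, batch size 1
(lengths vary); both unstated in the source and config-exposed.  The
dataset splits 95/5 with validation = floor(5 %) — 15 051 chains would
give 14 299/752.  Samples of ≥ 260 residues are reduced each epoch either
to one contiguous window or (probability 0.5) to two stitched windows, one
from each sequence half, of at least 64 residues each; labels are sliced
by the same index set, so stitched inter-segment pairs keep their true
long-range geometry.  Augmentation draws are rerolled every epoch.

## Synthetic data

`synthetic` generates (i) compact self-avoiding Cα walks (3.8 Å steps,
3.5 Å excluded volume, confinement radius 3.1·L^⅓ Å, regenerated until at
least 2L pairs have d < 8 Å at separation ≥ 12 — capped by the number of
such pairs for short chains); N/C placed with ideal bond lengths and a
111° N-CA-C angle, Cβ by the virtual construction; (ii) MSAs in which
disjoint contacting column pairs are jointly substituted through eight
residue classes with a fixed class pairing, at a configurable coupling
strength (default 0.9), against an independent mutation rate of 0.35 and
gap rate 0.05 — enough structure for inverse-covariance couplings to rank
true contacts first; (iii) templates as noisy contiguous copies of the
target (Gaussian coordinate noise, identity alignment on the covered
segment, confidence e^(−noise) uniformly, scores set to pass or fail the
good-template filter).

What this does *not* emulate: real phylogenetic correlation between
sequences, realistic amino-acid substitution matrices, alignment errors,
non-identity template alignments, and real secondary-structure statistics.
A network that succeeds here has demonstrably learned to read planted
covariation and template geometry through the documented tensor plumbing —
no more.  Scores on these fixtures say nothing quantitative about PDB-scale
accuracy.

## Scaled-down benchmark

The learnability experiment trains the tiny profile on 150 synthetic
targets (L = 48, MSA depth uniform in [30, 200]) for 20 epochs and scores
held-out (20 targets) top-L/5 precision at separation ≥ 12 against the
class contact-density baseline, requiring a 3× margin.  MSA subsampling is
off in this run: at fixture depths the log-uniform draw usually leaves too
few rows for the covariance estimate, and the experiment is meant to probe
feature→geometry learnability, not augmentation robustness.  Problem sizes
were chosen so the run completes in minutes on one CPU.

## Realization

A simplified stand-in for energy-minimization folding, and documented as
such: only the distance head is used.  Pairs with P(no contact) ≤ 0.5
(config-exposed τ) get the expectation of bin midpoints renormalized over
contact bins; the partial matrix is completed by graph shortest paths,
embedded by classical MDS, and polished by L-BFGS on the masked quadratic
stress Σ(‖xᵢ−xⱼ‖ − dᵢⱼ)².  The decoy protocol generates 120 randomized
embeddings, refines the 5 lowest-stress ones and returns the best.
Coordinates are defined up to rigid motion *and mirror image* (distances
cannot fix chirality), so reported RMSDs superpose with reflection
allowed.  Orientation restraints, full-atom geometry and physical energies
are out of scope.

## Statistical comparison

Paired per-target scores are compared by the half-resampling protocol:
10 times, half the targets are drawn and per-method means recorded; the 10
paired means are tested for normality of differences (Anderson–Darling at
5 %), then compared by the two-tailed paired t-test or, failing normality,
the Wilcoxon signed-rank test; significance at p < 0.05.  Degenerate
inputs (all differences zero / exactly constant) short-circuit to
non-significant / significant respectively, since neither test is defined
there.

## Numerical notes

All network math runs in float64; inference is bit-deterministic given a
seed, and training history is reproducible seed-for-seed.  Instance norm
uses ε = 10⁻⁵.  Posterior validity is enforced at 10⁻⁴ (archives) and
10⁻⁵ (network output) pixel-sum tolerance.  Restraint archives round-trip
bit-exactly through compressed `.npz`.  File boundaries are 1-based
(PDB, hit tables); everything in memory is 0-based.

## Known limitations

Production-scale training (tens of thousands of chains, GPU weeks) and the
associated benchmark accuracies are explicitly out of scope; no attempt is
made to reproduce published precision or TM-score figures.  The hit-table
dialect is this package's own; converting native HHsearch output is a
documented non-goal, as are mmCIF input, multi-chain assemblies,
pseudo-likelihood couplings and multi-head/triangle attention.
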