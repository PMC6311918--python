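# Methods

## Model

The package treats lncRNA–disease prioritization as label propagation on a
heterogeneous network. Nodes are the nd diseases and nl lncRNAs of a binary
association matrix *A*; a disease layer and an lncRNA layer are each weighted
by a similarity matrix and coupled through the known associations. The
underlying assumption is guilt-by-association: lncRNAs with similar
interaction profiles (and similar tissue expression) tend to associate with
similar diseases, so score mass seeded on known edges and diffused along both
layers accumulates on plausible unknown pairs.

### Similarity construction

* **Interaction-profile kernels.** The profile of a lncRNA is its column of
  *A*, of a disease its row. Kernel similarity is
  exp(−γ‖profile difference‖²) with bandwidth γ = γ′ / (mean squared profile
  norm), so γ adapts to the catalog's density; γ′ defaults to 1 for both
  axes. All kernel values lie in (0, 1] with unit diagonal. An all-zero *A*
  leaves the bandwidth undefined and is rejected.
* **Expression similarity.** For lncRNA pairs that both carry expression
  profiles (the subset L₁), the Spearman rank correlation across tissues,
  with average ranks for ties (the standard convention; the correlation is
  computed as the Pearson correlation of the rank-transformed vectors). A
  zero-variance profile is defined to correlate 0 with every partner — a flat
  profile carries no rank information — rather than propagate NaN. Pairs
  involving an unprofiled lncRNA are 0; the diagonal is 1 for profiled
  lncRNAs. Negative correlations pass through unclamped into the fusion; the
  normalization stage is where any resulting negative row mass is handled.
* **Fusion and transform.** SL = ew·SPC + (1−ew)·KL where both lncRNAs are in
  L₁, else KL; ew defaults to 1/2 and ew = 0 reproduces KL bit-for-bit.
  Disease similarity is the entry-wise logistic map
  SD = 1/(1 + exp(c·KD + d)), defaults c = −15, d = ln 9999, chosen so that
  KD = 0 maps to 10⁻⁴ and KD = 1 to ≈ 0.997: the transform is strictly
  increasing for c < 0 and keeps the disease layer strictly positive, hence
  connected.

### Laplacian normalization

The plain normalization is M̂(i,j) = M(i,j)/√(D(i,i)·D(j,j)) with D the
diagonal of row sums; rows or columns with non-positive sum are zeroed. The
two-step layer normalization applies this and then rescales: nonzero rows of
the lncRNA layer LL sum to 1, nonzero columns of the disease layer LD sum
to 1. The row/column asymmetry is intentional and matches the walk's update:
the score matrix multiplies LL on the right (each lncRNA's outgoing weight
must be a distribution over lncRNAs) and LD on the left (each disease column
distributes over diseases). On strictly positive symmetric input, step one
coincides exactly with the plain normalization; the test suite asserts this
equivalence on random instances. Zero patterns are preserved through both
steps, self-similarities are retained (no self-loop removal), and the
"entry ≠ 0" conditionals test exact stored zeros — entries are constructed,
not measured. If negative expression correlations make a row or column sum
non-positive, that row and column are zeroed with a warning; a row whose
nonzero entries cancel exactly in step two raises a degenerate-row error
naming the offender.

### The walk

From Rt₀ = A / (number of known associations) — a probability distribution
over known edges — the two restart walks are averaged at every step,
collapsing to

    RT_t = (α/2)(RT_{t-1}·LL + LD·RT_{t-1}) + (1−α)·Rt₀.

α (default 0.9) is the propagation weight; 1−α is the restart probability.
Convergence is declared when the maximum absolute elementwise change between
successive iterates falls below tol (default 10⁻¹⁰), the strictest common
norm and scale-free at this matrix size; the guard max_iter = 1000 reports
non-convergence through a flag instead of raising, so evaluation can proceed
(relevant at α = 1, where the restart anchor vanishes and the iteration may
only drift to its limit without a contraction guarantee). The fixed point
solves the Sylvester-type system
(I − (α/2)(LLᵀ⊗I + I⊗LD))·vec(RT) = (1−α)·vec(Rt₀); the test suite and the
acceptance script verify the iterate against a dense solve of this system to
10⁻⁸ on random small instances. The iteration is a pure function of its
inputs: repeated runs are bit-identical, and relabeling diseases or lncRNAs
permutes the output scores identically (permutation tests allow 10⁻¹²
because reordering changes floating-point summation order).

## Evaluation

LOOCV withholds each known association in turn and — because similarities
are functions of *A* — rebuilds KL, KD, SL, SD, LL, LD from the masked matrix
before rerunning the walk. The withheld pair is ranked, with average-tie
ranks, among **all** pairs unknown to the masked matrix, pooled globally
rather than within its disease; per-disease ranking is exposed separately
through `top_k_candidates` (ties there break lexicographically by lncRNA id
so output is deterministic). The ROC sweeps the rank cutoff over every
integer threshold: sensitivity is the fraction of withheld associations
ranked at or above the cutoff, 1−specificity the mean fraction of candidate
pairs above it; AUC is the trapezoidal area, which with this tie convention
equals the mean per-fold normalized Mann–Whitney count. `roc_auc` for
explicit positive/negative score lists uses thresholds at all distinct
scores with half-credit ties, asserted in the tests against brute-force
pairwise counting. The `alpha_sweep` helper repeats LOOCV over a grid of
propagation weights and reports the argmax, mirroring how the walk's single
free parameter is chosen in practice. LOOCV contains no randomness; folds
are independent and order-invariant.

## Synthetic data

The generator emulates the statistical shape of curated association
catalogs: a sparse bipartite binary matrix with community structure and
partial expression coverage. Diseases and lncRNAs are split into n_blocks
near-equal contiguous communities; A(i,j) ~ Bernoulli(p_in) within a
community and Bernoulli(p_out) across. Defaults — nd = 50, nl = 40,
n_blocks = 4, p_in = 0.4, p_out = 0.02, expr_coverage = 0.5, 22 tissues —
give a desk-scale analogue of a few-hundred-association catalog (the real
catalogs this mimics have 290–600 associations over 80–170 diseases) while
keeping a full LOOCV under a few seconds. A fraction expr_coverage of
lncRNAs receives expression vectors w·latent(block) + (1−w)·noise over
n_tissues tissues, with w found by bisection against the empirically
measured mean within-block Spearman correlation of the actually drawn
vectors (target expr_block_corr, default 0.6, a strong but noisy tissue
co-expression signal); calibrating by simulation is simpler and sufficient
because the similarity that consumes these vectors is rank-based. All draws
come from one PCG64 generator stream seeded once, so outputs are
bit-reproducible and partial regeneration is impossible by design. The
degree-preserving shuffle applies checkerboard swaps — (a,b),(c,d) →
(a,d),(c,b) when no duplicate edge arises — leaving every row and column sum
intact while destroying community structure, and serves as the negative
control.

What the generator does **not** emulate: disease ontology structure,
scale-free degree distributions, biased curation (well-studied cancers have
far more edges), and identifier noise between databases. Passing tests on
this generator therefore demonstrate that the machinery recovers planted
homophily signal, not that real-catalog accuracy is attained.

### A ceiling on synthetic LOOCV accuracy

Under the iid Bernoulli block model, conditional on the masked matrix the
withheld edge is exchangeable with every other same-community non-edge: no
scorer, however good, can rank it above them other than by chance. At the
default conditions this caps LOOCV AUC at ≈ 0.85 (measured 0.845 at seed 0
for a scorer handed the true community labels; ≈ 0.856 in expectation), and
the walk reaches 0.67 at α = 0.9 and 0.78 at the sweep-selected α. Observed
accuracy on this generator must be judged against that ceiling and against
the shuffled null (≈ 0.47–0.52), not against 1.0.

## Numerical choices and limitations

* Kernel distances use the Gram expansion ‖x‖² + ‖y‖² − 2⟨x,y⟩, clipped at 0
  and symmetrized, with the diagonal set to exactly 1.
* Score TSVs print 17 significant digits and read back bit-identically
  (`float_precision="round_trip"`).
* Identifier order is first appearance in the input (file order for dense
  tables) and is the single source of truth for every downstream matrix; all
  operations are permutation-equivariant, so the choice is arbitrary but
  fixed.
* Dense linear algebra throughout; at catalog scale (hundreds of nodes) a
  full LOOCV is seconds, and sparse optimization is deliberately out of
  scope.
* k-fold CV, bootstrap intervals, precision–recall curves, and DAG-based
  disease semantic similarity are not implemented.
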