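# Methods

## Elastic network and covariance

The structure is reduced to one bead per residue at the Cα position.
Identity is the author's (chain, residue number, insertion code) triple, kept
verbatim because region definitions (P-loops, switch regions, cofactor
ligand spheres) are written in author numbering. Beads within `cutoff`
(default 15 Å, the conventional coarse-grained ANM choice) interact through
identical harmonic springs of constant `gamma` (default 1; the normalized
covariance is invariant under rescaling `gamma`, so the unit is arbitrary).
The 3N×3N Hessian uses the standard anisotropic form: off-diagonal block
−γ d̂d̂ᵀ per contact pair, diagonal blocks closing the row sums to zero.

A connected network has exactly six zero eigenvalues (rigid translations and
rotations). We flag trivial modes by λ < 1e-8·λ_max and *require* exactly
six, treating any seventh near-zero mode as an error: in practice it always
signals a floppy or disconnected geometry whose covariance is meaningless.
Non-trivial modes are indexed 1-based from the slowest.

The residue-level covariance contracts each 3×3 residue-pair block of
Σ_k (1/λ_k) ν_k ν_kᵀ by its trace; on every tested system this equals the
block-traced Moore–Penrose pseudo-inverse of the Hessian to ~1e-15 relative
error. Normalization divides by √(C_ii C_jj). Mode-subtracted covariances
C_−k are renormalized by the *full* matrix's diagonal, so couplings with and
without a mode stay on a common scale; pruning statistics, however, are
recomputed on C_−k (we read "same procedures and cutoffs" as: same D_cut and
C_thresh constants, full procedure — including the statistical threshold —
applied afresh).

## Coupling graph

Edge lengths are A_ij = 1 − |C_ij| with |C_ij| clipped at C_thresh = 0.95,
so no edge is shorter than A_thresh = 0.05 (numerical stability: secondary-
structure neighbours would otherwise create near-zero edges that dominate
every geodesic). An edge exists only if |C_ij| ≥ μ_|C| + σ_|C| and
D_ij ≤ D_cut = 11 Å. Both statistics are computed over off-diagonal |C|
entries only (the all-ones diagonal would bias the threshold), and the
condition is applied to |C|: the coupling analysis deliberately retains
anti-correlated pairs, and a signed threshold would discard them. A
diagnostic (`min_connecting_cutoff`) reports the smallest distance cutoff
keeping the Cα graph connected, for choosing D_cut on unusual geometries.

Geodesics come from Dijkstra on the sparse edge set; unreachable pairs are
+inf and yield M_ij = 0. The mechanical coupling is the fraction
M = A_thresh·|C|/G (clipped |C|): the "ratio" reading is the only one under
which strong correlation plus a short pathway gives large M and long
pathways suppress it. M is symmetric with zero diagonal.

## Pathways and chokepoints

Shortest-path trees are reconstructed deterministically: a node's
predecessor is the smallest-index neighbour u with cost(u) + A(u,v) equal to
cost(v) (relative tolerance 1e-12). Among all co-optimal paths this selects
the one whose predecessors, read backwards from the target, are minimal —
one path per ordered pair, never an ensemble of co-optimal paths.
Betweenness χ accrues, for each ordered pair (s ∈ X, t ∈ Y, s ≠ t), the
pair weight on the path's interior nodes; endpoints accrue nothing. The
default weight 1/G_st makes strongly coupled (cheap-path) pairs dominate;
`M_st` and unweighted counting are available as pluggable alternatives since
the literature is not unanimous on the cost weighting. χ is reported raw and
as percent of its maximum; "within p% of the maximum" counts residues with
χ ≥ (100 − p)% of max, which makes the counts non-decreasing in p.

Mode influence rebuilds the entire graph/χ stage from C_−k with identical
constants and compares profiles via O_k = (χ_−k·χ₀)/(χ₀·χ₀). O_k is
asymmetric by design (denominator from the reference) and may exceed 1
(removing a mode can concentrate traffic on the reference chokepoints,
giving negative influence). If subtracting a mode disconnects every X–Y
pair, we take the χ_−k = 0 limit, O_k = 0 and I_k = 1: that single mode
carried all motions needed for the coupling. Repeated runs on identical
inputs give bit-identical I_k; there is no stochastic step in this pipeline.

## Displacements and pseudo-covariance

The conformational change between two structures is the unit 3N-vector ΔR of
per-residue coordinate differences on their common residues, after rigid
superposition (Kabsch, proper rotation enforced) on a caller-chosen fit
subset. Overlaps |ν_k·ΔR| quantify how much each mode points along the
observed change (ΔR is zero-padded onto the model's residue set and
renormalized first). The pseudo-covariance C′_ij = ΔR_i·ΔR_j is the Gram
matrix of the per-residue 3-vectors — rank at most 3, rank 1 only when all
displacements are parallel — normalized by its own diagonal with near-zero
displacement residues masked. Fed through the identical graph/χ pipeline it
answers what coupling that single motion would create; for nearly pure
rigid-body displacements the pruned pseudo-graph can carry no pathway at
all, which the pipeline reports as a null overlap rather than an error.

## HDX-MS statistics

%D is 100·(#D)/(#D at 24 h), per peptide and condition; centroid-based
deuterium counts are fractional, so no rounding is applied. For one
condition and timepoint (default 1 h, by which slow cooperative motions have
been sampled) the pairwise difference matrix D_ij = |d_i − d_j| captures
which peptides exchange alike; Pearson correlation between its rows is the
peptide–peptide similarity. Hierarchical clustering uses 1 − corr as the
distance with complete linkage. The cluster count is the silhouette-score
maximizer over k-means partitions (k ∈ [2, 12], 50 restarts, fixed seed,
ties broken toward smaller k); the literature's "established by k-means" is
underspecified, and silhouette is the standard deterministic reading — the
full score curve is reported so any other choice can be audited.
Zero-variance difference profiles are excluded with a warning rather than
poisoning the correlation matrix.

## Synthetic fixtures

The hinge model plants a known answer for the chokepoint analysis: two
jittered cubic lattices (64 beads each, 3.8 Å spacing — the Cα virtual-bond
length; 0.3 Å Gaussian jitter) joined by a 4-bead single-strand linker
across a 19 Å gap, so domains never touch within the contact cutoffs and
every inter-domain path must traverse the linker. The linker winds off-axis
(120° per bead, 3 Å radius): a perfectly straight strand would leave domain
torsion about its axis nearly free and split off a spurious seventh soft
mode. Generation fails fast if the contact graph is disconnected or the
domains touch. Rigid perturbation of a region (rotation about the region
centroid plus translation) provides exact ground truth for superposition and
displacement tests. Planted uptake tables give each block a
single-exponential exchange curve whose rate is fixed by the 1-hour mean,
mirrored (100 − %D) for anti-correlated blocks, plus i.i.d. Gaussian noise
clipped to [0, 100] (with a warning when clipping actually distorts).
All generators are pure functions of their spec and seed.

These fixtures emulate the *topology* of a multi-domain complex — a unique
communication bottleneck, block-structured exchange — but not realistic
protein packing, sequence effects or experimental back-exchange. Passing
tests therefore demonstrate correctness of the machinery and recoverability
of planted structure, not biological accuracy on any particular complex.

## Problem sizes and determinism

Tests and the acceptance script run on systems of 10–150 beads and 12–20
node graphs — sizes at which exhaustive path enumeration and dense
pseudo-inverses are exact oracles; the pipeline itself scales to
multi-thousand-residue complexes, where the one-off 3N×3N
eigendecomposition dominates the cost. The run manifest records inputs,
parameters, seed, package version and SHA-256 checksums of every artifact,
and contains no timestamps: identical config and seed reproduce it byte for
byte.

## Known limitations

Harmonic fluctuations about one equilibrium structure cannot describe
transient large-amplitude changes, and a pathway is a necessary but not
sufficient condition for causal allosteric control. The betweenness cost
weighting and the k-selection rule are documented choices among defensible
alternatives (both pluggable). PDB input is Cα-only: altloc resolution keeps
the first-listed conformer, residues without a Cα are dropped with a
warning, and mmCIF is not supported.
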