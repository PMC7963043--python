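# mechcoupling

Graph-theoretic analysis of **mechanical coupling** in protein complexes:
which distant regions of a complex move together *and* are connected by an
efficient communication pathway, which residues are the chokepoints of that
communication, and which normal modes carry it. The package was built for
studying allosteric signalling in large multi-subunit machines such as the
nitrogenase complex (the ATP-hydrolyzing Fe protein docked on the catalytic
MoFe protein, with P-loops, switch I/II regions and metal-cluster sites as
the regions of interest), but every stage works on any Cα-level structure.
An accompanying module implements the downstream statistics for
hydrogen/deuterium-exchange mass spectrometry (HDX-MS), the solution-phase
measurement used to cross-check coupling predictions.

## The model

Residues are beads at Cα positions joined by identical springs within a
cutoff (an anisotropic network model). Diagonalizing the 3N×3N Hessian gives
eigenpairs (λ_k, ν_k); discarding the six rigid-body modes, the residue
covariance is the inverse-eigenvalue-weighted mode sum

    C_raw = Σ_k (1/λ_k) ν_k ν_kᵀ   (block-traced to N×N, then normalized to unit diagonal)

From the normalized **C** and the Cα distance matrix **D**, a pruned
correlation graph is built with edge lengths

    A_ij = 1 − |C_ij|,   A_ij = 0 if |C_ij| < μ_|C| + σ_|C|  or  D_ij > D_cut

with |C_ij| clipped at C_thresh = 0.95 (so A_thresh = 0.05) and
D_cut = 11 Å by default. The geodesic matrix **G** accumulates edge lengths
along cheapest paths, and the **mechanical coupling**

    M_ij = A_thresh · |C_ij| / G_ij

is large only when two residues are both correlated and joined by an
efficient path. Chokepoints are ranked by cost-weighted betweenness χ: every
ordered pair (s ∈ X, t ∈ Y) contributes weight 1/G_st to the interior
residues of its tie-broken shortest path. The influence of normal mode k on
an X–Y pathway network is

    I_k = 1 − O_k,   O_k = (χ_−k · χ₀) / (χ₀ · χ₀)

where χ_−k is recomputed from the covariance with mode k subtracted
(C_−k = C − (1/λ_k) ν_k ν_kᵀ, renormalized by the full-matrix fluctuations).
The same overlap compares pathway networks from any two motions, e.g. the
rank-deficient pseudo-covariance C′_ij = ΔR_i·ΔR_j built from the unit
displacement ΔR between two crystal forms.

For HDX-MS, peptide deuterium counts become %D against each peptide's
24-hour reference; peptides are clustered by Pearson correlation of their
pairwise |d_i − d_j| difference profiles (hierarchical, 1 − corr distance,
complete linkage), with the cluster count chosen by silhouette-scored
k-means.

## Worked example

`examples/01_hinge_chokepoints.py` builds a synthetic two-domain structure
whose domains communicate only through a 4-residue linker, and asks which
residues carry the inter-domain communication:

```
structure: 132 residues, linker at indices [64, 65, 66, 67]
top 5 chokepoints (residue, %-of-max χ):
   L:2   100.0%
   L:3    87.7%
   L:4    51.2%
   L:1    46.0%
  A:55    39.1%
residues within 25/50/75% of the maximum χ: [2, 3, 8]
```

All four linker residues (chain L) top the ranking — the planted bottleneck
is recovered — and the χ distribution is sharp: only 2 residues lie within
25% of the maximum. `examples/02_mode_influence.py` then shows that the
slowest modes carry this coupling (I₁ = 0.850, I₂ = 0.416, decaying to
0.002 by mode 9): removing the hinge-bending mode largely destroys the
pathway network, while stiff local modes are irrelevant.

The other examples cover displacement/mode overlaps and pseudo-covariance
(`03`), HDX correlation clustering (`04`), and the config-driven end-to-end
run with its reproducibility manifest (`05`). A thin CLI mirrors the
stages: `mechcoupling anm|couple|betweenness|modes|rmsf|displacement|hdx|simulate|run`.

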