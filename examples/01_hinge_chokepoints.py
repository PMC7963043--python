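"""Find the chokepoint residues of a two-domain hinge protein model.

Builds a synthetic structure whose two domains communicate only through a
short linker, runs the full ANM → covariance → coupling-graph → betweenness
pipeline, and shows that the linker residues carry the communication.
"""

import numpy as np

from mechcoupling import (
    HingeModelSpec,
    PruningParams,
    betweenness,
    build_anm,
    build_coupling_graph,
    covariance_from_modes,
    geodesic_matrix,
    make_hinge_structure,
    mechanical_coupling,
    threshold_counts,
)

structure, linker_idx, regions = make_hinge_structure(HingeModelSpec(seed=0))
print(f"structure: {len(structure)} residues, linker at indices {linker_idx.tolist()}")

model = build_anm(structure)  # 15 Å cutoff, uniform springs
cov = covariance_from_modes(model)
graph = mechanical_coupling(geodesic_matrix(build_coupling_graph(cov, structure, PruningParams())))

profile = betweenness(graph, regions["domain_a"], regions["domain_b"])
order = np.argsort(profile.chi)[::-1][:5]
print("top 5 chokepoints (residue, %-of-max χ):")
for i in order:
    print(f"  {structure.labels[i]:>6s}  {profile.percent[i]:6.1f}%")

counts = threshold_counts(profile)
print("residues within 25/50/75% of the maximum χ:",
      [counts[w] for w in (25.0, 50.0, 75.0)])
# A sharp χ distribution (few residues near the maximum) means the
# inter-domain communication funnels through a handful of residues —
# here, by construction, the linker.
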