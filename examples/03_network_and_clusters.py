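"""Group mined peptides with an identity network and greedy clustering.

The sequence-similarity network keeps an edge when two peptides share
more than 64.29% global-alignment identity; connected components are
peptide groups and degree-0 nodes are singletons (candidate novel
peptides).  Greedy 90% clustering then picks representatives the way a
CD-HIT pass would, for tree building.
"""

import numpy as np

from aureomine import DEFAULT_SEED, build_ssn, greedy_cluster, identity_matrix
from aureomine.synthetic import mutate_peptide

rng = np.random.default_rng(777)
center_b, _ = mutate_peptide(DEFAULT_SEED, 0.7, rng, new_id="centerB")
family_a = [mutate_peptide(DEFAULT_SEED, 0.05, rng, new_id=f"a{i}")[0] for i in range(6)]
family_b = [mutate_peptide(center_b, 0.05, rng, new_id=f"b{i}")[0] for i in range(6)]
peptides = family_a + family_b

matrix = identity_matrix(peptides)
within = matrix.pid("a0", "a1")
between = matrix.pid("a0", "b0")
print(f"within-family identity  : {within:.1f}%")
print(f"between-family identity : {between:.1f}%")

ssn = build_ssn(matrix, edge_threshold_pct=64.29)
print(f"network components      : {ssn.n_components} "
      f"({len(ssn.singletons)} singletons)")
for i, component in enumerate(ssn.components):
    print(f"  group {i}: {', '.join(component)}")

clusters = greedy_cluster(peptides, threshold_fraction=0.90)
print(f"90% identity clusters   : {len(clusters.clusters)} "
      f"(representatives for the tree)")
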