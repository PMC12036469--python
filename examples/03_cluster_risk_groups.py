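"""Cluster variable-length embeddings into ordinal risk groups.

Embedding matrices of different epoch counts are compared with the energy
distance per embedding dimension (averaged over dimensions), giving each
night a distance-to-everyone feature vector.  k-means on those vectors,
silhouette model selection, a subsampled consensus matrix, and a-posteriori
mortality-ordered risk labels complete the stratification.
"""

import numpy as np
import pandas as pd

from sleepstrat import (
    EmbeddingMatrix,
    cluster_k,
    consensus_analysis,
    cross_solution_flow,
    label_risk_groups,
    project_samples,
    silhouette_by_k,
)

# three synthetic regimes in embedding space, with varying night lengths
rng = np.random.default_rng(0)
centers = [0.0, 2.5, 6.0]
embs, true_regime = [], []
for i in range(60):
    g = i % 3
    n_epochs = int(rng.integers(40, 90))
    vals = centers[g] + 0.4 * rng.standard_normal((8, n_epochs))
    embs.append(EmbeddingMatrix(vals, recording_id=f"night{i:02d}"))
    true_regime.append(g)

proj = project_samples(embs, metric="energy")
print("silhouette by k:")
print(silhouette_by_k(proj, range(2, 6), seed=0).to_string(index=False))

solutions = [cluster_k(proj, k, seed=0) for k in (2, 3)]
flow = cross_solution_flow(solutions)
print("flow k=2 -> k=3 (cluster_from, cluster_to, count):")
print(flow[["cluster_from", "cluster_to", "count"]].to_string(index=False))

cm = consensus_analysis(proj, k=3, n_iterations=50, seed=0)
print(f"consensus entries at 0 or 1: "
      f"{np.isin(np.round(cm.values, 6), [0.0, 1.0]).mean():.0%}")

# attach synthetic survival outcomes: regime 2 has the worst mortality
subjects = pd.DataFrame({
    "id": [e.recording_id for e in embs],
    "time_years": rng.uniform(5, 15, 60),
    "event": [int(rng.random() < 0.1 + 0.3 * g) for g in true_regime],
}).set_index("id")
labeled = label_risk_groups(solutions[1], subjects)
print("risk labels by cluster:", labeled.risk_labels)
# The silhouette table peaks at the planted k=3; the consensus matrix is
# an exact 0/1 block structure because the regimes are widely separated,
# and RG3 is the cluster with the highest crude death rate.
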