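"""Compare interactomes across several datasets.

Simulates three related studies sharing a common core of true
regulations plus dataset-specific ones, then computes the Venn cells of
shared interactions, the dataset-specific interactions, and the k-means
clustering of cross-dataset correlation profiles with the dataset
dendrogram/PCA built from the cluster centres.
"""

import numpy as np

import mirlink as ml
from mirlink.multiset import build_pair_matrix, cluster_datasets, cluster_pairs
from mirlink.synth import SimulationConfig, simulate_dataset

# a common regulatory core (30 pairs) shared by every dataset, plus 20
# dataset-specific regulations each
rng = np.random.default_rng(19)
mirnas = [f"mir-{i:03d}" for i in range(1, 31)]
genes = [f"gene-{i:03d}" for i in range(1, 301)]
gene_pool = list(rng.permutation(genes))
core = [(mirnas[rng.integers(0, 30)], gene_pool.pop()) for _ in range(30)]

results = []
for i, label in enumerate(["liver", "colon", "stomach"]):
    own = [(mirnas[rng.integers(0, 30)], gene_pool.pop()) for _ in range(20)]
    cfg = SimulationConfig(n_mirna=30, n_mrna=300, n_control=20, n_case=20,
                           n_true_pairs=50, beta=1.0, noise_sd=0.7, seed=20 + i)
    ds, truth, dbs = simulate_dataset(cfg, true_pairs=core + own)
    corr = ml.correlate_all(ds)
    sig = ml.significant_pairs(corr, 0.05)
    combined = ml.intersect_with_targets(
        sig, ml.diffexp_ttest(ds.mirna, ds.pheno),
        ml.diffexp_ttest(ds.mrna, ds.pheno), dbs)
    results.append(ml.DatasetResult(
        label=label, combined=combined,
        expressed_mirnas=frozenset(ds.mirna.feature_ids),
        expressed_mrnas=frozenset(ds.mrna.feature_ids), corr=corr))

venn = ml.shared_interactions(results)
print("Interactions per dataset:",
      {r.label: len(r.pairs) for r in results})
print(f"Union across datasets: {venn.union_size}; "
      f"shared by all three: {len(venn.in_all())}")

for r in results:
    spec = ml.specific_interactions(results, r.label)
    print(f"Specific to {r.label}: {len(spec)}")

matrix = build_pair_matrix(results)
print(f"\nPair matrix: {matrix.cor.shape[0]} pairs measured everywhere, "
      f"significant+predicted in >=1 dataset")
clustering = cluster_pairs(matrix, k=3, n_init=10, seed=0)
print("Cluster centres (mean correlation per dataset):")
print(clustering.centers.round(2).to_string())

tree = cluster_datasets(clustering.centers)
print("\nDataset PCA coordinates (correlation-matrix PCA):")
print(tree.pca_coords.round(2).to_string())
# Datasets whose interactions correlate similarly across the shared pairs
# sit close together in the PCA and merge early in the dendrogram.
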