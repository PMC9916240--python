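"""Exploratory structure: PCA of all samples, clustering of raw wastes.

Treated material drifts away from raw wastes in the 34-variable space
(accessibility down, complexity up). PCA shows the drift and flags
multivariate outliers; hierarchical clustering groups raw wastes by their
composition profiles.
"""
import numpy as np

from omstab import fit_pca, flag_outliers, generate_dataset, hca_cluster

dataset = generate_dataset(seed=1)
ids = sorted(dataset.samples)
X = np.vstack([dataset.samples[s].features for s in ids])

pca = fit_pca(X, 5)
print(f"PCA on {X.shape[0]} samples x 34 variables, 5 components:")
print(f"  R2(cum) = {pca.r2_cum:.3f}, Q2(cum) = {pca.q2_cum:.3f}")
print(f"  per-component R2: {np.round(pca.r2, 3)}")

# mean score of each route on the first component: treatment moves material
# along the dominant stability axis
scores = pca.scores[:, 0]
for route in ("raw", "AD", "compost", "AD+compost"):
    sel = [i for i, s in enumerate(ids) if dataset.samples[s].route == route]
    print(f"  mean PC1 score, {route:10s}: {scores[sel].mean():+7.2f}")

out = flag_outliers(pca, confidence=0.95, sample_ids=ids)
print(f"  flagged outside the 95% Hotelling T2 ellipse: {out or 'none'}")
print("  (flags are advisory - removal is an explicit run-config decision)")

wastes = dataset.wastes()
tree = hca_cluster(
    np.vstack([w.features for w in wastes]),
    k=5,
    sample_ids=[w.sample_id for w in wastes],
)
print(f"\nHCA of {len(wastes)} raw wastes into k = 5 groups:")
for g in sorted(set(tree.labels)):
    members = [w.sample_id for w, l in zip(wastes, tree.labels) if l == g]
    print(f"  group {g}: {', '.join(members)}")
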