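"""Measure how well a trained model's embedding space mirrors the taxonomy.

Per-class centroids -> geodesic distance matrix in the model's geometry ->
normalised comparison against the descriptor-derived ground-truth matrix:
mean absolute difference (lower = better aligned) and Spearman rank
correlation (higher = better aligned), plus the average-linkage dendrogram
merge table.
"""

from lorentznet import (EmbeddingSet, ModelConfig, SyntheticSpec, TrainConfig,
                        build_model, build_taxonomy, class_centroids, dendrogram,
                        generate_dataset, hierarchy_alignment,
                        taxonomy_ground_truth_labels, train)

tax = build_taxonomy([2, 2, 2])
spec = SyntheticSpec(image_size=16, n_per_class=40, seed=3)
images, labels, manifest = generate_dataset(tax, spec)
split = manifest["split"].to_numpy()
data = {"train": (images[split == "train"], labels[split == "train"])}

for geometry, epochs in (("euclidean", 15), ("lorentz", 30)):
    model = build_model(ModelConfig(geometry=geometry, n_classes=tax.n_classes,
                                    image_size=16), seed=3)
    model, _ = train(model, data, TrainConfig(epochs=epochs, learning_rate=0.05, batch_size=32,
                                              seed=3))
    emb = EmbeddingSet.from_model(model, images)
    emb.labels = labels
    res = hierarchy_alignment(emb, taxonomy_ground_truth_labels(tax),
                              m=model.manifold)
    print(f"{geometry:>10}: MAD {res.mad:.3f} "
          f"(95% CI {res.mad_ci[0]:.3f}-{res.mad_ci[1]:.3f}), "
          f"Spearman rho {res.spearman_rho:.3f} (p {res.spearman_p:.2g})")
    Z = dendrogram(class_centroids(emb), geometry, model.manifold)
    print(f"           first dendrogram merge: classes {int(Z[0,0])} and {int(Z[0,1])}")
# A lower MAD / higher rho means the model's class geometry tracks the
# generative tree; the hyperbolic head usually wins on MAD.
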