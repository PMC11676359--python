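"""Train the Euclidean and Lorentz classifiers on the same data.

Both models share one convolutional encoder initialisation; they differ
only in the head (affine vs clip -> exp-map -> Lorentz decoder, +1
curvature parameter).  Prints loss/Top-1/Top-5 for each and the learned
curvature.
"""

from lorentznet import (ModelConfig, SyntheticSpec, TrainConfig, build_model,
                        build_taxonomy, evaluate, generate_dataset, train)

tax = build_taxonomy([2, 2])
spec = SyntheticSpec(image_size=16, n_per_class=40, seed=7)
images, labels, manifest = generate_dataset(tax, spec)
split = manifest["split"].to_numpy()
data = {"train": (images[split == "train"], labels[split == "train"]),
        "val": (images[split == "val"], labels[split == "val"])}

for geometry, epochs in (("euclidean", 15), ("lorentz", 30)):
    model = build_model(ModelConfig(geometry=geometry, n_classes=tax.n_classes,
                                    image_size=16), seed=7)
    model, log = train(model, data, TrainConfig(epochs=epochs, learning_rate=0.05, batch_size=32,
                                                seed=7))
    rep = evaluate(model, data["val"])
    extra = f"  learned k={model.manifold.k:.3f}" if geometry == "lorentz" else ""
    print(f"{geometry:>10}: {model.n_parameters()} params | "
          f"val CE {rep.cross_entropy:.3f}, Top-1 {rep.top1:.1f}%, "
          f"Top-5 {rep.top5:.1f}%{extra}")
# The Lorentz variant carries exactly one extra parameter (the curvature)
# and typically needs roughly twice the epochs to converge.
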