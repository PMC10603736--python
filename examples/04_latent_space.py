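"""Quantify and visualise domain alignment in the latent space.

Trains the baseline and the adversarial method on a shifted pair, then
reports the two package proxies for "domain-invariant features": the
balanced accuracy of a post-hoc linear domain probe (0.5 = invariant) and
the k-nearest-neighbour mixing score (1 = domains interleave per class).
Optionally writes a 2-D PCA + t-SNE scatter to latent_space.png.
"""

import sys

import numpy as np

from aardapt import preprocessing as pp
from aardapt import synthetic as sy
from aardapt.latent import embed_2d, extract_latents, mixing_score, plot_embedding
from aardapt.preprocessing import Standardizer
from aardapt.training import (benchmark_config, domain_probe,
                              train_source_only, train_uda)

config = sy.SyntheticConfig(class_models=tuple(sy.dog_activity_models()),
                            samples_per_class=50, seed=1)
source, target = sy.generate_domain_pair(config,
                                         sy.shift_preset("sensor_position"))
pp.make_folds(source, seed=0)
pp.make_folds(target, seed=1)
scaler = Standardizer().fit(source.X[source.split_indices(0)[0]].astype(np.float32))
Xs = scaler.transform(source.X.astype(np.float32))
Xt = scaler.transform(target.X.astype(np.float32))
domains = np.concatenate([np.zeros(len(Xs), dtype=int),
                          np.ones(len(Xt), dtype=int)])
labels = np.concatenate([source.y, target.y])

for method in ("source_only", "dann"):
    cfg = benchmark_config(seed=0)
    if method == "source_only":
        bundle, _ = train_source_only(source, target, fold=0, cfg=cfg)
    else:
        bundle, _ = train_uda(source, target, method, fold=0, cfg=cfg)
    fs = extract_latents(bundle, Xs, layer="pooled")
    ft = extract_latents(bundle, Xt, layer="pooled")
    probe = domain_probe(fs, ft, seed=0)
    mix = mixing_score(np.concatenate([fs, ft]), domains, labels)["mean"]
    print(f"{method:12s} domain probe {probe:.3f}  mean mixing score {mix:.3f}")
    if "--plot" in sys.argv:
        emb = embed_2d(np.concatenate([fs, ft]), labels=labels,
                       domains=domains, perplexity=30.0, seed=0)
        ax = plot_embedding(emb, class_names=source.class_names,
                            title=method)
        ax.figure.savefig(f"latent_space_{method}.png", dpi=150,
                          bbox_inches="tight")

print("\nLower probe accuracy and higher mixing after adversarial training "
      "indicate that the extractor learned features a linear observer "
      "cannot assign to a domain — the mechanism behind the target-side "
      "accuracy gains.")
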