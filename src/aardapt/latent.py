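"""Latent-space analysis: pre-softmax features, 2-D embedding, mixing score.

The qualitative claim behind adaptation training is that it aligns the
target-domain feature cloud with the source cloud per class.  This module
extracts the classifier's pre-softmax latent vectors, reduces them with PCA
followed by t-SNE for visualisation, and quantifies source/target mixing
with a k-nearest-neighbour composition score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.neighbors import NearestNeighbors

from .models import ModelBundle
from .nn import Tensor, no_grad

__all__ = ["EmbeddingResult", "extract_latents", "embed_2d", "mixing_score",
           "plot_embedding"]


@dataclass
class EmbeddingResult:
    """2-D embedding of latent vectors with its provenance."""

    coords_2d: np.ndarray
    labels: np.ndarray
    domains: np.ndarray
    pca_variance_explained: float
    perplexity: float
    seed: int
    kl_divergence: float = float("nan")


def extract_latents(bundle: ModelBundle, X: np.ndarray,
                    layer: str = "logits", batch_size: int = 512) -> np.ndarray:
    """Inference-mode latent vectors for an array of windows.

    ``layer="logits"`` returns the final pre-softmax activations (width
    n_classes, the layer embedded for figure parity); ``layer="penultimate"``
    returns the 64-wide hidden state, which carries more geometry when the
    class count is small; ``layer="pooled"`` returns the 128-d extractor
    feature.
    """
    if layer not in ("logits", "penultimate", "pooled"):
        raise ValueError(f"unknown layer {layer!r}")
    bundle.eval()
    chunks = []
    with no_grad():
        for lo in range(0, len(X), batch_size):
            feats = bundle.extractor(Tensor(X[lo:lo + batch_size]))
            if layer == "pooled":
                chunks.append(feats.data)
                continue
            logits, hidden = bundle.classifier.forward_with_hidden(feats)
            chunks.append(logits.data if layer == "logits" else hidden[-1].data)
    return np.concatenate(chunks)


def embed_2d(features: np.ndarray, labels=None, domains=None,
             pca_dims: int = 50, perplexity: float = 30.0,
             seed: int = 0, n_iter: int = 1000) -> EmbeddingResult:
    """PCA (to ``pca_dims``) followed by seeded t-SNE to two dimensions.

    PCA is skipped when the feature width does not exceed ``pca_dims``; the
    t-SNE stage uses PCA initialisation and reports its final KL divergence.
    """
    features = np.asarray(features, dtype=float)
    n = len(features)
    if n <= 3 * perplexity:
        raise ValueError(
            f"{n} points is too few for perplexity {perplexity}; "
            f"use perplexity <= {max((n - 1) / 3.0, 1.0):.0f}")
    if features.shape[1] > pca_dims:
        pca = PCA(n_components=pca_dims, random_state=seed).fit(features)
        reduced = pca.transform(features)
        var = float(pca.explained_variance_ratio_.sum())
    else:
        reduced, var = features, 1.0
    tsne = TSNE(n_components=2, perplexity=perplexity, init="pca",
                random_state=seed, max_iter=n_iter)
    coords = tsne.fit_transform(reduced)
    return EmbeddingResult(
        coords_2d=coords,
        labels=np.asarray(labels) if labels is not None else np.zeros(n, dtype=int),
        domains=np.asarray(domains) if domains is not None else np.zeros(n, dtype=int),
        pca_variance_explained=var, perplexity=perplexity, seed=seed,
        kl_divergence=float(tsne.kl_divergence_))


def mixing_score(features: np.ndarray, domains: np.ndarray, labels: np.ndarray,
                 k: int = 10) -> dict:
    """Per-class source/target neighbourhood mixing, chance-normalised.

    For every point of a class, the fraction of its k nearest same-class
    neighbours that belong to the other domain is averaged and divided by
    the chance rate (the other domain's share of the remaining class
    points), then clipped to [0, 1].  1 means the two domains interleave
    perfectly within the class; 0 means they form separate clouds.  Scores
    are computed on the raw feature space by default, which makes them
    invariant to global rotation/translation.
    """
    features = np.asarray(features, dtype=float)
    domains = np.asarray(domains)
    labels = np.asarray(labels)
    scores: dict = {}
    for cls in np.unique(labels):
        mask = labels == cls
        dom = domains[mask]
        pts = features[mask]
        n_cls = len(pts)
        if len(np.unique(dom)) < 2:
            warnings.warn(f"class {cls!r} present in only one domain; "
                          "score omitted", stacklevel=2)
            continue
        k_eff = min(k, n_cls - 1)
        nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(pts)
        _, idx = nn.kneighbors(pts)
        neighbor_dom = dom[idx[:, 1:]]                 # drop self
        other_frac = (neighbor_dom != dom[:, None]).mean(axis=1)
        # chance rate for each point: other domain's share of remaining points
        n_other = np.where(dom == dom[0], (dom != dom[0]).sum(),
                           (dom == dom[0]).sum())
        chance = n_other / (n_cls - 1)
        score = float(np.mean(other_frac / chance))
        key = cls.item() if hasattr(cls, "item") else cls
        scores[key] = min(score, 1.0)
    if not scores:
        raise ValueError("no class is present in both domains")
    scores["mean"] = float(np.mean([v for v in scores.values()]))
    return scores


def plot_embedding(result: EmbeddingResult, class_names=None, ax=None,
                   title: str = ""):
    """Scatter the 2-D embedding: circles = source, triangles = target,
    one colour per class."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    classes = np.unique(result.labels)
    cmap = plt.get_cmap("tab10")
    for marker, dom_code, dom_name in (("o", 0, "source"), ("^", 1, "target")):
        for i, cls in enumerate(classes):
            mask = (result.labels == cls) & (result.domains == dom_code)
            if not mask.any():
                continue
            name = class_names[cls] if class_names is not None else str(cls)
            ax.scatter(result.coords_2d[mask, 0], result.coords_2d[mask, 1],
                       marker=marker, s=14, alpha=0.7, color=cmap(i % 10),
                       label=f"{name} ({dom_name})")
    ax.set_xlabel("t-SNE 1")
    ax.set_ylabel("t-SNE 2")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=6, markerscale=0.8, ncol=2)
    return ax
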