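"""Model interpretation: saliency maps, layer-feature embeddings, PCA.

The saliency map of a seed is the gradient of the selected-class
output with respect to every pixel of its input spectral matrix — the
one-hot "correct" vector picks the scalar to differentiate.  By
default the selected output is the softmax probability (the dense
head's "ten probability values"); the pre-softmax logit is exposed as
an alternative because probability gradients saturate once a class is
confidently predicted.

Layer features for the clustering visualization come from the stem
max pool, the last residual block (channel-averaged, then flattened)
and the dense layer (the raw length-K score vector).  t-SNE runs on a
PCA pre-reduction: 12 dimensions for the two convolutional layers, 6
for the dense layer (which only has K=10 features to begin with).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .models import Network

__all__ = [
    "SaliencyMap",
    "FeatureEmbedding",
    "PCAScores",
    "saliency",
    "extract_features",
    "tsne_embed",
    "pca_scores",
    "display_map",
]


@dataclass
class SaliencyMap:
    values: np.ndarray          # raw signed gradients, input-shaped
    seed_id: str
    target_class: int
    output_stage: str           # "probability" or "logit"


@dataclass
class FeatureEmbedding:
    coordinates: np.ndarray     # (n_samples, 2)
    source_layer: str
    perplexity: float
    pca_init_dims: int
    rng_seed: int


@dataclass
class PCAScores:
    scores: np.ndarray              # (n_samples, n_components)
    explained_variance_ratio: np.ndarray
    loadings: np.ndarray            # (n_components, n_features), orthonormal


def saliency(network: Network, matrix: np.ndarray, true_class: int,
             output_stage: str = "probability",
             seed_id: str = "") -> SaliencyMap:
    """Gradient of the true-class output w.r.t. every input pixel."""
    if output_stage not in ("probability", "logit"):
        raise ValueError("output_stage must be 'probability' or 'logit'")
    matrix = np.asarray(matrix)
    x = matrix[None] if matrix.ndim == network.spec.dims else matrix
    logits = network.forward(x, train=False)
    K = logits.shape[1]
    if not 0 <= true_class < K:
        raise ValueError(f"class index {true_class} out of range 0..{K - 1}")
    onehot = np.zeros(K, dtype=logits.dtype)
    onehot[true_class] = 1.0
    if output_stage == "logit":
        dlogits = np.broadcast_to(onehot, logits.shape).copy()
    else:
        p = nn.softmax(logits)
        # d p_c / d z = p_c * (onehot - p)
        dlogits = p[:, true_class:true_class + 1] * (onehot - p)
    grad = network.backward(dlogits.astype(logits.dtype))
    values = grad[0] if matrix.ndim == network.spec.dims else grad
    return SaliencyMap(values=np.asarray(values), seed_id=seed_id,
                       target_class=int(true_class),
                       output_stage=output_stage)


def display_map(smap: SaliencyMap) -> np.ndarray:
    """Absolute-valued, min-max scaled map for plotting."""
    a = np.abs(smap.values)
    lo, hi = a.min(), a.max()
    return (a - lo) / (hi - lo) if hi > lo else np.zeros_like(a)


def extract_features(network: Network, inputs: np.ndarray, layer: str,
                     batch_size: int = 256) -> np.ndarray:
    """Per-sample feature vectors from a capture layer.

    Convolutional feature maps are averaged over channels and
    flattened; the dense layer yields its length-K score vector.
    """
    if layer not in Network.CAPTURE_LAYERS:
        raise ValueError(f"unknown layer {layer!r}; "
                         f"choose from {Network.CAPTURE_LAYERS}")
    inputs = np.asarray(inputs)
    outs = []
    for i in range(0, len(inputs), batch_size):
        cap: dict = {}
        network.forward(inputs[i:i + batch_size], train=False, capture=cap)
        h = cap[layer]
        if layer != "Dense":
            h = h.mean(axis=-1)             # average over channels
            h = h.reshape(h.shape[0], -1)   # flatten spatial axes
        outs.append(np.asarray(h, dtype=np.float64))
    return np.concatenate(outs, axis=0)


def tsne_embed(features: np.ndarray, layer: str, perplexity: float = 30.0,
               rng_seed: int = 0) -> FeatureEmbedding:
    """2-D t-SNE of layer features after a PCA pre-reduction.

    The pre-reduction keeps 12 dimensions for the convolutional
    layers and 6 for the dense layer.
    """
    from sklearn.manifold import TSNE

    features = np.asarray(features, dtype=np.float64)
    n = len(features)
    if n < 3 * perplexity:
        raise ValueError(f"need at least {int(3 * perplexity)} samples for "
                         f"perplexity {perplexity}, got {n}")
    pca_dims = 6 if layer == "Dense" else 12
    pca_dims = min(pca_dims, features.shape[1], n - 1)
    ps = pca_scores(features, n_components=pca_dims)
    reduced = ps.scores
    emb = TSNE(n_components=2, perplexity=perplexity, init="pca",
               random_state=rng_seed).fit_transform(reduced)
    return FeatureEmbedding(coordinates=np.asarray(emb), source_layer=layer,
                            perplexity=perplexity, pca_init_dims=pca_dims,
                            rng_seed=rng_seed)


def pca_scores(X: np.ndarray, n_components: int = 3) -> PCAScores:
    """Principal-component scores of mean-centred spectra.

    Eigendecomposition of the covariance matrix; scores are the
    projections on the top eigenvectors, explained variance is
    λ_k / Σλ.  The sign of each eigenvector is fixed by making its
    largest-magnitude loading positive.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least two samples")
    n_components = min(n_components, *X.shape)
    Xc = X - X.mean(axis=0)
    n, p = Xc.shape
    # eigendecompose the smaller Gram/covariance matrix
    if p <= n:
        C = Xc.T @ Xc / (n - 1)
        lam, vec = np.linalg.eigh(C)
        order = np.argsort(lam)[::-1]
        lam = lam[order]
        V = vec[:, order]
    else:
        G = Xc @ Xc.T / (n - 1)
        lam, u = np.linalg.eigh(G)
        order = np.argsort(lam)[::-1]
        lam = lam[order]
        u = u[:, order]
        with np.errstate(divide="ignore", invalid="ignore"):
            V = Xc.T @ u / np.sqrt(np.maximum(lam, 1e-300) * (n - 1))
    lam = np.clip(lam, 0.0, None)
    V = V[:, :n_components]
    lam_k = lam[:n_components]
    # sign convention
    for k in range(V.shape[1]):
        j = np.argmax(np.abs(V[:, k]))
        if V[j, k] < 0:
            V[:, k] = -V[:, k]
    scores = Xc @ V
    total = lam.sum()
    evr = lam_k / total if total > 0 else np.zeros_like(lam_k)
    return PCAScores(scores=scores, explained_variance_ratio=evr,
                     loadings=V.T)
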