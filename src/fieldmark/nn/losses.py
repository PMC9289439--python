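"""Loss functions: softmax cross-entropy and the normalized-proxy loss.

The proxy loss assigns every class (here: every field plot) a learnable
proxy vector; an embedding is scored against all proxies by cosine
similarity scaled by a temperature, and penalized with softmax
cross-entropy against its own class's proxy. Both embeddings and proxies
are unit-normalized inside the loss, so only directions matter.
"""

from __future__ import annotations

import numpy as np


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over a batch; returns (loss, dlogits)."""
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    loss = float(-np.mean(np.log(p[np.arange(n), labels] + 1e-300)))
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, dlogits / n


def _normalize_rows(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    norms = np.linalg.norm(x, axis=1, keepdims=True)
    norms = np.maximum(norms, 1e-12)
    return x / norms, norms


def proxy_loss(
    embeddings: np.ndarray,
    labels: np.ndarray,
    proxies: np.ndarray,
    temperature: float,
) -> float:
    """Mean proxy cross-entropy:
    ``L = -log softmax_y( cos(e, p_c) / tau )`` averaged over the batch.

    Accepts a single d-vector or an (N, d) batch.
    """
    loss, _, _ = proxy_loss_grad(embeddings, labels, proxies, temperature)
    return loss


def proxy_loss_grad(
    embeddings: np.ndarray,
    labels: np.ndarray,
    proxies: np.ndarray,
    temperature: float,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Proxy loss with analytic gradients wrt embeddings and proxies.

    Returns (loss, d_embeddings, d_proxies), shapes matching the inputs.
    """
    single = embeddings.ndim == 1
    e = np.atleast_2d(np.asarray(embeddings, dtype=np.float64))
    p = np.asarray(proxies, dtype=np.float64)
    y = np.atleast_1d(np.asarray(labels))
    if y.max(initial=0) >= p.shape[0] or y.min(initial=0) < 0:
        raise IndexError("plot label outside the proxy bank")
    e_hat, e_norm = _normalize_rows(e)
    p_hat, p_norm = _normalize_rows(p)
    sims = e_hat @ p_hat.T / temperature  # (N, P)
    loss, dsims = softmax_cross_entropy(sims, y)
    de_hat = dsims @ p_hat / temperature
    dp_hat = dsims.T @ e_hat / temperature
    # back through row normalization: d x = (d x_hat - (d x_hat . x_hat) x_hat)/|x|
    de = (de_hat - (de_hat * e_hat).sum(axis=1, keepdims=True) * e_hat) / e_norm
    dp = (dp_hat - (dp_hat * p_hat).sum(axis=1, keepdims=True) * p_hat) / p_norm
    if single:
        de = de[0]
    return loss, de, dp
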