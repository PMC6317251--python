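"""Minimal NumPy neural-network core for the patch classifier.

Implements exactly the layer stack the classifier needs — one valid
convolution, ReLU, cross-channel local response normalization (LRN),
2x2 pooling, a hidden fully-connected layer with dropout, and a softmax
output — with hand-derived backward passes.  Kept deliberately small and
dtype-agnostic so the backward pass can be verified against central
finite differences in float64.
"""

from __future__ import annotations

from typing import Dict, Optional, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def init_params(
    rng: np.random.Generator,
    input_shape: Tuple[int, int],
    kernel_size: int,
    kernel_count: int,
    fc_units: int,
    n_classes: int = 2,
    dtype=np.float32,
) -> Dict[str, np.ndarray]:
    """Gaussian weights scaled by fan-in (He style), zero biases."""
    h, w = input_shape
    ho, wo = h - kernel_size + 1, w - kernel_size + 1
    ph, pw = ho // 2, wo // 2
    feat = ph * pw * kernel_count

    def gauss(shape, fan_in):
        return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)

    # Antithetic conv init: the second half of the kernels is the negation
    # of the first.  Guarantees that flat image regions of either sign
    # activate some units, so uniform-intensity tissue cannot collapse into
    # an indistinguishable all-dead-ReLU feature vector (the classic dying
    # ReLU failure, which otherwise depends on the luck of the draw).
    Wc = gauss((kernel_count, kernel_size, kernel_size), kernel_size**2)
    half_k = kernel_count // 2
    Wc[half_k : 2 * half_k] = -Wc[:half_k]

    return {
        "Wc": Wc,
        "bc": np.zeros(kernel_count, dtype=dtype),
        "W1": gauss((feat, fc_units), feat),
        "b1": np.zeros(fc_units, dtype=dtype),
        "W2": gauss((fc_units, n_classes), fc_units),
        "b2": np.zeros(n_classes, dtype=dtype),
    }


def _lrn_channel_sum(x: np.ndarray, n: int) -> np.ndarray:
    """Sum of x over a centred window of n channels (last axis), zero-padded."""
    half = (n - 1) // 2
    if half == 0:
        return x.copy()
    out = np.zeros_like(x)
    c = x.shape[-1]
    for off in range(-half, half + 1):
        lo, hi = max(0, -off), min(c, c - off)
        out[..., lo:hi] += x[..., lo + off : hi + off]
    return out


def forward(
    X: np.ndarray,
    params: Dict[str, np.ndarray],
    *,
    lrn_channels: int = 3,
    lrn_alpha: float = 1e-4,
    lrn_beta: float = 0.75,
    lrn_k: float = 2.0,
    pooling: str = "max",
    dropout_p: float = 0.5,
    train: bool = False,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[np.ndarray, dict]:
    """Forward pass.  Returns class probabilities (B, n_classes) and a cache.

    ``X`` has shape (B, H, W), already normalized.  Dropout is applied only
    when ``train`` is True (inverted dropout, so evaluation needs no
    rescaling).
    """
    k = params["Wc"].shape[1]
    windows = sliding_window_view(X, (k, k), axis=(1, 2))  # (B, Ho, Wo, k, k)
    z = np.tensordot(windows, params["Wc"], axes=([3, 4], [1, 2])) + params["bc"]
    a = np.maximum(z, 0.0)  # ReLU

    # LRN across channels: b = a / (k + alpha/n * sum a^2)^beta
    s = _lrn_channel_sum(a * a, lrn_channels)
    d = lrn_k + (lrn_alpha / lrn_channels) * s
    dmb = d ** (-lrn_beta)
    lrn = a * dmb

    B, ho, wo, K = lrn.shape
    ph, pw = ho // 2, wo // 2
    crop = lrn[:, : 2 * ph, : 2 * pw, :]
    tiles = crop.reshape(B, ph, 2, pw, 2, K)
    if pooling == "max":
        pooled = tiles.max(axis=(2, 4))
    elif pooling == "avg":
        pooled = tiles.mean(axis=(2, 4))
    else:
        raise ValueError(f"unknown pooling type {pooling!r}")

    flat = pooled.reshape(B, -1)
    h1 = flat @ params["W1"] + params["b1"]

    if train and dropout_p > 0:
        if rng is None:
            raise ValueError("training forward pass needs an rng for dropout")
        keep = 1.0 - dropout_p
        drop_mask = (rng.random(h1.shape) < keep) / keep
    else:
        drop_mask = None
    h1d = h1 * drop_mask if drop_mask is not None else h1
    h1r = np.maximum(h1d, 0.0)

    logits = h1r @ params["W2"] + params["b2"]
    shifted = logits - logits.max(axis=1, keepdims=True)
    expz = np.exp(shifted)
    probs = expz / expz.sum(axis=1, keepdims=True)

    cache = dict(
        windows=windows, z=z, a=a, d=d, dmb=dmb, lrn=lrn, tiles=tiles,
        pooled=pooled, flat=flat, h1=h1, drop_mask=drop_mask, h1d=h1d,
        h1r=h1r, probs=probs, pooling=pooling, shape=(B, ph, pw, K),
        lrn_channels=lrn_channels, lrn_alpha=lrn_alpha, lrn_beta=lrn_beta,
    )
    return probs, cache


def loss_and_grads(
    y: np.ndarray, params: Dict[str, np.ndarray], cache: dict
) -> Tuple[float, Dict[str, np.ndarray]]:
    """Mean cross-entropy loss and gradients w.r.t. all parameters.

    ``y`` holds integer class indices.  Must be called with the cache of a
    training-mode forward pass on the same batch.
    """
    probs = cache["probs"]
    B = probs.shape[0]
    eps = np.finfo(probs.dtype).tiny
    loss = float(-np.log(np.maximum(probs[np.arange(B), y], eps)).mean())

    dlogits = probs.copy()
    dlogits[np.arange(B), y] -= 1.0
    dlogits /= B

    grads: Dict[str, np.ndarray] = {}
    grads["W2"] = cache["h1r"].T @ dlogits
    grads["b2"] = dlogits.sum(axis=0)
    dh1r = dlogits @ params["W2"].T
    dh1d = dh1r * (cache["h1d"] > 0)
    dh1 = dh1d * cache["drop_mask"] if cache["drop_mask"] is not None else dh1d
    grads["W1"] = cache["flat"].T @ dh1
    grads["b1"] = dh1.sum(axis=0)
    dflat = dh1 @ params["W1"].T

    B_, ph, pw, K = cache["shape"]
    dpooled = dflat.reshape(B_, ph, pw, K)
    tiles = cache["tiles"]
    if cache["pooling"] == "max":
        pooled_b = cache["pooled"][:, :, None, :, None, :]
        is_max = tiles == pooled_b
        counts = is_max.sum(axis=(2, 4), keepdims=True)
        dtiles = is_max * (dpooled[:, :, None, :, None, :] / counts)
    else:
        dtiles = np.broadcast_to(
            dpooled[:, :, None, :, None, :] / 4.0, tiles.shape
        )
    dlrn = np.zeros_like(cache["lrn"])
    dlrn[:, : 2 * ph, : 2 * pw, :] = dtiles.reshape(B_, 2 * ph, 2 * pw, K)

    # LRN backward: da_j = g_j d_j^-beta - (2 alpha beta / n) a_j * W(g a d^(-beta-1))_j
    a, d, dmb = cache["a"], cache["d"], cache["dmb"]
    n, alpha, beta = cache["lrn_channels"], cache["lrn_alpha"], cache["lrn_beta"]
    u = dlrn * a * dmb / d  # g * a * d^(-beta-1)
    da = dlrn * dmb - (2.0 * alpha * beta / n) * a * _lrn_channel_sum(u, n)

    dz = da * (cache["z"] > 0)
    grads["Wc"] = np.tensordot(dz, cache["windows"], axes=([0, 1, 2], [0, 1, 2]))
    grads["bc"] = dz.sum(axis=(0, 1, 2))
    return loss, grads
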