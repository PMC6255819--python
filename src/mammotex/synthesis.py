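"""Gram-matrix texture statistics and deep synthesis.

A layer's Gram matrix ``G^l = F^l (F^l)^T`` (raw inner products of channel
activation vectors over spatial positions) summarizes which features
co-occur, discarding where.  The set of Gram matrices over a hierarchy of
layers is the texture signature of an image; two images with matching Gram
sets contain broadly the same features in different arrangements — the
metamer property this package studies.

Synthesis starts from seeded uniform white noise and minimizes

    L(x) = sum_l  w_l / (4 N_l^2 M_l^2) * sum_ij (G^l_ij(x) - A^l_ij)^2

by projected steepest descent on the pixels (Armijo backtracking line
search, pixels clamped to [0,1] after each accepted step), where ``A^l``
are the target image's Gram matrices, ``N_l`` the channel count and
``M_l`` the spatial position count of layer ``l``.  The per-layer
normalization makes layers of different sizes commensurate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InputError, NumericalFailureError, ParameterError, StructuralError
from .features import Network, _backward, _forward_cache, forward

__all__ = [
    "GramSet",
    "SynthesisOptions",
    "SynthesisResult",
    "gram_matrix",
    "gram_set",
    "synthesis_loss",
    "loss_gradient",
    "synthesize",
    "gram_distance",
    "gradient_check",
]


@dataclass(frozen=True)
class GramSet:
    """Per-gram-layer matrices plus the (N_l, M_l) sizes needed by the loss."""

    grams: tuple[np.ndarray, ...]
    layer_sizes: tuple[tuple[int, int], ...]  # (N_l, M_l) per gram layer
    layer_indices: tuple[int, ...]
    source_id: str | None = None

    def __post_init__(self):
        if len(self.grams) != len(self.layer_sizes):
            raise StructuralError("grams and layer_sizes length mismatch")


@dataclass(frozen=True)
class SynthesisOptions:
    """Knobs of the synthesis optimizer.

    ``layer_weights`` default to uniform 1/L over the L gram layers.
    ``init_image`` is a test hook: when given, it replaces the white-noise
    start (e.g. initializing at the original must terminate immediately
    with zero loss).
    """

    max_iters: int = 500
    tol: float = 1e-6
    init_seed: int = 0
    layer_weights: tuple[float, ...] | None = None
    armijo_c: float = 1e-4
    backtrack_shrink: float = 0.5
    init_step: float = 1.0
    min_step: float = 1e-16
    init_image: np.ndarray | None = None

    def __post_init__(self):
        if self.max_iters < 1:
            raise ParameterError("max_iters must be >= 1")
        if self.layer_weights is not None:
            w = np.asarray(self.layer_weights, dtype=float)
            if (w < 0).any() or not (w > 0).any():
                raise ParameterError("layer_weights must be nonnegative, not all zero")


@dataclass(frozen=True)
class SynthesisResult:
    image: np.ndarray
    loss_trajectory: np.ndarray  # post-projection objective, iteration 0 first
    iterations_run: int
    init_seed: int


def gram_matrix(feature_map: np.ndarray) -> np.ndarray:
    """Raw Gram matrix ``G_ij = sum_k F_ik F_jk`` of an (N, M) feature map.

    A (N, H, W) map is flattened over its spatial axes first.  The result
    is symmetric positive semidefinite by construction.
    """
    F = np.asarray(feature_map, dtype=float)
    if F.ndim >= 3:
        F = F.reshape(F.shape[0], -1)
    if F.ndim != 2 or F.size == 0:
        raise InputError("feature map must be a nonempty (N, M) array")
    if not np.isfinite(F).all():
        raise InputError("feature map contains non-finite values")
    return F @ F.T


def gram_set(network: Network, image, source_id: str | None = None) -> GramSet:
    """Gram matrices of every configured gram layer for one image."""
    stack = forward(network, image)
    grams, sizes, indices = [], [], []
    for gi, (N, M), flat in stack.gram_maps():
        grams.append(flat @ flat.T)
        sizes.append((N, M))
        indices.append(gi)
    return GramSet(tuple(grams), tuple(sizes), tuple(indices), source_id)


def _resolve_weights(n_layers, weights):
    if weights is None:
        return np.full(n_layers, 1.0 / n_layers)
    w = np.asarray(weights, dtype=float)
    if w.shape != (n_layers,):
        raise StructuralError(f"expected {n_layers} layer weights, got shape {w.shape}")
    return w


def _check_structure(a: GramSet, b: GramSet):
    if a.layer_sizes != b.layer_sizes or len(a.grams) != len(b.grams):
        raise StructuralError(
            f"Gram sets have mismatched layer structure: {a.layer_sizes} vs {b.layer_sizes}"
        )


def synthesis_loss(grams: GramSet, target: GramSet, weights=None) -> float:
    """Normalized squared Gram mismatch (see module docstring)."""
    _check_structure(grams, target)
    w = _resolve_weights(len(grams.grams), weights)
    total = 0.0
    for wl, G, A, (N, M) in zip(w, grams.grams, target.grams, grams.layer_sizes):
        if wl == 0.0:
            continue
        total += wl / (4.0 * N * N * M * M) * float(((G - A) ** 2).sum())
    return total


def _loss_and_gradient(network, caches, stack_gram_maps, target, w):
    """Loss plus dL/dpixels given a cached forward pass."""
    loss = 0.0
    grads_by_layer = {}
    for wl, (gi, (N, M), F), A in zip(w, stack_gram_maps, target.grams):
        G = F @ F.T
        diff = G - A
        loss += wl / (4.0 * N * N * M * M) * float((diff**2).sum())
        if wl != 0.0:
            # d/dF of wl/(4 N^2 M^2) * ||F F^T - A||_F^2  =  wl/(N^2 M^2) (G-A) F
            dF = (wl / (N * N * M * M)) * (diff @ F)
            spatial = caches[gi]["pre"].shape if caches[gi]["kind"] == "conv" else None
            if spatial is None:
                # gram layer on a pool output: recover its spatial shape
                spatial = (N,) + tuple(
                    caches[gi]["x_shape"][1 + d] // 2 for d in range(2)
                )
            grads_by_layer[gi] = dF.reshape(spatial)
    return loss, grads_by_layer


def loss_gradient(network: Network, image, target: GramSet, weights=None) -> np.ndarray:
    """Exact gradient of ``synthesis_loss(gram_set(net, x), target)`` wrt pixels."""
    stack, caches = _forward_cache(network, image)
    gm = stack.gram_maps()
    if len(gm) != len(target.grams):
        raise StructuralError("target Gram set does not match network gram layers")
    w = _resolve_weights(len(gm), weights)
    _, grads_by_layer = _loss_and_gradient(network, caches, gm, target, w)
    if not grads_by_layer:
        img = np.asarray(image, dtype=float)
        return np.zeros(img.shape)
    g, _ = _backward(network, caches, grads_by_layer)
    img = np.asarray(image, dtype=float)
    return g.reshape(img.shape)


def _eval_loss(network, image, target, w):
    stack, caches = _forward_cache(network, image)
    loss, _ = _loss_and_gradient(network, caches, stack.gram_maps(), target, w)
    return loss


def synthesize(network: Network, original, opts: SynthesisOptions | None = None) -> SynthesisResult:
    """Synthesize a Gram-matched counterpart of ``original`` from white noise.

    Projected steepest descent with Armijo backtracking: a trial step is
    accepted when the post-projection loss satisfies the sufficient-decrease
    condition ``f(x+) <= f(x) - (c/t) * ||x - x+||^2`` with ``x+ =
    clip(x - t g, 0, 1)``; otherwise the step shrinks.  An accepted step
    doubles the next trial step (warm start).  The recorded trajectory is
    post-projection and non-increasing by construction.
    """
    opts = opts or SynthesisOptions()
    original = np.asarray(original, dtype=float)
    target = gram_set(network, original)
    w = _resolve_weights(len(target.grams), opts.layer_weights)

    if opts.init_image is not None:
        x = np.asarray(opts.init_image, dtype=float).copy()
        if x.shape != original.shape:
            raise InputError("init_image shape must match the original")
    else:
        rng = np.random.default_rng(opts.init_seed)
        x = rng.uniform(0.0, 1.0, size=original.shape)

    f = _eval_loss(network, x, target, w)
    if not np.isfinite(f):
        raise NumericalFailureError("non-finite loss at initialization", iteration=0)
    traj = [f]
    t = opts.init_step
    iters = 0
    for it in range(1, opts.max_iters + 1):
        if f <= opts.tol:
            break
        stack, caches = _forward_cache(network, x)
        _, grads_by_layer = _loss_and_gradient(network, caches, stack.gram_maps(), target, w)
        g, _ = _backward(network, caches, grads_by_layer)
        g = g.reshape(x.shape)
        if not np.isfinite(g).all():
            raise NumericalFailureError("non-finite gradient", iteration=it)
        accepted = False
        while t >= opts.min_step:
            xn = np.clip(x - t * g, 0.0, 1.0)
            fn = _eval_loss(network, xn, target, w)
            if not np.isfinite(fn):
                raise NumericalFailureError("non-finite loss in line search", iteration=it)
            step = x - xn
            if fn <= f - (opts.armijo_c / t) * float((step * step).sum()):
                accepted = True
                break
            t *= opts.backtrack_shrink
        if not accepted:
            break  # no descent step exists at machine precision
        x, f = xn, fn
        traj.append(f)
        iters = it
        t = t * 2.0
    return SynthesisResult(
        image=x,
        loss_trajectory=np.asarray(traj),
        iterations_run=iters,
        init_seed=opts.init_seed,
    )


def gram_distance(a: GramSet, b: GramSet) -> float:
    """Symmetric texture dissimilarity: the synthesis loss at uniform weights."""
    return synthesis_loss(a, b, weights=None)


def gradient_check(network: Network, image, target: GramSet, weights=None,
                   h: float = 1e-3):
    """Compare :func:`loss_gradient` against central finite differences.

    Returns ``(max_rel_error, n_checked, n_skipped)`` where the relative
    error is normalized by the larger of the two gradients' max norms.
    Pixels whose +/-h stencil changes any ReLU active set are skipped: the
    objective has a kink there, so the central difference is not a valid
    derivative estimate (the analytic gradient reports the one-sided
    subgradient).  This mirrors the differentiability requirement of
    standard numerical gradient checkers.
    """
    x = np.asarray(image, dtype=float)
    g = loss_gradient(network, x, target, weights)
    w = _resolve_weights(len(target.grams), weights)

    def active_set(z):
        _, caches = _forward_cache(network, z)
        return [np.signbit(c["pre"]) for c in caches if c["kind"] == "conv"]

    fd = np.zeros_like(x)
    valid = np.ones(x.shape, dtype=bool)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        xp, xm = x.copy(), x.copy()
        xp[idx] += h
        xm[idx] -= h
        sp, sm = active_set(xp), active_set(xm)
        if not all(np.array_equal(a, b) for a, b in zip(sp, sm)):
            valid[idx] = False
            continue
        fd[idx] = (_eval_loss(network, xp, target, w)
                   - _eval_loss(network, xm, target, w)) / (2.0 * h)
    scale = max(np.abs(g[valid]).max(initial=0.0), np.abs(fd[valid]).max(initial=0.0))
    if scale == 0.0:
        return 0.0, int(valid.sum()), int((~valid).sum())
    rel = np.abs(g[valid] - fd[valid]).max() / scale
    return float(rel), int(valid.sum()), int((~valid).sum())
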