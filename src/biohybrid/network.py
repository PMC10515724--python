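"""Feedforward network for specific reaction rates.

The network maps normalized concentrations (element-wise division by the
per-species absolute maximum ``cmax``), optionally augmented with named extra
inputs (e.g. normalized culture volume), to the specific-rate vector ``v``:

    H_0 = c ⊘ cmax  (plus extras)
    H_i = sigma(w_i · H_{i-1} + b_i),   i = 1..nh
    v   = w_{nh+1} · H_nh + b_{nh+1}

Hidden activations are ``tanh`` (shallow/classical configuration) or ``ReLU``
(deep configuration); the output layer is affine and unscaled, so the network
learns rate magnitudes directly. Inverted dropout on hidden nodes is supported
for stochastic regularization during training.

Weight flattening order (used by all weight-space Jacobians/gradients): layer
by layer from the first hidden layer to the output layer, connection matrix in
row-major (C) order followed by the layer's bias vector.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .errors import ContractError
from .mechanistic import SpeciesSet

__all__ = [
    "ExtraInput",
    "NetworkLayout",
    "NetworkWeights",
    "DropoutMask",
    "count_weights",
    "normalize_inputs",
    "forward",
    "forward_with_cache",
    "jacobian_wrt_inputs",
    "jacobian_wrt_weights",
    "init_weights",
    "sample_dropout_mask",
]

_ACTIVATIONS = ("tanh", "relu")


@dataclass(frozen=True)
class ExtraInput:
    """A named non-concentration input with its normalization maximum."""

    name: str
    maximum: float

    def __post_init__(self):
        if not np.isfinite(self.maximum) or self.maximum <= 0:
            raise ContractError(f"extra input {self.name!r} needs a positive maximum")


@dataclass(frozen=True)
class NetworkLayout:
    """Architecture of the rate network.

    ``n_in`` equals the number of concentration inputs plus ``len(extra_inputs)``.
    """

    n_in: int
    hidden: tuple[int, ...]
    n_out: int
    activation: str = "tanh"
    extra_inputs: tuple[ExtraInput, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "hidden", tuple(int(w) for w in self.hidden))
        object.__setattr__(self, "extra_inputs", tuple(self.extra_inputs))
        if self.n_in < 1 or self.n_out < 1:
            raise ContractError("n_in and n_out must be >= 1")
        if any(w < 1 for w in self.hidden):
            raise ContractError("hidden widths must be >= 1")
        if self.activation not in _ACTIVATIONS:
            raise ContractError(f"activation must be one of {_ACTIVATIONS}")
        if len(self.extra_inputs) >= self.n_in:
            raise ContractError("extra inputs must leave room for concentration inputs")

    @property
    def n_conc_in(self) -> int:
        return self.n_in - len(self.extra_inputs)

    @property
    def layer_sizes(self) -> tuple[int, ...]:
        return (self.n_in, *self.hidden, self.n_out)


@dataclass
class NetworkWeights:
    """Per-layer connection matrices ``w`` and bias vectors ``b``."""

    w: list[np.ndarray]
    b: list[np.ndarray]

    def validate(self, layout: NetworkLayout) -> None:
        sizes = layout.layer_sizes
        if len(self.w) != len(sizes) - 1 or len(self.b) != len(sizes) - 1:
            raise ContractError("weight list length does not match layout")
        for i, (wi, bi) in enumerate(zip(self.w, self.b)):
            if wi.shape != (sizes[i + 1], sizes[i]) or bi.shape != (sizes[i + 1],):
                raise ContractError(f"layer {i + 1} weight shapes inconsistent with layout")
            if not (np.all(np.isfinite(wi)) and np.all(np.isfinite(bi))):
                raise ContractError(f"layer {i + 1} weights are not finite")

    def flatten(self) -> np.ndarray:
        parts = []
        for wi, bi in zip(self.w, self.b):
            parts.append(wi.ravel(order="C"))
            parts.append(bi)
        return np.concatenate(parts)

    @classmethod
    def unflatten(cls, layout: NetworkLayout, theta: np.ndarray) -> "NetworkWeights":
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (count_weights(layout),):
            raise ContractError(
                f"flat vector length {theta.size} != {count_weights(layout)}"
            )
        sizes = layout.layer_sizes
        w, b, pos = [], [], 0
        for i in range(len(sizes) - 1):
            n_out, n_prev = sizes[i + 1], sizes[i]
            w.append(theta[pos : pos + n_out * n_prev].reshape(n_out, n_prev).copy())
            pos += n_out * n_prev
            b.append(theta[pos : pos + n_out].copy())
            pos += n_out
        return cls(w, b)

    def copy(self) -> "NetworkWeights":
        return NetworkWeights([wi.copy() for wi in self.w], [bi.copy() for bi in self.b])


@dataclass(frozen=True)
class DropoutMask:
    """Per-hidden-layer binary keep vectors with the keep probability."""

    keep: tuple[np.ndarray, ...]
    p_keep: float

    def __post_init__(self):
        if not (0.0 < self.p_keep <= 1.0):
            raise ContractError("p_keep must be in (0, 1]")
        for m in self.keep:
            if not np.all(np.isin(m, (0.0, 1.0))):
                raise ContractError("mask entries must be 0 or 1")

    def validate(self, layout: NetworkLayout) -> None:
        if len(self.keep) != len(layout.hidden):
            raise ContractError("one keep vector per hidden layer required")
        for m, width in zip(self.keep, layout.hidden):
            if m.shape != (width,):
                raise ContractError("mask length must match hidden width")


def count_weights(layout: NetworkLayout) -> int:
    """Total trainable parameters: sum over layers of (n_prev + 1) * n."""
    sizes = layout.layer_sizes
    return int(sum((sizes[i] + 1) * sizes[i + 1] for i in range(len(sizes) - 1)))


def normalize_inputs(
    c: np.ndarray,
    species: SpeciesSet,
    layout: NetworkLayout,
    extras: Mapping[str, float] | None = None,
) -> np.ndarray:
    """Assemble the network input H0 = c ⊘ cmax plus normalized extras.

    ``c`` is clamped at >= 0 before normalization; each extra input is divided
    by its own declared maximum and appended in layout order.
    """
    c = np.asarray(c, dtype=float)
    if c.shape != (species.n,):
        raise ContractError("concentration vector does not match species roster")
    if species.n != layout.n_conc_in:
        raise ContractError(
            f"layout expects {layout.n_conc_in} concentration inputs, roster has {species.n}"
        )
    h0 = np.empty(layout.n_in)
    h0[: species.n] = np.maximum(c, 0.0) / species.cmax
    extras = extras or {}
    for j, xi in enumerate(layout.extra_inputs):
        if xi.name not in extras:
            raise ContractError(f"missing extra input {xi.name!r}")
        h0[species.n + j] = extras[xi.name] / xi.maximum
    return h0


def _act(z: np.ndarray, kind: str) -> np.ndarray:
    return np.tanh(z) if kind == "tanh" else np.maximum(z, 0.0)


def _act_deriv(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "tanh":
        t = np.tanh(z)
        return 1.0 - t * t
    return (z > 0).astype(float)  # ReLU subgradient at 0 is 0


def forward_with_cache(
    layout: NetworkLayout,
    weights: NetworkWeights,
    h0: np.ndarray,
    mask: DropoutMask | None = None,
) -> tuple[np.ndarray, list[np.ndarray], list[np.ndarray]]:
    """Forward pass returning (v, layer activations H_0..H_nh, pre-activations)."""
    h0 = np.asarray(h0, dtype=float)
    if h0.shape != (layout.n_in,):
        raise ContractError(f"H0 shape {h0.shape} != ({layout.n_in},)")
    if mask is not None:
        mask.validate(layout)
    acts = [h0]
    zs: list[np.ndarray] = []
    h = h0
    for i, width in enumerate(layout.hidden):
        z = weights.w[i] @ h + weights.b[i]
        zs.append(z)
        h = _act(z, layout.activation)
        if mask is not None:
            h = h * mask.keep[i] / mask.p_keep  # inverted dropout
        acts.append(h)
    v = weights.w[-1] @ h + weights.b[-1]
    return v, acts, zs


def forward(
    layout: NetworkLayout,
    weights: NetworkWeights,
    h0: np.ndarray,
    mask: DropoutMask | None = None,
) -> np.ndarray:
    """Specific-rate vector v for input H0 (output layer is affine)."""
    return forward_with_cache(layout, weights, h0, mask)[0]


def jacobian_wrt_inputs(
    layout: NetworkLayout,
    weights: NetworkWeights,
    h0: np.ndarray,
    mask: DropoutMask | None = None,
) -> np.ndarray:
    """∂v/∂H0 by the chain rule; shape (n_out, n_in)."""
    _, _, zs = forward_with_cache(layout, weights, h0, mask)
    jac = weights.w[-1].copy()
    for i in range(len(layout.hidden) - 1, -1, -1):
        d = _act_deriv(zs[i], layout.activation)
        if mask is not None:
            d = d * mask.keep[i] / mask.p_keep
        jac = (jac * d) @ weights.w[i]
    return jac


def jacobian_wrt_weights(
    layout: NetworkLayout,
    weights: NetworkWeights,
    h0: np.ndarray,
    mask: DropoutMask | None = None,
) -> np.ndarray:
    """∂v/∂(w, b) over the documented flattening order; shape (n_out, nw).

    Columns follow :meth:`NetworkWeights.flatten`: per layer, connections
    row-major then biases. The output-bias block is the identity.
    """
    v, acts, zs = forward_with_cache(layout, weights, h0, mask)
    n_out = layout.n_out
    nh = len(layout.hidden)
    # delta[l] = dv/dz_{l+1} (n_out x width of layer l+1), layers indexed 0..nh
    deltas: list[np.ndarray] = [None] * (nh + 1)
    deltas[nh] = np.eye(n_out)  # output layer is affine: dv/dz_out = I
    back = weights.w[-1]
    for i in range(nh - 1, -1, -1):
        d = _act_deriv(zs[i], layout.activation)
        if mask is not None:
            d = d * mask.keep[i] / mask.p_keep
        deltas[i] = back * d
        back = deltas[i] @ weights.w[i]
    blocks = []
    for l in range(nh + 1):
        delta = deltas[l]  # n_out x n_l
        h_prev = acts[l]  # n_{l-1}
        blocks.append(np.einsum("oj,k->ojk", delta, h_prev).reshape(n_out, -1))
        blocks.append(delta)
    return np.concatenate(blocks, axis=1)


def init_weights(layout: NetworkLayout, rng_seed: int | np.random.Generator) -> NetworkWeights:
    """Uniform(-0.01, 0.01) initialization of every connection and bias weight."""
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    sizes = layout.layer_sizes
    w = [rng.uniform(-0.01, 0.01, size=(sizes[i + 1], sizes[i])) for i in range(len(sizes) - 1)]
    b = [rng.uniform(-0.01, 0.01, size=sizes[i + 1]) for i in range(len(sizes) - 1)]
    return NetworkWeights(w, b)


def sample_dropout_mask(
    layout: NetworkLayout, p_drop: float, rng: np.random.Generator
) -> DropoutMask:
    """Independent Bernoulli(1 - p_drop) keep mask per hidden node."""
    if not (0.0 <= p_drop < 1.0):
        raise ContractError("p_drop must be in [0, 1) — dropping all nodes is degenerate")
    keep = tuple(
        (rng.random(width) >= p_drop).astype(float) for width in layout.hidden
    )
    return DropoutMask(keep, 1.0 - p_drop)
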