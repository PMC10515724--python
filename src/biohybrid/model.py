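"""The trainable hybrid model: balances + rate network + normalization."""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .errors import ContractError
from .mechanistic import (
    FeedStream,
    ProcessState,
    SpeciesSet,
    Trajectory,
    integrate_rk4,
)
from .network import (
    DropoutMask,
    ExtraInput,
    NetworkLayout,
    NetworkWeights,
    count_weights,
    forward,
    init_weights,
    normalize_inputs,
)

__all__ = ["HybridModel", "make_layout"]

#: reserved extra-input name for normalized culture volume
VOLUME_INPUT = "volume"


def make_layout(
    species: SpeciesSet,
    hidden: Sequence[int],
    activation: str,
    volume_input: float | None = None,
) -> NetworkLayout:
    """Layout with one input per species (plus optionally normalized volume)
    and one output per species."""
    extras = ()
    if volume_input is not None:
        extras = (ExtraInput(VOLUME_INPUT, float(volume_input)),)
    return NetworkLayout(
        n_in=species.n + len(extras),
        hidden=tuple(hidden),
        n_out=species.n,
        activation=activation,
        extra_inputs=extras,
    )


@dataclass
class HybridModel:
    """Network layout + weights + species roster, with simulation helpers.

    The network input is the clamped, cmax-normalized concentration vector,
    optionally followed by V/Vmax when the layout declares a ``volume`` extra
    input; the network output is the specific-rate vector (one per species).
    """

    species: SpeciesSet
    layout: NetworkLayout
    weights: NetworkWeights
    substep: float = 0.5

    def __post_init__(self):
        if self.layout.n_conc_in != self.species.n:
            raise ContractError("layout concentration inputs must match roster size")
        if self.layout.n_out != self.species.n:
            raise ContractError("layout must emit one rate per species")
        for xi in self.layout.extra_inputs:
            if xi.name != VOLUME_INPUT:
                raise ContractError(f"unsupported extra input {xi.name!r}")
        self.weights.validate(self.layout)

    @property
    def n_weights(self) -> int:
        return count_weights(self.layout)

    @classmethod
    def initialized(
        cls,
        species: SpeciesSet,
        hidden: Sequence[int],
        activation: str,
        seed: int | np.random.Generator,
        volume_input: float | None = None,
        substep: float = 0.5,
    ) -> "HybridModel":
        layout = make_layout(species, hidden, activation, volume_input)
        return cls(species, layout, init_weights(layout, seed), substep)

    def network_input(self, c: np.ndarray, V: float) -> np.ndarray:
        extras = {}
        if self.layout.extra_inputs:
            extras[VOLUME_INPUT] = float(V)
        return normalize_inputs(c, self.species, self.layout, extras)

    def rates(
        self, t: float, c: np.ndarray, V: float, mask: DropoutMask | None = None
    ) -> np.ndarray:
        return forward(self.layout, self.weights, self.network_input(c, V), mask)

    def with_weights(self, weights: NetworkWeights | np.ndarray) -> "HybridModel":
        if isinstance(weights, np.ndarray):
            weights = NetworkWeights.unflatten(self.layout, weights)
        return replace(self, weights=weights)

    def simulate(
        self,
        initial: ProcessState,
        streams: Sequence[FeedStream],
        output_times: np.ndarray,
        substep: float | None = None,
        mask: DropoutMask | None = None,
    ) -> Trajectory:
        """Integrate the full hybrid model with fixed-step RK4."""
        return integrate_rk4(
            lambda t, c, V: self.rates(t, c, V, mask),
            self.species,
            initial,
            streams,
            output_times,
            substep if substep is not None else self.substep,
        )
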