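"""In-memory containers for multi-experiment fed-batch datasets."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import ContractError
from .mechanistic import FeedStream, ProcessState, SpeciesSet

__all__ = ["Experiment", "ExperimentDataset"]


@dataclass
class Experiment:
    """One reactor run: initial state, feeds, and the measured time series.

    ``values`` and ``sigmas`` have shape (n_times, n_species); NaN in
    ``values`` marks a missing measurement, which is excluded from every
    residual count T.
    """

    id: str
    times: np.ndarray
    values: np.ndarray
    sigmas: np.ndarray
    c0: np.ndarray
    v0: float
    streams: tuple[FeedStream, ...]

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.sigmas = np.asarray(self.sigmas, dtype=float)
        self.c0 = np.asarray(self.c0, dtype=float)
        self.streams = tuple(self.streams)
        if np.any(np.diff(self.times) <= 0):
            raise ContractError(f"experiment {self.id}: times must be strictly increasing")
        if self.values.shape != (self.times.size, self.c0.size):
            raise ContractError(f"experiment {self.id}: values shape mismatch")
        if self.sigmas.shape != self.values.shape:
            raise ContractError(f"experiment {self.id}: sigma table must mirror values")
        measured = ~np.isnan(self.values)
        if np.any(measured & ~(self.sigmas > 0)):
            raise ContractError(
                f"experiment {self.id}: every measured point needs a positive sigma"
            )

    @property
    def measured(self) -> np.ndarray:
        return ~np.isnan(self.values)

    @property
    def n_residuals(self) -> int:
        """Number of scalar residuals this experiment contributes to T."""
        return int(self.measured.sum())

    def initial_state(self) -> ProcessState:
        return ProcessState(self.c0.copy(), self.v0, float(self.times[0]))


@dataclass
class ExperimentDataset:
    """A set of experiments over one species roster."""

    species: SpeciesSet
    experiments: list[Experiment]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = [e.id for e in self.experiments]
        if len(set(ids)) != len(ids):
            raise ContractError("experiment ids must be unique")
        for e in self.experiments:
            if e.c0.size != self.species.n:
                raise ContractError(f"experiment {e.id}: species count mismatch")

    @property
    def ids(self) -> list[str]:
        return [e.id for e in self.experiments]

    @property
    def n_residuals(self) -> int:
        return sum(e.n_residuals for e in self.experiments)

    def experiment(self, exp_id: str) -> Experiment:
        for e in self.experiments:
            if e.id == exp_id:
                return e
        raise ContractError(f"unknown experiment id {exp_id!r}")

    def subset(self, ids: Sequence[str]) -> "ExperimentDataset":
        return ExperimentDataset(
            self.species,
            [self.experiment(i) for i in ids],
            dict(self.provenance, subset=list(ids)),
        )

    def with_values(self, new_values: list[np.ndarray]) -> "ExperimentDataset":
        """Copy with replaced measurement tables (times/feeds/sigmas kept)."""
        if len(new_values) != len(self.experiments):
            raise ContractError("one value table per experiment required")
        exps = [
            replace(e, values=np.asarray(v, dtype=float))
            for e, v in zip(self.experiments, new_values)
        ]
        return ExperimentDataset(self.species, exps, dict(self.provenance))
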