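"""Error metrics, information criteria, resampling and structure comparison.

The weighted mean squared error

    WMSE = (1/T) * sum_t ((c*_t - c_t)/sigma_t)^2

is ~1 when a model fits measured data to the noise floor of a correctly
specified error model (chi-square concentration). Structures are ranked by
the corrected Akaike criterion

    AICc = T ln(WMSE) + 2 nw + 2 nw (nw + 1)/(T - nw - 1)

computed on the training subset, and by resampling: repeated training over
random train/test partitions of whole reactor experiments, with the chosen
structure the one with minimum mean test WMSE.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data import ExperimentDataset
from .errors import ContractError, DivergenceError, DomainError, TrainingError
from .gradients import wmse_objective
from .mechanistic import SpeciesSet
from .model import HybridModel

__all__ = [
    "ErrorModel",
    "PartitionPlan",
    "StructureStats",
    "SelectionReport",
    "wmse",
    "aicc",
    "resample_partitions",
    "evaluate_structure",
    "compare_structures",
]


@dataclass(frozen=True)
class ErrorModel:
    """Per-species measurement-SD rule.

    Two styles are supported:

    * ``relative`` — SD is a fraction of the measured value (the
      experimental-style rule: 5% for product, 10% for viable cells, 20% for
      the remaining metabolites), floored at ``floor_fraction * cmax`` so
      sigma never vanishes at zero concentration.
    * ``absolute_max`` — SD is a fraction of the species' absolute maximum
      concentration (the synthetic-style rule, default fraction 0.10).
    """

    kind: str
    fractions: dict = field(default_factory=dict)
    default_fraction: float = 0.20
    floor_fraction: float = 0.02

    def __post_init__(self):
        if self.kind not in ("relative", "absolute_max"):
            raise ContractError("kind must be 'relative' or 'absolute_max'")
        if self.default_fraction < 0 or self.floor_fraction < 0:
            raise ContractError("fractions must be >= 0")

    @classmethod
    def relative(
        cls,
        fractions: dict | None = None,
        default_fraction: float = 0.20,
        floor_fraction: float = 0.02,
    ) -> "ErrorModel":
        return cls("relative", dict(fractions or {}), default_fraction, floor_fraction)

    @classmethod
    def from_max(cls, fraction: float = 0.10, floor_fraction: float = 1e-6) -> "ErrorModel":
        return cls("absolute_max", {}, fraction, floor_fraction)

    def species_fraction(self, name: str) -> float:
        return float(self.fractions.get(name, self.default_fraction))

    def sigmas(self, values: np.ndarray, species: SpeciesSet) -> np.ndarray:
        """Per-point SD table for a (n_times, n_species) value table."""
        values = np.asarray(values, dtype=float)
        if values.ndim != 2 or values.shape[1] != species.n:
            raise ContractError("values must be (n_times, n_species)")
        frac = np.array([self.species_fraction(nm) for nm in species.names])
        floor = self.floor_fraction * species.cmax
        if self.kind == "relative":
            sig = np.abs(values) * frac[None, :]
        else:
            sig = np.broadcast_to(frac * species.cmax, values.shape).copy()
        sig = np.maximum(sig, floor[None, :])
        if not np.all(sig[~np.isnan(values)] > 0):
            raise ContractError("error model produced non-positive sigma")
        return sig


def wmse(predicted: np.ndarray, measured: np.ndarray, sigmas: np.ndarray) -> float:
    """Mean of squared residuals normalized by the measurement variance.

    NaN entries of ``measured`` (missing points) are excluded from T.
    """
    predicted = np.asarray(predicted, dtype=float)
    measured = np.asarray(measured, dtype=float)
    sigmas = np.asarray(sigmas, dtype=float)
    if predicted.shape != measured.shape or sigmas.shape != measured.shape:
        raise ContractError("predicted, measured and sigmas must be aligned")
    mask = ~np.isnan(measured)
    if not mask.any():
        raise ContractError("no measured residuals")
    if np.any(sigmas[mask] <= 0):
        raise ContractError("sigmas must be > 0")
    r = (measured[mask] - predicted[mask]) / sigmas[mask]
    return float(np.mean(r * r))


def aicc(wmse_train: float, T: int, nw: int) -> float:
    """Corrected Akaike criterion: T ln(WMSE) + 2 nw + 2 nw (nw+1)/(T-nw-1)."""
    if wmse_train <= 0:
        raise DomainError("AICc needs WMSE > 0")
    if T <= nw + 1:
        raise DomainError(f"AICc correction undefined for T={T} <= nw+1={nw + 1}")
    return float(T * math.log(wmse_train) + 2 * nw + 2 * nw * (nw + 1) / (T - nw - 1))


@dataclass(frozen=True)
class PartitionPlan:
    """Batch-wise train/test partitions shared across structures."""

    pairs: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...]
    seed: int

    def __post_init__(self):
        for train, test in self.pairs:
            if set(train) & set(test):
                raise ContractError("train and test experiments must be disjoint")

    def __len__(self) -> int:
        return len(self.pairs)


def resample_partitions(
    experiment_ids: Sequence[str],
    n_partitions: int,
    n_test: int,
    seed: int,
) -> PartitionPlan:
    """Uniform random draws of ``n_test`` test experiments per partition.

    The same plan is intended to be reused across structures so the resampling
    comparison is paired.
    """
    ids = list(experiment_ids)
    if n_test >= len(ids) or n_test < 1:
        raise ContractError("need 1 <= n_test < number of experiments")
    rng = np.random.default_rng(seed)
    pairs = []
    for _ in range(n_partitions):
        test_idx = rng.choice(len(ids), size=n_test, replace=False)
        test = tuple(ids[i] for i in sorted(test_idx))
        train = tuple(i for i in ids if i not in test)
        pairs.append((train, test))
    return PartitionPlan(tuple(pairs), seed)


@dataclass
class StructureStats:
    """Per-structure selection statistics over a partition plan."""

    label: str
    hidden: tuple[int, ...]
    activation: str
    n_weights: int
    train_wmse: list = field(default_factory=list)
    test_wmse: list = field(default_factory=list)
    test_wmse_noise_free: list = field(default_factory=list)
    aicc_values: list = field(default_factory=list)
    n_unstable: int = 0
    chosen: bool = False
    cpu_seconds: float = 0.0

    @staticmethod
    def _ms(vals) -> tuple[float, float]:
        arr = np.asarray([v for v in vals if np.isfinite(v)], dtype=float)
        if arr.size == 0:
            return (math.nan, math.nan)
        return float(arr.mean()), float(arr.std(ddof=1)) if arr.size > 1 else 0.0

    @property
    def train_mean(self) -> float:
        return self._ms(self.train_wmse)[0]

    @property
    def test_mean(self) -> float:
        return self._ms(self.test_wmse)[0]

    @property
    def stable(self) -> bool:
        return len(self.train_wmse) > 0

    def row(self) -> dict:
        tr = self._ms(self.train_wmse)
        te = self._ms(self.test_wmse)
        nf = self._ms(self.test_wmse_noise_free)
        ai = self._ms(self.aicc_values)
        return {
            "structure": self.label,
            "train_wmse_mean": tr[0],
            "train_wmse_sd": tr[1],
            "test_wmse_mean": te[0],
            "test_wmse_sd": te[1],
            "test_wmse_noise_free_mean": nf[0],
            "aicc_mean": ai[0],
            "aicc_sd": ai[1],
            "n_weights": self.n_weights,
            "n_unstable": self.n_unstable,
            "cpu_seconds": round(self.cpu_seconds, 2),
            "chosen": self.chosen,
        }


@dataclass
class SelectionReport:
    """Structure sweep summary; the chosen flag marks min mean test WMSE."""

    structures: list
    plan: PartitionPlan

    def finalize(self) -> "SelectionReport":
        stable = [s for s in self.structures if s.stable and np.isfinite(s.test_mean)]
        if stable:
            best = min(stable, key=lambda s: s.test_mean)
            for s in self.structures:
                s.chosen = s is best
        return self

    @property
    def chosen(self) -> StructureStats:
        for s in self.structures:
            if s.chosen:
                return s
        raise ContractError("report not finalized or no stable structure")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([s.row() for s in self.structures])


def _baseline_wmse(dataset: ExperimentDataset) -> float:
    """WMSE of per-species constant (mean) predictions — instability yardstick."""
    num = 0.0
    T = 0
    means = {}
    for si in range(dataset.species.n):
        vals = np.concatenate([e.values[:, si] for e in dataset.experiments])
        vals = vals[~np.isnan(vals)]
        means[si] = vals.mean() if vals.size else 0.0
    for e in dataset.experiments:
        for si in range(dataset.species.n):
            col, sig = e.values[:, si], e.sigmas[:, si]
            m = ~np.isnan(col)
            num += float(np.sum(((col[m] - means[si]) / sig[m]) ** 2))
            T += int(m.sum())
    return num / max(T, 1)


def evaluate_structure(
    dataset: ExperimentDataset,
    hidden: Sequence[int],
    activation: str,
    trainer_config,
    plan: PartitionPlan,
    volume_input: float | None = None,
    substep: float = 0.5,
    noise_free_test: ExperimentDataset | None = None,
    unstable_factor: float = 10.0,
) -> StructureStats:
    """Train one structure on every partition of the plan and collect stats.

    ``trainer_config`` selects the regime by type (:class:`AdamConfig` or
    :class:`LmmConfig`); the per-partition seed is derived from the config
    seed so different structures see identical partition/seed pairs. A
    partition is recorded as unstable when training diverges or its final
    train WMSE exceeds ``unstable_factor`` times the constant-prediction
    baseline.
    """
    from .model import HybridModel
    from .training import AdamConfig, LmmConfig, train_adam, train_lmm

    layout_probe = HybridModel.initialized(
        dataset.species, hidden, activation, seed=0, volume_input=volume_input,
        substep=substep,
    )
    stats = StructureStats(
        label="x".join(str(w) for w in hidden) or "linear",
        hidden=tuple(hidden),
        activation=activation,
        n_weights=layout_probe.n_weights,
    )
    baseline = _baseline_wmse(dataset)

    import dataclasses
    import time

    for p_idx, (train_ids, test_ids) in enumerate(plan.pairs):
        train_sub = dataset.subset(train_ids)
        test_sub = dataset.subset(test_ids)
        cfg = dataclasses.replace(trainer_config, seed=trainer_config.seed + 1000 * p_idx)
        model = HybridModel.initialized(
            dataset.species, hidden, activation, seed=cfg.seed,
            volume_input=volume_input, substep=substep,
        )
        t_start = time.process_time()
        try:
            if isinstance(cfg, AdamConfig):
                run = train_adam(model, train_sub, cfg, substep=substep)
            elif isinstance(cfg, LmmConfig):
                run = train_lmm(model, train_sub, cfg, substep=substep)
            else:
                raise ContractError(f"unknown trainer config {type(cfg)!r}")
            stats.cpu_seconds += time.process_time() - t_start
            fitted = model.with_weights(run.kept_weights)
            train_w, _, T_train = wmse_objective(fitted, train_sub, substep)
            test_w, _, _ = wmse_objective(fitted, test_sub, substep)
        except (DivergenceError, TrainingError):
            stats.cpu_seconds += time.process_time() - t_start
            stats.n_unstable += 1
            continue
        if not np.isfinite(train_w) or train_w > unstable_factor * baseline:
            stats.n_unstable += 1
            continue
        stats.train_wmse.append(train_w)
        stats.test_wmse.append(test_w)
        if noise_free_test is not None:
            nf_sub = noise_free_test.subset(test_ids)
            nf_w, _, _ = wmse_objective(fitted, nf_sub, substep)
            stats.test_wmse_noise_free.append(nf_w)
        try:
            stats.aicc_values.append(aicc(train_w, T_train, stats.n_weights))
        except DomainError:
            stats.aicc_values.append(math.nan)
    return stats


def compare_structures(a: dict | StructureStats, b: dict | StructureStats) -> dict:
    """Percentage differences between two structure summaries.

    Reductions are relative to ``a`` (100·(a−b)/a); increases are reported
    both relative to ``a`` (weights) and relative to ``b`` (by how much
    ``a``'s error exceeds ``b``'s). Values are returned unrounded; display
    rounds to one decimal.
    """

    def get(s, key):
        if isinstance(s, StructureStats):
            row = s.row()
            return row.get(key, math.nan)
        return s.get(key, math.nan)

    out = {}
    for key, name in (
        ("train_wmse_mean", "train"),
        ("test_wmse_mean", "test"),
        ("test_wmse_noise_free_mean", "test_noise_free"),
    ):
        va, vb = get(a, key), get(b, key)
        if np.isfinite(va) and np.isfinite(vb) and va != 0 and vb != 0:
            out[f"{name}_reduction_pct"] = 100.0 * (va - vb) / va
            out[f"{name}_increase_of_a_over_b_pct"] = 100.0 * (va - vb) / vb
    wa, wb = get(a, "n_weights"), get(b, "n_weights")
    if np.isfinite(wa) and np.isfinite(wb) and wa:
        out["weights_increase_pct"] = 100.0 * (wb - wa) / wa
    return out
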