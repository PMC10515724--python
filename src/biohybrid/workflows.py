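"""Reduced-scale study workflows: noise-floor recovery and structure sweeps.

These bundle the full pipeline (generate -> split -> train -> evaluate) at
problem sizes a single CPU handles in minutes, preserving the qualitative
comparisons of interest: denoising (noise-free test error below noisy test
error), the chi-square noise floor of the generating model, and shallow vs
deep structure selection by resampled test error.
"""

from __future__ import annotations

from dataclasses import dataclass

from .gradients import wmse_objective
from .model import HybridModel
from .selection import SelectionReport, evaluate_structure, resample_partitions
from .synthetic import cc_doe_split, ground_truth_wmse, make_cc_doe_dataset
from .training import AdamConfig, LmmConfig, train_adam

__all__ = ["NoiseFloorResult", "noise_floor_study", "structure_sweep_study"]

#: substep (h) used for reduced-scale training; evaluation uses 0.5 h
TRAIN_SUBSTEP = 4.0
EVAL_SUBSTEP = 0.5


@dataclass
class NoiseFloorResult:
    """Outcome of the reduced-scale denoising study."""

    train_wmse: float
    test_wmse_noisy: float
    test_wmse_noise_free: float
    ground_truth_noisy_wmse: float
    n_train_residuals: int
    n_test_residuals: int
    kept_iteration: int


def noise_floor_study(
    seed: int = 1,
    hidden: tuple[int, ...] = (10, 10),
    activation: str = "tanh",
    iterations: int = 1000,
    alpha: float = 0.005,
) -> NoiseFloorResult:
    """Train a hybrid model on the 5 center+square CC-DoE runs, test on the 4
    star runs, and compare against the generating model's noise floor.

    The expected pattern: the generating model's noisy WMSE sits near 1
    (chi-square mean); the trained model's noise-free test WMSE falls below
    its noisy test WMSE because the weighted objective filters the
    heterogeneous Gaussian error rather than fitting it.

    tanh hidden nodes are used at this reduced iteration budget: with the
    tiny uniform(-0.01, 0.01) initialization, ReLU nets spend most of a short
    budget escaping inactive-unit plateaus (zero subgradient), which is a
    budget artifact rather than a property of the method.
    """
    noisy, clean, _truth = make_cc_doe_dataset(seed=seed)
    train_ids, test_ids = cc_doe_split(noisy)
    train = noisy.subset(train_ids)
    test = noisy.subset(test_ids)
    # noise-free targets under the same sigma weighting as the noisy test
    test_nf = test.with_values([
        clean.experiment(i).values.copy() for i in test_ids
    ])

    vmax = noisy.provenance["volume_max"]
    model = HybridModel.initialized(
        noisy.species, hidden, activation, seed=seed,
        volume_input=vmax, substep=TRAIN_SUBSTEP,
    )
    cfg = AdamConfig(alpha=alpha, iterations=iterations, seed=seed)
    run = train_adam(model, train, cfg, substep=TRAIN_SUBSTEP)
    fitted = model.with_weights(run.kept_weights)

    w_train, _, T_train = wmse_objective(fitted, train, substep=EVAL_SUBSTEP)
    w_noisy, _, T_test = wmse_objective(fitted, test, substep=EVAL_SUBSTEP)
    w_nf, _, _ = wmse_objective(fitted, test_nf, substep=EVAL_SUBSTEP)
    gt = ground_truth_wmse(noisy, substep=EVAL_SUBSTEP)
    return NoiseFloorResult(
        train_wmse=w_train,
        test_wmse_noisy=w_noisy,
        test_wmse_noise_free=w_nf,
        ground_truth_noisy_wmse=gt,
        n_train_residuals=T_train,
        n_test_residuals=T_test,
        kept_iteration=run.kept_iteration,
    )


def structure_sweep_study(
    seed: int = 1,
    structures: tuple[tuple[tuple[int, ...], str], ...] = (
        ((12,), "tanh"),
        ((7, 7), "relu"),
        ((10, 10), "relu"),
    ),
    trainer: str = "adam",
    n_partitions: int = 2,
    n_test: int = 4,
    adam_iterations: int = 100,
    lmm_iterations: int = 15,
) -> SelectionReport:
    """Scaled-down structure sweep over resampled partitions of the 9 CC-DoE
    runs; returns the finalized report with the minimum-mean-test-WMSE
    structure flagged. The same partition plan is reused for every structure
    so the comparison is paired.
    """
    noisy, clean, _truth = make_cc_doe_dataset(seed=seed)
    plan = resample_partitions(noisy.ids, n_partitions, n_test, seed)
    vmax = noisy.provenance["volume_max"]
    if trainer == "adam":
        cfg = AdamConfig(alpha=0.005, iterations=adam_iterations, seed=seed)
    else:
        cfg = LmmConfig(max_iterations=lmm_iterations, restarts=2, patience=10, seed=seed)
    stats = [
        evaluate_structure(
            noisy, hidden, activation, cfg, plan,
            volume_input=vmax, substep=TRAIN_SUBSTEP,
            noise_free_test=clean,
        )
        for hidden, activation in structures
    ]
    return SelectionReport(stats, plan).finalize()
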