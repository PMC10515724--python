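"""The two training regimes for hybrid models.

``train_lmm`` is the classical scheme: damped Gauss-Newton (Levenberg-
Marquardt) steps on the weighted residual vector, gradients/Jacobians from the
indirect sensitivity equations, early stopping on a noise-augmented
validation copy of the training data, and multiple random restarts keeping
the best run.

``train_adam`` is the deep scheme: ADAM stochastic gradient steps with
semidirect sensitivity gradients and stochastic regularization (per-iteration
experiment minibatches and one dropout mask held fixed across the whole
gradient evaluation), run once from a single random initialization, keeping
the weights at the iteration with minimum full-batch maskless training WMSE.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .data import ExperimentDataset
from .errors import ContractError, DivergenceError, TrainingError
from .gradients import residual_jacobian, semidirect_gradient, wmse_objective
from .model import HybridModel
from .network import NetworkWeights, init_weights, sample_dropout_mask

__all__ = [
    "AdamConfig",
    "LmmConfig",
    "TrainingRun",
    "make_validation_set",
    "adam_update",
    "train_adam",
    "train_lmm",
    "damped_gauss_newton",
]


@dataclass(frozen=True)
class AdamConfig:
    """Hyperparameters of the deep training regime.

    Defaults follow the standard ADAM setting (step size 0.001, moment decays
    0.9/0.999, denominator offset 1e-7) with stochastic regularization at
    minibatch fraction 0.8 and dropout probability 0.2.
    """

    alpha: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    eta: float = 1e-7
    iterations: int = 1000
    minibatch_fraction: float = 0.8
    dropout_p: float = 0.2
    seed: int = 0
    max_consecutive_skips: int = 10

    def __post_init__(self):
        if not (0.0 < self.beta1 < 1.0 and 0.0 < self.beta2 < 1.0):
            raise ContractError("beta1 and beta2 must lie in (0, 1)")
        if self.alpha <= 0 or self.eta <= 0:
            raise ContractError("alpha and eta must be > 0")
        if not (0.0 < self.minibatch_fraction <= 1.0):
            raise ContractError("minibatch_fraction must be in (0, 1]")
        if not (0.0 <= self.dropout_p < 1.0):
            raise ContractError("dropout_p must be in [0, 1)")
        if self.iterations < 1:
            raise ContractError("iterations must be >= 1")


@dataclass(frozen=True)
class LmmConfig:
    """Hyperparameters of the classical training regime."""

    max_iterations: int = 1000
    restarts: int = 10
    lambda0: float = 1e-3
    lambda_up: float = 10.0
    lambda_down: float = 10.0
    patience: int = 25
    seed: int = 0
    ftol: float = 1e-12

    def __post_init__(self):
        if self.restarts < 1:
            raise ContractError("restarts must be >= 1")
        if self.lambda0 <= 0 or self.lambda_up <= 1 or self.lambda_down <= 1:
            raise ContractError("damping parameters must be positive (factors > 1)")
        if self.patience < 1 or self.max_iterations < 1:
            raise ContractError("patience and max_iterations must be >= 1")


@dataclass
class TrainingRun:
    """Optimizer trace plus the kept weights of one training event."""

    trainer: str
    train_wmse: np.ndarray
    val_wmse: np.ndarray | None
    kept_weights: NetworkWeights
    kept_iteration: int
    seed: int
    config: AdamConfig | LmmConfig
    info: dict = field(default_factory=dict)

    @property
    def kept_train_wmse(self) -> float:
        return float(self.train_wmse[self.kept_iteration])

    def to_dataframe(self) -> pd.DataFrame:
        d = {"iteration": np.arange(len(self.train_wmse)), "train_wmse": self.train_wmse}
        if self.val_wmse is not None:
            d["val_wmse"] = self.val_wmse
        return pd.DataFrame(d)


def make_validation_set(
    dataset: ExperimentDataset, rng: np.random.Generator | int
) -> ExperimentDataset:
    """Noise-augmented copy of a training subset for early stopping.

    Every measured value gets independent Gaussian noise with the same SD as
    its recorded measurement error; times, feeds and initial states are kept.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    new_values = []
    for exp in dataset.experiments:
        noise = rng.normal(0.0, 1.0, size=exp.values.shape) * exp.sigmas
        vals = np.where(exp.measured, exp.values + noise, exp.values)
        new_values.append(vals)
    out = dataset.with_values(new_values)
    out.provenance["augmented"] = True
    return out


def adam_update(
    theta: np.ndarray,
    g: np.ndarray,
    moments: tuple[np.ndarray, np.ndarray],
    iteration_index: int,
    config: AdamConfig,
) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """One bias-corrected ADAM step (iteration_index starts at 1)."""
    if iteration_index < 1:
        raise ContractError("iteration_index must be >= 1")
    m, v = moments
    m = config.beta1 * m + (1.0 - config.beta1) * g
    v = config.beta2 * v + (1.0 - config.beta2) * g * g
    m_hat = m / (1.0 - config.beta1**iteration_index)
    v_hat = v / (1.0 - config.beta2**iteration_index)
    theta_new = theta - config.alpha * m_hat / (np.sqrt(v_hat) + config.eta)
    return theta_new, (m, v)


def train_adam(
    model: HybridModel,
    dataset: ExperimentDataset,
    config: AdamConfig,
    substep: float | None = None,
) -> TrainingRun:
    """ADAM + semidirect sensitivities + stochastic regularization.

    A single random initialization (uniform on [-0.01, 0.01]) is drawn from
    ``config.seed``. Each iteration samples a minibatch of experiments
    (``ceil(fraction * n_train)`` without replacement) and one dropout mask,
    computes the semidirect gradient of the minibatch WMSE under the mask,
    applies the ADAM update, and records the full-batch maskless training
    WMSE; the kept weights are those of the trace argmin (iteration 0, the
    initialization, included).
    """
    rng = np.random.default_rng(config.seed)
    theta = init_weights(model.layout, rng).flatten()
    n_exp = len(dataset.experiments)
    n_mb = int(np.ceil(config.minibatch_fraction * n_exp))
    ids = dataset.ids

    trace = []
    w0, _, _ = wmse_objective(model.with_weights(theta), dataset, substep)
    trace.append(w0)
    best = (w0, theta.copy(), 0)

    m = np.zeros_like(theta)
    v = np.zeros_like(theta)
    n_updates = 0
    skips = 0
    consecutive = 0
    for it in range(1, config.iterations + 1):
        mb_ids = [ids[i] for i in rng.choice(n_exp, size=n_mb, replace=False)]
        mask = (
            sample_dropout_mask(model.layout, config.dropout_p, rng)
            if config.dropout_p > 0
            else None
        )
        try:
            res = semidirect_gradient(
                model, dataset.subset(mb_ids), weights=theta, substep=substep, mask=mask
            )
            g = res.g
            if not np.all(np.isfinite(g)):
                raise DivergenceError(np.nan, "non-finite gradient")
        except DivergenceError:
            skips += 1
            consecutive += 1
            trace.append(trace[-1])
            if consecutive > config.max_consecutive_skips:
                raise TrainingError(
                    f"{consecutive} consecutive non-finite gradients at iteration {it}"
                )
            continue
        consecutive = 0
        n_updates += 1
        theta, (m, v) = adam_update(theta, g, (m, v), n_updates, config)
        try:
            w_full, _, _ = wmse_objective(model.with_weights(theta), dataset, substep)
        except DivergenceError:
            w_full = np.inf
        trace.append(w_full)
        if w_full < best[0]:
            best = (w_full, theta.copy(), it)

    kept = NetworkWeights.unflatten(model.layout, best[1])
    return TrainingRun(
        trainer="adam",
        train_wmse=np.asarray(trace),
        val_wmse=None,
        kept_weights=kept,
        kept_iteration=best[2],
        seed=config.seed,
        config=config,
        info={"skipped_iterations": skips, "n_updates": n_updates},
    )


def damped_gauss_newton(
    residual_fn,
    jacobian_fn,
    x0: np.ndarray,
    max_iterations: int = 100,
    lambda0: float = 1e-3,
    lambda_up: float = 10.0,
    lambda_down: float = 10.0,
    ftol: float = 1e-12,
    max_inner: int = 12,
    callback=None,
):
    """Generic Levenberg-Marquardt loop on a residual vector.

    Minimizes ``sum(residual_fn(x)**2)``. ``residual_fn`` may raise
    :class:`DivergenceError` at a trial point, which rejects the step and
    increases the damping. Returns ``(x, sse_trace)``; ``callback(x, sse)``
    runs after every accepted step and may return True to stop early.
    """
    x = np.asarray(x0, dtype=float).copy()
    r = residual_fn(x)
    sse = float(r @ r)
    lam = lambda0
    trace = [sse]
    for _ in range(max_iterations):
        J = jacobian_fn(x)
        JtJ = J.T @ J
        Jtr = J.T @ r
        accepted = False
        for _ in range(max_inner):
            try:
                delta = np.linalg.solve(JtJ + lam * np.eye(JtJ.shape[0]), -Jtr)
            except np.linalg.LinAlgError:
                lam *= lambda_up
                continue
            x_try = x + delta
            try:
                r_try = residual_fn(x_try)
            except DivergenceError:
                lam *= lambda_up
                continue
            with np.errstate(over="ignore", invalid="ignore"):
                sse_try = float(r_try @ r_try)
            if np.isfinite(sse_try) and sse_try < sse:
                improvement = (sse - sse_try) / max(sse, 1e-300)
                x, r, sse = x_try, r_try, sse_try
                lam = max(lam / lambda_down, 1e-14)
                accepted = True
                trace.append(sse)
                if callback is not None and callback(x, sse):
                    return x, trace
                if improvement < ftol:
                    return x, trace
                break
            lam *= lambda_up
        if not accepted:
            break
    return x, trace


def train_lmm(
    model: HybridModel,
    dataset: ExperimentDataset,
    config: LmmConfig,
    substep: float | None = None,
) -> TrainingRun:
    """Levenberg-Marquardt + indirect sensitivities + cross-validation stop.

    The validation subset is a noise-augmented copy of the training data (one
    Gaussian draw per measured value, SD equal to the recorded measurement
    SD). Training stops when the validation WMSE has not improved for
    ``patience`` consecutive accepted steps; the kept weights are those at
    the minimum validation WMSE. The whole procedure restarts
    ``config.restarts`` times from fresh uniform(-0.01, 0.01) initializations
    and the run with the lowest validation WMSE is returned.
    """
    rng = np.random.default_rng(config.seed)
    T = dataset.n_residuals

    best_run = None
    restart_summaries = []
    for restart in range(config.restarts):
        theta0 = init_weights(model.layout, rng).flatten()
        val_set = make_validation_set(dataset, rng)

        state = {
            "best_val": np.inf,
            "best_theta": theta0.copy(),
            "best_iter": 0,
            "bad": 0,
            "train": [],
            "val": [],
        }

        def residual_fn(th):
            r, _ = _cached_rj(model, dataset, th, substep, jac=False)
            return r

        def jacobian_fn(th):
            _, J = _cached_rj(model, dataset, th, substep, jac=True)
            return J

        def callback(th, sse):
            train_wmse = sse / T
            try:
                val_wmse, _, _ = wmse_objective(
                    model.with_weights(th), val_set, substep
                )
            except DivergenceError:
                val_wmse = np.inf
            state["train"].append(train_wmse)
            state["val"].append(val_wmse)
            if val_wmse < state["best_val"]:
                state["best_val"] = val_wmse
                state["best_theta"] = th.copy()
                state["best_iter"] = len(state["train"]) - 1
                state["bad"] = 0
            else:
                state["bad"] += 1
            return state["bad"] >= config.patience

        try:
            damped_gauss_newton(
                residual_fn,
                jacobian_fn,
                theta0,
                max_iterations=config.max_iterations,
                lambda0=config.lambda0,
                lambda_up=config.lambda_up,
                lambda_down=config.lambda_down,
                ftol=config.ftol,
                callback=callback,
            )
        except DivergenceError:
            # diverged at the very first evaluation: skip this restart
            restart_summaries.append({"restart": restart, "status": "diverged"})
            continue

        if not state["train"]:
            # no step was ever accepted; evaluate the raw initialization
            try:
                tw, _, _ = wmse_objective(model.with_weights(theta0), dataset, substep)
                vw, _, _ = wmse_objective(model.with_weights(theta0), val_set, substep)
            except DivergenceError:
                restart_summaries.append({"restart": restart, "status": "diverged"})
                continue
            state["train"], state["val"] = [tw], [vw]
            state["best_val"], state["best_theta"], state["best_iter"] = vw, theta0, 0

        restart_summaries.append(
            {
                "restart": restart,
                "status": "ok",
                "best_val_wmse": state["best_val"],
                "best_train_wmse": state["train"][state["best_iter"]],
                "n_accepted": len(state["train"]),
            }
        )
        if best_run is None or state["best_val"] < best_run["best_val"]:
            best_run = dict(state, restart=restart)

    if best_run is None:
        raise TrainingError("all LMM restarts diverged")

    kept = NetworkWeights.unflatten(model.layout, best_run["best_theta"])
    return TrainingRun(
        trainer="lmm",
        train_wmse=np.asarray(best_run["train"]),
        val_wmse=np.asarray(best_run["val"]),
        kept_weights=kept,
        kept_iteration=best_run["best_iter"],
        seed=config.seed,
        config=config,
        info={"restarts": restart_summaries, "kept_restart": best_run["restart"]},
    )


# Small cache so the LM inner loop's residual evaluations do not recompute the
# expensive sensitivity Jacobian; keyed on the weight-vector bytes.
_rj_cache: dict[tuple, tuple[np.ndarray, np.ndarray | None]] = {}


def _cached_rj(model, dataset, theta, substep, jac):
    key = (id(model.layout), id(dataset), theta.tobytes())
    hit = _rj_cache.get(key)
    if hit is not None and (not jac or hit[1] is not None):
        return hit
    if jac:
        r, J = residual_jacobian(model, dataset, weights=theta, substep=substep)
    else:
        pred_r = _residuals_only(model, dataset, theta, substep)
        r, J = pred_r, None
    if len(_rj_cache) > 8:
        _rj_cache.clear()
    _rj_cache[key] = (r, J)
    return r, J


def _residuals_only(model, dataset, theta, substep):
    from .gradients import _effective_sigmas, _simulate_predictions

    model = model.with_weights(theta)
    substep = substep if substep is not None else model.substep
    rows = []
    for exp in dataset.experiments:
        pred = _simulate_predictions(model, exp, substep, None)
        sig = _effective_sigmas(exp, model.species.cmax)
        meas = exp.measured
        rows.append(((pred - exp.values) / sig)[meas])
    return np.concatenate(rows)
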