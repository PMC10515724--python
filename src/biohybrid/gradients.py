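"""Exact weight-space gradients of the weighted least-squares objective.

Two sensitivity-equation engines are provided, both returning the gradient of

    WMSE = (1/T) * sum_t ((c*_t - c_t) / sigma_t)^2

with respect to every network weight, where the sum runs over all measured
scalar residuals of a dataset subset and the model trajectory is the
fixed-step RK4 solution of the hybrid balances.

* ``indirect_gradient`` carries the full weight-space sensitivity matrix
  S = ∂(c, V)/∂θ (shape n_states x nw) through every RK4 stage — the carried
  system grows linearly with the number of network weights nw.

* ``semidirect_gradient`` factors each RK4 step into an nw-independent state
  propagator A (n_states x n_states) and per-stage rate-channel injection
  blocks C_i (n_states x n_out) — the sensitivities of the states with
  respect to the network's output channels — and assembles
  S+ = A·S + sum_i C_i·(∂v/∂θ at stage i) algebraically. The ODE-propagated
  blocks are independent of nw; only the network weight-Jacobians and the
  final composition touch weight space.

Both engines differentiate the *discrete* RK4 map exactly (forward mode), so
they agree with each other to machine precision and with central finite
differences of the discrete objective to O(h_fd^2). Sensitivities start at
zero: initial conditions do not depend on the weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import Experiment, ExperimentDataset
from .errors import ContractError, DivergenceError
from .mechanistic import build_step_grid, feed_mass_rate, total_feed_rate
from .model import HybridModel
from .network import (
    DropoutMask,
    NetworkWeights,
    forward,
    jacobian_wrt_inputs,
    jacobian_wrt_weights,
)

__all__ = [
    "GradientResult",
    "indirect_gradient",
    "semidirect_gradient",
    "fd_gradient",
    "residual_jacobian",
    "wmse_objective",
    "semidirect_carried_shape",
    "indirect_carried_shape",
]

#: floor on measurement SDs, as a fraction of the species cmax
SIGMA_FLOOR_FRACTION = 1e-6


@dataclass
class GradientResult:
    """Gradient + objective for one dataset subset at one weight vector."""

    g: np.ndarray
    objective: float
    per_experiment: dict[str, float]
    n_residuals: int
    carried_shape: tuple[int, int]


def semidirect_carried_shape(model: HybridModel) -> tuple[int, int]:
    """Shape of the ODE-carried sensitivity blocks: (n_states, n_out).

    n_states counts the concentrations plus the culture volume; the shape is
    independent of the number of network weights.
    """
    return (model.species.n + 1, model.layout.n_out)


def indirect_carried_shape(model: HybridModel) -> tuple[int, int]:
    """Shape of the carried weight-space sensitivity matrix: (n_states, nw)."""
    return (model.species.n + 1, model.n_weights)


def _effective_sigmas(exp: Experiment, cmax: np.ndarray) -> np.ndarray:
    floor = SIGMA_FLOOR_FRACTION * cmax
    return np.maximum(exp.sigmas, floor[None, :])


class _StageModel:
    """Per-stage RHS, state Jacobian and rate-channel pieces of one model."""

    def __init__(self, model: HybridModel, mask: DropoutMask | None):
        self.model = model
        self.mask = mask
        self.n = model.species.n
        self.ixv = model.species.xv_index
        self.cmax = model.species.cmax
        self.has_vol = bool(model.layout.extra_inputs)
        self.vmax = model.layout.extra_inputs[0].maximum if self.has_vol else 1.0

    def rates(self, c: np.ndarray, V: float) -> np.ndarray:
        h0 = self.model.network_input(c, V)
        return forward(self.model.layout, self.model.weights, h0, self.mask)

    def pieces(self, c, V, ftot, fconc, need_theta):
        """Return f (m,), J (m x m), xv, theta (n_out x nw or None)."""
        n, ixv = self.n, self.ixv
        h0 = self.model.network_input(c, V)
        v = forward(self.model.layout, self.model.weights, h0, self.mask)
        jin = jacobian_wrt_inputs(self.model.layout, self.model.weights, h0, self.mask)
        xv = c[ixv]
        dtot = ftot / V
        # chain through input clamping + normalization
        clamp = (c > 0).astype(float) / self.cmax
        dv_dc = jin[:, :n] * clamp[None, :]
        f = np.empty(n + 1)
        f[:n] = v * xv - c * dtot + fconc / V
        f[n] = ftot
        J = np.zeros((n + 1, n + 1))
        J[:n, :n] = xv * dv_dc - dtot * np.eye(n)
        J[:n, ixv] += v
        dfc_dV = c * (ftot / V**2) - fconc / V**2
        if self.has_vol:
            dfc_dV = dfc_dV + xv * jin[:, n] / self.vmax
        J[:n, n] = dfc_dV
        theta = None
        if need_theta:
            theta = jacobian_wrt_weights(self.model.layout, self.model.weights, h0, self.mask)
        return f, J, xv, theta


def _propagate_experiment(
    model: HybridModel,
    exp: Experiment,
    substep: float,
    mask: DropoutMask | None,
    method: str,
):
    """Walk the RK4 grid carrying weight-space sensitivities.

    Returns (pred, sens) with pred (T x n) the model concentrations at the
    measurement times and sens (T x n x nw) their weight sensitivities.
    """
    sm = _StageModel(model, mask)
    n = sm.n
    nw = model.n_weights
    grid = build_step_grid(exp.times, exp.streams, substep)
    meas_times = exp.times
    y = np.concatenate([exp.c0, [exp.v0]])
    S = np.zeros((n + 1, nw))

    n_meas = meas_times.size
    pred = np.empty((n_meas, n))
    sens = np.empty((n_meas, n, nw))
    m_idx = 0
    if abs(grid[0] - meas_times[0]) < 1e-9:
        pred[0], sens[0] = y[:n], S[:n]
        m_idx = 1

    stage_offsets = (0.0, 0.5, 0.5, 1.0)
    rk_weights = (1.0, 2.0, 2.0, 1.0)

    for a, b in zip(grid[:-1], grid[1:]):
        h = b - a
        tm = 0.5 * (a + b)
        errstate = np.errstate(over="ignore", invalid="ignore")
        errstate.__enter__()
        ftot = total_feed_rate(exp.streams, tm)
        fconc = feed_mass_rate(exp.streams, tm, n)

        ys = y
        if method == "indirect":
            Ss = S
            y_acc = np.zeros_like(y)
            S_acc = np.zeros_like(S)
            k = np.zeros_like(y)
            dS = np.zeros_like(S)
            for off, wgt in zip(stage_offsets, rk_weights):
                ys = y + h * off * k
                Ss = S + h * off * dS
                f, J, xv, theta = sm.pieces(ys[:n], ys[n], ftot, fconc, True)
                k = f
                dS = J @ Ss
                dS[:n] += xv * theta  # E @ theta: volume row is zero
                y_acc += wgt * k
                S_acc += wgt * dS
            y = y + (h / 6.0) * y_acc
            S = S + (h / 6.0) * S_acc
        else:  # semidirect
            # nw-independent propagation of A (m x m) and C_i (m x n_out)
            m = n + 1
            n_out = model.layout.n_out
            k = np.zeros_like(y)
            y_acc = np.zeros_like(y)
            M_prev = None
            coeff_prev: list[np.ndarray] = []
            A_acc = np.zeros((m, m))
            C_acc: list[np.ndarray] = []
            thetas: list[np.ndarray] = []
            for si, (off, wgt) in enumerate(zip(stage_offsets, rk_weights)):
                ys = y + h * off * k
                f, J, xv, theta = sm.pieces(ys[:n], ys[n], ftot, fconc, True)
                k = f
                y_acc += wgt * f
                thetas.append(theta)
                E = np.zeros((m, n_out))
                E[:n, :] = xv * np.eye(n)
                if si == 0:
                    M = J
                    coeff = [E]
                else:
                    M = J + (h * off) * (J @ M_prev)
                    coeff = [(h * off) * (J @ Cprev) for Cprev in coeff_prev]
                    coeff.append(E)
                A_acc += wgt * M
                while len(C_acc) < len(coeff):
                    C_acc.append(np.zeros((m, n_out)))
                for i, Ci in enumerate(coeff):
                    C_acc[i] += wgt * Ci
                M_prev, coeff_prev = M, coeff
            A = np.eye(m) + (h / 6.0) * A_acc
            S = A @ S
            for Ci, theta in zip(C_acc, thetas):
                S += (h / 6.0) * (Ci @ theta)
            y = y + (h / 6.0) * y_acc

        errstate.__exit__(None, None, None)
        if not np.all(np.isfinite(y)) or not np.all(np.isfinite(S)):
            raise DivergenceError(b)
        if m_idx < n_meas and abs(b - meas_times[m_idx]) < 1e-9:
            pred[m_idx], sens[m_idx] = y[:n], S[:n]
            m_idx += 1

    if m_idx != n_meas:
        raise ContractError("measurement grid not covered by integration grid")
    return pred, sens


def _simulate_predictions(model, exp, substep, mask):
    traj = model.simulate(
        exp.initial_state(), exp.streams, exp.times, substep=substep, mask=mask
    )
    return traj.conc


def wmse_objective(
    model: HybridModel,
    dataset: ExperimentDataset,
    substep: float | None = None,
    mask: DropoutMask | None = None,
) -> tuple[float, dict[str, float], int]:
    """Full WMSE over a dataset subset; returns (wmse, per-experiment SSE, T)."""
    substep = substep if substep is not None else model.substep
    total = 0.0
    T = 0
    per_exp: dict[str, float] = {}
    for exp in dataset.experiments:
        pred = _simulate_predictions(model, exp, substep, mask)
        sig = _effective_sigmas(exp, model.species.cmax)
        mask_meas = exp.measured
        r = (exp.values[mask_meas] - pred[mask_meas]) / sig[mask_meas]
        sse = float(np.dot(r, r))
        per_exp[exp.id] = sse
        total += sse
        T += r.size
    if T == 0:
        raise ContractError("dataset subset contains no measured residuals")
    return total / T, per_exp, T


def _sensitivity_gradient(model, dataset, weights, substep, mask, method):
    if weights is not None:
        model = model.with_weights(weights)
    substep = substep if substep is not None else model.substep
    nw = model.n_weights
    g = np.zeros(nw)
    total = 0.0
    T = dataset.n_residuals
    if T == 0:
        raise ContractError("dataset subset contains no measured residuals")
    per_exp: dict[str, float] = {}
    for exp in dataset.experiments:
        pred, sens = _propagate_experiment(model, exp, substep, mask, method)
        sig = _effective_sigmas(exp, model.species.cmax)
        meas = exp.measured
        resid = np.where(meas, exp.values - pred, 0.0)
        wres = np.where(meas, resid / sig**2, 0.0)
        sse = float(np.sum(np.where(meas, (resid / sig) ** 2, 0.0)))
        per_exp[exp.id] = sse
        total += sse
        # dWMSE/dtheta = (2/T) * sum (pred - c*)/sigma^2 * S
        g += (2.0 / T) * np.einsum("tc,tcw->w", -wres, sens)
    carried = (
        indirect_carried_shape(model)
        if method == "indirect"
        else semidirect_carried_shape(model)
    )
    return GradientResult(g, total / T, per_exp, T, carried)


def indirect_gradient(
    model: HybridModel,
    dataset: ExperimentDataset,
    weights: NetworkWeights | np.ndarray | None = None,
    substep: float | None = None,
    mask: DropoutMask | None = None,
) -> GradientResult:
    """WMSE gradient carrying the full ∂states/∂θ system (grows with nw)."""
    return _sensitivity_gradient(model, dataset, weights, substep, mask, "indirect")


def semidirect_gradient(
    model: HybridModel,
    dataset: ExperimentDataset,
    weights: NetworkWeights | np.ndarray | None = None,
    substep: float | None = None,
    mask: DropoutMask | None = None,
) -> GradientResult:
    """WMSE gradient via the factored rate-channel sensitivity propagation.

    The ODE-carried blocks have shape (n_states, n_out) regardless of network
    size; the weight Jacobian of the network is composed in afterwards.
    """
    return _sensitivity_gradient(model, dataset, weights, substep, mask, "semidirect")


def fd_gradient(
    model: HybridModel,
    dataset: ExperimentDataset,
    weights: NetworkWeights | np.ndarray | None = None,
    h: float = 1e-6,
    substep: float | None = None,
    mask: DropoutMask | None = None,
) -> np.ndarray:
    """Central finite differences of the WMSE objective (test oracle)."""
    if h <= 0:
        raise ContractError("FD step must be > 0")
    if weights is not None:
        model = model.with_weights(weights)
    theta0 = model.weights.flatten()
    g = np.empty_like(theta0)
    for i in range(theta0.size):
        tp = theta0.copy()
        tp[i] += h
        wp, _, _ = wmse_objective(model.with_weights(tp), dataset, substep, mask)
        tm = theta0.copy()
        tm[i] -= h
        wm, _, _ = wmse_objective(model.with_weights(tm), dataset, substep, mask)
        g[i] = (wp - wm) / (2.0 * h)
    return g


def residual_jacobian(
    model: HybridModel,
    dataset: ExperimentDataset,
    weights: NetworkWeights | np.ndarray | None = None,
    substep: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted residual vector r = (c - c*)/sigma and its Jacobian ∂r/∂θ.

    Used by the Levenberg-Marquardt trainer; rows are ordered by experiment,
    then time, then species, skipping missing measurements. Note
    WMSE = (1/T)·rᵀr.
    """
    if weights is not None:
        model = model.with_weights(weights)
    substep = substep if substep is not None else model.substep
    rows_r, rows_j = [], []
    for exp in dataset.experiments:
        pred, sens = _propagate_experiment(model, exp, substep, None, "indirect")
        sig = _effective_sigmas(exp, model.species.cmax)
        meas = exp.measured
        for ti in range(exp.times.size):
            for si in range(model.species.n):
                if meas[ti, si]:
                    rows_r.append((pred[ti, si] - exp.values[ti, si]) / sig[ti, si])
                    rows_j.append(sens[ti, si] / sig[ti, si])
    if not rows_r:
        raise ContractError("dataset subset contains no measured residuals")
    return np.asarray(rows_r), np.asarray(rows_j)
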