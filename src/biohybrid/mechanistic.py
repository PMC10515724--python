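"""Fed-batch macroscopic material balances and fixed-step RK4 integration.

The reactor model is the standard fed-batch state-space form: for the
concentration vector ``c`` (one entry per extracellular species, viable cell
density ``Xv`` included as a named species) and culture volume ``V``,

    dc/dt = v(c) * Xv + sum_k D_k * c_in_k - c * sum_k D_k
    dV/dt = V * sum_k D_k,          D_k = F_k / V

with ``v`` the vector of specific reaction rates (per unit viable biomass)
supplied by a kinetic callable — in the hybrid model, a neural network.
Feeds are piecewise-constant rate schedules; there is no outflow.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .errors import ContractError, DivergenceError, InvalidStateError

__all__ = [
    "SpeciesSet",
    "FeedStream",
    "ProcessState",
    "Trajectory",
    "RateFunction",
    "dilution_rate",
    "total_feed_rate",
    "hybrid_rhs",
    "build_step_grid",
    "integrate_rk4",
]

#: signature of a specific-rate callable: (t, c, V) -> v, one rate per species
RateFunction = Callable[[float, np.ndarray, float], np.ndarray]


@dataclass(frozen=True)
class SpeciesSet:
    """Ordered roster of measured species with their normalization maxima.

    Parameters
    ----------
    names
        Unique species identifiers; must contain the viable-cell species.
    cmax
        Strictly positive per-species absolute maximum concentrations used to
        normalize network inputs.
    units
        Optional per-species unit labels (display only).
    xv_name
        Name of the viable-cell-density species (identified by name, not by
        position).
    """

    names: tuple[str, ...]
    cmax: np.ndarray
    units: tuple[str, ...] | None = None
    xv_name: str = "Xv"

    def __post_init__(self):
        names = tuple(self.names)
        object.__setattr__(self, "names", names)
        cmax = np.asarray(self.cmax, dtype=float)
        object.__setattr__(self, "cmax", cmax)
        if len(set(names)) != len(names):
            raise ContractError("species names must be unique")
        if cmax.shape != (len(names),):
            raise ContractError(
                f"cmax has shape {cmax.shape}, expected ({len(names)},)"
            )
        if not np.all(np.isfinite(cmax)) or np.any(cmax <= 0):
            raise ContractError("cmax entries must be finite and > 0")
        if self.xv_name not in names:
            raise ContractError(f"viable-cell species {self.xv_name!r} not in roster")
        if self.units is not None and len(self.units) != len(names):
            raise ContractError("units length must match names")

    @property
    def n(self) -> int:
        return len(self.names)

    @property
    def xv_index(self) -> int:
        return self.names.index(self.xv_name)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise ContractError(f"unknown species {name!r}") from None


@dataclass(frozen=True)
class FeedStream:
    """One inlet stream: composition plus a piecewise-constant rate schedule.

    ``schedule`` is an ordered sequence of ``(t_start, t_end, rate)`` segments
    (hours, rate in volume/time). Outside every segment the rate is zero.
    """

    c_in: np.ndarray
    schedule: tuple[tuple[float, float, float], ...]
    name: str = "feed"

    def __post_init__(self):
        c_in = np.asarray(self.c_in, dtype=float)
        object.__setattr__(self, "c_in", c_in)
        sched = tuple((float(a), float(b), float(r)) for a, b, r in self.schedule)
        object.__setattr__(self, "schedule", sched)
        if not np.all(np.isfinite(c_in)) or np.any(c_in < 0):
            raise ContractError("feed compositions must be finite and >= 0")
        prev_end = -np.inf
        for a, b, r in sched:
            if b <= a:
                raise ContractError(f"empty/inverted segment ({a}, {b})")
            if a < prev_end:
                raise ContractError("feed segments overlap or are unordered")
            if r < 0:
                raise ContractError("feed rates must be >= 0")
            prev_end = b

    def rate_at(self, t: float) -> float:
        """Feed rate at time ``t`` (zero outside all segments)."""
        for a, b, r in self.schedule:
            if a <= t < b:
                return r
        return 0.0

    def breakpoints(self) -> list[float]:
        pts: list[float] = []
        for a, b, _ in self.schedule:
            pts.extend((a, b))
        return pts


@dataclass
class ProcessState:
    """Instantaneous reactor state: concentrations, volume, time."""

    c: np.ndarray
    V: float
    t: float = 0.0

    def __post_init__(self):
        self.c = np.asarray(self.c, dtype=float)
        if not np.all(np.isfinite(self.c)):
            raise InvalidStateError("concentrations must be finite")
        if not np.isfinite(self.V) or self.V <= 0:
            raise InvalidStateError(f"volume must be > 0, got {self.V}")


@dataclass
class Trajectory:
    """Simulation output on a strictly increasing time grid.

    ``conc`` has shape (n_times, n_species), ``volume`` (n_times,), ``rates``
    the specific-rate vector recorded at each output time (diagnostic only;
    trainers never read it).
    """

    times: np.ndarray
    conc: np.ndarray
    volume: np.ndarray
    rates: np.ndarray | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.conc = np.asarray(self.conc, dtype=float)
        self.volume = np.asarray(self.volume, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ContractError("trajectory times must be strictly increasing")
        if self.conc.shape[0] != self.times.size or self.volume.shape != self.times.shape:
            raise ContractError("one state per time point required")


def dilution_rate(
    streams: Sequence[FeedStream], t: float, V: float
) -> tuple[np.ndarray, float]:
    """Per-stream dilution rates D_k = F_k(t)/V and their total D.

    Raises
    ------
    InvalidStateError
        If ``V`` is not strictly positive.
    """
    if not np.isfinite(V) or V <= 0:
        raise InvalidStateError(f"volume must be > 0, got {V}")
    dk = np.array([s.rate_at(t) / V for s in streams], dtype=float)
    return dk, float(dk.sum())


def total_feed_rate(streams: Sequence[FeedStream], t: float) -> float:
    return float(sum(s.rate_at(t) for s in streams))


def feed_mass_rate(streams: Sequence[FeedStream], t: float, n: int) -> np.ndarray:
    """sum_k F_k(t) * c_in_k — volumetric species inflow (amount/time)."""
    acc = np.zeros(n)
    for s in streams:
        r = s.rate_at(t)
        if r:
            acc = acc + r * s.c_in
    return acc


def hybrid_rhs(
    state: ProcessState,
    v: np.ndarray,
    streams: Sequence[FeedStream],
    species: SpeciesSet,
) -> tuple[np.ndarray, float]:
    """Material-balance time derivatives (dc/dt, dV/dt) for given rates ``v``."""
    v = np.asarray(v, dtype=float)
    if v.shape != state.c.shape:
        raise ContractError(
            f"rate vector shape {v.shape} does not match species roster {state.c.shape}"
        )
    xv = state.c[species.xv_index]
    _, d_tot = dilution_rate(streams, state.t, state.V)
    dc = v * xv - state.c * d_tot + feed_mass_rate(streams, state.t, state.c.size) / state.V
    dv = state.V * d_tot  # = sum_k F_k
    return dc, dv


def build_step_grid(
    output_times: np.ndarray,
    streams: Sequence[FeedStream],
    substep: float,
) -> np.ndarray:
    """Integration grid: output times, feed breakpoints, then uniform substeps.

    Every inter-output interval is split at feed-schedule breakpoints so the
    feed rate is constant within each RK4 step; each resulting span is then
    subdivided into ceil(span/substep) equal steps.
    """
    output_times = np.asarray(output_times, dtype=float)
    if output_times.ndim != 1 or output_times.size < 1:
        raise ContractError("output_times must be a non-empty 1-D grid")
    if np.any(np.diff(output_times) <= 0):
        raise ContractError("output_times must be strictly increasing")
    if substep <= 0:
        raise ContractError("substep must be > 0")
    t0, t1 = output_times[0], output_times[-1]
    knots = {round(float(t), 12) for t in output_times}
    for s in streams:
        for b in s.breakpoints():
            if t0 < b < t1:
                knots.add(round(float(b), 12))
    ordered = sorted(knots)
    grid = [ordered[0]]
    for a, b in zip(ordered[:-1], ordered[1:]):
        nsub = max(1, int(np.ceil((b - a) / substep - 1e-9)))
        grid.extend(a + (b - a) * (i + 1) / nsub for i in range(nsub))
    return np.asarray(grid)


def rk4_step(
    f: Callable[[float, np.ndarray], np.ndarray],
    t: float,
    y: np.ndarray,
    h: float,
) -> np.ndarray:
    """One classical Runge-Kutta 4 step for a generic first-order system."""
    k1 = f(t, y)
    k2 = f(t + 0.5 * h, y + 0.5 * h * k1)
    k3 = f(t + 0.5 * h, y + 0.5 * h * k2)
    k4 = f(t + h, y + h * k3)
    return y + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


def integrate_rk4(
    rates: RateFunction,
    species: SpeciesSet,
    initial: ProcessState,
    streams: Sequence[FeedStream],
    output_times: np.ndarray,
    substep: float = 0.5,
    nonneg_project: bool = False,
    record_rates: bool = True,
) -> Trajectory:
    """Integrate the fed-batch balances with classical fixed-step RK4.

    Parameters
    ----------
    rates
        Callable ``(t, c, V) -> v`` returning the specific-rate vector. Any
        input clamping/normalization is the callable's responsibility (the
        hybrid model clamps concentrations at >= 0 before normalization).
    initial
        State at ``output_times[0]``.
    substep
        Maximum RK4 step h in hours. Feed breakpoints force extra step
        boundaries so the feed rate is constant within each step.
    nonneg_project
        If True, project concentrations to >= 0 after every step. Off by
        default: the balances are integrated unconstrained.

    Raises
    ------
    DivergenceError
        If the state becomes non-finite during integration.
    """
    output_times = np.asarray(output_times, dtype=float)
    if abs(output_times[0] - initial.t) > 1e-9:
        raise ContractError("initial state time must equal output_times[0]")
    n = species.n
    if initial.c.shape != (n,):
        raise ContractError("initial concentrations do not match species roster")
    grid = build_step_grid(output_times, streams, substep)
    ixv = species.xv_index

    c = initial.c.astype(float).copy()
    V = float(initial.V)

    n_out = output_times.size
    conc = np.empty((n_out, n))
    vol = np.empty(n_out)
    rec = np.empty((n_out, n)) if record_rates else None

    def emit(i_out: int, t: float) -> int:
        conc[i_out] = c
        vol[i_out] = V
        if rec is not None:
            rec[i_out] = rates(t, c, V)
        return i_out + 1

    out_idx = 0
    if abs(grid[0] - output_times[0]) < 1e-9:
        out_idx = emit(out_idx, grid[0])

    for a, b in zip(grid[:-1], grid[1:]):
        h = b - a
        tm = 0.5 * (a + b)  # feed rate is constant within the step
        ftot = total_feed_rate(streams, tm)
        fconc = feed_mass_rate(streams, tm, n)

        def f(t, y):
            c_, V_ = y[:n], y[n]
            v = np.asarray(rates(t, c_, V_), dtype=float)
            dc = v * c_[ixv] - c_ * (ftot / V_) + fconc / V_
            return np.concatenate([dc, [ftot]])

        with np.errstate(over="ignore", invalid="ignore"):
            y = rk4_step(f, a, np.concatenate([c, [V]]), h)
        if not np.all(np.isfinite(y)):
            raise DivergenceError(b)
        c, V = y[:n], float(y[n])
        if nonneg_project:
            c = np.maximum(c, 0.0)
        if out_idx < n_out and abs(b - output_times[out_idx]) < 1e-9:
            out_idx = emit(out_idx, b)

    if out_idx != n_out:
        raise ContractError("output grid not fully covered by integration grid")
    return Trajectory(output_times.copy(), conc, vol, rec)
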