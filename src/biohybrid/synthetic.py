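"""Synthetic CHO-like fed-batch datasets for testing the training machinery.

A reduced, fully documented ground-truth kinetic model (a surrogate with
Monod-type growth, overflow lactate metabolism with a production-to-
consumption shift on glucose depletion, glutaminolysis-driven ammonium with
late consumption, growth-coupled amino-acid uptake, and induced product
synthesis) is simulated over a 2-factor central composite design (CC-DoE) of
pre- and post-induction feed rates: 9 fed-batch runs, 240 h horizon, 24 h
sampling, 25 recorded extracellular variables. Heterogeneous Gaussian noise
with SD equal to 10% of each species' maximum concentration emulates
measurement error. Intracellular dynamics are intentionally absent: the
generator's job is the statistical structure of the data, not any specific
published flux model.

Units: time h; volume L; viable cells 1e9 cells/L (numerically equal to
Mcell/mL); product g/L; metabolites mM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .data import Experiment, ExperimentDataset
from .errors import ContractError, GenerationError
from .mechanistic import FeedStream, ProcessState, SpeciesSet, Trajectory, integrate_rk4

__all__ = [
    "SYNTHETIC_SPECIES",
    "EXPERIMENTAL_SPECIES",
    "GroundTruthModel",
    "DoEPlan",
    "NoiseSpec",
    "ccdoe_feed_rates",
    "simulate_ground_truth",
    "add_noise",
    "make_cc_doe_dataset",
    "make_experimental_style_dataset",
    "ground_truth_wmse",
    "cc_doe_split",
]

#: the 25 recorded extracellular variables of the synthetic configuration
SYNTHETIC_SPECIES = (
    "Xv", "mAb", "Ala", "Arg", "Asn", "Asp", "Cys", "Glc", "Gln", "Glu",
    "Pyr", "Gly", "His", "Ile", "Lac", "Leu", "Lys", "Met", "NH4", "Phe",
    "Pro", "Ser", "Thr", "Tyr", "Val",
)

#: the 30 measured variables of the experimental-style configuration
EXPERIMENTAL_SPECIES = (
    "Xv", "P", "Glc", "Lac", "Gln", "Glu", "NH4", "Pyr", "Glyc", "Cit",
    "Ala", "Arg", "Asn", "Asp", "Lcystin", "Gly", "His", "Ile", "Leu",
    "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val", "Ac",
    "For",
)

# growth-coupled uptake coefficient (mmol/1e9 cells) and maintenance uptake
# (mmol/1e9 cells/h) for the generic amino-acid pools
_AA_UPTAKE = {
    "Ala": None,  # produced (alanine overflow), handled explicitly
    "Arg": (0.9, 0.0015), "Asn": (1.6, 0.003), "Asp": (0.7, 0.001),
    "Cys": (0.5, 0.001), "Gly": None,  # produced
    "His": (0.4, 0.0008), "Ile": (1.1, 0.002), "Leu": (1.5, 0.0025),
    "Lys": (1.2, 0.002), "Met": (0.45, 0.0008), "Phe": (0.7, 0.0012),
    "Pro": (0.8, 0.0015), "Pyr": (0.9, 0.002), "Ser": (1.3, 0.0025),
    "Thr": (0.9, 0.0015), "Tyr": (0.55, 0.001), "Val": (1.2, 0.002),
    "Trp": (0.35, 0.0006), "Lcystin": (0.5, 0.001),
}

# initial concentrations (mM except Xv, product) at inoculation
_C0 = {
    "Xv": 3.0, "mAb": 0.0, "P": 0.0, "Glc": 35.0, "Gln": 4.5, "Lac": 1.5,
    "NH4": 0.8, "Glu": 1.0, "Ala": 2.0, "Arg": 1.5, "Asn": 2.5, "Asp": 1.0,
    "Cys": 0.6, "Lcystin": 0.6, "Gly": 1.0, "His": 0.6, "Ile": 1.5,
    "Leu": 2.0, "Lys": 1.8, "Met": 0.6, "Phe": 0.9, "Pro": 1.5, "Pyr": 1.0,
    "Ser": 1.8, "Thr": 1.5, "Tyr": 0.8, "Val": 1.8, "Trp": 0.5,
    "Glyc": 0.5, "Cit": 0.3, "Ac": 0.4, "For": 0.2,
}

# feed-stream composition (glucose/glutamine-rich with amino-acid make-up)
_FEED = {
    "Glc": 130.0, "Gln": 20.0, "Ala": 0.0, "Arg": 8.0, "Asn": 14.0,
    "Asp": 5.0, "Cys": 3.0, "Lcystin": 3.0, "Gly": 0.0, "His": 3.0,
    "Ile": 8.0, "Leu": 11.0, "Lys": 9.0, "Met": 3.0, "Phe": 5.0,
    "Pro": 7.0, "Pyr": 5.0, "Ser": 10.0, "Thr": 7.0, "Tyr": 4.0,
    "Val": 9.0, "Trp": 2.0,
}


@dataclass(frozen=True)
class GroundTruthModel:
    """Reduced CHO-like kinetic parameter set (the data-generating truth).

    All rate constants are non-negative; every consumption term carries a
    saturating ``c/(K+c)`` factor so simulated concentrations stay >= 0.
    The induction time emulates the production-phase temperature shift:
    growth slows and product synthesis accelerates after ``t_induction``.
    """

    mu_max: float = 0.04          # 1/h, maximum specific growth rate
    k_glc: float = 0.5             # mM, glucose Monod constant
    k_gln: float = 0.25            # mM, glutamine Monod constant
    ki_lac: float = 60.0           # mM, lactate growth inhibition
    kd0: float = 0.0015            # 1/h, basal death rate
    kd_starv: float = 0.008        # 1/h, extra death under glucose starvation
    post_induction_growth: float = 0.30  # growth multiplier after induction
    y_xv_glc: float = 0.30         # 1e9 cells/mmol glucose
    m_glc: float = 0.042           # mmol/1e9 cells/h, maintenance glucose uptake
    y_lac_glc: float = 1.5         # mmol lactate/mmol glucose (overflow)
    k_overflow: float = 8.0        # mM, glucose level sustaining overflow
    q_lac_cons: float = 0.15       # mmol/1e9 cells/h, max lactate consumption
    k_lac: float = 4.0             # mM, lactate consumption saturation
    ki_glc_lac: float = 1.0        # mM, glucose inhibition of lactate uptake
    y_xv_gln: float = 1.2          # 1e9 cells/mmol glutamine
    m_gln: float = 0.006           # mmol/1e9 cells/h
    y_nh4_gln: float = 0.75        # mmol ammonium/mmol glutamine
    q_nh4_cons: float = 0.012      # mmol/1e9 cells/h, late ammonium consumption
    k_nh4: float = 1.5             # mM
    ki_gln_nh4: float = 0.3        # mM, glutamine inhibition of NH4 uptake
    y_glu_gln: float = 0.10        # glutamate spill from glutaminolysis
    q_glu_cons: float = 0.015      # mmol/1e9 cells/h
    y_ala_gln: float = 0.30        # alanine overflow from glutaminolysis
    y_gly_gln: float = 0.08        # glycine spill
    q_mab: float = 0.0012          # g/1e9 cells/h, basal product synthesis
    induction_factor: float = 5.0  # product-rate multiplier after induction
    t_induction: float = 96.0      # h
    k_aa: float = 0.15             # mM, saturation constant of amino-acid uptake
    # overflow by-product yields for the experimental-style extra pools
    y_byproduct: dict = field(
        default_factory=lambda: {"Glyc": 0.04, "Cit": 0.02, "Ac": 0.05, "For": 0.03}
    )

    def specific_rates(self, species: SpeciesSet):
        """Rate callable ``(t, c, V) -> v`` for the given roster."""
        idx = {name: i for i, name in enumerate(species.names)}
        prod_name = "mAb" if "mAb" in idx else "P"
        aa_rows = []
        for name, coeffs in _AA_UPTAKE.items():
            if name in idx and coeffs is not None:
                aa_rows.append((idx[name], *coeffs))
        by_rows = [
            (idx[name], y) for name, y in self.y_byproduct.items() if name in idx
        ]
        i_xv, i_glc, i_gln = idx["Xv"], idx["Glc"], idx["Gln"]
        i_lac, i_nh4, i_glu = idx["Lac"], idx["NH4"], idx["Glu"]
        i_ala = idx.get("Ala")
        i_gly = idx.get("Gly")
        i_prod = idx[prod_name]
        p = self

        def rates(t, c, V):
            c = np.maximum(np.asarray(c, dtype=float), 0.0)
            glc, gln, lac, nh4 = c[i_glc], c[i_gln], c[i_lac], c[i_nh4]
            m_glc_sat = glc / (p.k_glc + glc)
            m_gln_sat = gln / (p.k_gln + gln)
            mu = p.mu_max * m_glc_sat * m_gln_sat * p.ki_lac / (p.ki_lac + lac)
            if t >= p.t_induction:
                mu *= p.post_induction_growth
            kd = p.kd0 + p.kd_starv * (1.0 - m_glc_sat)
            q_glc = (mu / p.y_xv_glc + p.m_glc) * m_glc_sat
            q_gln = (mu / p.y_xv_gln + p.m_gln) * m_gln_sat
            overflow = glc / (p.k_overflow + glc)
            v = np.zeros(species.n)
            v[i_xv] = mu - kd
            v[i_glc] = -q_glc
            v[i_gln] = -q_gln
            v[i_lac] = (
                p.y_lac_glc * q_glc * overflow
                - p.q_lac_cons
                * (lac / (p.k_lac + lac))
                * (p.ki_glc_lac / (p.ki_glc_lac + glc))
            )
            v[i_nh4] = (
                p.y_nh4_gln * q_gln
                - p.q_nh4_cons
                * (nh4 / (p.k_nh4 + nh4))
                * (p.ki_gln_nh4 / (p.ki_gln_nh4 + gln))
            )
            v[i_glu] = p.y_glu_gln * q_gln - p.q_glu_cons * c[i_glu] / (
                p.k_aa + c[i_glu]
            )
            if i_ala is not None:
                v[i_ala] = p.y_ala_gln * q_gln
            if i_gly is not None:
                v[i_gly] = p.y_gly_gln * q_gln
            q_p = p.q_mab * m_glc_sat
            if t >= p.t_induction:
                q_p *= p.induction_factor
            v[i_prod] = q_p
            for i, a, mnt in aa_rows:
                v[i] = -(a * mu + mnt) * c[i] / (p.k_aa + c[i])
            for i, y in by_rows:
                v[i] = y * q_glc * overflow
            return v

        return rates


@dataclass(frozen=True)
class DoEPlan:
    """2-factor central composite design over pre-/post-induction feed rates."""

    center: tuple[float, float]
    half_range: tuple[float, float]
    axial_alpha: float
    coded: tuple[tuple[float, float], ...]
    runs: tuple[tuple[float, float], ...]
    roles: tuple[str, ...]

    def __post_init__(self):
        if len(self.runs) != 9:
            raise ContractError("a 2-factor CC design has exactly 9 runs")


def ccdoe_feed_rates(
    center: tuple[float, float] = (5e-4, 1e-3),
    half_range: tuple[float, float] = (2.5e-4, 5e-4),
    axial_alpha: float = math.sqrt(2.0),
) -> DoEPlan:
    """The 9 (pre-induction, post-induction) feed-rate combinations.

    4 factorial (square) points at coded (+-1, +-1), 4 axial (star) points at
    (+-alpha, 0)/(0, +-alpha) and one center point, mapped to physical rates
    as center + coded * half_range (L/h).
    """
    if half_range[0] <= 0 or half_range[1] <= 0:
        raise ContractError("half-ranges must be > 0")
    a = float(axial_alpha)
    coded = [(-1.0, -1.0), (1.0, -1.0), (-1.0, 1.0), (1.0, 1.0),
             (-a, 0.0), (a, 0.0), (0.0, -a), (0.0, a), (0.0, 0.0)]
    roles = ("square",) * 4 + ("star",) * 4 + ("center",)
    runs = []
    for x1, x2 in coded:
        f1 = center[0] + x1 * half_range[0]
        f2 = center[1] + x2 * half_range[1]
        if f1 < 0 or f2 < 0:
            raise ContractError("design maps to a negative feed rate; shrink half_range")
        runs.append((f1, f2))
    return DoEPlan(tuple(center), tuple(half_range), a, tuple(coded), tuple(runs), roles)


@dataclass(frozen=True)
class NoiseSpec:
    """Gaussian measurement noise: SD = fraction x species maximum."""

    fraction: float = 0.10
    seed: int = 0

    def __post_init__(self):
        if self.fraction < 0:
            raise ContractError("noise fraction must be >= 0")


def _feed_vector(species: SpeciesSet, composition: dict) -> np.ndarray:
    return np.array([composition.get(n, 0.0) for n in species.names])


def _c0_vector(species: SpeciesSet) -> np.ndarray:
    return np.array([_C0[n] for n in species.names])


def simulate_ground_truth(
    model: GroundTruthModel,
    plan: DoEPlan,
    horizon: float = 240.0,
    sampling: float = 24.0,
    v0: float = 0.25,
    substep: float = 0.5,
    species_names: tuple[str, ...] = SYNTHETIC_SPECIES,
    feed_composition: dict | None = None,
) -> tuple[ExperimentDataset, dict[str, Trajectory]]:
    """Noiseless dataset over the design plan, plus the true trajectories.

    Each run uses one feed stream whose rate switches from the pre- to the
    post-induction value at the model's induction time. Sigma tables are set
    to 10% of each species' maximum over the noiseless data (the synthetic
    error model); ``add_noise`` perturbs the values consistently with them.
    Returns ``(dataset, truth)`` where ``truth`` maps experiment ids to
    trajectories carrying the true specific-rate series (never read by
    trainers).
    """
    times = np.arange(0.0, horizon + 1e-9, sampling)
    comp = dict(_FEED if feed_composition is None else feed_composition)
    # provisional roster for integration; cmax refined from the data afterwards
    probe = SpeciesSet(tuple(species_names), np.ones(len(species_names)))
    c_in = _feed_vector(probe, comp)
    c0 = _c0_vector(probe)
    rates = model.specific_rates(probe)

    role_counters: dict[str, int] = {}
    trajectories: dict[str, Trajectory] = {}
    run_meta: dict[str, dict] = {}
    for (f_pre, f_post), coded, role in zip(plan.runs, plan.coded, plan.roles):
        role_counters[role] = role_counters.get(role, 0) + 1
        exp_id = role[:2] + str(role_counters[role])
        stream = FeedStream(
            c_in,
            ((0.0, model.t_induction, f_pre), (model.t_induction, horizon, f_post)),
        )
        try:
            traj = integrate_rk4(
                rates, probe, ProcessState(c0.copy(), v0, 0.0), [stream], times,
                substep=substep, record_rates=True,
            )
        except Exception as exc:  # noqa: BLE001 - re-raise with run context
            raise GenerationError(f"run {exp_id} failed: {exc}") from exc
        if np.any(traj.conc < -1e-8):
            raise GenerationError(f"run {exp_id}: negative concentration in truth")
        traj.conc = np.maximum(traj.conc, 0.0)
        trajectories[exp_id] = traj
        run_meta[exp_id] = {
            "role": role, "coded": list(coded), "rates": [f_pre, f_post],
        }

    all_conc = np.concatenate([t.conc for t in trajectories.values()])
    cmax = all_conc.max(axis=0)
    if np.any(cmax <= 0):
        bad = [species_names[i] for i in np.where(cmax <= 0)[0]]
        raise GenerationError(f"species never observed above zero: {bad}")
    species = SpeciesSet(tuple(species_names), cmax)
    sigma_row = 0.10 * cmax

    experiments = []
    for exp_id, traj in trajectories.items():
        f_pre, f_post = run_meta[exp_id]["rates"]
        stream = FeedStream(
            c_in,
            ((0.0, model.t_induction, f_pre), (model.t_induction, horizon, f_post)),
        )
        experiments.append(
            Experiment(
                id=exp_id,
                times=times.copy(),
                values=traj.conc.copy(),
                sigmas=np.tile(sigma_row, (times.size, 1)),
                c0=c0.copy(),
                v0=v0,
                streams=(stream,),
            )
        )
    vmax = max(float(t.volume.max()) for t in trajectories.values())
    dataset = ExperimentDataset(
        species,
        experiments,
        provenance={
            "generator": "cc_doe_ground_truth",
            "noise": "none",
            "volume_max": vmax,
            "design": run_meta,
            "substep": substep,
        },
    )
    return dataset, trajectories


def add_noise(
    dataset: ExperimentDataset, spec: NoiseSpec
) -> ExperimentDataset:
    """Independent Gaussian perturbation per measurement.

    SD per species = ``spec.fraction`` x that species' maximum over the
    noiseless dataset; the sigma tables of the returned dataset record the
    SDs used (the weighting of the training objective). Negative noisy values
    are retained — measurement error can undershoot zero.
    """
    rng = np.random.default_rng(spec.seed)
    sigma_row = spec.fraction * dataset.species.cmax
    new_values = []
    new_exps = []
    for exp in dataset.experiments:
        noise = rng.normal(0.0, 1.0, size=exp.values.shape) * sigma_row[None, :]
        vals = np.where(exp.measured, exp.values + noise, exp.values)
        sig = np.tile(np.maximum(sigma_row, 1e-12), (exp.times.size, 1))
        new_exps.append(replace(exp, values=vals, sigmas=sig))
        new_values.append(vals)
    out = ExperimentDataset(
        dataset.species,
        new_exps,
        provenance=dict(
            dataset.provenance, noise=f"gaussian_{spec.fraction:g}_of_max", seed=spec.seed
        ),
    )
    return out


def cc_doe_split(dataset: ExperimentDataset) -> tuple[list[str], list[str]]:
    """Train on center + square (factorial) points, test on star (axial) points."""
    design = dataset.provenance.get("design")
    if not design:
        raise ContractError("dataset carries no CC-DoE design metadata")
    train = [i for i, m in design.items() if m["role"] in ("center", "square")]
    test = [i for i, m in design.items() if m["role"] == "star"]
    return train, test


def make_cc_doe_dataset(
    seed: int = 0,
    noise_fraction: float = 0.10,
    model: GroundTruthModel | None = None,
    plan: DoEPlan | None = None,
    substep: float = 0.5,
) -> tuple[ExperimentDataset, ExperimentDataset, dict[str, Trajectory]]:
    """Convenience wrapper: (noisy dataset, noiseless dataset, truth)."""
    model = model or GroundTruthModel()
    plan = plan or ccdoe_feed_rates()
    noiseless, truth = simulate_ground_truth(model, plan, substep=substep)
    noisy = add_noise(noiseless, NoiseSpec(noise_fraction, seed))
    return noisy, noiseless, truth


def ground_truth_wmse(
    dataset: ExperimentDataset,
    model: GroundTruthModel | None = None,
    substep: float = 0.5,
) -> float:
    """WMSE of the data-generating kinetic model against a (noisy) dataset.

    With correctly specified sigmas this concentrates near 1 (the noise
    floor); it is the yardstick trained hybrid models are compared against.
    """
    model = model or GroundTruthModel()
    rates = model.specific_rates(dataset.species)
    num = 0.0
    T = 0
    for exp in dataset.experiments:
        traj = integrate_rk4(
            rates, dataset.species, exp.initial_state(), exp.streams, exp.times,
            substep=substep, record_rates=False,
        )
        meas = exp.measured
        r = (exp.values[meas] - traj.conc[meas]) / exp.sigmas[meas]
        num += float(r @ r)
        T += r.size
    return num / T


def make_experimental_style_dataset(
    n_experiments: int = 24,
    seed: int = 0,
    horizon: float = 288.0,
    sampling: float = 24.0,
    v0: float = 0.25,
    substep: float = 0.5,
    missing_fraction: float = 0.0,
) -> ExperimentDataset:
    """A 30-variable dataset with the shape of a process-development campaign.

    Daily samples over ~12 days for ``n_experiments`` independent runs of a
    30-species variant of the ground-truth model (extra first-order by-product
    pools), with per-experiment randomized feed rates (+-50% around the
    center) and feed compositions (+-20% jitter). Measurement noise and sigma
    tables follow the experimental-style relative rule: 5% for product P, 10%
    for Xv, 20% for the remaining metabolites, floored at 2% of cmax.
    """
    from .selection import ErrorModel

    rng = np.random.default_rng(seed)
    probe = SpeciesSet(EXPERIMENTAL_SPECIES, np.ones(len(EXPERIMENTAL_SPECIES)))
    model = GroundTruthModel()
    rates = model.specific_rates(probe)
    times = np.arange(0.0, horizon + 1e-9, sampling)
    c0 = _c0_vector(probe)

    runs = []
    for i in range(n_experiments):
        comp = {
            k: v * rng.uniform(0.8, 1.2) for k, v in _FEED.items() if k in probe.names
        }
        f_pre = 5e-4 * rng.uniform(0.5, 1.5)
        f_post = 1e-3 * rng.uniform(0.5, 1.5)
        stream = FeedStream(
            _feed_vector(probe, comp),
            ((0.0, model.t_induction, f_pre), (model.t_induction, horizon, f_post)),
        )
        try:
            traj = integrate_rk4(
                rates, probe, ProcessState(c0.copy(), v0, 0.0), [stream], times,
                substep=substep, record_rates=False,
            )
        except Exception as exc:  # noqa: BLE001
            raise GenerationError(f"run {i} failed: {exc}") from exc
        runs.append((f"r{i + 1}", np.maximum(traj.conc, 0.0), stream, traj.volume))

    all_conc = np.concatenate([r[1] for r in runs])
    cmax = np.maximum(all_conc.max(axis=0), 1e-9)
    species = SpeciesSet(EXPERIMENTAL_SPECIES, cmax)
    err = ErrorModel.relative({"P": 0.05, "Xv": 0.10}, default_fraction=0.20)

    experiments = []
    for exp_id, truth_conc, stream, _vol in runs:
        sig_true = err.sigmas(truth_conc, species)
        noisy = truth_conc + rng.normal(0.0, 1.0, size=truth_conc.shape) * sig_true
        if missing_fraction > 0:
            drop = rng.random(noisy.shape) < missing_fraction
            drop[0, :] = False  # keep the initial sample complete
            noisy = np.where(drop, np.nan, noisy)
        sig = err.sigmas(np.where(np.isnan(noisy), truth_conc, np.abs(noisy)), species)
        experiments.append(
            Experiment(
                id=exp_id, times=times.copy(), values=noisy, sigmas=sig,
                c0=c0.copy(), v0=v0, streams=(stream,),
            )
        )
    vmax = max(float(r[3].max()) for r in runs)
    return ExperimentDataset(
        species,
        experiments,
        provenance={
            "generator": "experimental_style",
            "noise": "relative_5_10_20",
            "seed": seed,
            "volume_max": vmax,
        },
    )
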