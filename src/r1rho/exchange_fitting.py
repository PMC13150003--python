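"""Multi-state exchange fitting of R1rho dispersion data.

Dispersion datasets (R1rho or R2eff versus spinlock power and offset) are
fitted to two- and three-state exchange models.  The model prediction at
each point is the eigenvalue R1rho of the exchange-only Bloch-McConnell
generator (the eigenvalue whose eigenvector tracks the tilted-frame
magnetisation; on near-degeneracy, the least negative real part).
Minimisation is weighted Levenberg-Marquardt (lmfit) with multi-start
initialisation; uncertainties come from Monte-Carlo resampling of the data;
nested models are ranked by AICc, BIC (difference >= 10) and an F-test at
the 95% confidence level.

Topologies, with a = ground state, b/c = minor states:

    two_state   a-b
    linear      a-b-c        (chain: c exchanges only through b)
    star        b-a-c        (both minor states exchange with the ground)
    triangular  a-b, a-c, b-c

Each edge carries one total exchange rate k_ex = k_ij + k_ji; directed rates
follow detailed balance from the global populations, so cyclic topologies
are cycle-consistent by construction.  Minor-state offsets dw are in Hz
relative to the ground state (fixed at 0); one shared R1 and one shared R2
across states per spin by default.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import lmfit
import numpy as np
import pandas as pd
import scipy.stats

from .bloch_mcconnell import TWO_PI, build_exchange_generators, r1rho_eigen_batch

__all__ = [
    "TOPOLOGIES",
    "NESTED_PAIRS",
    "A2_WT_T9_TRIANGULAR",
    "A2_P16_LINEAR",
    "DispersionDataset",
    "ExchangeModelSpec",
    "FitResult",
    "ModelComparison",
    "model_r1rho",
    "simulate_dispersion_dataset",
    "default_fit_grid",
    "recovery_experiment",
    "fit_model",
    "mc_parameter_errors",
    "information_criteria",
    "compare_models",
]

# edge index pairs (state order: a=0, b=1, c=2) and edge parameter names
TOPOLOGIES: dict[str, list[tuple[int, int, str]]] = {
    "two_state": [(0, 1, "kex_ab")],
    "linear": [(0, 1, "kex_ab"), (1, 2, "kex_bc")],
    "star": [(0, 1, "kex_ab"), (0, 2, "kex_ac")],
    "triangular": [(0, 1, "kex_ab"), (0, 2, "kex_ac"), (1, 2, "kex_bc")],
}

# nesting relations used by the F-test (simpler, richer)
NESTED_PAIRS = {
    ("two_state", "linear"),
    ("two_state", "star"),
    ("two_state", "triangular"),
    ("linear", "triangular"),
    ("star", "triangular"),
}

# Reference parameter sets for the A2 DNA WCF/HG/ES2 system (state b = HG,
# state c = ES2), used as generating conditions for recovery experiments.
A2_WT_T9_TRIANGULAR: dict[str, float] = {
    "kex_ab": 2700.0,  # WCF <-> HG, s^-1
    "kex_ac": 500.0,  # WCF <-> ES2, s^-1
    "kex_bc": 3200.0,  # HG <-> ES2, s^-1
    "p_b": 0.006,
    "p_c": 0.009,
    "dw_b": -593.0,  # Hz
    "dw_c": 288.0,  # Hz
    "r1": 2.5,
    "r2": 22.5,
}

# Nebularine-substituted duplex: fast HG <-> ES2 edge and elevated ES2
# population; remaining parameters carried over from the wild-type set.
A2_P16_LINEAR: dict[str, float] = {
    "kex_ab": 2700.0,
    "kex_bc": 18000.0,
    "p_b": 0.006,
    "p_c": 0.193,
    "dw_b": -593.0,
    "dw_c": 288.0,
    "r1": 2.5,
    "r2": 22.5,
}

_DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "kex": (1.0, 2.0e5),
    "p": (1.0e-6, 0.5),
    "dw": (-10000.0, 10000.0),
    "r1": (0.01, 50.0),
    "r2": (0.1, 500.0),
}

# multi-start sampling ranges
_START_KEX = (50.0, 5.0e4)  # log-uniform
_START_P = (1.0e-4, 0.3)  # uniform
_START_DW = (-3000.0, 3000.0)  # uniform


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DispersionDataset:
    """Dispersion points for one spin.

    table columns: nu_sl_hz, offset_hz, value, sd.  observable_kind is
    'r1rho' or 'r2eff'; metadata may carry temperature / field annotations.
    """

    spin_label: str
    table: pd.DataFrame
    observable_kind: str = "r1rho"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"nu_sl_hz", "offset_hz", "value", "sd"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"table must have columns {sorted(required)}")
        if self.observable_kind not in ("r1rho", "r2eff"):
            raise ValueError(f"unknown observable_kind {self.observable_kind!r}")
        if np.any(self.table["sd"].to_numpy() <= 0):
            raise ValueError("all sd values must be > 0")

    @property
    def n_points(self) -> int:
        return len(self.table)


@dataclass(frozen=True)
class ExchangeModelSpec:
    """Fit-model definition: topology, bounds, fixed values, sharing.

    shared lists base parameter names estimated once across all datasets of
    a global fit; every other free parameter is duplicated per dataset.
    The default shares the kinetic parameters (edge rates and populations)
    while chemical shifts and relaxation rates stay spin-specific, the
    standard convention for global dispersion fits.
    """

    topology: str
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    fixed: dict[str, float] = field(default_factory=dict)
    shared: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if self.topology not in TOPOLOGIES:
            raise ValueError(f"unknown topology {self.topology!r}")

    @property
    def n_states(self) -> int:
        return 2 if self.topology == "two_state" else 3

    @property
    def param_names(self) -> list[str]:
        names = [name for _, _, name in TOPOLOGIES[self.topology]]
        if self.n_states == 2:
            names += ["p_b", "dw_b"]
        else:
            names += ["p_b", "p_c", "dw_b", "dw_c"]
        return names + ["r1", "r2"]

    @property
    def shared_names(self) -> frozenset[str]:
        if self.shared is not None:
            return self.shared
        return frozenset(n for n in self.param_names if n.startswith(("kex_", "p_")))

    def bound_for(self, name: str) -> tuple[float, float]:
        if name in self.bounds:
            return self.bounds[name]
        return _DEFAULT_BOUNDS[name.split("_")[0]]

    @property
    def symmetric_minor_states(self) -> bool:
        """Whether swapping the two minor states leaves the model invariant
        (true for triangular and star, not for the linear chain)."""
        return self.topology in ("triangular", "star")


@dataclass(frozen=True)
class FitResult:
    """Converged exchange fit: point estimates, uncertainties, statistics."""

    topology: str
    estimates: dict[str, float]
    stderr: dict[str, float]
    chi2: float
    n_points: int
    n_params: int
    aicc: float
    bic: float
    residuals: np.ndarray = field(repr=False)
    mc_sd: dict[str, float] | None = None
    n_starts: int = 0
    seed: int | None = None
    start_chi2: tuple[float, ...] = field(default_factory=tuple, repr=False)
    mc_n_failed: int = 0

    @property
    def red_chi2(self) -> float:
        return self.chi2 / max(self.n_points - self.n_params, 1)


@dataclass(frozen=True)
class ModelComparison:
    """Ranked candidate fits with the statistical evidence trail."""

    fits: tuple[FitResult, ...]
    f_tests: tuple[dict, ...]
    selected: FitResult
    justification: tuple[str, ...]
    disagreements: tuple[str, ...]


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------


def _unpack(topology: str, params: dict[str, float]):
    if topology == "two_state":
        p_b = params["p_b"]
        populations = np.array([1.0 - p_b, p_b])
        offsets = np.array([0.0, params["dw_b"]])
    else:
        p_b, p_c = params["p_b"], params["p_c"]
        populations = np.array([1.0 - p_b - p_c, p_b, p_c])
        offsets = np.array([0.0, params["dw_b"], params["dw_c"]])
    edges = [(i, j, params[name]) for i, j, name in TOPOLOGIES[topology]]
    return populations, offsets, edges


def model_r1rho(
    topology: str,
    params: dict[str, float],
    nu_sl: np.ndarray,
    offsets_hz: np.ndarray,
    observable_kind: str = "r1rho",
) -> np.ndarray:
    """Predicted R1rho (or R2eff) at each (nu_SL, Omega) point.

    Builds the exchange-only generator per point, selects the dispersion
    eigenvalue, and optionally removes the R1 projection along the
    population-averaged tilted frame to obtain R2eff.
    """
    nu_sl = np.atleast_1d(np.asarray(nu_sl, dtype=float))
    offsets_hz = np.atleast_1d(np.asarray(offsets_hz, dtype=float))
    populations, state_offsets, edges = _unpack(topology, params)
    gens = build_exchange_generators(
        populations, state_offsets, params["r1"], params["r2"], edges, nu_sl, offsets_hz
    )
    n = populations.size
    w1 = TWO_PI * nu_sl
    obar = TWO_PI * (float(np.dot(populations, state_offsets)) - offsets_hz)
    weff = np.hypot(w1, obar)
    st, ct = w1 / weff, obar / weff
    m0 = np.zeros((nu_sl.size, 3 * n))
    idx = 3 * np.arange(n)
    m0[:, idx] = populations[None, :] * st[:, None]
    m0[:, idx + 2] = populations[None, :] * ct[:, None]
    r1rho = r1rho_eigen_batch(gens, m0)
    if observable_kind == "r1rho":
        return r1rho
    if observable_kind == "r2eff":
        sin2 = (st * st)
        cos2 = ct * ct
        return (r1rho - params["r1"] * cos2) / sin2
    raise ValueError(f"unknown observable_kind {observable_kind!r}")


def default_fit_grid() -> pd.DataFrame:
    """Spinlock grid used for recovery experiments: 15 on-resonance powers
    from 1 to 6 kHz plus off-resonance scans (+/-1.5 kHz, 21 offsets) at
    250, 500 and 1000 Hz spinlock power."""
    rows = [(nu, 0.0) for nu in np.linspace(1000.0, 6000.0, 15)]
    for nu in (250.0, 500.0, 1000.0):
        rows += [(nu, om) for om in np.linspace(-1500.0, 1500.0, 21)]
    return pd.DataFrame(rows, columns=["nu_sl_hz", "offset_hz"])


def simulate_dispersion_dataset(
    topology: str,
    params: dict[str, float],
    grid: pd.DataFrame | None = None,
    noise_pct: float = 2.0,
    seed: int | None = None,
    observable_kind: str = "r2eff",
    spin_label: str = "sim",
) -> DispersionDataset:
    """Generate a noisy dispersion dataset from known exchange parameters.

    Gaussian noise with standard deviation noise_pct/100 of the true value
    is added per point; the sd column records that scale, so weighted fits
    see the correct uncertainties.
    """
    if grid is None:
        grid = default_fit_grid()
    nu = grid["nu_sl_hz"].to_numpy(dtype=float)
    om = grid["offset_hz"].to_numpy(dtype=float)
    truth = model_r1rho(topology, params, nu, om, observable_kind)
    sd = np.abs(truth) * noise_pct / 100.0
    rng = np.random.default_rng(seed)
    values = truth + rng.normal(0.0, 1.0, size=truth.shape) * sd if noise_pct > 0 else truth
    table = pd.DataFrame(
        {
            "nu_sl_hz": nu,
            "offset_hz": om,
            "value": values,
            "sd": np.where(sd > 0, sd, 1.0),
        }
    )
    return DispersionDataset(
        spin_label=spin_label,
        table=table,
        observable_kind=observable_kind,
        metadata={"generating_topology": topology, "noise_pct": noise_pct, "seed": seed},
    )


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------
#
# Exchange rates and populations are minimised on a log10 scale: their
# plausible ranges span several decades and the log parameterisation keeps
# the Levenberg-Marquardt steps well scaled, which matters for locating the
# sparse second-minor-state basin.  Chemical shifts and relaxation rates
# stay linear.  Values reported in FitResult are always on the linear scale.


def _is_log(name: str) -> bool:
    return name.startswith(("kex_", "p_"))


def _param_key(name: str, spec: ExchangeModelSpec, label: str) -> str:
    return name if name in spec.shared_names else f"{name}__{label}"


def _dataset_params(
    values: dict[str, float], spec: ExchangeModelSpec, label: str
) -> dict[str, float]:
    return {name: values[_param_key(name, spec, label)] for name in spec.param_names}


def _build_parameters(
    spec: ExchangeModelSpec, datasets: list[DispersionDataset]
) -> lmfit.Parameters:
    params = lmfit.Parameters()
    seen: set[str] = set()
    for ds in datasets:
        for name in spec.param_names:
            key = _param_key(name, spec, ds.spin_label)
            if key in seen:
                continue
            seen.add(key)
            lo, hi = spec.bound_for(name)
            if _is_log(name):
                lo, hi = math.log10(lo), math.log10(hi)
            if name in spec.fixed:
                v = spec.fixed[name]
                params.add(key, value=math.log10(v) if _is_log(name) else v, vary=False)
            else:
                params.add(key, value=0.5 * (lo + hi), min=lo, max=hi)
    return params


def _linear_values(params: lmfit.Parameters) -> dict[str, float]:
    return {
        k: (10.0 ** float(v.value) if _is_log(k) else float(v.value))
        for k, v in params.items()
    }


def _residual(params: lmfit.Parameters, spec: ExchangeModelSpec, datasets) -> np.ndarray:
    values = _linear_values(params)
    out = []
    for ds in datasets:
        p = _dataset_params(values, spec, ds.spin_label)
        pred = model_r1rho(
            spec.topology,
            p,
            ds.table["nu_sl_hz"].to_numpy(),
            ds.table["offset_hz"].to_numpy(),
            ds.observable_kind,
        )
        out.append((ds.table["value"].to_numpy() - pred) / ds.table["sd"].to_numpy())
    return np.concatenate(out)


def _set_value(par, value: float, log: bool) -> None:
    v = math.log10(value) if log else value
    par.value = float(np.clip(v, par.min + 1e-12, par.max - 1e-12))


def _random_start(
    params: lmfit.Parameters,
    spec: ExchangeModelSpec,
    datasets: list[DispersionDataset],
    rng: np.random.Generator,
) -> None:
    obs_floor = min(float(ds.table["value"].min()) for ds in datasets)
    obs_floor = max(obs_floor, 1.0)
    for key, par in params.items():
        if not par.vary:
            continue
        base = key.split("__")[0].split("_")[0]
        if base == "kex":
            _set_value(
                par,
                math.exp(rng.uniform(math.log(_START_KEX[0]), math.log(_START_KEX[1]))),
                True,
            )
        elif base == "p":
            _set_value(par, rng.uniform(*_START_P), True)
        elif base == "dw":
            _set_value(par, rng.uniform(*_START_DW), False)
        elif base == "r1":
            _set_value(par, rng.uniform(0.5, 5.0), False)
        else:  # r2
            _set_value(par, obs_floor * rng.uniform(0.5, 1.2), False)


def _apply_anchor(
    params: lmfit.Parameters,
    spec: ExchangeModelSpec,
    labels: list[str],
    anchor: dict[tuple[str, str], float],
    slot: str,
) -> None:
    """Seed one minor state (slot 'b' or 'c') of a three-state start from a
    converged two-state fit; the other minor state stays at its random
    draw.  Anchor values are on the linear scale, keyed by (two-state base
    name, dataset label)."""
    edge = "kex_ab" if slot == "b" else ("kex_bc" if spec.topology == "linear" else "kex_ac")
    for lab in labels:
        mapping = {
            _param_key(f"p_{slot}", spec, lab): anchor[("p_b", lab)],
            _param_key(f"dw_{slot}", spec, lab): anchor[("dw_b", lab)],
            _param_key(edge, spec, lab): anchor[("kex_ab", lab)],
            _param_key("r1", spec, lab): anchor[("r1", lab)],
            _param_key("r2", spec, lab): anchor[("r2", lab)],
        }
        for key, value in mapping.items():
            par = params[key]
            if par.vary:
                _set_value(par, value, _is_log(key))


def _needs_swap(values: dict[str, float], spec: ExchangeModelSpec, labels: list[str]) -> bool:
    if not spec.symmetric_minor_states:
        return False
    dw_b = values.get(_param_key("dw_b", spec, labels[0]))
    dw_c = values.get(_param_key("dw_c", spec, labels[0]))
    return dw_b is not None and dw_c is not None and dw_b > dw_c


def _swap_minor_states(
    d: dict[str, float], spec: ExchangeModelSpec, labels: list[str]
) -> dict[str, float]:
    swapped = dict(d)
    swap_pairs = [("p_b", "p_c"), ("dw_b", "dw_c"), ("kex_ab", "kex_ac")]
    for na, nb in swap_pairs:
        for lab in labels:
            ka, kb = _param_key(na, spec, lab), _param_key(nb, spec, lab)
            if ka in d and kb in d:
                swapped[ka], swapped[kb] = d[kb], d[ka]
    return swapped


def _canonicalize(values: dict[str, float], spec: ExchangeModelSpec, labels: list[str]) -> dict:
    """Resolve the minor-state labelling degeneracy of symmetric topologies
    (triangular, star): order the two minor states by increasing (shared or
    first-dataset) chemical-shift offset."""
    if _needs_swap(values, spec, labels):
        return _swap_minor_states(values, spec, labels)
    return values


def _minimize(params, spec, datasets, max_nfev):
    res = lmfit.minimize(
        _residual, params, args=(spec, datasets), method="leastsq", max_nfev=max_nfev
    )
    return float(np.sum(np.asarray(res.residual) ** 2)), res


def fit_model(
    datasets: list[DispersionDataset] | DispersionDataset,
    spec: ExchangeModelSpec,
    n_starts: int = 20,
    seed: int | None = None,
    max_nfev: int = 4000,
    explore_nfev: int = 700,
    n_polish: int = 3,
) -> FitResult:
    """Weighted least-squares fit of one exchange model, staged multi-start.

    All datasets are fitted simultaneously; parameters listed in
    spec.shared_names are common, everything else is per dataset.  For a
    two-state model, n_starts random initialisations (log-uniform exchange
    rates, uniform populations and offsets) are explored.  Three-state
    models first run a short two-state prefit whose minor state seeds one
    slot of every start (alternating between the two minor-state slots)
    while the remaining state and edges stay at their random draws -- a
    staged strategy that reliably locates the sparse second-state basin
    where flat random restarts stall.  Every start is explored with a
    bounded Levenberg-Marquardt budget and the best few are polished to
    convergence; the best-chi-squared result wins.
    """
    if isinstance(datasets, DispersionDataset):
        datasets = [datasets]
    if len(datasets) == 0:
        raise ValueError("need at least one dataset")
    params = _build_parameters(spec, datasets)
    k_free = sum(1 for p in params.values() if p.vary)
    n_total = sum(ds.n_points for ds in datasets)
    for ds in datasets:
        if ds.n_points < k_free + 2:
            raise ValueError(
                f"dataset {ds.spin_label!r}: {ds.n_points} points cannot constrain "
                f"{k_free} free parameters (need >= {k_free + 2})"
            )
    rng = np.random.default_rng(seed)
    labels = [ds.spin_label for ds in datasets]

    anchor = None
    if spec.topology != "two_state":
        prefit_spec = ExchangeModelSpec(
            topology="two_state",
            bounds=spec.bounds,
            fixed={k: v for k, v in spec.fixed.items() if k in ("kex_ab", "p_b", "dw_b", "r1", "r2")},
            shared=None,
        )
        try:
            prefit = fit_model(
                datasets,
                prefit_spec,
                n_starts=max(8, n_starts // 2),
                seed=int(rng.integers(2**31)),
                explore_nfev=500,
                n_polish=2,
            )
            anchor = {
                (name, lab): _dataset_params(prefit.estimates, prefit_spec, lab)[name]
                for lab in labels
                for name in prefit_spec.param_names
            }
        except Exception:
            anchor = None  # fall back to flat random starts

    explored = []
    failures = []
    for i in range(max(n_starts, 1)):
        _random_start(params, spec, datasets, rng)
        if anchor is not None:
            _apply_anchor(params, spec, labels, anchor, "b" if i % 2 == 0 else "c")
        try:
            chi2, res = _minimize(params, spec, datasets, explore_nfev)
            explored.append((chi2, res))
        except Exception as exc:
            failures.append(str(exc))
    if not explored:
        raise RuntimeError(f"all {n_starts} starts failed: {failures}")
    explored.sort(key=lambda t: t[0])
    best = None
    for chi2, res in explored[: max(n_polish, 1)]:
        try:
            chi2p, resp = _minimize(res.params, spec, datasets, max_nfev)
        except Exception:
            chi2p, resp = chi2, res
        if best is None or chi2p < best[0]:
            best = (chi2p, resp)
    chi2, res = best
    values = _linear_values(res.params)
    stderr = {}
    for k, v in res.params.items():
        if not v.vary:
            continue
        if v.stderr is None:
            stderr[k] = float("nan")
        elif _is_log(k):
            stderr[k] = float(v.stderr) * math.log(10.0) * values[k]
        else:
            stderr[k] = float(v.stderr)
    if _needs_swap(values, spec, labels):
        values = _swap_minor_states(values, spec, labels)
        stderr = _swap_minor_states(stderr, spec, labels)
    aicc, bic = information_criteria(chi2, n_total, k_free)
    return FitResult(
        topology=spec.topology,
        estimates=values,
        stderr=stderr,
        chi2=chi2,
        n_points=n_total,
        n_params=k_free,
        aicc=aicc,
        bic=bic,
        residuals=np.asarray(res.residual),
        n_starts=n_starts,
        seed=seed,
        start_chi2=tuple(c for c, _ in explored),
    )


def mc_parameter_errors(
    fit: FitResult,
    datasets: list[DispersionDataset] | DispersionDataset,
    spec: ExchangeModelSpec,
    n_replicas: int = 500,
    seed: int | None = None,
    max_nfev: int = 2000,
) -> FitResult:
    """Monte-Carlo parameter uncertainties for a converged fit.

    Each replica redraws every observable from Normal(value, sd), refits
    from the point estimates (single start), and the per-parameter standard
    deviation across replicas is recorded as mc_sd.  More than 10% replica
    failures raise.  Deterministic for a fixed seed.
    """
    if isinstance(datasets, DispersionDataset):
        datasets = [datasets]
    rng = np.random.default_rng(seed)
    params = _build_parameters(spec, datasets)
    labels = [ds.spin_label for ds in datasets]
    samples: dict[str, list[float]] = {k: [] for k, p in params.items() if p.vary}
    failed = 0
    for _ in range(n_replicas):
        fake_sets = []
        for ds in datasets:
            tab = ds.table.copy()
            tab["value"] = tab["value"].to_numpy() + rng.normal(
                0.0, 1.0, size=len(tab)
            ) * tab["sd"].to_numpy()
            fake_sets.append(
                DispersionDataset(ds.spin_label, tab, ds.observable_kind, ds.metadata)
            )
        for k, p in params.items():
            if p.vary:
                _set_value(p, fit.estimates[k], _is_log(k))
        try:
            _, res = _minimize(params, spec, fake_sets, max_nfev)
            values = _canonicalize(_linear_values(res.params), spec, labels)
            for k in samples:
                samples[k].append(values[k])
        except Exception:
            failed += 1
    if failed > 0.1 * n_replicas:
        raise RuntimeError(f"{failed}/{n_replicas} Monte-Carlo replicas failed")
    mc_sd = {k: float(np.std(v, ddof=1)) for k, v in samples.items() if len(v) > 1}
    return dataclasses.replace(fit, mc_sd=mc_sd, mc_n_failed=failed)


def recovery_experiment(
    topology: str,
    params: dict[str, float],
    n_seeds: int = 10,
    noise_pct: float = 2.0,
    n_starts: int = 20,
    n_replicas: int = 50,
    seed: int = 1,
    grid: pd.DataFrame | None = None,
    observable_kind: str = "r2eff",
    fixed: dict[str, float] | None = None,
) -> dict:
    """Parameter-recovery harness: simulate -> fit -> Monte-Carlo, repeated.

    For each of n_seeds independent noise realisations a dispersion dataset
    is generated from the given parameter set, fitted with the staged
    multi-start, and Monte-Carlo uncertainties are estimated.  R1 is fixed
    at its generating value by default: the R2eff transform removes the R1
    projection, leaving R1 unidentifiable from R2eff data, as it would be
    determined by an independent measurement in practice.

    Returns a dict with per-seed estimates / mc sds and, per parameter, the
    median recovered value plus the count of seeds whose estimate lies
    within 3 Monte-Carlo standard deviations of the truth.
    """
    if fixed is None:
        fixed = {"r1": params["r1"]}
    spec = ExchangeModelSpec(topology, fixed=fixed)
    free_names = [n for n in spec.param_names if n not in fixed]
    per_seed = []
    ss = np.random.SeedSequence(seed)
    for child in ss.spawn(n_seeds):
        rng = np.random.default_rng(child)
        s_data, s_fit, s_mc = (int(x) for x in rng.integers(2**31, size=3))
        ds = simulate_dispersion_dataset(
            topology, params, grid=grid, noise_pct=noise_pct, seed=s_data,
            observable_kind=observable_kind,
        )
        fit = fit_model(ds, spec, n_starts=n_starts, seed=s_fit)
        fit = mc_parameter_errors(fit, ds, spec, n_replicas=n_replicas, seed=s_mc)
        est, sd = {}, {}
        for name in free_names:
            key = name if name in fit.estimates else f"{name}__{ds.spin_label}"
            est[name] = fit.estimates[key]
            sd[name] = fit.mc_sd.get(key, float("nan"))
        per_seed.append(
            {"estimates": est, "mc_sd": sd, "chi2": fit.chi2, "fit": fit, "dataset": ds}
        )
    summary = {}
    for name in free_names:
        vals = np.array([r["estimates"][name] for r in per_seed])
        truth = params.get(name)
        within = sum(
            abs(r["estimates"][name] - truth) <= 3.0 * r["mc_sd"][name]
            for r in per_seed
            if truth is not None and np.isfinite(r["mc_sd"][name])
        )
        summary[name] = {
            "median": float(np.median(vals)),
            "truth": truth,
            "n_within_3sd": int(within),
            "n_seeds": n_seeds,
        }
    return {"topology": topology, "per_seed": per_seed, "summary": summary}


# ---------------------------------------------------------------------------
# model selection
# ---------------------------------------------------------------------------


def information_criteria(chi2: float, n_points: int, n_params: int) -> tuple[float, float]:
    """AICc and BIC under the Gaussian weighted-least-squares likelihood:

        AIC  = N ln(chi2 / N) + 2 k
        AICc = AIC + 2 k (k + 1) / (N - k - 1)
        BIC  = N ln(chi2 / N) + k ln N
    """
    if n_points <= n_params + 1:
        raise ValueError("AICc undefined for N <= k + 1")
    chi2 = max(chi2, 1e-300)
    aic = n_points * math.log(chi2 / n_points) + 2 * n_params
    aicc = aic + 2 * n_params * (n_params + 1) / (n_points - n_params - 1)
    bic = n_points * math.log(chi2 / n_points) + n_params * math.log(n_points)
    return aicc, bic


def _f_test(simple: FitResult, rich: FitResult) -> dict:
    """F-test for a nested model pair; p < alpha favours the richer model."""
    dk = rich.n_params - simple.n_params
    dof = rich.n_points - rich.n_params
    if dk <= 0 or dof <= 0:
        raise ValueError("F-test requires k_rich > k_simple and N > k_rich")
    num = (simple.chi2 - rich.chi2) / dk
    den = rich.chi2 / dof
    F = num / den if den > 0 else float("inf")
    p = float(scipy.stats.f.sf(F, dk, dof)) if F > 0 else 1.0
    return {"simple": simple.topology, "rich": rich.topology, "F": F, "p": p}


def compare_models(
    fits: list[FitResult],
    alpha: float = 0.05,
    bic_threshold: float = 10.0,
) -> ModelComparison:
    """Rank candidate fits of the same data.

    A richer nested model replaces the incumbent only when all three rules
    agree: F-test p < alpha, BIC improves by >= bic_threshold, and AICc is
    lower.  Partial agreement is reported as a disagreement note without
    changing the selection.  Non-nested pairs skip the F-test; equal-size
    non-nested alternatives are ranked by AICc with BIC concurrence.  Ties
    fall to the model with fewest parameters.
    """
    if len(fits) < 2:
        raise ValueError("need at least two candidate fits")
    n0 = fits[0].n_points
    if any(f.n_points != n0 for f in fits):
        raise ValueError("all candidate fits must be on the same data")
    ordered = sorted(fits, key=lambda f: (f.n_params, f.chi2))
    f_tests = []
    justification = []
    disagreements = []
    selected = ordered[0]
    justification.append(
        f"start from simplest candidate {selected.topology} (k={selected.n_params})"
    )
    for cand in ordered[1:]:
        if cand.n_params == selected.n_params:
            if (cand.aicc < selected.aicc) and (cand.bic < selected.bic):
                justification.append(
                    f"{cand.topology} preferred over {selected.topology}: lower AICc and BIC "
                    "(non-nested pair, F-test skipped)"
                )
                selected = cand
            continue
        nested = (selected.topology, cand.topology) in NESTED_PAIRS
        if not nested:
            disagreements.append(
                f"F-test skipped for non-nested pair {selected.topology} vs {cand.topology}"
            )
            continue
        ft = _f_test(selected, cand)
        f_tests.append(ft)
        f_ok = ft["p"] < alpha
        dbic = selected.bic - cand.bic
        bic_ok = dbic >= bic_threshold
        aicc_ok = cand.aicc < selected.aicc
        if f_ok and bic_ok and aicc_ok:
            justification.append(
                f"{cand.topology} preferred over {selected.topology}: "
                f"F-test p={ft['p']:.3g} < {alpha}, dBIC={dbic:.1f} >= {bic_threshold}, "
                f"dAICc={selected.aicc - cand.aicc:.1f} > 0"
            )
            selected = cand
        else:
            verdicts = [f"F-test {'favours' if f_ok else 'rejects'} (p={ft['p']:.3g})",
                        f"dBIC={dbic:.1f} ({'>=' if bic_ok else '<'} {bic_threshold})",
                        f"AICc {'favours' if aicc_ok else 'rejects'}"]
            msg = f"{cand.topology} vs {selected.topology}: " + "; ".join(verdicts)
            if f_ok or bic_ok or aicc_ok:
                disagreements.append("rules disagree - " + msg)
            justification.append(f"retain {selected.topology} ({msg})")
    return ModelComparison(
        fits=tuple(ordered),
        f_tests=tuple(f_tests),
        selected=selected,
        justification=tuple(justification),
        disagreements=tuple(disagreements),
    )
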