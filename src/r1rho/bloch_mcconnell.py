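"""Bloch-McConnell generators for exchanging spin systems under a spinlock.

The rotating-frame evolution of an n-site exchange network is written as a
homogeneous linear system dM/dt = L M over the basis

    {I_x, I_y, I_z} per exchange site              (dimension 3 n)

optionally extended by a dipolar-coupled neighbour proton replicated in every
site,

    {S_x, S_y, S_z} per exchange site              (dimension 6 n)

Per-site blocks carry the resonance offset relative to the spinlock carrier,
the spinlock nutation (RF field along +x) and the auto-relaxation rates;
chemical exchange couples identical operators across sites with
detailed-balance rates; dipolar cross-relaxation couples I_z with S_z
(rate -sigma) and I_x/I_y with S_x/S_y (rate -mu), with site-specific rates
because exchange can modulate the interproton distance.

R1rho is extracted either from the eigenvalue spectrum of the exchange-only
generator (the fitting route) or from mono-exponential decay fits of
propagated spinlock trajectories (the simulation route, which accommodates
the dipolar partner).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .spin_physics import RelaxationRates, TumblingModel, dipolar_rates

TWO_PI = 2.0 * math.pi

__all__ = [
    "SiteState",
    "DipolarPartner",
    "ExchangeNetwork",
    "SpinlockSchedule",
    "TiltedFrameGeometry",
    "tilted_frame_geometry",
    "build_generator",
    "build_exchange_generators",
    "propagate",
    "propagate_trajectory",
    "simulate_spinlock_experiment",
    "r1rho_from_eigenvalue",
    "r1rho_eigen_batch",
    "r1rho_from_decay",
    "r2eff_transform",
    "r1rho_from_r2eff",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SiteState:
    """One conformer of the observed spin.

    offset is the chemical-shift offset of this state from the ground-state
    resonance in Hz (Delta omega / 2 pi); positive means downfield of the
    reference.  r1/r2 in s^-1.
    """

    label: str
    population: float
    offset: float
    r1: float
    r2: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.population <= 1.0):
            raise ValueError(f"population of {self.label} must be in [0, 1]")
        if not (self.r1 > 0):
            raise ValueError(f"r1 of {self.label} must be > 0")
        if self.r2 < self.r1:
            raise ValueError(f"r2 of {self.label} must be >= r1")


@dataclass(frozen=True)
class DipolarPartner:
    """Neighbour proton dipolar-coupled to the observed spin.

    distance_per_site maps every exchange-state label to the interproton
    distance in Angstrom in that state.  initial_mode controls whether the
    alignment pulse of the spinlock element touches the partner:
    'selective' leaves it at +z equilibrium, 'nonselective' rotates it
    together with the observed spin.
    """

    offset: float
    r1: float
    r2: float
    distance_per_site: dict[str, float]
    initial_mode: str = "selective"

    def __post_init__(self) -> None:
        if self.initial_mode not in ("selective", "nonselective"):
            raise ValueError(f"unknown initial_mode {self.initial_mode!r}")
        for label, r in self.distance_per_site.items():
            if not (r > 0):
                raise ValueError(f"distance for state {label!r} must be > 0")
        if not (self.r1 > 0 and self.r2 >= self.r1):
            raise ValueError("partner rates must satisfy r1 > 0 and r2 >= r1")


class ExchangeNetwork:
    """Exchange states plus edge rates k_ex = k_ij + k_ji.

    Edges are given as a mapping from an (unordered) pair of state labels to
    the total exchange rate of that edge in s^-1.  Directed rates follow
    detailed balance: k_ij = k_ex * p_j / (p_i + p_j).
    """

    def __init__(
        self,
        states: list[SiteState],
        edges: dict[tuple[str, str], float],
        topology_tag: str = "generic",
    ) -> None:
        labels = [s.label for s in states]
        if len(set(labels)) != len(labels):
            raise ValueError("state labels must be unique")
        ptot = sum(s.population for s in states)
        if abs(ptot - 1.0) > 1e-9:
            raise ValueError(f"populations must sum to 1 (got {ptot})")
        norm_edges: dict[frozenset, float] = {}
        for (a, b), kex in edges.items():
            if a not in labels or b not in labels or a == b:
                raise ValueError(f"invalid edge ({a!r}, {b!r})")
            if not (kex > 0):
                raise ValueError(f"edge ({a}, {b}): k_ex must be > 0")
            norm_edges[frozenset((a, b))] = float(kex)
        # connectivity
        if len(states) > 1:
            seen = {labels[0]}
            frontier = [labels[0]]
            while frontier:
                cur = frontier.pop()
                for e in norm_edges:
                    if cur in e:
                        (other,) = e - {cur}
                        if other not in seen:
                            seen.add(other)
                            frontier.append(other)
            if seen != set(labels):
                raise ValueError("exchange network must be connected")
        self.states = list(states)
        self.edges = norm_edges
        self.topology_tag = topology_tag
        self._index = {lab: i for i, lab in enumerate(labels)}

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.states]

    @property
    def populations(self) -> np.ndarray:
        return np.array([s.population for s in self.states])

    @property
    def offsets(self) -> np.ndarray:
        """State offsets from the ground-state resonance, Hz."""
        return np.array([s.offset for s in self.states])

    def rate_matrix(self) -> np.ndarray:
        """Directed rates K[i, j] = k_{i->j} in s^-1 (detailed balance)."""
        n = self.n_states
        p = self.populations
        K = np.zeros((n, n))
        for pair, kex in self.edges.items():
            a, b = sorted(pair, key=lambda lab: self._index[lab])
            i, j = self._index[a], self._index[b]
            psum = p[i] + p[j]
            if psum <= 0:
                continue  # edge between two unpopulated states carries no flux
            K[i, j] = kex * p[j] / psum
            K[j, i] = kex * p[i] / psum
        return K

    def kinetic_matrix(self) -> np.ndarray:
        """Exchange generator E with dm/dt = E m for any spin operator;
        E[i, j] = k_{j->i} off-diagonal, columns sum to zero."""
        K = self.rate_matrix()
        E = K.T.copy()
        np.fill_diagonal(E, -K.sum(axis=1))
        return E


@dataclass(frozen=True)
class SpinlockSchedule:
    """One spinlock condition: RF amplitude nu_SL (Hz), carrier offset
    Omega_SL (Hz, relative to the ground-state resonance), and the list of
    spinlock durations tau_SL in seconds."""

    power: float
    offset: float
    durations: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (self.power > 0):
            raise ValueError("spinlock power must be > 0")
        if len(self.durations) == 0:
            raise ValueError("durations must be non-empty")
        if any(d < 0 for d in self.durations):
            raise ValueError("durations must be non-negative")


@dataclass(frozen=True)
class TiltedFrameGeometry:
    """Effective-field amplitude (rad/s) and tilt angle theta (rad) with
    theta = arctan(omega_SL / |Omega_bar|), Omega_bar being the reference
    offset of the observed spin relative to the carrier."""

    omega_eff: float
    theta: float


def tilted_frame_geometry(
    network: ExchangeNetwork,
    power: float,
    offset: float,
    average: str = "population",
) -> TiltedFrameGeometry:
    """Tilted-frame geometry at one spinlock condition.

    average='population' uses the population-averaged resonance offset,
    'ground' uses the ground-state (first state) offset only.
    """
    w1 = TWO_PI * power
    if average == "population":
        obar = TWO_PI * float(np.dot(network.populations, network.offsets - offset))
    elif average == "ground":
        obar = TWO_PI * (network.states[0].offset - offset)
    else:
        raise ValueError(f"unknown average mode {average!r}")
    weff = math.hypot(w1, obar)
    theta = math.atan2(w1, abs(obar))
    return TiltedFrameGeometry(omega_eff=weff, theta=theta)


def _signed_tilt(network: ExchangeNetwork, power: float, offset: float) -> tuple[float, float]:
    """(sin, cos) of the signed tilt angle of the average effective field;
    cos carries the sign of the average offset."""
    w1 = TWO_PI * power
    obar = TWO_PI * float(np.dot(network.populations, network.offsets - offset))
    weff = math.hypot(w1, obar)
    return w1 / weff, obar / weff


# ---------------------------------------------------------------------------
# generator construction
# ---------------------------------------------------------------------------


def _site_block(delta: float, w1: float, r1: float, r2: float) -> np.ndarray:
    """3x3 single-spin Bloch block for basis (x, y, z): precession delta about
    +z, nutation w1 about +x, relaxation toward zero."""
    return np.array(
        [
            [-r2, -delta, 0.0],
            [delta, -r2, -w1],
            [0.0, w1, -r1],
        ]
    )


def build_generator(
    network: ExchangeNetwork,
    power: float,
    offset: float,
    partner: DipolarPartner | None = None,
    tumbling: TumblingModel | None = None,
    sigma_scale: float = 1.0,
    mu_scale: float = 1.0,
    additive_auto: bool = False,
    thermal_recovery: bool = False,
) -> np.ndarray:
    """Assemble the evolution generator L with dM/dt = L M.

    Basis ordering: [I_x, I_y, I_z] for each site in network order, then
    (if a partner is present) [S_x, S_y, S_z] for each site.  sigma_scale /
    mu_scale rescale the cross-relaxation rates (0 disables them), used to
    dissect artifact contributions.  additive_auto adds the computed dipolar
    auto-relaxation rho1/rho2 on top of the user-specified R1/R2 (off by
    default: fixed input rates are taken as already containing them).

    By default relaxation is homogeneous (decay toward zero), the natural
    frame for a decay-rate measurement.  thermal_recovery=True instead
    returns the augmented (dim+1) matrix whose inhomogeneous term restores
    the thermal equilibrium magnetisation (+z scaled by site populations);
    propagate vectors extended with a trailing 1.
    """
    n = network.n_states
    w1 = TWO_PI * power
    E = network.kinetic_matrix()
    ex = np.kron(E, np.eye(3))

    if partner is not None:
        if tumbling is None:
            raise ValueError("tumbling model required when a dipolar partner is present")
        missing = [lab for lab in network.labels if lab not in partner.distance_per_site]
        if missing:
            raise ValueError(f"partner distances missing for states {missing}")
        rates = [
            dipolar_rates(partner.distance_per_site[lab], tumbling).scaled(sigma_scale, mu_scale)
            for lab in network.labels
        ]
    else:
        rates = None

    dim = 3 * n if partner is None else 6 * n
    L = np.zeros((dim, dim))
    L[: 3 * n, : 3 * n] += ex
    for i, site in enumerate(network.states):
        delta = TWO_PI * (site.offset - offset)
        r1, r2 = site.r1, site.r2
        if additive_auto and rates is not None:
            r1 = r1 + rates[i].rho1_dip
            r2 = r2 + rates[i].rho2_dip
        L[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] += _site_block(delta, w1, r1, r2)

    if partner is not None:
        assert rates is not None
        off = 3 * n
        L[off:, off:] += ex
        delta_s = TWO_PI * (partner.offset - offset)
        for i in range(n):
            r1s, r2s = partner.r1, partner.r2
            if additive_auto:
                r1s = r1s + rates[i].rho1_dip
                r2s = r2s + rates[i].rho2_dip
            L[off + 3 * i : off + 3 * i + 3, off + 3 * i : off + 3 * i + 3] += _site_block(
                delta_s, w1, r1s, r2s
            )
            # cross-relaxation couples identical transverse / longitudinal
            # operators of the two spins within the same exchange site
            mu_i, sg_i = rates[i].mu, rates[i].sigma
            for c, rate in ((0, mu_i), (1, mu_i), (2, sg_i)):
                L[3 * i + c, off + 3 * i + c] += -rate
                L[off + 3 * i + c, 3 * i + c] += -rate

    if not np.all(np.isfinite(L)):
        raise ValueError("generator contains non-finite entries")
    if thermal_recovery:
        m_eq = np.zeros(dim)
        idx = 3 * np.arange(n) + 2
        m_eq[idx] = network.populations
        if partner is not None:
            m_eq[3 * n + idx] = network.populations
        aug = np.zeros((dim + 1, dim + 1))
        aug[:dim, :dim] = L
        aug[:dim, dim] = -L @ m_eq  # steady state = m_eq
        return aug
    return L


def build_exchange_generators(
    populations: np.ndarray,
    offsets_hz: np.ndarray,
    r1: np.ndarray | float,
    r2: np.ndarray | float,
    edges: list[tuple[int, int, float]],
    powers: np.ndarray,
    carrier_offsets: np.ndarray,
) -> np.ndarray:
    """Vectorised exchange-only generator stack, shape (N, 3n, 3n).

    Raw-array fast path used by the dispersion fitter: one generator per
    (power, carrier offset) pair, no dipolar partner.  edges are
    (i, j, k_ex) index triples.
    """
    populations = np.asarray(populations, dtype=float)
    offsets_hz = np.asarray(offsets_hz, dtype=float)
    powers = np.asarray(powers, dtype=float)
    carrier_offsets = np.asarray(carrier_offsets, dtype=float)
    n = populations.size
    N = powers.size
    r1 = np.broadcast_to(np.asarray(r1, dtype=float), (n,))
    r2 = np.broadcast_to(np.asarray(r2, dtype=float), (n,))

    K = np.zeros((n, n))
    for i, j, kex in edges:
        psum = populations[i] + populations[j]
        if psum <= 0:
            continue
        K[i, j] += kex * populations[j] / psum
        K[j, i] += kex * populations[i] / psum
    E = K.T.copy()
    np.fill_diagonal(E, -K.sum(axis=1))

    L = np.zeros((N, 3 * n, 3 * n))
    L += np.kron(E, np.eye(3))[None, :, :]
    idx = 3 * np.arange(n)
    w1 = TWO_PI * powers  # (N,)
    delta = TWO_PI * (offsets_hz[None, :] - carrier_offsets[:, None])  # (N, n)
    L[:, idx, idx] += -r2[None, :]
    L[:, idx + 1, idx + 1] += -r2[None, :]
    L[:, idx + 2, idx + 2] += -r1[None, :]
    L[:, idx, idx + 1] += -delta
    L[:, idx + 1, idx] += delta
    L[:, idx + 1, idx + 2] += -w1[:, None]
    L[:, idx + 2, idx + 1] += w1[:, None]
    return L


# ---------------------------------------------------------------------------
# propagation
# ---------------------------------------------------------------------------


def propagate(L: np.ndarray, m0: np.ndarray, tau: float) -> np.ndarray:
    """exp(L tau) m0 via scaling-and-squaring matrix exponential."""
    if tau < 0:
        raise ValueError("tau must be non-negative")
    if not np.all(np.isfinite(L)):
        raise ValueError("generator contains non-finite entries")
    return scipy.linalg.expm(L * tau) @ m0


def propagate_trajectory(L: np.ndarray, m0: np.ndarray, taus: np.ndarray) -> np.ndarray:
    """Magnetisation at each tau via eigendecomposition, shape (len(taus), dim).

    Agrees with repeated scaling-and-squaring exponentials to ~1e-10 relative
    for the well-conditioned generators arising here.
    """
    taus = np.asarray(taus, dtype=float)
    if np.any(taus < 0):
        raise ValueError("taus must be non-negative")
    w, V = np.linalg.eig(L)
    c = np.linalg.solve(V, m0.astype(complex))
    out = np.einsum("tk,jk->tj", np.exp(np.outer(taus, w)) * c[None, :], V)
    return out.real


def simulate_spinlock_experiment(
    network: ExchangeNetwork,
    schedule: SpinlockSchedule,
    partner: DipolarPartner | None = None,
    tumbling: TumblingModel | None = None,
    sigma_scale: float = 1.0,
    mu_scale: float = 1.0,
    additive_auto: bool = False,
) -> np.ndarray:
    """Simulate the spinlock pulse element and return intensities per tau_SL.

    Equilibrium z magnetisation of the observed spin (distributed across
    sites by population) is rotated into the plane of the effective field,
    evolved under the generator for each duration, rotated back, and the
    summed observed-spin z magnetisation is returned.  The partner starts at
    +z equilibrium (selective mode) or is rotated along (nonselective).
    """
    L = build_generator(
        network,
        schedule.power,
        schedule.offset,
        partner=partner,
        tumbling=tumbling,
        sigma_scale=sigma_scale,
        mu_scale=mu_scale,
        additive_auto=additive_auto,
    )
    n = network.n_states
    p = network.populations
    st, ct = _signed_tilt(network, schedule.power, schedule.offset)
    dim = L.shape[0]
    m0 = np.zeros(dim)
    idx = 3 * np.arange(n)
    m0[idx] = p * st
    m0[idx + 2] = p * ct
    if partner is not None:
        off = 3 * n
        if partner.initial_mode == "nonselective":
            m0[off + idx] = p * st
            m0[off + idx + 2] = p * ct
        else:
            m0[off + idx + 2] = p
    traj = propagate_trajectory(L, m0, np.asarray(schedule.durations))
    # return pulse projects the locked component back onto +z
    signal = traj[:, idx].sum(axis=1) * st + traj[:, idx + 2].sum(axis=1) * ct
    return signal


# ---------------------------------------------------------------------------
# R1rho extraction
# ---------------------------------------------------------------------------


def r1rho_eigen_batch(generators: np.ndarray, m0: np.ndarray) -> np.ndarray:
    """R1rho for a stack of exchange-only generators.

    For each generator the eigenvalue is selected whose eigenvector has
    maximal overlap with the initial tilted-frame magnetisation m0 (overlap
    weight |<m0|v_k><w_k|m0>|); on near-degeneracy (second weight > 0.999 of
    the first) the least negative real part among the two wins.  Returns
    -Re(lambda_selected), shape (N,).
    """
    w, V = np.linalg.eig(generators)
    c = np.linalg.solve(V, m0[..., None].astype(complex))[..., 0]
    proj = np.einsum("nm,nmk->nk", m0, V)
    weight = np.abs(proj * c)
    order = np.argsort(-weight, axis=1)
    rows = np.arange(weight.shape[0])
    top, second = order[:, 0], order[:, 1]
    near = weight[rows, second] > 0.999 * weight[rows, top]
    re_top = w.real[rows, top]
    re_sec = w.real[rows, second]
    sel = np.where(near & (re_sec > re_top), second, top)
    return -w.real[rows, sel]


def r1rho_from_eigenvalue(
    network: ExchangeNetwork, power: float, offset: float
) -> float:
    """Eigenvalue R1rho of the exchange-only system at one spinlock point.

    The dipolar partner is deliberately not supported here: dispersion
    fitting uses exchange-only matrices, and the simulator quantifies when
    that is safe.
    """
    edges = []
    for pair, kex in network.edges.items():
        a, b = sorted(pair, key=lambda lab: network._index[lab])
        edges.append((network._index[a], network._index[b], kex))
    gens = build_exchange_generators(
        network.populations,
        network.offsets,
        np.array([s.r1 for s in network.states]),
        np.array([s.r2 for s in network.states]),
        edges,
        np.array([power]),
        np.array([offset]),
    )
    n = network.n_states
    st, ct = _signed_tilt(network, power, offset)
    m0 = np.zeros((1, 3 * n))
    idx = 3 * np.arange(n)
    m0[0, idx] = network.populations * st
    m0[0, idx + 2] = network.populations * ct
    return float(r1rho_eigen_batch(gens, m0)[0])


def r1rho_from_decay(
    intensities: np.ndarray, durations: np.ndarray
) -> float:
    """Mono-exponential decay rate of a propagated / measured intensity curve.

    Unweighted least squares of I0 exp(-R tau); the noise-weighted variant
    lives in decay_analysis.  Requires >= 3 distinct durations.
    """
    intensities = np.asarray(intensities, dtype=float)
    durations = np.asarray(durations, dtype=float)
    if intensities.shape != durations.shape or intensities.size < 3:
        raise ValueError("need >= 3 matching (duration, intensity) points")
    if np.unique(durations).size < 3:
        raise ValueError("need >= 3 distinct durations")
    if np.any(intensities <= 0) or np.any(np.diff(intensities[np.argsort(durations)]) > 0):
        warnings.warn("non-monotone or non-positive intensities: decay fit may be unreliable")
    pos = intensities > 0
    slope, logi0 = np.polyfit(durations[pos], np.log(intensities[pos]), 1)
    p0 = (math.exp(logi0), -slope)
    from scipy.optimize import curve_fit

    popt, _ = curve_fit(
        lambda t, i0, r: i0 * np.exp(-r * t), durations, intensities, p0=p0, maxfev=10000
    )
    return float(popt[1])


def r2eff_transform(r1rho: float, r1_avg: float, geometry: TiltedFrameGeometry) -> float:
    """R2eff = (R1rho - R1 cos^2 theta) / sin^2 theta."""
    s2 = math.sin(geometry.theta) ** 2
    if s2 <= 0:
        raise ValueError("tilt angle theta = 0: R2eff undefined")
    return (r1rho - r1_avg * math.cos(geometry.theta) ** 2) / s2


def r1rho_from_r2eff(r2eff: float, r1_avg: float, geometry: TiltedFrameGeometry) -> float:
    """Inverse of r2eff_transform."""
    return r2eff * math.sin(geometry.theta) ** 2 + r1_avg * math.cos(geometry.theta) ** 2
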