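"""Mono-exponential decay fitting with per-spectrum noise weighting.

Peak intensities I(tau_SL) are fitted to I0 exp(-R tau) by weighted
least squares (Levenberg-Marquardt through lmfit), with per-point weights
1 / rms^2 where rms = I / (2 * sino) is the baseline noise of the spectrum
the point came from.  Parameter uncertainties follow from Monte-Carlo
resampling: each replica redraws every intensity from a normal distribution
centred on the fitted curve with the per-point rms as scale, is refitted,
and the standard deviation of the replica rates is reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np

__all__ = [
    "DecayCurve",
    "RateEstimate",
    "fit_decay",
    "monte_carlo_rate_sd",
    "fit_intensity_table",
]


@dataclass(frozen=True)
class DecayCurve:
    """One decay: spinlock durations (s), peak intensities (a.u.) and the
    exported signal-to-noise values, all of equal length >= 3."""

    durations: np.ndarray
    intensities: np.ndarray
    sino: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "durations", np.asarray(self.durations, dtype=float))
        object.__setattr__(self, "intensities", np.asarray(self.intensities, dtype=float))
        object.__setattr__(self, "sino", np.asarray(self.sino, dtype=float))
        n = self.durations.size
        if not (n >= 3 and self.intensities.size == n and self.sino.size == n):
            raise ValueError("durations, intensities, sino must share a length >= 3")
        if np.any(self.sino <= 0):
            raise ValueError("sino values must be > 0")
        if np.any(self.durations < 0):
            raise ValueError("durations must be non-negative")
        if np.unique(self.durations).size < 2:
            raise ValueError("durations must not all be equal")

    @property
    def rms(self) -> np.ndarray:
        """Per-point baseline noise, rms = I / (2 * sino)."""
        return np.abs(self.intensities) / (2.0 * self.sino)


@dataclass(frozen=True)
class RateEstimate:
    """Fitted decay rate with its uncertainty.

    sd is the Monte-Carlo standard deviation when n_replicas > 0, otherwise
    the asymptotic (covariance-based) standard error of the point fit.
    """

    rate: float
    sd: float
    amplitude: float
    n_replicas: int = 0
    n_failed: int = 0
    residuals: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)

    def __post_init__(self) -> None:
        if not np.isfinite(self.rate):
            raise ValueError("rate must be finite")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


def _initial_guess(curve: DecayCurve) -> tuple[float, float]:
    """Amplitude from the earliest point, rate from a log-linear regression
    of the positive intensities (robust starting point)."""
    order = np.argsort(curve.durations)
    i0 = curve.intensities[order][0]
    pos = curve.intensities > 0
    if pos.sum() >= 2 and np.unique(curve.durations[pos]).size >= 2:
        slope = np.polyfit(curve.durations[pos], np.log(curve.intensities[pos]), 1)[0]
        rate = -slope
    else:
        rate = 1.0 / max(curve.durations.max(), 1e-6)
    if rate <= 0:
        rate = 1e-3
    return float(i0), float(rate)


def fit_decay(curve: DecayCurve) -> RateEstimate:
    """Weighted least-squares fit of I0 exp(-R tau).

    Weights are 1/rms^2; a rising intensity series yields a warning and may
    return a negative rate.  Raises on non-convergence with residual
    diagnostics.
    """
    order = np.argsort(curve.durations)
    if np.any(np.diff(curve.intensities[order]) > 0) or np.any(curve.intensities <= 0):
        warnings.warn("non-monotone or non-positive intensities: rate may be unreliable")
    i0_guess, rate_guess = _initial_guess(curve)
    params = lmfit.Parameters()
    params.add("amplitude", value=i0_guess)
    params.add("rate", value=rate_guess)
    rms = curve.rms

    def residual(p):
        model = p["amplitude"].value * np.exp(-p["rate"].value * curve.durations)
        return (curve.intensities - model) / rms

    # weights are absolute 1-sigma uncertainties -> no red-chi2 rescaling
    result = lmfit.minimize(residual, params, method="leastsq", scale_covar=False)
    if not result.success:
        raise RuntimeError(
            f"decay fit failed: {result.message}; residuals={np.asarray(result.residual)}"
        )
    rate = float(result.params["rate"].value)
    stderr = result.params["rate"].stderr
    return RateEstimate(
        rate=rate,
        sd=float(stderr) if stderr is not None else 0.0,
        amplitude=float(result.params["amplitude"].value),
        n_replicas=0,
        residuals=np.asarray(result.residual),
    )


def monte_carlo_rate_sd(
    curve: DecayCurve,
    n_replicas: int = 500,
    seed: int | None = None,
    scheme: str = "parametric",
) -> RateEstimate:
    """Monte-Carlo uncertainty of the decay rate.

    scheme='parametric' (default) redraws intensities around the fitted
    curve with the per-point rms as the noise scale; scheme='residual'
    resamples the fit residuals with replacement instead.  Replicas that
    fail to converge are excluded; more than 10% exclusions raise.
    Deterministic for a fixed seed.
    """
    if n_replicas < 2:
        raise ValueError("n_replicas must be >= 2")
    if scheme not in ("parametric", "residual"):
        raise ValueError(f"unknown scheme {scheme!r}")
    point = fit_decay(curve)
    model = point.amplitude * np.exp(-point.rate * curve.durations)
    rms = curve.rms
    rng = np.random.default_rng(seed)
    rates = []
    failed = 0
    resid = curve.intensities - model
    for _ in range(n_replicas):
        if scheme == "parametric":
            fake = model + rng.normal(0.0, 1.0, size=model.shape) * rms
        else:
            fake = model + rng.choice(resid, size=resid.shape, replace=True)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rep = fit_decay(DecayCurve(curve.durations, fake, curve.sino))
            rates.append(rep.rate)
        except RuntimeError:
            failed += 1
    if failed > 0.1 * n_replicas:
        raise RuntimeError(f"{failed}/{n_replicas} Monte-Carlo replicas failed to converge")
    sd = float(np.std(rates, ddof=1)) if len(rates) > 1 else 0.0
    return RateEstimate(
        rate=point.rate,
        sd=sd,
        amplitude=point.amplitude,
        n_replicas=len(rates),
        n_failed=failed,
        residuals=point.residuals,
    )


def fit_intensity_table(
    table,
    n_replicas: int = 500,
    seed: int | None = None,
):
    """Fit every (power, offset) condition of an intensity table.

    The table needs columns power_hz, offset_hz, duration_s, intensity,
    sino (the plain-text export dialect).  Returns a pandas DataFrame with
    one row per condition: power_hz, offset_hz, r1rho, sd.  Monte-Carlo
    seeds are derived per condition from the master seed so the result is
    reproducible and independent of condition order.
    """
    import pandas as pd

    required = {"power_hz", "offset_hz", "duration_s", "intensity", "sino"}
    if not required.issubset(table.columns):
        raise ValueError(f"intensity table must have columns {sorted(required)}")
    rows = []
    for i, ((power, offset), grp) in enumerate(
        sorted(table.groupby(["power_hz", "offset_hz"]), key=lambda kv: kv[0])
    ):
        curve = DecayCurve(
            grp["duration_s"].to_numpy(),
            grp["intensity"].to_numpy(),
            grp["sino"].to_numpy(),
        )
        sub_seed = None
        if seed is not None:
            sub_seed = int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % 2**31)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = monte_carlo_rate_sd(curve, n_replicas=n_replicas, seed=sub_seed)
        rows.append((power, offset, est.rate, est.sd))
    return pd.DataFrame(rows, columns=["power_hz", "offset_hz", "r1rho", "sd"])
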