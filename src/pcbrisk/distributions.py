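"""Distribution specifications and lognormal moment matching.

Concentration data for persistent lipophilic residues are strictly positive
and right-skewed, so the synthetic generator models each congener as a
lognormal, optionally truncated to a printed [minimum, maximum] window.
Two fitting routines are provided:

``fit_lognormal_moments``
    Closed-form moment match of the *untruncated* lognormal: the fitted
    distribution has exactly the requested arithmetic mean and SD.

``fit_truncated_lognormal``
    Numeric moment match of the lognormal *after* truncation to a window:
    the truncated mean is matched exactly (the truncated mean is strictly
    increasing in ``mu``, so a 1-D root find suffices) and the truncated SD
    as closely as the window geometry allows. A narrow window bounds the
    achievable SD from above (a unimodal density on [L, U] cannot be more
    dispersed than roughly a uniform), so some requested SDs are
    unattainable; the fit then returns the closest achievable SD.

Exposure parameters (intake rate, body weight, ...) are described by small
``DistributionSpec`` objects supporting point, uniform, positive truncated
normal, and lognormal families.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping

import numpy as np
from scipy import optimize, special

from .errors import ConfigError, InvalidParameterError

__all__ = [
    "MomentSpec",
    "LognormalParams",
    "fit_lognormal_moments",
    "lognormal_moments",
    "truncated_lognormal_moments",
    "truncated_mass",
    "fit_truncated_lognormal",
    "sample_truncated_lognormal",
    "DistributionSpec",
]

_SQRT2 = math.sqrt(2.0)


def _phi(z: np.ndarray | float) -> np.ndarray | float:
    """Standard normal CDF."""
    return 0.5 * (1.0 + special.erf(np.asarray(z, dtype=float) / _SQRT2))


def _log_phi_diff(hi: float, lo: float) -> float:
    """log(Phi(hi) - Phi(lo)) for hi >= lo, stable in both tails.

    Works in log space and reflects to the complementary CDF when the
    interval sits in the upper tail, so far-tail differences keep full
    relative precision instead of cancelling.
    """
    if hi <= lo:
        return -math.inf
    if math.isfinite(hi) and math.isfinite(lo) and hi + lo > 0.0:
        hi, lo = -lo, -hi  # Phi(hi)-Phi(lo) == Phi(-lo)-Phi(-hi)
    lb = float(special.log_ndtr(hi))
    la = float(special.log_ndtr(lo)) if lo > -math.inf else -math.inf
    if la == -math.inf:
        return lb
    ratio = math.exp(min(la - lb, 0.0))
    if ratio >= 1.0:  # difference underflows: no resolvable mass in [lo, hi]
        return -math.inf
    return lb + math.log1p(-ratio)


@dataclasses.dataclass(frozen=True)
class MomentSpec:
    """Summary moments of one congener in one group: mean, SD and range.

    All values are concentrations in ng/g fat. ``minimum``/``maximum`` default
    to an unconstrained positive support.
    """

    mean: float
    sd: float
    minimum: float = 0.0
    maximum: float = math.inf

    def __post_init__(self) -> None:
        if not (self.mean > 0.0):
            raise InvalidParameterError(f"mean must be > 0, got {self.mean}")
        if not (self.sd >= 0.0):
            raise InvalidParameterError(f"sd must be >= 0, got {self.sd}")
        if not (self.minimum <= self.mean <= self.maximum):
            raise InvalidParameterError(
                f"require minimum <= mean <= maximum, got "
                f"[{self.minimum}, {self.maximum}] around {self.mean}"
            )

    def fit(self) -> "LognormalParams":
        """Lognormal parameters whose truncation to the range matches the moments."""
        return fit_truncated_lognormal(self.mean, self.sd, self.minimum, self.maximum)


@dataclasses.dataclass(frozen=True)
class LognormalParams:
    """Log-scale location ``mu`` and spread ``sigma`` (>= 0) of a lognormal."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.mu):
            raise InvalidParameterError(f"mu must be finite, got {self.mu}")
        if not (self.sigma >= 0.0):
            raise InvalidParameterError(f"sigma must be >= 0, got {self.sigma}")


def fit_lognormal_moments(mean: float, sd: float) -> LognormalParams:
    """Match a lognormal to an arithmetic mean and standard deviation.

    Uses the exact inversion ``sigma^2 = ln(1 + (sd/mean)^2)`` and
    ``mu = ln(mean) - sigma^2 / 2``; ``sd = 0`` degenerates to a point mass
    at ``mean``.

    Parameters
    ----------
    mean
        Target arithmetic mean, must be > 0.
    sd
        Target arithmetic standard deviation, must be >= 0.
    """
    if not (mean > 0.0):
        raise InvalidParameterError(f"mean must be > 0, got {mean}")
    if not (sd >= 0.0):
        raise InvalidParameterError(f"sd must be >= 0, got {sd}")
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return LognormalParams(mu=mu, sigma=math.sqrt(sigma2))


def lognormal_moments(params: LognormalParams) -> tuple[float, float]:
    """Arithmetic (mean, sd) of the untruncated lognormal."""
    mean = math.exp(params.mu + params.sigma**2 / 2.0)
    var = (math.exp(params.sigma**2) - 1.0) * mean**2
    return mean, math.sqrt(var)


def truncated_mass(params: LognormalParams, lower: float, upper: float) -> float:
    """Probability mass of the lognormal inside [lower, upper]."""
    if params.sigma == 0.0:
        return 1.0 if lower <= math.exp(params.mu) <= upper else 0.0
    a = (math.log(max(lower, 1e-300)) - params.mu) / params.sigma
    b = (math.log(upper) - params.mu) / params.sigma if math.isfinite(upper) else math.inf
    return float(_phi(b) - _phi(a))


def truncated_lognormal_moments(
    params: LognormalParams, lower: float, upper: float
) -> tuple[float, float]:
    """Arithmetic (mean, sd) of the lognormal restricted to [lower, upper].

    Closed form via partial expectations: with ``a, b`` the standardized log
    bounds and ``Z = Phi(b) - Phi(a)``,

    ``E[X]   = exp(mu + sigma^2/2)  * (Phi(b - sigma)  - Phi(a - sigma))  / Z``
    ``E[X^2] = exp(2mu + 2 sigma^2) * (Phi(b - 2sigma) - Phi(a - 2sigma)) / Z``
    """
    mu, sigma = params.mu, params.sigma
    if sigma == 0.0:
        x = math.exp(mu)
        if not (lower <= x <= upper):
            raise InvalidParameterError("point mass outside truncation window")
        return x, 0.0
    a = (math.log(lower) - mu) / sigma if lower > 0.0 else -math.inf
    b = (math.log(upper) - mu) / sigma if math.isfinite(upper) else math.inf
    log_z = _log_phi_diff(b, a)
    if log_z < -700.0:  # below exp() underflow: no resolvable mass
        raise InvalidParameterError("truncation window carries no mass")
    m1 = math.exp(mu + sigma**2 / 2.0 + _log_phi_diff(b - sigma, a - sigma) - log_z)
    m2 = math.exp(
        2.0 * mu + 2.0 * sigma**2 + _log_phi_diff(b - 2.0 * sigma, a - 2.0 * sigma) - log_z
    )
    var = max(m2 - m1**2, 0.0)
    return float(m1), math.sqrt(var)


def _mu_for_truncated_mean(sigma: float, mean: float, lower: float, upper: float) -> float:
    """Solve for mu so the [lower, upper]-truncated lognormal has the given mean.

    The truncated mean is strictly increasing in mu with range (lower, upper),
    so Brent's method on a widening bracket always succeeds for
    lower < mean < upper.
    """

    log_center = (
        0.5 * (math.log(max(lower, 1e-300)) + math.log(upper))
        if math.isfinite(upper)
        else math.log(mean)
    )

    def err(mu: float) -> float:
        try:
            m, _ = truncated_lognormal_moments(LognormalParams(mu, sigma), lower, upper)
        except InvalidParameterError:
            # mu so far from the window that no mass registers: the truncated
            # mean limits to the nearer endpoint, which fixes the sign
            m = lower if mu < log_center else upper
        return m - mean

    # the truncated mean approaches the endpoints on a sigma^2 scale in mu,
    # so expand the bracket by doubling steps
    lo, hi = math.log(mean) - 1.0, math.log(mean) + 1.0
    step = 1.0
    while err(lo) >= 0.0:
        lo -= step
        step *= 2.0
    step = 1.0
    while err(hi) <= 0.0:
        hi += step
        step *= 2.0
    return float(optimize.brentq(err, lo, hi, xtol=1e-13, rtol=8.9e-16))


def fit_truncated_lognormal(
    mean: float, sd: float, lower: float, upper: float, min_mass: float = 0.01
) -> LognormalParams:
    """Lognormal parameters whose truncation to [lower, upper] matches (mean, sd).

    The mean is matched exactly (to root-finder precision). The SD is matched
    exactly whenever it is achievable on the window, otherwise the closest
    achievable SD is used. The search over ``sigma`` is restricted to
    parameters that keep at least ``min_mass`` of the lognormal's mass inside
    the window, both to keep rejection sampling practical and because a
    narrow window bounds the achievable SD anyway (a unimodal density on
    [L, U] cannot exceed roughly the uniform SD).

    Raises
    ------
    InvalidParameterError
        If ``mean`` is not strictly inside (lower, upper), or bounds invalid.
    """
    if not (mean > 0.0):
        raise InvalidParameterError(f"mean must be > 0, got {mean}")
    if not (sd >= 0.0):
        raise InvalidParameterError(f"sd must be >= 0, got {sd}")
    if not (0.0 <= lower < upper):
        raise InvalidParameterError(f"invalid truncation window [{lower}, {upper}]")
    if not math.isfinite(upper) and lower <= 0.0:
        return fit_lognormal_moments(mean, sd)
    if not (lower < mean < upper) and not (lower <= mean <= upper and sd == 0.0):
        raise InvalidParameterError(
            f"mean {mean} must lie inside the truncation window ({lower}, {upper})"
        )
    if sd == 0.0:
        return LognormalParams(mu=math.log(mean), sigma=0.0)

    def solve(sigma: float) -> tuple[LognormalParams, float] | None:
        """Mean-matching params at this sigma, or None if infeasible."""
        try:
            mu = _mu_for_truncated_mean(sigma, mean, lower, upper)
            params = LognormalParams(mu, sigma)
            m, s = truncated_lognormal_moments(params, lower, upper)
        except InvalidParameterError:
            return None
        if abs(m - mean) > 1e-8 * mean:  # root finder stalled at a mass cliff
            return None
        if truncated_mass(params, lower, upper) < min_mass:
            return None
        return params, s

    # coarse scan of the feasible sigma range, then refine to an exact sd
    # match inside the first bracketing cell
    grid = np.geomspace(1e-4, 8.0, 40)
    feasible: list[tuple[float, LognormalParams, float]] = []
    for sigma in grid:
        res = solve(float(sigma))
        if res is not None:
            feasible.append((float(sigma), res[0], res[1]))
    if not feasible:  # cannot happen for mean inside the window; be safe
        raise InvalidParameterError(
            f"no feasible truncated lognormal for mean {mean} on [{lower}, {upper}]"
        )
    bracket = None
    for (s0, _, sd0), (s1, _, sd1) in zip(feasible, feasible[1:]):
        if (sd0 - sd) * (sd1 - sd) <= 0.0:
            bracket = (s0, s1)
            break
    if bracket is not None:
        sigma = float(
            optimize.brentq(
                lambda s: (r[1] if (r := solve(s)) else sd) - sd, *bracket, xtol=1e-12
            )
        )
        res = solve(sigma)
        if res is not None:
            return res[0]
    # no exact match achievable: take the feasible sigma closest in sd
    _, params, _ = min(feasible, key=lambda t: abs(t[2] - sd))
    return params


def sample_truncated_lognormal(
    params: LognormalParams,
    lower: float,
    upper: float,
    size: int,
    rng: np.random.Generator,
    min_mass: float = 1e-4,
) -> np.ndarray:
    """Draw from the lognormal restricted to [lower, upper] by rejection.

    Out-of-window draws are redrawn until the requested size is reached.
    Rejection keeps the draw mechanism identical to the unconstrained case;
    a window carrying less than ``min_mass`` of the distribution's mass
    (acceptance < 0.01%) is treated as infeasible.
    """
    from .errors import GenerationError

    if upper < lower:
        raise GenerationError(f"infeasible bounds: maximum {upper} < minimum {lower}")
    if params.sigma == 0.0:
        x = math.exp(params.mu)
        if not (lower <= x <= upper):
            raise GenerationError("degenerate distribution lies outside bounds")
        return np.full(size, x)
    mass = truncated_mass(params, lower, upper)
    if mass < min_mass:
        raise GenerationError(
            f"truncation window [{lower}, {upper}] retains only {mass:.2e} of the mass"
        )
    out = np.empty(size)
    filled = 0
    while filled < size:
        need = size - filled
        draw = rng.lognormal(mean=params.mu, sigma=params.sigma, size=max(need, 16))
        keep = draw[(draw >= lower) & (draw <= upper)][:need]
        out[filled : filled + keep.size] = keep
        filled += keep.size
    return out


_FAMILIES = ("point", "uniform", "normal", "lognormal")


@dataclasses.dataclass(frozen=True)
class DistributionSpec:
    """Specification of a positive random exposure parameter.

    Families
    --------
    point : value
    uniform : low, high
    normal : mean, sd  (truncated at 0 to keep the support positive)
    lognormal : mean, sd  (arithmetic moments, matched exactly)
    """

    family: str
    params: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ConfigError(
                f"unknown distribution family {self.family!r}; expected one of {_FAMILIES}"
            )
        object.__setattr__(self, "params", dict(self.params))
        try:
            self._validate()
        except KeyError as exc:
            raise ConfigError(f"{self.family} spec missing parameter {exc}") from exc

    def _validate(self) -> None:
        p = self.params
        if self.family == "point":
            if not (p["value"] > 0.0):
                raise ConfigError(f"point value must be > 0, got {p['value']}")
        elif self.family == "uniform":
            if not (0.0 <= p["low"] < p["high"]):
                raise ConfigError(f"uniform requires 0 <= low < high, got {p}")
        elif self.family in ("normal", "lognormal"):
            if not (p["mean"] > 0.0) or not (p["sd"] >= 0.0):
                raise ConfigError(f"{self.family} requires mean > 0 and sd >= 0, got {p}")

    # -- constructors ----------------------------------------------------
    @classmethod
    def point(cls, value: float) -> "DistributionSpec":
        return cls("point", {"value": float(value)})

    @classmethod
    def uniform(cls, low: float, high: float) -> "DistributionSpec":
        return cls("uniform", {"low": float(low), "high": float(high)})

    @classmethod
    def normal(cls, mean: float, sd: float) -> "DistributionSpec":
        return cls("normal", {"mean": float(mean), "sd": float(sd)})

    @classmethod
    def lognormal(cls, mean: float, sd: float) -> "DistributionSpec":
        return cls("lognormal", {"mean": float(mean), "sd": float(sd)})

    @classmethod
    def from_dict(cls, spec: Mapping[str, float | str]) -> "DistributionSpec":
        """Build from a config mapping like ``{"family": "uniform", "low": 15, "high": 70}``."""
        if isinstance(spec, (int, float)):
            return cls.point(float(spec))
        d = dict(spec)
        family = str(d.pop("family", "point"))
        return cls(family, {k: float(v) for k, v in d.items()})

    def to_dict(self) -> dict[str, float | str]:
        return {"family": self.family, **self.params}

    # -- behaviour -------------------------------------------------------
    def mean(self) -> float:
        """Analytic mean (for the truncated normal, the pre-truncation mean)."""
        p = self.params
        if self.family == "point":
            return p["value"]
        if self.family == "uniform":
            return 0.5 * (p["low"] + p["high"])
        return p["mean"]

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        p = self.params
        if self.family == "point":
            return np.full(n, p["value"])
        if self.family == "uniform":
            return rng.uniform(p["low"], p["high"], size=n)
        if self.family == "normal":
            if p["sd"] == 0.0:
                return np.full(n, p["mean"])
            out = rng.normal(p["mean"], p["sd"], size=n)
            while True:  # redraw the non-positive tail to keep support positive
                bad = out <= 0.0
                if not bad.any():
                    return out
                out[bad] = rng.normal(p["mean"], p["sd"], size=int(bad.sum()))
        # lognormal
        lp = fit_lognormal_moments(p["mean"], p["sd"])
        if lp.sigma == 0.0:
            return np.full(n, p["mean"])
        return rng.lognormal(lp.mu, lp.sigma, size=n)
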