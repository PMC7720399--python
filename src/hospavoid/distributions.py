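"""Method-of-moments distribution fitting for decision-model parameters.

Every model input is carried as a (mean, sd) pair plus the natural
parameters of an assigned family:

* ``normal`` for cost parameters, parameterised either directly from a
  sample or by the 95 %-confidence-interval-spans-±20 % rule
  (:func:`normal_sd_from_20pct`);
* ``gamma`` for right-skewed positive quantities (length of stay, the
  hospital bed-day cost), moment-matched so the fitted distribution
  reproduces the sample mean and variance exactly;
* ``beta`` for probabilities and utilities, moment-matched on (mean, sd).

A spec with ``sd == 0`` is a degenerate point mass: sampling it returns the
mean.  This is the zero-variance guard that makes a probabilistic
sensitivity analysis with all SDs at zero collapse onto the deterministic
base case.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "DistributionSpec",
    "InfeasibleDistributionError",
    "fit_normal",
    "fit_gamma_moments",
    "gamma_from_moments",
    "beta_from_moments",
    "normal_sd_from_20pct",
]

logger = logging.getLogger(__name__)

#: z quantile used to convert a 95 % normal confidence interval to an SD.
Z_95 = 1.959964


class InfeasibleDistributionError(ValueError):
    """Raised when no member of the requested family has the given moments."""


@dataclass(frozen=True)
class DistributionSpec:
    """A distribution family together with its moments and natural parameters.

    Parameters
    ----------
    family : {"normal", "gamma", "beta"}
    mean, sd : float
        The first two moments the fit was asked to reproduce.
    params : mapping
        Natural parameters: ``{"mu", "sigma"}``, ``{"shape", "scale"}`` or
        ``{"alpha", "beta"}``.  Empty for a degenerate (sd = 0) spec.
    """

    family: str
    mean: float
    sd: float
    params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in ("normal", "gamma", "beta"):
            raise ValueError(f"unknown distribution family {self.family!r}")
        if not (math.isfinite(self.mean) and math.isfinite(self.sd)):
            raise ValueError("mean and sd must be finite")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")

    @property
    def degenerate(self) -> bool:
        return self.sd == 0.0

    def sample(
        self,
        rng: np.random.Generator,
        size: int | None = None,
        truncate_at_zero: bool = False,
    ) -> np.ndarray | float:
        """Draw from the fitted distribution.

        ``truncate_at_zero`` resamples negative values (only relevant for the
        normal family; costs cannot be negative).  Degenerate specs return
        the mean without consuming randomness beyond a shape-compatible array.
        """
        n = 1 if size is None else size
        if self.degenerate:
            out = np.full(n, self.mean, dtype=float)
        elif self.family == "normal":
            out = rng.normal(self.params["mu"], self.params["sigma"], n)
            if truncate_at_zero:
                bad = out < 0
                while bad.any():
                    out[bad] = rng.normal(
                        self.params["mu"], self.params["sigma"], int(bad.sum())
                    )
                    bad = out < 0
        elif self.family == "gamma":
            out = rng.gamma(self.params["shape"], self.params["scale"], n)
        else:
            out = rng.beta(self.params["alpha"], self.params["beta"], n)
        return float(out[0]) if size is None else out

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "mean": self.mean,
            "sd": self.sd,
            "params": dict(self.params),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "DistributionSpec":
        return cls(d["family"], float(d["mean"]), float(d["sd"]), dict(d.get("params", {})))


def fit_normal(values) -> DistributionSpec:
    """Moment fit of a normal distribution: sample mean and SD (n−1 denominator).

    Used for the annual number of hospital admissions, where a symmetric
    distribution describes the year-to-year count well.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("fit_normal requires at least 2 values")
    mu = float(np.mean(x))
    sigma = float(np.std(x, ddof=1))
    return DistributionSpec("normal", mu, sigma, {"mu": mu, "sigma": sigma})


def gamma_from_moments(mean: float, sd: float) -> DistributionSpec:
    """Gamma spec with the given mean and SD (shape = mean²/var, scale = var/mean)."""
    if mean <= 0:
        raise ValueError("gamma mean must be positive")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if sd == 0:
        return DistributionSpec("gamma", mean, 0.0, {})
    var = sd * sd
    shape = mean * mean / var
    scale = var / mean
    return DistributionSpec("gamma", mean, sd, {"shape": shape, "scale": scale})


def fit_gamma_moments(values) -> DistributionSpec:
    """Moment fit of a gamma distribution to positive data (e.g. lengths of stay).

    The returned spec reproduces the sample mean and variance exactly.
    Degenerate samples (zero variance) are rejected: a gamma distribution
    cannot be a point mass, so the caller should model such data as a
    constant instead.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("fit_gamma_moments requires at least 2 values")
    if (x <= 0).any():
        raise ValueError("gamma fit requires strictly positive values")
    var = float(np.var(x, ddof=1))
    if var == 0:
        raise ValueError(
            "zero variance: all values equal; model this as a degenerate "
            "point mass, not a gamma distribution"
        )
    return gamma_from_moments(float(np.mean(x)), math.sqrt(var))


def beta_from_moments(mean: float, sd: float, cap_variance: bool = False) -> DistributionSpec:
    """Beta spec matching (mean, sd) by the method of moments.

    With ν = mean(1−mean)/sd² − 1, the parameters are α = mean·ν and
    β = (1−mean)·ν.  Feasibility requires sd² < mean(1−mean); an infeasible
    sd raises :class:`InfeasibleDistributionError` stating the bound, unless
    ``cap_variance`` is set, in which case the variance is capped at
    0.95·mean(1−mean) and a warning is logged.
    """
    if not 0 < mean < 1:
        raise ValueError("beta mean must lie strictly inside (0, 1)")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if sd == 0:
        return DistributionSpec("beta", mean, 0.0, {})
    bound = mean * (1.0 - mean)
    var = sd * sd
    if var >= bound:
        if not cap_variance:
            raise InfeasibleDistributionError(
                f"sd^2 = {var:.6g} is not below the feasibility bound "
                f"mean*(1-mean) = {bound:.6g} for mean = {mean:.6g}"
            )
        var = 0.95 * bound
        logger.warning(
            "beta variance capped: requested sd=%.6g infeasible for mean=%.6g; "
            "using sd=%.6g",
            sd,
            mean,
            math.sqrt(var),
        )
        sd = math.sqrt(var)
    nu = bound / var - 1.0
    return DistributionSpec(
        "beta", mean, sd, {"alpha": mean * nu, "beta": (1.0 - mean) * nu}
    )


def normal_sd_from_20pct(mean: float) -> float:
    """SD such that the 95 % CI of Normal(mean, sd) spans mean ± 20 %.

    This is the uncertainty convention applied to unit-cost parameters:
    sd = 0.20·mean / 1.959964.
    """
    return 0.20 * mean / Z_95
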