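"""Parametric concentration distributions for Monte Carlo inputs.

Tissue concentrations enter the exposure model either as raw per-sample
vectors or as printed summary statistics (mean ± SD).  Both are turned into a
:class:`DistributionSpec` — a small immutable description of a positive-valued
distribution that can be sampled through its inverse CDF (the primitive the
Latin-hypercube sampler needs).

Supported families
------------------
``lognormal``
    Parameterised by the log-scale mean ``mu`` and log-scale SD ``sigma``.
    The default family: concentration data here are right-skewed (median
    below mean in every tissue), and a lognormal guarantees positivity.
``normal_truncated_at_zero``
    A normal with location/scale (pre-truncation) restricted to [0, ∞);
    offered as a sensitivity alternative to the lognormal.
``point_mass``
    A degenerate distribution; the zero-SD limit of either family.

Moment matching
---------------
From a printed mean m and SD s, the lognormal parameters follow the closed
form

    sigma^2 = ln(1 + (s/m)^2),   mu = ln(m) - sigma^2 / 2,

so the analytic mean and SD of the returned spec equal (m, s) exactly.  For
the truncated normal no closed form exists and the pre-truncation
location/scale are solved numerically so the *post-truncation* moments match.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "DistributionSpec",
    "lognormal_from_moments",
    "truncated_normal_from_moments",
    "fit_from_samples",
]

Family = Literal["lognormal", "normal_truncated_at_zero", "point_mass"]
Provenance = Literal["fit_from_samples", "moment_matched_from_summary"]


@dataclass(frozen=True)
class DistributionSpec:
    """An immutable, samplable concentration distribution.

    Parameters
    ----------
    family:
        One of ``lognormal``, ``normal_truncated_at_zero``, ``point_mass``.
    params:
        Family-specific parameters: ``(mu, sigma)`` for lognormal (log scale),
        ``(loc, scale)`` for the truncated normal (pre-truncation), and
        ``(value,)`` for a point mass.
    provenance:
        Whether the spec came from raw samples or from a printed summary.
    """

    family: Family
    params: tuple[float, ...]
    provenance: Provenance = field(default="moment_matched_from_summary", compare=False)

    def __post_init__(self) -> None:
        if self.family == "lognormal":
            mu, sigma = self.params
            if sigma < 0:
                raise ValueError("lognormal sigma must be >= 0")
        elif self.family == "normal_truncated_at_zero":
            loc, scale = self.params
            if scale < 0:
                raise ValueError("truncated-normal scale must be >= 0")
        elif self.family == "point_mass":
            (value,) = self.params
            if value < 0:
                raise ValueError("point mass must be non-negative")
        else:  # pragma: no cover - guarded by Literal typing
            raise ValueError(f"unknown family {self.family!r}")

    # -- scipy plumbing ----------------------------------------------------
    def _frozen(self):
        if self.family == "lognormal":
            mu, sigma = self.params
            return stats.lognorm(s=sigma, scale=math.exp(mu))
        if self.family == "normal_truncated_at_zero":
            loc, scale = self.params
            a = (0.0 - loc) / scale
            return stats.truncnorm(a=a, b=np.inf, loc=loc, scale=scale)
        raise ValueError("point_mass has no scipy counterpart")

    # -- sampling primitive ------------------------------------------------
    def ppf(self, q: np.ndarray | float) -> np.ndarray | float:
        """Inverse CDF; for a point mass this is the constant value."""
        if self.family == "point_mass":
            (value,) = self.params
            return np.full_like(np.asarray(q, dtype=float), value) if np.ndim(q) else value
        if self.family == "lognormal":
            mu, sigma = self.params
            if sigma == 0.0:
                const = math.exp(mu)
                return np.full_like(np.asarray(q, dtype=float), const) if np.ndim(q) else const
        return self._frozen().ppf(q)

    # -- analytic moments --------------------------------------------------
    def mean(self) -> float:
        if self.family == "point_mass":
            return self.params[0]
        if self.family == "lognormal":
            mu, sigma = self.params
            return math.exp(mu + sigma**2 / 2.0)
        return float(self._frozen().mean())

    def sd(self) -> float:
        if self.family == "point_mass":
            return 0.0
        if self.family == "lognormal":
            mu, sigma = self.params
            return self.mean() * math.sqrt(math.expm1(sigma**2))
        return float(self._frozen().std())

    def median(self) -> float:
        if self.family == "point_mass":
            return self.params[0]
        if self.family == "lognormal":
            mu, _ = self.params
            return math.exp(mu)
        return float(self._frozen().median())

    def scaled(self, k: float) -> "DistributionSpec":
        """The distribution of k·X for k > 0 (same family)."""
        if k <= 0:
            raise ValueError("scale factor must be positive")
        if self.family == "point_mass":
            return DistributionSpec("point_mass", (self.params[0] * k,), self.provenance)
        if self.family == "lognormal":
            mu, sigma = self.params
            return DistributionSpec("lognormal", (mu + math.log(k), sigma), self.provenance)
        loc, scale = self.params
        return DistributionSpec(
            "normal_truncated_at_zero", (loc * k, scale * k), self.provenance
        )


def lognormal_from_moments(mean: float, sd: float) -> DistributionSpec:
    """Lognormal spec whose analytic mean and SD equal ``mean`` and ``sd``.

    ``sd = 0`` degrades to a point mass at ``mean``.
    """
    if mean <= 0:
        raise ValueError("mean must be positive")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if sd == 0:
        return DistributionSpec("point_mass", (float(mean),))
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return DistributionSpec("lognormal", (mu, math.sqrt(sigma2)))


def truncated_normal_from_moments(mean: float, sd: float) -> DistributionSpec:
    """Truncated-at-zero normal whose post-truncation moments match.

    Solves numerically for the pre-truncation (loc, scale); for mean >> sd the
    truncation is negligible and (loc, scale) ≈ (mean, sd).
    """
    if mean <= 0:
        raise ValueError("mean must be positive")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if sd == 0:
        return DistributionSpec("point_mass", (float(mean),))
    if sd >= mean:
        # the zero-truncated normal's CV is bounded by 1 (exponential limit)
        raise ValueError(
            "a normal truncated at zero cannot attain sd >= mean (CV >= 1); "
            "use the lognormal family for such moments"
        )

    def residual(theta: np.ndarray) -> np.ndarray:
        loc, log_scale = theta
        scale = math.exp(log_scale)
        dist = stats.truncnorm(a=(0.0 - loc) / scale, b=np.inf, loc=loc, scale=scale)
        return np.array([dist.mean() - mean, dist.std() - sd])

    sol = optimize.root(residual, x0=np.array([mean, math.log(sd)]), method="hybr")
    if not sol.success:  # pragma: no cover - well-conditioned for mean, sd > 0
        raise RuntimeError(f"moment matching failed: {sol.message}")
    loc, log_scale = sol.x
    return DistributionSpec("normal_truncated_at_zero", (float(loc), math.exp(log_scale)))


def spec_from_moments(family: str, mean: float, sd: float) -> DistributionSpec:
    """Dispatch helper used by scenario-config deserialisation."""
    if family == "lognormal":
        return lognormal_from_moments(mean, sd)
    if family == "normal_truncated_at_zero":
        return truncated_normal_from_moments(mean, sd)
    if family == "point_mass":
        if sd != 0:
            raise ValueError("point_mass requires sd = 0")
        return DistributionSpec("point_mass", (float(mean),))
    raise ValueError(f"unknown family {family!r}")


def fit_from_samples(
    values: Sequence[float] | np.ndarray,
    family: Family = "lognormal",
) -> DistributionSpec:
    """Maximum-likelihood fit of ``family`` to raw concentration samples.

    For the lognormal, mu and sigma are the mean and SD (n denominator, the
    MLE) of the log values.  A constant sample collapses to a point mass
    regardless of the requested family.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 samples to fit a distribution")
    if np.all(x == x[0]):
        return DistributionSpec("point_mass", (float(x[0]),), provenance="fit_from_samples")
    if family == "lognormal":
        if np.any(x <= 0):
            raise ValueError("lognormal fit requires strictly positive values")
        logs = np.log(x)
        mu = float(np.mean(logs))
        sigma = float(np.std(logs, ddof=0))
        return DistributionSpec("lognormal", (mu, sigma), provenance="fit_from_samples")
    if family == "normal_truncated_at_zero":
        if np.any(x < 0):
            raise ValueError("truncated-normal fit requires non-negative values")

        def nll(theta: np.ndarray) -> float:
            loc, log_scale = theta
            scale = math.exp(log_scale)
            return -float(
                np.sum(
                    stats.truncnorm.logpdf(
                        x, a=(0.0 - loc) / scale, b=np.inf, loc=loc, scale=scale
                    )
                )
            )

        x0 = np.array([float(np.mean(x)), math.log(float(np.std(x, ddof=0)))])
        res = optimize.minimize(nll, x0, method="Nelder-Mead")
        loc, log_scale = res.x
        return DistributionSpec(
            "normal_truncated_at_zero",
            (float(loc), math.exp(float(log_scale))),
            provenance="fit_from_samples",
        )
    raise ValueError(f"cannot fit family {family!r}")
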