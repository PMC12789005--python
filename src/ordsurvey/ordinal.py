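"""Latent-normal ordered-probit primitives.

An ordinal answer with categories ``1..K`` is modelled as a censoring of a
latent normal variable ``z ~ N(mu, sigma^2)``: the respondent reports
category ``k`` when ``theta_{k-1} < z <= theta_k``, where
``theta_1 < ... < theta_{K-1}`` are thresholds on the latent scale and the
virtual extremes are ``theta_0 = -inf``, ``theta_K = +inf``.  The cell
probability is the normal mass between adjacent thresholds,

    p(y = k | mu, sigma, theta) = Phi((theta_k - mu)/sigma)
                                - Phi((theta_{k-1} - mu)/sigma).

The latent scale is identified by fixing the two extreme thresholds to the
bounds of the response scale, ``theta_1 = 1.5`` and ``theta_{K-1} = K - 0.5``;
only the interior thresholds are free parameters.  Questions offering an
"I don't know" (DK) option get a separate mixture weight ``delta``: with
probability ``delta`` the respondent answers DK, otherwise an ordinal
category drawn from the probit cells.  DK is never treated as an ordinal
category of its own.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import ndtr

from .errors import EmptyStratumError, ParameterError

__all__ = [
    "OrdinalParams",
    "PriorSpec",
    "fixed_threshold_bounds",
    "default_thresholds",
    "category_probabilities",
    "dk_adjusted_probabilities",
    "log_likelihood",
    "log_prior",
]

_LOG_FLOOR = -1e300  # representable stand-in for log(0)


def fixed_threshold_bounds(n_categories: int) -> tuple[float, float]:
    """Fixed values of the two extreme thresholds for a K-category scale.

    With categories coded ``1..K`` and interior thresholds given priors
    centred at ``j + 0.5``, anchoring ``theta_1 = 1.5`` and
    ``theta_{K-1} = K - 0.5`` identifies ``mu`` and ``sigma``.
    """
    if n_categories < 3:
        raise ParameterError(f"need K >= 3 categories, got {n_categories}")
    return 1.5, n_categories - 0.5


def default_thresholds(n_categories: int) -> np.ndarray:
    """Evenly spaced thresholds ``(1.5, 2.5, ..., K - 0.5)``."""
    lo, hi = fixed_threshold_bounds(n_categories)
    return np.linspace(lo, hi, n_categories - 1)


@dataclass(frozen=True)
class OrdinalParams:
    """One group's latent-model parameters.

    Parameters
    ----------
    mu : float
        Latent mean, on the scale spanned by the categories ``1..K``.
    sigma : float
        Latent standard deviation, ``> 0``.
    thresholds : sequence of float
        Full threshold vector ``theta_1..theta_{K-1}`` including the two
        fixed extremes ``theta_1 = 1.5`` and ``theta_{K-1} = K - 0.5``.
    delta : float, optional
        DK probability in ``[0, 1]``; ``None`` for questions without a DK
        option.
    """

    mu: float
    sigma: float
    thresholds: np.ndarray
    delta: Optional[float] = None

    def __post_init__(self) -> None:
        th = np.asarray(self.thresholds, dtype=float)
        if th.ndim != 1 or th.size < 2:
            raise ParameterError("thresholds must be a 1-D vector of length K-1 >= 2")
        object.__setattr__(self, "thresholds", th)
        k = th.size + 1
        lo, hi = fixed_threshold_bounds(k)
        if th[0] != lo or th[-1] != hi:
            raise ParameterError(
                f"extreme thresholds are fixed at ({lo}, {hi}) for K={k}; "
                f"got ({th[0]}, {th[-1]})"
            )
        if not self.sigma > 0:
            raise ParameterError(f"sigma must be > 0, got {self.sigma}")
        if self.delta is not None and not 0.0 <= self.delta <= 1.0:
            raise ParameterError(f"delta must be in [0, 1], got {self.delta}")

    @property
    def n_categories(self) -> int:
        return self.thresholds.size + 1

    @property
    def has_dk(self) -> bool:
        return self.delta is not None


@dataclass(frozen=True)
class PriorSpec:
    """Weakly informative priors for a K-category ordinal model.

    ``mu ~ N(mu_mean, mu_sd^2)`` centred at the midpoint of the scale,
    ``sigma ~ U(sigma_lo, sigma_hi)``, each free interior threshold
    ``theta_j ~ N(j + 0.5, theta_sd^2)``, and ``delta ~ U(0, 1)``.
    Defaults follow :meth:`default`: sd equal to ``K`` for the normal
    priors and ``U(0.01, 10K)`` for sigma — wide relative to a scale
    spanning ``1..K``.
    """

    mu_mean: float
    mu_sd: float
    sigma_lo: float
    sigma_hi: float
    theta_sd: float
    delta_lo: float = 0.0
    delta_hi: float = 1.0

    def __post_init__(self) -> None:
        if self.mu_sd <= 0 or self.theta_sd <= 0:
            raise ParameterError("prior sds must be positive")
        if not (self.sigma_lo < self.sigma_hi and self.delta_lo < self.delta_hi):
            raise ParameterError("uniform prior bounds must be ordered")

    @classmethod
    def default(cls, n_categories: int) -> "PriorSpec":
        k = n_categories
        return cls(
            mu_mean=(k + 1) / 2.0,
            mu_sd=float(k),
            sigma_lo=0.01,
            sigma_hi=10.0 * k,
            theta_sd=float(k),
        )

    def to_dict(self) -> dict:
        return {
            "mu_mean": self.mu_mean,
            "mu_sd": self.mu_sd,
            "sigma_lo": self.sigma_lo,
            "sigma_hi": self.sigma_hi,
            "theta_sd": self.theta_sd,
            "delta_lo": self.delta_lo,
            "delta_hi": self.delta_hi,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PriorSpec":
        return cls(**d)


def category_probabilities(params: OrdinalParams) -> np.ndarray:
    """Ordinal cell probabilities ``p(y = k)`` for ``k = 1..K``.

    Implements the normal-CDF difference between adjacent thresholds with
    virtual thresholds at ``-inf`` and ``+inf``.  The result is
    non-negative and sums to 1 to machine precision.

    Raises
    ------
    ParameterError
        If the thresholds are not strictly increasing.
    """
    th = params.thresholds
    if np.any(np.diff(th) <= 0):
        raise ParameterError("thresholds must be strictly increasing")
    z = np.empty(params.n_categories + 1)
    z[0], z[-1] = -np.inf, np.inf
    z[1:-1] = (th - params.mu) / params.sigma
    cdf = ndtr(z)
    return np.diff(cdf)


def dk_adjusted_probabilities(delta: float, p: np.ndarray) -> np.ndarray:
    """Full answer distribution ``(delta, (1 - delta) * p)``.

    The first entry is the DK probability, the remaining ``K`` entries the
    down-weighted ordinal cells; the vector sums to 1 whenever ``p`` does.
    """
    if not 0.0 <= delta <= 1.0:
        raise ParameterError(f"delta must be in [0, 1], got {delta}")
    p = np.asarray(p, dtype=float)
    return np.concatenate(([delta], (1.0 - delta) * p))


def _category_counts(codes: np.ndarray, n_categories: int) -> np.ndarray:
    """Counts of each ordinal code 1..K (sufficient statistics)."""
    codes = np.asarray(codes, dtype=int)
    if codes.size and (codes.min() < 1 or codes.max() > n_categories):
        raise ParameterError(
            f"ordinal codes must lie in 1..{n_categories}; "
            f"saw range [{codes.min()}, {codes.max()}]"
        )
    return np.bincount(codes, minlength=n_categories + 1)[1:]


def log_likelihood(data, params: OrdinalParams) -> float:
    """Log-likelihood of an encoded response vector.

    ``sum_i log((1 - delta) * p(y_i)) + dk_count * log(delta)`` when the
    question carries a DK channel, else ``sum_i log p(y_i)``.  Because the
    ordered-probit likelihood depends on the data only through the
    per-category counts, the sum is evaluated from counts.  Returns the
    representable floor (≈ ``-1e300``) when any observed category has zero
    probability, so samplers reject rather than crash.

    Parameters
    ----------
    data : EncodedVector
        Encoded stratum responses (ordinal codes plus a DK count).
    params : OrdinalParams
        Must have ``delta`` set if and only if ``data`` has a DK channel.
    """
    if data.n_total == 0:
        raise EmptyStratumError(
            f"no usable responses for question {data.question_id!r} "
            f"(group {data.group!r}); cannot evaluate a likelihood"
        )
    if params.has_dk != data.has_dk:
        raise ParameterError(
            "DK channel mismatch: params.delta is "
            f"{'set' if params.has_dk else 'absent'} but the data "
            f"{'declares' if data.has_dk else 'does not declare'} a DK option"
        )
    if np.any(np.diff(params.thresholds) <= 0):
        raise ParameterError("thresholds must be strictly increasing")
    counts = _category_counts(data.ordinal_codes, params.n_categories)
    return _loglik_from_counts(
        counts, data.dk_count, params.mu, params.sigma, params.thresholds, params.delta
    )


def _loglik_from_counts(
    counts: np.ndarray,
    dk_count: int,
    mu: float,
    sigma: float,
    thresholds: np.ndarray,
    delta: Optional[float],
) -> float:
    """Counts-based likelihood kernel (assumes ordered thresholds, sigma > 0).

    The ordered-probit likelihood depends on the data only through the
    per-category counts, so fits evaluate this O(K) kernel instead of a
    per-observation sum.  Zero-probability cells with observations return
    the representable floor rather than -inf so Metropolis steps reject
    cleanly.
    """
    z = np.empty(thresholds.size + 2)
    z[0], z[-1] = -np.inf, np.inf
    z[1:-1] = (thresholds - mu) / sigma
    p = np.diff(ndtr(z))
    with np.errstate(divide="ignore"):
        log_p = np.log(p)
    log_p = np.where(np.isfinite(log_p), log_p, _LOG_FLOOR)
    total = float(counts @ log_p)
    if delta is not None:
        n_ord = int(counts.sum())
        if dk_count > 0:
            total += dk_count * (math.log(delta) if delta > 0 else _LOG_FLOOR)
        if n_ord > 0:
            om = 1.0 - delta
            total += n_ord * (math.log(om) if om > 0 else _LOG_FLOOR)
    return max(total, _LOG_FLOOR)


def _normal_logpdf(x: float, mean: float, sd: float) -> float:
    z = (x - mean) / sd
    return -0.5 * z * z - math.log(sd) - 0.5 * math.log(2.0 * math.pi)


def log_prior(params: OrdinalParams, spec: PriorSpec) -> float:
    """Joint log prior density of one group's parameters.

    Sums the normal log-density for ``mu``, the uniform for ``sigma``, the
    normal for each *free* interior threshold (extremes are fixed, hence
    carry no prior), and the uniform for ``delta`` when present.  Returns
    ``-inf`` outside the support: ``sigma`` beyond its uniform bounds,
    ``delta`` outside its bounds, or a non-increasing threshold vector.
    """
    th = params.thresholds
    if np.any(np.diff(th) <= 0):
        return -np.inf
    if not spec.sigma_lo <= params.sigma <= spec.sigma_hi:
        return -np.inf
    total = _normal_logpdf(params.mu, spec.mu_mean, spec.mu_sd)
    total += -math.log(spec.sigma_hi - spec.sigma_lo)
    # free interior thresholds: theta_j for j = 2..K-2, prior centre j + 0.5
    for j in range(1, th.size - 1):
        total += _normal_logpdf(th[j], (j + 1) + 0.5, spec.theta_sd)
    if params.has_dk:
        if not spec.delta_lo <= params.delta <= spec.delta_hi:
            return -np.inf
        total += -math.log(spec.delta_hi - spec.delta_lo)
    return total
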