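"""Rural/urban group model and population-weighted country estimates.

The group-based model gives each group g in {rural, urban} its own latent
mean and standard deviation (and DK probability, when the question offers
one) while sharing a single threshold vector, because the answer
categories mean the same thing regardless of where the respondent lives:

    p(y = k | g) = Phi((theta_k - mu_g)/sigma_g) - Phi((theta_{k-1} - mu_g)/sigma_g).

Survey panels balanced 50/50 between rural and urban respondents do not
reflect any country's real population split, so country-level answer
distributions are obtained *after* fitting, by mixing the two groups'
category-probability vectors draw by draw with the country's true rural
population share w_R:

    p_country = w_R * p_rural + (1 - w_R) * p_urban        (per posterior draw)

which propagates the full joint posterior into the country estimate.

A pooled single-group fit (no rural/urban split) is also provided; it is
the same likelihood with one (mu, sigma) pair and is the natural check
that the group model nests it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .errors import EmptyStratumError, ParameterError
from .mcmc import McmcConfig, PosteriorDraws, sample_posterior, summarize
from .ordinal import (
    PriorSpec,
    _category_counts,
    _loglik_from_counts,
    _normal_logpdf,
    default_thresholds,
    fixed_threshold_bounds,
)
from .survey_io import EncodedVector

__all__ = [
    "GroupParams",
    "CategoryProbs",
    "fit_single_group",
    "fit_group_model",
    "group_level_posterior",
    "country_category_posterior",
    "group_contrast",
]


@dataclass(frozen=True)
class GroupParams:
    """Point values of the group model (mainly used as simulation truth)."""

    mu_r: float
    mu_u: float
    sigma_r: float
    sigma_u: float
    thresholds: np.ndarray
    delta_r: Optional[float] = None
    delta_u: Optional[float] = None

    def __post_init__(self) -> None:
        th = np.asarray(self.thresholds, dtype=float)
        object.__setattr__(self, "thresholds", th)
        if (self.delta_r is None) != (self.delta_u is None):
            raise ParameterError("delta must be set for both groups or neither")
        if self.sigma_r <= 0 or self.sigma_u <= 0:
            raise ParameterError("group sigmas must be > 0")

    @property
    def n_categories(self) -> int:
        return self.thresholds.size + 1

    @property
    def has_dk(self) -> bool:
        return self.delta_r is not None


@dataclass
class CategoryProbs:
    """Posterior distribution over answer-category probabilities.

    ``draws`` has one row per posterior draw and one column per answer
    option, ordered ``(DK, cat_1..cat_K)`` when the question has a DK
    option and ``(cat_1..cat_K)`` otherwise; every row sums to 1.
    """

    question_id: str
    country: Optional[str]
    level: str  # rural | urban | country | all
    labels: tuple[str, ...]
    draws: np.ndarray

    def __post_init__(self) -> None:
        self.draws = np.asarray(self.draws, dtype=float)
        if self.draws.ndim != 2 or self.draws.shape[1] != len(self.labels):
            raise ParameterError("draws must be (n_draws, n_options) matching labels")
        sums = self.draws.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ParameterError("each draw's probability vector must sum to 1")

    @property
    def mean(self) -> np.ndarray:
        return self.draws.mean(axis=0)

    @property
    def median(self) -> np.ndarray:
        return np.median(self.draws, axis=0)

    def interval(self, level: float = 0.95) -> np.ndarray:
        a = (1.0 - level) / 2.0
        return np.quantile(self.draws, [a, 1.0 - a], axis=0)

    def to_frame(self) -> pd.DataFrame:
        lo, hi = self.interval()
        return pd.DataFrame(
            {
                "country": self.country,
                "question": self.question_id,
                "level": self.level,
                "category": list(self.labels),
                "mean": self.mean,
                "median": self.median,
                "lower": lo,
                "upper": hi,
            }
        )


# ---------------------------------------------------------------------------
# parameter-vector plumbing


def _free_theta_names(k: int) -> list[str]:
    return [f"theta_{j}" for j in range(2, k - 1)]


def _assemble_thresholds(k: int, free: np.ndarray) -> np.ndarray:
    lo, hi = fixed_threshold_bounds(k)
    th = np.empty(k - 1)
    th[0], th[-1] = lo, hi
    th[1:-1] = free
    return th


def _theta_log_prior(th: np.ndarray, spec: PriorSpec) -> float:
    if np.any(np.diff(th) <= 0):
        return -np.inf
    total = 0.0
    for j in range(1, th.size - 1):
        total += _normal_logpdf(th[j], (j + 1) + 0.5, spec.theta_sd)
    return total


def _scalar_priors(mu: float, sigma: float, delta: Optional[float], spec: PriorSpec) -> float:
    if not spec.sigma_lo <= sigma <= spec.sigma_hi:
        return -np.inf
    total = _normal_logpdf(mu, spec.mu_mean, spec.mu_sd)
    total -= np.log(spec.sigma_hi - spec.sigma_lo)
    if delta is not None:
        if not spec.delta_lo <= delta <= spec.delta_hi:
            return -np.inf
        total -= np.log(spec.delta_hi - spec.delta_lo)
    return total


def _initial_vectors(
    k: int,
    has_dk: bool,
    n_groups: int,
    cfg: McmcConfig,
    dk_fracs: Sequence[float],
) -> list[np.ndarray]:
    """Over-dispersed but in-support chain starts, deterministic in the seed."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xC0FFEE]))
    mid = (k + 1) / 2.0
    inits = []
    for _ in range(cfg.n_chains):
        parts = []
        for g in range(n_groups):
            parts.append([mid + rng.uniform(-1.0, 1.0)])
        for g in range(n_groups):
            parts.append([np.exp(rng.uniform(-0.5, 0.5))])
        free = default_thresholds(k)[1:-1] + rng.uniform(-0.2, 0.2, size=max(k - 3, 0))
        parts.append(free)
        if has_dk:
            for g in range(n_groups):
                base = min(max(dk_fracs[g], 0.02), 0.98)
                parts.append([float(np.clip(base + rng.uniform(-0.02, 0.02), 0.01, 0.99))])
        inits.append(np.concatenate(parts))
    return inits


def _check_nonempty(data: EncodedVector) -> None:
    if data.is_empty:
        raise EmptyStratumError(
            f"stratum {data.group!r} of question {data.question_id!r} "
            f"(country {data.country!r}) has no usable responses"
        )


# ---------------------------------------------------------------------------
# fitting


def fit_single_group(
    data: EncodedVector,
    priors: Optional[PriorSpec] = None,
    cfg: Optional[McmcConfig] = None,
) -> PosteriorDraws:
    """Posterior for one pooled stratum: (mu, sigma, free thetas[, delta])."""
    _check_nonempty(data)
    k = data.n_categories
    priors = priors or PriorSpec.default(k)
    cfg = cfg or McmcConfig()
    counts = _category_counts(data.ordinal_codes, k)
    dk = data.dk_count
    has_dk = data.has_dk
    n_free = k - 3

    def log_post(v: np.ndarray) -> float:
        mu, sigma = v[0], v[1]
        free = v[2 : 2 + n_free]
        delta = v[2 + n_free] if has_dk else None
        th = _assemble_thresholds(k, free)
        lp = _scalar_priors(mu, sigma, delta, priors) + _theta_log_prior(th, priors)
        if not np.isfinite(lp):
            return -np.inf
        return lp + _loglik_from_counts(counts, dk, mu, sigma, th, delta)

    names = ["mu", "sigma", *_free_theta_names(k)] + (["delta"] if has_dk else [])
    frac = dk / data.n_total if data.n_total else 0.0
    init = _initial_vectors(k, has_dk, 1, cfg, [frac])
    draws = sample_posterior(log_post, init, cfg, names, model="single_group")
    draws.provenance.update(
        {"K": k, "has_dk": has_dk, "question_id": data.question_id, "country": data.country}
    )
    return draws


def fit_group_model(
    rural: EncodedVector,
    urban: EncodedVector,
    priors: Optional[PriorSpec] = None,
    cfg: Optional[McmcConfig] = None,
) -> PosteriorDraws:
    """Joint posterior of the rural/urban model with shared thresholds.

    The likelihood is the sum of the two strata's ordered-probit
    log-likelihoods evaluated at group-specific (mu_g, sigma_g[, delta_g])
    but a single threshold vector; priors are independent and identical
    across groups, encoding no prior rural/urban difference.
    """
    _check_nonempty(rural)
    _check_nonempty(urban)
    if rural.n_categories != urban.n_categories:
        raise ParameterError("rural and urban strata disagree on K")
    if rural.has_dk != urban.has_dk:
        raise ParameterError("rural and urban strata disagree on the DK channel")
    k = rural.n_categories
    has_dk = rural.has_dk
    priors = priors or PriorSpec.default(k)
    cfg = cfg or McmcConfig()
    counts_r = _category_counts(rural.ordinal_codes, k)
    counts_u = _category_counts(urban.ordinal_codes, k)
    dk_r, dk_u = rural.dk_count, urban.dk_count
    n_free = k - 3

    def log_post(v: np.ndarray) -> float:
        mu_r, mu_u, s_r, s_u = v[0], v[1], v[2], v[3]
        free = v[4 : 4 + n_free]
        d_r = v[4 + n_free] if has_dk else None
        d_u = v[5 + n_free] if has_dk else None
        th = _assemble_thresholds(k, free)
        lp = (
            _scalar_priors(mu_r, s_r, d_r, priors)
            + _scalar_priors(mu_u, s_u, d_u, priors)
            + _theta_log_prior(th, priors)
        )
        if not np.isfinite(lp):
            return -np.inf
        return (
            lp
            + _loglik_from_counts(counts_r, dk_r, mu_r, s_r, th, d_r)
            + _loglik_from_counts(counts_u, dk_u, mu_u, s_u, th, d_u)
        )

    names = ["mu_R", "mu_U", "sigma_R", "sigma_U", *_free_theta_names(k)]
    if has_dk:
        names += ["delta_R", "delta_U"]
    fracs = [
        dk_r / rural.n_total if rural.n_total else 0.0,
        dk_u / urban.n_total if urban.n_total else 0.0,
    ]
    init = _initial_vectors(k, has_dk, 2, cfg, fracs)
    draws = sample_posterior(log_post, init, cfg, names, model="group")
    draws.provenance.update(
        {"K": k, "has_dk": has_dk, "question_id": rural.question_id, "country": rural.country}
    )
    return draws


# ---------------------------------------------------------------------------
# posterior category probabilities


def _probs_matrix(
    mu: np.ndarray, sigma: np.ndarray, free: np.ndarray, k: int, delta: Optional[np.ndarray]
) -> np.ndarray:
    """Per-draw answer-probability vectors, vectorised over draws."""
    lo, hi = fixed_threshold_bounds(k)
    n = mu.size
    th = np.empty((n, k - 1))
    th[:, 0], th[:, -1] = lo, hi
    if k > 3:
        th[:, 1:-1] = free
    z = (th - mu[:, None]) / sigma[:, None]
    cdf = np.concatenate(
        [np.zeros((n, 1)), ndtr(z), np.ones((n, 1))], axis=1
    )
    p = np.diff(cdf, axis=1)
    if delta is not None:
        p = np.concatenate([delta[:, None], (1.0 - delta[:, None]) * p], axis=1)
    return p


def _group_prob_draws(draws: PosteriorDraws, suffix: str) -> np.ndarray:
    k = draws.provenance["K"]
    has_dk = draws.provenance["has_dk"]
    mu = draws.pooled(f"mu_{suffix}")
    sigma = draws.pooled(f"sigma_{suffix}")
    free = np.column_stack(
        [draws.pooled(nm) for nm in _free_theta_names(k)]
    ) if k > 3 else np.empty((mu.size, 0))
    delta = draws.pooled(f"delta_{suffix}") if has_dk else None
    return _probs_matrix(mu, sigma, free, k, delta)


def _option_labels(k: int, has_dk: bool, labels: Optional[Sequence[str]]) -> tuple[str, ...]:
    cats = tuple(labels) if labels else tuple(str(i) for i in range(1, k + 1))
    return (("DK",) + cats) if has_dk else cats


def group_level_posterior(
    draws: PosteriorDraws,
    group: str,
    labels: Optional[Sequence[str]] = None,
) -> CategoryProbs:
    """Answer-probability posterior for one group ("rural" or "urban")."""
    suffix = {"rural": "R", "urban": "U"}[group]
    p = _group_prob_draws(draws, suffix)
    k = draws.provenance["K"]
    return CategoryProbs(
        question_id=draws.provenance.get("question_id", "?"),
        country=draws.provenance.get("country"),
        level=group,
        labels=_option_labels(k, draws.provenance["has_dk"], labels),
        draws=p,
    )


def country_category_posterior(
    draws: PosteriorDraws,
    rural_proportion: float,
    labels: Optional[Sequence[str]] = None,
) -> CategoryProbs:
    """Country-level answer probabilities by population-weighted mixing.

    For every posterior draw the rural and urban answer-probability
    vectors (DK-adjusted where applicable) are combined as
    ``w_R * p_rural + (1 - w_R) * p_urban`` with the country's true rural
    population share ``w_R``; summaries are then taken over draws.  The
    mixing is linear and per-draw, so the posterior mean of the country
    vector is exactly the same convex combination of the groups' posterior
    means.
    """
    if not 0.0 <= rural_proportion <= 1.0:
        raise ParameterError(
            f"rural_proportion must be in [0, 1], got {rural_proportion}"
        )
    p_r = _group_prob_draws(draws, "R")
    p_u = _group_prob_draws(draws, "U")
    mixed = rural_proportion * p_r + (1.0 - rural_proportion) * p_u
    k = draws.provenance["K"]
    return CategoryProbs(
        question_id=draws.provenance.get("question_id", "?"),
        country=draws.provenance.get("country"),
        level="country",
        labels=_option_labels(k, draws.provenance["has_dk"], labels),
        draws=mixed,
    )


def group_contrast(draws: PosteriorDraws) -> pd.DataFrame:
    """Posterior summaries of urban-minus-rural parameter differences.

    Rows: ``mu_U - mu_R``, ``sigma_U - sigma_R`` and, when the question
    has a DK option, ``delta_U - delta_R``; the ``ci_excludes_zero``
    column is the package's "credible difference" flag.
    """
    pairs = [("mu_U", "mu_R"), ("sigma_U", "sigma_R")]
    if draws.provenance.get("has_dk"):
        pairs.append(("delta_U", "delta_R"))
    names, diffs = [], []
    for hi, lo in pairs:
        names.append(f"{hi} - {lo}")
        diffs.append(draws.per_chain(hi) - draws.per_chain(lo))
    contrast = PosteriorDraws(
        parameter_names=names,
        draws=np.stack(diffs, axis=2),
        provenance=dict(draws.provenance, model="group_contrast"),
    )
    return summarize(contrast)
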