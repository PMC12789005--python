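"""Linear-predictor (covariate) ordered-probit model.

The latent mean of respondent i becomes a linear function of individual
covariates,

    mu_i = alpha + b_location * urban_i + b_sex * male_i
         + b_age * age_std_i + sum_l b_pol_l * politics_{il},

with rural, female and political centre as reference levels and age
standardised to sample mean 0 / sd 1 for sampler stability (the per-year
coefficient is recovered by dividing by the age sd, and the report carries
that constant).  The latent standard deviation, the shared thresholds and
the DK probability are modelled exactly as in the group-free model and do
not depend on the covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .errors import EmptyStratumError, ParameterError, ValidationError
from .mcmc import McmcConfig, PosteriorDraws, sample_posterior, summarize
from .ordinal import PriorSpec, _LOG_FLOOR, default_thresholds
from .group_model import _assemble_thresholds, _free_theta_names, _theta_log_prior
from .survey_io import DK, EncodedVector, SurveyDataset

__all__ = [
    "DESIGN_COLUMNS",
    "DesignMatrix",
    "CovariatePriors",
    "build_design",
    "fit_covariate_model",
    "coefficient_report",
]

DESIGN_COLUMNS = (
    "intercept",
    "location_urban",
    "sex_male",
    "age_std",
    "pol_xleft",
    "pol_left",
    "pol_right",
    "pol_xright",
)

_POLITICS_DUMMY = {
    "extreme_left": "pol_xleft",
    "left": "pol_left",
    "right": "pol_right",
    "extreme_right": "pol_xright",
}


@dataclass
class DesignMatrix:
    """Covariate rows aligned one-to-one with ordinal observations.

    ``age_mean``/``age_sd`` are the standardisation constants (raw years)
    recorded for back-transformation; ``n_dropped`` counts respondents
    removed by listwise deletion of missing covariates;
    ``unidentifiable`` lists constant columns (no information in the
    stratum to estimate their coefficient).
    """

    X: np.ndarray
    columns: tuple[str, ...] = DESIGN_COLUMNS
    age_mean: float = 0.0
    age_sd: float = 1.0
    n_dropped: int = 0
    unidentifiable: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.columns):
            raise ParameterError("X must be (n, n_columns)")


def build_design(
    dataset: SurveyDataset,
    question_id: str,
    country: Optional[str] = None,
) -> tuple[EncodedVector, DesignMatrix]:
    """Encode one stratum's answers together with aligned covariate rows.

    Respondents are included when they gave a usable answer (ordinal or
    DK) *and* have complete covariates; respondents with politics
    ``missing`` are listwise-deleted (their count is recorded on the
    returned design).  Design rows are built only for ordinal answers —
    the DK probability does not depend on covariates, so DK respondents
    contribute only to the DK count.

    Raises
    ------
    ValidationError
        If the politics column is missing for every respondent in the
        stratum (the politics contrasts are then unidentifiable as
        specified).
    """
    q = dataset.question(question_id)
    frame = dataset.frame
    mask = pd.Series(True, index=frame.index)
    if country is not None:
        mask &= frame["country"] == country
    sub = frame.loc[mask]
    sub = sub[~sub[question_id].isna()]
    if len(sub) == 0:
        raise EmptyStratumError(
            f"no usable responses for question {question_id!r} in {country!r}"
        )
    if (sub["politics"] == "missing").all():
        raise ValidationError(
            f"politics is missing for every respondent in {country!r}; "
            "the political-orientation contrasts are unidentifiable"
        )
    complete = sub["politics"] != "missing"
    n_dropped = int((~complete).sum())
    sub = sub[complete]

    is_dk = sub[question_id] == DK
    ordinal = sub[~is_dk]
    codes = ordinal[question_id].astype(int).to_numpy()
    dk_count = int(is_dk.sum())

    ages = ordinal["age"].astype(float).to_numpy()
    age_mean = float(ages.mean())
    age_sd = float(ages.std(ddof=1)) if ages.size > 1 else 0.0
    unident = []
    if age_sd > 0:
        age_std = (ages - age_mean) / age_sd
    else:
        age_std = np.zeros_like(ages)
        age_sd = 1.0
        unident.append("age_std")

    n = len(ordinal)
    X = np.zeros((n, len(DESIGN_COLUMNS)))
    X[:, 0] = 1.0
    X[:, 1] = (ordinal["location"] == "urban").to_numpy(dtype=float)
    X[:, 2] = (ordinal["sex"] == "male").to_numpy(dtype=float)
    X[:, 3] = age_std
    for level, col in _POLITICS_DUMMY.items():
        X[:, DESIGN_COLUMNS.index(col)] = (ordinal["politics"] == level).to_numpy(dtype=float)

    for j, col in enumerate(DESIGN_COLUMNS[1:], start=1):
        if col not in unident and np.all(X[:, j] == X[0, j]):
            unident.append(col)
    if unident:
        warnings.warn(
            f"constant design columns in {question_id!r}/{country!r}: {unident}; "
            "their coefficients are unidentifiable (posterior = prior)",
            stacklevel=2,
        )

    encoded = EncodedVector(
        ordinal_codes=codes,
        dk_count=dk_count,
        question_id=question_id,
        group="all",
        n_categories=q.n_categories,
        has_dk=q.has_dont_know,
        country=country,
    )
    design = DesignMatrix(
        X=X,
        age_mean=age_mean,
        age_sd=age_sd,
        n_dropped=n_dropped,
        unidentifiable=tuple(unident),
    )
    return encoded, design


@dataclass(frozen=True)
class CovariatePriors:
    """Priors for the linear-predictor model.

    Near-flat normals on the intercept and slopes — ``alpha ~ N((K+1)/2,
    (10K)^2)`` and ``beta ~ N(0, (10K)^2)`` — encode no prior direction or
    magnitude for any effect; sigma, thresholds and delta reuse the base
    ordinal priors.
    """

    base: PriorSpec
    alpha_mean: float
    alpha_sd: float
    beta_sd: float

    @classmethod
    def default(cls, n_categories: int) -> "CovariatePriors":
        k = n_categories
        return cls(
            base=PriorSpec.default(k),
            alpha_mean=(k + 1) / 2.0,
            alpha_sd=10.0 * k,
            beta_sd=10.0 * k,
        )


def _coef_names() -> list[str]:
    return ["alpha"] + [f"b_{c}" for c in DESIGN_COLUMNS[1:]]


def fit_covariate_model(
    encoded: EncodedVector,
    design: DesignMatrix,
    priors: Optional[CovariatePriors] = None,
    cfg: Optional[McmcConfig] = None,
) -> PosteriorDraws:
    """Posterior over (alpha, betas, sigma, free thetas[, delta]).

    Each ordinal observation enters the ordered-probit likelihood with its
    own latent mean ``mu_i`` from the linear predictor; sigma and the
    thresholds are common, and the DK channel (when present) is a single
    covariate-free mixture weight.
    """
    if encoded.is_empty:
        raise EmptyStratumError(
            f"stratum of question {encoded.question_id!r} has no usable responses"
        )
    if design.X.shape[0] != encoded.ordinal_codes.size:
        raise ParameterError(
            "design rows must align with the ordinal observations "
            f"({design.X.shape[0]} rows vs {encoded.ordinal_codes.size} codes)"
        )
    k = encoded.n_categories
    has_dk = encoded.has_dk
    priors = priors or CovariatePriors.default(k)
    cfg = cfg or McmcConfig()
    base = priors.base
    X = design.X
    codes = encoded.ordinal_codes
    dk_count = encoded.dk_count
    n_obs = codes.size
    n_coef = X.shape[1]
    n_free = k - 3
    # per-observation threshold indices into the padded vector
    # (-inf, theta_1..theta_{K-1}, +inf): upper bound at codes, lower at codes-1
    idx_both = np.concatenate([codes, codes - 1])
    # the Gibbs sweep changes one coordinate per call, so the linear
    # predictor is unchanged for sigma/theta/delta updates: cache it
    _cache = {"beta": None, "mu2": None}

    def log_post(v: np.ndarray) -> float:
        beta = v[:n_coef]
        sigma = v[n_coef]
        free = v[n_coef + 1 : n_coef + 1 + n_free]
        delta = v[n_coef + 1 + n_free] if has_dk else None
        if not base.sigma_lo <= sigma <= base.sigma_hi:
            return -np.inf
        if delta is not None and not base.delta_lo <= delta <= base.delta_hi:
            return -np.inf
        th = _assemble_thresholds(k, free)
        lp = _theta_log_prior(th, base)
        if not np.isfinite(lp):
            return -np.inf
        za = (beta[0] - priors.alpha_mean) / priors.alpha_sd
        zb = beta[1:] / priors.beta_sd
        lp += -0.5 * (za * za + float(zb @ zb))
        if delta is not None:
            lp -= np.log(base.delta_hi - base.delta_lo)

        if _cache["beta"] is None or not np.array_equal(beta, _cache["beta"]):
            mu_i = X @ beta
            _cache["mu2"] = np.concatenate([mu_i, mu_i])
            _cache["beta"] = beta.copy()
        th_pad = np.concatenate(([-np.inf], th, [np.inf]))
        cdf = ndtr((th_pad[idx_both] - _cache["mu2"]) / sigma)
        p = cdf[:n_obs] - cdf[n_obs:]
        # clip instead of -inf: a zero-probability cell contributes a huge
        # but finite penalty, so Metropolis steps reject cleanly
        ll = float(np.log(np.maximum(p, 1e-300)).sum())
        if delta is not None:
            if dk_count > 0:
                ll += dk_count * (np.log(delta) if delta > 0 else _LOG_FLOOR)
            om = 1.0 - delta
            ll += n_obs * (np.log(om) if om > 0 else _LOG_FLOOR)
        return lp + max(ll, _LOG_FLOOR)

    names = _coef_names() + ["sigma", *_free_theta_names(k)]
    if has_dk:
        names.append("delta")

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xBE7A]))
    mid = (k + 1) / 2.0
    frac = dk_count / encoded.n_total if encoded.n_total else 0.0
    init = []
    for _ in range(cfg.n_chains):
        v = [mid + rng.uniform(-1.0, 1.0)]
        v += list(rng.uniform(-0.3, 0.3, size=n_coef - 1))
        v.append(np.exp(rng.uniform(-0.5, 0.5)))
        v += list(default_thresholds(k)[1:-1] + rng.uniform(-0.2, 0.2, size=n_free))
        if has_dk:
            v.append(float(np.clip(frac + rng.uniform(-0.02, 0.02), 0.01, 0.99)))
        init.append(np.array(v))

    draws = sample_posterior(log_post, init, cfg, names, model="covariate")
    draws.provenance.update(
        {
            "K": k,
            "has_dk": has_dk,
            "question_id": encoded.question_id,
            "country": encoded.country,
            "age_mean": design.age_mean,
            "age_sd": design.age_sd,
            "n_dropped": design.n_dropped,
            "unidentifiable": list(design.unidentifiable),
        }
    )
    return draws


def coefficient_report(draws: PosteriorDraws) -> pd.DataFrame:
    """Tabular coefficient report for one covariate fit.

    One row per free parameter with posterior mean, sd, 95% interval,
    R-hat and the ``ci_excludes_zero`` flag, plus a derived
    ``b_age_std_per_year`` row (the age effect divided by the age sd in
    years, so it reads "latent units per year of age").  The age sd used
    for the conversion is stored in ``DataFrame.attrs['age_sd_years']``.
    """
    table = summarize(draws)
    age_sd = draws.provenance.get("age_sd")
    if age_sd and "b_age_std" in table.index:
        per_chain = draws.per_chain("b_age_std") / age_sd
        extra = PosteriorDraws(
            parameter_names=["b_age_std_per_year"],
            draws=per_chain[:, :, None],
        )
        table = pd.concat([table, summarize(extra)])
    table.attrs["age_sd_years"] = age_sd
    table.attrs["unidentifiable"] = draws.provenance.get("unidentifiable", [])
    return table
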