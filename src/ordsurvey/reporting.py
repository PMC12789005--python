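"""Batch fitting runs and their tabular artifacts.

These functions tie the pipeline together for many country/question
strata and write plain delimiter-separated tables plus a JSON run
manifest (seed, config hash, package version), so any artifact can be
regenerated byte-for-byte from the manifest alone.  Percentages for
display are rounded half-up to whole percent; the tables keep full
precision.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .covariates import build_design, coefficient_report, fit_covariate_model
from .errors import ValidationError
from .group_model import (
    country_category_posterior,
    fit_group_model,
    group_contrast,
    group_level_posterior,
)
from .mcmc import McmcConfig, summarize
from .survey_io import SurveyDataset, encode_responses

__all__ = [
    "display_percent",
    "run_fit_group",
    "run_fit_covariate",
    "write_manifest",
]


def display_percent(p: float) -> int:
    """Round a probability to a whole percent, half away from zero."""
    return int(Decimal(p * 100).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def _config_hash(payload: dict) -> str:
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(out_dir: Path, command: str, cfg: McmcConfig, extra: dict) -> dict:
    manifest = {
        "command": command,
        "package_version": __version__,
        "seed": cfg.seed,
        "mcmc": asdict(cfg),
        **extra,
    }
    manifest["config_hash"] = _config_hash(manifest)
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=str, sort_keys=True)
        fh.write("\n")
    return manifest


def _select(dataset: SurveyDataset, questions, countries):
    qids = [q.question_id for q in dataset.schema]
    questions = list(questions) if questions else qids
    unknown = set(questions) - set(qids)
    if unknown:
        raise ValidationError(f"unknown questions requested: {sorted(unknown)}")
    countries = list(countries) if countries else list(dataset.countries)
    return questions, countries


def run_fit_group(
    dataset: SurveyDataset,
    meta: pd.DataFrame,
    out_dir,
    cfg: Optional[McmcConfig] = None,
    questions: Optional[Sequence[str]] = None,
    countries: Optional[Sequence[str]] = None,
    rhat_threshold: float = 1.1,
) -> dict:
    """Fit the rural/urban group model per country x question.

    Writes ``category_probs.csv`` (rural, urban and population-weighted
    country rows per answer option), ``group_params.csv`` (posterior
    summaries incl. R-hat), ``contrasts.csv`` (urban - rural differences)
    and ``manifest.json``.  Returns the manifest with a ``converged``
    flag that is false if any R-hat exceeded the threshold.
    """
    cfg = cfg or McmcConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    questions, countries = _select(dataset, questions, countries)
    missing = sorted(set(countries) - set(meta.index))
    if missing:
        raise ValidationError(f"countries missing from the metadata table: {missing}")

    prob_rows, param_rows, contrast_rows = [], [], []
    worst_rhat = 0.0
    for qid in questions:
        q = dataset.question(qid)
        labels = q.labels_or_default()
        for code in countries:
            rural = encode_responses(dataset, qid, code, "rural")
            urban = encode_responses(dataset, qid, code, "urban")
            draws = fit_group_model(rural, urban, cfg=cfg)
            table = summarize(draws)
            worst_rhat = max(worst_rhat, float(table["rhat"].max()))
            table = table.reset_index(names="parameter")
            table.insert(0, "question", qid)
            table.insert(0, "country", code)
            param_rows.append(table)

            w_r = float(meta.loc[code, "rural_proportion"])
            for probs in (
                group_level_posterior(draws, "rural", labels),
                group_level_posterior(draws, "urban", labels),
                country_category_posterior(draws, w_r, labels),
            ):
                prob_rows.append(probs.to_frame())

            ct = group_contrast(draws).reset_index(names="parameter")
            ct.insert(0, "question", qid)
            ct.insert(0, "country", code)
            contrast_rows.append(ct)

    pd.concat(prob_rows, ignore_index=True).to_csv(out_dir / "category_probs.csv", index=False)
    pd.concat(param_rows, ignore_index=True).to_csv(out_dir / "group_params.csv", index=False)
    pd.concat(contrast_rows, ignore_index=True).to_csv(out_dir / "contrasts.csv", index=False)
    converged = worst_rhat <= rhat_threshold
    return write_manifest(
        out_dir,
        "fit-group",
        cfg,
        {
            "questions": questions,
            "countries": countries,
            "rhat_threshold": rhat_threshold,
            "worst_rhat": worst_rhat,
            "converged": bool(converged),
        },
    )


def run_fit_covariate(
    dataset: SurveyDataset,
    out_dir,
    cfg: Optional[McmcConfig] = None,
    questions: Optional[Sequence[str]] = None,
    countries: Optional[Sequence[str]] = None,
    rhat_threshold: float = 1.1,
) -> dict:
    """Fit the linear-predictor model per country x question.

    Writes ``coefficients.csv`` (one row per coefficient per fit, with
    the per-year age conversion) and ``manifest.json``.
    """
    cfg = cfg or McmcConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    questions, countries = _select(dataset, questions, countries)

    rows = []
    worst_rhat = 0.0
    for qid in questions:
        for code in countries:
            encoded, design = build_design(dataset, qid, code)
            draws = fit_covariate_model(encoded, design, cfg=cfg)
            report = coefficient_report(draws)
            worst_rhat = max(worst_rhat, float(report["rhat"].max()))
            report = report.reset_index(names="parameter")
            report.insert(0, "question", qid)
            report.insert(0, "country", code)
            report["age_sd_years"] = design.age_sd
            report["n_dropped_missing_covariates"] = design.n_dropped
            rows.append(report)

    pd.concat(rows, ignore_index=True).to_csv(out_dir / "coefficients.csv", index=False)
    converged = worst_rhat <= rhat_threshold
    return write_manifest(
        out_dir,
        "fit-covariate",
        cfg,
        {
            "questions": questions,
            "countries": countries,
            "rhat_threshold": rhat_threshold,
            "worst_rhat": worst_rhat,
            "converged": bool(converged),
        },
    )
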