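"""Synthetic spontaneous-report generator.

Emits linked DEMO/DRUG/REAC tables in the three-table spontaneous-report
layout together with a ground-truth record, so every downstream stage of the
pipeline has a parameter-recovery or count-consistency test without any
external download.

Generative model
----------------
Per case: sex, a decade age band (the latent age is the band midpoint),
height and weight drawn from sex-specific normals (so BMI is defined), and
independent Bernoulli exposure to each catalog drug.  Target-class (fracture)
events follow a per-term logistic model whose linear predictor is the term's
baseline log-odds plus the planted log odds ratios of the case's drugs plus
demographic confounding terms.  A case whose target class fires reports its
fired fracture term(s); all other cases report background events drawn
per-term from baseline probabilities (at least one).  Data-quality nuisances
are layered on top: exact duplicate DRUG/REAC rows, implausible
height/weight pairs yielding BMI < 10 or > 100, per-field missing
demographics, and an involvement category per drug row, only the
``suspected`` fraction of which survives the cohort filter.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Mapping, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .config import (AGE_BAND_MIDPOINTS, AGE_BANDS, CONFOUNDER_CENTERS,
                     INVOLVEMENT_CATEGORIES, ScenarioConfig)
from . import jader_io

__all__ = ["CohortTruth", "generate_cohort", "write_fixture"]

_OUTCOME_VOCAB = ("recovered", "recovering", "not recovered", "unknown")
_OUTCOME_PROBS = (0.45, 0.20, 0.20, 0.15)


@dataclass
class CohortTruth:
    """Ground truth behind one generated database.

    ``cases`` holds the latent per-case covariates (before missingness) and
    flags; the scalar counts let count-conservation tests assert exact
    bookkeeping through the cleaning stages.
    """

    scenario: ScenarioConfig
    cases: pd.DataFrame
    planted_effects: Mapping[Tuple[str, str], float]
    exposure_counts: Dict[str, int]
    outlier_case_ids: Tuple[str, ...]
    n_target_cases: int
    n_drug_rows: int          # before duplication
    n_reac_rows: int          # before duplication
    n_dup_drug_rows: int
    n_dup_reac_rows: int


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float, size: int) -> np.ndarray:
    x = rng.normal(mean, sd, size)
    return np.clip(x, lo, hi)


def generate_cohort(
    config: ScenarioConfig,
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, CohortTruth]:
    """Generate (demo, drug, reac, truth) for one scenario.

    The same configuration (including seed) always yields identical tables.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_cases
    demo_model = config.demographics

    case_id = np.array([f"C{i:07d}" for i in range(n)])

    # demographics ---------------------------------------------------------
    female = rng.random(n) < demo_model.p_female
    band_names = [b for b in AGE_BANDS if demo_model.age_band_probs.get(b, 0.0) > 0]
    band_probs = np.array([demo_model.age_band_probs[b] for b in band_names])
    band_idx = rng.choice(len(band_names), size=n, p=band_probs / band_probs.sum())
    age_band = np.array(band_names, dtype=object)[band_idx]
    age_years = np.array([AGE_BAND_MIDPOINTS[b] for b in band_names])[band_idx]

    height = np.where(
        female,
        _truncated_normal(rng, *demo_model.height_cm["female"], 110.0, 200.0, n),
        _truncated_normal(rng, *demo_model.height_cm["male"], 110.0, 210.0, n),
    ).round(1)
    weight = np.where(
        female,
        _truncated_normal(rng, *demo_model.weight_kg["female"], 25.0, 150.0, n),
        _truncated_normal(rng, *demo_model.weight_kg["male"], 25.0, 160.0, n),
    ).round(1)

    # keep ordinary cases inside a plausible BMI band so the only
    # implausible anthropometrics are the deliberately injected ones
    h_m2_all = (height / 100.0) ** 2
    weight = np.clip(weight, 12.5 * h_m2_all, 60.0 * h_m2_all).round(1)

    # implausible anthropometrics: force BMI > 100 or < 10
    is_outlier = rng.random(n) < config.outlier_rate
    out_idx = np.flatnonzero(is_outlier)
    high = out_idx[rng.random(out_idx.size) < 0.5]
    low = np.setdiff1d(out_idx, high)
    h_m2 = (height / 100.0) ** 2
    weight[high] = (h_m2[high] * rng.uniform(101.0, 160.0, high.size)).round(1)
    weight[low] = (h_m2[low] * rng.uniform(3.0, 9.5, low.size)).round(1)
    bmi = weight / h_m2

    # drug exposure --------------------------------------------------------
    p_exp = np.array([d.p_exposure for d in config.drugs])
    exposed = rng.random((n, len(config.drugs))) < p_exp  # (cases x drugs)

    # target-class events: per-term logistic model -------------------------
    conf = config.confounding
    z = np.zeros(n)
    if "age" in conf:
        z += conf["age"] * (age_years - CONFOUNDER_CENTERS["age"])
    if "female" in conf:
        z += conf["female"] * female
    if "bmi" in conf:
        z += conf["bmi"] * (bmi - CONFOUNDER_CENTERS["bmi"])

    drug_names = list(config.drug_names())
    drug_col = {d: j for j, d in enumerate(drug_names)}
    target_terms = list(config.target_terms)
    baselines = {e.term: e.p_baseline for e in config.events}

    beta = np.zeros((len(drug_names), len(target_terms)))
    for (drug, term), val in config.planted_effects.items():
        if term in target_terms:
            beta[drug_col[drug], target_terms.index(term)] = val
    eta = logit(np.array([baselines[t] for t in target_terms]))[None, :] \
        + z[:, None] + exposed.astype(float) @ beta
    target_fired = rng.random((n, len(target_terms))) < expit(eta)
    is_target_case = target_fired.any(axis=1)

    # background events for non-target cases ------------------------------
    bg_terms = list(config.background_terms)
    p_bg = np.array([baselines[t] for t in bg_terms])
    bg_fired = rng.random((n, len(bg_terms))) < p_bg
    bg_fired[is_target_case, :] = False
    none_idx = np.flatnonzero(~is_target_case & ~bg_fired.any(axis=1))
    if none_idx.size:
        forced = rng.choice(len(bg_terms), size=none_idx.size, p=p_bg / p_bg.sum())
        bg_fired[none_idx, forced] = True

    # REAC table -----------------------------------------------------------
    t_case, t_term = np.nonzero(target_fired)
    b_case, b_term = np.nonzero(bg_fired)
    reac_case = np.concatenate([case_id[t_case], case_id[b_case]])
    reac_term = np.concatenate([
        np.array(target_terms, dtype=object)[t_term] if t_term.size else np.empty(0, object),
        np.array(bg_terms, dtype=object)[b_term] if b_term.size else np.empty(0, object),
    ])
    order = np.argsort(reac_case, kind="stable")
    reac_case, reac_term = reac_case[order], reac_term[order]
    outcome = rng.choice(_OUTCOME_VOCAB, size=reac_case.size, p=_OUTCOME_PROBS)
    reac = pd.DataFrame({
        "case_id": reac_case,
        "preferred_term": reac_term,
        "outcome": outcome,
    })

    # DRUG table -----------------------------------------------------------
    d_case, d_drug = np.nonzero(exposed)
    involvement = rng.choice(
        INVOLVEMENT_CATEGORIES, size=d_case.size, p=np.asarray(config.involvement_mix))
    atc = np.array([d.atc_code for d in config.drugs], dtype=object)[d_drug]
    drug = pd.DataFrame({
        "case_id": case_id[d_case],
        "drug_name": np.array(drug_names, dtype=object)[d_drug],
        "involvement": involvement,
        "atc_code": atc,
    })

    # exact duplicate rows -------------------------------------------------
    n_drug_rows, n_reac_rows = len(drug), len(reac)
    dup_drug = rng.random(n_drug_rows) < config.duplicate_rate
    dup_reac = rng.random(n_reac_rows) < config.duplicate_rate
    drug = drug.iloc[np.repeat(np.arange(n_drug_rows), 1 + dup_drug)].reset_index(drop=True)
    reac = reac.iloc[np.repeat(np.arange(n_reac_rows), 1 + dup_reac)].reset_index(drop=True)

    # DEMO table with missingness -----------------------------------------
    miss = config.missingness
    u_sex = rng.random(n)
    u_age = rng.random(n)
    # one shared uniform for height and weight: anthropometric fields tend to
    # be missing together in real reports, and nesting keeps both marginal
    # missingness probabilities exact
    u_anthro = rng.random(n)
    sex_out = np.where(female, "female", "male").astype(object)
    sex_out[u_sex < miss.get("sex", 0.0)] = np.nan
    age_out = age_band.copy()
    age_out[u_age < miss.get("age", 0.0)] = np.nan
    height_out = height.copy()
    height_out[u_anthro < miss.get("height", 0.0)] = np.nan
    if config.weight_banded:
        weight_out = np.array(
            [f"{int(w // 10) * 10} kg range" for w in weight], dtype=object)
        weight_out[u_anthro < miss.get("weight", 0.0)] = np.nan
    else:
        weight_out = weight.copy()
        weight_out[u_anthro < miss.get("weight", 0.0)] = np.nan
    demo = pd.DataFrame({
        "case_id": case_id,
        "sex": sex_out,
        "age_band": age_out,
        "height_cm": height_out,
        "weight_kg": weight_out,
    })

    cases = pd.DataFrame({
        "case_id": case_id,
        "female": female,
        "age_years": age_years,
        "height_cm": height,
        "weight_kg": weight,
        "bmi": bmi,
        "is_outlier": is_outlier,
        "is_target_case": is_target_case,
        "n_target_terms": target_fired.sum(axis=1),
        "n_background_terms": bg_fired.sum(axis=1),
        "n_drugs": exposed.sum(axis=1),
    })
    truth = CohortTruth(
        scenario=config,
        cases=cases,
        planted_effects=dict(config.planted_effects),
        exposure_counts={d: int(c) for d, c in zip(drug_names, exposed.sum(axis=0))},
        outlier_case_ids=tuple(case_id[is_outlier]),
        n_target_cases=int(is_target_case.sum()),
        n_drug_rows=n_drug_rows,
        n_reac_rows=n_reac_rows,
        n_dup_drug_rows=int(dup_drug.sum()),
        n_dup_reac_rows=int(dup_reac.sum()),
    )
    return demo, drug, reac, truth


def write_fixture(tables, directory, truth: CohortTruth | None = None,
                  encoding: str = "utf-8") -> Dict[str, Path]:
    """Write (demo, drug, reac) under ``directory``; optionally the truth record.

    Returns a mapping from logical name to path.  Files round-trip through
    :mod:`pvsignal.jader_io` with equality.
    """
    demo, drug, reac = tables
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "demo": directory / "demo.csv",
        "drug": directory / "drug.csv",
        "reac": directory / "reac.csv",
    }
    jader_io.write_table(demo, paths["demo"], "DEMO", encoding=encoding)
    jader_io.write_table(drug, paths["drug"], "DRUG", encoding=encoding)
    jader_io.write_table(reac, paths["reac"], "REAC", encoding=encoding)
    if truth is not None:
        paths["truth"] = directory / "truth.json"
        paths["truth_cases"] = directory / "truth_cases.csv"
        scalars = {
            "n_cases": truth.scenario.n_cases,
            "seed": truth.scenario.seed,
            "n_target_cases": truth.n_target_cases,
            "n_drug_rows": truth.n_drug_rows,
            "n_reac_rows": truth.n_reac_rows,
            "n_dup_drug_rows": truth.n_dup_drug_rows,
            "n_dup_reac_rows": truth.n_dup_reac_rows,
            "outlier_case_ids": list(truth.outlier_case_ids),
            "exposure_counts": truth.exposure_counts,
            "planted_effects": {f"{d}||{t}": v
                                for (d, t), v in truth.planted_effects.items()},
        }
        paths["truth"].write_text(json.dumps(scalars, indent=1, sort_keys=True))
        truth.cases.to_csv(paths["truth_cases"], index=False)
    return paths


def table_digest(df: pd.DataFrame) -> str:
    """Stable content digest of a table (order-sensitive), for determinism tests."""
    payload = df.to_csv(index=False).encode()
    return hashlib.sha256(payload).hexdigest()
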