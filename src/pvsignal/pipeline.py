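"""End-to-end pipeline: data -> cohort -> screen -> univariate -> model -> PCA.

``run_pipeline`` drives every stage from a single :class:`PipelineConfig`,
writes each stage's tables and figures under the output directory, logs the
cohort-flowchart counts, and finishes with a manifest of artifact digests so
reruns can be compared byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple

import pandas as pd

from . import cohort as cohort_mod
from . import jader_io, multivariate, pca, signals, synthetic, univariate
from .config import ScenarioConfig
from .errors import ConfigurationError, PvSignalError

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "STAGES"]

STAGES = ("simulate", "cohort", "screen", "univariate", "model", "pca")


@dataclass
class PipelineConfig:
    """Inputs, thresholds and output location for one pipeline run.

    Exactly one of ``input_dir`` (directory holding demo.csv/drug.csv/
    reac.csv) or ``scenario`` (synthetic generator configuration) must be
    given.
    """

    output_dir: Path
    input_dir: Optional[Path] = None
    scenario: Optional[ScenarioConfig] = None
    term_rule: object = "fracture"
    min_reports: int = 0
    signal_ror: float = 1.0
    signal_p: float = 0.05
    drug_min_reports: int = 50
    event_min_reports: int = 70
    max_model_drugs: Optional[int] = None   # cap on screened drugs entering the model
    bmi_bounds: Tuple[float, float] = (10.0, 100.0)
    encoding: str = "utf-8"
    until: str = "pca"
    figures: bool = True
    extra: dict = field(default_factory=dict)

    def validate(self) -> None:
        if (self.input_dir is None) == (self.scenario is None):
            raise ConfigurationError(
                "input_dir/scenario", "exactly one input source must be given")
        if self.until not in STAGES:
            raise ConfigurationError("until", f"must be one of {STAGES}")
        for name in ("min_reports", "drug_min_reports", "event_min_reports"):
            if getattr(self, name) < 0:
                raise ConfigurationError(name, "must be nonnegative")
        if not (0 < self.signal_p <= 1):
            raise ConfigurationError("signal_p", "must lie in (0, 1]")


@dataclass
class PipelineResult:
    """Artifact manifest and headline numbers of one run."""

    output_dir: Path
    manifest: Dict[str, str]
    report: Optional[cohort_mod.CohortReport] = None
    n_drugs_screened: int = 0
    n_signals: int = 0
    model_n_used: int = 0
    pca_shape: Tuple[int, int] = (0, 0)

    def write_manifest(self) -> Path:
        path = self.output_dir / "manifest.json"
        path.write_text(json.dumps(self.manifest, indent=1, sort_keys=True))
        return path


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _record(result: PipelineResult, path: Path) -> None:
    result.manifest[str(path.relative_to(result.output_dir))] = _sha256(path)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the pipeline through ``config.until``; returns the manifest.

    Raises on the first stage error after logging the cause; partial outputs
    written so far stay on disk.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = PipelineResult(output_dir=out, manifest={})
    stop = STAGES.index(config.until)

    # --- stage: simulate / load ------------------------------------------
    if config.scenario is not None:
        logger.info("simulate: generating %d cases (seed %d)",
                    config.scenario.n_cases, config.scenario.seed)
        demo, drug, reac, truth = synthetic.generate_cohort(config.scenario)
        paths = synthetic.write_fixture((demo, drug, reac), out / "tables", truth)
        for p in paths.values():
            _record(result, p)
    else:
        indir = Path(config.input_dir)
        for name in ("demo.csv", "drug.csv", "reac.csv"):
            if not (indir / name).exists():
                raise FileNotFoundError(f"missing input file: {indir / name}")
        demo = jader_io.read_table(indir / "demo.csv", "DEMO", encoding=config.encoding)
        drug = jader_io.read_table(indir / "drug.csv", "DRUG", encoding=config.encoding)
        reac = jader_io.read_table(indir / "reac.csv", "REAC", encoding=config.encoding)
    if stop < STAGES.index("cohort"):
        result.write_manifest()
        return result

    # --- stage: cohort ----------------------------------------------------
    rows, report = cohort_mod.build_analysis_table(
        demo, drug, reac, term_rule=config.term_rule, bmi_bounds=config.bmi_bounds)
    result.report = report
    logger.info("cohort: %s", {k: v for k, v in report.__dict__.items() if k != "extra"})
    _record(result, report.write(out / "cohort_report.txt"))
    rows_path = out / "analysis_rows.csv"
    rows.to_csv(rows_path, index=False)
    _record(result, rows_path)
    if stop < STAGES.index("screen"):
        result.write_manifest()
        return result

    # --- stage: screen ----------------------------------------------------
    screen = signals.screen_drugs(
        rows, min_reports=config.min_reports,
        signal_ror=config.signal_ror, signal_p=config.signal_p)
    screen_df = signals.results_frame(screen)
    result.n_drugs_screened = len(screen)
    result.n_signals = int(screen_df["is_signal"].sum()) if len(screen_df) else 0
    logger.info("screen: %d drugs, %d signals", result.n_drugs_screened, result.n_signals)
    screen_path = out / "signals.csv"
    screen_df.to_csv(screen_path, index=False)
    _record(result, screen_path)
    if config.figures:
        _record(result, signals.volcano_plot(screen, out / "volcano.png"))
    if stop < STAGES.index("univariate"):
        result.write_manifest()
        return result

    # --- stage: univariate ------------------------------------------------
    chars = univariate.characteristics_table(rows)
    chars_path = out / "characteristics.csv"
    chars.to_csv(chars_path, index=False)
    _record(result, chars_path)
    if stop < STAGES.index("model"):
        result.write_manifest()
        return result

    # --- stage: model -----------------------------------------------------
    signal_drugs = [r.drug_name for r in screen if r.is_signal]
    if config.max_model_drugs is not None:
        signal_drugs = signal_drugs[:config.max_model_drugs]
    if signal_drugs:
        spec = multivariate.LogisticSpec(drug_indicators=tuple(signal_drugs))
        design, outcome = multivariate.build_design(rows, spec)
        fit = multivariate.fit_logistic(
            design, outcome, groups=rows.loc[design.index, "case_id"])
        multivariate.unit_and_range_or(fit, design)
        result.model_n_used = fit.n_used
        model_df = fit.params.copy()
        model_df.index.name = "term"
        for cov, value in fit.unit_or.items():
            model_df.loc[f"unit_or:{cov}", "odds_ratio"] = value
        for cov, value in fit.range_or.items():
            model_df.loc[f"range_or:{cov}", "odds_ratio"] = value
        model_path = out / "model.csv"
        model_df.to_csv(model_path)
        _record(result, model_path)
        logger.info("model: n_used=%d converged=%s", fit.n_used, fit.converged)
    else:
        logger.warning("model: no signal drugs; stage skipped")
    if stop < STAGES.index("pca"):
        result.write_manifest()
        return result

    # --- stage: pca -------------------------------------------------------
    try:
        drugs_sel, events_sel = pca.select_entities(
            rows, signal_drugs,
            drug_min_reports=config.drug_min_reports,
            event_min_reports=config.event_min_reports)
        matrix = pca.build_ror_matrix(rows, drugs_sel, events_sel)
        pca_map = pca.pca_correlation(matrix)
        result.pca_shape = matrix.values.shape
        matrix_path = out / "lnror_matrix.csv"
        matrix.to_frame().to_csv(matrix_path)
        _record(result, matrix_path)
        loadings_path = out / "pca_loadings.csv"
        pca_map.loadings_frame().to_csv(loadings_path)
        _record(result, loadings_path)
        scores_path = out / "pca_scores.csv"
        pca_map.scores_frame().to_csv(scores_path)
        _record(result, scores_path)
        ratio_path = out / "pca_variance.csv"
        pd.DataFrame({
            "component": [f"PC{i + 1}" for i in range(len(pca_map.eigenvalues))],
            "eigenvalue": pca_map.eigenvalues,
            "explained_variance_ratio": pca_map.explained_variance_ratio,
        }).to_csv(ratio_path, index=False)
        _record(result, ratio_path)
        if config.figures:
            for p in pca.biplot(pca_map, out / "pca_loadings.png", out / "pca_scores.png"):
                _record(result, p)
        logger.info("pca: %d drugs x %d events; PC1 %.1f%%, PC2 %.1f%%",
                    *matrix.values.shape,
                    100 * pca_map.explained_variance_ratio[0],
                    100 * pca_map.explained_variance_ratio[1])
    except PvSignalError as exc:
        logger.warning("pca: stage skipped (%s)", exc)

    result.write_manifest()
    return result
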