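"""End-to-end study orchestration.

``run_study`` reproduces the shape of a two-group longitudinal screening
analysis: cohort descriptives, per-marker univariate longitudinal
classification (the single-biomarker model, q = 2), the joint multivariate
classification (all four biomarkers, q = 8), and a performance grid of
sensitivity / specificity / AUC with confidence interval per strategy and
validation mode.  Every stochastic component is driven by the single
config seed, so a config fully determines every reported number.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import BIOMARKERS, GDM, CohortTable, read_cohort
from .descriptives import GroupSummary, describe_by_group
from .discriminant import ClassificationResult, cross_validate
from .evaluation import evaluate_scores
from .mlmm import ModelSpec, MultivariateLongitudinalModel
from .simulate import GeneratorParams, default_generator_params, generate_cohort

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """The pipeline configuration violates an invariant."""


@dataclass
class PipelineConfig:
    """Everything needed to rerun a study deterministically."""

    seed: int
    cohort_csv: str | None = None
    generator: GeneratorParams | None = None
    markers: tuple[str, ...] = BIOMARKERS
    covariates: tuple[str, ...] = ("age", "bmi", "sbp", "dbp")
    resubstitution: bool = True
    cv_folds: int | None = 10
    ci_method: str = "delong"
    ci_level: float = 0.95
    n_boot: int = 2000
    outdir: str | None = None
    log_level: str = "INFO"

    def __post_init__(self):
        if self.seed is None:
            raise ConfigError("a seed is mandatory")
        if not self.resubstitution and not self.cv_folds:
            raise ConfigError("at least one validation mode must be enabled")
        if self.cohort_csv is None and self.generator is None:
            self.generator = default_generator_params()
        unknown = set(self.markers) - set(BIOMARKERS)
        if unknown:
            raise ConfigError(f"unknown marker(s): {sorted(unknown)}")

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "cohort_csv": self.cohort_csv,
            "generator": None if self.generator is None else self.generator.to_dict(),
            "markers": list(self.markers),
            "covariates": list(self.covariates),
            "resubstitution": self.resubstitution,
            "cv_folds": self.cv_folds,
            "ci_method": self.ci_method,
            "ci_level": self.ci_level,
            "n_boot": self.n_boot,
            "log_level": self.log_level,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        gen = d.get("generator")
        return cls(
            seed=d["seed"],
            cohort_csv=d.get("cohort_csv"),
            generator=None if gen is None else GeneratorParams.from_dict(gen),
            markers=tuple(d.get("markers", BIOMARKERS)),
            covariates=tuple(d.get("covariates", ("age", "bmi", "sbp", "dbp"))),
            resubstitution=d.get("resubstitution", True),
            cv_folds=d.get("cv_folds", 10),
            ci_method=d.get("ci_method", "delong"),
            ci_level=d.get("ci_level", 0.95),
            n_boot=d.get("n_boot", 2000),
            outdir=d.get("outdir"),
            log_level=d.get("log_level", "INFO"),
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = (
            json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        )
        return cls.from_dict(data)

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()


def _jsonify(obj):
    """Recursively convert to JSON-safe builtins (NaN -> None)."""
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, np.ndarray)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if math.isnan(f) else f
    return obj


def _round_half_up_pct(x: float) -> int:
    return int(Decimal(100 * x).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def _metrics_from_classification(
    cr: ClassificationResult, config: PipelineConfig
) -> tuple[dict, dict]:
    roc = evaluate_scores(
        cr.scores,
        cr.true_groups,
        pi1=cr.pi1,
        pi2=cr.pi2,
        ci_level=config.ci_level,
        ci_method=config.ci_method,
        seed=config.seed,
        n_boot=config.n_boot,
    )
    bayes = roc.operating_points["bayes"]
    youden = roc.operating_points["youden"]
    metrics = {
        "auc": roc.auc,
        "auc_ci": list(roc.auc_ci),
        "ci_level": config.ci_level,
        "sens_bayes": bayes.sensitivity,
        "spec_bayes": bayes.specificity,
        "threshold_bayes": bayes.threshold,
        "sens_youden": youden.sensitivity,
        "spec_youden": youden.specificity,
        "threshold_youden": youden.threshold,
        "pi1": cr.pi1,
        "pi2": cr.pi2,
        "n": int(len(cr.table)),
        "n_gdm": int(np.sum(cr.true_groups == GDM)),
    }
    roc_points = {"fpr": roc.fpr.tolist(), "tpr": roc.sens.tolist()}
    return metrics, roc_points


def _strategy_spec(markers, config: PipelineConfig) -> ModelSpec:
    return ModelSpec(
        response_markers=tuple(markers), fixed_covariates=tuple(config.covariates)
    )


def _run_strategy(
    table: CohortTable, spec: ModelSpec, config: PipelineConfig
) -> dict:
    """Fit + classify + evaluate one strategy under each validation mode."""
    out = {}
    if config.resubstitution:
        model = MultivariateLongitudinalModel(table, spec)
        res = model.fit()
        cr = res.to_classifier().classify(table)
        metrics, roc_points = _metrics_from_classification(cr, config)
        metrics["fit_converged"] = res.converged
        metrics["loglik"] = res.loglik
        out["resubstitution"] = {"metrics": metrics, "roc": roc_points}
    if config.cv_folds:
        cr = cross_validate(
            table, spec, folds=config.cv_folds, seed=config.seed
        )
        metrics, roc_points = _metrics_from_classification(cr, config)
        out["cross_validation"] = {"metrics": metrics, "roc": roc_points}
    return out


def run_univariate(table: CohortTable, marker: str, config: PipelineConfig) -> dict:
    """Single-biomarker longitudinal strategy (q = 2) for one marker."""
    return _run_strategy(table, _strategy_spec((marker,), config), config)


def run_multivariate(table: CohortTable, config: PipelineConfig) -> dict:
    """Joint strategy over all configured markers (q = 2p)."""
    return _run_strategy(table, _strategy_spec(config.markers, config), config)


@dataclass
class StudyReport:
    """Full study output: descriptives, performance grid, provenance."""

    config: PipelineConfig
    descriptives: GroupSummary
    performance: dict  # {strategy: {mode: {"metrics":..., "roc":...}}}
    provenance: dict

    def to_dict(self) -> dict:
        return _jsonify(
            {
                "provenance": self.provenance,
                "group_sizes": self.descriptives.group_sizes,
                "characteristics": self.descriptives.characteristics.to_dict(
                    orient="records"
                ),
                "marker_trends": self.descriptives.marker_trends.to_dict(
                    orient="records"
                ),
                "performance": self.performance,
            }
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)

    def performance_grid(self, mode: str = "resubstitution") -> pd.DataFrame:
        """Rows: four univariate strategies + the multivariate one."""
        rows = []
        for strategy, modes in self.performance.items():
            if mode not in modes:
                continue
            m = modes[mode]["metrics"]
            rows.append(
                {
                    "strategy": strategy,
                    "sensitivity": m["sens_bayes"],
                    "specificity": m["spec_bayes"],
                    "auc": m["auc"],
                    "auc_ci_low": m["auc_ci"][0],
                    "auc_ci_high": m["auc_ci"][1],
                }
            )
        return pd.DataFrame(rows)

    def to_markdown(self) -> str:
        lines = [
            "# Study report",
            "",
            f"- config hash: `{self.provenance['config_sha256']}`",
            f"- seed: {self.provenance['seed']}",
            f"- package version: {self.provenance['package_version']}",
            f"- subjects: {self.descriptives.group_sizes}",
            "",
            "## Marker trends by group",
            "",
            "| marker | visit | non-GDM | GDM | p (group) |",
            "|---|---|---|---|---|",
        ]
        for _, r in self.descriptives.marker_trends.iterrows():
            p = "" if pd.isna(r["p_group"]) else f"{r['p_group']:.3g}"
            lines.append(
                f"| {r['marker']} | {r['visit']} | {r['non_gdm']} | {r['gdm']} | {p} |"
            )
        for mode in ("resubstitution", "cross_validation"):
            grid = self.performance_grid(mode)
            if grid.empty:
                continue
            lines += [
                "",
                f"## Predictive performance ({mode.replace('_', ' ')})",
                "",
                "Sensitivity/specificity at the Bayes threshold ln(pi2/pi1);"
                " percentages rounded half-up.",
                "",
                "| strategy | sensitivity | specificity | AUC | "
                f"{int(100 * self.config.ci_level)}% CI for AUC |",
                "|---|---|---|---|---|",
            ]
            for _, r in grid.iterrows():
                lines.append(
                    f"| {r['strategy']} | {_round_half_up_pct(r['sensitivity'])} "
                    f"| {_round_half_up_pct(r['specificity'])} "
                    f"| {_round_half_up_pct(r['auc'])} "
                    f"| {_round_half_up_pct(r['auc_ci_low'])}"
                    f"-{_round_half_up_pct(r['auc_ci_high'])} |"
                )
        lines.append("")
        return "\n".join(lines)


def load_or_generate_cohort(config: PipelineConfig) -> CohortTable:
    if config.cohort_csv is not None:
        return read_cohort(config.cohort_csv)
    return generate_cohort(config.generator, seed=config.seed)


def run_study(config: PipelineConfig) -> StudyReport:
    """Run descriptives + univariate + multivariate strategies end to end."""
    logging.basicConfig(level=config.log_level)
    table = load_or_generate_cohort(config)
    logger.info("cohort: %d subjects, groups %s", table.n_subjects, table.group_counts())

    descriptives = describe_by_group(table)
    performance = {}
    for marker in config.markers:
        logger.info("univariate strategy: %s", marker)
        performance[marker] = run_univariate(table, marker, config)
    logger.info("multivariate strategy: %s", "+".join(config.markers))
    performance["multivariate"] = run_multivariate(table, config)

    provenance = {
        "config_sha256": config.config_hash(),
        "seed": config.seed,
        "package_version": __version__,
        "config": config.to_dict(),
    }
    report = StudyReport(
        config=config,
        descriptives=descriptives,
        performance=performance,
        provenance=provenance,
    )
    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(report.to_json())
        (outdir / "report.md").write_text(report.to_markdown())
        for strategy, modes in performance.items():
            for mode, payload in modes.items():
                roc = payload["roc"]
                pd.DataFrame(roc).to_csv(
                    outdir / f"roc_{mode}_{strategy}.csv", index=False
                )
    return report
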