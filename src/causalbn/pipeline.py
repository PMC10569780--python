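"""End-to-end analysis pipeline.

Orchestrates the full workflow: cohort loading or simulation, exclusion of
early postoperative deaths, outcome discretization, node-mode selection,
constrained structure learning per algorithm (with the whitelist-retry
safety loop), causal-role classification, association screening, propensity
stratification with CMH balance checks, and a family of Cox models (crude,
one per graph-derived confounder set, and one on the screen-derived
propensity covariates).  All artifacts are written to an output directory
with a hash manifest; reruns with an identical configuration produce
byte-identical payloads.
"""

from __future__ import annotations

import hashlib
import json
import os
import warnings
from dataclasses import asdict, dataclass, field

import pandas as pd
import yaml

from . import effect_estimation as ee
from .bn_core import ConstraintSet, DiscreteDataset, validate_constraints, write_dot, write_graphml
from .causal_id import CausalRoleReport, build_report, treatment_outcome_association
from .structure_learning import LearnedStructure, learn_with_whitelist_retry
from .synthetic_cohort import (
    ScenarioConfig,
    apply_exclusions,
    discretize_outcomes,
    make_ground_truth,
    read_cohort,
    sample_cohort,
    simplify_node_set,
)

__all__ = [
    "AnalysisConfig",
    "AnalysisReport",
    "StageError",
    "default_constraints",
    "default_layers",
    "run_analysis",
]

ALGORITHMS = ("npc_like", "mmhc", "sm_exact")
COMPARISONS = ("adjuvant_vs_surgery", "capox_vs_capmono")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and a machine code."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class AnalysisConfig:
    """Structured configuration for one pipeline run."""

    scenario: str | None = "confounded"  # named synthetic scenario ...
    input_path: str | None = None  # ... or a cohort file (TSV) instead
    comparison: str = "adjuvant_vs_surgery"
    algorithms: tuple[str, ...] = ALGORITHMS
    node_mode: str = "simplified"
    alpha: float = 0.05
    score_kind: str = "BIC"
    seed: int = 0
    n: int = 1000
    output_dir: str | None = None

    def __post_init__(self) -> None:
        self.algorithms = tuple(self.algorithms)
        if not self.algorithms or any(a not in ALGORITHMS for a in self.algorithms):
            raise ValueError(f"algorithms must be a non-empty subset of {ALGORITHMS}")
        if self.comparison not in COMPARISONS:
            raise ValueError(f"comparison must be one of {COMPARISONS}")
        if self.scenario is None and self.input_path is None:
            raise ValueError("either a scenario or an input path is required")

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if raw.get("algorithms") is not None:
            raw["algorithms"] = tuple(raw["algorithms"])
        return cls(**raw)


def default_layers() -> dict[str, int]:
    """The expert layer ordering of the cohort schema.

    Demographics sit on top (nothing causes sex or age), then fitness
    (comorbidity count, physical-status score), then tumour pathology, then
    treatment, then recurrence, then the survival nodes.  Edges may only run
    downward or within a layer; e.g. a survival node can never point at the
    physical-status score.  The map is a documented reconstruction of the
    published ordering and can be overridden via a constraints file.
    """
    layers = {
        "sex": 0,
        "age3": 1,
        "comorbidities": 2,
        "ASA": 2,
        "pT": 3,
        "pN": 3,
        "subsite": 3,
        "grade": 3,
        "treatment": 4,
        "rec_01y": 5,
        "rec_02y": 5,
    }
    for k in range(1, 6):
        layers[f"surv_{k:02d}y"] = 6
    return layers


def default_constraints(comparison: str = "adjuvant_vs_surgery") -> ConstraintSet:
    """Layer-derived constraint set (identical for both comparisons)."""
    if comparison not in COMPARISONS:
        raise ValueError(f"comparison must be one of {COMPARISONS}")
    from .bn_core import constraints_from_layers

    return constraints_from_layers(default_layers())


@dataclass
class AnalysisReport:
    """Everything one run produced, serializable to JSON."""

    config: AnalysisConfig
    structures: dict[str, LearnedStructure]
    role_reports: dict[str, CausalRoleReport]
    association: dict
    propensity: dict
    cmh: dict
    cox_table: pd.DataFrame
    log: list[str] = field(default_factory=list)

    def to_payload(self) -> dict:
        return {
            "config": asdict(self.config),
            "graphs": {
                alg: {
                    "edges": sorted(map(list, s.graph.edges)),
                    "algorithm": s.algorithm,
                    "ambiguous_regions": len(s.ambiguous),
                    "violations": validate_constraints(s.graph, s.constraints),
                    "treatment_outcome_association": treatment_outcome_association(
                        s.graph,
                        "treatment",
                        {n for n in s.graph.nodes if n.startswith("surv_")},
                    ),
                    "resolution_log": s.resolution_log,
                }
                for alg, s in self.structures.items()
            },
            "roles": {alg: r.to_dict() for alg, r in self.role_reports.items()},
            "association_screen": self.association,
            "propensity": self.propensity,
            "cmh": self.cmh,
            "cox_models": self.cox_table.to_dict(orient="records"),
            "log": self.log,
        }


def _prepare_cohort(config: AnalysisConfig, log: list[str]):
    if config.input_path:
        cohort = read_cohort(config.input_path)
        gt = None
    else:
        scenario = config.scenario
        if config.comparison == "capox_vs_capmono" and scenario == "confounded":
            scenario = "null_effect"
        gt = make_ground_truth(ScenarioConfig(scenario, config.n, config.seed))
        cohort = sample_cohort(gt, config.n, config.seed)
    required = {"treatment", "time", "event", "rec_time", "rec_event"}
    missing = required - set(cohort.columns)
    if missing:
        raise StageError("load", "missing_columns", f"cohort lacks {sorted(missing)}")
    cohort, removed = apply_exclusions(cohort)
    log.append(f"excluded {removed} early postoperative deaths (day <= 90)")
    return cohort, gt


def run_analysis(config: AnalysisConfig) -> AnalysisReport:
    """Execute the full pipeline for one configuration."""
    log: list[str] = []
    cohort, _ = _prepare_cohort(config, log)

    try:
        dataset = discretize_outcomes(cohort)
        dataset = simplify_node_set(dataset, config.node_mode)
    except Exception as err:
        raise StageError("discretize", "bad_outcomes", str(err)) from err

    constraints = default_constraints(config.comparison)
    outcome_nodes = {n for n in dataset.names if n.startswith(("surv_", "rec_"))}
    survival_nodes = {n for n in dataset.names if n.startswith("surv_")}

    structures: dict[str, LearnedStructure] = {}
    role_reports: dict[str, CausalRoleReport] = {}
    for alg in config.algorithms:
        try:
            s = learn_with_whitelist_retry(
                dataset,
                constraints,
                algorithm=alg,
                alpha=config.alpha,
                score_kind=config.score_kind,
            )
        except Exception as err:
            raise StageError("learn", alg, str(err)) from err
        structures[alg] = s
        role_reports[alg] = build_report(s.graph, "treatment", outcome_nodes)
        log.append(
            f"{alg}: {len(s.graph.edges)} edges, "
            f"confounders {sorted(role_reports[alg].confounders())}"
        )

    # association screen on pretreatment covariates
    covariates = [
        c
        for c in cohort.columns
        if c not in ("treatment", "time", "event", "rec_time", "rec_event")
    ]
    try:
        screen = ee.association_screen(cohort, "treatment", covariates)
    except Exception as err:
        raise StageError("screen", "association", str(err)) from err
    screened = ee.significant_covariates(screen, config.alpha)
    association = {
        v: {
            "statistic": r.statistic,
            "df": r.df,
            "p_value": r.p_value,
            "significant": (not r.degenerate) and r.p_value < config.alpha,
        }
        for v, r in screen.items()
    }

    # propensity + CMH balance
    propensity_payload: dict = {"covariates": screened}
    cmh_payload: dict = {}
    if screened:
        try:
            prop = ee.fit_propensity(cohort, screened, "treatment")
        except Exception as err:
            raise StageError("propensity", "fit", str(err)) from err
        propensity_payload.update(
            coefficients={k: float(v) for k, v in prop.coefficients.items()},
            bin_edges=[float(x) for x in prop.bin_edges],
            separation_warning=prop.separation_warning,
        )
        t_bin = (
            cohort["treatment"].astype(str)
            == str(sorted(cohort["treatment"].astype(str).unique())[1])
        ).to_numpy(int)
        for var in screened:
            levels = (
                list(cohort[var].cat.categories)
                if isinstance(cohort[var].dtype, pd.CategoricalDtype)
                else sorted(cohort[var].astype(str).unique())
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                factor = ee.dichotomize(cohort[var], str(levels[-1]))
            marginal = ee.cmh_test(t_bin, factor, [0] * len(cohort))
            stratified = ee.cmh_test(t_bin, factor, prop.strata)
            cmh_payload[var] = {
                "level": str(levels[-1]),
                "marginal_p": marginal.p_value,
                "stratified_p": stratified.p_value,
                "stratified_statistic": stratified.statistic,
            }

    # Cox models: crude, per-graph confounder sets, propensity covariates
    fits: dict[str, ee.CoxFit] = {}
    fits["crude"] = ee.fit_cox(cohort, ["treatment"])
    for alg, report in role_reports.items():
        conf = sorted(report.confounders())
        fits[f"bn_{alg}"] = ee.fit_cox(cohort, ["treatment", *conf])
    if screened:
        fits["propensity_screen"] = ee.fit_cox(cohort, ["treatment", *screened])
    treatment_term = next(k for k in fits["crude"].hr if k.startswith("treatment["))
    cox_table = ee.hr_comparison_table(fits, treatment_term)

    report = AnalysisReport(
        config=config,
        structures=structures,
        role_reports=role_reports,
        association=association,
        propensity=propensity_payload,
        cmh=cmh_payload,
        cox_table=cox_table,
        log=log,
    )
    if config.output_dir:
        _write_artifacts(report, config.output_dir)
    return report


def _write_artifacts(report: AnalysisReport, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    files: list[str] = []
    for alg, s in report.structures.items():
        dot = os.path.join(outdir, f"graph_{alg}.dot")
        gml = os.path.join(outdir, f"graph_{alg}.graphml")
        write_dot(s.graph, dot)
        write_graphml(s.graph, gml)
        files += [dot, gml]
    payload_path = os.path.join(outdir, "report.json")
    with open(payload_path, "w") as fh:
        json.dump(report.to_payload(), fh, indent=2, sort_keys=True, default=str)
    files.append(payload_path)
    md_path = os.path.join(outdir, "hr_table.md")
    with open(md_path, "w") as fh:
        fh.write(ee.hr_table_markdown(report.cox_table) + "\n")
    files.append(md_path)

    manifest = {}
    for f in files:
        with open(f, "rb") as fh:
            manifest[os.path.basename(f)] = hashlib.sha256(fh.read()).hexdigest()
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
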