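"""Synthetic registry-like cohorts with a known causal ground truth.

Real cancer-registry data of this kind are held by the registry and cannot be
redistributed, so every analysis here is exercised on synthetic cohorts drawn
from an explicit generating model: a DAG with conditional probability tables
over categorical pretreatment covariates and treatment, a proportional-hazards
survival model (exponential baseline by default, Weibull shape available), an
independent recurrence process, and administrative censoring from a uniform
follow-up window.  The generator therefore knows the true graph, the true
confounders, and the true treatment log hazard ratio — the recovery targets
of every downstream test.

Four named scenarios cover the qualitatively distinct regimes:

* ``confounded`` — confounding by indication: sicker patients (positive
  nodal status, worse physical status, older age) are less likely to receive
  adjuvant treatment while nodal status and physical status also raise the
  death hazard; true treatment HR 0.45.
* ``unconfounded`` — same outcome model but treatment assigned by coin flip.
* ``null_effect`` — regimen choice (combination vs monotherapy) driven by age
  and comorbidity count, with zero true treatment effect and a hazard that
  depends on nodal status only: treatment and survival are truly unrelated.
* ``unmeasured_confounder`` — a hidden frailty drives both treatment and
  hazard and is dropped from the emitted data, creating a spurious
  treatment-survival dependence no measured adjustment can remove.

Preprocessing mirrors registry practice: early postoperative deaths
(within 90 days of surgery, boundary inclusive) are excluded, overall
survival is discretized into Boolean yearly nodes with NA for
administratively censored horizons, recurrence similarly for the first two
years, and age is binned into 70-74 / 75-79 / 80+.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import log
from typing import Mapping

import numpy as np
import pandas as pd

from .bn_core import DAG, DiscreteDataset, Variable, write_dot

__all__ = [
    "YEAR_DAYS",
    "SCENARIOS",
    "Cpt",
    "HazardModel",
    "GroundTruth",
    "ScenarioConfig",
    "make_ground_truth",
    "sample_cohort",
    "apply_exclusions",
    "discretize_outcomes",
    "discretize_age",
    "simplify_node_set",
    "expected_skeleton",
    "write_cohort",
    "read_cohort",
    "ground_truth_to_json",
]

YEAR_DAYS = 365.25

SCENARIOS = ("confounded", "unconfounded", "null_effect", "unmeasured_confounder")

# the cohort schema: variable -> ordered levels
SCHEMA: dict[str, tuple[str, ...]] = {
    "sex": ("male", "female"),
    "age3": ("70-74", "75-79", "80+"),
    "comorbidities": ("0", "1", "2+"),
    "ASA": ("I", "II", "III+"),
    "pT": ("1-2", "3", "4"),
    "pN": ("1", "2"),
    "subsite": ("proximal", "distal", "unknown"),
    "grade": ("1-2", "3", "unknown"),
}

_ROOT_PROBS: dict[str, tuple[float, ...]] = {
    "sex": (0.55, 0.45),
    "age3": (0.40, 0.35, 0.25),
    "comorbidities": (0.35, 0.40, 0.25),
    "pT": (0.15, 0.65, 0.20),
    "grade": (0.70, 0.20, 0.10),
}

# pretreatment structure shared by every scenario: physical-status score is
# driven by the comorbidity count, tumour subsite differs by sex, and nodal
# involvement rises with differentiation grade — associations consistently
# present in registry cohorts of this disease
def _base_covariate_cpts() -> dict[str, "Cpt"]:
    cpts = {v: Cpt((), np.array([_ROOT_PROBS[v]])) for v in _ROOT_PROBS}
    cpts["ASA"] = Cpt(
        ("comorbidities",),
        np.array(
            [
                [0.55, 0.35, 0.10],  # 0 comorbidities
                [0.25, 0.50, 0.25],  # 1
                [0.10, 0.40, 0.50],  # 2+
            ]
        ),
    )
    cpts["subsite"] = Cpt(
        ("sex",),
        np.array(
            [
                [0.40, 0.50, 0.10],  # male
                [0.62, 0.28, 0.10],  # female
            ]
        ),
    )
    cpts["pN"] = Cpt(
        ("grade",),
        np.array(
            [
                [0.68, 0.32],  # grade 1-2
                [0.38, 0.62],  # grade 3
                [0.55, 0.45],  # unknown
            ]
        ),
    )
    return cpts


_COVARIATE_EDGES = [("comorbidities", "ASA"), ("sex", "subsite"), ("grade", "pN")]


@dataclass
class Cpt:
    """Conditional probability table: one row per parent configuration."""

    parents: tuple[str, ...]
    table: np.ndarray  # shape (prod(parent cards), n_levels); rows sum to 1

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table, float)
        if not np.allclose(self.table.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("CPT rows must sum to 1 within 1e-12")


@dataclass
class HazardModel:
    """Proportional-hazards model: rate = baseline * exp(sum of effects).

    ``baseline_rate`` is in events per person-year at the reference levels;
    ``effects[(var, level)]`` are additive log hazard ratios; ``shape`` is the
    Weibull shape (1 = exponential, the default).
    """

    baseline_rate: float
    effects: dict[tuple[str, str], float] = field(default_factory=dict)
    treatment_log_hr: float = 0.0
    shape: float = 1.0

    def log_rate(self, cohort: pd.DataFrame, treated: np.ndarray) -> np.ndarray:
        eta = np.full(len(cohort), log(self.baseline_rate))
        for (var, level), beta in self.effects.items():
            eta += beta * (cohort[var].astype(str).to_numpy() == level)
        eta += self.treatment_log_hr * treated
        return eta


@dataclass
class GroundTruth:
    """Everything the generator knows: graph, CPTs, hazards, censoring, estimand."""

    graph: DAG  # covariates + treatment (+ unmeasured nodes)
    cpts: dict[str, Cpt]
    levels: dict[str, tuple[str, ...]]
    survival: HazardModel
    recurrence: HazardModel
    followup_years: tuple[float, float]  # uniform administrative follow-up window
    unmeasured: set[str]
    treatment_levels: tuple[str, str]  # (referent, treated)
    scenario: str

    @property
    def true_log_hr(self) -> float:
        return self.survival.treatment_log_hr

    @property
    def true_hr(self) -> float:
        return float(np.exp(self.survival.treatment_log_hr))


@dataclass
class ScenarioConfig:
    """A fully reproducible cohort recipe: (name, n, seed) plus overrides."""

    name: str
    n: int = 1000
    seed: int = 0
    effects: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.name!r}; choose from {SCENARIOS}")


def _logistic_cpt(
    parents: tuple[str, ...],
    levels: Mapping[str, tuple[str, ...]],
    intercept: float,
    coef: Mapping[tuple[str, str], float],
) -> Cpt:
    """Binary-child CPT from a logistic model on categorical parents."""
    cards = [len(levels[p]) for p in parents]
    q = int(np.prod(cards))
    table = np.zeros((q, 2))
    for row in range(q):
        rem, eta = row, intercept
        for p, card in zip(reversed(parents), reversed(cards)):
            code = rem % card
            rem //= card
            eta += coef.get((p, levels[p][code]), 0.0)
        p1 = 1.0 / (1.0 + np.exp(-eta))
        table[row] = (1.0 - p1, p1)
    return Cpt(parents, table)


def make_ground_truth(config: ScenarioConfig) -> GroundTruth:
    """Build the generating model for a named scenario.

    Effect sizes are fixed design constants chosen so that every conditional
    distribution shifts by at least 0.2 in absolute probability across parent
    levels, giving structure-recovery tests high power at n = 10,000.
    ``config.effects`` may override ``treatment_log_hr`` and
    ``baseline_rate``.
    """
    name = config.name
    levels: dict[str, tuple[str, ...]] = dict(SCHEMA)
    cpts: dict[str, Cpt] = _base_covariate_cpts()
    edges: list[tuple[str, str]] = list(_COVARIATE_EDGES)
    unmeasured: set[str] = set()

    if name in ("confounded", "unconfounded"):
        levels["treatment"] = ("no", "yes")
        if name == "confounded":
            t_parents = ("age3", "ASA", "pN")
            cpts["treatment"] = _logistic_cpt(
                t_parents,
                levels,
                intercept=1.2,
                coef={
                    ("age3", "75-79"): -0.9,
                    ("age3", "80+"): -2.2,
                    ("ASA", "II"): -1.1,
                    ("ASA", "III+"): -2.0,
                    ("pN", "2"): -1.4,
                },
            )
            edges += [(p, "treatment") for p in t_parents]
        else:
            cpts["treatment"] = Cpt((), np.array([[0.60, 0.40]]))
        survival = HazardModel(
            baseline_rate=0.20,
            effects={("pN", "2"): 0.70, ("ASA", "II"): 0.35, ("ASA", "III+"): 0.80},
            treatment_log_hr=log(0.45),
        )
        recurrence = HazardModel(baseline_rate=0.15, effects={("pN", "2"): 0.80})
        treatment_levels = ("no", "yes")
    elif name == "null_effect":
        levels["treatment"] = ("CapMono", "CAPOX")
        t_parents = ("age3", "comorbidities")
        cpts["treatment"] = _logistic_cpt(
            t_parents,
            levels,
            intercept=1.2,
            coef={
                ("age3", "75-79"): -1.3,
                ("age3", "80+"): -2.6,
                ("comorbidities", "1"): -0.8,
                ("comorbidities", "2+"): -1.5,
            },
        )
        edges += [(p, "treatment") for p in t_parents]
        survival = HazardModel(
            baseline_rate=0.20, effects={("pN", "2"): 0.70}, treatment_log_hr=0.0
        )
        recurrence = HazardModel(baseline_rate=0.15, effects={("pN", "2"): 0.80})
        treatment_levels = ("CapMono", "CAPOX")
    elif name == "unmeasured_confounder":
        levels["treatment"] = ("no", "yes")
        levels["U"] = ("0", "1")
        cpts["U"] = Cpt((), np.array([[0.5, 0.5]]))
        cpts["treatment"] = _logistic_cpt(
            ("U",), levels, intercept=0.847, coef={("U", "1"): -1.946}
        )  # P(treated | U=0) = 0.70, P(treated | U=1) = 0.25
        edges.append(("U", "treatment"))
        unmeasured = {"U"}
        survival = HazardModel(
            baseline_rate=0.18, effects={("U", "1"): 0.90}, treatment_log_hr=0.0
        )
        recurrence = HazardModel(baseline_rate=0.15, effects={})
        treatment_levels = ("no", "yes")
    else:  # pragma: no cover - guarded by ScenarioConfig
        raise ValueError(name)

    if "treatment_log_hr" in config.effects:
        survival.treatment_log_hr = float(config.effects["treatment_log_hr"])
    if "baseline_rate" in config.effects:
        survival.baseline_rate = float(config.effects["baseline_rate"])

    graph = DAG(list(levels), edges)
    return GroundTruth(
        graph=graph,
        cpts=cpts,
        levels=levels,
        survival=survival,
        recurrence=recurrence,
        followup_years=(3.0, 10.0),
        unmeasured=unmeasured,
        treatment_levels=treatment_levels,
        scenario=name,
    )


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------


def _sample_node(
    node: str,
    gt: GroundTruth,
    codes: dict[str, np.ndarray],
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    cpt = gt.cpts[node]
    if not cpt.parents:
        rows = np.zeros(n, dtype=np.int64)
    else:
        rows = np.zeros(n, dtype=np.int64)
        for p in cpt.parents:
            rows = rows * len(gt.levels[p]) + codes[p]
    u = rng.random(n)
    cum = np.cumsum(cpt.table, axis=1)
    return (u[:, None] > cum[rows]).sum(axis=1).astype(np.int64)


def _draw_times(
    hm: HazardModel, cohort: pd.DataFrame, treated: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Event times in years from a proportional-hazards Weibull model."""
    rate = np.exp(hm.log_rate(cohort, treated))
    e = rng.exponential(1.0, len(cohort))
    return (e / rate) ** (1.0 / hm.shape)


def sample_cohort(gt: GroundTruth, n: int, seed: int) -> pd.DataFrame:
    """Draw a cohort by ancestral sampling; deterministic per (gt, n, seed).

    Returns one row per patient: categorical covariates and treatment,
    survival follow-up (``time`` in whole days since surgery, ``event``) and
    recurrence follow-up (``rec_time``, ``rec_event``).  Unmeasured
    ground-truth nodes are dropped from the output.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    order = gt.graph.topological_order()
    codes: dict[str, np.ndarray] = {}
    for node in order:
        codes[node] = _sample_node(node, gt, codes, n, rng)

    frame = pd.DataFrame(
        {
            v: pd.Categorical.from_codes(codes[v], categories=list(gt.levels[v]))
            for v in order
        }
    )
    treated = (codes["treatment"] == 1).astype(float)
    t_death = _draw_times(gt.survival, frame, treated, rng)
    t_rec = _draw_times(gt.recurrence, frame, treated * 0.0, rng)
    fu = rng.uniform(*gt.followup_years, n)

    event = t_death <= fu
    time_days = np.maximum(np.round(np.minimum(t_death, fu) * YEAR_DAYS), 1.0)
    # recurrence follow-up is censored administratively only: death does not
    # truncate it, keeping the recurrence nodes independent of survival given
    # their shared covariates (see the methods note on competing risks)
    rec_event = t_rec <= fu
    rec_days = np.maximum(np.round(np.minimum(t_rec, fu) * YEAR_DAYS), 1.0)

    out = frame.drop(columns=sorted(gt.unmeasured))
    out["time"] = time_days
    out["event"] = event
    out["rec_time"] = rec_days
    out["rec_event"] = rec_event
    return out


def apply_exclusions(cohort: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop early postoperative deaths: event within 90 days of surgery.

    The boundary is inclusive ("within 90 days" reads as day <= 90): a death
    on day 90 is excluded, day 91 retained; censored records always stay.
    Returns the filtered cohort and the number of removals.
    """
    drop = cohort["event"].astype(bool) & (cohort["time"] <= 90)
    return cohort.loc[~drop].reset_index(drop=True), int(drop.sum())


def discretize_age(age_years: float) -> str:
    """Bin an age in years into 70-74 / 75-79 / 80+ (cohort is 70 and older)."""
    if age_years < 70:
        raise ValueError("cohort is restricted to ages 70 and older")
    if age_years < 75:
        return "70-74"
    if age_years < 80:
        return "75-79"
    return "80+"


def _yearly_nodes(
    time_days: np.ndarray, event: np.ndarray, horizons: tuple[int, ...], prefix: str
) -> dict[str, np.ndarray]:
    """Boolean yearly outcome codes: 1 = beyond horizon, 0 = event by horizon,
    -1 (NA) = administratively censored before the horizon."""
    out = {}
    for k in horizons:
        cut = k * YEAR_DAYS
        code = np.where(
            time_days > cut, 1, np.where(event.astype(bool), 0, -1)
        ).astype(np.int16)
        out[f"{prefix}{k:02d}y"] = code
    return out


def discretize_outcomes(
    cohort: pd.DataFrame,
    survival_horizons: tuple[int, ...] = (1, 2, 3, 4, 5),
    recurrence_horizons: tuple[int, ...] = (1, 2),
) -> DiscreteDataset:
    """Discretize follow-up into Boolean yearly outcome nodes.

    ``surv_0ky`` is "alive beyond k years": yes if follow-up exceeds k years
    (a death at exactly k years counts as not-beyond), no if death occurred by
    then, NA if the patient was censored alive earlier.  Recurrence nodes are
    analogous ("recurrence-free beyond k years"); horizons of three years and
    over are not offered because short recurrence follow-up leaves them
    dominated by NAs.
    """
    if any(k >= 3 for k in recurrence_horizons):
        raise ValueError("recurrence horizons of >= 3 years are excluded")
    variables: list[Variable] = []
    columns: list[np.ndarray] = []
    for name in cohort.columns:
        if name in ("time", "event", "rec_time", "rec_event"):
            continue
        s = cohort[name]
        lv = (
            tuple(str(x) for x in s.cat.categories)
            if isinstance(s.dtype, pd.CategoricalDtype)
            else tuple(sorted(s.astype(str).unique()))
        )
        variables.append(Variable(str(name), lv))
        columns.append(pd.Categorical(s.astype(str), categories=lv).codes.astype(np.int16))

    t = cohort["time"].to_numpy(float)
    e = cohort["event"].to_numpy(bool)
    for nm, code in _yearly_nodes(
        cohort["rec_time"].to_numpy(float),
        cohort["rec_event"].to_numpy(bool),
        tuple(recurrence_horizons),
        "rec_",
    ).items():
        variables.append(Variable(nm, ("no", "yes")))
        columns.append(code)
    for nm, code in _yearly_nodes(t, e, tuple(survival_horizons), "surv_").items():
        variables.append(Variable(nm, ("no", "yes")))
        columns.append(code)
    return DiscreteDataset(variables, np.column_stack(columns))


def simplify_node_set(dataset: DiscreteDataset, mode: str = "full") -> DiscreteDataset:
    """Select outcome nodes: ``full`` keeps all yearly nodes, ``simplified``
    keeps only the last recurrence and survival node."""
    outcome = [n for n in dataset.names if n.startswith(("surv_", "rec_"))]
    if not outcome:
        raise ValueError("dataset has no outcome nodes")
    if mode == "full":
        return dataset
    if mode == "simplified":
        last_rec = max((n for n in outcome if n.startswith("rec_")), default=None)
        last_surv = max((n for n in outcome if n.startswith("surv_")), default=None)
        keep = [n for n in dataset.names if n not in outcome]
        keep += [n for n in (last_rec, last_surv) if n]
        return dataset.select(keep)
    raise ValueError(f"unknown node mode {mode!r}")


def expected_skeleton(gt: GroundTruth, mode: str = "simplified") -> set[frozenset[str]]:
    """The undirected ground-truth skeleton of the discretized dataset.

    Combines the covariate/treatment graph with the edges induced by the
    hazard models: every survival node attaches to each survival-hazard
    covariate (and to treatment when the true effect is nonzero), recurrence
    nodes to each recurrence-hazard covariate.  Meaningful for the simplified
    node mode; the full mode's yearly nodes are deterministically chained and
    carry no unique faithful skeleton.
    """
    measured = [v for v in gt.graph.nodes if v not in gt.unmeasured]
    edges = {
        frozenset((u, v))
        for u, v in gt.graph.edges
        if u not in gt.unmeasured and v not in gt.unmeasured
    }
    surv_nodes = ["surv_05y"] if mode == "simplified" else [
        f"surv_{k:02d}y" for k in (1, 2, 3, 4, 5)
    ]
    rec_nodes = ["rec_02y"] if mode == "simplified" else ["rec_01y", "rec_02y"]
    for y in surv_nodes:
        for (var, _), beta in gt.survival.effects.items():
            if beta != 0 and var in measured:
                edges.add(frozenset((var, y)))
        if gt.survival.treatment_log_hr != 0:
            edges.add(frozenset(("treatment", y)))
    for y in rec_nodes:
        for (var, _), beta in gt.recurrence.effects.items():
            if beta != 0 and var in measured:
                edges.add(frozenset((var, y)))
    return edges


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def write_cohort(cohort: pd.DataFrame, path: str) -> None:
    cohort.to_csv(path, sep="\t", index=False)


def read_cohort(path: str, levels: Mapping[str, tuple[str, ...]] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    levels = levels or SCHEMA
    for col, lv in levels.items():
        if col in df.columns:
            df[col] = pd.Categorical(df[col].astype(str), categories=list(lv))
    if "treatment" in df.columns and "treatment" not in levels:
        df["treatment"] = df["treatment"].astype("category")
    return df


def ground_truth_to_json(gt: GroundTruth) -> dict:
    return {
        "scenario": gt.scenario,
        "nodes": list(gt.graph.nodes),
        "edges": sorted(map(list, gt.graph.edges)),
        "unmeasured": sorted(gt.unmeasured),
        "true_hr": gt.true_hr,
        "survival": {
            "baseline_rate": gt.survival.baseline_rate,
            "effects": {f"{v}={lv}": b for (v, lv), b in gt.survival.effects.items()},
            "treatment_log_hr": gt.survival.treatment_log_hr,
        },
        "followup_years": list(gt.followup_years),
    }


def write_ground_truth(gt: GroundTruth, json_path: str, dot_path: str | None = None) -> None:
    import json

    with open(json_path, "w") as fh:
        json.dump(ground_truth_to_json(gt), fh, indent=2)
    if dot_path:
        write_dot(gt.graph, dot_path)
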