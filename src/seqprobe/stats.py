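"""Quantification suite over metric tables: linear models and nested ANOVA.

Works on a tidy long table with one row per (dataset, condition, class pair,
rep, epoch, metric) value.  Four families of tests mirror the analysis grid:

1. data-source difference — does the metric differ between datasets,
2. reshuffled-null baseline — does the ordered condition differ from its
   null within a dataset,
3. class and epoch models — class-pair-only, epoch-only, and epoch x class
   fits within a dataset,
4. class contribution — the adjusted-R² gain of epoch x class over epoch
   alone, with the extra-sum-of-squares F test.

Effect sizes are adjusted R²; raw p-values are always reported next to the
conventional star thresholds (0.05, 0.01, 0.001, 0.0001).  Epoch enters as a
continuous 1-based covariate; categorical predictors are treatment-coded
with the lexicographically first level as reference.  Rep-level records are
analyzed un-averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .metrics import METRIC_NAMES

__all__ = [
    "RegressionReport",
    "validate_long_table",
    "fit_linear",
    "source_difference_test",
    "null_baseline_test",
    "class_epoch_models",
    "class_contribution_anova",
    "quantification_report",
    "significance_stars",
]

REQUIRED_COLUMNS = ("dataset", "condition", "label_pair", "rep", "epoch", "metric", "value")

_CATEGORICAL = {"dataset", "condition", "label_pair", "rep"}


@dataclass
class RegressionReport:
    response: str
    terms: tuple[str, ...]
    formula: str
    n: int
    r2: float
    adj_r2: float
    f_stat: float
    f_pvalue: float
    params: dict = field(default_factory=dict)
    # nested comparison (present only for the ANOVA contribution test)
    nested_terms: tuple[str, ...] | None = None
    delta_r2: float | None = None
    delta_adj_r2: float | None = None
    nested_f: float | None = None
    nested_f_pvalue: float | None = None

    @property
    def stars(self) -> str:
        return significance_stars(self.f_pvalue)

    def as_dict(self) -> dict:
        d = {
            "response": self.response, "terms": list(self.terms),
            "formula": self.formula, "n": self.n,
            "r2": self.r2, "adj_r2": self.adj_r2,
            "f_stat": self.f_stat, "f_pvalue": self.f_pvalue,
            "stars": self.stars, "params": self.params,
        }
        if self.nested_terms is not None:
            d.update({
                "nested_terms": list(self.nested_terms),
                "delta_r2": self.delta_r2,
                "delta_adj_r2": self.delta_adj_r2,
                "nested_f": self.nested_f,
                "nested_f_pvalue": self.nested_f_pvalue,
                "nested_stars": significance_stars(self.nested_f_pvalue),
            })
        return d


def significance_stars(p: float | None) -> str:
    if p is None or not np.isfinite(p):
        return ""
    for threshold, mark in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*")):
        if p < threshold:
            return mark
    return ""


def validate_long_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"long table is missing required column(s): {missing}")
    bad_metric = set(table["metric"]) - set(METRIC_NAMES)
    if bad_metric:
        raise ValueError(f"unknown metric name(s): {sorted(bad_metric)}")
    v = pd.to_numeric(table["value"], errors="raise")
    if (v < -1).any() or (v > 1).any():
        raise ValueError("metric values must lie in [-1, 1]")
    return table


def _formula_term(term: str) -> str:
    if ":" in term:
        a, b = term.split(":", 1)
        return f"{_formula_term(a)}:{_formula_term(b)}"
    return f"C({term})" if term in _CATEGORICAL else term


def fit_linear(table: pd.DataFrame, metric: str, terms) -> RegressionReport:
    """OLS of one metric on the given terms over a long metric table.

    Categorical terms are treatment-coded; ``epoch`` is continuous.  A
    rank-deficient design raises, naming the terms involved.
    """
    validate_long_table(table)
    terms = tuple(terms)
    sub = table[table["metric"] == metric].copy()
    if len(sub) == 0:
        raise ValueError(f"no rows for metric {metric!r}")
    for term in terms:
        for col in term.split(":"):
            if col in _CATEGORICAL and sub[col].nunique() < 2 and len(terms) == 1:
                raise ValueError(
                    f"predictor {col!r} has a single level; nothing to compare"
                )
    formula = "value ~ " + " + ".join(_formula_term(t) for t in terms)
    model = smf.ols(formula, data=sub)
    X = model.exog
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(f"rank-deficient design for terms {terms}; collinear predictors")
    if len(sub) <= X.shape[1] + 1:
        raise ValueError(
            f"n={len(sub)} rows is too few for {X.shape[1]} parameters"
        )
    fit = model.fit()
    # a constant response has nothing to explain: report a zero effect rather
    # than the 0/0 that R^2 would otherwise produce
    degenerate = float(np.var(sub["value"].to_numpy(dtype=float))) < 1e-24
    report = RegressionReport(
        response=metric,
        terms=terms,
        formula=formula,
        n=int(fit.nobs),
        r2=0.0 if degenerate else float(fit.rsquared),
        adj_r2=0.0 if degenerate else float(fit.rsquared_adj),
        f_stat=0.0 if degenerate else float(fit.fvalue),
        f_pvalue=1.0 if degenerate else float(fit.f_pvalue),
        params={k: float(v) for k, v in fit.params.items()},
    )
    report._fit = fit  # kept for nested comparisons
    report._degenerate = degenerate
    return report


def source_difference_test(table: pd.DataFrame, metric: str) -> RegressionReport:
    """Does the metric differ between data sources (ordered condition only)?"""
    sub = table[table["condition"] == "ordered"]
    if sub["dataset"].nunique() < 2:
        raise ValueError("source difference test needs at least 2 datasets")
    return fit_linear(sub, metric, ("dataset",))


def null_baseline_test(table: pd.DataFrame, metric: str, dataset_id: str) -> RegressionReport:
    """Ordered vs reshuffled comparison within one dataset."""
    sub = table[table["dataset"] == dataset_id]
    conditions = set(sub["condition"])
    if not {"ordered", "reshuffled"} <= conditions:
        raise ValueError(
            f"dataset {dataset_id!r} needs both ordered and reshuffled rows; has {sorted(conditions)}"
        )
    return fit_linear(sub, metric, ("condition",))


def class_epoch_models(
    table: pd.DataFrame, metric: str, dataset_id: str
) -> tuple[RegressionReport, RegressionReport, RegressionReport]:
    """(class-only, epoch-only, epoch x class) fits within one dataset."""
    sub = table[(table["dataset"] == dataset_id) & (table["condition"] == "ordered")]
    if sub["label_pair"].nunique() < 2:
        raise ValueError("class models need at least 2 class pairs")
    if sub["epoch"].nunique() < 2:
        raise ValueError("epoch models need at least 2 epochs")
    class_only = fit_linear(sub, metric, ("label_pair",))
    epoch_only = fit_linear(sub, metric, ("epoch",))
    interaction = fit_linear(sub, metric, ("epoch", "label_pair", "epoch:label_pair"))
    return class_only, epoch_only, interaction


def class_contribution_anova(table: pd.DataFrame, metric: str, dataset_id: str) -> RegressionReport:
    """Adjusted-R² gain of epoch x class over epoch alone, with nested F test."""
    _, epoch_only, interaction = class_epoch_models(table, metric, dataset_id)
    interaction.nested_terms = epoch_only.terms
    interaction.delta_r2 = interaction.r2 - epoch_only.r2
    interaction.delta_adj_r2 = interaction.adj_r2 - epoch_only.adj_r2
    if interaction._degenerate:
        interaction.nested_f = 0.0
        interaction.nested_f_pvalue = 1.0
    else:
        comparison = anova_lm(epoch_only._fit, interaction._fit)
        interaction.nested_f = float(comparison["F"].iloc[1])
        interaction.nested_f_pvalue = float(comparison["Pr(>F)"].iloc[1])
    return interaction


def quantification_report(table: pd.DataFrame, metrics=METRIC_NAMES) -> dict:
    """Run the full grid over every metric and dataset present.

    Returns a JSON-serializable dict with one block per test family.  Blocks
    whose preconditions the table cannot satisfy (e.g. a single dataset, or
    no reshuffled condition) are skipped with a notice, and the total number
    of tests run is counted so users can apply their own multiplicity
    control.
    """
    validate_long_table(table)
    datasets = sorted(table["dataset"].unique())
    report: dict = {"data_source_difference": {}, "baseline_null": {},
                    "epoch_and_class": {}, "class_contribution": {},
                    "notices": [], "n_tests": 0}

    for metric in metrics:
        if metric not in set(table["metric"]):
            continue
        if len(datasets) >= 2:
            rep = source_difference_test(table, metric)
            report["data_source_difference"][metric] = rep.as_dict()
            report["n_tests"] += 1
        else:
            report["notices"].append(f"{metric}: single dataset, source test skipped")
        for did in datasets:
            sub = table[table["dataset"] == did]
            key = f"{did}:{metric}"
            if {"ordered", "reshuffled"} <= set(sub["condition"]):
                rep = null_baseline_test(table, metric, did)
                report["baseline_null"][key] = rep.as_dict()
                report["n_tests"] += 1
            else:
                report["notices"].append(f"{key}: missing a condition, null test skipped")
            ordered = sub[sub["condition"] == "ordered"]
            if ordered["label_pair"].nunique() >= 2 and ordered["epoch"].nunique() >= 2:
                cls, epoch, inter = class_epoch_models(table, metric, did)
                contrib = class_contribution_anova(table, metric, did)
                report["epoch_and_class"][key] = {
                    "class_only": cls.as_dict(),
                    "epoch_only": epoch.as_dict(),
                    "epoch_x_class": inter.as_dict(),
                }
                report["class_contribution"][key] = contrib.as_dict()
                report["n_tests"] += 4
            else:
                report["notices"].append(f"{key}: class/epoch models skipped")
    return report


def render_report(report: dict) -> str:
    """Plain-text rendering of the quantification grid."""
    lines = ["Quantification report (adjusted R^2, stars by F-test p-value)", ""]
    for block, title in (
        ("data_source_difference", "Data source difference"),
        ("baseline_null", "Baseline null (ordered vs reshuffled)"),
        ("epoch_and_class", "Epoch and class models"),
        ("class_contribution", "Contribution of class beyond epoch"),
    ):
        lines.append(title)
        entries = report.get(block, {})
        if not entries:
            lines.append("  (none)")
        for key, rep in entries.items():
            if block == "epoch_and_class":
                for name, r in rep.items():
                    lines.append(
                        f"  {key} [{name}]: adjR2={r['adj_r2']:.4f}{r['stars']} (n={r['n']})"
                    )
            else:
                extra = ""
                if rep.get("delta_adj_r2") is not None:
                    extra = (f"  deltaAdjR2={rep['delta_adj_r2']:.4f}"
                             f"{rep.get('nested_stars', '')}")
                lines.append(
                    f"  {key}: adjR2={rep['adj_r2']:.4f}{rep['stars']} (n={rep['n']}){extra}"
                )
        lines.append("")
    lines.append(f"tests run: {report.get('n_tests', 0)} (no multiplicity correction applied)")
    return "\n".join(lines)
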