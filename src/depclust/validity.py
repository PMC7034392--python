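"""Convergent validity: demographic associations and correlate effect sizes.

A severity classification worth using should relate to what severity is
known to relate to. Two checks:

* Pearson chi-squared (no continuity correction) between each categorical
  demographic variable and the severity levels.
* One-way ANOVA of each auxiliary scale across severity levels, with
  eta-squared (SS_between / SS_total) as the effect size, plus the
  per-level means that show the direction of the gradient.

p-values are reported without multiple-testing correction; the report
records how many tests were run so readers can adjust if they wish.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import SurveyTable

__all__ = [
    "AssociationReport",
    "chi_squared_association",
    "anova_eta_squared",
    "validity_battery",
]


def chi_squared_association(categories, labels) -> tuple[float, int, float]:
    """Pearson chi-squared of a categorical variable vs. severity levels.

    Returns ``(statistic, df, p)`` with df = (levels-1)(categories-1).
    """
    cat = np.asarray(categories)
    lab = np.asarray(labels)
    if cat.shape != lab.shape:
        raise ValueError("categories and labels must have equal length")
    table = pd.crosstab(cat, lab)
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError(
            "need at least 2 observed categories and 2 observed levels"
        )
    if (table.to_numpy().sum(axis=0) == 0).any() or (table.to_numpy().sum(axis=1) == 0).any():
        raise ValueError("empty margin: expected cell count of zero")
    res = stats.chi2_contingency(table.to_numpy(), correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def anova_eta_squared(scores, labels) -> tuple[float, float, dict]:
    """One-way ANOVA F and eta-squared of a real score across levels.

    eta-squared = SS_between / SS_total. Constant scores (zero total sum
    of squares) degenerate to F = 0, eta-squared = 0.
    """
    x = np.asarray(scores, dtype=float)
    g = np.asarray(labels)
    if x.shape != g.shape:
        raise ValueError("scores and labels must have equal length")
    levels = np.unique(g)
    if len(levels) < 2:
        raise ValueError("need at least 2 levels with observations")
    grand = x.mean()
    ss_total = float(((x - grand) ** 2).sum())
    means = {}
    ss_between = 0.0
    ss_within = 0.0
    for lv in levels:
        xi = x[g == lv]
        means[lv.item() if hasattr(lv, "item") else lv] = float(xi.mean())
        ss_between += xi.size * (xi.mean() - grand) ** 2
        ss_within += float(((xi - xi.mean()) ** 2).sum())
    if ss_total == 0.0:
        return 0.0, 0.0, means
    df_b = len(levels) - 1
    df_w = x.size - len(levels)
    f_stat = (ss_between / df_b) / (ss_within / df_w) if ss_within > 0 else float("inf")
    return float(f_stat), float(ss_between / ss_total), means


@dataclass
class AssociationReport:
    """Chi-squared and ANOVA results over all configured variables."""

    demographic: dict = field(default_factory=dict)  # name -> {chi2, df, p}
    correlate: dict = field(default_factory=dict)    # name -> {F, eta_squared, level_means}
    n_tests: int = 0

    def demographic_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.demographic).T

    def correlate_table(self) -> pd.DataFrame:
        rows = {
            name: {"F": rec["F"], "eta_squared": rec["eta_squared"]}
            for name, rec in self.correlate.items()
        }
        return pd.DataFrame(rows).T

    def level_means_table(self) -> pd.DataFrame:
        """Per-level correlate means — the severity-gradient summary."""
        return pd.DataFrame(
            {name: rec["level_means"] for name, rec in self.correlate.items()}
        )

    def to_dict(self) -> dict:
        return {
            "demographic": self.demographic,
            "correlate": {
                name: {
                    "F": rec["F"],
                    "eta_squared": rec["eta_squared"],
                    "level_means": {str(k): v for k, v in rec["level_means"].items()},
                }
                for name, rec in self.correlate.items()
            },
            "n_tests": self.n_tests,
        }


def validity_battery(
    table: SurveyTable,
    labels,
    demographic_cols=None,
    correlate_cols=None,
) -> AssociationReport:
    """Run both association tests over all configured columns."""
    labels = np.asarray(labels)
    if labels.shape != (table.n,):
        raise ValueError("labels must have one entry per respondent")
    report = AssociationReport()

    if demographic_cols is None:
        demographic_cols = [] if table.demographics is None \
            else list(table.demographics.columns)
    if correlate_cols is None:
        correlate_cols = [] if table.correlates is None \
            else list(table.correlates.columns)

    for col in demographic_cols:
        if table.demographics is None or col not in table.demographics.columns:
            raise ValueError(f"demographic column {col!r} not present in table")
        chi2, df, p = chi_squared_association(
            table.demographics[col].to_numpy(), labels
        )
        report.demographic[col] = {"chi2": chi2, "df": df, "p": p}

    for col in correlate_cols:
        if table.correlates is None or col not in table.correlates.columns:
            raise ValueError(f"correlate column {col!r} not present in table")
        f_stat, eta2, means = anova_eta_squared(
            table.correlates[col].to_numpy(), labels
        )
        report.correlate[col] = {"F": f_stat, "eta_squared": eta2, "level_means": means}

    report.n_tests = len(report.demographic) + len(report.correlate)
    return report
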