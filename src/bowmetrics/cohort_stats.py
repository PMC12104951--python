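"""Cohort-level statistics for Bowman's-layer thickness studies.

Works on a per-subject table (one eye, one visit per subject) carrying
the pipeline's measured thicknesses and the clinical covariates, and
reproduces the standard analysis chain: per-group summaries, one-way
ANOVA with Tukey post hoc pairwise comparisons, the ordinary
least-squares association of Bowman thickness (BT) with central corneal
thickness (CCT), and a general-linear-model test of whether the BT/CCT
ratio depends on diagnosis, age, sex, Kmax or epithelial thickness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AnalysisReport",
    "prepare_cohort",
    "group_summary",
    "compare_groups",
    "fit_bt_cct",
    "ratio_analysis",
    "analyze_cohort",
]

SUMMARY_VARS = ["age_y", "bt_um", "et_um", "cct_um", "kmax_d", "ratio_bt_et", "ratio_bt_cct"]


@dataclass
class AnalysisReport:
    """Everything the analysis stage computes, JSON-serialisable."""

    group_summary: dict
    comparisons: dict
    bt_cct: dict
    ratio: dict
    n_by_group: dict
    meta: dict = field(default_factory=dict)

    def to_jsonable(self) -> dict:
        return {
            "group_summary": self.group_summary,
            "comparisons": self.comparisons,
            "bt_cct": self.bt_cct,
            "ratio": self.ratio,
            "n_by_group": self.n_by_group,
            "meta": self.meta,
        }


def prepare_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and derive the ratio columns (always recomputed).

    Requires ``group, age_y, sex, bt_um, et_um, cct_um, kmax_d``; drops
    records with non-positive CCT or missing BT.
    """
    required = {"group", "age_y", "sex", "bt_um", "et_um", "cct_um", "kmax_d"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort table lacks columns: {sorted(missing)}")
    out = df.copy()
    out = out[(out.cct_um > 0) & out.bt_um.notna()]
    out["ratio_bt_cct"] = out.bt_um / out.cct_um
    out["ratio_bt_et"] = out.bt_um / out.et_um
    return out


def group_summary(cohort: pd.DataFrame) -> dict:
    """Per-group mean/SD/min/max of every summary variable."""
    cohort = prepare_cohort(cohort)
    out: dict[str, dict] = {}
    for label, g in cohort.groupby("group", sort=True):
        if len(g) < 2:
            raise ValueError(f"group {label!r} has fewer than 2 subjects")
        vars_out = {}
        for v in SUMMARY_VARS:
            col = g[v].astype(float)
            vars_out[v] = {
                "mean": float(col.mean()),
                "sd": float(col.std(ddof=1)),
                "min": float(col.min()),
                "max": float(col.max()),
            }
        vars_out["n"] = int(len(g))
        vars_out["n_female"] = int((g.sex == "F").sum())
        out[str(label)] = vars_out
    return out


def compare_groups(cohort: pd.DataFrame, variable: str = "bt_um") -> dict:
    """One-way ANOVA across groups plus Tukey HSD pairwise p-values."""
    cohort = prepare_cohort(cohort)
    groups = [g[variable].to_numpy(dtype=float) for _, g in cohort.groupby("group")]
    labels = sorted(cohort.group.unique())
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 subjects each")
    degenerate = all(np.ptp(g) == 0 for g in groups)
    if degenerate:
        return {
            "variable": variable,
            "anova_F": float("nan"),
            "anova_p": float("nan"),
            "pairwise": {},
            "degenerate": True,
        }
    F, p = stats.f_oneway(*groups)
    tukey = pairwise_tukeyhsd(
        cohort[variable].to_numpy(dtype=float), cohort.group.to_numpy(), alpha=0.05
    )
    pairwise = {}
    res = tukey.summary().data[1:]
    for row in res:
        pairwise[f"{row[0]}-{row[1]}"] = float(row[3])
    return {
        "variable": variable,
        "anova_F": float(F),
        "anova_p": float(p),
        "pairwise": pairwise,
        "degenerate": False,
    }


def fit_bt_cct(cohort: pd.DataFrame, covariates: list[str] | None = None) -> dict:
    """OLS of measured BT on CCT, optionally with extra covariates.

    Returns slope/intercept/R^2/p for the CCT term.  In the
    single-covariate case R^2 equals the squared Pearson correlation.
    """
    cohort = prepare_cohort(cohort)
    if len(cohort) < 3:
        raise ValueError("need at least 3 subjects")
    if np.ptp(cohort.cct_um.to_numpy()) == 0:
        return {"singular": True}
    terms = ["cct_um"] + list(covariates or [])
    formula = "bt_um ~ " + " + ".join(terms)
    model = smf.ols(formula, data=cohort).fit()
    return {
        "slope": float(model.params["cct_um"]),
        "intercept": float(model.params["Intercept"]),
        "r_squared": float(model.rsquared),
        "p_cct": float(model.pvalues["cct_um"]),
        "n": int(model.nobs),
        "covariates": terms,
        "singular": False,
    }


def ratio_analysis(cohort: pd.DataFrame, adjust: str = "none") -> dict:
    """Is the BT/CCT ratio independent of diagnosis and covariates?

    Fits an ordinary GLM of the ratio on diagnosis (categorical), age,
    sex, Kmax and epithelial thickness, reporting a Type-II ANOVA
    p-value per factor (optionally Holm-adjusted across the factor
    family) and per-group ratio summaries.
    """
    cohort = prepare_cohort(cohort)
    per_group = {
        str(label): {
            "mean": float(g.ratio_bt_cct.mean()),
            "sd": float(g.ratio_bt_cct.std(ddof=1)),
        }
        for label, g in cohort.groupby("group")
    }
    model = smf.ols(
        "ratio_bt_cct ~ C(group) + age_y + C(sex) + kmax_d + et_um", data=cohort
    ).fit()
    name_map = {
        "C(group)": "diagnosis",
        "age_y": "age",
        "C(sex)": "sex",
        "kmax_d": "kmax",
        "et_um": "epithelial_thickness",
    }
    if model.df_resid < 1:
        # saturated design (tiny cohort): factor tests are undefined
        factor_p = {}
    else:
        anova = sm.stats.anova_lm(model, typ=2)
        factor_p = {
            name_map[k]: float(anova.loc[k, "PR(>F)"])
            for k in name_map
            if k in anova.index
        }
    out = {
        "per_group": per_group,
        "pooled_mean": float(cohort.ratio_bt_cct.mean()),
        "pooled_mean_percent": float(100.0 * cohort.ratio_bt_cct.mean()),
        "factor_p": factor_p,
        "adjust": adjust,
    }
    if adjust == "holm" and factor_p:
        keys = list(factor_p)
        _, adj, _, _ = multipletests([factor_p[k] for k in keys], method="holm")
        out["factor_p_adjusted"] = {k: float(v) for k, v in zip(keys, adj)}
    elif adjust != "none":
        raise ValueError(f"unknown adjustment {adjust!r}")
    return out


def analyze_cohort(cohort: pd.DataFrame, adjust: str = "none") -> AnalysisReport:
    """Run the full analysis chain on a per-subject table."""
    cohort = prepare_cohort(cohort)
    if cohort.empty:
        raise ValueError("empty cohort: no analyzable eyes")
    summary = group_summary(cohort)
    comparisons = {v: compare_groups(cohort, v) for v in ("bt_um", "et_um", "cct_um")}
    bt_cct = fit_bt_cct(cohort)
    ratio = ratio_analysis(cohort, adjust=adjust)
    n_by_group = {str(k): int(v) for k, v in cohort.group.value_counts().items()}
    return AnalysisReport(
        group_summary=summary,
        comparisons=comparisons,
        bt_cct=bt_cct,
        ratio=ratio,
        n_by_group=n_by_group,
    )
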