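"""Per-age-cohort statistics: two-way ANOVA, a posteriori power, summaries.

Each age cohort is analysed with an additive linear model
``length ~ C(status) + C(year)`` (no interaction: many status x year cells of
the pooled design hold at most one observation).  Sums of squares are Type II
by default, appropriate for the unbalanced design; Types I and III are
available for sensitivity.  A posteriori power of the status test uses
Cohen's f² derived from the partial eta² of the status effect,
``f² = eta² / (1 - eta²)``, and the noncentral F distribution with
noncentrality ``lambda = f² * (u + v + 1)``.

Cohorts that cannot support the two-way model are gated, not forced: a single
year class (all observations born the same year), a single status, exhausted
residual degrees of freedom, or perfect status/year collinearity each yield a
result with the corresponding gate and no test statistics.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .cohorts import AgeCohortDataset
from .data_model import AnalysisConfig

GATE_ANALYZED = "analyzed"
GATE_SINGLE_YEAR = "skipped_single_year"
GATE_SINGLE_STATUS = "skipped_single_status"
GATE_INSUFFICIENT_DF = "skipped_insufficient_df"
GATE_COLLINEAR = "skipped_collinear"


@dataclass
class AgeCohortResult:
    """Two-way ANOVA output for one age cohort (NaN fields when gated)."""

    age: int
    gate: str
    n: int = 0
    status_F: float = float("nan")
    status_DF: int = 0
    status_p: float = float("nan")
    year_F: float = float("nan")
    year_DF: int = 0
    year_p: float = float("nan")
    residual_DF: int = 0
    partial_eta_sq_status: float = float("nan")
    cohens_f2: float = float("nan")
    power: float = float("nan")
    diagnostic: str = ""


def anova_table(
    data: pd.DataFrame,
    response: str = "length",
    factors: tuple[str, ...] = ("status", "year"),
    ss_type: int = 2,
) -> pd.DataFrame:
    """Fit an additive categorical OLS model and return its ANOVA table.

    The same engine serves the two-way analysis and one-factor checks
    (pass a single factor).  Type III uses sum-to-zero contrasts.
    """
    contrast = ", Sum" if ss_type == 3 else ""
    formula = f"{response} ~ " + " + ".join(f"C({f}{contrast})" for f in factors)
    model = smf.ols(formula, data=data).fit()
    table = sm.stats.anova_lm(model, typ=ss_type)
    # normalise row labels to bare factor names
    table.index = [
        idx.replace("C(", "").replace(", Sum", "").replace(")", "")
        for idx in table.index
    ]
    return table


def posthoc_power(
    u: int,
    v: int,
    alpha: float = 0.05,
    partial_eta_sq: float | None = None,
    f2: float | None = None,
) -> float:
    """Power of a completed F test at the observed (or supplied) effect size.

    Exactly one of ``partial_eta_sq`` or ``f2`` must be given.  The test has
    ``u`` numerator and ``v`` denominator degrees of freedom; power is
    ``P(F'(u, v, f² (u + v + 1)) > F_crit(alpha, u, v))``.  At f² = 0 the
    noncentral distribution is central and power equals alpha exactly.
    """
    if (partial_eta_sq is None) == (f2 is None):
        raise ValueError("give exactly one of partial_eta_sq or f2")
    if f2 is None:
        if not 0 <= partial_eta_sq < 1:
            raise ValueError(f"partial eta^2 must be in [0, 1), got {partial_eta_sq}")
        f2 = partial_eta_sq / (1.0 - partial_eta_sq)
    if f2 < 0:
        raise ValueError(f"f^2 must be >= 0, got {f2}")
    if u < 1 or v < 1:
        raise ValueError("degrees of freedom must be >= 1")
    crit = sps.f.isf(alpha, u, v)
    if f2 == 0.0:
        return float(alpha)
    lam = f2 * (u + v + 1)
    return float(sps.ncf.sf(crit, u, v, lam))


def two_way_anova(
    dataset: AgeCohortDataset, cfg: AnalysisConfig | None = None
) -> AgeCohortResult:
    """Status + year ANOVA for one age cohort, with gating and power."""
    cfg = cfg or AnalysisConfig()
    data = dataset.data
    base = dict(age=dataset.age, n=len(data))
    if dataset.n_status_levels < 2:
        return AgeCohortResult(
            gate=GATE_SINGLE_STATUS,
            diagnostic="only one protection status present", **base,
        )
    if dataset.n_year_levels < 2:
        return AgeCohortResult(
            gate=GATE_SINGLE_YEAR,
            diagnostic="all observations belong to the same year class", **base,
        )
    n = len(data)
    u = dataset.n_status_levels - 1
    year_df = dataset.n_year_levels - 1
    v = n - 1 - u - year_df
    if v < 1:
        return AgeCohortResult(
            gate=GATE_INSUFFICIENT_DF,
            diagnostic=f"residual DF {v} < 1", **base,
        )
    # perfect collinearity: status constant within every year level
    if (data.groupby("year")["status"].nunique() == 1).all():
        return AgeCohortResult(
            gate=GATE_COLLINEAR,
            diagnostic="status is perfectly determined by year class", **base,
        )
    table = anova_table(data, ss_type=cfg.ss_type)
    ss_status = float(table.loc["status", "sum_sq"])
    ss_resid = float(table.loc["Residual", "sum_sq"])
    eta2 = ss_status / (ss_status + ss_resid)
    f2 = eta2 / (1.0 - eta2)
    resid_df = int(table.loc["Residual", "df"])
    power = posthoc_power(u=u, v=resid_df, alpha=cfg.alpha, f2=f2)
    return AgeCohortResult(
        gate=GATE_ANALYZED,
        status_F=float(table.loc["status", "F"]),
        status_DF=int(table.loc["status", "df"]),
        status_p=float(table.loc["status", "PR(>F)"]),
        year_F=float(table.loc["year", "F"]),
        year_DF=int(table.loc["year", "df"]),
        year_p=float(table.loc["year", "PR(>F)"]),
        residual_DF=resid_df,
        partial_eta_sq_status=eta2,
        cohens_f2=f2,
        power=power,
        **base,
    )


def analyze_cohorts(
    datasets: dict[int, AgeCohortDataset], cfg: AnalysisConfig | None = None
) -> pd.DataFrame:
    """Run the per-age ANOVA over all cohorts; one row per age.

    p-values are reported unadjusted (matching the study convention of
    independent per-age tests); a Holm-adjusted status p-value column
    ``status_p_holm`` is appended as a clearly separate extension.
    """
    cfg = cfg or AnalysisConfig()
    results = [two_way_anova(ds, cfg) for _, ds in sorted(datasets.items())]
    df = pd.DataFrame([dataclasses.asdict(r) for r in results])
    analyzed = df["gate"] == GATE_ANALYZED
    df["status_p_holm"] = np.nan
    if analyzed.any():
        df.loc[analyzed, "status_p_holm"] = multipletests(
            df.loc[analyzed, "status_p"], method="holm"
        )[1]
    return df


def absolute_difference(mean_mr: float, mean_fr: float) -> float:
    return abs(mean_mr - mean_fr)


def percent_difference(mean_mr: float, mean_fr: float) -> float:
    """Percent difference with the midpoint of the two means as denominator."""
    mid = 0.5 * (mean_mr + mean_fr)
    return 100.0 * abs(mean_mr - mean_fr) / mid


def summary_table(
    datasets: dict[int, AgeCohortDataset],
    decimals: int | None = None,
) -> pd.DataFrame:
    """Per-age MR/FR means, standard errors and their differences (mm).

    SE is the sample SD over sqrt(n) (NaN for n = 1).  If a status is absent
    at an age its cells, and both difference cells, are NaN.  ``decimals``
    rounds for display only.
    """
    rows = []
    for age, ds in sorted(datasets.items()):
        row: dict = {"age": age}
        for status, tag in (("MR", "mr"), ("FR", "fr")):
            vals = ds.data.loc[ds.data["status"] == status, "length"]
            row[f"{tag}_n"] = int(len(vals))
            row[f"{tag}_mean"] = float(vals.mean()) if len(vals) else np.nan
            row[f"{tag}_se"] = (
                float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) >= 2 else np.nan
            )
        if np.isnan(row["mr_mean"]) or np.isnan(row["fr_mean"]):
            row["abs_diff"] = row["pct_diff"] = np.nan
        else:
            row["abs_diff"] = absolute_difference(row["mr_mean"], row["fr_mean"])
            row["pct_diff"] = percent_difference(row["mr_mean"], row["fr_mean"])
        rows.append(row)
    table = pd.DataFrame(rows).set_index("age")
    if decimals is not None:
        value_cols = [c for c in table.columns if not c.endswith("_n")]
        table[value_cols] = table[value_cols].round(decimals)
    return table
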