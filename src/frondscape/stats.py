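"""The study's statistical decision cascade.

Responses from a clone × light factorial design are screened for variance
homogeneity (Brown–Forsythe/Levene) and residual normality (Shapiro–Wilk),
log-transformed on violation, decomposed by a balanced two-way ANOVA with
omega-squared effect sizes, and followed up along the branch the ANOVA
indicates: per-light one-way ANOVAs when the factors interact; clone
comparisons (one-way ANOVA + Tukey, or Kruskal–Wallis + Mann–Whitney for
pigment-type responses) with Bonferroni correction when only the clone main
effect is significant; and per-clone two-sample F- and t-tests whenever the
light main effect is significant.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InsufficientDataError, InvalidArgumentError, TransformFailureError

ALPHA = 0.05


def _validate_table(table: pd.DataFrame) -> pd.DataFrame:
    required = {"response", "clone", "light"}
    missing = required - set(table.columns)
    if missing:
        raise InvalidArgumentError(f"design table missing columns: {sorted(missing)}")
    if not np.all(np.isfinite(table["response"].to_numpy(dtype=float))):
        raise InvalidArgumentError("responses must be finite")
    return table


@dataclass(frozen=True)
class AssumptionChecks:
    levene_p: float
    shapiro_p: float
    log_transform_applied: bool
    table: pd.DataFrame
    warning: str | None = None


def _cell_residuals(table: pd.DataFrame) -> np.ndarray:
    means = table.groupby(["clone", "light"])["response"].transform("mean")
    return (table["response"] - means).to_numpy(dtype=float)


def check_assumptions(
    table: pd.DataFrame, alpha: float = ALPHA, center: str = "median"
) -> AssumptionChecks:
    """Levene (median-centred by default) + Shapiro–Wilk on cell residuals.

    If either test rejects at ``alpha``, responses are natural-log
    transformed (requires strictly positive responses) and the transformed
    table returned with the flag set. Degenerate (constant) responses pass
    through untransformed with a warning.
    """
    table = _validate_table(table)
    groups = [g["response"].to_numpy(dtype=float)
              for _, g in table.groupby(["clone", "light"])]
    resid = _cell_residuals(table)
    if np.allclose(resid, resid[0]) or all(np.allclose(g, g[0]) for g in groups):
        return AssumptionChecks(1.0, 1.0, False, table,
                                warning="constant responses; assumption tests degenerate")
    levene_p = float(sps.levene(*groups, center=center).pvalue)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        shapiro_p = float(sps.shapiro(resid).pvalue)
    if levene_p < alpha or shapiro_p < alpha:
        if (table["response"] <= 0).any():
            raise TransformFailureError(
                "log-transform required but responses are not all positive"
            )
        transformed = table.copy()
        transformed["response"] = np.log(transformed["response"].to_numpy(dtype=float))
        return AssumptionChecks(levene_p, shapiro_p, True, transformed)
    return AssumptionChecks(levene_p, shapiro_p, False, table)


def two_way_anova_omega(table: pd.DataFrame) -> pd.DataFrame:
    """Balanced two-factor ANOVA with ω² effect sizes.

    Returns a table indexed by term (clone, light, clone:light, error,
    total) with sum of squares, df, mean square, F, p and ω², where
    ω² = (SS_term − df_term·MS_error)/(SS_total + MS_error), reported
    unclamped (small negative values are legitimate for null terms). For
    all-constant responses every SS is zero and ω² is 0 by convention.
    Near-balanced designs are handled by the same cell-mean decomposition
    with a warning; it coincides with type-III SS only when balanced.
    """
    table = _validate_table(table)
    y = table["response"].to_numpy(dtype=float)
    n = y.size
    cell_sizes = table.groupby(["clone", "light"])["response"].size()
    if (cell_sizes < 2).any():
        raise InsufficientDataError("need >= 2 replicates per cell")
    if cell_sizes.nunique() > 1:
        warnings.warn("unbalanced design: cell-mean SS decomposition is approximate",
                      stacklevel=2)
    grand = y.mean()
    ss_total = float(np.sum((y - grand) ** 2))
    a_levels = table.groupby("clone")["response"]
    b_levels = table.groupby("light")["response"]
    ss_a = float(sum(g.size * (g.mean() - grand) ** 2 for _, g in a_levels))
    ss_b = float(sum(g.size * (g.mean() - grand) ** 2 for _, g in b_levels))
    cells = table.groupby(["clone", "light"])["response"]
    ss_cells = float(sum(g.size * (g.mean() - grand) ** 2 for _, g in cells))
    ss_ab = ss_cells - ss_a - ss_b
    ss_err = ss_total - ss_cells
    n_a = table["clone"].nunique()
    n_b = table["light"].nunique()
    df_a, df_b = n_a - 1, n_b - 1
    df_ab = df_a * df_b
    df_err = n - n_a * n_b
    if df_err <= 0:
        raise InsufficientDataError("zero error degrees of freedom")
    ms_err = ss_err / df_err

    rows = {}
    for term, ss, df in (("clone", ss_a, df_a), ("light", ss_b, df_b),
                         ("clone:light", ss_ab, df_ab)):
        ms = ss / df if df else np.nan
        if ss_total == 0.0:
            f_val, p, omega = 0.0, 1.0, 0.0
        elif ms_err == 0.0:
            f_val, p = np.inf, 0.0
            omega = ss / ss_total
        else:
            f_val = ms / ms_err
            p = float(sps.f.sf(f_val, df, df_err))
            omega = (ss - df * ms_err) / (ss_total + ms_err)
        rows[term] = {"ss": ss, "df": df, "ms": ms, "F": f_val, "p": p, "omega_sq": omega}
    rows["error"] = {"ss": ss_err, "df": df_err, "ms": ms_err,
                     "F": np.nan, "p": np.nan, "omega_sq": np.nan}
    rows["total"] = {"ss": ss_total, "df": n - 1, "ms": np.nan,
                     "F": np.nan, "p": np.nan, "omega_sq": np.nan}
    return pd.DataFrame(rows).T


class Branch(str, Enum):
    INTERACTION = "interaction"
    CLONE_MAIN = "clone_main"
    LIGHT_MAIN = "light_main"
    NONE = "none"


def bonferroni(p_raw: float | np.ndarray, n_comparisons: int):
    """Bonferroni adjustment, min(1, p·m); monotone and idempotent at 1."""
    return np.minimum(1.0, np.asarray(p_raw, dtype=float) * n_comparisons)


def _pairwise_clones(values: dict[str, np.ndarray], parametric: bool) -> pd.DataFrame:
    pairs = list(itertools.combinations(sorted(values), 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        if parametric:
            res = sps.tukey_hsd(*[values[k] for k in sorted(values)])
            names = sorted(values)
            p_raw = float(res.pvalue[names.index(a), names.index(b)])
            test = "tukey"
        else:
            p_raw = float(sps.mannwhitneyu(values[a], values[b],
                                           alternative="two-sided").pvalue)
            test = "mann-whitney"
        rows.append({"group_a": a, "group_b": b, "test": test,
                     "p_raw": p_raw, "p_adj": float(bonferroni(p_raw, m))})
    return pd.DataFrame(rows)


def _one_way_clone_p(sub: pd.DataFrame, parametric: bool) -> float:
    groups = [g.to_numpy(dtype=float) for _, g in sub.groupby("clone")["response"]]
    if parametric:
        return float(sps.f_oneway(*groups).pvalue)
    return float(sps.kruskal(*groups).pvalue)


def light_contrasts(table: pd.DataFrame) -> pd.DataFrame:
    """Per-clone two-sample F-test (variance ratio) and Welch-free t-test."""
    rows = []
    for clone, sub in table.groupby("clone"):
        lo = sub.loc[sub["light"] == "low", "response"].to_numpy(dtype=float)
        hi = sub.loc[sub["light"] == "high", "response"].to_numpy(dtype=float)
        v_lo, v_hi = np.var(lo, ddof=1), np.var(hi, ddof=1)
        if v_hi == 0 and v_lo == 0:
            f_stat, f_p = np.nan, np.nan
        else:
            f_stat = v_lo / v_hi if v_hi > 0 else np.inf
            dfn, dfd = lo.size - 1, hi.size - 1
            p_one = sps.f.sf(f_stat, dfn, dfd) if np.isfinite(f_stat) else 0.0
            f_p = float(min(1.0, 2.0 * min(p_one, 1.0 - p_one)))
        t_p = float(sps.ttest_ind(lo, hi).pvalue)
        rows.append({"clone": clone, "f_stat": f_stat, "f_p": f_p,
                     "t_p": t_p, "mean_diff": float(lo.mean() - hi.mean())})
    return pd.DataFrame(rows)


@dataclass
class AnovaCascadeResult:
    """Full output of the decision cascade for one response."""

    assumptions: AssumptionChecks
    two_way: pd.DataFrame
    branches_taken: list[Branch]
    posthoc: dict[str, pd.DataFrame] = field(default_factory=dict)
    one_way_p: dict[str, float] = field(default_factory=dict)
    light_contrasts: pd.DataFrame | None = None

    @property
    def branch_taken(self) -> Branch:
        """The dominant branch (interaction > clone main > light main > none)."""
        return self.branches_taken[0] if self.branches_taken else Branch.NONE


def cascade(
    table: pd.DataFrame, alpha: float = ALPHA, mode: str = "parametric"
) -> AnovaCascadeResult:
    """Run the complete decision cascade on one response.

    ``mode='pigment'`` switches the clone-comparison branch to
    Kruskal–Wallis + pairwise Mann–Whitney (used for pigment
    concentrations); both branches apply Bonferroni correction across the
    pairwise comparisons of the executed branch. Branches are not mutually
    exclusive: a significant light main effect triggers the per-clone
    F-/t-contrasts regardless of the clone-branch outcome.
    """
    if mode not in ("parametric", "pigment"):
        raise InvalidArgumentError("mode must be 'parametric' or 'pigment'")
    parametric = mode == "parametric"
    checks = check_assumptions(table, alpha=alpha)
    work = checks.table
    two_way = two_way_anova_omega(work)
    p_int = two_way.loc["clone:light", "p"]
    p_clone = two_way.loc["clone", "p"]
    p_light = two_way.loc["light", "p"]

    branches: list[Branch] = []
    posthoc: dict[str, pd.DataFrame] = {}
    one_way_p: dict[str, float] = {}
    contrasts = None

    if p_int < alpha:
        branches.append(Branch.INTERACTION)
        for light, sub in work.groupby("light"):
            one_way_p[f"clones@{light}"] = _one_way_clone_p(sub, parametric)
            values = {str(c): g.to_numpy(dtype=float)
                      for c, g in sub.groupby("clone")["response"]}
            posthoc[f"clones@{light}"] = _pairwise_clones(values, parametric)
    elif p_clone < alpha:
        branches.append(Branch.CLONE_MAIN)
        one_way_p["clones_overall"] = _one_way_clone_p(work, parametric)
        values = {str(c): g.to_numpy(dtype=float)
                  for c, g in work.groupby("clone")["response"]}
        posthoc["clones_overall"] = _pairwise_clones(values, parametric)

    if p_light < alpha:
        branches.append(Branch.LIGHT_MAIN)
        contrasts = light_contrasts(work)

    if not branches:
        branches = [Branch.NONE]
    return AnovaCascadeResult(
        assumptions=checks, two_way=two_way, branches_taken=branches,
        posthoc=posthoc, one_way_p=one_way_p, light_contrasts=contrasts,
    )


def ancova_light_contrast(
    frond_table: pd.DataFrame,
    response: str = "mean_yii",
    covariate: str = "frond_length_mm",
    group: str = "light",
) -> tuple[float, float]:
    """Common-slope ANCOVA of a frond-mean parameter on light.

    Fits ``response ~ covariate + C(group)`` by OLS and returns the adjusted
    group effect (contrast level minus the alphabetically-first reference
    level; for the light factor this is low − high) and its p-value.
    """
    import statsmodels.formula.api as smf

    df = frond_table[[response, covariate, group]].dropna().copy()
    if df[covariate].nunique() < 2 or df[group].nunique() < 2:
        raise InsufficientDataError("ANCOVA needs variation in covariate and group")
    model = smf.ols(f"{response} ~ {covariate} + C({group})", data=df).fit()
    term = next(name for name in model.params.index if name.startswith(f"C({group})"))
    effect = float(model.params[term])
    p = float(model.pvalues[term])
    return effect, p
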