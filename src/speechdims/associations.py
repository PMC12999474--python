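"""Associations between speech factors, clinical FTD dimensions and brain ROIs.

Bonferroni-corrected bivariate correlations, covariate-adjusted ROI-level
general linear models with standardized coefficients, moderation
(interaction) tests, optional max-statistic permutation correction across an
ROI set, and per-group descriptive statistics (ANOVA / chi-square with
effect sizes and Bonferroni post hoc contrasts).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


class AssociationError(ValueError):
    """Design problem in an association analysis (collinearity, degeneracy)."""


@dataclass
class AssociationResult:
    """One predictor-outcome association (Pearson r or standardized beta)."""

    pair: tuple[str, str]
    estimate: float
    ci: tuple[float, float]
    p_raw: float
    p_adjusted: float
    n_used: int
    family_size: int
    flag: str | None = None


def _bonferroni(p: float, m: int) -> float:
    return min(1.0, m * p)


def _fisher_ci(r: float, n: int, alpha: float = 0.05) -> tuple[float, float]:
    if n < 4 or abs(r) >= 1.0:
        return (np.nan, np.nan)
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    zc = stats.norm.ppf(1 - alpha / 2)
    return (float(np.tanh(z - zc * se)), float(np.tanh(z + zc * se)))


def correlate_with_correction(
    scores_a: pd.DataFrame,
    scores_b: pd.DataFrame,
    alpha: float = 0.05,
    family_size: int | None = None,
) -> list[AssociationResult]:
    """Pearson correlations of every column pair with Bonferroni correction.

    Inputs are participant-indexed frames (aligned on their index); rows with
    a missing value in a pair are dropped for that pair, and ``n_used`` is
    reported per pair.  The default family is all j x k pairs.
    """
    a, b = scores_a.align(scores_b, join="inner", axis=0)
    m = family_size or (a.shape[1] * b.shape[1])
    results = []
    for ca in a.columns:
        for cb in b.columns:
            xy = pd.concat([a[ca], b[cb]], axis=1).dropna()
            n = len(xy)
            if n < 4:
                results.append(AssociationResult(
                    pair=(ca, cb), estimate=np.nan, ci=(np.nan, np.nan),
                    p_raw=np.nan, p_adjusted=np.nan, n_used=n, family_size=m,
                    flag="fewer than 4 complete pairs"))
                continue
            x, y = xy.iloc[:, 0].to_numpy(), xy.iloc[:, 1].to_numpy()
            if x.std() == 0 or y.std() == 0:
                results.append(AssociationResult(
                    pair=(ca, cb), estimate=np.nan, ci=(np.nan, np.nan),
                    p_raw=np.nan, p_adjusted=np.nan, n_used=n, family_size=m,
                    flag="zero-variance column"))
                continue
            r, p = stats.pearsonr(x, y)
            results.append(AssociationResult(
                pair=(ca, cb), estimate=float(r), ci=_fisher_ci(r, n, alpha),
                p_raw=float(p), p_adjusted=_bonferroni(float(p), m),
                n_used=n, family_size=m))
    return results


def _design_matrix(
    factor: pd.Series,
    covariates: pd.DataFrame | None,
    group_col: str = "group",
    reference_group: str = "HC",
    extra: dict[str, pd.Series] | None = None,
) -> pd.DataFrame:
    """Standardize continuous predictors, dummy-code the group column."""
    parts: dict[str, pd.Series] = {}
    fs = factor.astype(float)
    parts[factor.name or "factor"] = (fs - fs.mean()) / fs.std(ddof=1)
    if covariates is not None:
        for col in covariates.columns:
            s = covariates[col]
            if col == group_col or s.dtype == object or isinstance(
                    s.dtype, pd.CategoricalDtype):
                levels = [g for g in pd.unique(s.dropna()) if g != reference_group]
                for lev in sorted(map(str, levels)):
                    parts[f"{group_col}_{lev}"] = (s.astype(str) == lev).astype(float)
            else:
                sf = s.astype(float)
                sd = sf.std(ddof=1)
                parts[col] = (sf - sf.mean()) / sd if sd > 0 else sf * 0.0
    if extra:
        parts.update(extra)
    return pd.DataFrame(parts)


def roi_association(
    y: pd.Series,
    factor: pd.Series,
    covariates: pd.DataFrame | None = None,
    reference_group: str = "HC",
    family_size: int = 1,
) -> AssociationResult:
    """Standardized coefficient of a speech factor on an ROI measure.

    OLS of standardized y on the standardized factor plus covariates (age,
    sex, TIV, diagnostic group as dummies with the healthy-control reference).
    Complete cases only; dropped rows are reflected in ``n_used``.
    """
    name = factor.name or "factor"
    X = _design_matrix(factor, covariates, reference_group=reference_group)
    df = pd.concat([y.rename("_y"), X], axis=1).dropna()
    n = len(df)
    k_params = X.shape[1] + 1
    if n <= k_params + 10:
        raise AssociationError(
            f"only {n} complete cases for {k_params} parameters")
    ys = df["_y"].astype(float)
    ysd = ys.std(ddof=1)
    if ysd == 0:
        raise AssociationError("outcome has zero variance")
    ys = (ys - ys.mean()) / ysd
    Xd = sm.add_constant(df.drop(columns="_y"))
    rank = np.linalg.matrix_rank(Xd.to_numpy())
    if rank < Xd.shape[1]:
        corr = Xd.drop(columns="const").corr().abs()
        np.fill_diagonal(corr.values, 0)
        worst = corr.stack().idxmax()
        raise AssociationError(f"collinear covariates (e.g. {worst})")
    fit = sm.OLS(ys, Xd).fit()
    est = float(fit.params[name])
    ci = fit.conf_int().loc[name]
    p = float(fit.pvalues[name])
    return AssociationResult(
        pair=(name, y.name or "roi"), estimate=est,
        ci=(float(ci[0]), float(ci[1])), p_raw=p,
        p_adjusted=_bonferroni(p, family_size), n_used=n,
        family_size=family_size)


def moderation_test(
    y: pd.Series,
    factor: pd.Series,
    moderator: pd.Series,
    covariates: pd.DataFrame | None = None,
    reference_group: str = "HC",
) -> AssociationResult:
    """Interaction test: does the moderator change the factor-ROI slope?

    OLS with mean-centered factor, mean-centered moderator, their product
    and the covariates; the reported estimate is the product term's
    standardized coefficient.
    """
    mod = moderator.astype(float)
    if mod.std(ddof=1) == 0 or mod.dropna().nunique() < 2:
        raise AssociationError("moderator has no variance")
    fname = factor.name or "factor"
    mname = moderator.name or "moderator"
    fc = factor.astype(float)
    fc = (fc - fc.mean()) / fc.std(ddof=1)
    mc = (mod - mod.mean()) / mod.std(ddof=1)
    inter = (fc * mc).rename(f"{fname}_x_{mname}")
    X = _design_matrix(factor, covariates, reference_group=reference_group,
                       extra={mname: mc, inter.name: inter})
    df = pd.concat([y.rename("_y"), X], axis=1).dropna()
    n = len(df)
    if n <= X.shape[1] + 11:
        raise AssociationError(f"only {n} complete cases")
    ys = df["_y"].astype(float)
    ys = (ys - ys.mean()) / ys.std(ddof=1)
    fit = sm.OLS(ys, sm.add_constant(df.drop(columns="_y"))).fit()
    term = inter.name
    ci = fit.conf_int().loc[term]
    return AssociationResult(
        pair=(term, y.name or "roi"), estimate=float(fit.params[term]),
        ci=(float(ci[0]), float(ci[1])), p_raw=float(fit.pvalues[term]),
        p_adjusted=float(fit.pvalues[term]), n_used=n, family_size=1)


def max_statistic_permutation(
    roi_table: pd.DataFrame,
    factor: pd.Series,
    covariates: pd.DataFrame | None = None,
    n_permutations: int = 10_000,
    seed: int = 0,
    reference_group: str = "HC",
) -> pd.DataFrame:
    """Family-wise correction across an ROI set by max-|t| permutation.

    The factor column is permuted against the (fixed) outcome/covariate rows;
    each ROI's observed |t| is compared with the permutation distribution of
    the maximum |t| across ROIs.  A desk-scale analogue of image-space
    FWE correction, not a reimplementation of it.
    """
    rng = np.random.default_rng(seed)
    name = factor.name or "factor"

    def tvals(fac: pd.Series) -> np.ndarray:
        out = np.empty(roi_table.shape[1])
        for j, col in enumerate(roi_table.columns):
            X = _design_matrix(fac.rename(name), covariates,
                               reference_group=reference_group)
            df = pd.concat([roi_table[col].rename("_y"), X], axis=1).dropna()
            fit = sm.OLS(df["_y"], sm.add_constant(df.drop(columns="_y"))).fit()
            out[j] = fit.tvalues[name]
        return out

    obs = tvals(factor)
    maxes = np.empty(n_permutations)
    values = factor.to_numpy()
    for b in range(n_permutations):
        perm = pd.Series(rng.permutation(values), index=factor.index, name=name)
        maxes[b] = np.max(np.abs(tvals(perm)))
    p_fwe = [(np.sum(maxes >= abs(t)) + 1) / (n_permutations + 1) for t in obs]
    return pd.DataFrame({"roi": roi_table.columns, "t": obs, "p_fwe": p_fwe})


# ---------------------------------------------------------------------------
# Group descriptives
# ---------------------------------------------------------------------------

@dataclass
class GroupVariableStats:
    variable: str
    test: str                      # "anova" or "chisq"
    statistic: float
    p: float
    effect_size: float             # eta squared or Cramer's V
    effect_name: str
    contrasts: list[dict[str, object]] = field(default_factory=list)
    flag: str | None = None


def _eta_squared(groups: list[np.ndarray]) -> float:
    allv = np.concatenate(groups)
    grand = allv.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_total = np.sum((allv - grand) ** 2)
    return float(ss_between / ss_total) if ss_total > 0 else 0.0


def _cramers_v(table: np.ndarray, chi2: float) -> float:
    n = table.sum()
    r, c = table.shape
    return float(np.sqrt(chi2 / (n * (min(r, c) - 1))))


def group_descriptives(
    data: pd.DataFrame,
    variables: list[str],
    group_col: str = "group",
    categorical: tuple[str, ...] = ("sex",),
    alpha: float = 0.05,
) -> list[GroupVariableStats]:
    """Per-variable group comparison with effect sizes and post hoc contrasts.

    Continuous variables: one-way ANOVA with eta squared and Bonferroni
    pairwise Welch t contrasts labelled with their direction.  Categorical:
    chi-square with Cramer's V and pairwise 2-group chi-squares.
    """
    levels = list(pd.unique(data[group_col].dropna()))
    if len(levels) < 2 or any(
            (data[group_col] == g).sum() < 2 for g in levels):
        raise AssociationError("need >= 2 groups with >= 2 members each")
    n_pairs = len(levels) * (len(levels) - 1) // 2
    out = []
    for var in variables:
        if var in categorical:
            table = pd.crosstab(data[group_col], data[var]).to_numpy()
            chi2, p, _, expected = stats.chi2_contingency(table)
            flag = "expected cell count < 1" if np.any(expected < 1) else None
            contrasts = []
            for i in range(len(levels)):
                for j in range(i + 1, len(levels)):
                    sub = data[data[group_col].isin([levels[i], levels[j]])]
                    t2 = pd.crosstab(sub[group_col], sub[var]).to_numpy()
                    c2, pp, *_ = stats.chi2_contingency(t2)
                    contrasts.append({
                        "pair": (levels[i], levels[j]), "statistic": float(c2),
                        "p_adjusted": _bonferroni(float(pp), n_pairs),
                        "direction": "≠",
                    })
            out.append(GroupVariableStats(
                variable=var, test="chisq", statistic=float(chi2), p=float(p),
                effect_size=_cramers_v(table, chi2), effect_name="cramers_v",
                contrasts=contrasts, flag=flag))
        else:
            groups = [data.loc[data[group_col] == g, var].dropna().to_numpy()
                      for g in levels]
            F, p = stats.f_oneway(*groups)
            contrasts = []
            for i in range(len(levels)):
                for j in range(i + 1, len(levels)):
                    t, pp = stats.ttest_ind(groups[i], groups[j])
                    direction = ("<" if groups[i].mean() < groups[j].mean()
                                 else ">")
                    contrasts.append({
                        "pair": (levels[i], levels[j]), "statistic": float(t),
                        "p_adjusted": _bonferroni(float(pp), n_pairs),
                        "direction": direction,
                    })
            out.append(GroupVariableStats(
                variable=var, test="anova", statistic=float(F), p=float(p),
                effect_size=_eta_squared(groups), effect_name="eta_squared",
                contrasts=contrasts))
    return out


def results_to_frame(results: list[AssociationResult]) -> pd.DataFrame:
    """Flatten association results for CSV/JSON export."""
    return pd.DataFrame([
        {
            "predictor": r.pair[0], "outcome": r.pair[1],
            "estimate": r.estimate, "ci_low": r.ci[0], "ci_high": r.ci[1],
            "p_raw": r.p_raw, "p_adjusted": r.p_adjusted,
            "n_used": r.n_used, "family_size": r.family_size, "flag": r.flag,
        }
        for r in results
    ])
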