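"""Mixed-model trend tests on protocol results tables.

Each movement statistic is modelled as a linear mixed model against the
systematically varied variable (coded categorical), with the simulation run
(environment) as a random intercept:

    response ~ level  +  (1 | run)

fitted by maximum likelihood. The model is compared with the null
``response ~ 1 + (1 | run)`` by a likelihood-ratio test,
``chi2 = 2 (logLik_full - logLik_null)`` on ``n_levels - 1`` degrees of
freedom. A significant LRT is followed by all-pairs post-hoc comparisons of
level means with familywise (Holm) adjustment, to describe the shape of the
trend. ML (rather than REML) estimation is used because the LRT compares
models differing in fixed effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning


@dataclass(frozen=True)
class PairwiseComparison:
    """One post-hoc level-pair contrast (difference of level means)."""

    level_a: float
    level_b: float
    estimate: float
    p_adjusted: float


@dataclass
class TrendTestResult:
    """Outcome of one likelihood-ratio trend test.

    ``posthoc`` is populated only when the LRT is significant at ``alpha``;
    ``adjustment`` records the familywise correction applied. ``degenerate``
    flags tables with zero response variance, for which the test is
    trivially null (chi2 = 0, p = 1).
    """

    response: str
    predictor: str
    chi_square: float
    df: int
    p_value: float
    posthoc: list[PairwiseComparison] = field(default_factory=list)
    adjustment: str = "holm"
    degenerate: bool = False

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p_value < alpha


def _fit_ml(formula: str, data: pd.DataFrame, groups: pd.Series):
    # When the random-intercept variance collapses to the boundary the
    # post-fit Hessian can be singular under lbfgs; fall through to more
    # forgiving optimizers before giving up.
    last_err: Exception | None = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        model = smf.mixedlm(formula, data=data, groups=groups)
        for method in ("lbfgs", "powell", "cg", "nm"):
            try:
                result = model.fit(reml=False, method=[method], maxiter=2000)
            except (np.linalg.LinAlgError, ValueError) as exc:
                last_err = exc
                continue
            if np.isfinite(result.llf):  # some optimizers "succeed" at llf=inf
                return result
            last_err = RuntimeError(f"non-finite log-likelihood under {method}")
    raise RuntimeError(f"mixed-model fit failed for {formula!r}") from last_err


def _posthoc_pairs(
    result, levels: list[float], alpha_names: list[str]
) -> list[PairwiseComparison]:
    """All-pairs contrasts of level means from treatment-coded fixed effects.

    Level means differ only through the treatment dummies, so the contrast
    between two levels is the difference of their dummy coefficients (the
    reference level's coefficient being zero). Wald z-tests with Holm
    adjustment control the familywise error rate.
    """
    params = result.params
    cov = result.cov_params()
    # coefficient vector position per level; reference level -> None
    k = len(levels)
    estimates, variances, pairs = [], [], []
    coef_index = {levels[0]: None}
    for lev, name in zip(levels[1:], alpha_names):
        coef_index[lev] = name
    for i in range(k):
        for j in range(i + 1, k):
            ci, cj = coef_index[levels[i]], coef_index[levels[j]]
            bi = params[ci] if ci is not None else 0.0
            bj = params[cj] if cj is not None else 0.0
            vi = cov.loc[ci, ci] if ci is not None else 0.0
            vj = cov.loc[cj, cj] if cj is not None else 0.0
            cij = cov.loc[ci, cj] if ci is not None and cj is not None else 0.0
            estimates.append(bj - bi)
            variances.append(max(vi + vj - 2 * cij, 0.0))
            pairs.append((levels[i], levels[j]))
    estimates = np.asarray(estimates)
    se = np.sqrt(np.asarray(variances))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, estimates / se, 0.0)
    p_raw = 2 * sps.norm.sf(np.abs(z))
    _, p_adj, _, _ = multipletests(p_raw, method="holm")
    return [
        PairwiseComparison(a, b, float(est), float(p))
        for (a, b), est, p in zip(pairs, estimates, p_adj)
    ]


def fit_trend_test(
    table: pd.DataFrame,
    response: str,
    predictor: str,
    group: str = "env_id",
    alpha: float = 0.05,
) -> TrendTestResult:
    """LRT of a categorical level effect in a random-intercept mixed model.

    ``table`` is a long-format results table with one observation per
    (run, level); rows with a missing response are dropped. Requires at
    least two levels and two runs.
    """
    data = table[[group, predictor, response]].dropna().copy()
    levels = sorted(data[predictor].unique())
    if len(levels) < 2:
        raise ValueError("need at least 2 predictor levels")
    if data[group].nunique() < 2:
        raise ValueError("need at least 2 runs (random-factor groups)")
    df = len(levels) - 1

    y = data[response].to_numpy(dtype=float)
    if np.ptp(y) == 0.0:  # identical responses: trivially no trend
        return TrendTestResult(response, predictor, 0.0, df, 1.0, degenerate=True)

    data["_lvl"] = pd.Categorical(data[predictor], categories=levels, ordered=True)
    full = _fit_ml(f"{response} ~ C(_lvl)", data, data[group])
    null = _fit_ml(f"{response} ~ 1", data, data[group])
    chi2 = max(2.0 * (full.llf - null.llf), 0.0)
    p = float(sps.chi2.sf(chi2, df))

    result = TrendTestResult(response, predictor, float(chi2), df, p)
    if p < alpha:
        fe_names = [n for n in full.params.index if n.startswith("C(_lvl)")]
        result.posthoc = _posthoc_pairs(full, levels, fe_names)
    return result


def level_medians(table: pd.DataFrame, response: str, predictor: str) -> pd.Series:
    """Per-level median of a response, indexed by sorted level value."""
    return table.dropna(subset=[response]).groupby(predictor)[response].median().sort_index()


def trend_direction(medians: pd.Series) -> str:
    """Crude trend label from level medians via Spearman rank correlation."""
    if len(medians) < 2 or medians.nunique() == 1:
        return "flat"
    rho, p = sps.spearmanr(np.arange(len(medians)), medians.to_numpy())
    if p < 0.05 and rho > 0:
        return "increasing"
    if p < 0.05 and rho < 0:
        return "decreasing"
    return "no clear pattern"


def summarize_trends(
    table: pd.DataFrame,
    predictor: str,
    responses: tuple[str, ...] = ("max_distance", "n_switches", "prop_wild"),
    group: str = "env_id",
) -> pd.DataFrame:
    """Trend summary across responses: LRT, direction, post-hoc significance.

    One row per response with the LRT chi-square / df / p, the direction of
    the level-median trend, and the fraction of post-hoc pairs significant
    at 0.05 — the ingredients of an arrow-style results table, reported as
    the underlying pattern rather than a verbal grade.
    """
    rows = []
    for resp in responses:
        if resp not in table.columns or table[resp].dropna().empty:
            continue
        res = fit_trend_test(table, resp, predictor, group=group)
        meds = level_medians(table, resp, predictor)
        n_sig = sum(c.p_adjusted < 0.05 for c in res.posthoc)
        rows.append({
            "response": resp,
            "predictor": predictor,
            "chi_square": res.chi_square,
            "df": res.df,
            "p_value": res.p_value,
            "direction": trend_direction(meds),
            "n_posthoc_pairs": len(res.posthoc),
            "n_posthoc_significant": n_sig,
        })
    return pd.DataFrame(rows)
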