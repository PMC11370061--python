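"""Group-level statistics for subtype and motor-noise contrasts.

Two-group phenotype contrasts use Welch's t when both groups pass a
Shapiro-Wilk normality screen and a two-sample rank-sum (Mann-Whitney)
test otherwise; Cohen's d (pooled SD) is always reported. Motor-noise
group differences use one-way ANOVA with post hoc pairwise Welch tests.
Competing group structures for an outcome are compared by AIC of one-way
OLS fits. Phase-resolved noise (feedforward vs feedback, within subject)
is modelled with a linear mixed model: fixed effects group, phase and
their interaction, random intercept per subject.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class GroupComparisonResult:
    variable: str
    groups: tuple
    test: str  # welch_t | rank_sum
    statistic: float
    p_value: float
    cohens_d: float  # sign convention: mean(group1) - mean(group2)
    n: tuple


@dataclass
class AnovaResult:
    f_statistic: float
    p_value: float
    pairwise: list = field(default_factory=list)  # GroupComparisonResult per pair


@dataclass
class LMMResult:
    fixed_effects: dict
    interaction_f: float
    interaction_df: tuple  # (numerator, denominator)
    interaction_p: float
    random_intercept_var: float
    residual_var: float
    n_subjects: int
    n_observations: int
    per_phase_contrasts: list = field(default_factory=list)
    singular_fallback: bool = False


def cohens_d(x, y) -> float:
    """Standardised mean difference (x minus y) with pooled SD."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("each sample needs n >= 2")
    pooled = np.sqrt(((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2))
    if pooled == 0:
        raise ValueError("zero pooled standard deviation")
    return float((x.mean() - y.mean()) / pooled)


def compare_groups(
    values,
    labels,
    variable: str = "",
    gaussian_check_alpha: float = 0.05,
) -> GroupComparisonResult:
    """Two-group contrast with a data-driven choice of test.

    Each group is screened with Shapiro-Wilk; if either deviates from
    normality at ``gaussian_check_alpha`` the rank-sum branch is taken.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, got {len(groups)}")
    x = values[labels == groups[0]]
    y = values[labels == groups[1]]
    if len(x) < 3 or len(y) < 3:
        raise ValueError("each group needs n >= 3")
    normal = all(stats.shapiro(g).pvalue >= gaussian_check_alpha for g in (x, y))
    if normal:
        t = stats.ttest_ind(x, y, equal_var=False)
        test, statistic, p = "welch_t", float(t.statistic), float(t.pvalue)
    else:
        logger.info("%s: non-Gaussian group, rank-sum branch", variable or "contrast")
        u = stats.mannwhitneyu(x, y, alternative="two-sided")
        test, statistic, p = "rank_sum", float(u.statistic), float(u.pvalue)
    return GroupComparisonResult(
        variable, (groups[0], groups[1]), test, statistic, p, cohens_d(x, y), (len(x), len(y))
    )


def anova_posthoc(values, labels, variable: str = "motor_noise") -> AnovaResult:
    """One-way ANOVA across >= 3 groups plus all pairwise Welch contrasts."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = list(pd.unique(labels))
    if len(groups) < 3:
        raise ValueError("need at least 3 groups")
    samples = [values[labels == g] for g in groups]
    if any(len(s) < 3 for s in samples):
        raise ValueError("each group needs n >= 3")
    f, p = stats.f_oneway(*samples)
    pairwise = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            t = stats.ttest_ind(samples[i], samples[j], equal_var=False)
            pairwise.append(
                GroupComparisonResult(
                    variable,
                    (groups[i], groups[j]),
                    "welch_t",
                    float(t.statistic),
                    float(t.pvalue),
                    cohens_d(samples[i], samples[j]),
                    (len(samples[i]), len(samples[j])),
                )
            )
    return AnovaResult(float(f), float(p), pairwise)


def aic_compare(outcome, groups_a, groups_b) -> float:
    """AIC(model A) - AIC(model B) for one-way OLS group models.

    Negative values favour model A. Both models must be fit on exactly the
    same rows.
    """
    import statsmodels.api as sm

    outcome = np.asarray(outcome, dtype=float)
    if len(groups_a) != len(outcome) or len(groups_b) != len(outcome):
        raise ValueError("models must be fit on the same rows")
    aics = []
    for g in (groups_a, groups_b):
        X = pd.get_dummies(pd.Series(np.asarray(g)), drop_first=True, dtype=float)
        X = sm.add_constant(X, has_constant="add")
        aics.append(sm.OLS(outcome, X).fit().aic)
    return float(aics[0] - aics[1])


def fit_group_phase_lmm(long: pd.DataFrame) -> LMMResult:
    """Random-intercept mixed model for phase-resolved motor noise.

    ``long`` needs columns subject, group, phase, value, with both phases
    present for every subject. The group x phase interaction is tested with
    a Wald F statistic using the between-within denominator degrees of
    freedom (observations - subjects - fixed-effect parameters). A singular
    random-intercept fit falls back to OLS on the same fixed effects, with
    the fallback flagged.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    required = {"subject", "group", "phase", "value"}
    if not required.issubset(long.columns):
        raise ValueError(f"long table needs columns {sorted(required)}")
    counts = long.groupby("subject")["phase"].nunique()
    if (counts < 2).any():
        raise ValueError("every subject must contribute both phases")

    formula = "value ~ C(group) * C(phase)"
    fallback = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = smf.mixedlm(formula, long, groups=long["subject"]).fit(reml=True)
            converged = fit.converged
            re_var = float(fit.cov_re.iloc[0, 0])
        except Exception:
            converged, re_var = False, np.nan
    if not converged or not np.isfinite(re_var):
        logger.warning("singular/failed mixed fit; falling back to OLS fixed effects")
        fallback = True
        fit = smf.ols(formula, long).fit()
        re_var = 0.0
        resid_var = float(fit.mse_resid)
    else:
        resid_var = float(fit.scale)

    inter_names = [nm for nm in fit.params.index if ":" in nm]
    q = len(inter_names)
    constraint = ", ".join(f"{nm} = 0" for nm in inter_names)
    wald = fit.wald_test(constraint, scalar=True, use_f=False)
    chi2 = float(np.squeeze(wald.statistic))
    f_stat = chi2 / q
    n_obs = len(long)
    n_subj = long["subject"].nunique()
    df_denom = max(1, n_obs - n_subj - len(fit.params))
    p = float(stats.f.sf(f_stat, q, df_denom))

    contrasts = []
    for phase, sub in long.groupby("phase"):
        groups = list(pd.unique(sub["group"]))
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                x = sub.loc[sub["group"] == groups[i], "value"]
                y = sub.loc[sub["group"] == groups[j], "value"]
                t = stats.ttest_ind(x, y, equal_var=False)
                contrasts.append(
                    GroupComparisonResult(
                        f"noise[{phase}]",
                        (groups[i], groups[j]),
                        "welch_t",
                        float(t.statistic),
                        float(t.pvalue),
                        cohens_d(x, y),
                        (len(x), len(y)),
                    )
                )
    fe = {nm: float(v) for nm, v in fit.params.items() if nm != "Group Var"}
    return LMMResult(
        fixed_effects=fe,
        interaction_f=f_stat,
        interaction_df=(q, df_denom),
        interaction_p=p,
        random_intercept_var=0.0 if fallback else re_var,
        residual_var=resid_var,
        n_subjects=n_subj,
        n_observations=n_obs,
        per_phase_contrasts=contrasts,
        singular_fallback=fallback,
    )
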