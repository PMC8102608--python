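"""Cohort-level statistics for community flux profiles.

Group screens (rank-sum with FDR, exact tests on binary secretion),
secretion-diversity regression with fractional-polynomial functional-form
selection, logistic classification AUC, Sobel–Goodman mediation with
bootstrap confidence intervals, random-forest stratification, and
agreement of in-silico group differences with an external metabolomic
direction table.

Conventions fixed here: Benjamini–Hochberg FDR, two-sided tests
throughout, single-term (FP1) fractional polynomials, and percentile
bootstrap confidence intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import binomtest, fisher_exact, mannwhitneyu, norm, t as t_dist
from statsmodels.stats.multitest import multipletests

from .metrics import collapse_coupled_columns

__all__ = [
    "TestResult",
    "RegressionResult",
    "MediationResult",
    "ClassifierResult",
    "AgreementResult",
    "benjamini_hochberg",
    "wilcoxon_fdr_screen",
    "fisher_secretion_screen",
    "freeman_halton",
    "secreted_count_regression",
    "classify_auc",
    "mediation_analysis",
    "rf_stratify",
    "direction_agreement",
    "directions_from_screen",
    "FP1_POWERS",
]


@dataclass
class TestResult:
    feature_id: str
    statistic: float
    p_value: float
    q_value: float
    groups: Tuple[str, ...]


@dataclass
class RegressionResult:
    params: pd.Series
    b: float  # designated group effect
    ci: Tuple[float, float]
    t: float
    p: float
    df_resid: int
    chosen_power: Optional[float]
    deviances: Dict[float, float]
    form_p: float  # deviance-difference test of chosen form vs linear
    n: int


@dataclass
class MediationResult:
    total: float
    direct: float
    indirect: float
    proportion_mediated: float
    ci: Tuple[float, float]  # percentile bootstrap CI of the indirect effect
    proportion_ci: Tuple[float, float]
    z: float  # Sobel z
    p: float  # two-sided Sobel p
    goodman_z: float
    n_bootstrap: int
    n: int


@dataclass
class ClassifierResult:
    auc: Optional[float] = None
    oob_error: Optional[float] = None
    feature_ranking: Optional[pd.Series] = None  # mean decrease in accuracy
    n_trees: Optional[int] = None
    coef: Optional[float] = None


@dataclass
class AgreementResult:
    n_agree: int
    n_disagree: int
    percent_agreement: float
    binomial_p: float
    fisher_p: float
    reported: str = "binomial"  # which test is the headline number


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# group screens
# ---------------------------------------------------------------------------


def wilcoxon_fdr_screen(
    features: pd.DataFrame,
    groups: pd.Series,
    pair: Tuple[str, str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-sided rank-sum test per feature between two groups, BH-corrected.

    All-tied features are emitted with p = 1, not dropped.  Returns a
    DataFrame with ``feature_id``, ``statistic``, ``p_value``, ``q_value``,
    ``significant`` (q < ``alpha``) and the sign of the group difference
    (median of ``pair[1]`` minus ``pair[0]``).
    """
    g1, g2 = pair
    idx1 = groups.index[groups == g1]
    idx2 = groups.index[groups == g2]
    if len(idx1) < 3 or len(idx2) < 3:
        raise ValueError("need >= 3 samples per group")
    rows = []
    for feat in features.columns:
        x = features.loc[idx1, feat].values.astype(float)
        y = features.loc[idx2, feat].values.astype(float)
        if np.all(np.concatenate([x, y]) == x[0]):
            stat, p = np.nan, 1.0
        else:
            res = mannwhitneyu(x, y, alternative="two-sided", method="auto")
            stat, p = float(res.statistic), float(res.pvalue)
        rows.append((feat, stat, p, float(np.median(y) - np.median(x))))
    out = pd.DataFrame(
        rows, columns=["feature_id", "statistic", "p_value", "median_diff"]
    )
    out["q_value"] = benjamini_hochberg(out["p_value"].values)
    out["significant"] = out["q_value"] < alpha
    out.attrs["groups"] = pair
    return out


def freeman_halton(table: np.ndarray) -> float:
    """Exact conditional (Freeman–Halton) test for a 2 × k table.

    Enumerates all tables with the observed margins; the p-value is the
    total probability of tables no more probable than the observed one
    under the multivariate hypergeometric null.
    """
    table = np.asarray(table, dtype=int)
    if table.shape[0] != 2:
        raise ValueError("freeman_halton expects a 2 x k table")
    col = table.sum(axis=0)
    r1 = int(table[0].sum())
    n = int(table.sum())

    def log_p(top: Sequence[int]) -> float:
        lp = -(gammaln(n + 1) - gammaln(r1 + 1) - gammaln(n - r1 + 1))
        for cj, nj in zip(col, top):
            lp += gammaln(cj + 1) - gammaln(nj + 1) - gammaln(cj - nj + 1)
        return lp

    obs = log_p(table[0])
    total = 0.0
    k = len(col)

    def rec(j: int, remaining: int, prefix: List[int]):
        nonlocal total
        if j == k - 1:
            if remaining <= col[j]:
                lp = log_p(prefix + [remaining])
                if lp <= obs + 1e-9:
                    total += np.exp(lp)
            return
        lo = max(0, remaining - int(col[j + 1:].sum()))
        hi = min(col[j], remaining)
        for v in range(lo, hi + 1):
            rec(j + 1, remaining - v, prefix + [v])

    rec(0, r1, [])
    return float(min(1.0, total))


def fisher_secretion_screen(
    binary: pd.DataFrame,
    groups: pd.Series,
    alpha: float = 0.05,
) -> Tuple[pd.DataFrame, List[str]]:
    """Exact tests of binary secretion against the study group.

    Perfectly coupled duplicate features are collapsed first, so the FDR
    correction runs over independent features only (the number of tests is
    the number of independent dichotomised secretions).  Two groups use
    Fisher's 2×2 exact test; three use the Freeman–Halton extension.
    Features constant across all samples are skipped (returned in the
    second element with the representative's coupled group).
    """
    levels = [g for g in pd.unique(groups) if g is not None]
    if len(levels) < 2:
        raise ValueError("need >= 2 groups")
    collapsed, coupled = collapse_coupled_columns(binary.astype(bool))
    rows = []
    skipped: List[str] = []
    for feat in collapsed.columns:
        v = collapsed[feat]
        if v.all() or (~v).all():
            skipped.append(feat)
            continue
        table = np.array(
            [
                [int(v[groups == g].sum()) for g in levels],
                [int((~v[groups == g]).sum()) for g in levels],
            ]
        )
        if len(levels) == 2:
            p = float(fisher_exact(table)[1])
        else:
            p = freeman_halton(table)
        rows.append((feat, p))
    out = pd.DataFrame(rows, columns=["feature_id", "p_value"])
    if len(out):
        out["q_value"] = benjamini_hochberg(out["p_value"].values)
        out["significant"] = out["q_value"] < alpha
    out.attrs["groups"] = tuple(levels)
    out.attrs["coupled_groups"] = coupled
    return out, skipped


# ---------------------------------------------------------------------------
# secretion-diversity regression with FP1 form selection
# ---------------------------------------------------------------------------

FP1_POWERS = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)


def _fp_transform(x: np.ndarray, power: float) -> np.ndarray:
    if power == 0.0:
        return np.log(x)
    return x ** power


def _check_full_rank(X: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the first column that does not increase the rank
        r = 0
        for j in range(X.shape[1]):
            rj = np.linalg.matrix_rank(X[:, : j + 1])
            if rj == r:
                raise ValueError(f"singular design: column {names[j]!r} is collinear")
            r = rj
        raise ValueError("singular design")


def secreted_count_regression(
    counts: pd.Series,
    n_strains: pd.Series,
    groups: pd.Series,
    effect_level: Optional[str] = None,
    reference_level: Optional[str] = None,
) -> RegressionResult:
    """OLS of secreted-metabolite counts on group plus a strain-count term.

    The functional dependence on the number of strains is chosen by an
    FP1 (single-term fractional polynomial) search over powers
    ``{-2, -1, -0.5, 0 (log), 0.5, 1, 2, 3}``, taking the power with
    minimal deviance; ``form_p`` is the chi-square(1) deviance-difference
    test of the chosen form against the linear one.  The designated group
    coefficient ``b`` (by default the last group level in cohort order)
    is reported with its 95% CI and t-test.
    """
    import statsmodels.api as sm

    df = pd.DataFrame(
        {"count": counts, "n_strains": n_strains, "group": groups}
    ).dropna()
    if len(df) < 10:
        raise ValueError("need >= 10 samples")
    if (df["n_strains"] < 1).any():
        raise ValueError("n_strains must be >= 1")
    levels = [g for g in pd.unique(df["group"])]
    reference = reference_level or levels[0]
    others = [g for g in levels if g != reference]
    effect = effect_level or others[-1]

    def design(power: float) -> Tuple[np.ndarray, List[str]]:
        cols = [np.ones(len(df))]
        names = ["const"]
        for g in others:
            cols.append((df["group"] == g).astype(float).values)
            names.append(f"group[{g}]")
        cols.append(_fp_transform(df["n_strains"].values.astype(float), power))
        names.append(f"fp({power})")
        return np.column_stack(cols), names

    fits = {}
    deviances: Dict[float, float] = {}
    for power in FP1_POWERS:
        X, names = design(power)
        _check_full_rank(X, names)
        fit = sm.OLS(df["count"].values.astype(float), X).fit()
        fits[power] = (fit, names)
        deviances[power] = float(-2.0 * fit.llf)

    chosen = min(FP1_POWERS, key=lambda p: (deviances[p], abs(p - 1.0)))
    fit, names = fits[chosen]
    from scipy.stats import chi2

    delta = deviances[1.0] - deviances[chosen]
    form_p = float(chi2.sf(max(0.0, delta), df=1)) if chosen != 1.0 else 1.0

    params = pd.Series(fit.params, index=names)
    j = names.index(f"group[{effect}]")
    ci_arr = fit.conf_int(alpha=0.05)
    b = float(fit.params[j])
    return RegressionResult(
        params=params,
        b=b,
        ci=(float(ci_arr[j][0]), float(ci_arr[j][1])),
        t=float(fit.tvalues[j]),
        p=float(fit.pvalues[j]),
        df_resid=int(fit.df_resid),
        chosen_power=chosen,
        deviances=deviances,
        form_p=form_p,
        n=len(df),
    )


# ---------------------------------------------------------------------------
# logistic classification AUC
# ---------------------------------------------------------------------------


def classify_auc(score: pd.Series, labels: pd.Series) -> ClassifierResult:
    """Univariate logistic classification with AUC.

    ``labels`` must contain exactly two classes; the positive class is the
    one sorting last.  The AUC is the concordance of the raw score with
    the positive class and equals the Mann–Whitney statistic
    U / (n1 * n2) exactly; the logistic coefficient of the score is
    reported alongside.
    """
    from scipy.stats import rankdata
    from sklearn.linear_model import LogisticRegression

    score = score.astype(float)
    classes = sorted(pd.unique(labels))
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    y = (labels == classes[1]).astype(int).values
    X = score.values.reshape(-1, 1)
    clf = LogisticRegression(C=1e6, solver="lbfgs", max_iter=1000)
    clf.fit(X, y)
    # concordance via midranks: AUC = (R1 - n1(n1+1)/2) / (n1 n0)
    pos = score.values[y == 1]
    neg = score.values[y == 0]
    ranks = rankdata(np.concatenate([pos, neg]))
    n1, n0 = len(pos), len(neg)
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    auc = float(u / (n1 * n0))
    return ClassifierResult(auc=auc, coef=float(clf.coef_[0, 0]))


# ---------------------------------------------------------------------------
# mediation
# ---------------------------------------------------------------------------


def _ols_coef_se(X: np.ndarray, y: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    n, p = X.shape
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = max(n - p, 1)
    sigma2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(np.clip(np.diag(xtx_inv) * sigma2, 0.0, None))
    return coef, se


def mediation_analysis(
    outcome: pd.Series,
    exposure: pd.Series,
    mediator: pd.Series,
    n_boot: int = 1000,
    seed: int = 0,
) -> MediationResult:
    """Sobel–Goodman mediation with non-parametric bootstrap CIs.

    Product-of-coefficients decomposition over three OLS fits:
    ``mediator ~ exposure`` (path a), ``outcome ~ exposure + mediator``
    (paths c' and b) and ``outcome ~ exposure`` (total c).  For linear
    models ``total = direct + indirect`` exactly.  Confidence intervals
    are percentile bootstrap over samples with ``n_boot`` replications,
    deterministic given ``seed``.
    """
    df = pd.DataFrame(
        {"y": outcome, "x": exposure, "m": mediator}
    ).dropna().astype(float)
    n = len(df)
    if n < 20:
        raise ValueError("need >= 20 samples for mediation analysis")
    if df["m"].nunique() < 2:
        raise ValueError("no mediator variance")
    y = df["y"].values
    x = df["x"].values
    m = df["m"].values
    ones = np.ones(n)

    def paths(yv, xv, mv):
        Xa = np.column_stack([ones[: len(xv)], xv])
        a_coef, a_se = _ols_coef_se(Xa, mv)
        Xb = np.column_stack([ones[: len(xv)], xv, mv])
        b_coef, b_se = _ols_coef_se(Xb, yv)
        c_coef, _ = _ols_coef_se(Xa, yv)
        a, sa = a_coef[1], a_se[1]
        b, sb = b_coef[2], b_se[2]
        direct = b_coef[1]
        total = c_coef[1]
        return a, sa, b, sb, direct, total

    a, sa, b, sb, direct, total = paths(y, x, m)
    indirect = a * b
    sobel_se = np.sqrt(b**2 * sa**2 + a**2 * sb**2)
    goodman_var = b**2 * sa**2 + a**2 * sb**2 - sa**2 * sb**2
    z = indirect / sobel_se if sobel_se > 0 else np.nan
    goodman_z = (
        indirect / np.sqrt(goodman_var) if goodman_var > 0 else np.nan
    )
    p = float(2 * norm.sf(abs(z))) if np.isfinite(z) else np.nan
    proportion = indirect / total if abs(total) > 1e-12 else np.nan

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    boot_prop = np.empty(n_boot)
    o = np.ones(n)
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        yb, xb, mb = y[idx], x[idx], m[idx]
        if np.all(mb == mb[0]) or np.all(xb == xb[0]):
            boots[i] = np.nan
            boot_prop[i] = np.nan
            continue
        Xa = np.column_stack([o, xb])
        ab, *_ = np.linalg.lstsq(Xa, mb, rcond=None)
        Xb = np.column_stack([o, xb, mb])
        bb, *_ = np.linalg.lstsq(Xb, yb, rcond=None)
        cb, *_ = np.linalg.lstsq(Xa, yb, rcond=None)
        boots[i] = ab[1] * bb[2]
        boot_prop[i] = boots[i] / cb[1] if abs(cb[1]) > 1e-12 else np.nan
    ci = tuple(np.nanpercentile(boots, [2.5, 97.5]))
    prop_ci = tuple(np.nanpercentile(boot_prop, [2.5, 97.5]))

    return MediationResult(
        total=float(total),
        direct=float(direct),
        indirect=float(indirect),
        proportion_mediated=float(proportion),
        ci=(float(ci[0]), float(ci[1])),
        proportion_ci=(float(prop_ci[0]), float(prop_ci[1])),
        z=float(z),
        p=p,
        goodman_z=float(goodman_z) if np.isfinite(goodman_z) else np.nan,
        n_bootstrap=n_boot,
        n=n,
    )


# ---------------------------------------------------------------------------
# random forests
# ---------------------------------------------------------------------------


def rf_stratify(
    features: pd.DataFrame,
    labels: pd.Series,
    n_trees: int = 5000,
    seed: int = 0,
    n_permutation_repeats: int = 10,
) -> ClassifierResult:
    """Random-forest stratification with OOB error and accuracy-based ranking.

    A standard random-forest classifier is grown with ``n_trees`` trees;
    roughly one third of the samples fall outside each tree's bootstrap
    draw and estimate the out-of-bag error.  Features are ranked by mean
    decrease in accuracy under permutation.
    """
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.inspection import permutation_importance

    if n_trees < 100:
        warnings.warn(f"n_trees = {n_trees} is low; rankings will be noisy")
    if len(features) < 10 or labels.nunique() < 2:
        raise ValueError("need >= 10 samples and >= 2 classes")
    X = features.values.astype(float)
    y = labels.values
    clf = RandomForestClassifier(
        n_estimators=n_trees,
        oob_score=True,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # OOB warning on tiny data
        clf.fit(X, y)
    oob_error = float(1.0 - clf.oob_score_)
    imp = permutation_importance(
        clf, X, y, n_repeats=n_permutation_repeats, random_state=seed,
        scoring="accuracy",
    )
    ranking = pd.Series(
        imp.importances_mean, index=features.columns, name="mean_decrease_accuracy"
    ).sort_values(ascending=False)
    return ClassifierResult(
        oob_error=oob_error, feature_ranking=ranking, n_trees=n_trees
    )


# ---------------------------------------------------------------------------
# metabolomic direction agreement
# ---------------------------------------------------------------------------


def directions_from_screen(screen: pd.DataFrame, alpha: float = 0.05) -> pd.Series:
    """Turn a rank-sum screen into a direction table.

    Significant features (q < ``alpha``) are labelled ``up``/``down`` by
    the sign of the median group difference; the rest ``nonsignificant``.
    """
    direction = np.where(
        screen["q_value"] < alpha,
        np.where(screen["median_diff"] > 0, "up", "down"),
        "nonsignificant",
    )
    return pd.Series(direction, index=screen["feature_id"].values, name="direction")


def direction_agreement(
    in_silico: pd.Series, reference: pd.Series
) -> AgreementResult:
    """Agreement of in-silico directions with a reference direction table.

    Counted over metabolites carrying a significant (``up``/``down``)
    direction in both tables.  Two tests against chance agreement are
    computed and labelled: a two-sided binomial test of the agreement
    count against 0.5 (the headline number) and a Fisher exact test of
    the observed agree/disagree split against an even split.
    """
    shared = in_silico.index.intersection(reference.index)
    mask = (
        in_silico.loc[shared].isin(["up", "down"])
        & reference.loc[shared].isin(["up", "down"])
    )
    overlap = shared[mask]
    if len(overlap) == 0:
        raise ValueError("no metabolites significant in both tables")
    agree = int((in_silico.loc[overlap] == reference.loc[overlap]).sum())
    n = len(overlap)
    disagree = n - agree
    binom_p = float(binomtest(agree, n, 0.5).pvalue)
    even = [n // 2, n - n // 2]
    fisher_p = float(fisher_exact([[agree, disagree], even])[1])
    return AgreementResult(
        n_agree=agree,
        n_disagree=disagree,
        percent_agreement=100.0 * agree / n,
        binomial_p=binom_p,
        fisher_p=fisher_p,
        reported="binomial",
    )
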