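"""Response-classification statistics: group tests, feature filtering,
logistic modeling, ROC and paired-AUC comparison.

The analysis chain mirrors a conventional small-cohort biomarker study:

1. Mann-Whitney U test per candidate feature between the two response
   groups (exact null for tiny untied samples, tie- and
   continuity-corrected normal approximation otherwise).
2. Redundancy filtering: among features with p < alpha, greedily retain in
   ascending-p order, dropping any candidate whose absolute Spearman rank
   correlation with an already-retained feature reaches the threshold
   (default 0.6).
3. Maximum-likelihood logistic regression on the retained features, with
   Wald statistics, odds ratios and 95% CIs per term.
4. ROC analysis with the rank-based AUC (ties get half credit), a
   Youden-optimal cutoff, and DeLong confidence intervals; paired models
   are compared with the DeLong test.

CR (complete response) is the positive class throughout, so markers that
fall under effective treatment get negative logistic coefficients.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InvalidInputError

__all__ = [
    "GroupTestResult",
    "LogisticFit",
    "RocResult",
    "EQ4_MODEL_POST",
    "mann_whitney",
    "spearman_filter",
    "wald_or_ci",
    "fit_logistic",
    "predict_prob",
    "roc_analysis",
    "delong_test",
    "run_full_analysis",
]

#: published combined-model coefficients (post-treatment Ktrans, ve and
#: co-occurrence entropy), shipped as a named preset:
#: f(x) = 1 / (1 + exp(-(26.772 - 17.010*ktrans - 15.854*ve - 3.235*entropy)))
EQ4_MODEL_POST: dict[str, float] = {
    "intercept": 26.772,
    "ktrans_post": -17.010,
    "ve_post": -15.854,
    "entropy_post": -3.235,
}


@dataclass
class GroupTestResult:
    feature: str
    u_statistic: float
    p_value: float


@dataclass
class TermStats:
    """Reporting arithmetic for one logistic term."""

    coef: float
    std_error: float
    wald: float
    p_value: float
    odds_ratio: float
    ci95: tuple[float, float]


@dataclass
class LogisticFit:
    features: list[str]
    terms: dict[str, TermStats]
    converged: bool
    separation: bool = False

    @property
    def coefficients(self) -> dict[str, float]:
        return {name: t.coef for name, t in self.terms.items()}


@dataclass
class RocResult:
    auc: float
    ci95: tuple[float, float]
    cutoff: float
    sensitivity: float
    specificity: float
    direction: str = ">"  # ">": score >= cutoff predicts positive


def mann_whitney(x, y) -> GroupTestResult:
    """Two-sided Mann-Whitney U test.

    Exact enumeration of the null when n1+n2 <= 12 with no ties, otherwise
    the normal approximation with tie and continuity corrections.  The U
    statistic reported is that of ``x``.  A constant pooled sample carries
    no rank information: p = 1 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InvalidInputError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        warnings.warn("constant pooled sample: U test is uninformative")
        return GroupTestResult("", x.size * y.size / 2.0, 1.0)
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size + y.size <= 12 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return GroupTestResult("", float(res.statistic), float(min(res.pvalue, 1.0)))


def spearman_filter(
    table: pd.DataFrame,
    candidates: list[str],
    pvals: dict[str, float],
    threshold: float = 0.6,
) -> list[str]:
    """Greedy redundancy filter on Spearman rank correlation.

    Candidates are visited in ascending order of their group-test p-value;
    one is retained only if |rho| < threshold against every feature already
    retained.
    """
    retained: list[str] = []
    for cand in sorted(candidates, key=lambda c: (pvals[c], c)):
        ok = True
        for kept in retained:
            pair = table[[cand, kept]].dropna()
            rho = sps.spearmanr(pair[cand], pair[kept]).statistic
            if np.isfinite(rho) and abs(rho) >= threshold:
                ok = False
                break
        if ok:
            retained.append(cand)
    return retained


def wald_or_ci(coef: float, std_error: float, z: float = 1.96) -> dict[str, float]:
    """Wald statistic, odds ratio and 95% CI from a coefficient and its SE.

    Wald = (coef/SE)^2, OR = exp(coef), CI = exp(coef -/+ z*SE); the Wald
    p-value is chi-square with 1 df.
    """
    wald = (coef / std_error) ** 2
    with np.errstate(over="ignore"):
        return {
            "wald": wald,
            "p_value": float(sps.chi2.sf(wald, df=1)),
            "odds_ratio": float(np.exp(coef)),
            "ci_low": float(np.exp(coef - z * std_error)),
            "ci_high": float(np.exp(coef + z * std_error)),
        }


def _logit_mle(x: np.ndarray, y: np.ndarray):
    """Maximum-likelihood logistic fit (IRLS/Newton via statsmodels).

    Returns (beta, covariance, converged); the covariance is the inverse
    observed information at the optimum.  Failures surface as
    non-convergence, never as an exception.
    """
    import statsmodels.api as sm

    k = x.shape[1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, x).fit(disp=0, maxiter=200)
            return (
                np.asarray(res.params),
                np.asarray(res.cov_params()),
                bool(res.mle_retvals.get("converged", False)),
            )
        except Exception:
            # separation or a singular information matrix: fall back to a
            # capped IRLS (binomial GLM) so the diverging iterate is still
            # reported, flagged as non-converged upstream
            try:
                res = sm.GLM(y, x, family=sm.families.Binomial()).fit(maxiter=25)
                return np.asarray(res.params), np.asarray(res.cov_params()), False
            except Exception:
                return np.zeros(k), np.full((k, k), np.nan), False


def fit_logistic(
    table: pd.DataFrame,
    features: list[str],
    outcome,
    positive_class: str = "CR",
) -> LogisticFit:
    """Logistic regression of class membership on the given features.

    ``outcome`` is the vector of class labels (or the name of the label
    column in ``table``).  Separation — diverging coefficients or zero
    residual deviance — is flagged, never silent; the coefficients of the
    last iteration are still reported with a warning.
    """
    if isinstance(outcome, str):
        outcome = table[outcome]
    labels = np.asarray(outcome)
    y = (labels == positive_class).astype(float)
    if len(np.unique(y)) < 2:
        raise InvalidInputError("need both outcome classes present")
    if not features:
        raise InvalidInputError("need at least one feature")
    data = table[features].to_numpy(dtype=float)
    x = np.column_stack([np.ones(len(y)), data])
    beta, cov, converged = _logit_mle(x, y)

    eta = np.clip(x @ beta, -500, 500)
    mu = 1.0 / (1.0 + np.exp(-eta))
    fitted_hard = np.all((mu > 0.999) == (y == 1)) and np.all((mu < 0.001) == (y == 0))
    separation = bool(np.max(np.abs(beta)) > 1e3 or (fitted_hard and not converged))
    if separation:
        warnings.warn("possible complete separation: coefficients are unstable")

    names = ["intercept"] + list(features)
    terms: dict[str, TermStats] = {}
    for i, name in enumerate(names):
        se = float(np.sqrt(cov[i, i])) if np.isfinite(cov[i, i]) else np.nan
        if se and np.isfinite(se) and se > 0:
            rep = wald_or_ci(beta[i], se)
        else:
            with np.errstate(over="ignore"):
                rep = {
                    "wald": np.nan, "p_value": np.nan,
                    "odds_ratio": float(np.exp(beta[i])),
                    "ci_low": np.nan, "ci_high": np.nan,
                }
        terms[name] = TermStats(
            coef=float(beta[i]),
            std_error=se,
            wald=float(rep["wald"]),
            p_value=float(rep["p_value"]),
            odds_ratio=float(rep["odds_ratio"]),
            ci95=(float(rep["ci_low"]), float(rep["ci_high"])),
        )
    return LogisticFit(
        features=list(features), terms=terms, converged=converged, separation=separation
    )


def predict_prob(fit, x) -> np.ndarray | float:
    """Logistic response probability for a fitted or preset model.

    ``fit`` is a :class:`LogisticFit` or a mapping of coefficients
    containing an ``intercept`` entry (e.g. :data:`EQ4_MODEL_POST`);
    ``x`` is a mapping or DataFrame supplying every model feature.
    """
    coefs = fit.coefficients if isinstance(fit, LogisticFit) else dict(fit)
    if "intercept" not in coefs:
        raise InvalidInputError("model must include an intercept term")
    lp = np.asarray(coefs["intercept"], dtype=float)
    for name, c in coefs.items():
        if name == "intercept":
            continue
        if isinstance(x, pd.DataFrame):
            if name not in x.columns:
                raise InvalidInputError(f"missing feature {name!r}")
            vals = x[name].to_numpy(dtype=float)
        else:
            if name not in x:
                raise InvalidInputError(f"missing feature {name!r}")
            vals = np.asarray(x[name], dtype=float)
        lp = lp + c * vals
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-lp))


def _structural_components(scores: np.ndarray, y: np.ndarray):
    """DeLong structural components V10 (per positive) and V01 (per negative)."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    # psi(X, Y) = 1 if X > Y, 0.5 if tie, 0 otherwise
    psi = (pos[:, None] > neg[None, :]) + 0.5 * (pos[:, None] == neg[None, :])
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    return v10, v01


def roc_analysis(
    scores,
    labels,
    positive_class: str = "CR",
    direction: str = "auto",
) -> RocResult:
    """ROC with rank-based AUC, Youden cutoff and DeLong 95% CI.

    ``direction`` ">" means higher scores indicate the positive class, "<"
    the opposite; "auto" picks whichever gives AUC >= 0.5 (the convention
    of common ROC packages).  Ties in Youden's J are broken toward higher
    sensitivity.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    y = (labels == positive_class).astype(int)
    n1, n0 = int(y.sum()), int((1 - y).sum())
    if n1 == 0 or n0 == 0:
        raise InvalidInputError("both classes must be present")

    def rank_auc(s: np.ndarray) -> float:
        ranks = sps.rankdata(s)
        u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
        return u / (n1 * n0)

    auc_gt = rank_auc(scores)
    if direction == "auto":
        direction = ">" if auc_gt >= 0.5 else "<"
    oriented = scores if direction == ">" else -scores
    auc = rank_auc(oriented)

    v10, v01 = _structural_components(oriented, y)
    var = (np.var(v10, ddof=1) / n1 if n1 > 1 else 0.0) + (
        np.var(v01, ddof=1) / n0 if n0 > 1 else 0.0
    )
    half = 1.96 * np.sqrt(max(var, 0.0))
    ci = (max(0.0, auc - half), min(1.0, auc + half))

    # Youden-optimal cutoff over midpoints between consecutive unique scores
    uniq = np.unique(oriented)
    thresholds = np.concatenate(
        [[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]]
    )
    best = None
    for thr in thresholds:
        sens = float((oriented[y == 1] >= thr).mean())
        spec = float((oriented[y == 0] < thr).mean())
        j = sens + spec - 1.0
        # strict improvement, or equal J with higher sensitivity
        if best is None or j > best[0] + 1e-12 or (
            abs(j - best[0]) <= 1e-12 and sens > best[1]
        ):
            best = (j, sens, spec, thr)
    _, sens, spec, thr = best
    cutoff = thr if direction == ">" else -thr
    return RocResult(
        auc=float(auc), ci95=ci, cutoff=float(cutoff),
        sensitivity=sens, specificity=spec, direction=direction,
    )


def delong_test(scores_a, scores_b, labels, positive_class: str = "CR") -> float:
    """Two-sided DeLong test for two paired ROC AUCs on the same subjects."""
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels)
    if scores_a.shape != scores_b.shape or scores_a.shape != labels.shape:
        raise InvalidInputError("paired scores and labels must have equal length")
    y = (labels == positive_class).astype(int)
    n1, n0 = int(y.sum()), int((1 - y).sum())
    if n1 == 0 or n0 == 0:
        raise InvalidInputError("both classes must be present")
    v10a, v01a = _structural_components(scores_a, y)
    v10b, v01b = _structural_components(scores_b, y)
    auc_a, auc_b = v10a.mean(), v10b.mean()
    var = (
        (np.var(v10a - v10b, ddof=1) / n1 if n1 > 1 else 0.0)
        + (np.var(v01a - v01b, ddof=1) / n0 if n0 > 1 else 0.0)
    )
    if var <= 0:
        if not np.allclose(auc_a, auc_b):
            warnings.warn("degenerate DeLong variance with unequal AUCs")
        return 1.0
    z = (auc_a - auc_b) / np.sqrt(var)
    return float(2.0 * sps.norm.sf(abs(z)))


def run_full_analysis(
    table: pd.DataFrame,
    alpha: float = 0.05,
    rho_threshold: float = 0.6,
    positive_class: str = "CR",
) -> dict:
    """The full statistics chain on a wide pre/post/change feature table.

    Runs the group test on every feature column, filters the significant
    ones for rank-correlation redundancy, fits the combined logistic model
    on the retained set, computes per-feature and model ROC results, and
    compares the post / change / change-plus-post model variants with the
    DeLong test.  Deterministic for a fixed input table.
    """
    feature_cols = [c for c in table.columns if c not in ("patient_id", "group")]
    labels = table["group"].to_numpy()
    classes = np.unique(labels)
    if len(classes) != 2:
        raise InvalidInputError("table must contain exactly two groups")
    other = [c for c in classes if c != positive_class][0]

    group_tests: dict[str, GroupTestResult] = {}
    for col in feature_cols:
        sub = table[[col, "group"]].dropna()
        if sub[col].nunique() <= 1 or sub["group"].nunique() < 2:
            continue
        res = mann_whitney(
            sub.loc[sub["group"] == positive_class, col],
            sub.loc[sub["group"] == other, col],
        )
        res.feature = col
        group_tests[col] = res

    pvals = {c: r.p_value for c, r in group_tests.items()}
    candidates = [c for c, p in pvals.items() if p < alpha]
    retained = spearman_filter(table, candidates, pvals, rho_threshold)

    roc_single = {
        c: roc_analysis(table[c], labels, positive_class, direction="auto")
        for c in candidates
    }

    def _variant(cands: list[str]):
        if not cands:
            return None, None, None
        kept = spearman_filter(table, cands, pvals, rho_threshold)
        fit = fit_logistic(table, kept, labels, positive_class)
        probs = predict_prob(fit, table)
        roc = roc_analysis(probs, labels, positive_class, direction=">")
        return fit, probs, roc

    variants = {}
    probs_by_model = {}
    for name, cands in (
        ("model_post", [c for c in candidates if c.endswith("_post")]),
        ("model_change", [c for c in candidates if c.endswith("_change")]),
        ("model_change_post",
         [c for c in candidates if c.endswith("_post") or c.endswith("_change")]),
    ):
        fit, probs, roc = _variant(cands)
        if fit is not None:
            variants[name] = {"fit": fit, "roc": roc}
            probs_by_model[name] = probs

    delong = {}
    names = list(probs_by_model)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            delong[f"{a}_vs_{b}"] = delong_test(
                probs_by_model[a], probs_by_model[b], labels, positive_class
            )

    combined_fit, _, combined_roc = _variant(retained) if retained else (None, None, None)

    return {
        "group_tests": group_tests,
        "candidates": candidates,
        "retained": retained,
        "combined_fit": combined_fit,
        "combined_roc": combined_roc,
        "roc_single": roc_single,
        "variants": variants,
        "delong": delong,
    }


def report_to_tables(report: dict, table: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Flatten a :func:`run_full_analysis` report into printable tables.

    Returns group-comparison, ROC and logistic-term tables shaped like the
    summary tables of a clinical biomarker paper.
    """
    rows = []
    for feat, res in report["group_tests"].items():
        for grp in sorted(table["group"].unique()):
            vals = table.loc[table["group"] == grp, feat].dropna()
            rows.append(
                {"feature": feat, "group": grp, "mean": vals.mean(),
                 "sd": vals.std(ddof=1), "p_value": res.p_value}
            )
    comparison = pd.DataFrame(rows)

    roc_rows = [
        {"feature": f, "auc": r.auc, "ci_low": r.ci95[0], "ci_high": r.ci95[1],
         "cutoff": r.cutoff, "sensitivity_pct": 100 * r.sensitivity,
         "specificity_pct": 100 * r.specificity}
        for f, r in report["roc_single"].items()
    ]
    if report.get("combined_roc") is not None:
        r = report["combined_roc"]
        roc_rows.append(
            {"feature": "combined_model", "auc": r.auc, "ci_low": r.ci95[0],
             "ci_high": r.ci95[1], "cutoff": r.cutoff,
             "sensitivity_pct": 100 * r.sensitivity,
             "specificity_pct": 100 * r.specificity}
        )
    roc_table = pd.DataFrame(roc_rows)

    logit_rows = []
    fit = report.get("combined_fit")
    if fit is not None:
        for name, t in fit.terms.items():
            logit_rows.append(
                {"term": name, "coefficient": t.coef, "std_error": t.std_error,
                 "wald": t.wald, "p_value": t.p_value, "odds_ratio": t.odds_ratio,
                 "ci_low": t.ci95[0], "ci_high": t.ci95[1]}
            )
    logistic_table = pd.DataFrame(logit_rows)
    return {"comparison": comparison, "roc": roc_table, "logistic": logistic_table}
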