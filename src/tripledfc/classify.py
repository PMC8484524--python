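"""Binary logistic-regression diagnosis with backward elimination and ROC.

For each group contrast (HC vs SCD, HC vs aMCI, SCD vs aMCI), candidate
predictors (cluster extracts and cognitive composites) enter univariate
models; the multivariable model is pruned by likelihood-ratio backward
elimination at p < 0.05.  Discrimination is summarised by the in-sample ROC
curve, trapezoidal AUC, and the sensitivity/specificity at the operating
point maximising Youden's J.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit
from sklearn.metrics import roc_curve


@dataclass
class LogisticFit:
    predictors: list[str]
    params: np.ndarray          # intercept first
    log_likelihood: float
    converged: bool
    separation: bool


@dataclass
class ClassifierResult:
    contrast: tuple[str, str]
    predictors: list[str]
    coefficients: dict[str, float]
    auc: float
    sensitivity: float
    specificity: float
    threshold: float
    roc_points: pd.DataFrame = field(repr=False, default=None)

    def __post_init__(self) -> None:
        assert 0.0 <= self.auc <= 1.0
        assert 0.0 <= self.sensitivity <= 1.0 and 0.0 <= self.specificity <= 1.0


def fit_logistic(X: np.ndarray | pd.DataFrame, y: np.ndarray,
                 predictors: list[str] | None = None) -> LogisticFit:
    """Maximum-likelihood logistic fit with intercept.

    Complete separation is detected (near-zero deviance or exploding
    coefficients) and reported via the ``separation`` flag rather than
    raising.
    """
    if isinstance(X, pd.DataFrame):
        predictors = predictors or list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        predictors = predictors or [f"x{i}" for i in range(X.shape[1])]
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    design = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, design).fit(disp=0, maxiter=200)
            converged = bool(res.mle_retvals.get("converged", False))
            params, llf = np.asarray(res.params), float(res.llf)
        except Exception:  # perfect separation raised by statsmodels
            params = _ridge_logistic(design, y)
            llf = _log_likelihood(design, y, params)
            converged = True
    # complete separation: every case is predicted (almost) perfectly
    p_hat = expit(design @ params)
    separation = bool(np.all(np.abs(p_hat - y) < 0.025) or
                      np.abs(params).max() > 50.0)
    return LogisticFit(predictors, params, llf, converged, separation)


def _log_likelihood(design: np.ndarray, y: np.ndarray, params: np.ndarray) -> float:
    eta = design @ params
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _ridge_logistic(design: np.ndarray, y: np.ndarray, lam: float = 1e-4,
                    n_iter: int = 100) -> np.ndarray:
    """Weakly penalised Newton (IRLS) fit; stabilises separated data."""
    beta = np.zeros(design.shape[1])
    pen = lam * np.eye(design.shape[1])
    pen[0, 0] = 0.0  # never penalise the intercept
    for _ in range(n_iter):
        p = expit(design @ beta)
        w = np.clip(p * (1 - p), 1e-10, None)
        grad = design.T @ (y - p) - pen @ beta
        hess = (design * w[:, None]).T @ design + pen
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.abs(step).max() < 1e-8:
            break
    return beta


def predict_proba(fit: LogisticFit, X: np.ndarray | pd.DataFrame) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        X = X[fit.predictors].to_numpy(dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    eta = fit.params[0] + X @ fit.params[1:]
    return expit(eta)


def likelihood_ratio_test(ll_full: float, ll_reduced: float, df: int = 1
                          ) -> tuple[float, float]:
    """LR statistic 2*(ll_full - ll_reduced) and its chi-squared p-value."""
    lr = max(0.0, 2.0 * (ll_full - ll_reduced))
    return lr, float(stats.chi2.sf(lr, df))


def backward_eliminate(X: pd.DataFrame, y: np.ndarray,
                       alpha: float = 0.05) -> LogisticFit:
    """Likelihood-ratio backward elimination.

    Iteratively drops the predictor whose removal has the largest LR
    p-value while that p >= ``alpha``; ties break to the earliest predictor
    in column order.  May return an intercept-only model.
    """
    if X.shape[1] < 1:
        raise ValueError("need at least one candidate predictor")
    y = np.asarray(y, dtype=float)
    kept = list(X.columns)
    while kept:
        full = fit_logistic(X[kept], y)
        pvals = []
        for name in kept:
            reduced_cols = [c for c in kept if c != name]
            if reduced_cols:
                red = fit_logistic(X[reduced_cols], y)
                ll_red = red.log_likelihood
            else:
                p1 = y.mean()
                ll_red = float(np.sum(y * np.log(p1) + (1 - y) * np.log(1 - p1)))
            _, p = likelihood_ratio_test(full.log_likelihood, ll_red)
            pvals.append(p)
        worst = int(np.argmax(pvals))
        if pvals[worst] >= alpha:
            kept.pop(worst)
        else:
            break
    if kept:
        return fit_logistic(X[kept], y)
    p1 = float(np.clip(y.mean(), 1e-12, 1 - 1e-12))
    ll = float(np.sum(y * np.log(p1) + (1 - y) * np.log(1 - p1)))
    return LogisticFit([], np.array([np.log(p1 / (1 - p1))]), ll, True, False)


def roc_summary(scores: np.ndarray, y: np.ndarray,
                contrast: tuple[str, str] = ("neg", "pos"),
                predictors: list[str] | None = None,
                coefficients: dict[str, float] | None = None
                ) -> ClassifierResult:
    """ROC curve, trapezoidal AUC and the Youden-optimal operating point.

    Ties on Youden's J break toward higher sensitivity.
    """
    y = np.asarray(y, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, thresholds = roc_curve(y, scores)
    auc = float(np.trapezoid(tpr, fpr))
    j = tpr - fpr
    best_j = j.max()
    cand = np.flatnonzero(np.isclose(j, best_j))
    best = cand[int(np.argmax(tpr[cand]))]
    return ClassifierResult(
        contrast=contrast,
        predictors=predictors or [],
        coefficients=coefficients or {},
        auc=auc,
        sensitivity=float(tpr[best]),
        specificity=float(1.0 - fpr[best]),
        threshold=float(thresholds[best]),
        roc_points=pd.DataFrame({"fpr": fpr, "tpr": tpr,
                                 "threshold": thresholds}),
    )


def cross_validated_scores(X: pd.DataFrame, y: np.ndarray,
                           n_splits: int = 5,
                           seed: int = 0) -> np.ndarray:
    """Out-of-fold predicted probabilities from stratified K-fold refits."""
    from sklearn.model_selection import StratifiedKFold

    scores = np.empty(len(y), dtype=float)
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    for train, test in skf.split(X, y):
        fit = fit_logistic(X.iloc[train], y[train])
        scores[test] = predict_proba(fit, X.iloc[test])
    return scores


def classify_contrast(features: pd.DataFrame, groups, pair: tuple[str, str],
                      alpha: float = 0.05, standardize: bool = True,
                      cross_validate: bool = False) -> dict:
    """Univariate + multivariable diagnosis of one group contrast.

    The second group of ``pair`` is coded 1.  Univariately significant
    predictors (LR p < alpha) are candidates for the multivariable backward
    elimination; if none reach significance, all predictors enter.
    Returns univariate results and the multivariable :class:`ClassifierResult`.

    Discrimination is apparent (in-sample) by default, matching how such
    clinical models are usually reported; ``cross_validate`` swaps in
    out-of-fold scores from stratified 5-fold refits of the selected model.
    """
    g = pd.Series(np.asarray(groups))
    sel = g.isin(pair).to_numpy()
    X = features.loc[sel].reset_index(drop=True).copy()
    y = (g[sel] == pair[1]).to_numpy(int)
    if standardize:
        X = (X - X.mean()) / X.std(ddof=0).replace(0.0, 1.0)
    ll_null = float(np.sum(y * np.log(np.clip(y.mean(), 1e-12, 1)) +
                           (1 - y) * np.log(np.clip(1 - y.mean(), 1e-12, 1))))
    univariate = {}
    candidates = []
    for col in X.columns:
        f = fit_logistic(X[[col]], y)
        _, p = likelihood_ratio_test(f.log_likelihood, ll_null)
        res = roc_summary(predict_proba(f, X[[col]]), y, pair, [col])
        univariate[col] = {"lr_p": p, "auc": res.auc, "separation": f.separation}
        if p < alpha:
            candidates.append(col)
    if not candidates:
        candidates = list(X.columns)
    final = backward_eliminate(X[candidates], y, alpha)
    if final.predictors:
        if cross_validate:
            scores = cross_validated_scores(X[final.predictors], y)
        else:
            scores = predict_proba(final, X[final.predictors])
    else:
        scores = np.full(len(y), y.mean())
    coefs = dict(zip(["intercept"] + final.predictors, final.params))
    multi = roc_summary(scores, y, pair, final.predictors, coefs)
    return {"univariate": univariate, "multivariable": multi, "fit": final}
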