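"""Plot-level carbon models: log-log power fits, the daisy chain, and the
percentile multiple regression.

All model families are fitted by ordinary least squares after natural-log
transformation of the power-law forms:

* power model        ACD = a * X**b          (X one of AvgH, LorH, BA, TCH)
* basal-area link    BA' = a + b * TCH       (untransformed OLS)
* daisy chain        ACD = a * BA'**b1 * TCH**b2
* percentile MLR     ln ACD = b0 + sum_j b_j * ln(metric_j) + eps,
                     reduced by backward elimination at alpha = 0.05.

Goodness of fit is reported as R^2 on the log scale (where fitting happens),
root-mean-square error of the back-transformed predictions in original
units, and k-fold cross-validated R^2 on pooled out-of-fold predictions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "PowerModelFit", "LinearFit", "DaisyChainFit", "MLRFit",
    "fit_power", "fit_ba_link", "fit_daisy_chain", "fit_percentile_mlr",
    "evaluate", "cross_validate", "predict_acd", "MLR_CANDIDATES",
]

MLR_CANDIDATES = ("h25", "h50", "h75", "h90", "h95",
                  "d25", "d50", "d75", "d90", "d95", "cc")


@dataclass(frozen=True)
class PowerModelFit:
    """y = a * x**b fitted as ln y = ln a + b ln x."""

    a: float
    b: float
    r2: float
    rmse_back: float
    n: int
    cv_r2: float | None = None
    r2_back: float | None = None

    def predict(self, x):
        return self.a * np.asarray(x, float) ** self.b


@dataclass(frozen=True)
class LinearFit:
    """y = intercept + slope * x, untransformed OLS."""

    intercept: float
    slope: float
    r2: float
    rmse: float
    n: int

    def predict(self, x):
        return self.intercept + self.slope * np.asarray(x, float)


@dataclass(frozen=True)
class DaisyChainFit:
    """Two-stage model: TCH -> BA' (linear), then ACD = a * BA'**b1 * TCH**b2."""

    link: LinearFit
    a: float
    b1: float
    b2: float
    r2: float
    rmse_back: float
    n: int
    cv_r2: float | None = None

    def predict(self, tch):
        tch = np.asarray(tch, float)
        ba_hat = self.link.predict(tch)
        if np.any(ba_hat <= 0):
            raise ValueError("linear BA link predicts non-positive basal area; "
                             "restrict predictions to the fitted TCH domain")
        return self.a * ba_hat ** self.b1 * tch ** self.b2


@dataclass(frozen=True)
class MLRFit:
    """Backward-eliminated log-log multiple regression on percentile metrics."""

    predictors: tuple[str, ...]
    intercept: float
    coefficients: dict[str, float]
    resid_sd: float
    r2: float
    rmse_back: float
    n: int
    cv_r2: float | None = None

    def predict(self, metrics: pd.DataFrame):
        lp = np.full(len(metrics), self.intercept)
        for name, beta in self.coefficients.items():
            x = metrics[name].to_numpy(float)
            if np.any(x <= 0):
                raise ValueError(f"predictor {name} must be positive for prediction")
            lp += beta * np.log(x)
        return np.exp(lp)


def _check_positive(name, v):
    v = np.asarray(v, float)
    bad = np.flatnonzero(~(v > 0) | ~np.isfinite(v))
    if bad.size:
        raise ValueError(f"{name} must be strictly positive and finite; "
                         f"offending indices {bad[:10].tolist()}")
    return v


def _log_r2(resid, ly):
    sst = np.sum((ly - ly.mean()) ** 2)
    if sst == 0:
        return 0.0
    return float(1.0 - np.sum(resid ** 2) / sst)


def fit_power(x, y, cv_folds: int | None = None, seed: int = 0,
              bias_correction: bool = False) -> PowerModelFit:
    """Fit y = a * x**b by OLS of ln y on ln x.

    R^2 is reported on the log scale; ``rmse_back`` is the RMSE of
    exp(fitted) against y in original units (no back-transformation bias
    correction unless ``bias_correction``, which applies Baskerville's
    exp(s^2/2) smearing factor).  ``cv_folds`` adds a cross-validated R^2.
    """
    x = _check_positive("x", x)
    y = _check_positive("y", y)
    if x.size != y.size or x.size < 3:
        raise ValueError("need matched x, y with n >= 3")
    lx, ly = np.log(x), np.log(y)
    if np.ptp(lx) == 0:
        # degenerate design: constant predictor
        a = float(np.exp(ly.mean()))
        return PowerModelFit(a=a, b=0.0, r2=0.0,
                             rmse_back=float(np.sqrt(np.mean((a - y) ** 2))),
                             n=int(x.size), r2_back=0.0)
    res = sm.OLS(ly, sm.add_constant(lx)).fit()
    smear = float(np.exp(res.mse_resid / 2.0)) if bias_correction else 1.0
    a = float(np.exp(res.params[0])) * smear
    b = float(res.params[1])
    yhat = a * x ** b
    fit = PowerModelFit(
        a=a, b=b, r2=float(res.rsquared),
        rmse_back=float(np.sqrt(np.mean((yhat - y) ** 2))),
        n=int(x.size),
        r2_back=_log_r2(y - yhat, y),
    )
    if cv_folds:
        cv = cross_validate(lambda xt, yt: fit_power(xt, yt,
                                                     bias_correction=bias_correction),
                            x, y, k=cv_folds, seed=seed)
        fit = PowerModelFit(**{**fit.__dict__, "cv_r2": cv})
    return fit


def fit_ba_link(tch, ba) -> LinearFit:
    """Untransformed OLS of plot basal area on TCH (the BA' link)."""
    tch = _check_positive("tch", tch)
    ba = _check_positive("ba", ba)
    if tch.size < 3:
        raise ValueError("need n >= 3 for the BA link")
    res = sm.OLS(ba, sm.add_constant(tch)).fit()
    resid = ba - res.fittedvalues
    return LinearFit(intercept=float(res.params[0]), slope=float(res.params[1]),
                     r2=float(res.rsquared),
                     rmse=float(np.sqrt(np.mean(resid ** 2))), n=int(tch.size))


def fit_daisy_chain(tch, ba, acd, cv_folds: int | None = None,
                    seed: int = 0) -> DaisyChainFit:
    """Two-stage fit: BA' = a + b*TCH, then ln ACD ~ ln BA' + ln TCH.

    The second stage regresses log carbon density on the *fitted* basal
    area, so the whole chain needs only TCH at prediction time.
    """
    tch = _check_positive("tch", tch)
    ba = _check_positive("ba", ba)
    acd = _check_positive("acd", acd)
    if tch.size < 4:
        raise ValueError("need n >= 4 to fit the two-predictor daisy chain")
    link = fit_ba_link(tch, ba)
    ba_hat = link.predict(tch)
    if np.any(ba_hat <= 0):
        raise ValueError("fitted BA' is non-positive for some plots; restrict "
                         "the TCH domain before daisy-chain fitting")
    X = sm.add_constant(np.column_stack([np.log(ba_hat), np.log(tch)]))
    ly = np.log(acd)
    res = sm.OLS(ly, X).fit()
    a = float(np.exp(res.params[0]))
    b1, b2 = float(res.params[1]), float(res.params[2])
    yhat = a * ba_hat ** b1 * tch ** b2
    fit = DaisyChainFit(link=link, a=a, b1=b1, b2=b2, r2=float(res.rsquared),
                        rmse_back=float(np.sqrt(np.mean((yhat - acd) ** 2))),
                        n=int(tch.size))
    if cv_folds:
        cv = _cv_daisy(tch, ba, acd, cv_folds, seed)
        fit = DaisyChainFit(**{**fit.__dict__, "cv_r2": cv})
    return fit


def _cv_daisy(tch, ba, acd, k, seed):
    folds = _fold_indices(len(tch), k, seed)
    pred = np.empty_like(acd)
    for test_idx in folds:
        train = np.setdiff1d(np.arange(len(tch)), test_idx)
        if train.size < 4:
            raise ValueError("fold leaves < 4 training points; use smaller k")
        f = fit_daisy_chain(tch[train], ba[train], acd[train])
        pred[test_idx] = f.predict(tch[test_idx])
    return _pooled_cv_r2(acd, pred)


def fit_percentile_mlr(metrics: pd.DataFrame, acd,
                       candidates=MLR_CANDIDATES, alpha: float = 0.05,
                       family_wise: bool = True,
                       cv_folds: int | None = None, seed: int = 0) -> MLRFit:
    """Backward-eliminated log-log multiple regression of ACD on LiDAR metrics.

    Starts from the full model in ln of every candidate metric and repeatedly
    drops the non-intercept coefficient with the largest p-value until every
    retained p-value clears the removal threshold, then refits on the
    survivors.  With ``family_wise`` (default) the threshold is the
    Bonferroni-corrected ``alpha / n_candidates``: because elimination keeps
    the *smallest* p-values to the end, a plain per-test ``alpha`` would
    falsely retain at least one irrelevant metric with probability
    ~``1 - (1-alpha)**n_candidates``, not ``alpha``.  Exactly duplicated
    predictor columns are dropped with a warning before selection.
    """
    acd = _check_positive("acd", acd)
    cols = list(candidates)
    for c in cols:
        _check_positive(c, metrics[c])
    if len(metrics) <= len(cols) + 1:
        raise ValueError("need more plots than candidate predictors")

    logx = {c: np.log(metrics[c].to_numpy(float)) for c in cols}
    # collinearity guard: keep one survivor of any identical column pair
    kept = []
    for c in cols:
        if any(np.allclose(logx[c], logx[o]) for o in kept):
            warnings.warn(f"dropping predictor {c}: duplicate of a retained column",
                          stacklevel=2)
            continue
        kept.append(c)
    cols = kept

    threshold = alpha / len(cols) if (family_wise and cols) else alpha
    ly = np.log(acd)
    while cols:
        X = sm.add_constant(np.column_stack([logx[c] for c in cols]))
        res = sm.OLS(ly, X).fit()
        pvals = res.pvalues[1:]
        worst = int(np.argmax(pvals))
        if pvals[worst] < threshold:
            break
        cols = cols[:worst] + cols[worst + 1:]
    if cols:
        X = sm.add_constant(np.column_stack([logx[c] for c in cols]))
        res = sm.OLS(ly, X).fit()
        intercept = float(res.params[0])
        coefs = {c: float(b) for c, b in zip(cols, res.params[1:])}
        r2 = float(res.rsquared)
        resid_sd = float(np.sqrt(res.mse_resid))
        lp = res.fittedvalues
    else:
        intercept = float(ly.mean())
        coefs = {}
        r2 = 0.0
        resid_sd = float(ly.std(ddof=1)) if len(ly) > 1 else 0.0
        lp = np.full_like(ly, intercept)
    yhat = np.exp(lp)
    fit = MLRFit(predictors=tuple(cols), intercept=intercept,
                 coefficients=coefs, resid_sd=resid_sd, r2=r2,
                 rmse_back=float(np.sqrt(np.mean((yhat - acd) ** 2))),
                 n=int(len(acd)))
    if cv_folds:
        cv = _cv_mlr(metrics, acd, candidates, alpha, cv_folds, seed)
        fit = MLRFit(**{**fit.__dict__, "cv_r2": cv})
    return fit


def _cv_mlr(metrics, acd, candidates, alpha, k, seed):
    folds = _fold_indices(len(acd), k, seed)
    pred = np.empty_like(acd)
    idx_all = np.arange(len(acd))
    for test_idx in folds:
        train = np.setdiff1d(idx_all, test_idx)
        f = fit_percentile_mlr(metrics.iloc[train], acd[train],
                               candidates=candidates, alpha=alpha)
        pred[test_idx] = f.predict(metrics.iloc[test_idx])
    return _pooled_cv_r2(acd, pred)


def evaluate(fit, x, y) -> dict[str, float]:
    """Out-of-sample goodness of fit: R^2 and back-transformed RMSE."""
    y = np.asarray(y, float)
    yhat = np.asarray(fit.predict(x), float)
    return {"r2": _pooled_cv_r2(y, yhat),
            "rmse_back": float(np.sqrt(np.mean((yhat - y) ** 2)))}


def _fold_indices(n, k, seed):
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError("need n >= k for k-fold cross-validation")
    order = np.random.default_rng(seed).permutation(n)
    return np.array_split(order, k)


def _pooled_cv_r2(y, pred):
    sst = np.sum((y - y.mean()) ** 2)
    if sst == 0:
        return 0.0
    return float(1.0 - np.sum((y - pred) ** 2) / sst)


def cross_validate(fit_fn, x, y, k: int = 10, seed: int = 0) -> float:
    """k-fold cross-validated R^2 on pooled out-of-fold predictions.

    Folds come from a seeded shuffle; ``k = n`` gives the jackknife
    (leave-one-out).  ``fit_fn(x_train, y_train)`` must return an object
    with ``predict``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    folds = _fold_indices(len(y), k, seed)
    pred = np.empty_like(y)
    idx_all = np.arange(len(y))
    for test_idx in folds:
        train = np.setdiff1d(idx_all, test_idx)
        if train.size < 3:
            raise ValueError("fold leaves < 3 training points; use smaller k")
        f = fit_fn(x[train], y[train])
        pred[test_idx] = f.predict(x[test_idx])
    return _pooled_cv_r2(y, pred)


def predict_acd(fit, predictors):
    """Vectorized carbon-density prediction for any fitted model."""
    return fit.predict(predictors)
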