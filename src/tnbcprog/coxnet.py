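"""Elastic-net Cox proportional-hazards modelling with bootstrap OOB tuning.

The prognostic workflow fits Cox models penalized by a mix of lasso (L1) and
ridge (L2) terms,

    minimize  -(1/n) * ll(beta)  +  lambda * [ alpha * ||beta||_1
                                               + (1 - alpha)/2 * ||beta||_2^2 ],

where ``ll`` is the Breslow partial log-likelihood and the problem is solved
on internally standardized features (mean 0, population-variance 1).  The
regularization pair (alpha, lambda) is chosen by drawing bootstrap resamples
of the training cohort, fitting every grid point on each in-bag set, scoring
it by Cox deviance on the out-of-bag subjects, and taking the pair with the
lowest average out-of-bag deviance.  A final model is then fit to the full
training set at the chosen pair.

Single-feature inputs (e.g. a clinical-stage-only model) bypass the penalty
entirely and are fit by unpenalized Newton-Raphson.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._cd import cd_solve
from ._rng import substream
from ._survival import (
    CoxData,
    breslow_loglik,
    breslow_saturated_loglik,
    newton_cox,
)

__all__ = [
    "TuningGrid",
    "CoxnetFit",
    "FittedCoxnetModel",
    "ConvergenceError",
    "cox_partial_loglik",
    "cox_deviance",
    "fit_coxnet",
    "kkt_max_violation",
    "bootstrap_oob_tune",
    "train_prognostic_model",
    "risk_score",
]


class ConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class TuningGrid:
    """Regularization grid searched by the bootstrap tuner.

    Defaults: nine mixing values alpha = 0.1 ... 0.9 (step 0.1) and twenty
    penalty strengths lambda log-spaced from 1e2 down to 1e-2.
    """

    alphas: tuple = tuple(np.round(np.arange(0.1, 1.0, 0.1), 10))
    lambdas: tuple = tuple(np.logspace(2, -2, 20))

    def __post_init__(self):
        if len(self.alphas) == 0 or len(self.lambdas) == 0:
            raise ValueError("tuning grid must be non-empty")
        if any(a <= 0 or a > 1 for a in self.alphas):
            raise ValueError("alphas must lie in (0, 1]")
        if any(l <= 0 for l in self.lambdas):
            raise ValueError("lambdas must be positive")

    @property
    def points(self) -> list[tuple[float, float]]:
        return [(a, l) for a in self.alphas for l in self.lambdas]


def cox_partial_loglik(beta, X, time, event) -> float:
    """Breslow partial log-likelihood of ``beta`` on the given data.

    At ``beta = 0`` with distinct event times this is
    ``-sum over events of log(risk-set size)``.
    """
    event = np.asarray(event)
    if event.sum() == 0:
        warnings.warn("no events: partial log-likelihood is identically 0")
        return 0.0
    return breslow_loglik(beta, X, time, event)


def cox_deviance(beta, X, time, event, *, per_event: bool = False) -> float:
    """Cox deviance ``2 * (ll_saturated - ll(beta))``.

    With no tied event times the saturated term vanishes and the deviance is
    ``-2 * ll(beta)``.  ``per_event=True`` divides by the number of events.
    """
    event = np.asarray(event)
    d = event.sum()
    if d == 0:
        return 0.0
    dev = 2.0 * (breslow_saturated_loglik(time, event) - cox_partial_loglik(beta, X, time, event))
    return float(dev / d) if per_event else float(dev)


@dataclass
class CoxnetFit:
    """A single penalized fit: coefficients on both scales plus diagnostics."""

    alpha: float
    lam: float
    beta: np.ndarray  # original feature scale
    beta_std: np.ndarray  # standardized scale (the optimization variable)
    mean: np.ndarray
    sd: np.ndarray
    n_iter: int


def _standardize(X: np.ndarray):
    mu = X.mean(axis=0)
    sd = X.std(axis=0)  # population (1/n) standard deviation
    if np.any(sd == 0):
        raise ValueError("zero-variance feature passed to fit_coxnet; remove it first")
    return (X - mu) / sd, mu, sd


def _irls_fit(Xs, cox: CoxData, alpha, lam, beta0, tol, max_outer, inner_sweeps=1000):
    """Proximal-Newton outer loop: quadratic (diagonal-Hessian) working
    model solved by coordinate descent, with backtracking on the true
    penalized objective so weakly penalized, high-dimensional fits cannot
    oscillate."""
    n, p = Xs.shape
    beta = beta0.copy()
    eta = Xs @ beta

    def objective(b, e):
        pen = lam * (alpha * np.abs(b).sum() + 0.5 * (1 - alpha) * (b**2).sum())
        return -cox.loglik(e) / n + pen

    f = objective(beta, eta)
    stalled = 0
    for it in range(1, max_outer + 1):
        g, h = cox.eta_grad_diag_hess(eta)
        h = np.maximum(h, 1e-9)
        w = h / n
        z = eta + g / h
        prop = beta.copy()
        eta_prop = eta.copy()
        cd_solve(Xs, w, z, prop, eta_prop, lam * alpha, lam * (1.0 - alpha), 0.1 * tol,
                 inner_sweeps)
        delta = prop - beta
        step = 1.0
        while step > 1e-10:
            cand = beta + step * delta
            eta_c = Xs @ cand
            f_c = objective(cand, eta_c)
            if np.isfinite(f_c) and f_c <= f + 1e-12:
                break
            step *= 0.5
        else:
            # no descent possible: numerically stationary
            return beta, it
        moved = np.max(np.abs(cand - beta))
        decrease = f - f_c
        beta, eta, f = cand, eta_c, f_c
        if moved < tol:
            return beta, it
        # near-flat objective: remaining drift is numerically meaningless
        stalled = stalled + 1 if decrease < 1e-13 * max(1.0, abs(f)) else 0
        if stalled >= 2:
            return beta, it
    raise ConvergenceError(
        f"elastic-net Cox did not converge in {max_outer} IRLS iterations "
        f"(alpha={alpha}, lambda={lam}, p={p}, last step={moved:.3g})"
    )


def fit_coxnet(
    X,
    time,
    event,
    alpha: float,
    lam: float,
    *,
    tol: float = 1e-7,
    max_outer: int = 1000,
) -> CoxnetFit:
    """Fit one elastic-net Cox model at a fixed (alpha, lambda).

    Features are standardized internally; coefficients are returned on both
    the standardized and the original scale.  Convergence is declared when
    the largest coefficient change across an outer reweighting iteration
    falls below ``tol``.
    """
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must lie in (0, 1]")
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    Xs, mu, sd = _standardize(X)
    cox = CoxData(time, event)
    if cox.n_events == 0:
        raise ValueError("no events in the training data")
    beta_std, n_iter = _irls_fit(Xs, cox, alpha, lam, np.zeros(X.shape[1]), tol, max_outer)
    return CoxnetFit(
        alpha=alpha, lam=lam, beta=beta_std / sd, beta_std=beta_std, mean=mu, sd=sd, n_iter=n_iter
    )


def kkt_max_violation(fit: CoxnetFit, X, time, event) -> float:
    """Largest violation of the elastic-net stationarity conditions.

    On the standardized scale the subgradient conditions require
    ``(1/n) dll/dbeta_j = lambda*(1-alpha)*beta_j + lambda*alpha*s_j`` with
    ``s_j = sign(beta_j)`` for active features and ``|s_j| <= 1`` otherwise.
    """
    X = np.asarray(X, dtype=float)
    Xs = (X - fit.mean) / fit.sd
    n = Xs.shape[0]
    cox = CoxData(time, event)
    g, _ = cox.eta_grad_diag_hess(Xs @ fit.beta_std)
    grad = Xs.T @ g / n  # (1/n) dll/dbeta on standardized scale
    lam, alpha = fit.lam, fit.alpha
    active = fit.beta_std != 0
    viol_inactive = np.maximum(np.abs(grad[~active]) - lam * alpha, 0.0)
    resid = grad[active] - lam * (1 - alpha) * fit.beta_std[active] - lam * alpha * np.sign(
        fit.beta_std[active]
    )
    pieces = [viol_inactive, np.abs(resid)]
    return float(max((p.max() for p in pieces if p.size), default=0.0))


def _fit_path(Xs, cox: CoxData, alpha, lambdas_desc, tol, max_outer):
    """Warm-started fits along a descending lambda path (standardized X)."""
    p = Xs.shape[1]
    beta = np.zeros(p)
    out = []
    for lam in lambdas_desc:
        beta, _ = _irls_fit(Xs, cox, alpha, lam, beta, tol, max_outer)
        out.append(beta.copy())
    return out


def _grid_label(alpha: float, lam: float) -> str:
    return f"a{alpha:g}_l{lam:.6g}"


@dataclass
class TuningResult:
    alpha: float
    lam: float
    deviance_table: pd.DataFrame  # resample x grid point
    mean_deviance: pd.Series
    n_redraws: int


def bootstrap_oob_tune(
    X,
    time,
    event,
    grid: TuningGrid | None = None,
    B: int = 100,
    seed: int = 0,
    *,
    per_event: bool = False,
    tol: float = 1e-3,
    max_redraws: int = 1000,
) -> TuningResult:
    """Choose (alpha, lambda) by average out-of-bag Cox deviance.

    Each of ``B`` resamples draws n subjects with replacement; every grid
    point is fit on the in-bag subjects (warm-started along each alpha's
    descending lambda path) and scored by Breslow deviance on the out-of-bag
    subjects.  Resamples whose in-bag or out-of-bag set carries no events are
    redrawn.  Ties in the mean deviance break toward the largest lambda, then
    the largest alpha (the most parsimonious model).

    Tuning fits use a relaxed coefficient tolerance (default 1e-3): the OOB
    deviance surface is flat far below that resolution, and only the final
    full-data fit needs the tight default.
    """
    grid = grid or TuningGrid()
    X = np.asarray(X, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    n = X.shape[0]
    if event.sum() < 2:
        raise ValueError("need at least two events to tune by resampling")
    lambdas_desc = np.sort(np.asarray(grid.lambdas, dtype=float))[::-1]
    labels = [_grid_label(a, l) for a in grid.alphas for l in lambdas_desc]
    dev = np.empty((B, len(labels)))
    total_redraws = 0
    for b in range(B):
        rng = substream(seed, "bootstrap", b)
        while True:
            idx = rng.integers(0, n, size=n)
            oob = np.setdiff1d(np.arange(n), idx)
            if oob.size and event[idx].sum() > 0 and event[oob].sum() > 0:
                break
            total_redraws += 1
            if total_redraws > max_redraws:
                raise RuntimeError(
                    f"exceeded {max_redraws} bootstrap redraws; data too degenerate to tune"
                )
        Xb = X[idx]
        sd = Xb.std(axis=0)
        keep = sd > 0  # in-bag constant columns carry no information
        Xs = (Xb[:, keep] - Xb[:, keep].mean(axis=0)) / sd[keep]
        cox_ib = CoxData(time[idx], event[idx])
        X_oob, t_oob, e_oob = X[oob], time[oob], event[oob]
        col = 0
        for a in grid.alphas:
            betas_std = _fit_path(Xs, cox_ib, a, lambdas_desc, tol, max_outer=1000)
            for beta_std in betas_std:
                beta = np.zeros(X.shape[1])
                beta[keep] = beta_std / sd[keep]
                dev[b, col] = cox_deviance(beta, X_oob, t_oob, e_oob, per_event=per_event)
                col += 1
    table = pd.DataFrame(dev, columns=labels)
    table.index.name = "resample"
    mean_dev = table.mean(axis=0)
    # argmin of mean deviance; ties break to largest lambda, then largest alpha
    candidates = [
        (mean_dev[_grid_label(a, lam)], -lam, -a, a, lam)
        for a in grid.alphas
        for lam in lambdas_desc
    ]
    _, _, _, a_star, l_star = min(candidates)
    if total_redraws:
        warnings.warn(f"{total_redraws} degenerate bootstrap resamples redrawn")
    return TuningResult(
        alpha=a_star,
        lam=l_star,
        deviance_table=table,
        mean_deviance=mean_dev,
        n_redraws=total_redraws,
    )


@dataclass
class FittedCoxnetModel:
    """The final prognostic model for one feature-category combination.

    ``coef`` holds original-scale coefficients; ``scaled_coef`` the
    coefficients multiplied by each feature's (population) standard
    deviation, i.e. the standardized-scale values used to compare the
    relative contribution of selected features.  An all-zero coefficient
    vector ("empty selection") is a valid, flagged state.
    """

    alpha: float | None
    lam: float | None
    coef: pd.Series
    scaled_coef: pd.Series
    feature_mean: pd.Series
    feature_sd: pd.Series
    categories: tuple
    seed: int | None
    training_cohort: str | None = None
    tuning: TuningResult | None = field(default=None, repr=False)
    penalized: bool = True
    n_features_input: int = 0
    n_features_after_filter: int = 0

    @property
    def selected_features(self) -> list[str]:
        return list(self.coef.index[self.coef != 0])

    @property
    def is_empty(self) -> bool:
        return len(self.selected_features) == 0

    def to_json(self, path) -> None:
        payload = {
            "alpha": self.alpha,
            "lambda": self.lam,
            "penalized": self.penalized,
            "categories": list(self.categories),
            "seed": self.seed,
            "training_cohort": self.training_cohort,
            "features": list(self.coef.index),
            "coef": self.coef.tolist(),
            "scaled_coef": self.scaled_coef.tolist(),
            "feature_mean": self.feature_mean.tolist(),
            "feature_sd": self.feature_sd.tolist(),
            "n_features_input": self.n_features_input,
            "n_features_after_filter": self.n_features_after_filter,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "FittedCoxnetModel":
        with open(path) as fh:
            d = json.load(fh)
        idx = pd.Index(d["features"])
        return cls(
            alpha=d["alpha"],
            lam=d["lambda"],
            coef=pd.Series(d["coef"], index=idx),
            scaled_coef=pd.Series(d["scaled_coef"], index=idx),
            feature_mean=pd.Series(d["feature_mean"], index=idx),
            feature_sd=pd.Series(d["feature_sd"], index=idx),
            categories=tuple(d["categories"]),
            seed=d["seed"],
            training_cohort=d["training_cohort"],
            penalized=d["penalized"],
            n_features_input=d["n_features_input"],
            n_features_after_filter=d["n_features_after_filter"],
        )


def train_prognostic_model(
    features,
    time,
    event,
    categories,
    *,
    grid: TuningGrid | None = None,
    B: int = 100,
    seed: int = 0,
    sparse_threshold: float = 0.05,
    per_event: bool = False,
    training_cohort: str | None = None,
) -> FittedCoxnetModel:
    """Run the full training workflow for one category combination.

    Pipeline: subset columns by feature category -> drop sparse features
    (non-zero in <= ``sparse_threshold`` of training samples) -> keep one of
    any perfectly correlated group -> bootstrap OOB tuning -> final elastic
    net fit on all training samples.  A single remaining feature is fit by
    an unpenalized Cox model instead (no regularization is meaningful for
    one predictor representing the clinical standard).
    """
    from .features import FeatureMatrix, dedup_perfect_correlation, filter_sparse

    if isinstance(features, FeatureMatrix):
        mat = features.select_categories(categories)
    else:
        mat = features
        if not isinstance(mat, pd.DataFrame):
            raise TypeError("features must be a FeatureMatrix or DataFrame")
    if mat.shape[1] == 0:
        raise ValueError("no features in the requested categories")
    n_input = mat.shape[1]
    mat = filter_sparse(mat, threshold=sparse_threshold)
    mat = dedup_perfect_correlation(mat)
    n_kept = mat.shape[1]
    X = mat.to_numpy(dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    idx = mat.columns

    if n_kept == 1:
        res = newton_cox(X, time, event)
        coef = pd.Series(res.beta, index=idx)
        model = FittedCoxnetModel(
            alpha=None,
            lam=None,
            coef=coef,
            scaled_coef=coef * sd,
            feature_mean=pd.Series(mu, index=idx),
            feature_sd=pd.Series(sd, index=idx),
            categories=tuple(categories),
            seed=seed,
            training_cohort=training_cohort,
            penalized=False,
            n_features_input=n_input,
            n_features_after_filter=n_kept,
        )
        return model

    tuning = bootstrap_oob_tune(
        X, time, event, grid=grid, B=B, seed=seed, per_event=per_event
    )
    fit = fit_coxnet(X, time, event, tuning.alpha, tuning.lam)
    coef = pd.Series(fit.beta, index=idx)
    model = FittedCoxnetModel(
        alpha=tuning.alpha,
        lam=tuning.lam,
        coef=coef,
        scaled_coef=pd.Series(fit.beta_std, index=idx),
        feature_mean=pd.Series(fit.mean, index=idx),
        feature_sd=pd.Series(fit.sd, index=idx),
        categories=tuple(categories),
        seed=seed,
        training_cohort=training_cohort,
        tuning=tuning,
        penalized=True,
        n_features_input=n_input,
        n_features_after_filter=n_kept,
    )
    if model.is_empty:
        warnings.warn(
            "elastic net selected no features; the model is valid but degenerate"
        )
    return model


def risk_score(model: FittedCoxnetModel, X: pd.DataFrame) -> pd.Series:
    """Linear-predictor risk score ``X . beta`` on the original feature scale.

    An empty model yields all-zero scores (flagged by ``model.is_empty``).
    """
    sel = model.selected_features
    missing = [f for f in sel if f not in X.columns]
    if missing:
        raise KeyError(f"feature columns missing from X: {missing[:5]}")
    if not sel:
        return pd.Series(0.0, index=X.index, name="risk_score")
    score = X[sel].to_numpy(dtype=float) @ model.coef[sel].to_numpy()
    return pd.Series(score, index=X.index, name="risk_score")
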