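"""Breslow partial-likelihood machinery for right-censored survival data.

Everything survival-related in the package — the univariate Cox fits, the
stratified likelihood-ratio comparisons, and the penalized elastic-net model
— shares this one implementation of the Breslow partial likelihood, its
gradient and (full or diagonal) Hessian, so that deviances computed in
different stages are directly comparable.

Conventions
-----------
* Ties are handled by Breslow's approximation: all subjects with tied event
  times share one risk-set denominator.
* The saturated partial log-likelihood is ``-sum_k d_k log d_k`` over event
  times with multiplicity ``d_k`` (zero when event times are distinct), so
  the deviance ``2 (ll_sat - ll)`` reduces to ``-2 ll`` in the untied case.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CoxData",
    "breslow_loglik",
    "breslow_saturated_loglik",
    "eta_grad_diag_hess",
    "newton_cox",
    "NewtonCoxResult",
]


class CoxData:
    """Pre-sorted risk-set structure for one stratum.

    Groups subjects by unique time (ascending); reverse-cumulative sums over
    groups give risk-set totals at each event time in O(n log n) once, O(n)
    per evaluation.
    """

    def __init__(self, time: np.ndarray, event: np.ndarray):
        time = np.asarray(time, dtype=float)
        event = np.asarray(event)
        if time.ndim != 1 or time.shape != event.shape:
            raise ValueError("time and event must be 1-D and equal length")
        if np.any(~np.isfinite(time)) or np.any(time <= 0):
            raise ValueError("times must be finite and positive")
        ev = event.astype(float)
        if not np.all(np.isin(ev, (0.0, 1.0))):
            raise ValueError("event must be coded 0/1")
        self.n = time.size
        self.order = np.argsort(time, kind="stable")
        self.t = time[self.order]
        self.e = ev[self.order].astype(bool)
        # group index per sorted subject: consecutive runs of equal time
        new_grp = np.empty(self.n, dtype=bool)
        new_grp[0] = True
        new_grp[1:] = self.t[1:] != self.t[:-1]
        self.grp = np.cumsum(new_grp) - 1  # 0-based group id, ascending time
        self.n_groups = int(self.grp[-1]) + 1
        # events per group
        self.d = np.bincount(self.grp, weights=self.e, minlength=self.n_groups)
        self.n_events = int(self.e.sum())
        d_pos = self.d[self.d > 0]
        self.loglik_saturated = -float(np.sum(d_pos * np.log(d_pos)))

    def _group_rev_cumsum(self, x_sorted: np.ndarray) -> np.ndarray:
        """Sum of ``x`` over subjects in groups >= k, for each group k."""
        gsum = np.zeros((self.n_groups,) + x_sorted.shape[1:])
        np.add.at(gsum, self.grp, x_sorted)
        return np.cumsum(gsum[::-1], axis=0)[::-1]

    def loglik(self, eta: np.ndarray) -> float:
        eta_s = np.asarray(eta, dtype=float)[self.order]
        eta_s = eta_s - eta_s.max()  # invariant shift, guards overflow
        r = np.exp(eta_s)
        s0 = self._group_rev_cumsum(r)
        ev_grp = self.d > 0
        ll = float(eta_s[self.e].sum() - np.sum(self.d[ev_grp] * np.log(s0[ev_grp])))
        # undo the shift: sum_events eta was shifted by max; the log S0 term too
        # shift cancels exactly: each event contributes -shift in eta and each
        # d_k log S0_k term gains -d_k*shift; totals are equal, so ll is exact.
        return ll

    def eta_grad_diag_hess(self, eta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Gradient and diagonal Hessian of the log-likelihood w.r.t. eta.

        Returned in the original (unsorted) subject order.
        """
        eta_s = np.asarray(eta, dtype=float)[self.order]
        shift = eta_s.max()
        r = np.exp(eta_s - shift)
        s0 = self._group_rev_cumsum(r)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(self.d > 0, self.d / s0, 0.0)
            b = np.where(self.d > 0, self.d / s0**2, 0.0)
        A = np.cumsum(a)[self.grp]
        B = np.cumsum(b)[self.grp]
        g_s = self.e.astype(float) - r * A
        h_s = r * A - r**2 * B
        g = np.empty_like(g_s)
        h = np.empty_like(h_s)
        g[self.order] = g_s
        h[self.order] = h_s
        return g, h

    def grad_hess_beta(
        self, beta: np.ndarray, X: np.ndarray
    ) -> tuple[float, np.ndarray, np.ndarray]:
        """Log-likelihood, score vector and observed information w.r.t. beta."""
        beta = np.asarray(beta, dtype=float)
        X = np.asarray(X, dtype=float)
        eta = X @ beta
        eta_s = eta[self.order]
        shift = eta_s.max()
        r = np.exp(eta_s - shift)
        Xs = X[self.order]
        s0 = self._group_rev_cumsum(r)
        s1 = self._group_rev_cumsum(r[:, None] * Xs)
        m2 = self._group_rev_cumsum(r[:, None, None] * (Xs[:, :, None] * Xs[:, None, :]))
        ev_grp = self.d > 0
        d = self.d[ev_grp]
        s0e, s1e, m2e = s0[ev_grp], s1[ev_grp], m2[ev_grp]
        # shift cancels: sum(d) == n_events
        ll = float((eta_s[self.e] - shift).sum() - np.sum(d * np.log(s0e)))
        xbar = s1e / s0e[:, None]
        score = Xs[self.e].sum(axis=0) - (d[:, None] * xbar).sum(axis=0)
        info = np.einsum("k,kij->ij", d, m2e / s0e[:, None, None]) - np.einsum(
            "k,ki,kj->ij", d, xbar, xbar
        )
        return ll, score, info


@dataclass
class NewtonCoxResult:
    """Unpenalized (possibly stratified) Cox fit."""

    beta: np.ndarray
    se: np.ndarray
    loglik: float
    loglik_null: float
    n_iter: int
    converged: bool
    covariance: np.ndarray = field(repr=False, default=None)

    @property
    def lr_statistic(self) -> float:
        return 2.0 * (self.loglik - self.loglik_null)


def _strata_blocks(time, event, strata):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if strata is None:
        return [(np.arange(time.size), CoxData(time, event))]
    strata = np.asarray(strata)
    blocks = []
    for s in np.unique(strata):
        idx = np.flatnonzero(strata == s)
        blocks.append((idx, CoxData(time[idx], event[idx])))
    return blocks


def breslow_loglik(beta, X, time, event, strata=None) -> float:
    """Breslow partial log-likelihood at ``beta`` (summed over strata)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != np.asarray(time).size:
        X = X.T
    eta = X @ np.asarray(beta, dtype=float)
    return float(sum(cd.loglik(eta[idx]) for idx, cd in _strata_blocks(time, event, strata)))


def breslow_saturated_loglik(time, event, strata=None) -> float:
    return float(
        sum(cd.loglik_saturated for _, cd in _strata_blocks(time, event, strata))
    )


def eta_grad_diag_hess(eta, time, event, strata=None):
    g = np.empty(np.asarray(eta).size)
    h = np.empty_like(g)
    for idx, cd in _strata_blocks(time, event, strata):
        gi, hi = cd.eta_grad_diag_hess(np.asarray(eta, dtype=float)[idx])
        g[idx], h[idx] = gi, hi
    return g, h


def newton_cox(
    X,
    time,
    event,
    strata=None,
    *,
    max_iter: int = 100,
    tol: float = 1e-9,
) -> NewtonCoxResult:
    """Maximize the Breslow partial likelihood by Newton-Raphson.

    Intended for low-dimensional fits (univariate scans, the clinical-only
    model, nested likelihood-ratio comparisons); high-dimensional fitting
    goes through the penalized solver.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if np.any(np.std(X, axis=0) == 0):
        raise ValueError("zero-variance covariate in Cox model")
    blocks = _strata_blocks(time, event, strata)
    n_events = sum(cd.n_events for _, cd in blocks)
    if n_events == 0:
        raise ValueError("no events observed; Cox model undefined")

    def eval_all(beta):
        ll = 0.0
        score = np.zeros(p)
        info = np.zeros((p, p))
        for idx, cd in blocks:
            lli, si, ii = cd.grad_hess_beta(beta, X[idx])
            ll += lli
            score += si
            info += ii
        return ll, score, info

    beta = np.zeros(p)
    ll, score, info = eval_all(beta)
    ll_null = ll
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "singular information matrix; covariates may be collinear"
            ) from exc
        # step-halving to guarantee ascent
        for _ in range(30):
            cand = beta + step
            ll_new, score_new, info_new = eval_all(cand)
            if ll_new >= ll - 1e-12:
                break
            step *= 0.5
        beta, ll, score, info = cand, ll_new, score_new, info_new
        if np.max(np.abs(score)) < tol:
            converged = True
            break
    cov = np.linalg.inv(info)
    return NewtonCoxResult(
        beta=beta,
        se=np.sqrt(np.diag(cov)),
        loglik=ll,
        loglik_null=ll_null,
        n_iter=it,
        converged=converged,
        covariance=cov,
    )
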