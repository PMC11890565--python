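"""Univariate association machinery.

Binomial (logistic) GLMs for frequency comparisons, univariate and
stratified Cox proportional-hazards fits, Wilcoxon rank-sum tests (exact by
enumeration for small samples), Benjamini-Hochberg FDR control, Kaplan-Meier
curves with log-rank tests, and the TP53 recurrent-missense immune-signature
screen.

Every result records the analysis family it was adjusted within, because
FDR control is only meaningful relative to its family of tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from ._survival import newton_cox

__all__ = [
    "TestResult",
    "binomial_glm_univariate",
    "cox_univariate",
    "wilcoxon_rank_sum",
    "bh_adjust",
    "km_logrank",
    "tp53_immune_screen",
    "results_to_frame",
]

_Z975 = sps.norm.ppf(0.975)


@dataclass
class TestResult:
    feature: str
    estimate: float  # odds ratio or hazard ratio
    ci_low: float
    ci_high: float
    p: float
    fdr_p: float | None = None
    family: str = ""
    n_used: int = 0
    flags: tuple = field(default_factory=tuple)


def results_to_frame(results) -> pd.DataFrame:
    rows = [
        (r.feature, r.estimate, r.ci_low, r.ci_high, r.p, r.fdr_p, r.family, r.n_used,
         ";".join(r.flags))
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=["feature", "estimate", "ci_low", "ci_high", "p", "fdr_p", "family",
                 "n_used", "flags"],
    )


def adjust_family(results, family: str) -> list:
    """BH-adjust the raw p-values of a list of TestResults in place."""
    ps = np.array([r.p for r in results])
    adj = bh_adjust(ps) if ps.size else ps
    for r, a in zip(results, adj):
        r.fdr_p = float(a)
        r.family = family
    return results


def binomial_glm_univariate(
    outcome, feature, dataset=None, *, name: str = "feature", family: str = ""
) -> TestResult:
    """Logistic model ``outcome ~ feature (+ dataset fixed effect)``.

    Reports the Wald odds-ratio estimate, 95% CI and p-value for the
    feature term.  Complete separation is detected and flagged; no silent
    estimate is returned in that case.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(feature, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class; model undefined")
    cols = {"const": np.ones_like(x), name: x}
    if dataset is not None:
        d = pd.get_dummies(pd.Series(np.asarray(dataset)), drop_first=True, dtype=float)
        for c in d.columns:
            cols[f"dataset[{c}]"] = d[c].to_numpy()
    X = pd.DataFrame(cols)
    flags: list[str] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
            coef = float(fit.params[name])
            se = float(fit.bse[name])
        except Exception:
            coef, se = np.nan, np.nan
            flags.append("fit_failed")
    if np.isfinite(coef) and (abs(coef) > 15 or se > 100):
        flags.append("separation")
    if "separation" in flags or "fit_failed" in flags:
        return TestResult(
            feature=name, estimate=np.nan, ci_low=np.nan, ci_high=np.nan, p=np.nan,
            family=family, n_used=y.size, flags=tuple(flags),
        )
    z = coef / se if se > 0 else 0.0
    p = 2.0 * sps.norm.sf(abs(z)) if se > 0 else 1.0
    return TestResult(
        feature=name,
        estimate=float(np.exp(coef)),
        ci_low=float(np.exp(coef - _Z975 * se)),
        ci_high=float(np.exp(coef + _Z975 * se)),
        p=float(p),
        family=family,
        n_used=y.size,
        flags=tuple(flags),
    )


def cox_univariate(
    time, event, feature, strata=None, *, name: str = "feature", family: str = ""
) -> TestResult:
    """Univariate (optionally stratified) Breslow Cox fit for one feature."""
    x = np.asarray(feature, dtype=float)
    if np.std(x) == 0:
        raise ValueError("feature is constant; hazard ratio undefined")
    res = newton_cox(x[:, None], time, event, strata=strata)
    coef = float(res.beta[0])
    se = float(res.se[0])
    z = coef / se
    with np.errstate(over="ignore"):
        lo, hi = np.exp(coef - _Z975 * se), np.exp(coef + _Z975 * se)
    return TestResult(
        feature=name,
        estimate=float(np.exp(coef)),
        ci_low=float(lo),
        ci_high=float(hi),
        p=float(2.0 * sps.norm.sf(abs(z))),
        family=family,
        n_used=x.size,
        flags=() if res.converged else ("not_converged",),
    )


def _ranksum_exact(x: np.ndarray, y: np.ndarray, alternative: str) -> float:
    """Exact rank-sum p by enumerating all C(m+n, m) group assignments.

    Uses midranks throughout, so ties are handled exactly as well.
    """
    m, n = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    w_obs = ranks[:m].sum()
    total = 0
    ge = 0
    le = 0
    for comb in combinations(range(m + n), m):
        w = ranks[list(comb)].sum()
        total += 1
        if w >= w_obs - 1e-9:
            ge += 1
        if w <= w_obs + 1e-9:
            le += 1
    if alternative == "greater":
        return ge / total
    if alternative == "less":
        return le / total
    return min(1.0, 2.0 * min(ge, le) / total)


def wilcoxon_rank_sum(x, y, alternative: str = "two-sided") -> float:
    """Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact by full enumeration when m + n <= 20 (valid under ties); normal
    approximation with midrank tie correction and continuity correction
    otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    if np.unique(np.concatenate([x, y])).size == 1:
        return 1.0
    if x.size + y.size <= 20:
        return float(_ranksum_exact(x, y, alternative))
    res = sps.mannwhitneyu(x, y, alternative=alternative, method="asymptotic")
    return float(res.pvalue)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def km_logrank(time, event, group):
    """Kaplan-Meier curves per group plus the k-sample log-rank test.

    Returns ``(curves, statistic, p)`` where ``curves`` maps group label to
    a DataFrame of (time, survival) coordinates.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test

    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    group = pd.Series(np.asarray(group))
    labels = group.unique()
    if len(labels) < 2:
        raise ValueError("need at least two groups for a log-rank test")
    curves = {}
    for lab in labels:
        mask = (group == lab).to_numpy()
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event[mask])
        sf = kmf.survival_function_
        curves[lab] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
        )
    lr = multivariate_logrank_test(time, group.to_numpy(), event)
    return curves, float(lr.test_statistic), float(lr.p_value)


def tp53_immune_screen(
    signatures: pd.DataFrame,
    variant_matrix: pd.DataFrame,
    variant_classes,
    normal_ids,
    *,
    min_count: int = 10,
    alpha: float = 0.05,
):
    """Screen immune signatures for recurrent-TP53-missense-specific elevation.

    For each signature and each mutation group — one group per recurrent
    (count >= ``min_count``) missense protein change, plus the pooled
    nonsense group — a one-sided (greater) rank-sum test compares tumor
    samples in the group against normal samples; all tests are BH-adjusted
    as one family.  A signature is selected iff its adjusted p < ``alpha``
    for at least one recurrent missense group AND its adjusted p >= ``alpha``
    for the nonsense group (the neoantigen-control criterion).

    Returns ``(selected_signature_list, results_frame)``.
    """
    normal_ids = pd.Index(normal_ids).intersection(signatures.index)
    if len(normal_ids) == 0:
        raise ValueError("no normal samples present in the signature matrix")
    classes = dict(variant_classes)
    counts = variant_matrix.sum(axis=0)
    missense_groups = {
        v: variant_matrix.index[variant_matrix[v] == 1]
        for v in variant_matrix.columns
        if classes.get(v) == "missense" and counts[v] >= min_count
    }
    nonsense_cols = [v for v in variant_matrix.columns if classes.get(v) == "nonsense"]
    nonsense_ids = variant_matrix.index[variant_matrix[nonsense_cols].sum(axis=1) > 0]
    groups = dict(missense_groups)
    groups["nonsense"] = nonsense_ids

    rows = []
    normals = signatures.loc[normal_ids]
    for sig in sorted(signatures.columns):
        for gname, ids in groups.items():
            ids = pd.Index(ids).intersection(signatures.index)
            if len(ids) == 0:
                rows.append((sig, gname, np.nan))
                continue
            p = wilcoxon_rank_sum(
                signatures.loc[ids, sig].to_numpy(),
                normals[sig].to_numpy(),
                alternative="greater",
            )
            rows.append((sig, gname, p))
    frame = pd.DataFrame(rows, columns=["signature", "group", "p"])
    ok = frame["p"].notna()
    frame.loc[ok, "fdr_p"] = bh_adjust(frame.loc[ok, "p"].to_numpy())

    selected = []
    for sig, sub in frame.groupby("signature", sort=True):
        mis = sub[(sub["group"] != "nonsense") & (sub["fdr_p"] < alpha)]
        non = sub[sub["group"] == "nonsense"]
        nonsense_ok = non.empty or non["fdr_p"].isna().all() or (non["fdr_p"] >= alpha).all()
        if len(mis) and nonsense_ok:
            selected.append(sig)
    return selected, frame
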