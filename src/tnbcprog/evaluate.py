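"""Test-set discrimination and incremental prognostic value.

Harrell's concordance index measures how well a continuous risk score
orders observed survival; tertile (or median) risk groups visualize the
separation with Kaplan-Meier curves; and nested likelihood-ratio
comparisons quantify how much prognostic information a risk score adds to
tumor stage (the clinical standard), and vice versa.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._survival import newton_cox
from .stats import km_logrank

__all__ = ["harrell_c", "tertile_groups", "lr_increment", "evaluate_model", "EvaluationReport"]


def harrell_c(time, event, risk) -> float:
    """Harrell's concordance index.

    A pair (i, j) is comparable iff the shorter observed time is an event
    (tied times are not comparable).  A pair is concordant when the subject
    with the shorter time has the higher risk; risk ties count 0.5.
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event).astype(bool)
    r = np.asarray(risk, dtype=float)
    # comparable: t_i < t_j and e_i (subject i fails first, observed)
    earlier = t[:, None] < t[None, :]
    comparable = earlier & e[:, None]
    n_comp = comparable.sum()
    if n_comp == 0:
        raise ValueError("no comparable pairs; concordance undefined")
    higher = r[:, None] > r[None, :]
    tied = r[:, None] == r[None, :]
    concordant = (comparable & higher).sum()
    half = (comparable & tied).sum()
    return float((concordant + 0.5 * half) / n_comp)


def tertile_groups(scores: pd.Series, test_set: pd.Series, *, mode: str = "tertile"):
    """Cut risk scores into low/medium/high groups within each test set.

    Cutoffs are the 1/3 and 2/3 quantiles (or the median, in ``median``
    mode) of each test set's own scores, so sets with disjoint score ranges
    are grouped independently.  Constant scores within a set collapse to a
    single flagged group.
    """
    if mode not in ("tertile", "median"):
        raise ValueError("mode must be 'tertile' or 'median'")
    scores = pd.Series(scores)
    test_set = pd.Series(test_set).loc[scores.index]
    groups = pd.Series("", index=scores.index, name="risk_group", dtype=object)
    flags = {}
    for ds, idx in scores.groupby(test_set).groups.items():
        s = scores.loc[idx]
        if len(s) < 3:
            raise ValueError(f"test set {ds!r} has fewer than 3 patients")
        if s.nunique() == 1:
            groups.loc[idx] = "low"
            flags[ds] = "degenerate_constant_scores"
            continue
        if mode == "tertile":
            q1, q2 = s.quantile([1 / 3, 2 / 3])
            groups.loc[idx] = np.where(s <= q1, "low", np.where(s <= q2, "medium", "high"))
        else:
            med = s.median()
            groups.loc[idx] = np.where(s <= med, "low", "high")
    return groups, flags


@dataclass
class LRIncrement:
    """Nested stratified-Cox comparison of stage and a risk score."""

    lr_stage: float
    lr_score: float
    lr_joint: float
    pct_increase_score_over_stage: float | None
    pct_increase_stage_over_score: float | None
    p_stage_joint: float
    p_score_joint: float
    p_stage_only: float
    p_score_only: float
    flags: tuple = ()


def _wald_p(res, j):
    from scipy.stats import norm

    z = res.beta[j] / res.se[j]
    return float(2 * norm.sf(abs(z)))


def lr_increment(time, event, risk, stage, strata=None) -> LRIncrement:
    """Likelihood-ratio statistics of stage-only, score-only and joint
    stratified Cox models, and the percent change in each addition order.

    The stage coefficient losing significance in the joint model is the
    expected signature of a score that already embeds stage.
    """
    risk = np.asarray(risk, dtype=float)
    stage = np.asarray(stage, dtype=float)
    flags = []
    r = np.corrcoef(risk, stage)[0, 1] if np.std(risk) > 0 and np.std(stage) > 0 else np.nan
    if np.isfinite(r) and abs(r) >= 1.0 - 1e-12:
        flags.append("collinear_score_stage")
    fit_stage = newton_cox(stage[:, None], time, event, strata=strata)
    fit_score = newton_cox(risk[:, None], time, event, strata=strata)
    if flags:
        # joint model unidentifiable; report the nested fits only
        return LRIncrement(
            lr_stage=fit_stage.lr_statistic,
            lr_score=fit_score.lr_statistic,
            lr_joint=max(fit_stage.lr_statistic, fit_score.lr_statistic),
            pct_increase_score_over_stage=None,
            pct_increase_stage_over_score=None,
            p_stage_joint=np.nan,
            p_score_joint=np.nan,
            p_stage_only=_wald_p(fit_stage, 0),
            p_score_only=_wald_p(fit_score, 0),
            flags=tuple(flags),
        )
    X = np.column_stack([stage, risk])
    fit_joint = newton_cox(X, time, event, strata=strata)
    lr_stage = fit_stage.lr_statistic
    lr_score = fit_score.lr_statistic
    lr_joint = fit_joint.lr_statistic
    pct_score = 100.0 * (lr_joint - lr_stage) / lr_stage if lr_stage > 0 else None
    pct_stage = 100.0 * (lr_joint - lr_score) / lr_score if lr_score > 0 else None
    return LRIncrement(
        lr_stage=lr_stage,
        lr_score=lr_score,
        lr_joint=lr_joint,
        pct_increase_score_over_stage=pct_score,
        pct_increase_stage_over_score=pct_stage,
        p_stage_joint=_wald_p(fit_joint, 0),
        p_score_joint=_wald_p(fit_joint, 1),
        p_stage_only=_wald_p(fit_stage, 0),
        p_score_only=_wald_p(fit_score, 0),
        flags=tuple(flags),
    )


@dataclass
class EvaluationReport:
    c_index_combined: float
    c_index_per_set: dict
    risk_groups: pd.Series = field(repr=False, default=None)
    logrank_statistic: float | None = None
    logrank_p: float | None = None
    lr: LRIncrement | None = None
    flags: tuple = ()

    def to_dict(self) -> dict:
        d = {
            "c_index_combined": self.c_index_combined,
            "c_index_per_set": self.c_index_per_set,
            "logrank_statistic": self.logrank_statistic,
            "logrank_p": self.logrank_p,
            "flags": list(self.flags),
        }
        if self.lr is not None:
            d["lr_increment"] = {
                "lr_stage": self.lr.lr_stage,
                "lr_score": self.lr.lr_score,
                "lr_joint": self.lr.lr_joint,
                "pct_increase_score_over_stage": self.lr.pct_increase_score_over_stage,
                "pct_increase_stage_over_score": self.lr.pct_increase_stage_over_score,
                "p_stage_joint": self.lr.p_stage_joint,
                "p_score_joint": self.lr.p_score_joint,
                "p_stage_only": self.lr.p_stage_only,
                "p_score_only": self.lr.p_score_only,
                "flags": list(self.lr.flags),
            }
        return d


def evaluate_model(
    scores: pd.Series,
    time,
    event,
    test_set: pd.Series,
    stage=None,
    *,
    group_mode: str = "tertile",
) -> EvaluationReport:
    """Full test-set evaluation of one model's risk scores.

    Combined C-index is computed on pooled patients (per-set values are
    also reported).  Degenerate all-equal scores (an empty model) yield a
    flagged C of 0.5 rather than an error, so a no-feature model's pathway
    still completes.
    """
    scores = pd.Series(scores)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    test_set = pd.Series(test_set).loc[scores.index]
    flags = []
    degenerate = scores.nunique() == 1
    if degenerate:
        flags.append("degenerate_constant_scores")
        c_combined = 0.5
        c_per_set = {ds: 0.5 for ds in test_set.unique()}
    else:
        c_combined = harrell_c(time, event, scores.to_numpy())
        c_per_set = {}
        for ds in test_set.unique():
            m = (test_set == ds).to_numpy()
            try:
                c_per_set[ds] = harrell_c(time[m], event[m], scores.to_numpy()[m])
            except ValueError:
                c_per_set[ds] = np.nan
    groups, gflags = tertile_groups(scores, test_set, mode=group_mode)
    flags.extend(f"{ds}:{f}" for ds, f in gflags.items())
    lr_stat = lr_p = None
    if groups.nunique() >= 2:
        _, lr_stat, lr_p = km_logrank(time, event, groups)
    lr = None
    if stage is not None and not degenerate:
        lr = lr_increment(time, event, scores.to_numpy(), np.asarray(stage, dtype=float),
                          strata=test_set.to_numpy())
    elif stage is not None and degenerate:
        flags.append("lr_increment_skipped_degenerate_scores")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return EvaluationReport(
            c_index_combined=c_combined,
            c_index_per_set=c_per_set,
            risk_groups=groups,
            logrank_statistic=lr_stat,
            logrank_p=lr_p,
            lr=lr,
            flags=tuple(flags),
        )
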