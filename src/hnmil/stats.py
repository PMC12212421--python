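"""Evaluation and inference statistics.

AUROC (Mann-Whitney form) with class-stratified bootstrap confidence
intervals, paired score-permutation tests between models, Kaplan-Meier /
logrank / Cox stratification at the training-median score cutoff,
score-to-clinical correlations (Spearman and point-biserial), and
Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass
class AurocResult:
    auroc: float
    ci_low: float
    ci_high: float
    n_boot: int


@dataclass
class CoxResult:
    hr: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    p: Optional[float]
    degenerate: bool = False


@dataclass
class StratificationResult:
    cutoff: float
    high_risk: np.ndarray  # boolean per test patient
    hr: Optional[float]
    hr_ci: Optional[tuple[float, float]]
    logrank_p: Optional[float]
    degenerate_flag: bool


@dataclass
class KMCurve:
    timeline: np.ndarray
    survival: np.ndarray  # right-continuous step values at timeline points

    def evaluate(self, t: float) -> float:
        idx = np.searchsorted(self.timeline, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Probability of concordance, ties counted 1/2 (Mann-Whitney U form)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC requires both classes present")
    ranks = sps.rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def bootstrap_auroc_ci(
    scores: Sequence[float],
    labels: Sequence[int],
    n_boot: int = 1000,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> AurocResult:
    """Class-stratified bootstrap: resample within each class preserving counts."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    rng = rng if rng is not None else np.random.default_rng(seed)
    pos, neg = scores[labels == 1], scores[labels == 0]
    point = auroc(scores, labels)
    boots = np.empty(n_boot)
    lab = np.concatenate([np.ones(len(pos), dtype=int), np.zeros(len(neg), dtype=int)])
    for b in range(n_boot):
        sp = pos[rng.integers(0, len(pos), len(pos))]
        sn = neg[rng.integers(0, len(neg), len(neg))]
        boots[b] = auroc(np.concatenate([sp, sn]), lab)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return AurocResult(point, float(lo), float(hi), n_boot)


def permutation_auroc_test(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    labels: Sequence[int],
    n: int = 1000,
    alternative: str = "two-sided",
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Paired model comparison by per-patient score swapping.

    Under the null of exchangeable models, each patient's two scores are
    swapped independently with probability 1/2 to build the null distribution
    of the AUROC difference; the p-value carries the +1 finite-resampling
    correction.
    """
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if sa.shape != sb.shape or sa.shape[0] != labels.shape[0]:
        raise ValueError("paired scores and labels must have equal length")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    rng = rng if rng is not None else np.random.default_rng(seed)
    obs = auroc(sa, labels) - auroc(sb, labels)
    null = np.empty(n)
    for i in range(n):
        swap = rng.random(len(sa)) < 0.5
        pa = np.where(swap, sb, sa)
        pb = np.where(swap, sa, sb)
        null[i] = auroc(pa, labels) - auroc(pb, labels)
    if alternative == "two-sided":
        extreme = np.abs(null) >= abs(obs) - 1e-12
    elif alternative == "greater":
        extreme = null >= obs - 1e-12
    else:
        extreme = null <= obs + 1e-12
    return float((1 + extreme.sum()) / (n + 1))


def km_curve(times: Sequence[float], events: Sequence[int]) -> KMCurve:
    """Product-limit survival estimate with right censoring."""
    times = np.asarray(times, dtype=float)
    if (times < 0).any():
        raise ValueError("times must be nonnegative")
    kmf = KaplanMeierFitter()
    kmf.fit(times, np.asarray(events, dtype=int))
    timeline = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    return KMCurve(timeline=timeline, survival=surv)


def logrank_test(
    times: Sequence[float], events: Sequence[int], groups: Sequence[int]
) -> tuple[float, float]:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups, dtype=int)
    if (groups == 1).sum() == 0 or (groups == 0).sum() == 0:
        raise ValueError("logrank test requires two nonempty groups")
    res = _ll_logrank(
        times[groups == 0], times[groups == 1],
        event_observed_A=events[groups == 0], event_observed_B=events[groups == 1],
    )
    return float(res.test_statistic), float(res.p_value)


def cox_hr_binary(
    times: Sequence[float], events: Sequence[int], groups: Sequence[int]
) -> CoxResult:
    """Univariate Cox fit of a high-vs-low-risk indicator (Efron ties).

    HR > 1 means the high-risk (group = 1) arm has more events.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups, dtype=int)
    if events[groups == 1].sum() == 0 and events[groups == 0].sum() == 0:
        return CoxResult(None, None, None, None, degenerate=True)
    df = pd.DataFrame({"t": times, "e": events, "g": groups})
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="t", event_col="e")
    except Exception:
        return CoxResult(None, None, None, None, degenerate=True)
    row = cph.summary.loc["g"]
    return CoxResult(
        hr=float(np.exp(row["coef"])),
        ci_low=float(np.exp(row["coef lower 95%"])),
        ci_high=float(np.exp(row["coef upper 95%"])),
        p=float(row["p"]),
        degenerate=False,
    )


def stratify_by_median(
    train_scores: Sequence[float],
    test_scores: Sequence[float],
    test_times: Sequence[float],
    test_events: Sequence[int],
) -> StratificationResult:
    """Split test patients at the training-median score and assess separation.

    Scores strictly above the cutoff are high-risk; ties go to low-risk.  When
    the split leaves a group empty or only one group with events, the result
    is flagged degenerate and HR / logrank are not reported.
    """
    train_scores = np.asarray(train_scores, dtype=float)
    if train_scores.size == 0:
        raise ValueError("training scores must be nonempty")
    cutoff = float(np.median(train_scores))
    test_scores = np.asarray(test_scores, dtype=float)
    events = np.asarray(test_events, dtype=int)
    high = test_scores > cutoff
    n_hi, n_lo = int(high.sum()), int((~high).sum())
    degenerate = (
        n_hi == 0
        or n_lo == 0
        or events[high].sum() == 0
        or events[~high].sum() == 0
    )
    if degenerate:
        return StratificationResult(cutoff, high, None, None, None, True)
    cox = cox_hr_binary(test_times, events, high.astype(int))
    _, p = logrank_test(test_times, events, high.astype(int))
    if cox.degenerate:
        return StratificationResult(cutoff, high, None, None, float(p), True)
    return StratificationResult(
        cutoff, high, cox.hr, (cox.ci_low, cox.ci_high), float(p), False
    )


#: variable -> correlation kind used against MIL scores
CORRELATION_KINDS = {
    "age": "spearman",
    "t_stage": "spearman",
    "n_stage": "spearman",
    "sex": "pointbiserial",
    "chemo": "pointbiserial",
    "hpv_positive": "pointbiserial",
}


def correlate_scores_clinical(
    scores: Sequence[float], clinical: pd.DataFrame
) -> pd.DataFrame:
    """Spearman rho for ordinal/numeric variables, point-biserial for binary."""
    scores = np.asarray(scores, dtype=float)
    if len(scores) != len(clinical):
        raise ValueError("scores and clinical table must be aligned")
    rows = []
    for var, kind in CORRELATION_KINDS.items():
        if var not in clinical.columns:
            continue
        x = clinical[var].to_numpy(dtype=float)
        ok = np.isfinite(x)
        if np.unique(x[ok]).size < 2:
            rows.append({"variable": var, "kind": kind, "coefficient": np.nan,
                         "p": np.nan, "flagged_constant": True})
            continue
        if kind == "spearman":
            r, p = sps.spearmanr(scores[ok], x[ok])
        else:
            r, p = sps.pointbiserialr(x[ok].astype(int), scores[ok])
        rows.append({"variable": var, "kind": kind, "coefficient": float(r),
                     "p": float(p), "flagged_constant": False})
    return pd.DataFrame(rows)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
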