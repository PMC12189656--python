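"""Diagnostic-test-accuracy statistics for PVR features vs angiographic PAD.

ROC analysis with bootstrap confidence intervals, Youden-index cut-off
selection, 2x2 contingency metrics, Cohen's kappa for interrater agreement,
nonparametric group comparisons, and the revascularisation-response rule
(MSA increase >= 0.1 mmHg). `evaluate_cohort` ties these together for a
limb-level cohort with GLASS labels, excluding non-pulsatile limbs from
quantitative analysis as the clinical workflow does.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_curve as _sk_roc_curve

from pvrkit.errors import ValidationError

__all__ = [
    "ROCResult",
    "ContingencyMetrics",
    "KappaResult",
    "roc",
    "youden_cutoff",
    "contingency",
    "cohens_kappa",
    "mann_whitney_u",
    "kruskal_wallis",
    "chi_square",
    "revasc_response",
    "evaluate_cohort",
    "ENDPOINTS",
]

#: Endpoint definitions over (GLASS stage rank, inframalleolar descriptor).
ENDPOINTS = {
    "any_pad": lambda stage_rank, imd: stage_rank >= 1,
    "severe_pad": lambda stage_rank, imd: stage_rank >= 2,
    "very_severe": lambda stage_rank, imd: stage_rank >= 3,
    "imd_disease": lambda stage_rank, imd: imd in ("P1", "P2"),
}

#: Disease direction per quantitative feature: obstruction lowers amplitude
#: and prolongs the upstroke.
FEATURE_DIRECTIONS = {
    "msa_mmhg": "lower_is_disease",
    "ust_ms": "higher_is_disease",
    "usr": "higher_is_disease",
}


@dataclass(frozen=True)
class ROCResult:
    """Empirical ROC curve with trapezoidal AUC and bootstrap 95% CI."""

    thresholds: np.ndarray
    sens: np.ndarray
    spec: np.ndarray
    auc: float
    auc_ci_low: float
    auc_ci_high: float
    direction: str
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class ContingencyMetrics:
    """2x2 table counts and the derived accuracy fractions.

    Ratios with zero denominators are reported as None, not 0.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None


@dataclass(frozen=True)
class KappaResult:
    """Unweighted Cohen's kappa with observed/expected agreement."""

    observed_agreement: float
    expected_agreement: float
    kappa: float
    n_pairs: int


def _score_sign(direction: str) -> float:
    if direction == "higher_is_disease":
        return 1.0
    if direction == "lower_is_disease":
        return -1.0
    raise ValidationError(f"unknown direction {direction!r}")


def _auc_trapezoid(scores: np.ndarray, labels: np.ndarray) -> float:
    fpr, tpr, _ = _sk_roc_curve(labels, scores)
    return float(np.trapezoid(tpr, fpr))


def roc(
    scores,
    labels,
    direction: str = "higher_is_disease",
    n_boot: int = 2000,
    seed: int = 0,
) -> ROCResult:
    """Empirical ROC over all distinct thresholds.

    AUC is the trapezoidal area, equal to P(score_pos > score_neg) + 0.5
    P(equal) under the stated direction (Mann-Whitney tie convention). The
    95% CI is a seeded stratified bootstrap (percentile interval, resampling
    positives and negatives separately).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape:
        raise ValidationError("scores and labels must have the same length")
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("roc requires at least one positive and one negative label")

    sign = _score_sign(direction)
    oriented = sign * scores
    fpr, tpr, thr = _sk_roc_curve(labels, oriented)
    auc = float(np.trapezoid(tpr, fpr))

    rng = np.random.default_rng(seed)
    pos = oriented[labels == 1]
    neg = oriented[labels == 0]
    boots = np.empty(n_boot)
    for i in range(n_boot):
        bp = rng.choice(pos, size=n_pos, replace=True)
        bn = rng.choice(neg, size=n_neg, replace=True)
        boots[i] = _auc_trapezoid(
            np.concatenate([bp, bn]),
            np.concatenate([np.ones(n_pos, int), np.zeros(n_neg, int)]),
        )
    lo, hi = np.percentile(boots, [2.5, 97.5])

    return ROCResult(
        thresholds=sign * thr,  # back on the original scale
        sens=tpr,
        spec=1.0 - fpr,
        auc=auc,
        auc_ci_low=float(min(lo, auc)),
        auc_ci_high=float(max(hi, auc)),
        direction=direction,
        n_pos=n_pos,
        n_neg=n_neg,
    )


def youden_cutoff(rocresult: ROCResult) -> tuple[float, float, float]:
    """Cut-off maximising Youden's J = sens + spec - 1 (ties -> higher spec)."""
    j = rocresult.sens + rocresult.spec - 1.0
    best = np.flatnonzero(j == j.max())
    idx = best[int(np.argmax(rocresult.spec[best]))]
    return (
        float(rocresult.thresholds[idx]),
        float(rocresult.sens[idx]),
        float(rocresult.spec[idx]),
    )


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def contingency(tp: int, fp: int, fn: int, tn: int) -> ContingencyMetrics:
    """Exact accuracy fractions from 2x2 counts; undefined ratios are None."""
    for name, v in (("tp", tp), ("fp", fp), ("fn", fn), ("tn", tn)):
        if v < 0:
            raise ValidationError(f"{name} must be >= 0, got {v}")
    return ContingencyMetrics(
        tp=tp, fp=fp, fn=fn, tn=tn,
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        ppv=_ratio(tp, tp + fp),
        npv=_ratio(tn, tn + fn),
    )


def cohens_kappa(ratings_a, ratings_b, categories=None) -> KappaResult:
    """Unweighted Cohen's kappa between two raters.

    kappa = (po - pe) / (1 - pe) from the k x k confusion matrix, with
    observed (po) and chance-expected (pe) agreement reported.
    """
    a = np.asarray(ratings_a)
    b = np.asarray(ratings_b)
    if a.size == 0:
        raise ValidationError("cohens_kappa requires non-empty rating vectors")
    if a.shape != b.shape:
        raise ValidationError("rating vectors must have the same length")
    cats = list(categories) if categories is not None else sorted(set(a) | set(b))
    index = {c: i for i, c in enumerate(cats)}
    k = len(cats)
    cm = np.zeros((k, k))
    for x, y in zip(a, b):
        cm[index[x], index[y]] += 1
    n = cm.sum()
    po = float(np.trace(cm) / n)
    pe = float((cm.sum(axis=1) / n) @ (cm.sum(axis=0) / n))
    kappa = (po - pe) / (1.0 - pe) if pe < 1.0 else 1.0
    return KappaResult(observed_agreement=po, expected_agreement=pe, kappa=kappa, n_pairs=int(n))


def _check_groups(*groups) -> list[np.ndarray]:
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrs):
        raise ValidationError("groups must be non-empty")
    pooled = np.concatenate(arrs)
    if np.all(pooled == pooled[0]):
        raise ValidationError("all observations are tied; rank variance is zero")
    return arrs


def mann_whitney_u(x, y, method: str = "auto") -> tuple[float, float]:
    """Mann-Whitney U with two-sided p.

    method 'asymptotic' uses the tie-corrected normal approximation;
    'exact' enumerates the full permutation distribution of U (feasible for
    small samples); 'auto' picks exact when both groups have <= 8
    observations.
    """
    x, y = _check_groups(x, y)
    if method == "auto":
        method = "exact" if max(x.size, y.size) <= 8 else "asymptotic"
    if method == "exact":

        def statistic(a, b):
            return sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").statistic

        res = sps.permutation_test(
            (x, y), statistic, permutation_type="independent",
            alternative="two-sided", n_resamples=np.inf,
        )
        return float(res.statistic), float(res.pvalue)
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(groups) -> tuple[float, float]:
    """Kruskal-Wallis H with tie-corrected chi-square p."""
    arrs = _check_groups(*groups)
    if len(arrs) < 2:
        raise ValidationError("kruskal_wallis requires at least two groups")
    h, p = sps.kruskal(*arrs)
    return float(h), float(p)


def chi_square(table) -> tuple[float, float]:
    """Pearson chi-square test of independence (no continuity correction)."""
    table = np.asarray(table, dtype=float)
    if np.any(table < 0):
        raise ValidationError("table counts must be >= 0")
    stat, p, _, _ = sps.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def revasc_response(
    pre_msa,
    post_msa,
    success_labels,
    threshold: float = 0.1,
) -> ContingencyMetrics:
    """Responder rule after revascularisation: MSA increase >= threshold.

    The increase is inclusive (a delta of exactly ``threshold`` counts as a
    response). Returns the 2x2 metrics of responder status vs angiographic
    success.
    """
    pre = np.asarray(pre_msa, dtype=float)
    post = np.asarray(post_msa, dtype=float)
    success = np.asarray(success_labels).astype(bool)
    if not (pre.shape == post.shape == success.shape):
        raise ValidationError("pre, post and success arrays must have the same length")
    # inclusive threshold with a float-safe margin (values are mmHg)
    responder = (post - pre) >= threshold - 1e-9
    tp = int(np.sum(responder & success))
    fp = int(np.sum(responder & ~success))
    fn = int(np.sum(~responder & success))
    tn = int(np.sum(~responder & ~success))
    return contingency(tp, fp, fn, tn)


def _metrics_dict(m: ContingencyMetrics) -> dict:
    return {
        "tp": m.tp, "fp": m.fp, "fn": m.fn, "tn": m.tn,
        "sensitivity": m.sensitivity, "specificity": m.specificity,
        "ppv": m.ppv, "npv": m.npv,
    }


def evaluate_cohort(
    records,
    endpoints=("any_pad", "severe_pad", "very_severe", "imd_disease"),
    features=("msa_mmhg", "ust_ms", "usr"),
    subgroup: str | None = None,
    n_boot: int = 2000,
    seed: int = 0,
) -> dict:
    """Full diagnostic-test-accuracy report for a limb cohort.

    For every endpoint x feature: ROC with bootstrap CI, the Youden cut-off
    and its 2x2 metrics. Non-pulsatile limbs are excluded from the
    quantitative analysis. ``subgroup`` restricts to a boolean column of the
    cohort table (e.g. ``abi_ge_1_3`` or ``infection``). Single-class or
    empty strata produce an explicit skip record instead of numbers.
    """
    from pvrkit.cohort import cohort_to_frame

    df = records if isinstance(records, pd.DataFrame) else cohort_to_frame(records)
    total = len(df)
    if subgroup is not None:
        if subgroup not in df.columns:
            raise ValidationError(f"unknown subgroup column {subgroup!r}")
        df = df[df[subgroup].astype(bool)]
    analyzed = df[df["pulsatile"].astype(bool)].reset_index(drop=True)

    report: dict = {
        "n_limbs": total,
        "n_in_subgroup": len(df),
        "n_non_pulsatile": int(len(df) - len(analyzed)),
        "n_analyzed": len(analyzed),
        "subgroup": subgroup,
        "endpoints": {},
    }
    stage_rank = analyzed["glass_stage"].map({"0": 0, "I": 1, "II": 2, "III": 3})
    for ep in endpoints:
        rule = ENDPOINTS[ep]
        y = np.array(
            [rule(r, i) for r, i in zip(stage_rank, analyzed["imd"])], dtype=int
        )
        ep_report: dict = {"n_pos": int(y.sum()), "n_neg": int(len(y) - y.sum())}
        if len(y) == 0 or y.sum() == 0 or y.sum() == len(y):
            ep_report["skipped"] = "endpoint has fewer than two classes in this stratum"
            report["endpoints"][ep] = ep_report
            continue
        ep_report["features"] = {}
        for feat in features:
            scores = analyzed[feat].to_numpy(dtype=float)
            direction = FEATURE_DIRECTIONS[feat]
            r = roc(scores, y, direction=direction, n_boot=n_boot, seed=seed)
            cutoff, sens, spec = youden_cutoff(r)
            sign = _score_sign(direction)
            pred = (sign * scores) >= (sign * cutoff)
            m = contingency(
                tp=int(np.sum(pred & (y == 1))),
                fp=int(np.sum(pred & (y == 0))),
                fn=int(np.sum(~pred & (y == 1))),
                tn=int(np.sum(~pred & (y == 0))),
            )
            ep_report["features"][feat] = {
                "auc": round(r.auc, 4),
                "auc_ci_low": round(r.auc_ci_low, 4),
                "auc_ci_high": round(r.auc_ci_high, 4),
                "direction": direction,
                "cutoff": cutoff,
                "youden_sensitivity": sens,
                "youden_specificity": spec,
                "contingency": _metrics_dict(m),
            }
        report["endpoints"][ep] = ep_report
    return report
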