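"""Validation statistics: relative expression, gated group comparison,
correlation, ROC/AUC, composite biomarker scoring."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

from .manifest_io import BetaMatrix, SampleSheet

logger = logging.getLogger(__name__)


@dataclass
class ComparisonResult:
    test_used: str  # "t" | "mannwhitney"
    statistic: float
    p: float
    summary_case: tuple[float, float, float] | tuple[float, float]
    summary_control: tuple[float, float, float] | tuple[float, float]
    normality_note: str = "normality gated by Lilliefors-corrected KS"


@dataclass
class CorrelationResult:
    method: str  # "pearson" | "spearman"
    r: float
    p: float
    n: int


@dataclass
class ROCResult:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    youden_cutoff: float
    sensitivity: float
    specificity: float
    positive_is_low: bool


def ddct(
    ct_target: np.ndarray,
    ct_reference: np.ndarray,
    calibrator_delta_ct: float,
) -> np.ndarray:
    """Per-sample relative expression 2^-(dCt - calibrator dCt)."""
    ct_target = np.asarray(ct_target, dtype=float)
    ct_reference = np.asarray(ct_reference, dtype=float)
    if not (np.isfinite(ct_target).all() and np.isfinite(ct_reference).all()):
        raise ValueError("Ct values must be finite")
    delta_ct = ct_target - ct_reference
    return 2.0 ** (-(delta_ct - calibrator_delta_ct))


def relative_expression(sheet: SampleSheet) -> pd.DataFrame:
    """2^-ddCt expression per sample, calibrated to the control-group mean dCt."""
    df = sheet.df
    if "ct_target" not in df.columns or "ct_reference" not in df.columns:
        raise ValueError("sample sheet lacks ct_target/ct_reference columns")
    ok = df["ct_target"].notna() & df["ct_reference"].notna()
    sub = df[ok]
    dct = sub["ct_target"].to_numpy() - sub["ct_reference"].to_numpy()
    control = (sub["group"] == "control").to_numpy()
    if not control.any():
        raise ValueError("no control samples with Ct values")
    calibrator = float(dct[control].mean())
    expr = ddct(sub["ct_target"].to_numpy(), sub["ct_reference"].to_numpy(), calibrator)
    return pd.DataFrame(
        {
            "sample_id": sub["sample_id"].to_numpy(),
            "group": sub["group"].to_numpy(),
            "relative_expression": expr,
        }
    )


def _is_normal(x: np.ndarray, alpha: float = 0.05) -> bool:
    x = np.asarray(x, dtype=float)
    if x.size < 4 or np.ptp(x) == 0:
        return False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            _, p = lilliefors(x, dist="norm")
        except Exception:
            return False
    return p > alpha


def compare_groups(values, groups, alpha: float = 0.05) -> ComparisonResult:
    """Two-group comparison with a KS (Lilliefors) normality gate.

    Both groups normal: two-sample t with mean +/- SD summaries; otherwise
    Mann-Whitney U with median (25th, 75th percentile) summaries.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = sorted(set(groups), key=lambda g: (g != "case", str(g)))
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {levels}")
    a = values[groups == levels[0]]
    b = values[groups == levels[1]]
    if min(a.size, b.size) < 2:
        raise ValueError("each group needs >= 2 values")
    if _is_normal(a, alpha) and _is_normal(b, alpha):
        stat, p = stats.ttest_ind(a, b, equal_var=True)
        return ComparisonResult(
            test_used="t",
            statistic=float(stat),
            p=float(p),
            summary_case=(float(a.mean()), float(a.std(ddof=1))),
            summary_control=(float(b.mean()), float(b.std(ddof=1))),
        )
    if np.array_equal(np.sort(a), np.sort(b)):
        p = 1.0
        stat = a.size * b.size / 2.0
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        stat, p = float(res.statistic), float(res.pvalue)

    def _summ(x):
        return (
            float(np.median(x)),
            float(np.percentile(x, 25)),
            float(np.percentile(x, 75)),
        )

    return ComparisonResult(
        test_used="mannwhitney",
        statistic=float(stat),
        p=float(p),
        summary_case=_summ(a),
        summary_control=_summ(b),
    )


def correlate(
    x, y, method: Literal["auto", "pearson", "spearman"] = "auto"
) -> CorrelationResult:
    """Paired correlation; 'auto' picks Pearson when both variables pass the
    normality gate, Spearman otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in correlate input")
    if method == "auto":
        method = "pearson" if (_is_normal(x) and _is_normal(y)) else "spearman"
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationResult(method=method, r=float(r), p=float(p), n=int(x.size))


def roc(score, labels, positive_is_low: bool = False) -> ROCResult:
    """Empirical ROC over all thresholds with trapezoid AUC and Youden cutoff.

    ``labels`` are boolean/0-1 (1 = positive class); ``positive_is_low``
    inverts the score so that low values mark positives.  Equal scores are
    treated as a single threshold.
    """
    s = np.asarray(score, dtype=float)
    y = np.asarray(labels).astype(bool)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    oriented = -s if positive_is_low else s
    thresholds = np.unique(oriented)[::-1]  # descending; predict positive if >= thr
    tpr = np.empty(thresholds.size + 2)
    fpr = np.empty(thresholds.size + 2)
    tpr[0], fpr[0] = 0.0, 0.0
    for i, thr in enumerate(thresholds, start=1):
        pred = oriented >= thr
        tpr[i] = (pred & y).sum() / n_pos
        fpr[i] = (pred & ~y).sum() / n_neg
    tpr[-1], fpr[-1] = 1.0, 1.0
    auc = float(np.trapezoid(tpr, fpr))
    j = tpr - fpr
    best = int(np.argmax(j[1:-1])) + 1 if thresholds.size else 0
    thr_opt = thresholds[best - 1] if thresholds.size else np.nan
    cutoff = -thr_opt if positive_is_low else thr_opt
    return ROCResult(
        thresholds=np.concatenate(([np.inf], thresholds, [-np.inf])),
        tpr=tpr,
        fpr=fpr,
        auc=auc,
        youden_cutoff=float(cutoff),
        sensitivity=float(tpr[best]) if thresholds.size else 0.0,
        specificity=float(1.0 - fpr[best]) if thresholds.size else 1.0,
        positive_is_low=positive_is_low,
    )


def biomarker_composite(
    bm: BetaMatrix, dmp_ids: Sequence[str], method: Literal["mean", "pc1"] = "mean"
) -> pd.Series:
    """Per-sample composite methylation score over a gene's DMPs."""
    ids = list(dmp_ids)
    if not ids:
        raise ValueError("empty DMP id set")
    idx = bm.probe_index()
    missing = [p for p in ids if p not in idx]
    if missing:
        raise KeyError(f"probes not in beta matrix: {missing[:5]}")
    sub = bm.beta[[idx[p] for p in ids]]
    if method == "mean":
        vals = np.nanmean(sub, axis=0)
    elif method == "pc1":
        X = sub.T - np.nanmean(sub.T, axis=0, keepdims=True)
        _, _, Vt = np.linalg.svd(np.nan_to_num(X), full_matrices=False)
        vals = np.nan_to_num(X) @ Vt[0]
        # orient PC1 to correlate positively with mean beta so it stays a
        # methylation-like score
        mean_score = np.nanmean(sub, axis=0)
        if np.corrcoef(vals, mean_score)[0, 1] < 0:
            vals = -vals
    else:
        raise ValueError(f"unknown composite method {method!r}")
    return pd.Series(vals, index=bm.sample_ids, name="composite")


def phenotype_correlation_matrix(
    bm: BetaMatrix,
    sheet: SampleSheet,
    dmp_ids: Sequence[str],
    variables: Sequence[str] = ("age", "ft3", "ft4", "tsh"),
) -> pd.DataFrame:
    """Tidy per-(probe, variable) correlation grid with the normality gate."""
    idx = bm.probe_index()
    rows = []
    order = {s: i for i, s in enumerate(bm.sample_ids)}
    cols = [order[s] for s in sheet.sample_ids]
    for var in variables:
        if var not in sheet.df.columns:
            logger.warning("variable %r missing from sample sheet; skipped", var)
            continue
        v = sheet.df[var].to_numpy(dtype=float)
        for pid in dmp_ids:
            beta = bm.beta[idx[pid]][cols]
            ok = np.isfinite(beta) & np.isfinite(v)
            if ok.sum() < 3 or np.ptp(v[ok]) == 0 or np.ptp(beta[ok]) == 0:
                logger.warning("skipping %s vs %s (degenerate data)", pid, var)
                continue
            res = correlate(beta[ok], v[ok], method="auto")
            rows.append(
                {
                    "probe_id": pid,
                    "variable": var,
                    "method": res.method,
                    "r": res.r,
                    "p": res.p,
                    "n": res.n,
                }
            )
    return pd.DataFrame(rows, columns=["probe_id", "variable", "method", "r", "p", "n"])
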