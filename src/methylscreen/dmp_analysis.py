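"""Differential methylation position calling and global methylation description.

Delta-beta is case mean minus control mean.  Two per-probe tests are offered:
a plain unequal-variance two-sample t, and an empirical-Bayes moderated t in
which per-probe pooled variances are shrunk toward a prior estimated from all
probes by moment matching on the log scale, with the prior degrees of freedom
added to the residual degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, NamedTuple

import numpy as np
import pandas as pd
from scipy import special, stats

from .manifest_io import BetaMatrix, Manifest, PROMOTER_REGIONS, SampleSheet


@dataclass(frozen=True)
class DMPRecord:
    probe_id: str
    mean_beta_case: float
    mean_beta_control: float
    delta_beta: float
    p_raw: float
    p_adj: float
    direction: str  # "hyper" | "hypo"


class GroupStats(NamedTuple):
    probe_ids: list[str]
    mean_case: np.ndarray
    mean_control: np.ndarray
    delta_beta: np.ndarray


def _split_groups(bm: BetaMatrix, sheet: SampleSheet) -> tuple[np.ndarray, np.ndarray]:
    if list(sheet.sample_ids) != list(bm.sample_ids):
        order = {s: i for i, s in enumerate(bm.sample_ids)}
        missing = [s for s in sheet.sample_ids if s not in order]
        if missing:
            raise ValueError(f"samples in sheet but not beta matrix: {missing[:5]}")
        cols = [order[s] for s in sheet.sample_ids]
        beta = bm.beta[:, cols]
    else:
        beta = bm.beta
    sheet.require_two_groups()
    case = beta[:, sheet.group_mask("case")]
    control = beta[:, sheet.group_mask("control")]
    return case, control


def group_stats(bm: BetaMatrix, sheet: SampleSheet) -> GroupStats:
    """Per-probe group means and delta-beta (case minus control)."""
    case, control = _split_groups(bm, sheet)
    mc = np.nanmean(case, axis=1)
    mn = np.nanmean(control, axis=1)
    return GroupStats(list(bm.probe_ids), mc, mn, mc - mn)


def _trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y by Newton iteration (monotone decreasing)."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif / x) < tol:
            break
    return float(x)


def _fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled inverse-chi-square prior to observed variances.

    Returns (d0, s0_sq); d0 may be inf when variances look homogeneous.
    """
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.mean(s2[ok])) if ok.any() else 1e-8
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def _welch_p(case: np.ndarray, control: np.ndarray) -> np.ndarray:
    res = stats.ttest_ind(case, control, axis=1, equal_var=False, nan_policy="omit")
    p = np.asarray(res.pvalue, dtype=float)
    # degenerate probes: zero variance in both groups
    v1 = np.nanvar(case, axis=1)
    v2 = np.nanvar(control, axis=1)
    degen = (v1 == 0) & (v2 == 0)
    if degen.any():
        equal = np.isclose(np.nanmean(case, axis=1), np.nanmean(control, axis=1))
        p[degen & equal] = 1.0
        p[degen & ~equal] = 0.0
    return np.clip(np.nan_to_num(p, nan=1.0), 0.0, 1.0)


def _moderated_p(case: np.ndarray, control: np.ndarray) -> np.ndarray:
    n1, n2 = case.shape[1], control.shape[1]
    df = n1 + n2 - 2
    m1 = np.nanmean(case, axis=1)
    m2 = np.nanmean(control, axis=1)
    ss = np.nansum((case - m1[:, None]) ** 2, axis=1) + np.nansum(
        (control - m2[:, None]) ** 2, axis=1
    )
    s2 = ss / df
    d0, s0_sq = _fit_variance_prior(s2, df)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = df + d0
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / se
    t = np.where(se == 0, 0.0, t)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return np.clip(p, 0.0, 1.0)


def dmp_test(
    bm: BetaMatrix,
    sheet: SampleSheet,
    method: Literal["welch_t", "moderated_t"] = "moderated_t",
) -> np.ndarray:
    """Two-sided per-probe p-values for the case/control mean difference."""
    case, control = _split_groups(bm, sheet)
    if method == "welch_t":
        return _welch_p(case, control)
    if method == "moderated_t":
        return _moderated_p(case, control)
    raise ValueError(f"unknown method {method!r}")


def adjust_bh(p_raw) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, returned in input order."""
    p = np.asarray(p_raw, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def call_dmps(
    gs: GroupStats,
    p_raw,
    p_adj,
    alpha: float = 0.05,
    delta_min: float = 0.1,
) -> list[DMPRecord]:
    """DMPs at adjusted p < alpha and |delta beta| > delta_min (both strict)."""
    p_raw = np.asarray(p_raw, dtype=float)
    p_adj = np.asarray(p_adj, dtype=float)
    out = []
    for i, pid in enumerate(gs.probe_ids):
        if p_adj[i] < alpha and abs(gs.delta_beta[i]) > delta_min:
            out.append(
                DMPRecord(
                    probe_id=pid,
                    mean_beta_case=float(gs.mean_case[i]),
                    mean_beta_control=float(gs.mean_control[i]),
                    delta_beta=float(gs.delta_beta[i]),
                    p_raw=float(p_raw[i]),
                    p_adj=float(p_adj[i]),
                    direction="hyper" if gs.delta_beta[i] > 0 else "hypo",
                )
            )
    return out


def run_dmp_analysis(
    bm: BetaMatrix,
    sheet: SampleSheet,
    method: Literal["welch_t", "moderated_t"] = "moderated_t",
    alpha: float = 0.05,
    delta_min: float = 0.1,
) -> tuple[list[DMPRecord], GroupStats, np.ndarray, np.ndarray]:
    """Full stage: stats, test, BH adjustment, calling."""
    gs = group_stats(bm, sheet)
    p_raw = dmp_test(bm, sheet, method=method)
    p_adj = adjust_bh(p_raw)
    return call_dmps(gs, p_raw, p_adj, alpha, delta_min), gs, p_raw, p_adj


def dmps_to_frame(dmps: list[DMPRecord]) -> pd.DataFrame:
    cols = [
        "probe_id",
        "mean_beta_case",
        "mean_beta_control",
        "delta_beta",
        "p_raw",
        "p_adj",
        "direction",
    ]
    return pd.DataFrame([d.__dict__ for d in dmps], columns=cols)


def dmps_from_frame(df: pd.DataFrame) -> list[DMPRecord]:
    return [
        DMPRecord(
            probe_id=str(r.probe_id),
            mean_beta_case=float(r.mean_beta_case),
            mean_beta_control=float(r.mean_beta_control),
            delta_beta=float(r.delta_beta),
            p_raw=float(r.p_raw),
            p_adj=float(r.p_adj),
            direction=str(r.direction),
        )
        for r in df.itertuples(index=False)
    ]


def pca_embed(bm: BetaMatrix, k: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Mean-centered principal-component scores for samples over the probes.

    Returns (scores frame indexed by sample with columns PC1..PCk, variance
    fractions per component).
    """
    X = bm.beta.T  # samples x probes
    n, p = X.shape
    if k > min(n, p):
        raise ValueError(f"k={k} exceeds min(n_samples, n_probes)={min(n, p)}")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, _ = np.linalg.svd(Xc, full_matrices=False)
    scores = U[:, :k] * S[:k]
    total = float((S**2).sum())
    frac = (S[:k] ** 2) / total if total > 0 else np.zeros(k)
    frame = pd.DataFrame(
        scores, index=bm.sample_ids, columns=[f"PC{i + 1}" for i in range(k)]
    )
    return frame, frac


REGION_SUBSETS = ("genome", "promoter", "IGR", "body", "3UTR", "5UTR")


def _region_probe_ids(manifest: Manifest, region: str, universe: set[str]) -> list[str]:
    if region == "genome":
        return [p.probe_id for p in manifest if p.probe_id in universe]
    out = []
    for p in manifest:
        if p.probe_id not in universe:
            continue
        regions = {r for _, r in p.gene_mappings}
        if region == "promoter" and regions & set(PROMOTER_REGIONS):
            out.append(p.probe_id)
        elif region == "IGR" and not regions:
            out.append(p.probe_id)
        elif region == "body" and "Body" in regions:
            out.append(p.probe_id)
        elif region == "3UTR" and "3UTR" in regions:
            out.append(p.probe_id)
        elif region == "5UTR" and "5UTR" in regions:
            out.append(p.probe_id)
    return out


def region_methylation_compare(
    bm: BetaMatrix, sheet: SampleSheet, manifest: Manifest, region: str = "genome"
) -> tuple[float, float, float]:
    """Pooled probe-x-sample beta comparison within a genomic-region subset.

    Returns (median_case, median_control, Mann-Whitney two-sided p).
    """
    if region not in REGION_SUBSETS:
        raise ValueError(f"unknown region {region!r}; choose from {REGION_SUBSETS}")
    ids = _region_probe_ids(manifest, region, set(bm.probe_ids))
    if not ids:
        raise ValueError(f"region {region!r} matches no probes")
    sub = bm.subset_probes(ids)
    case, control = _split_groups(sub, sheet)
    a = case.ravel()
    b = control.ravel()
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if np.array_equal(a, b):
        return float(np.median(a)), float(np.median(b)), 1.0
    stat = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(np.median(a)), float(np.median(b)), float(stat.pvalue)
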