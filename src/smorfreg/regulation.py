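"""Negative-binomial Wald differential expression with BH correction.

A deliberately transparent two-group re-implementation of the DESeq2 recipe:
median-of-ratios size factors, gene-wise method-of-moments dispersions
shrunk toward the panel mean (prior df estimated from the excess spread of
the gene-wise estimates over their sampling noise; without this moderation
the Wald test is badly anti-conservative at n=3 per group), per-group NB
mean MLEs at fixed dispersion, a Wald z from the observed information,
two-sided normal p-values and Benjamini-Hochberg adjustment.  No LFC
shrinkage, no Cook's filtering, no independent filtering.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

DEFAULT_LFC_MIN = 1.0
DEFAULT_FDR_MAX = 0.05
MIN_DISPERSION = 1e-8
_MEAN_FLOOR = 1e-8


def size_factors(cm: pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-sample normalization factors.

    Uses features with nonzero counts in every sample; the factor vector is
    renormalized to geometric mean 1.
    """
    counts = cm.to_numpy(dtype=float)
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no feature has nonzero counts in all samples; prefilter the matrix"
        )
    sub = counts[positive]
    log_geomean = np.log(sub).mean(axis=1)
    ratios = np.log(sub) - log_geomean[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=cm.columns, name="size_factor")


def _nb_loglik_grad(m: float, y: np.ndarray, s: np.ndarray, alpha: float) -> float:
    u = s * m
    return float(np.sum(y - (y + 1.0 / alpha) * (alpha * u) / (1.0 + alpha * u)))


def _fit_group_mean(y: np.ndarray, s: np.ndarray, alpha: float) -> float:
    """MLE of the NB mean parameter for one group at fixed dispersion."""
    if y.sum() == 0:
        return _MEAN_FLOOR
    hi = 10.0 * float(np.max(y / s)) + 1.0
    lo = 1e-12
    g_lo = _nb_loglik_grad(lo, y, s, alpha)
    g_hi = _nb_loglik_grad(hi, y, s, alpha)
    if g_lo <= 0:
        return lo
    if g_hi >= 0:
        return hi
    return float(optimize.brentq(lambda m: _nb_loglik_grad(m, y, s, alpha), lo, hi))


def _group_information(m: float, y: np.ndarray, s: np.ndarray, alpha: float) -> float:
    """Observed information for eta = log(mean) of one group at the MLE."""
    u = s * m
    return float(np.sum((y + 1.0 / alpha) * (alpha * u) / (1.0 + alpha * u) ** 2))


def _raw_mom_dispersions(
    norm: np.ndarray, groups: Sequence[np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature method-of-moments dispersions on normalized counts.

    Residuals are centered within each design group so planted fold-changes
    do not inflate the estimate.  Returns (raw alpha, per-feature mean);
    raw values may be negative (sub-Poisson samples) and are moderated
    downstream.
    """
    n = norm.shape[1]
    p = len(groups)
    ss = np.zeros(norm.shape[0])
    for idx in groups:
        sub = norm[:, idx]
        ss = ss + ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    var = ss / max(n - p, 1)
    mean = norm.mean(axis=1)
    safe_mean = np.maximum(mean, 1e-12)
    raw = (var - mean) / safe_mean**2
    return raw, mean


def _moderated_dispersions(
    raw: np.ndarray, mean: np.ndarray, n: int, p: int
) -> np.ndarray:
    """Shrink gene-wise MoM dispersions toward the panel mean.

    The prior degrees of freedom are estimated from the excess of the robust
    spread of log gene-wise estimates over their expected sampling noise
    (chi-square reference inflated by the Poisson share (1 + 1/(alpha*mu))^2).
    A panel whose spread is fully explained by sampling noise collapses to
    the pooled mean dispersion; genuinely heterogeneous panels retain
    gene-wise structure.
    """
    from scipy.special import polygamma

    d = max(n - p, 1)
    informative = mean > 1.0
    if informative.sum() >= 10:
        pool = raw[informative]
        hi = np.quantile(pool, 0.99)
        prior = float(np.mean(np.clip(pool, 0.0, hi)))
    else:
        prior = float(np.mean(raw)) if raw.size else MIN_DISPERSION
    prior = max(prior, MIN_DISPERSION)

    pos = (raw > 0) & informative
    if pos.sum() >= 10:
        lr = np.log(raw[pos])
        s2 = (1.4826 * np.median(np.abs(lr - np.median(lr)))) ** 2
        ref = float(polygamma(1, d / 2.0)) * float(
            np.median((1.0 + 1.0 / (prior * np.maximum(mean[pos], 1e-12))) ** 2)
        )
        excess = max(s2 - ref, 1e-3)
    else:
        excess = 1e-3
    # prior df from trigamma(d0/2) = excess
    d0 = 2.0 * float(
        optimize.brentq(lambda x: polygamma(1, x) - excess, 1e-3, 1e8)
    )
    w = d / (d0 + d)
    gene = np.maximum(raw, MIN_DISPERSION)
    alpha = np.exp((1.0 - w) * math.log(prior) + w * np.log(gene))
    return np.maximum(alpha, MIN_DISPERSION)


def nb_wald_de(
    cm: pd.DataFrame,
    design: Mapping[str, str],
    control: str,
    treatment: str,
    lfc_min: float = DEFAULT_LFC_MIN,
    fdr_max: float = DEFAULT_FDR_MAX,
    strict_lfc: bool = False,
    sf: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Two-group NB Wald differential expression (treatment vs control).

    Returns a DESeq2-style frame indexed by feature with columns baseMean,
    log2FoldChange, lfcSE, stat, pvalue, padj, significant.  All-zero
    features are excluded from testing and from the BH denominator.
    """
    design = dict(design)
    ctrl_samples = [s for s in cm.columns if design.get(s) == control]
    trt_samples = [s for s in cm.columns if design.get(s) == treatment]
    if len(ctrl_samples) < 2 or len(trt_samples) < 2:
        raise ValueError(
            "need >=2 samples per group for a dispersion estimate "
            f"(control={len(ctrl_samples)}, treatment={len(trt_samples)})"
        )
    # canonical sample order (matrix order, not group order) so that swapping
    # the control/treatment labels negates every log2fc bit-for-bit
    used = [s for s in cm.columns if s in set(ctrl_samples) | set(trt_samples)]
    sub = cm[used]
    if sf is None:
        sf = size_factors(sub)
    s = sf.loc[used].to_numpy(dtype=float)
    counts = sub.to_numpy(dtype=float)
    is_ctrl = np.array([design[x] == control for x in used])
    idx_c = np.where(is_ctrl)[0]
    idx_t = np.where(~is_ctrl)[0]
    ln2 = math.log(2.0)

    norm_all = counts / s
    raw, means = _raw_mom_dispersions(norm_all, (idx_c, idx_t))
    alphas = _moderated_dispersions(raw, means, len(used), 2)

    rows = []
    for i, fid in enumerate(sub.index):
        y = counts[i]
        if y.sum() == 0:
            rows.append((fid, 0.0, np.nan, np.nan, np.nan, np.nan))
            continue
        norm = norm_all[i]
        alpha = float(alphas[i])
        m0 = _fit_group_mean(y[idx_c], s[idx_c], alpha)
        m1 = _fit_group_mean(y[idx_t], s[idx_t], alpha)
        m0 = max(m0, _MEAN_FLOOR)
        m1 = max(m1, _MEAN_FLOOR)
        lfc = (math.log(m1) - math.log(m0)) / ln2
        info0 = _group_information(m0, y[idx_c], s[idx_c], alpha)
        info1 = _group_information(m1, y[idx_t], s[idx_t], alpha)
        var_eta = (1.0 / info0 if info0 > 0 else np.inf) + (
            1.0 / info1 if info1 > 0 else np.inf
        )
        se = math.sqrt(var_eta) / ln2
        z = lfc / se if se > 0 and np.isfinite(se) else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append((fid, float(norm.mean()), lfc, se, z, p))

    df = pd.DataFrame(
        rows,
        columns=["feature_id", "baseMean", "log2FoldChange", "lfcSE", "stat", "pvalue"],
    ).set_index("feature_id")
    tested = df["pvalue"].notna()
    padj = pd.Series(np.nan, index=df.index)
    if tested.any():
        padj[tested] = multipletests(df.loc[tested, "pvalue"], method="fdr_bh")[1]
    df["padj"] = padj
    if strict_lfc:
        big = df["log2FoldChange"].abs() > lfc_min
    else:
        big = df["log2FoldChange"].abs() >= lfc_min
    df["significant"] = big & (df["padj"] < fdr_max)
    df["significant"] = df["significant"].fillna(False)
    return df


def significant_sets(results: pd.DataFrame) -> dict[str, set]:
    sig = results[results["significant"]]
    return {
        "up": set(sig[sig["log2FoldChange"] > 0].index),
        "down": set(sig[sig["log2FoldChange"] < 0].index),
        "either": set(sig.index),
    }


def de_overlap(results_by_condition: Mapping[str, pd.DataFrame]) -> dict:
    """Venn partition counts of significant features across conditions,
    reported separately for up, down and either direction."""
    if len(results_by_condition) < 2:
        raise ValueError("need >=2 conditions for an overlap report")
    out: dict[str, dict] = {}
    for direction in ("up", "down", "either"):
        sets = {
            cond: significant_sets(res)[direction]
            for cond, res in results_by_condition.items()
        }
        universe = set().union(*sets.values())
        partitions: dict[str, int] = {}
        for feat in universe:
            members = tuple(c for c in sorted(sets) if feat in sets[c])
            key = "&".join(members)
            partitions[key] = partitions.get(key, 0) + 1
        out[direction] = dict(sorted(partitions.items()))
    return out


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """Plain BH adjustment (monotone, idempotent); exposed for testing."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]
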