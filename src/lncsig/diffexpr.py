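"""Transparent negative-binomial differential expression.

A deliberately simple, fully specified stand-in for the usual RNA-seq DE
stack: median-of-ratios size factors, method-of-moments dispersion,
per-feature Wald test with a delta-method standard error, BH adjustment,
FPKM, and a mean-count "expressed" filter.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .models import CountMatrix, ValidationError

__all__ = [
    "DEResult",
    "NormFactors",
    "size_factors",
    "estimate_dispersion",
    "nb_wald_test",
    "bh_adjust",
    "fpkm",
    "filter_expressed",
    "de_results_to_frame",
]

log = logging.getLogger(__name__)

PSEUDOCOUNT = 0.5
DISPERSION_FLOOR = 1e-8


@dataclass(frozen=True)
class DEResult:
    feature_id: str
    base_mean: float
    log2fc: float
    se: float
    p: float
    padj: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 and 0.0 <= self.padj <= 1.0):
            raise ValidationError(f"{self.feature_id}: p-values must be in [0,1]")
        if not np.isfinite(self.log2fc):
            raise ValidationError(f"{self.feature_id}: log2fc must be finite")
        if self.base_mean < 0:
            raise ValidationError(f"{self.feature_id}: base_mean must be >= 0")


class NormFactors(dict):
    """Mapping sample id -> positive size factor, geometric mean 1."""

    def as_array(self, sample_ids) -> np.ndarray:
        return np.array([self[s] for s in sample_ids], dtype=float)


def size_factors(cm: CountMatrix) -> NormFactors:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    For each all-positive feature the per-sample ratio to the feature's
    geometric mean is computed; a sample's factor is the median ratio.
    When no feature is positive in every sample, a pseudo-reference
    built from positive entries only is used instead (logged warning).
    """
    arr = cm.values.astype(float)
    if arr.shape[1] < 2:
        raise ValidationError("size factors need at least 2 samples")
    with np.errstate(divide="ignore"):
        logc = np.log(arr)
    allpos = (arr > 0).all(axis=1)
    if allpos.any():
        log_gm = logc[allpos].mean(axis=1)
        ratios = arr[allpos] / np.exp(log_gm)[:, None]
        s = np.median(ratios, axis=0)
    else:
        anypos = (arr > 0).any(axis=1)
        if not anypos.any():
            raise ValidationError("all counts are zero; size factors undefined")
        msg = "no feature with all-positive counts; falling back to positive-count pseudo-reference"
        log.warning(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=2)
        sub = logc[anypos]
        pos = np.isfinite(sub)
        log_gm = np.where(pos, sub, 0.0).sum(axis=1) / pos.sum(axis=1)
        s = np.empty(arr.shape[1])
        for j in range(arr.shape[1]):
            col = sub[:, j] - log_gm
            col = col[np.isfinite(col)]
            if col.size == 0:
                raise ValidationError(f"sample {cm.sample_ids[j]!r} has no positive counts")
            s[j] = np.median(np.exp(col))
    s = s / np.exp(np.mean(np.log(s)))
    return NormFactors(zip(cm.sample_ids, s))


def estimate_dispersion(
    cm: CountMatrix,
    factors: NormFactors,
    groups: dict[str, list[str]],
    floor: float = DISPERSION_FLOOR,
    method: str = "shrink",
    prior_df: float = 16.0,
) -> dict[str, float]:
    """Per-feature method-of-moments NB dispersion on normalized counts.

    The within-group sample variance is pooled across groups and
    combined with the overall normalized mean:
    ``alpha_raw = (s2 - mu) / mu**2``.

    method="mom" returns ``max(alpha_raw, floor)`` per feature.  At
    small replicate numbers that raw estimate is so noisy (about half
    the estimates collapse to the floor) that the downstream Wald test
    is badly anti-conservative, so the default method="shrink" pulls
    each estimate toward a robust cross-feature center with ``prior_df``
    pseudo-degrees-of-freedom before flooring.
    """
    if method not in ("mom", "shrink"):
        raise ValidationError(f"unknown dispersion method {method!r}")
    sample_index = {s: i for i, s in enumerate(cm.sample_ids)}
    for name, members in groups.items():
        if len(members) < 2:
            raise ValidationError(f"group {name!r} has {len(members)} sample(s); replication required")
    arr = cm.values.astype(float)
    sf = factors.as_array(cm.sample_ids)
    norm = arr / sf[None, :]

    ss = np.zeros(arr.shape[0])
    df = 0
    used: list[int] = []
    for members in groups.values():
        idx = [sample_index[s] for s in members]
        used.extend(idx)
        sub = norm[:, idx]
        ss += sub.var(axis=1, ddof=1) * (len(idx) - 1)
        df += len(idx) - 1
    s2 = ss / df
    mu = norm[:, used].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(mu > 0, (s2 - mu) / np.maximum(mu, 1e-300) ** 2, 0.0)
    if method == "mom":
        alpha = np.maximum(raw, floor)
    else:
        clipped = np.clip(raw, 0.0, np.quantile(raw, 0.99) if raw.size else 0.0)
        center = float(clipped.mean()) if raw.size else 0.0
        alpha = np.maximum((df * np.maximum(raw, 0.0) + prior_df * center) / (df + prior_df), floor)
    return dict(zip(cm.feature_ids, alpha))


def nb_wald_test(
    cm: CountMatrix,
    factors: NormFactors,
    dispersions: dict[str, float],
    group_a: list[str],
    group_b: list[str],
    pseudocount: float = PSEUDOCOUNT,
) -> list[DEResult]:
    """Per-feature Wald test of condition B over condition A.

    log2fc = log2((mean normalized B + c) / (mean normalized A + c));
    the standard error comes from the delta method applied to the NB
    variance mu + alpha*mu^2 of each sample's normalized count.
    """
    if set(group_a) & set(group_b):
        raise ValidationError("groups must be disjoint")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValidationError("each group needs >= 2 samples")
    missing = [f for f in cm.feature_ids if f not in dispersions]
    if missing:
        raise ValidationError(f"features missing from dispersion map: {missing[:5]}")

    sample_index = {s: i for i, s in enumerate(cm.sample_ids)}
    ia = [sample_index[s] for s in group_a]
    ib = [sample_index[s] for s in group_b]
    arr = cm.values.astype(float)
    sf = factors.as_array(cm.sample_ids)
    norm = arr / sf[None, :]
    alpha = np.array([dispersions[f] for f in cm.feature_ids])

    c = pseudocount
    m_a = norm[:, ia].mean(axis=1)
    m_b = norm[:, ib].mean(axis=1)
    lfc = np.log2((m_b + c) / (m_a + c))

    def var_of_group_mean(mean_norm: np.ndarray, idx: list[int]) -> np.ndarray:
        mu = mean_norm + c
        v = np.zeros_like(mu)
        for j in idx:
            v += mu / sf[j] + alpha * mu**2
        return v / len(idx) ** 2

    ln2 = np.log(2.0)
    var_a = var_of_group_mean(m_a, ia) / (m_a + c) ** 2
    var_b = var_of_group_mean(m_b, ib) / (m_b + c) ** 2
    se = np.sqrt(var_a + var_b) / ln2
    z = lfc / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    padj = bh_adjust(list(p))
    base_mean = norm[:, ia + ib].mean(axis=1)
    return [
        DEResult(f, float(bm), float(l), float(s), float(pp), float(pa))
        for f, bm, l, s, pp, pa in zip(cm.feature_ids, base_mean, lfc, se, p, padj)
    ]


def bh_adjust(pvals: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValidationError("p-values must be in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return list(out)


def fpkm(cm: CountMatrix, totals: dict[str, float] | None = None) -> pd.DataFrame:
    """Fragments per kilobase per million mapped reads.

    ``FPKM_ij = count_ij / (length_i/1000 * total_j/1e6)``.  Totals
    default to each sample's column sum.
    """
    missing = [f for f in cm.feature_ids if f not in cm.feature_lengths]
    if missing:
        raise ValidationError(f"features without length: {missing[:5]}")
    lengths = np.array([cm.feature_lengths[f] for f in cm.feature_ids], dtype=float)
    if (lengths <= 0).any():
        raise ValidationError("feature lengths must be > 0")
    if totals is None:
        tot = cm.values.sum(axis=0).astype(float)
    else:
        tot = np.array([totals[s] for s in cm.sample_ids], dtype=float)
    if (tot <= 0).any():
        raise ValidationError("per-sample totals must be > 0")
    vals = cm.values / (lengths[:, None] / 1e3 * tot[None, :] / 1e6)
    return pd.DataFrame(vals, index=cm.feature_ids, columns=cm.sample_ids)


def filter_expressed(
    cm: CountMatrix,
    factors: NormFactors,
    min_mean: float = 1.0,
    condition: str | None = None,
) -> list[str]:
    """Feature ids whose mean normalized count in ``condition`` (or over
    all samples when None) is at least ``min_mean``."""
    if condition is None:
        samples = cm.sample_ids
    else:
        if condition not in set(cm.condition.values()):
            raise ValidationError(f"unknown condition label {condition!r}")
        samples = cm.samples_in(condition)
    idx = [cm.sample_ids.index(s) for s in samples]
    sf = factors.as_array(cm.sample_ids)
    norm = cm.values.astype(float) / sf[None, :]
    means = norm[:, idx].mean(axis=1)
    return [f for f, m in zip(cm.feature_ids, means) if m >= min_mean]


def de_results_to_frame(results: list[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in results],
            "base_mean": [r.base_mean for r in results],
            "log2fc": [r.log2fc for r in results],
            "se": [r.se for r in results],
            "p": [r.p for r in results],
            "padj": [r.padj for r in results],
        }
    ).set_index("feature_id")
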