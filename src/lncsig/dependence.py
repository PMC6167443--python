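"""Knockout-reversal analysis of the core signature and cross-dataset
fold-change concordance.

Reversal is defined on the KO-vs-WT log2 fold change: an up-set feature
is reversed when it drops by at least the threshold in the knockout, a
down-set feature when it rises by at least the threshold; the
non-differential background uses the direction-free rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb, sqrt
from statistics import median
from typing import Mapping

import numpy as np
from scipy import stats

from .diffexpr import DEResult
from .models import ValidationError
from .signature import SignatureSet

__all__ = [
    "ReversalReport",
    "reversal_flags",
    "reversal_report",
    "mann_whitney",
    "cross_dataset_concordance",
]

LFC_THRESHOLD = 0.5
EXACT_MW_LIMIT = 16


@dataclass
class ReversalReport:
    per_set: dict  # set name -> {n, median_ko_lfc, fraction_reversed}
    fisher_odds_ratio: float | None
    fisher_p: float | None
    rank_tests: dict  # set name -> {U, p} vs nondiff


def _ko_lfc_map(ko_results: list[DEResult]) -> dict[str, float]:
    return {r.feature_id: r.log2fc for r in ko_results}


def reversal_flags(sig: SignatureSet, ko_results: list[DEResult],
                   lfc_threshold: float = LFC_THRESHOLD) -> dict[str, bool]:
    lfc = _ko_lfc_map(ko_results)
    missing = sig.universe - set(lfc)
    if missing:
        raise ValidationError(f"features missing from KO results: {sorted(missing)[:5]}")
    out: dict[str, bool] = {}
    for f in sig.up:
        out[f] = lfc[f] <= -lfc_threshold
    for f in sig.down:
        out[f] = lfc[f] >= lfc_threshold
    for f in sig.nondiff:
        out[f] = abs(lfc[f]) >= lfc_threshold
    return out


def reversal_report(sig: SignatureSet, ko_results: list[DEResult],
                    lfc_threshold: float = LFC_THRESHOLD) -> ReversalReport:
    """Fractions reversed per set, Fisher enrichment of core reversal
    over the non-differential background, and Mann-Whitney rank tests of
    the KO fold changes (down-set sign-flipped) against nondiff."""
    flags = reversal_flags(sig, ko_results, lfc_threshold)
    lfc = _ko_lfc_map(ko_results)

    per_set = {}
    for name, members in (("up", sig.up), ("down", sig.down), ("nondiff", sig.nondiff)):
        vals = [lfc[f] for f in members]
        per_set[name] = {
            "n": len(members),
            "median_ko_lfc": median(vals) if vals else None,
            "fraction_reversed": (sum(flags[f] for f in members) / len(members)) if members else None,
        }

    core_rev = sum(flags[f] for f in sig.core)
    nd_rev = sum(flags[f] for f in sig.nondiff)
    if sig.core and sig.nondiff:
        # the reversal claim is directional, so the enrichment p is the
        # one-sided (greater) hypergeometric tail; the direction-free
        # background rate would otherwise make the two-sided test fire
        # on core *depletion* under a null knockout
        b, d = len(sig.core) - core_rev, len(sig.nondiff) - nd_rev
        odds = (core_rev * d) / (b * nd_rev) if b * nd_rev > 0 else None
        n_tot = len(sig.core) + len(sig.nondiff)
        p = float(stats.hypergeom.sf(core_rev - 1, n_tot, core_rev + nd_rev, len(sig.core)))
    else:
        odds, p = None, None

    rank_tests = {}
    nd_vals = [lfc[f] for f in sig.nondiff]
    for name, members, sign in (("up", sig.up, 1.0), ("down", sig.down, -1.0)):
        vals = [sign * lfc[f] for f in members]
        if vals and nd_vals:
            u, pu = mann_whitney(vals, [sign * v for v in nd_vals])
            rank_tests[name] = {"U": u, "p": pu}
        else:
            rank_tests[name] = {"U": None, "p": None, "note": "empty set"}
    return ReversalReport(per_set=per_set, fisher_odds_ratio=odds, fisher_p=p,
                          rank_tests=rank_tests)


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    # number of (x_i, y_j) pairs with x_i > y_j, ties counting 1/2
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def mann_whitney(x: list[float], y: list[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U with midrank ties.

    Exact p by full enumeration of group assignments when the pooled
    size is at most 16 (ties handled by enumerating the observed
    pooled values), otherwise a normal approximation with tie and
    continuity corrections.
    """
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("mann_whitney requires non-empty samples")
    xa, ya = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    nx, ny = len(xa), len(ya)
    u_obs = _u_statistic(xa, ya)
    mean_u = nx * ny / 2.0

    n = nx + ny
    if n <= EXACT_MW_LIMIT:
        pooled = np.concatenate([xa, ya])
        dev_obs = abs(u_obs - mean_u)
        hits = 0
        total = comb(n, nx)
        idx = np.arange(n)
        for chosen in combinations(range(n), nx):
            mask = np.zeros(n, dtype=bool)
            mask[list(chosen)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            if abs(u - mean_u) >= dev_obs - 1e-12:
                hits += 1
        return u_obs, hits / total

    pooled = np.concatenate([xa, ya])
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum())) / (n * (n - 1))
    var_u = nx * ny / 12.0 * ((n + 1) - tie_term)
    if var_u <= 0:
        return u_obs, 1.0
    dev = abs(u_obs - mean_u)
    z = max(dev - 0.5, 0.0) / sqrt(var_u)
    return u_obs, float(min(1.0, 2.0 * stats.norm.sf(z)))


def cross_dataset_concordance(lfc_a: Mapping[str, float], lfc_b: Mapping[str, float]) -> dict:
    """Pearson r, Spearman rho and sign concordance of two fold-change
    maps over their shared feature ids (zero fold changes are excluded
    from sign concordance)."""
    shared = sorted(set(lfc_a) & set(lfc_b))
    if len(shared) < 3:
        raise ValidationError(f"need >= 3 shared features, found {len(shared)}")
    a = np.array([lfc_a[f] for f in shared])
    b = np.array([lfc_b[f] for f in shared])
    pearson = float(stats.pearsonr(a, b).statistic)
    spearman = float(stats.spearmanr(a, b).statistic)
    nz = (a != 0) & (b != 0)
    concord = float((np.sign(a[nz]) == np.sign(b[nz])).mean()) if nz.any() else float("nan")
    return {
        "n_shared": len(shared),
        "pearson_r": pearson,
        "spearman_rho": spearman,
        "sign_concordance": concord,
    }
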