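"""Signature calling and positional classification of lncRNA.

Calls up/down/non-differential sets from DE results, summarizes them,
and classifies each lncRNA by genomic position relative to
protein-coding genes (sense / antisense / lincRNA, plus an intronic
flag for loci lying wholly inside a coding gene's intron).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from .coloc import fisher_exact_2x2
from .diffexpr import DEResult
from .models import GeneModel, GenomeAnnotation, ValidationError

__all__ = [
    "SignatureSet",
    "PositionalClass",
    "call_signature",
    "summarize_signature",
    "classify_position",
    "classify_all",
    "positional_enrichment",
]

log = logging.getLogger(__name__)

CATEGORIES = ("sense", "antisense", "lincRNA")


@dataclass
class SignatureSet:
    """Disjoint up / down / non-differential feature sets partitioning
    the expressed universe."""

    up: set[str]
    down: set[str]
    nondiff: set[str]
    alpha: float
    universe_size: int = field(init=False)

    def __post_init__(self) -> None:
        if self.up & self.down or self.up & self.nondiff or self.down & self.nondiff:
            raise ValidationError("up/down/nondiff sets must be pairwise disjoint")
        self.universe_size = len(self.up) + len(self.down) + len(self.nondiff)

    @property
    def core(self) -> set[str]:
        return self.up | self.down

    @property
    def universe(self) -> set[str]:
        return self.up | self.down | self.nondiff


@dataclass
class PositionalClass:
    """Positional category and intronic flag per feature id."""

    category: dict[str, str]
    intronic: dict[str, bool]

    def __post_init__(self) -> None:
        bad = {f: c for f, c in self.category.items() if c not in CATEGORIES}
        if bad:
            raise ValidationError(f"unknown positional categories: {bad}")


def call_signature(results: list[DEResult], expressed: set[str], alpha: float = 0.05,
                   use_raw_p: bool = False) -> SignatureSet:
    """Partition the expressed universe by DE significance at ``alpha``.

    up: significant with log2fc > 0; down: significant with log2fc < 0;
    nondiff: everything else.  Significance uses BH-adjusted p unless
    ``use_raw_p``.
    """
    by_id = {r.feature_id: r for r in results}
    missing = expressed - set(by_id)
    if missing:
        raise ValidationError(f"expressed features missing from results: {sorted(missing)[:5]}")
    up, down = set(), set()
    for f in expressed:
        r = by_id[f]
        sig = (r.p if use_raw_p else r.padj) < alpha
        if sig and r.log2fc > 0:
            up.add(f)
        elif sig and r.log2fc < 0:
            down.add(f)
    return SignatureSet(up=up, down=down, nondiff=expressed - up - down, alpha=alpha)


def summarize_signature(sig: SignatureSet) -> dict:
    """Counts plus the percentage of the universe that is differential,
    reported to one decimal.

    The percentage is truncated (not rounded) to one decimal place: the
    headline figure this reproduces was evidently truncated at the
    source (245/1765 prints as 13.8, not 13.9).
    """
    if sig.universe_size == 0:
        raise ValidationError("empty expressed universe")
    n_up, n_down = len(sig.up), len(sig.down)
    pct = math.floor(1000.0 * (n_up + n_down) / sig.universe_size + 1e-9) / 10.0
    return {
        "n_up": n_up,
        "n_down": n_down,
        "n_expressed": sig.universe_size,
        "pct_differential": pct,
    }


def classify_position(lnc: GeneModel, annotation: GenomeAnnotation) -> tuple[str, bool]:
    """Classify a lncRNA against the coding genes of ``annotation``.

    sense: span overlap with a coding gene on the same strand (wins on
    ties); antisense: overlap only on the opposite strand; lincRNA: no
    overlap.  The intronic flag is true when the lncRNA lies entirely
    within some coding gene's span yet overlaps none of its exons.
    """
    if lnc.biotype != "lncRNA":
        raise ValidationError(f"{lnc.id}: classify_position requires biotype lncRNA, got {lnc.biotype!r}")
    same = opposite = False
    intronic = False
    for g in annotation.genes:
        if g.biotype != "coding" or g.chrom != lnc.chrom:
            continue
        if not g.overlaps(lnc.start, lnc.end):
            continue
        if g.strand == lnc.strand:
            same = True
        else:
            opposite = True
        if g.start <= lnc.start and lnc.end <= g.end:
            if not any(a < lnc.end and lnc.start < b for a, b in g.exons):
                intronic = True
    if same and opposite:
        log.debug("%s overlaps coding genes on both strands; sense precedence", lnc.id)
    if same:
        return "sense", intronic
    if opposite:
        return "antisense", intronic
    return "lincRNA", False


def classify_all(annotation: GenomeAnnotation, features: list[str] | None = None) -> PositionalClass:
    lncs = annotation.lncrnas()
    if features is not None:
        wanted = set(features)
        lncs = [g for g in lncs if g.id in wanted]
    category, intronic = {}, {}
    for g in lncs:
        category[g.id], intronic[g.id] = classify_position(g, annotation)
    return PositionalClass(category=category, intronic=intronic)


def positional_enrichment(sig: SignatureSet, classes: PositionalClass) -> dict:
    """Per-category proportions and Fisher tests of each core set
    against the non-differential background."""
    missing = sig.universe - set(classes.category)
    if missing:
        raise ValidationError(f"features without positional class: {sorted(missing)[:5]}")
    report: dict = {}
    n_nondiff = len(sig.nondiff)
    for cat in CATEGORIES:
        cat_report: dict = {}
        nondiff_in = sum(1 for f in sig.nondiff if classes.category[f] == cat)
        cat_report["nondiff"] = {
            "n": n_nondiff,
            "proportion": nondiff_in / n_nondiff if n_nondiff else float("nan"),
        }
        for name, members in (("up", sig.up), ("down", sig.down)):
            n_set = len(members)
            set_in = sum(1 for f in members if classes.category[f] == cat)
            entry: dict = {
                "n": n_set,
                "proportion": set_in / n_set if n_set else float("nan"),
            }
            if n_set == 0:
                entry["odds_ratio"] = None
                entry["p"] = None
                entry["note"] = "empty core set; test not applicable"
            else:
                odds, p = fisher_exact_2x2(set_in, n_set - set_in, nondiff_in, n_nondiff - nondiff_in)
                entry["odds_ratio"] = odds
                entry["p"] = p
            cat_report[name] = entry
        report[cat] = cat_report
    return report
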