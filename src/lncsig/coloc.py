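"""ChIP-peak colocalization: promoter/gene-body peak flags per feature
and core-vs-nondiff enrichment."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

from scipy.stats import hypergeom

from .models import GeneModel, GenomeAnnotation, Peak, ValidationError

if TYPE_CHECKING:  # circular at runtime only
    from .signature import SignatureSet

__all__ = [
    "PeakFlags",
    "promoter_region",
    "has_peak",
    "count_peaks",
    "compute_peak_flags",
    "fisher_exact_2x2",
    "peak_enrichment",
]

PROMOTER_UP = 2000
PROMOTER_DOWN = 500


@dataclass
class PeakFlags:
    """Per-feature boolean peak presence, with the promoter extents used."""

    flags: dict[str, bool]
    n_peaks: dict[str, int] = field(default_factory=dict)
    promoter_up: int = PROMOTER_UP
    promoter_down: int = PROMOTER_DOWN

    def __post_init__(self) -> None:
        if self.promoter_up < 0 or self.promoter_down < 0:
            raise ValidationError("promoter extents must be non-negative")


def promoter_region(gene: GeneModel, upstream: int = PROMOTER_UP, downstream: int = PROMOTER_DOWN,
                    chrom_length: int | None = None) -> tuple[int, int]:
    """Strand-aware promoter window around the TSS, clipped to the
    chromosome: + strand [start-up, start+down); - strand
    [end-down, end+up)."""
    if upstream < 0 or downstream < 0:
        raise ValidationError("promoter extents must be non-negative")
    if gene.strand == "+":
        lo, hi = gene.start - upstream, gene.start + downstream
    else:
        lo, hi = gene.end - downstream, gene.end + upstream
    lo = max(lo, 0)
    if chrom_length is not None:
        hi = min(hi, chrom_length)
    return lo, hi


def _intervals(gene: GeneModel, upstream: int, downstream: int,
               chrom_length: int | None) -> list[tuple[int, int]]:
    prom = promoter_region(gene, upstream, downstream, chrom_length)
    out = [(gene.start, gene.end)]
    if prom[0] < prom[1]:
        out.append(prom)
    return out


def has_peak(gene: GeneModel, peaks: Sequence[Peak], upstream: int = PROMOTER_UP,
             downstream: int = PROMOTER_DOWN, chrom_length: int | None = None) -> bool:
    """True iff any peak overlaps >=1 bp of the gene body or promoter
    window (same chromosome; peak strand is ignored)."""
    regions = _intervals(gene, upstream, downstream, chrom_length)
    for p in peaks:
        if p.chrom != gene.chrom:
            continue
        for lo, hi in regions:
            if p.start < hi and lo < p.end:
                return True
    return False


def count_peaks(gene: GeneModel, peaks: Sequence[Peak], upstream: int = PROMOTER_UP,
                downstream: int = PROMOTER_DOWN, chrom_length: int | None = None) -> int:
    regions = _intervals(gene, upstream, downstream, chrom_length)
    return sum(
        1
        for p in peaks
        if p.chrom == gene.chrom and any(p.start < hi and lo < p.end for lo, hi in regions)
    )


def compute_peak_flags(annotation: GenomeAnnotation, peaks: Sequence[Peak],
                       features: Sequence[str] | None = None,
                       upstream: int = PROMOTER_UP, downstream: int = PROMOTER_DOWN) -> PeakFlags:
    genes = annotation.lncrnas() if features is None else [annotation[f] for f in features]
    by_chrom: dict[str, list[Peak]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)
    flags, counts = {}, {}
    for g in genes:
        cl = annotation.chrom_lengths.get(g.chrom)
        sub = by_chrom.get(g.chrom, [])
        counts[g.id] = count_peaks(g, sub, upstream, downstream, cl)
        flags[g.id] = counts[g.id] > 0
    return PeakFlags(flags=flags, n_peaks=counts, promoter_up=upstream, promoter_down=downstream)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> tuple[float | None, float]:
    """Fisher's exact test on the table [[a, b], [c, d]].

    Returns the sample odds ratio (None when b*c == 0 makes it
    undefined, unless the table is degenerate-zero in the numerator
    too) and the two-sided p-value: the sum of hypergeometric
    probabilities, margins fixed, of tables no more probable than the
    one observed.
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValidationError("table entries must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    if n == 0:
        raise ValidationError("all-zero 2x2 table")
    if b * c > 0:
        odds: float | None = (a * d) / (b * c)
    else:
        odds = None  # a zero denominator cell: flagged not-applicable
    row1, col1 = a + b, a + c
    rv = hypergeom(n, row1, col1)
    lo = max(0, col1 - (c + d))
    hi = min(row1, col1)
    p_obs = rv.pmf(a)
    total = 0.0
    for k in range(lo, hi + 1):
        pk = rv.pmf(k)
        if pk <= p_obs * (1 + 1e-9):
            total += pk
    return odds, float(min(total, 1.0))


def peak_enrichment(sig: "SignatureSet", flags: PeakFlags) -> dict:
    """Compare peak frequency in the core (up+down) set against the
    non-differential background: frequencies, their ratio, Fisher OR
    and p, plus a per-direction breakdown."""
    missing = sig.universe - set(flags.flags)
    if missing:
        raise ValidationError(f"features without peak flags: {sorted(missing)[:5]}")
    if not sig.nondiff:
        raise ValidationError("empty non-differential background")

    def freq(members: set[str]) -> tuple[int, float]:
        k = sum(1 for f in members if flags.flags[f])
        return k, (k / len(members) if members else float("nan"))

    report: dict = {}
    k_nd, f_nd = freq(sig.nondiff)
    for name, members in (("core", sig.core), ("up", sig.up), ("down", sig.down)):
        k, f = freq(members)
        entry: dict = {"n": len(members), "n_with_peak": k, "frequency": f,
                       "nondiff_frequency": f_nd}
        if not members:
            entry.update(ratio=None, odds_ratio=None, p=None, note="empty set")
        else:
            entry["ratio"] = (f / f_nd) if f_nd > 0 else None
            odds, p = fisher_exact_2x2(k, len(members) - k, k_nd, len(sig.nondiff) - k_nd)
            entry["odds_ratio"] = odds
            entry["p"] = p
        report[name] = entry
    report["nondiff"] = {"n": len(sig.nondiff), "n_with_peak": k_nd, "frequency": f_nd}
    report["promoter_up"] = flags.promoter_up
    report["promoter_down"] = flags.promoter_down
    return report
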