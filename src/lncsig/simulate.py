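"""Synthetic data with planted structure for every downstream analysis.

Each generator is a pure function of its configuration and seed:
annotations with lncRNA placed to realize assigned positional classes,
ChIP peaks enriched at core-signature loci, negative-binomial counts
with planted fold changes that revert in the knockout condition,
pairwise alignments with planted conserved blocks, and qPCR plates with
planted folds.  The planted ground truth is returned alongside so
recovery can be measured.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .models import (
    AlignmentPair,
    CountMatrix,
    GeneModel,
    GenomeAnnotation,
    Peak,
    ValidationError,
)

__all__ = [
    "SimConfig",
    "SimTruth",
    "TruthRecord",
    "rng_for",
    "simulate_annotation",
    "simulate_peaks",
    "simulate_counts",
    "simulate_alignment",
    "simulate_qpcr",
    "write_truth",
    "read_truth",
]

CONDITIONS = ("naive", "treg_wt", "treg_kiko")


def rng_for(seed: int, stage: str) -> np.random.Generator:
    """A generator keyed by (seed, stage name): adding a stage never
    perturbs another stage's stream."""
    digest = hashlib.sha256(stage.encode()).digest()
    stage_key = int.from_bytes(digest[:8], "big")
    return np.random.default_rng(np.random.SeedSequence([seed, stage_key]))


@dataclass(frozen=True)
class SimConfig:
    n_coding: int = 500
    n_lnc: int = 2000
    n_up: int = 190
    n_down: int = 55
    lfc_mean: float = 2.0
    lfc_sd: float = 0.5
    dispersion: float = 0.1
    reps: int = 3
    peak_rate_base: float = 0.2
    peak_enrich: float = 2.0
    background_peak_rate: float = 5e-6  # peaks per bp of genome
    reversal_prob: float = 0.8
    position_mix: tuple[float, float, float] = (0.15, 0.15, 0.70)  # sense, antisense, lincRNA
    mean_log: float = 5.0
    sd_log: float = 1.5
    size_factor_range: tuple[float, float] = (0.5, 2.0)
    chrom_length: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_up + self.n_down > self.n_lnc:
            raise ValidationError("n_up + n_down must not exceed n_lnc")
        for name in ("peak_rate_base", "reversal_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0,1], got {v}")
        if self.dispersion <= 0:
            raise ValidationError("dispersion must be > 0")
        if self.reps < 2:
            raise ValidationError("reps must be >= 2")
        if abs(sum(self.position_mix) - 1.0) > 1e-9 or any(p < 0 for p in self.position_mix):
            raise ValidationError("position_mix must be non-negative and sum to 1")
        if self.peak_enrich < 0 or self.background_peak_rate < 0:
            raise ValidationError("peak rates must be non-negative")


@dataclass
class TruthRecord:
    feature_id: str
    core_direction: str  # up | down | none
    true_lfc: float
    positional_class: str  # sense | antisense | lincRNA
    has_planted_peak: bool = False
    reverts_in_ko: bool = False

    def __post_init__(self) -> None:
        if self.core_direction == "up" and self.true_lfc <= 0:
            raise ValidationError(f"{self.feature_id}: up direction needs positive lfc")
        if self.core_direction == "down" and self.true_lfc >= 0:
            raise ValidationError(f"{self.feature_id}: down direction needs negative lfc")
        if self.core_direction == "none" and self.true_lfc != 0:
            raise ValidationError(f"{self.feature_id}: non-core features have lfc 0")


@dataclass
class SimTruth:
    records: dict[str, TruthRecord]

    def in_direction(self, direction: str) -> set[str]:
        return {f for f, r in self.records.items() if r.core_direction == direction}

    @property
    def core(self) -> set[str]:
        return self.in_direction("up") | self.in_direction("down")


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

# cassette layout (bp, relative): coding gene spans [2000, 8000) with
# exons [2000,3500) and [6500,8000); lincRNA slots sit in the 12 kb gap
_CASSETTE = 20_000
_GENE_REL = (2000, 8000)
_EXONS_REL = ((2000, 3500), (6500, 8000))
_INTRON_REL = (3500, 6500)


def simulate_annotation(config: SimConfig) -> tuple[GenomeAnnotation, SimTruth]:
    """Lay out coding genes on tiled cassettes and place each lncRNA to
    realize its sampled positional class exactly.

    When any sense-class lncRNA is present, the first one is placed
    wholly inside its host gene's intron (intronic flag planted).
    """
    rng = rng_for(config.seed, "annotation")
    n_slots = config.n_coding + config.n_lnc
    needed = n_slots * _CASSETTE
    chrom_len = config.chrom_length if config.chrom_length is not None else needed
    if chrom_len < needed:
        raise ValidationError(
            f"chromosome length {chrom_len} too short; need >= {needed} "
            f"({n_slots} slots x {_CASSETTE} bp) - increase chrom_length or reduce feature counts"
        )
    chrom = "chrS1"
    genes: list[GeneModel] = []

    coding_offsets = []
    for i in range(config.n_coding):
        off = i * _CASSETTE
        coding_offsets.append(off)
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneModel(
                id=f"pc{i:05d}", chrom=chrom, strand=strand,
                start=off + _GENE_REL[0], end=off + _GENE_REL[1], biotype="coding",
                exons=tuple((off + a, off + b) for a, b in _EXONS_REL),
            )
        )

    # assign classes, core membership, lfcs
    classes = rng.choice(np.array(["sense", "antisense", "lincRNA"]),
                         size=config.n_lnc, p=list(config.position_mix))
    lnc_ids = [f"lnc{i:05d}" for i in range(config.n_lnc)]
    core_idx = rng.choice(config.n_lnc, size=config.n_up + config.n_down, replace=False)
    directions = {}
    for k, i in enumerate(core_idx):
        directions[i] = "up" if k < config.n_up else "down"
    lfc_mag = np.abs(rng.normal(config.lfc_mean, config.lfc_sd, config.n_lnc))
    lfc_mag = np.maximum(lfc_mag, 0.25)  # keep planted effects non-trivial
    reverts = rng.random(config.n_lnc) < config.reversal_prob

    records: dict[str, TruthRecord] = {}
    if config.n_coding == 0 and any(c in ("sense", "antisense") for c in classes):
        raise ValidationError("sense/antisense lncRNA require n_coding > 0")

    intronic_planted = False
    host_cycle = 0
    for i, (lid, cls) in enumerate(zip(lnc_ids, classes)):
        slot_off = (config.n_coding + i) * _CASSETTE
        if cls == "lincRNA":
            # own cassette, far from any coding gene
            start = slot_off + 9000 + int(rng.integers(0, 2000))
            end = start + int(rng.integers(500, 2500))
            strand = "+" if rng.random() < 0.5 else "-"
            exons = ((start, end),)
        else:
            host = genes[host_cycle % config.n_coding]
            host_cycle += 1
            off = coding_offsets[(host_cycle - 1) % config.n_coding]
            if cls == "sense" and not intronic_planted:
                # fully inside the host intron, same strand
                start = off + _INTRON_REL[0] + 200
                end = off + _INTRON_REL[1] - 200
                intronic_planted = True
            else:
                # overlap the host span; jitter so copies differ
                start = off + _GENE_REL[0] + int(rng.integers(0, 2000))
                end = start + int(rng.integers(1500, 4000))
            strand = host.strand if cls == "sense" else ("-" if host.strand == "+" else "+")
            exons = ((start, end),)
        genes.append(GeneModel(id=lid, chrom=chrom, strand=strand, start=start, end=end,
                               biotype="lncRNA", exons=exons))
        direction = directions.get(i, "none")
        if direction == "up":
            lfc = float(lfc_mag[i])
        elif direction == "down":
            lfc = -float(lfc_mag[i])
        else:
            lfc = 0.0
        records[lid] = TruthRecord(
            feature_id=lid, core_direction=direction, true_lfc=lfc,
            positional_class=str(cls),
            reverts_in_ko=bool(reverts[i]) if direction != "none" else False,
        )
    annotation = GenomeAnnotation(genes=genes, chrom_lengths={chrom: chrom_len})
    return annotation, SimTruth(records=records)


# ---------------------------------------------------------------------------
# Peaks
# ---------------------------------------------------------------------------

def simulate_peaks(annotation: GenomeAnnotation, truth: SimTruth, config: SimConfig,
                   promoter_up: int = 2000) -> list[Peak]:
    """Plant one peak per flagged lncRNA (probability ``peak_rate_base``
    for non-core, ``peak_rate_base * peak_enrich`` for core) inside its
    gene body or promoter window, plus uniform background peaks at
    ``background_peak_rate`` per bp.  Updates ``truth`` peak flags in
    place."""
    rng = rng_for(config.seed, "peaks")
    core_rate = min(1.0, config.peak_rate_base * config.peak_enrich)
    peaks: list[Peak] = []
    for g in annotation.lncrnas():
        rec = truth.records[g.id]
        rate = core_rate if rec.core_direction != "none" else config.peak_rate_base
        flagged = rng.random() < rate
        rec.has_planted_peak = bool(flagged)
        if not flagged:
            continue
        if g.strand == "+":
            lo = max(0, g.start - promoter_up)
            hi = g.end
        else:
            lo = g.start
            hi = min(annotation.chrom_lengths[g.chrom], g.end + promoter_up)
        width = int(rng.integers(100, 400))
        pos = int(rng.integers(lo, max(lo + 1, hi - width)))
        peaks.append(Peak(chrom=g.chrom, start=pos, end=pos + width))
    for chrom, length in sorted(annotation.chrom_lengths.items()):
        n_bg = rng.poisson(config.background_peak_rate * length)
        for _ in range(n_bg):
            width = int(rng.integers(100, 400))
            pos = int(rng.integers(0, max(1, length - width)))
            peaks.append(Peak(chrom=chrom, start=pos, end=pos + width))
    return peaks


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------

def simulate_counts(annotation: GenomeAnnotation, truth: SimTruth, config: SimConfig) -> CountMatrix:
    """NB counts per feature for ``reps`` samples in each of the naive,
    treg_wt and treg_kiko conditions.

    Core features get baseline means in naive, baseline * 2^lfc in
    treg_wt, and revert to baseline in treg_kiko when flagged (else keep
    the treg_wt mean).  Per-sample size factors are uniform on the log
    scale over ``size_factor_range``.
    """
    rng = rng_for(config.seed, "counts")
    feature_ids = [g.id for g in annotation.genes]
    n_feat = len(feature_ids)
    baseline = rng.lognormal(config.mean_log, config.sd_log, n_feat)

    lfc = np.zeros(n_feat)
    revert = np.zeros(n_feat, dtype=bool)
    for i, fid in enumerate(feature_ids):
        rec = truth.records.get(fid)
        if rec is not None and rec.core_direction != "none":
            lfc[i] = rec.true_lfc
            revert[i] = rec.reverts_in_ko

    mu_naive = baseline
    mu_wt = baseline * 2.0**lfc
    mu_kiko = np.where(revert, baseline, mu_wt)

    sample_ids, condition = [], {}
    mus = []
    for cond, mu in zip(CONDITIONS, (mu_naive, mu_wt, mu_kiko)):
        for r in range(1, config.reps + 1):
            sid = f"{cond}_{r}"
            sample_ids.append(sid)
            condition[sid] = cond
            mus.append(mu)
    mu_mat = np.stack(mus, axis=1)

    lo, hi = config.size_factor_range
    sf = np.exp(rng.uniform(math.log(lo), math.log(hi), len(sample_ids)))
    mu_mat = mu_mat * sf[None, :]

    r_nb = 1.0 / config.dispersion
    counts = rng.negative_binomial(r_nb, r_nb / (r_nb + mu_mat))
    lengths = {g.id: g.length for g in annotation.genes}
    return CountMatrix(counts, condition, lengths, feature_ids=feature_ids, sample_ids=sample_ids)


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def simulate_alignment(length: int, blocks: list[tuple[int, int, float]],
                       background_identity: float, config: SimConfig) -> AlignmentPair:
    """A gapless alignment pair whose per-column match probability is the
    block identity inside each planted block and ``background_identity``
    elsewhere."""
    prev_end = None
    for (s, e, ident) in sorted(blocks):
        if not (0 <= s < e <= length):
            raise ValidationError(f"block ({s},{e}) outside [0,{length})")
        if not 0.0 <= ident <= 1.0:
            raise ValidationError("block identity must be in [0,1]")
        if prev_end is not None and s < prev_end:
            raise ValidationError("blocks must not overlap")
        prev_end = e
    if not 0.0 <= background_identity <= 1.0:
        raise ValidationError("background_identity must be in [0,1]")
    rng = rng_for(config.seed, "alignment")
    p_match = np.full(length, background_identity)
    for (s, e, ident) in blocks:
        p_match[s:e] = ident
    seq_a = rng.choice(_BASES, size=length)
    match = rng.random(length) < p_match
    shift = rng.integers(1, 4, size=length)  # a different base, uniformly
    idx_a = np.searchsorted(_BASES, seq_a)
    seq_b = np.where(match, seq_a, _BASES[(idx_a + shift) % 4])
    return AlignmentPair("sim_a", "sim_b", "".join(seq_a), "".join(seq_b))


# ---------------------------------------------------------------------------
# qPCR plates
# ---------------------------------------------------------------------------

def simulate_qpcr(true_folds: dict[str, float], ref_ct: float = 20.0,
                  noise_sd: float = 0.0, seed: int = 0, *,
                  target_gene: str = "target", ref_genes: tuple[str, ...] = ("ref1", "ref2"),
                  calibrator: str = "calibrator", calibrator_ct: float = 25.0,
                  n_reps: int = 3):
    """CT plate with planted folds relative to ``calibrator``.

    Target CT = calibrator CT - log2(fold) + noise; reference genes sit
    at ``ref_ct`` + noise in every sample.  A fold of 0 marks a
    knockout: its target wells are undetected.
    """
    from .qpcr import CtTable  # local import avoids a cycle at module load

    for s, f in true_folds.items():
        if f < 0:
            raise ValidationError(f"fold for {s!r} must be non-negative")
    rng = rng_for(seed, "qpcr")
    table = CtTable()
    samples = dict(true_folds)
    samples.setdefault(calibrator, 1.0)
    for sample, fold in samples.items():
        for _ in range(n_reps):
            if fold == 0.0:
                table.add(sample, target_gene, None)
            else:
                ct = calibrator_ct - math.log2(fold) + rng.normal(0.0, noise_sd)
                table.add(sample, target_gene, float(np.clip(ct, 1e-6, 45.0)))
            for g in ref_genes:
                ct = ref_ct + rng.normal(0.0, noise_sd)
                table.add(sample, g, float(np.clip(ct, 1e-6, 45.0)))
    return table


# ---------------------------------------------------------------------------
# Truth I/O and provenance
# ---------------------------------------------------------------------------

def write_truth(truth: SimTruth, path: str | Path) -> None:
    rows = [asdict(r) for r in truth.records.values()]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_truth(path: str | Path) -> SimTruth:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    records = {
        row.feature_id: TruthRecord(
            feature_id=row.feature_id, core_direction=row.core_direction,
            true_lfc=float(row.true_lfc), positional_class=row.positional_class,
            has_planted_peak=bool(row.has_planted_peak), reverts_in_ko=bool(row.reverts_in_ko),
        )
        for row in df.itertuples()
    }
    return SimTruth(records=records)


def write_provenance(config: SimConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(asdict(config), fh, indent=2, sort_keys=True)
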