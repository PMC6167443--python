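"""Core domain types and readers/writers for GTF, BED, count-table and
aligned-FASTA inputs.

All internal coordinates are 0-based, half-open (BED-like).  GTF I/O is
the only place the 1-based inclusive convention appears, and the
conversion happens exactly once at that boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "GeneModel",
    "GenomeAnnotation",
    "Peak",
    "CountMatrix",
    "AlignmentPair",
    "ValidationError",
    "ParseError",
    "read_gtf",
    "write_gtf",
    "read_bed",
    "write_bed",
    "read_counts",
    "write_counts",
    "read_alignment_fasta",
    "write_alignment_fasta",
]

BIOTYPES = ("coding", "lncRNA")
ALPHABET = frozenset("ACGTN-")


class ValidationError(ValueError):
    """An object violates a documented invariant."""


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


@dataclass(frozen=True)
class GeneModel:
    """A strand-aware, exon-structured gene feature.

    Coordinates are 0-based half-open.  ``exons`` are (start, end)
    intervals sorted, non-overlapping and contained in [start, end).
    """

    id: str
    chrom: str
    strand: str
    start: int
    end: int
    biotype: str = "coding"
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.id}: strand must be '+' or '-', got {self.strand!r}")
        if not self.start < self.end:
            raise ValidationError(f"gene {self.id}: start {self.start} must be < end {self.end}")
        if self.biotype not in BIOTYPES:
            raise ValidationError(f"gene {self.id}: biotype must be one of {BIOTYPES}, got {self.biotype!r}")
        object.__setattr__(self, "exons", tuple((int(a), int(b)) for a, b in self.exons))
        prev_end = None
        for (a, b) in self.exons:
            if not (self.start <= a < b <= self.end):
                raise ValidationError(f"gene {self.id}: exon ({a},{b}) not within [{self.start},{self.end})")
            if prev_end is not None and a < prev_end:
                raise ValidationError(f"gene {self.id}: exons overlap or are unsorted at ({a},{b})")
            prev_end = b

    @property
    def length(self) -> int:
        """Summed exon length, falling back to span length when exonless."""
        if self.exons:
            return sum(b - a for a, b in self.exons)
        return self.end - self.start

    def introns(self) -> list[tuple[int, int]]:
        out = []
        for (a1, b1), (a2, b2) in zip(self.exons, self.exons[1:]):
            if b1 < a2:
                out.append((b1, a2))
        return out

    def overlaps(self, start: int, end: int, chrom: str | None = None) -> bool:
        if chrom is not None and chrom != self.chrom:
            return False
        return self.start < end and start < self.end


@dataclass
class GenomeAnnotation:
    """A set of gene models on named chromosomes with known lengths."""

    genes: list[GeneModel]
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.id in seen:
                raise ValidationError(f"duplicate gene id {g.id!r}")
            seen.add(g.id)
            if g.chrom in self.chrom_lengths and g.end > self.chrom_lengths[g.chrom]:
                raise ValidationError(
                    f"gene {g.id} extends to {g.end}, beyond {g.chrom} length {self.chrom_lengths[g.chrom]}"
                )
        self._by_id = {g.id: g for g in self.genes}

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self._by_id[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def __len__(self) -> int:
        return len(self.genes)

    def coding(self) -> list[GeneModel]:
        return [g for g in self.genes if g.biotype == "coding"]

    def lncrnas(self) -> list[GeneModel]:
        return [g for g in self.genes if g.biotype == "lncRNA"]

    def on_chrom(self, chrom: str) -> list[GeneModel]:
        return [g for g in self.genes if g.chrom == chrom]


@dataclass(frozen=True)
class Peak:
    """A strandless ChIP peak interval (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValidationError(f"peak {self.chrom}:{self.start}-{self.end}: start must be < end")
        if self.score is not None and self.score < 0:
            raise ValidationError(f"peak {self.chrom}:{self.start}-{self.end}: score must be >= 0")


class CountMatrix:
    """Integer read counts, features x samples, with condition labels.

    Parameters
    ----------
    counts
        DataFrame indexed by feature id with one column per sample, or
        a 2-D array combined with ``feature_ids``/``sample_ids``.
    condition
        Mapping sample id -> condition label; required for every sample.
    feature_lengths
        Mapping feature id -> length in bp (used for FPKM).
    """

    def __init__(
        self,
        counts: pd.DataFrame | np.ndarray,
        condition: Mapping[str, str],
        feature_lengths: Mapping[str, int] | None = None,
        feature_ids: Sequence[str] | None = None,
        sample_ids: Sequence[str] | None = None,
    ) -> None:
        if not isinstance(counts, pd.DataFrame):
            counts = pd.DataFrame(np.asarray(counts), index=list(feature_ids), columns=list(sample_ids))
        arr = counts.to_numpy()
        if arr.size and (not np.issubdtype(arr.dtype, np.integer)):
            if not np.all(np.equal(np.mod(arr, 1), 0)):
                raise ValidationError("counts must be integral")
            counts = counts.astype(np.int64)
            arr = counts.to_numpy()
        if arr.size and (arr < 0).any():
            raise ValidationError("counts must be non-negative")
        for s in counts.columns:
            if s not in condition:
                raise ValidationError(f"sample {s!r} has no condition label")
        self.counts = counts
        self.condition = dict(condition)
        self.feature_lengths = dict(feature_lengths or {})

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def values(self) -> np.ndarray:
        return self.counts.to_numpy()

    def samples_in(self, condition: str) -> list[str]:
        out = [s for s in self.sample_ids if self.condition[s] == condition]
        if not out:
            raise ValidationError(f"no samples with condition {condition!r}")
        return out

    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(self.condition[s], None)
        return list(seen)

    def subset_features(self, ids: Iterable[str]) -> "CountMatrix":
        ids = list(ids)
        return CountMatrix(self.counts.loc[ids], self.condition, self.feature_lengths)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            self.counts.equals(other.counts)
            and self.condition == other.condition
            and self.feature_lengths == other.feature_lengths
        )


class AlignmentPair:
    """A gapped pairwise alignment over {A,C,G,T,N,-}.

    Columns where both sequences are gaps are dropped on construction;
    they carry no identity information.
    """

    def __init__(self, name_a: str, name_b: str, seq_a: str, seq_b: str) -> None:
        seq_a, seq_b = seq_a.upper(), seq_b.upper()
        if len(seq_a) != len(seq_b):
            raise ValidationError(
                f"aligned sequences have unequal lengths ({len(seq_a)} vs {len(seq_b)})"
            )
        bad = (set(seq_a) | set(seq_b)) - ALPHABET
        if bad:
            raise ValidationError(f"alignment contains invalid symbols: {sorted(bad)}")
        keep = [i for i, (x, y) in enumerate(zip(seq_a, seq_b)) if not (x == "-" and y == "-")]
        self.name_a = name_a
        self.name_b = name_b
        self.seq_a = "".join(seq_a[i] for i in keep)
        self.seq_b = "".join(seq_b[i] for i in keep)

    def __len__(self) -> int:
        return len(self.seq_a)

    def swapped(self) -> "AlignmentPair":
        return AlignmentPair(self.name_b, self.name_a, self.seq_b, self.seq_a)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AlignmentPair):
            return NotImplemented
        return (self.name_a, self.name_b, self.seq_a, self.seq_b) == (
            other.name_a,
            other.name_b,
            other.seq_a,
            other.seq_b,
        )


# ---------------------------------------------------------------------------
# GTF I/O
# ---------------------------------------------------------------------------

_CHROM_LEN_PRAGMA = "#!chrom-length"


def _parse_attributes(text: str, lineno: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        parts = chunk.split(None, 1)
        if len(parts) != 2:
            raise ParseError(f"line {lineno}: malformed attribute {chunk!r}")
        key, val = parts
        attrs[key] = val.strip().strip('"')
    return attrs


def read_gtf(path: str | Path) -> GenomeAnnotation:
    """Read gene/exon records from a GTF file into a :class:`GenomeAnnotation`.

    GTF coordinates (1-based, inclusive) are converted to the internal
    0-based half-open convention.  Biotype comes from the
    ``gene_biotype`` attribute, defaulting to ``coding`` when absent.
    Chromosome lengths are taken from ``#!chrom-length`` pragma lines if
    present, otherwise inferred as the maximum gene end per chromosome.
    """
    gene_rows: dict[str, dict] = {}
    exon_rows: dict[str, list[tuple[int, int]]] = {}
    chrom_lengths: dict[str, int] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith(_CHROM_LEN_PRAGMA):
                parts = line.split()
                if len(parts) != 3:
                    raise ParseError(f"line {lineno}: malformed chrom-length pragma")
                chrom_lengths[parts[1]] = int(parts[2])
                continue
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"line {lineno}: expected 9 tab-separated fields, got {len(fields)}")
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attr_s = fields
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(f"line {lineno}: non-integer coordinates {start_s!r}/{end_s!r}") from None
            if end1 < start1:
                raise ValidationError(f"line {lineno}: end {end1} < start {start1}")
            start, end = start1 - 1, end1  # to 0-based half-open
            attrs = _parse_attributes(attr_s, lineno)
            gid = attrs.get("gene_id")
            if gid is None:
                raise ParseError(f"line {lineno}: missing gene_id attribute")
            if feature == "gene":
                gene_rows[gid] = {
                    "chrom": chrom,
                    "strand": strand,
                    "start": start,
                    "end": end,
                    "biotype": attrs.get("gene_biotype", "coding"),
                }
                order.append(gid)
            elif feature == "exon":
                exon_rows.setdefault(gid, []).append((start, end))
    genes = []
    for gid in order:
        row = gene_rows[gid]
        exons = tuple(sorted(exon_rows.get(gid, [])))
        genes.append(GeneModel(id=gid, exons=exons, **row))
    for gid in exon_rows:
        if gid not in gene_rows:
            raise ParseError(f"exon record references unknown gene {gid!r}")
    if not chrom_lengths:
        for g in genes:
            chrom_lengths[g.chrom] = max(chrom_lengths.get(g.chrom, 0), g.end)
    return GenomeAnnotation(genes=genes, chrom_lengths=chrom_lengths)


def write_gtf(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Write gene+exon GTF records, 1-based inclusive, deterministically
    ordered by (chrom, start, id)."""
    with open(path, "w") as fh:
        fh.write("##gtf\n")
        for chrom in sorted(annotation.chrom_lengths):
            fh.write(f"{_CHROM_LEN_PRAGMA} {chrom} {annotation.chrom_lengths[chrom]}\n")
        for g in sorted(annotation.genes, key=lambda g: (g.chrom, g.start, g.id)):
            attrs = f'gene_id "{g.id}"; gene_biotype "{g.biotype}";'
            fh.write(
                f"{g.chrom}\tlncsig\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for (a, b) in g.exons:
                fh.write(
                    f"{g.chrom}\tlncsig\texon\t{a + 1}\t{b}\t.\t{g.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# BED I/O
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[Peak]:
    """Read a BED3+ file of peaks (0-based half-open, kept verbatim).

    Column 5, when present, is interpreted as the peak score.
    """
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"line {lineno}: BED needs at least 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(f"line {lineno}: non-integer coordinates") from None
            score = None
            if len(fields) >= 5 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError:
                    raise ParseError(f"line {lineno}: non-numeric score {fields[4]!r}") from None
            peaks.append(Peak(chrom=fields[0], start=start, end=end, score=score))
    return peaks


def write_bed(peaks: Sequence[Peak], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            score = "." if p.score is None else repr(p.score)
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\tpeak_{i}\t{score}\n")


# ---------------------------------------------------------------------------
# Count table I/O
# ---------------------------------------------------------------------------

def read_counts(
    counts_path: str | Path,
    conditions_path: str | Path | None = None,
    lengths_path: str | Path | None = None,
) -> CountMatrix:
    """Read a TSV count table (features x samples, header row of sample ids)
    plus side-car TSVs mapping samples to conditions and features to lengths.

    Without a conditions side-car every sample is labelled ``"na"``.
    """
    df = pd.read_csv(counts_path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ValidationError(f"{counts_path}: ragged or missing entries in count table")
    try:
        arr = df.to_numpy()
        if not np.all(np.equal(np.mod(arr, 1), 0)):
            raise ValidationError(f"{counts_path}: non-integer count")
    except TypeError:
        raise ValidationError(f"{counts_path}: non-numeric count") from None
    if (arr < 0).any():
        raise ValidationError(f"{counts_path}: negative count")
    df = df.astype(np.int64)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)

    if conditions_path is not None:
        cond_df = pd.read_csv(conditions_path, sep="\t", dtype=str)
        condition = dict(zip(cond_df.iloc[:, 0], cond_df.iloc[:, 1]))
    else:
        condition = {s: "na" for s in df.columns}

    lengths: dict[str, int] = {}
    if lengths_path is not None:
        len_df = pd.read_csv(lengths_path, sep="\t")
        lengths = {str(k): int(v) for k, v in zip(len_df.iloc[:, 0], len_df.iloc[:, 1])}
    return CountMatrix(df, condition, lengths)


def write_counts(cm: CountMatrix, counts_path: str | Path,
                 conditions_path: str | Path | None = None,
                 lengths_path: str | Path | None = None) -> None:
    cm.counts.to_csv(counts_path, sep="\t", index_label="feature_id")
    if conditions_path is not None:
        pd.DataFrame(
            {"sample_id": cm.sample_ids, "condition": [cm.condition[s] for s in cm.sample_ids]}
        ).to_csv(conditions_path, sep="\t", index=False)
    if lengths_path is not None:
        items = sorted(cm.feature_lengths.items())
        pd.DataFrame({"feature_id": [k for k, _ in items], "length": [v for _, v in items]}).to_csv(
            lengths_path, sep="\t", index=False
        )


# ---------------------------------------------------------------------------
# Aligned FASTA I/O
# ---------------------------------------------------------------------------

def read_alignment_fasta(path: str | Path) -> AlignmentPair:
    """Read an aligned FASTA with exactly two equal-length records."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise ValidationError(f"{path}: expected exactly 2 aligned records, found {len(records)}")
    a, b = records
    return AlignmentPair(a.id, b.id, str(a.seq), str(b.seq))


def write_alignment_fasta(aln: AlignmentPair, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{aln.name_a}\n{aln.seq_a}\n>{aln.name_b}\n{aln.seq_b}\n")
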