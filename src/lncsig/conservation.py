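"""Conserved-region detection in a pairwise alignment.

A column matches when both symbols are identical non-gap, non-N bases
(case-insensitive at read time); gap-versus-base and anything involving
N count as mismatches.  Regions are built by sliding a window of
exactly ``min_len`` columns one step at a time, marking columns covered
by any window whose identity exceeds ``min_id``, merging marked columns
into maximal runs, dropping runs not longer than ``min_len``, and
trimming runs whose overall identity does not exceed ``min_id`` one
column at a time from their lower-identity end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .models import AlignmentPair, ValidationError

__all__ = ["ConservedRegion", "window_identity", "find_ecrs", "ecr_to_sequence_coords",
           "MIN_LEN", "MIN_ID"]

log = logging.getLogger(__name__)

MIN_LEN = 100
MIN_ID = 0.70


@dataclass(frozen=True)
class ConservedRegion:
    """Alignment-column interval (0-based half-open) with its identity."""

    start: int
    end: int
    identity: float

    @property
    def length(self) -> int:
        return self.end - self.start


def _match_columns(aln: AlignmentPair) -> np.ndarray:
    a = np.frombuffer(aln.seq_a.encode(), dtype="S1")
    b = np.frombuffer(aln.seq_b.encode(), dtype="S1")
    return (a == b) & (a != b"-") & (a != b"N")


def window_identity(aln: AlignmentPair, start: int, end: int) -> float:
    """Fraction of matching columns in [start, end)."""
    if not (0 <= start < end <= len(aln)):
        raise ValidationError(f"window [{start},{end}) invalid for alignment of length {len(aln)}")
    m = _match_columns(aln)
    return float(m[start:end].mean())


def find_ecrs(aln: AlignmentPair, min_len: int = MIN_LEN, min_id: float = MIN_ID) -> list[ConservedRegion]:
    """Detect maximal conserved runs longer than ``min_len`` columns with
    identity above ``min_id``; see the module docstring for the exact
    construction."""
    n = len(aln)
    if n < min_len:
        log.info("alignment length %d < min_len %d; no regions reportable", n, min_len)
        return []
    m = _match_columns(aln).astype(np.int64)
    csum = np.concatenate([[0], np.cumsum(m)])
    # identity of every width-min_len window, step 1
    win = (csum[min_len:] - csum[:-min_len]) / min_len
    good = win > min_id
    covered = np.zeros(n, dtype=bool)
    # window i covers columns [i, i+min_len)
    starts = np.flatnonzero(good)
    for i in starts:
        covered[i : i + min_len] = True

    regions: list[ConservedRegion] = []
    i = 0
    while i < n:
        if not covered[i]:
            i += 1
            continue
        j = i
        while j < n and covered[j]:
            j += 1
        reg = _trim_run(m, csum, i, j, min_len, min_id)
        if reg is not None:
            regions.append(reg)
        i = j

    for r in regions:
        assert r.length > min_len and r.identity > min_id
    return regions


def _run_identity(csum: np.ndarray, s: int, e: int) -> float:
    return (csum[e] - csum[s]) / (e - s)


def _trim_run(m: np.ndarray, csum: np.ndarray, s: int, e: int,
              min_len: int, min_id: float) -> ConservedRegion | None:
    if e - s <= min_len:
        return None
    ident = _run_identity(csum, s, e)
    while ident <= min_id:
        if e - s - 1 <= min_len:
            return None
        # trim one column from whichever end anchors the lower-identity
        # terminal window
        left_id = _run_identity(csum, s, s + min_len)
        right_id = _run_identity(csum, e - min_len, e)
        if left_id <= right_id:
            s += 1
        else:
            e -= 1
        ident = _run_identity(csum, s, e)
    return ConservedRegion(start=s, end=e, identity=float(ident))


def ecr_to_sequence_coords(region: ConservedRegion, aln: AlignmentPair, which: str) -> tuple[int, int]:
    """Map an alignment-column interval onto the ungapped coordinates of
    sequence ``which`` ("a" or "b"); boundaries on gaps shrink inward.
    Returns an empty interval (start == end) when the region is entirely
    gapped in the chosen sequence."""
    if which not in ("a", "b"):
        raise ValidationError("which must be 'a' or 'b'")
    seq = aln.seq_a if which == "a" else aln.seq_b
    if not (0 <= region.start < region.end <= len(aln)):
        raise ValidationError("region outside alignment")
    nongap = np.frombuffer(seq.encode(), dtype="S1") != b"-"
    csum = np.concatenate([[0], np.cumsum(nongap)])
    start = int(csum[region.start])
    end = int(csum[region.end])
    return start, end
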