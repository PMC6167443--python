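"""Relative expression by the 2^-ddCT method with multi-reference
normalization.

Replicate CT values are averaged per (sample, gene) first; the delta-CT
subtracts the arithmetic mean of the per-reference-gene mean CTs
(equivalent to geometric-mean normalization on the expression scale).
Undetected wells carry no CT value and are treated as missing, never
imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .models import ValidationError

__all__ = [
    "CtTable",
    "RelExpr",
    "UndetectedError",
    "read_ct_table",
    "write_ct_table",
    "delta_ct",
    "ddct_fold",
    "knockout_check",
]

CT_MAX = 45.0
ABSENCE_FOLD_FLOOR = 0.01


class UndetectedError(ValueError):
    """Every replicate of a required gene failed to amplify."""


@dataclass
class CtTable:
    """CT replicate values per (sample, gene); None marks an undetected
    replicate."""

    records: dict[tuple[str, str], list[float | None]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (sample, gene), reps in self.records.items():
            for ct in reps:
                if ct is not None and not (0.0 < ct <= CT_MAX):
                    raise ValidationError(
                        f"CT {ct} for ({sample}, {gene}) outside (0, {CT_MAX}]"
                    )

    def add(self, sample: str, gene: str, ct: float | None) -> None:
        self.records.setdefault((sample, gene), []).append(ct)
        if ct is not None and not (0.0 < ct <= CT_MAX):
            del self.records[(sample, gene)][-1]
            raise ValidationError(f"CT {ct} for ({sample}, {gene}) outside (0, {CT_MAX}]")

    def detected(self, sample: str, gene: str) -> list[float]:
        return [c for c in self.records.get((sample, gene), []) if c is not None]

    def mean_ct(self, sample: str, gene: str) -> float:
        vals = self.detected(sample, gene)
        if not vals:
            raise UndetectedError(f"gene {gene!r} undetected in sample {sample!r}")
        return sum(vals) / len(vals)

    def samples(self) -> list[str]:
        seen: dict[str, None] = {}
        for (s, _g) in self.records:
            seen.setdefault(s, None)
        return list(seen)


@dataclass(frozen=True)
class RelExpr:
    sample: str
    gene: str
    delta_ct: float
    fold: float
    calibrator: str

    def __post_init__(self) -> None:
        if not self.fold > 0:
            raise ValidationError("fold must be positive")


def read_ct_table(path: str | Path) -> CtTable:
    """Read a TSV with columns sample, gene, replicate, ct (NA for an
    undetected well)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "gene": str})
    needed = {"sample", "gene", "ct"}
    if not needed <= set(df.columns):
        raise ValidationError(f"{path}: CT table needs columns {sorted(needed)}")
    table = CtTable()
    for _, row in df.iterrows():
        ct = row["ct"]
        table.add(row["sample"], row["gene"], None if pd.isna(ct) else float(ct))
    return table


def write_ct_table(table: CtTable, path: str | Path) -> None:
    rows = []
    for (sample, gene), reps in table.records.items():
        for i, ct in enumerate(reps, start=1):
            rows.append({"sample": sample, "gene": gene, "replicate": i,
                         "ct": "NA" if ct is None else ct})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def delta_ct(table: CtTable, sample: str, target_gene: str, ref_genes: Sequence[str]) -> float:
    """Mean target CT minus the arithmetic mean of the per-reference
    mean CTs."""
    if not ref_genes:
        raise ValidationError("at least one reference gene required")
    target = table.mean_ct(sample, target_gene)
    refs = [table.mean_ct(sample, g) for g in ref_genes]
    return target - sum(refs) / len(refs)


def ddct_fold(table: CtTable, sample: str, calibrator: str, target_gene: str,
              ref_genes: Sequence[str]) -> RelExpr:
    """Fold change of ``sample`` relative to ``calibrator``:
    2^-(dCT_sample - dCT_calibrator)."""
    d_s = delta_ct(table, sample, target_gene, ref_genes)
    d_c = delta_ct(table, calibrator, target_gene, ref_genes)
    return RelExpr(sample=sample, gene=target_gene, delta_ct=d_s,
                   fold=2.0 ** (-(d_s - d_c)), calibrator=calibrator)


def knockout_check(table: CtTable, gene: str, ko_samples: Iterable[str],
                   wt_samples: Iterable[str], ref_genes: Sequence[str],
                   fold_floor: float = ABSENCE_FOLD_FLOOR) -> dict:
    """Per-KO-sample fold versus the WT mean, plus an ``all_absent``
    verdict: true iff every KO replicate is undetected or its fold falls
    below ``fold_floor``."""
    wt_samples = list(wt_samples)
    ko_samples = list(ko_samples)
    for s in wt_samples:
        if not table.detected(s, gene):
            raise UndetectedError(f"gene {gene!r} undetected in WT sample {s!r}")
    wt_dcts = [delta_ct(table, s, gene, ref_genes) for s in wt_samples]
    wt_dct = sum(wt_dcts) / len(wt_dcts)

    folds: dict[str, float | None] = {}
    all_absent = True
    for s in ko_samples:
        if not table.detected(s, gene):
            folds[s] = None
            continue
        d = delta_ct(table, s, gene, ref_genes)
        fold = 2.0 ** (-(d - wt_dct))
        folds[s] = fold
        if fold >= fold_floor:
            all_absent = False
    return {"gene": gene, "folds": folds, "all_absent": all_absent, "fold_floor": fold_floor}
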