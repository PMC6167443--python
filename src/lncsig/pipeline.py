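"""End-to-end orchestration: simulate -> DE -> signature -> classify ->
colocalization -> reversal -> concordance -> report.

All randomness flows from the single config seed through per-stage
substreams (stage-name hash), so adding a stage never perturbs the
others and reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import coloc, dependence, diffexpr, signature, simulate
from .models import ValidationError, write_bed, write_counts, write_gtf

__all__ = ["PipelineConfig", "validate_config", "run_pipeline", "make_report"]

log = logging.getLogger(__name__)

_THRESHOLD_RANGES = {
    "alpha": (0.0, 1.0),
    "min_mean": (0.0, float("inf")),
    "promoter_up": (0, 10_000_000),
    "promoter_down": (0, 10_000_000),
    "lfc_threshold": (0.0, float("inf")),
    "min_len": (1, 10_000_000),
    "min_id": (0.0, 1.0),
    "concordance_noise_sd": (0.0, float("inf")),
}


@dataclass
class PipelineConfig:
    sim: simulate.SimConfig = field(default_factory=simulate.SimConfig)
    alpha: float = 0.05
    use_raw_p: bool = False
    min_mean: float = 1.0
    promoter_up: int = 2000
    promoter_down: int = 500
    lfc_threshold: float = 0.5
    min_len: int = 100
    min_id: float = 0.70
    concordance_noise_sd: float = 0.3
    seed: int = 0
    outdir: str = "lncsig_run"

    def __post_init__(self) -> None:
        for name, (lo, hi) in _THRESHOLD_RANGES.items():
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValidationError(f"{name}={v} outside [{lo}, {hi}]")
        # a single seed governs the whole run, including simulation
        self.sim = dataclasses.replace(self.sim, seed=self.seed)

    def config_hash(self) -> str:
        payload = json.dumps(
            {**{k: v for k, v in asdict(self).items() if k != "outdir"}},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def validate_config(path: str | Path) -> PipelineConfig:
    """Load a flat JSON config; unknown keys are errors, not warnings."""
    with open(path) as fh:
        raw = json.load(fh)
    sim_keys = {f.name for f in dataclasses.fields(simulate.SimConfig)}
    pipe_keys = {f.name for f in dataclasses.fields(PipelineConfig)} - {"sim"}
    unknown = [k for k in raw if k not in sim_keys | pipe_keys]
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    sim_kwargs = {k: v for k, v in raw.items() if k in sim_keys}
    if "position_mix" in sim_kwargs:
        sim_kwargs["position_mix"] = tuple(sim_kwargs["position_mix"])
    if "size_factor_range" in sim_kwargs:
        sim_kwargs["size_factor_range"] = tuple(sim_kwargs["size_factor_range"])
    pipe_kwargs = {k: v for k, v in raw.items() if k in pipe_keys}
    cfg = PipelineConfig(sim=simulate.SimConfig(**sim_kwargs), **pipe_kwargs)
    return cfg


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on freshly simulated data, writing each stage's
    artifact before the next starts, and return the aggregated report."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("lncsig")
    root.addHandler(handler)
    if root.level > logging.INFO or root.level == logging.NOTSET:
        root.setLevel(logging.INFO)
    stage = "setup"
    try:
        log.info("config: %s", asdict(config))
        simulate.write_provenance(config.sim, out / "provenance.json")

        stage = "simulate"
        annotation, truth = simulate.simulate_annotation(config.sim)
        peaks = simulate.simulate_peaks(annotation, truth, config.sim,
                                        promoter_up=config.promoter_up)
        cm = simulate.simulate_counts(annotation, truth, config.sim)
        write_gtf(annotation, out / "annotation.gtf")
        write_bed(peaks, out / "peaks.bed")
        write_counts(cm, out / "counts.tsv", out / "conditions.tsv", out / "feature_lengths.tsv")
        simulate.write_truth(truth, out / "truth.tsv")

        stage = "de"
        factors = diffexpr.size_factors(cm)
        lnc_ids = [g.id for g in annotation.lncrnas()]
        expressed_all = diffexpr.filter_expressed(cm, factors, config.min_mean, condition="treg_wt")
        expressed = sorted(set(expressed_all) & set(lnc_ids))
        groups = {c: cm.samples_in(c) for c in simulate.CONDITIONS}
        dispersions = diffexpr.estimate_dispersion(cm, factors, groups)
        de = diffexpr.nb_wald_test(cm, factors, dispersions,
                                   groups["naive"], groups["treg_wt"])
        diffexpr.de_results_to_frame(de).to_csv(out / "de_treg_vs_naive.tsv", sep="\t")

        stage = "signature"
        de_lnc = [r for r in de if r.feature_id in set(expressed)]
        # re-adjust within the expressed lncRNA universe
        padj = diffexpr.bh_adjust([r.p for r in de_lnc])
        de_lnc = [dataclasses.replace(r, padj=pa) for r, pa in zip(de_lnc, padj)]
        sig = signature.call_signature(de_lnc, set(expressed), config.alpha,
                                       use_raw_p=config.use_raw_p)
        summary = signature.summarize_signature(sig)
        rows = [{"feature_id": f, "set": name}
                for name, members in (("up", sig.up), ("down", sig.down), ("nondiff", sig.nondiff))
                for f in sorted(members)]
        pd.DataFrame(rows).to_csv(out / "signature.tsv", sep="\t", index=False)

        stage = "classify"
        classes = signature.classify_all(annotation, expressed)
        pd.DataFrame(
            {"feature_id": list(classes.category),
             "category": list(classes.category.values()),
             "intronic": [classes.intronic[f] for f in classes.category]}
        ).to_csv(out / "positional_classes.tsv", sep="\t", index=False)
        pos_enrich = signature.positional_enrichment(sig, classes)
        _write_json(pos_enrich, out / "positional_enrichment.json")

        stage = "coloc"
        flags = coloc.compute_peak_flags(annotation, peaks, expressed,
                                         config.promoter_up, config.promoter_down)
        pd.DataFrame(
            {"feature_id": list(flags.flags),
             "has_peak": list(flags.flags.values()),
             "n_peaks": [flags.n_peaks[f] for f in flags.flags]}
        ).to_csv(out / "peak_flags.tsv", sep="\t", index=False)
        coloc_report = coloc.peak_enrichment(sig, flags)
        _write_json(coloc_report, out / "colocalization.json")

        stage = "reversal"
        ko_de = diffexpr.nb_wald_test(cm, factors, dispersions,
                                      groups["treg_wt"], groups["treg_kiko"])
        diffexpr.de_results_to_frame(ko_de).to_csv(out / "de_kiko_vs_wt.tsv", sep="\t")
        rev = dependence.reversal_report(sig, ko_de, config.lfc_threshold)
        rev_dict = {"per_set": rev.per_set, "fisher_odds_ratio": rev.fisher_odds_ratio,
                    "fisher_p": rev.fisher_p, "rank_tests": rev.rank_tests,
                    "lfc_threshold": config.lfc_threshold}
        _write_json(rev_dict, out / "reversal.json")

        stage = "concordance"
        # emulate an independent dataset sharing the planted fold changes
        rng = simulate.rng_for(config.seed, "concordance")
        core_called = sorted(sig.core)
        est_lfc = {r.feature_id: r.log2fc for r in de_lnc}
        truth_lfc = {f: truth.records[f].true_lfc for f in core_called if f in truth.records}
        lfc_a = {f: est_lfc[f] for f in truth_lfc}
        lfc_b = {f: truth_lfc[f] + rng.normal(0.0, config.concordance_noise_sd)
                 for f in truth_lfc}
        if len(lfc_a) >= 3:
            concord = dependence.cross_dataset_concordance(lfc_a, lfc_b)
        else:
            concord = {"note": "fewer than 3 shared core features", "n_shared": len(lfc_a)}
        _write_json(concord, out / "concordance.json")

        stage = "report"
        report = make_report(config, summary, pos_enrich, coloc_report, rev_dict, concord)
        _write_json(report, out / "report.json")
        return report
    except Exception as exc:
        raise RuntimeError(
            f"pipeline failed at stage {stage!r} (artifacts up to the previous "
            f"stage are in {out})"
        ) from exc
    finally:
        root.removeHandler(handler)
        handler.close()


def make_report(config: PipelineConfig, summary: dict, pos_enrich: dict,
                coloc_report: dict, reversal: dict, concordance: dict) -> dict:
    import lncsig

    return {
        "signature_summary": summary,
        "positional_enrichment": pos_enrich,
        "colocalization": coloc_report,
        "reversal": reversal,
        "concordance": concordance,
        "provenance": {
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "lncsig_version": lncsig.__version__,
            "numpy_version": np.__version__,
        },
    }
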