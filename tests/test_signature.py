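import numpy as np
import pytest

from lncsig.diffexpr import DEResult
from lncsig.models import GeneModel, GenomeAnnotation, ValidationError
from lncsig.signature import (
    PositionalClass,
    SignatureSet,
    call_signature,
    classify_all,
    classify_position,
    positional_enrichment,
    summarize_signature,
)

from .conftest import random_annotation


def _res(fid, lfc, p, padj=None):
    return DEResult(fid, 10.0, lfc, 1.0, p, padj if padj is not None else p)


class TestSignatureSet:
    def test_partition_invariant(self):
        s = SignatureSet(up={"a"}, down={"b"}, nondiff={"c", "d"}, alpha=0.05)
        assert s.universe_size == 4
        assert s.core == {"a", "b"}

    def test_overlap_rejected(self):
        with pytest.raises(ValidationError):
            SignatureSet(up={"a"}, down={"a"}, nondiff=set(), alpha=0.05)


class TestCallSignature:
    def test_all_null(self):
        results = [_res(f"f{i}", 1.0, 1.0) for i in range(5)]
        sig = call_signature(results, {f"f{i}" for i in range(5)}, 0.05)
        assert sig.up == set() and sig.down == set()
        assert sig.nondiff == {f"f{i}" for i in range(5)}

    def test_single_up(self):
        results = [_res("a", 2.0, 0.0), _res("b", 0.5, 0.9)]
        sig = call_signature(results, {"a", "b"}, 0.05)
        assert sig.up == {"a"} and sig.down == set()

    def test_down_direction(self):
        sig = call_signature([_res("a", -2.0, 0.0)], {"a"}, 0.05)
        assert sig.down == {"a"}

    def test_raw_p_flag(self):
        results = [_res("a", 2.0, 0.01, padj=0.2)]
        assert call_signature(results, {"a"}, 0.05).up == set()
        assert call_signature(results, {"a"}, 0.05, use_raw_p=True).up == {"a"}

    def test_missing_feature_rejected(self):
        with pytest.raises(ValidationError):
            call_signature([_res("a", 1.0, 0.5)], {"a", "b"}, 0.05)


class TestSummarize:
    def test_reported_counts(self):
        # 190 up + 55 down of 1765 expressed -> 13.8%
        sig = SignatureSet(up={f"u{i}" for i in range(190)},
                           down={f"d{i}" for i in range(55)},
                           nondiff={f"n{i}" for i in range(1765 - 245)}, alpha=0.05)
        assert summarize_signature(sig)["pct_differential"] == 13.8

    def test_zero_percent(self):
        sig = SignatureSet(up=set(), down=set(), nondiff={f"n{i}" for i in range(100)}, alpha=0.05)
        assert summarize_signature(sig)["pct_differential"] == 0.0

    def test_hundred_percent(self):
        sig = SignatureSet(up={f"u{i}" for i in range(50)},
                           down={f"d{i}" for i in range(50)}, nondiff=set(), alpha=0.05)
        assert summarize_signature(sig)["pct_differential"] == 100.0

    def test_empty_universe_rejected(self):
        with pytest.raises(ValidationError):
            summarize_signature(SignatureSet(up=set(), down=set(), nondiff=set(), alpha=0.05))


def _lnc(start, end, strand="+", chrom="chr1", id="x"):
    return GeneModel(id=id, chrom=chrom, strand=strand, start=start, end=end,
                     biotype="lncRNA", exons=((start, end),))


class TestClassifyPosition:
    @pytest.fixture
    def ann(self):
        coding = GeneModel(id="pc", chrom="chr1", strand="+", start=100, end=500,
                           biotype="coding", exons=((100, 200), (400, 500)))
        return GenomeAnnotation(genes=[coding], chrom_lengths={"chr1": 5000})

    def test_sense(self, ann):
        assert classify_position(_lnc(200, 300, "+"), ann)[0] == "sense"

    def test_antisense(self, ann):
        assert classify_position(_lnc(200, 300, "-"), ann)[0] == "antisense"

    def test_lincRNA(self, ann):
        assert classify_position(_lnc(600, 700, "+"), ann) == ("lincRNA", False)

    def test_intronic_flag(self, ann):
        # fully inside the intron (200..400), overlapping no exon
        cat, intronic = classify_position(_lnc(250, 350, "+"), ann)
        assert (cat, intronic) == ("sense", True)
        cat, intronic = classify_position(_lnc(250, 350, "-"), ann)
        assert (cat, intronic) == ("antisense", True)

    def test_exon_overlap_not_intronic(self, ann):
        assert classify_position(_lnc(150, 250, "+"), ann) == ("sense", False)

    def test_sense_precedence_on_ties(self):
        genes = [
            GeneModel(id="p1", chrom="chr1", strand="+", start=0, end=300, biotype="coding"),
            GeneModel(id="p2", chrom="chr1", strand="-", start=200, end=600, biotype="coding"),
        ]
        ann = GenomeAnnotation(genes=genes, chrom_lengths={"chr1": 1000})
        assert classify_position(_lnc(250, 280, "+"), ann)[0] == "sense"
        assert classify_position(_lnc(250, 280, "-"), ann)[0] == "sense"

    def test_non_lnc_rejected(self, ann):
        with pytest.raises(ValidationError):
            classify_position(ann["pc"], ann)

    @pytest.mark.parametrize("seed", range(20))
    def test_strand_antisymmetry(self, seed):
        rng = np.random.default_rng(seed)
        ann = random_annotation(rng)
        for g in ann.lncrnas():
            cat, _ = classify_position(g, ann)
            flipped = GeneModel(id=g.id, chrom=g.chrom,
                                strand="-" if g.strand == "+" else "+",
                                start=g.start, end=g.end, biotype="lncRNA", exons=g.exons)
            cat_f, _ = classify_position(flipped, ann)
            if cat == "lincRNA":
                assert cat_f == "lincRNA"
            else:
                # flipping can only swap sense<->antisense unless overlaps
                # exist on both strands (where sense precedence wins twice)
                both = any(
                    c.biotype == "coding" and c.chrom == g.chrom and c.overlaps(g.start, g.end)
                    and c.strand == "+"
                    for c in ann.genes
                ) and any(
                    c.biotype == "coding" and c.chrom == g.chrom and c.overlaps(g.start, g.end)
                    and c.strand == "-"
                    for c in ann.genes
                )
                if both:
                    assert cat == cat_f == "sense"
                else:
                    assert {cat, cat_f} == {"sense", "antisense"}

    @pytest.mark.parametrize("seed", range(25))
    def test_against_per_base_oracle(self, seed):
        # exhaustive per-base overlap oracle (8 extra annotations per seed
        # keep the 200-annotation budget of the module invariant reasonable)
        rng = np.random.default_rng(seed)
        for _ in range(8):
            ann = random_annotation(rng, n_coding=3, n_lnc=4, chrom_len=3000)
            for g in ann.lncrnas():
                same = opp = False
                for pos in range(g.start, g.end):
                    for c in ann.coding():
                        if c.chrom == g.chrom and c.start <= pos < c.end:
                            if c.strand == g.strand:
                                same = True
                            else:
                                opp = True
                expected = "sense" if same else ("antisense" if opp else "lincRNA")
                assert classify_position(g, ann)[0] == expected


class TestPositionalEnrichment:
    def _classes(self, mapping):
        return PositionalClass(category=mapping, intronic={f: False for f in mapping})

    def test_null_mix(self):
        up = {f"u{i}" for i in range(20)}
        nd = {f"n{i}" for i in range(40)}
        cats = {}
        for i, f in enumerate(sorted(up)):
            cats[f] = "lincRNA" if i % 2 == 0 else "sense"
        for i, f in enumerate(sorted(nd)):
            cats[f] = "lincRNA" if i % 2 == 0 else "sense"
        sig = SignatureSet(up=up, down=set(), nondiff=nd, alpha=0.05)
        rep = positional_enrichment(sig, self._classes(cats))
        assert rep["lincRNA"]["up"]["odds_ratio"] == pytest.approx(1.0)
        assert rep["lincRNA"]["up"]["p"] > 0.5

    def test_fully_concentrated_matches_hypergeometric(self):
        from math import comb

        up = {f"u{i}" for i in range(4)}
        nd = {f"n{i}" for i in range(6)}
        cats = {**{f: "lincRNA" for f in up}, **{f: "sense" for f in nd}}
        sig = SignatureSet(up=up, down=set(), nondiff=nd, alpha=0.05)
        rep = positional_enrichment(sig, self._classes(cats))
        # all 4 lincRNA in the up set: only one table this extreme
        expected = comb(4, 4) * comb(6, 0) / comb(10, 4)
        assert rep["lincRNA"]["up"]["p"] == pytest.approx(expected)

    def test_empty_core_set_marked(self):
        nd = {f"n{i}" for i in range(5)}
        sig = SignatureSet(up=set(), down=set(), nondiff=nd, alpha=0.05)
        rep = positional_enrichment(sig, self._classes({f: "lincRNA" for f in nd}))
        assert rep["lincRNA"]["up"]["p"] is None

    def test_planted_lincRNA_excess_recovered(self):
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(20):
            up = {f"u{i}" for i in range(60)}
            nd = {f"n{i}" for i in range(300)}
            cats = {}
            for f in up:
                cats[f] = "lincRNA" if rng.random() < 0.8 else "sense"
            for f in nd:
                cats[f] = "lincRNA" if rng.random() < 0.4 else "sense"
            sig = SignatureSet(up=up, down=set(), nondiff=nd, alpha=0.05)
            rep = positional_enrichment(sig, self._classes(cats))
            if rep["lincRNA"]["up"]["odds_ratio"] > 1 and rep["lincRNA"]["up"]["p"] < 0.01:
                hits += 1
        assert hits == 20

    def test_missing_classes_rejected(self):
        sig = SignatureSet(up={"a"}, down=set(), nondiff={"b"}, alpha=0.05)
        with pytest.raises(ValidationError):
            positional_enrichment(sig, self._classes({"a": "sense"}))
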