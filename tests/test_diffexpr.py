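import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lncsig import simulate
from lncsig.diffexpr import (
    DEResult,
    bh_adjust,
    estimate_dispersion,
    filter_expressed,
    fpkm,
    nb_wald_test,
    size_factors,
)
from lncsig.models import CountMatrix, ValidationError


def _cm(arr, conditions=None, lengths=None):
    arr = np.asarray(arr)
    samples = [f"s{j}" for j in range(arr.shape[1])]
    cond = conditions or {s: "a" for s in samples}
    return CountMatrix(arr, cond, lengths or {},
                       feature_ids=[f"f{i}" for i in range(arr.shape[0])],
                       sample_ids=samples)


class TestSizeFactors:
    def test_scaled_pair(self):
        # sample2 exactly 4x sample1 -> factors (0.5, 2.0)
        rng = np.random.default_rng(0)
        col = rng.integers(1, 100, size=30)
        cm = _cm(np.stack([col, 4 * col], axis=1))
        f = size_factors(cm)
        assert f["s0"] == pytest.approx(0.5)
        assert f["s1"] == pytest.approx(2.0)

    def test_identical_samples(self):
        cm = _cm(np.tile(np.arange(1, 11)[:, None], (1, 3)))
        f = size_factors(cm)
        assert all(v == pytest.approx(1.0) for v in f.values())

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_direct_formula(self, seed):
        # independent brute-force median-of-ratios
        rng = np.random.default_rng(seed)
        arr = rng.integers(1, 500, size=(50, 4))
        cm = _cm(arr)
        f = size_factors(cm)
        gm = np.array([np.prod(row.astype(float)) ** (1 / 4) for row in arr])
        raw = np.array([np.median(arr[:, j] / gm) for j in range(4)])
        expected = raw / np.prod(raw) ** (1 / 4)
        got = f.as_array(cm.sample_ids)
        assert got == pytest.approx(expected)

    def test_geometric_mean_one(self):
        rng = np.random.default_rng(3)
        cm = _cm(rng.integers(1, 50, size=(20, 5)))
        f = size_factors(cm)
        assert np.prod(f.as_array(cm.sample_ids)) == pytest.approx(1.0)

    def test_feature_permutation_invariance(self):
        rng = np.random.default_rng(4)
        arr = rng.integers(1, 50, size=(20, 4))
        f1 = size_factors(_cm(arr))
        f2 = size_factors(_cm(arr[rng.permutation(20)]))
        for s in f1:
            assert f1[s] == pytest.approx(f2[s])

    def test_sample_scaling_equivariance(self):
        rng = np.random.default_rng(5)
        arr = rng.integers(1, 50, size=(30, 3))
        scaled = arr.copy()
        scaled[:, 1] *= 3
        f0 = size_factors(_cm(arr)).as_array(["s0", "s1", "s2"])
        f1 = size_factors(_cm(scaled)).as_array(["s0", "s1", "s2"])
        raw0, raw1 = f0 / f0[0], f1 / f1[0]
        assert raw1[1] / raw0[1] == pytest.approx(3.0)
        assert raw1[2] / raw0[2] == pytest.approx(1.0)

    def test_poscounts_fallback_warns(self):
        arr = np.array([[5, 0, 3], [0, 4, 2], [7, 2, 0]])
        with pytest.warns(RuntimeWarning):
            f = size_factors(_cm(arr))
        assert all(v > 0 for v in f.values())


class TestDispersion:
    @staticmethod
    def _groups(cm):
        n = len(cm.sample_ids)
        return {"a": cm.sample_ids[: n // 2], "b": cm.sample_ids[n // 2 :]}

    def test_poisson_counts_floor_mom(self):
        # Poisson (alpha=0): most raw moment estimates land at the floor
        hits = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            cm = _cm(rng.poisson(50, size=(200, 6)))
            d = estimate_dispersion(cm, size_factors(cm), self._groups(cm), method="mom")
            a = np.array(list(d.values()))
            hits.append((a <= 1e-8).mean())
        assert np.mean(hits) > 0.5

    def test_nb_counts_recover_alpha(self):
        meds = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            mu, alpha = 100.0, 0.1
            r = 1 / alpha
            cm = _cm(rng.negative_binomial(r, r / (r + mu), size=(200, 6)))
            d = estimate_dispersion(cm, size_factors(cm), self._groups(cm))
            meds.append(np.median(list(d.values())))
        assert 0.05 <= np.median(meds) <= 0.2

    def test_constant_feature_at_floor(self):
        arr = np.vstack([np.full(6, 20), np.arange(1, 7) * 10])
        cm = _cm(arr)
        f = {s: 1.0 for s in cm.sample_ids}
        from lncsig.diffexpr import NormFactors

        d = estimate_dispersion(cm, NormFactors(f), self._groups(cm), method="mom")
        assert d["f0"] == pytest.approx(1e-8)

    def test_single_replicate_group_rejected(self):
        cm = _cm(np.ones((5, 3), dtype=int))
        with pytest.raises(ValidationError):
            estimate_dispersion(cm, size_factors(cm), {"a": ["s0"], "b": ["s1", "s2"]})

    def test_unknown_method_rejected(self):
        cm = _cm(np.ones((5, 4), dtype=int))
        with pytest.raises(ValidationError):
            estimate_dispersion(cm, size_factors(cm), self._groups(cm), method="magic")


class TestWald:
    def test_identical_groups_null(self):
        rng = np.random.default_rng(0)
        col = rng.integers(10, 100, size=50)
        arr = np.tile(col[:, None], (1, 4))
        cm = _cm(arr)
        f = size_factors(cm)
        d = {fid: 0.1 for fid in cm.feature_ids}
        res = nb_wald_test(cm, f, d, ["s0", "s1"], ["s2", "s3"])
        for r in res:
            assert r.log2fc == pytest.approx(0.0)
            assert r.p == pytest.approx(1.0)

    def test_eightfold_shift_low_dispersion(self):
        base = np.full(20, 4000)
        arr = np.stack([base, base, 8 * base, 8 * base], axis=1)
        cm = _cm(arr)
        from lncsig.diffexpr import NormFactors

        f = NormFactors({s: 1.0 for s in cm.sample_ids})
        d = {fid: 1e-8 for fid in cm.feature_ids}
        res = nb_wald_test(cm, f, d, ["s0", "s1"], ["s2", "s3"])
        for r in res:
            assert r.log2fc == pytest.approx(3.0, abs=1e-3)

    def test_null_type_one_error(self):
        # acceptance criterion 3 at reduced seed count (full version in
        # test_acceptance)
        rng = np.random.default_rng(11)
        base = rng.lognormal(5, 1.5, 2000)
        r = 1 / 0.1
        counts = rng.negative_binomial(r, r / (r + base[:, None]), size=(2000, 6))
        cm = _cm(counts)
        f = size_factors(cm)
        groups = {"a": ["s0", "s1", "s2"], "b": ["s3", "s4", "s5"]}
        d = estimate_dispersion(cm, f, groups)
        res = nb_wald_test(cm, f, d, groups["a"], groups["b"])
        frac = np.mean([r_.p < 0.05 for r_ in res])
        assert 0.03 <= frac <= 0.07

    def test_overlapping_groups_rejected(self):
        cm = _cm(np.ones((3, 4), dtype=int))
        with pytest.raises(ValidationError):
            nb_wald_test(cm, size_factors(cm), {f: 0.1 for f in cm.feature_ids},
                         ["s0", "s1"], ["s1", "s2"])

    def test_missing_dispersion_rejected(self):
        cm = _cm(np.ones((3, 4), dtype=int))
        with pytest.raises(ValidationError):
            nb_wald_test(cm, size_factors(cm), {"f0": 0.1}, ["s0", "s1"], ["s2", "s3"])


class TestBH:
    def test_step_up_arithmetic(self):
        # frozen from the step-up formula: p*(m/i), min from the tail
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])

    def test_all_equal(self):
        assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_against_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        for _ in range(10):
            p = rng.random(50)
            expected = multipletests(p, method="fdr_bh")[1]
            assert bh_adjust(list(p)) == pytest.approx(list(expected))

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_dominates_raw_and_order_monotone(self, pvals):
        adj = bh_adjust(pvals)
        assert all(0 <= a <= 1 for a in adj)
        assert all(a >= p - 1e-12 for a, p in zip(adj, pvals))
        order = np.argsort(pvals)
        ranked = np.array(adj)[order]
        assert all(ranked[i] <= ranked[i + 1] + 1e-12 for i in range(len(ranked) - 1))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.2])


class TestFpkm:
    def test_closed_form(self):
        cm = _cm([[1000]], lengths={"f0": 2000})
        vals = fpkm(cm, totals={"s0": 10_000_000})
        assert vals.iloc[0, 0] == pytest.approx(50.0)

    def test_zero_counts(self):
        cm = _cm([[0]], lengths={"f0": 500})
        assert fpkm(cm, totals={"s0": 1e6}).iloc[0, 0] == 0.0

    def test_doubling_totals_halves(self):
        cm = _cm([[100], [200]], lengths={"f0": 1000, "f1": 1000})
        v1 = fpkm(cm, totals={"s0": 1e6})
        v2 = fpkm(cm, totals={"s0": 2e6})
        assert np.allclose(v2.to_numpy() * 2, v1.to_numpy())

    def test_missing_length_rejected(self):
        cm = _cm([[1], [2]], lengths={"f0": 100})
        with pytest.raises(ValidationError):
            fpkm(cm, totals={"s0": 1e6})


class TestFilterExpressed:
    def test_min_mean_zero_keeps_all(self):
        cm = _cm(np.zeros((4, 3), dtype=int) + [[1], [0], [5], [0]])
        f = size_factors(cm)
        assert filter_expressed(cm, f, min_mean=0.0) == cm.feature_ids

    def test_all_zero_excluded(self):
        arr = np.array([[0, 0, 0], [10, 10, 10]])
        cm = _cm(arr)
        f = size_factors(cm)
        assert filter_expressed(cm, f, min_mean=1.0) == ["f1"]

    def test_threshold_split(self):
        # planted means exactly bracket the threshold with unit factors
        arr = np.array([[2, 2, 2], [1, 1, 1], [0, 0, 0]])
        cm = _cm(arr)
        from lncsig.diffexpr import NormFactors

        f = NormFactors({s: 1.0 for s in cm.sample_ids})
        assert filter_expressed(cm, f, min_mean=1.5) == ["f0"]
        assert filter_expressed(cm, f, min_mean=1.0) == ["f0", "f1"]

    def test_unknown_condition_rejected(self):
        cm = _cm(np.ones((2, 2), dtype=int))
        with pytest.raises(ValidationError):
            filter_expressed(cm, size_factors(cm), condition="missing")


class TestDEResult:
    def test_invariants(self):
        with pytest.raises(ValidationError):
            DEResult("f", 1.0, np.inf, 1.0, 0.5, 0.5)
        with pytest.raises(ValidationError):
            DEResult("f", 1.0, 0.0, 1.0, 1.5, 0.5)

    def test_padj_dominates_p_in_pipeline_results(self, small_dataset):
        _ann, _truth, _peaks, cm = small_dataset
        f = size_factors(cm)
        groups = {c: cm.samples_in(c) for c in simulate.CONDITIONS}
        d = estimate_dispersion(cm, f, groups)
        res = nb_wald_test(cm, f, d, groups["naive"], groups["treg_wt"])
        for r in res:
            assert r.padj >= r.p - 1e-12
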