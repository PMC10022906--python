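"""Signal-to-noise AUC, limit of detection, and the QC filtering chain."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ipmndsp import (
    ProbeCountMatrix,
    ValidationError,
    collapse_probes,
    compute_lod,
    compute_snauc,
    filter_aois,
    filter_genes,
    filter_probes,
    is_detected,
)
from ipmndsp.qc import aoi_lods, run_qc


def brute_force_auc(pos, neg):
    wins = sum((p > n_) + 0.5 * (p == n_) for p in pos for n_ in neg)
    return wins / (len(pos) * len(neg))


from conftest import make_probe_matrix as make_matrix


class TestSnauc:
    @pytest.mark.parametrize(
        "gene,neg,expected",
        [
            ([5, 6, 7], [1, 2, 3], 1.0),  # complete separation
            ([3, 1], [2, 2], 0.5),  # two wins, two losses
            ([2, 3], [2, 1], 0.875),  # 3 wins + one tie at 1/2
        ],
    )
    def test_hand_examples(self, gene, neg, expected):
        assert compute_snauc(gene, neg) == pytest.approx(expected)

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n_pos, n_neg = rng.integers(1, 51, size=2)
            pos = rng.integers(0, 20, size=n_pos)
            neg = rng.integers(0, 20, size=n_neg)
            assert compute_snauc(pos, neg) == pytest.approx(brute_force_auc(pos, neg))

    @given(
        pos=st.lists(st.integers(0, 100), min_size=1, max_size=20),
        neg=st.lists(st.integers(0, 100), min_size=1, max_size=20),
    )
    @settings(max_examples=50, deadline=None, derandomize=True, database=None)
    def test_invariant_under_monotone_transform(self, pos, neg):
        base = compute_snauc(pos, neg)
        f = lambda v: [np.expm1(x / 10.0) + 3 for x in v]  # strictly increasing
        assert compute_snauc(f(pos), f(neg)) == pytest.approx(base)

    def test_empty_class_raises(self):
        with pytest.raises(ValidationError, match="positive"):
            compute_snauc([], [1, 2])
        with pytest.raises(ValidationError, match="negative"):
            compute_snauc([1, 2], [])


class TestLod:
    def test_constant_and_zero_vectors(self):
        assert compute_lod([4] * 75) == 4
        assert compute_lod([0] * 75) == 0

    def test_linear_interpolation_convention(self):
        # independent oracle: h = (n-1)*q, interpolate adjacent order stats
        values = np.arange(1, 11, dtype=float)
        h = (len(values) - 1) * 0.9
        lo, frac = int(np.floor(h)), h - int(np.floor(h))
        expected = values[lo] + frac * (values[lo + 1] - values[lo])
        assert compute_lod(values) == pytest.approx(expected)
        rng = np.random.default_rng(1)
        for _ in range(20):
            v = np.sort(rng.integers(0, 100, size=rng.integers(2, 80)))
            h = (len(v) - 1) * 0.9
            lo, frac = int(np.floor(h)), h - np.floor(h)
            hi = min(lo + 1, len(v) - 1)
            assert compute_lod(v) == pytest.approx(v[lo] + frac * (v[hi] - v[lo]))

    def test_empty_raises(self):
        with pytest.raises(ValidationError):
            compute_lod([])


def test_detection_boundary():
    # equality with the LOD is not "below", hence detected
    assert is_detected(5, 5)
    assert not is_detected(4.9, 5)
    assert is_detected(0, 0)


class TestFilterAois:
    def make(self, totals_and_snaucs):
        # one high gene probe per AOI controls totals; negatives control snAUC
        cols = {}
        for i, (total, sep) in enumerate(totals_and_snaucs):
            cols[f"a{i}"] = (total, sep)
        gene_rows = [[cols[a][0] - 30 for a in cols]]  # bulk of the counts
        neg_rows = [[1 if cols[a][1] else 10**6 for a in cols] for _ in range(3)]
        genes2 = [[10 for _ in cols] for _ in range(3)]
        m = make_matrix(gene_rows + genes2, neg_rows, aois=list(cols))
        return m

    def test_low_count_aoi_removed_with_reason(self):
        m = self.make([(99_000, True), (500_000, True)])
        filtered, records = filter_aois(m)
        assert list(filtered.aoi_ids) == ["a1"]
        failed = next(r for r in records if r.aoi_id == "a0")
        assert not failed.passed and "low counts" in failed.reasons

    def test_snauc_boundary_is_strict(self):
        gene_rows = [[100] * 4, [4] * 4, [1] * 4, [1] * 4]
        neg_rows = [[2] * 4, [2] * 4]
        m = make_matrix(gene_rows, neg_rows)
        # snAUC here: pairs = 4x2=8 per AOI; wins: 100>2 (2), 4>2 (2); 1<2 loses
        rec = filter_aois(m, min_counts=0, min_snauc=0.4)[1][0]
        assert rec.snauc == pytest.approx(0.5)
        with pytest.raises(ValidationError, match="no AOIs pass"):
            filter_aois(m, min_counts=0, min_snauc=0.5)  # equality fails

    def test_passing_aoi_retained(self):
        m = self.make([(500_000, True)])
        filtered, records = filter_aois(m)
        assert records[0].passed and list(filtered.aoi_ids) == ["a0"]


class TestFilterProbes:
    def make_detection_matrix(self, n_detected, n_aois=100):
        # negatives all 10 -> LOD 10 everywhere; probe counts 10 (detected) or 0
        probe = [10] * n_detected + [0] * (n_aois - n_detected)
        anchor = [10] * n_aois
        neg = [[10] * n_aois for _ in range(5)]
        return make_matrix([probe, anchor], neg)

    @pytest.mark.parametrize("n_detected,kept", [(19, False), (20, True), (100, True)])
    def test_boundary(self, n_detected, kept):
        m = self.make_detection_matrix(n_detected)
        out = filter_probes(m)
        assert ("G000_p1" in out.counts.index) is kept

    def test_negative_probes_never_removed(self):
        m = make_matrix([[10] * 10], [[0] * 10, [10] * 10])
        out = filter_probes(m)
        assert out.n_negative_probes == 2


class TestCollapse:
    def test_geometric_mean_examples(self):
        probes = ["GA_p1", "GA_p2", "GB_p1", "GB_p2", "GB_p3", "GC_p1", "GC_p2", "NEG_p1"]
        counts = pd.DataFrame(
            {"a0": [1, 4, 2, 2, 2, 0, 8, 3]}, index=probes
        )
        manifest = pd.DataFrame(
            {
                "gene": ["GA", "GA", "GB", "GB", "GB", "GC", "GC", ""],
                "is_negative": [False] * 7 + [True],
            },
            index=probes,
        )
        expr = collapse_probes(ProbeCountMatrix(counts, manifest))
        assert expr.values.loc["GA", "a0"] == pytest.approx(2.0)
        assert expr.values.loc["GB", "a0"] == pytest.approx(2.0)
        # zero replaced by 1 before the geometric mean
        assert expr.values.loc["GC", "a0"] == pytest.approx(np.sqrt(8))

    def test_chain_is_invariant_to_probe_row_order(self, small_dataset):
        pcm, _, _ = small_dataset
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(pcm.counts))
        shuffled = ProbeCountMatrix(pcm.counts.iloc[perm], pcm.manifest.iloc[perm])

        def chain(m):
            m = filter_probes(m)
            expr = collapse_probes(m)
            return filter_genes(expr, aoi_lods(m))

        a, b = chain(pcm), chain(shuffled)
        pd.testing.assert_frame_equal(a.values, b.values)


class TestFilterGenes:
    def make_expr_and_lods(self, detected_in, n_aois=100):
        vals = [[10.0] * detected_in + [1.0] * (n_aois - detected_in), [10.0] * n_aois]
        from conftest import expr_matrix

        expr = expr_matrix(vals, stage="collapsed_raw", genes=["gA", "gB"])
        lods = pd.Series(5.0, index=expr.aoi_ids)
        return expr, lods

    @pytest.mark.parametrize("detected_in,kept", [(19, False), (20, True), (100, True)])
    def test_at_least_20_percent_boundary(self, detected_in, kept):
        expr, lods = self.make_expr_and_lods(detected_in)
        out = filter_genes(expr, lods)
        assert ("gA" in out.genes) is kept

    def test_no_genes_left_raises(self):
        expr, lods = self.make_expr_and_lods(0)
        with pytest.raises(ValidationError):
            filter_genes(expr, lods + 100.0)


def test_run_qc_end_to_end(small_dataset):
    pcm, annotation, _ = small_dataset
    expr, pcm_f, records, lods = run_qc(pcm)
    assert expr.stage == "collapsed_raw"
    assert set(expr.aoi_ids) <= set(pcm.aoi_ids)
    assert all(0 <= r.snauc <= 1 for r in records)
    assert all(r.passed == (not r.reasons) for r in records)
    assert len(lods) == len(expr.aoi_ids)
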