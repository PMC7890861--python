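"""Rarefaction, alpha/beta diversity, ordination, cohort-structure tests."""

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix

from flavopipe.community import (
    bray_curtis,
    chao1,
    compare_shift_magnitude,
    compare_within_between_subject,
    filter_min_total_reads,
    pcoa,
    rarefaction_depth_scan,
    rarefy_table,
    shannon,
)
from flavopipe.types import OtuTable, SampleRecord


def make_table(rows, samples=None, otus=None):
    rows = np.atleast_2d(rows)
    samples = samples or [f"s{i}" for i in range(rows.shape[0])]
    otus = otus or [f"o{i}" for i in range(rows.shape[1])]
    return OtuTable(pd.DataFrame(rows, index=samples, columns=otus))


class TestRarefy:
    def test_below_depth_sample_dropped(self):
        table = make_table([[4999, 0], [3000, 2500]])
        out = rarefy_table(table, 5000, seed=0)
        assert out.sample_ids == ["s1"]

    def test_row_sums_equal_depth_and_bounded_by_original(self):
        table = make_table([[3000, 2500, 10], [7000, 1, 0]])
        out = rarefy_table(table, 5000, seed=1)
        assert (out.counts.sum(axis=1) == 5000).all()
        assert (out.counts.to_numpy() <= table.counts.loc[out.sample_ids].to_numpy()).all()

    def test_deterministic_per_seed(self):
        table = make_table([[3000, 2500, 10], [7000, 1, 0]])
        a = rarefy_table(table, 5000, seed=42)
        b = rarefy_table(table, 5000, seed=42)
        assert a.counts.equals(b.counts)
        c = rarefy_table(table, 5000, seed=43)
        assert not a.counts.equals(c.counts)

    def test_no_sample_deep_enough_rejected(self):
        with pytest.raises(ValueError):
            rarefy_table(make_table([[10, 10]]), 5000, seed=0)

    def test_non_integer_counts_rejected_at_construction(self):
        with pytest.raises(ValueError):
            OtuTable(pd.DataFrame([[1.5, 2.0]], index=["s"], columns=["a", "b"]))


class TestDepthScan:
    def test_single_sample_retention(self):
        table = make_table([[60, 40]])
        scan = rarefaction_depth_scan(table, [50, 200], seed=0)
        assert list(scan.samples_retained) == [1, 0]

    def test_absurd_depth_retains_nothing(self):
        table = make_table([[60, 40], [10, 5]])
        scan = rarefaction_depth_scan(table, [10, 10**9], seed=0)
        assert scan.samples_retained.iloc[-1] == 0

    def test_retained_counts_non_increasing(self, small_cohort):
        table, _ = small_cohort
        scan = rarefaction_depth_scan(table, [500, 1000, 2000, 4000, 8000, 16000], 3)
        assert (np.diff(scan.samples_retained) <= 0).all()


class TestAlphaDiversity:
    @pytest.mark.parametrize(
        "counts, expected",
        [([5, 5, 5], 3.0), ([1, 1, 2], 3.5), ([1, 0, 0], 1.0)],
    )
    def test_chao1_known_values(self, counts, expected):
        assert chao1(counts) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "counts, expected", [([8], 0.0), ([4, 4], 1.0), ([1, 1, 1, 1], 2.0)]
    )
    def test_shannon_known_values(self, counts, expected):
        assert shannon(counts) == pytest.approx(expected)

    def test_bounds_on_random_vectors(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            counts = rng.integers(0, 30, size=rng.integers(2, 40))
            if counts.sum() == 0:
                continue
            observed = int((counts > 0).sum())
            assert chao1(counts) >= observed
            assert 0.0 <= shannon(counts) <= np.log2(len(counts)) + 1e-12

    @pytest.mark.parametrize("func", [chao1, shannon])
    def test_all_zero_rejected(self, func):
        with pytest.raises(ValueError):
            func([0, 0, 0])


class TestBrayCurtis:
    def test_known_values(self):
        table = make_table([[3, 1], [1, 3], [3, 1], [0, 5]],
                           samples=["a", "b", "c", "d"])
        dm = bray_curtis(table)
        assert dm["a", "b"] == pytest.approx(0.5)  # 1 - 2(1+1)/8
        assert dm["a", "c"] == pytest.approx(0.0)
        # disjoint support
        dm2 = bray_curtis(make_table([[5, 0], [0, 7]]))
        assert dm2["s0", "s1"] == pytest.approx(1.0)

    def test_symmetry_identity_bounds_on_generated_data(self, small_cohort):
        table, _ = small_cohort
        dm = bray_curtis(table)
        data = dm.data
        assert np.allclose(data, data.T)
        assert np.allclose(np.diag(data), 0.0)
        assert ((data >= 0) & (data <= 1)).all()

    def test_all_zero_sample_named_in_error(self):
        counts = pd.DataFrame([[1, 2], [0, 0]], index=["ok", "bad"], columns=["a", "b"])
        with pytest.raises(ValueError, match="bad"):
            bray_curtis(counts)


class TestPcoa:
    def test_equilateral_triangle_gives_two_equal_eigenvalues(self):
        dm = DistanceMatrix(
            [[0, 1, 1], [1, 0, 1], [1, 1, 0]], ids=["a", "b", "c"]
        )
        result = pcoa(dm)
        positive = result.eigenvalues[result.eigenvalues > 1e-12]
        assert len(positive) == 2
        assert positive[0] == pytest.approx(positive[1])

    def test_collinear_points_explained_entirely_by_axis_one(self):
        xs = np.array([0.0, 1.0, 2.5, 4.0])
        d = np.abs(xs[:, None] - xs[None, :])
        result = pcoa(DistanceMatrix(d, ids=list("abcd")))
        assert result.explained_fraction[0] == pytest.approx(1.0)

    def test_round_trips_euclidean_configuration(self):
        rng = np.random.default_rng(8)
        points = rng.normal(size=(10, 2))
        d = np.linalg.norm(points[:, None] - points[None, :], axis=-1)
        result = pcoa(DistanceMatrix(d, ids=[str(i) for i in range(10)]))
        coords = result.coordinates.to_numpy()
        d_rec = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        assert np.abs(d_rec - d).max() < 1e-8

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            pcoa(DistanceMatrix([[0, 1], [1, 0]], ids=["a", "b"]))


def _meta(entries):
    return [SampleRecord(*e) for e in entries]


class TestWithinBetweenSubject:
    def test_duplicate_samples_within_subject(self):
        # two samples per subject with identical compositions -> d_within = 0
        table = make_table(
            [[10, 0, 5], [10, 0, 5], [0, 8, 2], [0, 8, 2], [3, 3, 3], [3, 3, 3]],
            samples=["a0", "a1", "b0", "b1", "c0", "c1"],
        )
        dm = bray_curtis(table)
        meta = _meta(
            [
                ("a0", "A", "placebo", "week0"), ("a1", "A", "placebo", "week24"),
                ("b0", "B", "placebo", "week0"), ("b1", "B", "placebo", "week24"),
                ("c0", "C", "cranberry", "week0"), ("c1", "C", "cranberry", "week24"),
            ]
        )
        w, b, p = compare_within_between_subject(dm, meta)
        assert w == 0.0
        assert b > 0.0
        assert p < 0.05

    def test_no_subject_pairs_rejected(self):
        table = make_table([[1, 2], [3, 4]], samples=["x", "y"])
        dm = bray_curtis(table)
        meta = _meta([("x", "S1", "placebo", "week0"), ("y", "S2", "placebo", "week0")])
        with pytest.raises(ValueError):
            compare_within_between_subject(dm, meta)

    def test_null_not_anticonservative_under_permuted_labels(self):
        """With no subject effect the within/between comparison must not
        reject more often than nominal. (Exact uniformity is not expected:
        distance pairs sharing a sample are correlated, a property of the
        naive all-pairs comparison this method deliberately replicates, and
        that correlation makes the test conservative.)"""
        rng = np.random.default_rng(123)
        pvals = []
        for _ in range(200):
            points = rng.normal(size=(12, 3))
            d = np.linalg.norm(points[:, None] - points[None, :], axis=-1)
            d = d / (d.max() + 1e-9)
            ids = [f"s{i}" for i in range(12)]
            dm = DistanceMatrix(d, ids=ids)
            subjects = rng.permutation(np.repeat(np.arange(6), 2))
            meta = _meta(
                [
                    (ids[i], f"S{subjects[i]}", "placebo",
                     "week0" if i % 2 == 0 else "week24")
                    for i in range(12)
                ]
            )
            pvals.append(compare_within_between_subject(dm, meta)[2])
        pvals = np.array(pvals)
        for alpha in (0.01, 0.05, 0.10):
            band = 3 * np.sqrt(alpha * (1 - alpha) / len(pvals))
            assert (pvals < alpha).mean() <= alpha + band
        # and the comparison should still be responsive, not degenerate
        assert np.median(pvals) < 0.9

    def test_strong_subject_effect_detected(self):
        from flavopipe.synth import CohortSpec, generate_cohort

        hits = 0
        for seed in range(20):
            spec = CohortSpec(
                n_subjects_cranberry=6, n_subjects_placebo=6, n_taxa=50,
                depth_range=(2000, 4000), subject_effect_scale=2.0, seed=seed,
            )
            table, meta = generate_cohort(spec)
            _, _, p = compare_within_between_subject(bray_curtis(table), meta)
            if p < 1e-4:
                hits += 1
        assert hits >= 18


class TestShiftMagnitude:
    def _shift_fixture(self, rng, arm_scale):
        ids, meta, points = [], [], []
        for i, (arm, scale) in enumerate(
            [("cranberry", arm_scale[0])] * 6 + [("placebo", arm_scale[1])] * 6
        ):
            base = rng.normal(size=3)
            for visit in ("week0", "week24"):
                sid = f"s{i}_{visit}"
                ids.append(sid)
                meta.append(SampleRecord(sid, f"S{i}", arm, visit))
                points.append(base + (rng.normal(size=3) * scale if visit == "week24" else 0))
        d = np.linalg.norm(
            np.array(points)[:, None] - np.array(points)[None, :], axis=-1
        )
        return DistanceMatrix(d / (d.max() + 1e-9), ids=ids), meta

    def test_null_rarely_significant(self):
        rng = np.random.default_rng(21)
        hits = sum(
            compare_shift_magnitude(*self._shift_fixture(rng, (0.5, 0.5)))[2] >= 0.05
            for _ in range(50)
        )
        assert hits >= 45

    def test_larger_shift_in_one_arm_detected(self):
        rng = np.random.default_rng(22)
        hits = sum(
            compare_shift_magnitude(*self._shift_fixture(rng, (0.1, 2.0)))[2] < 0.05
            for _ in range(50)
        )
        assert hits >= 45

    def test_single_subject_per_arm_rejected(self):
        rng = np.random.default_rng(23)
        dm, meta = self._shift_fixture(rng, (0.5, 0.5))
        keep = {"S0", "S6"}
        meta_small = [m for m in meta if m.subject_id in keep]
        with pytest.raises(ValueError):
            compare_shift_magnitude(dm, meta_small)


def test_min_total_read_filter():
    table = make_table([[9, 10, 0], [0, 5, 3]])
    out = filter_min_total_reads(table, 10)
    assert out.otu_ids == ["o1"]
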