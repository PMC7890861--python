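"""Paired differential-abundance pipeline: filters, fold-changes, tests."""

import numpy as np
import pandas as pd
import pytest

from flavopipe.community import filter_min_total_reads, rarefy_table
from flavopipe.differential import (
    differential_features,
    differential_pathways,
    exact_sequence_abundance,
    filter_for_differential,
    log2_fold_change,
    pairwise_differences_validation,
)
from flavopipe.synth import CohortSpec, generate_cohort
from flavopipe.types import AnalysisConfig, OtuTable, SampleRecord


def _paired_meta(n_subjects, arms):
    meta, samples = [], []
    for i in range(n_subjects):
        for visit in ("week0", "week24"):
            sid = f"S{i}_{visit}"
            samples.append(sid)
            meta.append(SampleRecord(sid, f"S{i}", arms[i], visit))
    return meta, samples


class TestFilterForDifferential:
    def _table(self, n_subjects, present_in, arms=None):
        arms = arms or ["placebo"] * n_subjects
        meta, samples = _paired_meta(n_subjects, arms)
        counts = np.zeros((len(samples), 2), dtype=int)
        counts[:, 0] = 5  # keeper OTU present everywhere
        counts[:present_in, 1] = 1
        table = OtuTable(pd.DataFrame(counts, index=samples, columns=["keep", "rare"]))
        return table, meta

    def test_prevalence_boundary_is_inclusive(self, default_config):
        # 25 samples: present in 6 (24%) -> dropped; in 7 (28%) -> kept.
        # Use 25 paired samples via 12.5 -> use 50 samples from 25 subjects.
        table, meta = self._table(25, present_in=12)  # 12/50 = 24%
        filtered, _ = filter_for_differential(table, meta, default_config)
        assert filtered.otu_ids == ["keep"]
        table, meta = self._table(25, present_in=13)  # 13/50 = 26%
        filtered, _ = filter_for_differential(table, meta, default_config)
        assert "rare" in filtered.otu_ids

    def test_unpaired_subject_excluded(self, default_config):
        meta, samples = _paired_meta(3, ["placebo"] * 3)
        meta = [m for m in meta if m.sample_id != "S2_week24"]
        counts = pd.DataFrame(
            np.full((6, 2), 4), index=samples, columns=["a", "b"]
        )
        filtered, subjects = filter_for_differential(
            OtuTable(counts), meta, default_config
        )
        assert subjects == ["S0", "S1"]
        assert "S2_week0" not in filtered.sample_ids

    def test_counts_of_retained_features(self, default_config):
        rng = np.random.default_rng(0)
        meta, samples = _paired_meta(10, ["placebo"] * 5 + ["cranberry"] * 5)
        counts = rng.integers(1, 50, size=(20, 10))
        counts[:, 7:] = 0
        counts[0, 7:] = 1  # 3 OTUs in 1/20 = 5% of samples -> dropped
        table = OtuTable(
            pd.DataFrame(counts, index=samples, columns=[f"o{i}" for i in range(10)])
        )
        filtered, _ = filter_for_differential(table, meta, default_config)
        assert len(filtered.otu_ids) == 7

    def test_no_paired_subjects_rejected(self, default_config):
        meta = [SampleRecord("x", "S1", "placebo", "week0")]
        table = OtuTable(pd.DataFrame([[3]], index=["x"], columns=["a"]))
        with pytest.raises(ValueError):
            filter_for_differential(table, meta, default_config)


class TestLog2FoldChange:
    @pytest.mark.parametrize(
        "wk0, wk24, expected", [(0, 0, 0.0), (1, 3, 1.0), (7, 31, 2.0)]
    )
    def test_known_values(self, wk0, wk24, expected):
        assert log2_fold_change(wk0, wk24) == pytest.approx(expected)

    def test_pathway_pseudocount(self):
        assert log2_fold_change(0, 0.008, pseudocount=0.001) == pytest.approx(
            np.log2(0.009 / 0.001)
        )

    def test_negative_reads_rejected(self):
        with pytest.raises(ValueError):
            log2_fold_change(-1, 5)


class TestDifferentialFeatures:
    def test_planted_taxon_recovered(self):
        cfg = AnalysisConfig()
        hits = 0
        for seed in range(5):
            table, meta = generate_cohort(CohortSpec(seed=seed))
            rarefied = filter_min_total_reads(rarefy_table(table, 5000, seed))
            filtered, _ = filter_for_differential(rarefied, meta, cfg)
            res = differential_features(filtered, meta, cfg)
            top = res.iloc[0]
            if top.feature_id == "OTU41" and top.p_adj < cfg.alpha:
                hits += 1
        assert hits >= 4

    def test_invariant_to_feature_and_sample_order(self, small_cohort):
        table, meta = small_cohort
        cfg = AnalysisConfig()
        filtered, _ = filter_for_differential(table, meta, cfg)
        res = differential_features(filtered, meta, cfg)
        rng = np.random.default_rng(1)
        shuffled = OtuTable(
            filtered.counts.iloc[
                rng.permutation(len(filtered.sample_ids)),
                rng.permutation(len(filtered.otu_ids)),
            ]
        )
        res2 = differential_features(shuffled, meta, cfg)
        merged = res.merge(res2, on="feature_id", suffixes=("", "_2"))
        assert np.allclose(merged.p, merged.p_2)
        assert np.allclose(merged.delta, merged.delta_2)

    def test_fold_change_zero_for_doubly_absent_subjects(self, default_config):
        meta, samples = _paired_meta(4, ["placebo", "placebo", "cranberry", "cranberry"])
        counts = pd.DataFrame(
            {"a": [4, 8, 2, 2, 5, 5, 1, 3], "b": [0] * 8},
            index=samples,
        )
        counts.loc["S0_week0", "b"] = 0  # subject S0 absent both visits
        res = differential_features(OtuTable(counts), meta, default_config)
        row = res[res.feature_id == "b"].iloc[0]
        assert row.median_fc_cranberry == 0.0 and row.median_fc_placebo == 0.0


class TestPairwiseDifferencesValidation:
    def test_identical_profiles_give_p_one(self):
        meta, samples = _paired_meta(4, ["placebo", "placebo", "cranberry", "cranberry"])
        profile = np.array([0.2, 0.3, 0.5])
        rel = pd.DataFrame(
            np.tile(profile, (8, 1)), index=samples, columns=["a", "b", "c"]
        )
        res = pairwise_differences_validation(rel, meta)
        assert (res.p == 1.0).all()

    def test_concordant_with_fold_change_test_on_planted_fixture(self):
        cfg = AnalysisConfig()
        table, meta = generate_cohort(CohortSpec(seed=0))
        rarefied = filter_min_total_reads(rarefy_table(table, 5000, 0))
        filtered, _ = filter_for_differential(rarefied, meta, cfg)
        fc_res = differential_features(filtered, meta, cfg)
        rel = filtered.counts.div(filtered.counts.sum(axis=1), axis=0)
        pd_res = pairwise_differences_validation(rel, meta)
        assert pd_res.iloc[0].feature_id == fc_res.iloc[0].feature_id == "OTU41"

    def test_direction_agrees_with_fold_change_sign(self):
        cfg = AnalysisConfig()
        table, meta = generate_cohort(CohortSpec(seed=3))
        rarefied = filter_min_total_reads(rarefy_table(table, 5000, 3))
        filtered, _ = filter_for_differential(rarefied, meta, cfg)
        fc = differential_features(filtered, meta, cfg).set_index("feature_id")
        rel = filtered.counts.div(filtered.counts.sum(axis=1), axis=0)
        pdv = pairwise_differences_validation(rel, meta).set_index("feature_id")
        both = fc.join(pdv, lsuffix="_fc")
        agreed = total = 0
        for fc_col, rel_col in [
            ("median_fc_cranberry", "median_diff_cranberry"),
            ("median_fc_placebo", "median_diff_placebo"),
        ]:
            a, b = both[fc_col], both[rel_col]
            informative = (a != 0) & (b != 0)
            agreed += int((np.sign(a[informative]) == np.sign(b[informative])).sum())
            total += int(informative.sum())
        assert agreed / total >= 0.95


class TestDifferentialPathways:
    def _pathway_fixture(self, seed, shift=1.0, n_features=40):
        rng = np.random.default_rng(seed)
        arms = ["cranberry"] * 18 + ["placebo"] * 16
        meta, samples = _paired_meta(34, arms)
        base = rng.lognormal(3, 1, size=(34, n_features))
        data = {}
        for i, subject in enumerate(range(34)):
            wk0 = base[i] * rng.lognormal(0, 0.2, n_features)
            wk24 = base[i] * rng.lognormal(0, 0.2, n_features)
            if arms[subject] == "placebo":
                wk24[0] *= shift
            data[f"S{subject}_week0"] = wk0
            data[f"S{subject}_week24"] = wk24
        features = pd.DataFrame(data, index=[f"PWY{i}" for i in range(n_features)])
        return features[samples], meta

    def test_per_arm_prevalence_filter(self):
        cfg = AnalysisConfig()
        arms = ["cranberry"] * 10 + ["placebo"] * 10
        meta, samples = _paired_meta(20, arms)
        values = np.ones((2, 40))
        # feature 'skew': 60% of cranberry subjects, 40% of placebo subjects
        skew = np.zeros(40)
        for i in range(6):
            skew[2 * i] = skew[2 * i + 1] = 1.0  # cranberry subjects 0-5
        for i in range(10, 14):
            skew[2 * i] = skew[2 * i + 1] = 1.0  # placebo subjects 10-13
        table = pd.DataFrame(
            np.vstack([values, skew[None, :]]),
            index=["base1", "base2", "skew"],
            columns=samples,
        )
        res = differential_pathways(table, meta, cfg, cfg.pathway_pseudocount)
        assert "skew" not in set(res.feature_id)
        assert {"base1", "base2"} <= set(res.feature_id)

    def test_planted_pathway_shift_detected(self):
        cfg = AnalysisConfig()
        hits = 0
        for seed in range(10):
            features, meta = self._pathway_fixture(seed, shift=4.0)
            res = differential_pathways(features, meta, cfg, cfg.pathway_pseudocount)
            top = res.iloc[0]
            if top.feature_id == "PWY0" and top.p_adj < 0.05:
                hits += 1
        assert hits >= 9


class TestExactSequenceAbundance:
    QUERY = "ACGTACGGTTACCAGGCATTACCGGATCCGGGATATTACCAGGACCAGGACCTTTACGGA" * 2

    def test_window_match_counted_and_mismatch_not(self):
        window = self.QUERY[5:105]
        mismatch = "A" + window[1:] if window[0] != "A" else "C" + window[1:]
        out = exact_sequence_abundance(
            {"s": [window, mismatch, "G" * 100]}, self.QUERY
        )
        assert out["s"] == pytest.approx(1 / 3)

    def test_reverse_complement_counted(self):
        from Bio.Seq import Seq

        window = str(Seq(self.QUERY[10:110]).reverse_complement())
        out = exact_sequence_abundance({"s": [window]}, self.QUERY)
        assert out["s"] == 1.0

    def test_empty_query_rejected(self):
        with pytest.raises(ValueError):
            exact_sequence_abundance({"s": ["ACGT"]}, "")
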