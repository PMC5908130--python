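"""RPM normalization, detectability filter, differential abundance, cluster
summaries and qPCR concordance."""

import numpy as np
import pandas as pd
import pytest

from plasmir.mapping import CountMatrix
from plasmir.quantify import (cluster_summary, detectable_features,
                              differential_test, mean_centred_profiles,
                              qpcr_concordance, rpm_normalize)
from plasmir.simulate import (SimulationConfig, sample_truth,
                              simulate_count_matrix, simulate_qpcr)


def _cm(features, classes=None, sheet=None):
    features = pd.DataFrame(features)
    if classes is None:
        classes = pd.DataFrame(0.0, index=["transcripts", "genome"],
                               columns=features.columns)
    if sheet is None:
        sheet = pd.DataFrame(index=features.columns)
    sheet.index.name = "sample_id"
    return CountMatrix(features, classes, sheet)


class TestRPM:
    def test_equal_split(self):
        cm = _cm({"s1": {"a": 5.0, "b": 5.0}})
        rpm = rpm_normalize(cm)
        assert rpm.features["s1"].tolist() == [500000.0, 500000.0]

    def test_scale_invariance(self):
        cm1 = _cm({"s1": {"a": 5.0, "b": 15.0}})
        cm3 = _cm({"s1": {"a": 15.0, "b": 45.0}})
        pd.testing.assert_frame_equal(rpm_normalize(cm1).features,
                                      rpm_normalize(cm3).features)

    def test_all_mapped_denominator_sums_to_one_million(self):
        classes = pd.DataFrame({"s1": [30.0, 10.0]},
                               index=["transcripts", "genome"])
        cm = _cm({"s1": {"a": 40.0, "b": 20.0}}, classes=classes)
        rpm_all = rpm_normalize(cm, "all_mapped")
        assert rpm_all.mapped_totals()["s1"] == pytest.approx(1e6)
        rpm_mir = rpm_normalize(cm, "mirna_mapped")
        assert rpm_mir.features["s1"].sum() == pytest.approx(1e6)
        assert rpm_mir.mapped_totals()["s1"] > 1e6

    def test_zero_total_sample_rejected(self):
        cm = _cm({"good": {"a": 5.0}, "empty": {"a": 0.0}})
        with pytest.raises(ValueError, match="empty"):
            rpm_normalize(cm)


class TestDetectability:
    def _sheet(self, n_case, n_ctrl):
        ids = [f"c{i}" for i in range(n_case)] + [f"k{i}" for i in range(n_ctrl)]
        return pd.DataFrame(
            {"condition": ["case"] * n_case + ["control"] * n_ctrl},
            index=pd.Index(ids, name="sample_id"))

    def test_inclusive_thresholds(self):
        """10 reads in 8 of 11 samples passes (8 >= ceil(0.7*11) = 8);
        9 reads everywhere fails the inclusive >= 10 count rule."""
        sheet = self._sheet(11, 11)
        case_ids = sheet.index[:11]
        counts = pd.DataFrame(0.0, index=["edge", "low"], columns=sheet.index)
        counts.loc["edge", case_ids[:8]] = 10.0
        counts.loc["low"] = 9.0
        det = detectable_features(counts, sheet)
        assert "edge" in det.groups["case"]
        assert "edge" not in det.groups["control"]
        assert "low" not in det.universe

    def test_shared_unique_decomposition(self):
        sheet = self._sheet(3, 3)
        counts = pd.DataFrame(
            {s: {"both": 50.0, "case_only": 50.0 if s.startswith("c") else 0.0,
                 "ctrl_only": 0.0 if s.startswith("c") else 50.0}
             for s in sheet.index})
        det = detectable_features(counts, sheet)
        assert det.shared == {"both"}
        assert det.unique["case"] == {"case_only"}
        assert det.unique["control"] == {"ctrl_only"}
        assert len(det.universe) == len(det.shared) + sum(
            len(u) for u in det.unique.values())

    def test_monotone_in_min_reads(self, rng):
        sheet = self._sheet(5, 5)
        counts = pd.DataFrame(rng.integers(0, 40, size=(30, 10)).astype(float),
                              index=[f"f{i}" for i in range(30)],
                              columns=sheet.index)
        sets = [detectable_features(counts, sheet, min_reads=t).universe
                for t in (5, 10, 20, 40)]
        for bigger, smaller in zip(sets, sets[1:]):
            assert smaller <= bigger

    def test_pooled_scope_and_small_group_rejection(self):
        sheet = self._sheet(1, 3)
        counts = pd.DataFrame(20.0, index=["f"], columns=sheet.index)
        with pytest.raises(ValueError):
            detectable_features(counts, sheet)
        det = detectable_features(counts, sheet, scope="pooled")
        assert det.groups["pooled"] == {"f"}


class TestDifferentialTest:
    def _sheet(self, n=11):
        ids = [f"c{i}" for i in range(n)] + [f"k{i}" for i in range(n)]
        return pd.DataFrame({"condition": ["case"] * n + ["control"] * n},
                            index=pd.Index(ids, name="sample_id"))

    def test_identical_groups_not_significant(self):
        sheet = self._sheet(4)
        rpm = pd.DataFrame([[100.0] * 8], index=["f"], columns=sheet.index)
        res = differential_test(rpm, sheet)
        assert res.loc["f", "log2fc"] == 0.0
        assert res.loc["f", "p_value"] == 1.0
        assert not res.loc["f", "significant"]

    def test_fold_change_gate(self, rng):
        """|log2FC| = 0.50 stays below the 1.5-fold gate (log2 1.5 ~ 0.585)
        no matter how small the p-value."""
        sheet = self._sheet(11)
        base = 2.0 ** rng.normal(10, 0.01, size=11)
        rpm = pd.DataFrame([np.concatenate([base * 2 ** 0.50, base])],
                           index=["f"], columns=sheet.index)
        res = differential_test(rpm, sheet)
        assert res.loc["f", "p_value"] < 1e-6
        assert abs(res.loc["f", "log2fc"]) < np.log2(1.5)
        assert not res.loc["f", "significant"]
        res2 = differential_test(rpm, sheet, fold_threshold=1.05)
        assert res2.loc["f", "significant"].item()

    def test_welch_close_to_permutation_oracle(self, rng):
        """On n=11 vs 11 Gaussian draws the Welch p agrees with a
        label-permutation p within 0.02."""
        sheet = self._sheet(11)
        x = rng.normal(8.0, 1.0, size=(6, 22))
        x[:3, :11] += 0.8
        rpm = pd.DataFrame(2.0 ** x - 1.0, columns=sheet.index,
                           index=[f"f{i}" for i in range(6)])
        welch = differential_test(rpm, sheet, test="welch")
        perm = differential_test(rpm, sheet, test="permutation",
                                 n_permutations=20000, seed=3)
        assert np.allclose(welch["p_value"], perm["p_value"], atol=0.02)

    def test_bh_q_values_reported(self, rng):
        sheet = self._sheet(5)
        rpm = pd.DataFrame(rng.integers(10, 1000, size=(20, 10)).astype(float),
                           columns=sheet.index,
                           index=[f"f{i}" for i in range(20)])
        res = differential_test(rpm, sheet)
        assert ((res["q_value"] >= res["p_value"] - 1e-12)
                & (res["q_value"] <= 1.0)).all()

    def test_group_smaller_than_two_rejected(self):
        sheet = pd.DataFrame({"condition": ["case", "control", "control"]},
                             index=pd.Index(["a", "b", "c"], name="sample_id"))
        rpm = pd.DataFrame([[1.0, 2.0, 3.0]], index=["f"], columns=sheet.index)
        with pytest.raises(ValueError):
            differential_test(rpm, sheet)


class TestProfilesAndClusters:
    def test_mean_centred_rows(self, rng):
        rpm = pd.DataFrame(rng.random((5, 6)) * 100,
                           index=[f"f{i}" for i in range(5)],
                           columns=[f"s{i}" for i in range(6)])
        centred = mean_centred_profiles(rpm)
        assert np.allclose(centred.mean(axis=1), 0.0, atol=1e-12)
        again = centred.sub(centred.mean(axis=1), axis=0)
        pd.testing.assert_frame_equal(centred, again)

    def test_constant_row_all_zeros(self):
        rpm = pd.DataFrame([[7.0, 7.0, 7.0]], index=["f"], columns=list("abc"))
        assert (mean_centred_profiles(rpm).to_numpy() == 0).all()

    def test_cluster_summary_partition(self):
        ann = pd.DataFrame({
            "feature_id": ["a", "b", "c", "d"],
            "chrom": ["chr14", "chr14", "chr19", "chr1"],
            "start": [0, 30, 0, 0],
            "cluster_label": ["clusterA", "clusterA", "clusterB", "none"],
        })
        de = pd.DataFrame({
            "log2fc": [-1.0, -0.9, 0.8, 0.1],
            "p_value": [0.01, 0.02, 0.01, 0.9],
            "significant": [True, True, True, False],
        }, index=pd.Index(["a", "b", "c", "d"], name="feature_id"))
        summary, track = cluster_summary(de, ann)
        assert summary.loc["clusterA", "n_significant"] == 2
        assert summary.loc["clusterA", "n_significant_negative"] == 2
        assert summary["fraction_of_significant"].sum() == pytest.approx(1.0)
        assert set(track.columns) >= {"chrom", "position", "log2fc", "significant"}

    def test_cluster_summary_no_significant(self):
        ann = pd.DataFrame({"feature_id": ["a"], "chrom": ["chr1"],
                            "start": [0], "cluster_label": ["none"]})
        de = pd.DataFrame({"log2fc": [0.0], "p_value": [1.0],
                           "significant": [False]},
                          index=pd.Index(["a"], name="feature_id"))
        summary, _ = cluster_summary(de, ann)
        assert (summary["n_significant"] == 0).all()
        assert summary["fraction_of_significant"].sum() == 0.0

    def test_simulated_cluster_downregulation_recovered(self):
        """A -1 log2FC planted on every cluster member is recovered with
        negative significant calls inside the cluster."""
        cfg = SimulationConfig(n_mirna=120, cluster_sizes=(10, 8),
                               effect_log2fc=-1.0, effect_fraction=1.0,
                               read_depth=200000, seed=21)
        from plasmir.simulate import build_reference_bundle
        bundle = build_reference_bundle(cfg)
        truth = sample_truth(cfg, bundle)
        counts, sheet = simulate_count_matrix(cfg, truth,
                                              compartments=("whole_plasma",))
        rpm = counts * 1e6 / counts.sum(axis=0)
        res = differential_test(rpm, sheet, annotation=bundle.annotation)
        summary, _ = cluster_summary(res, bundle.annotation)
        sig_in_clusters = (summary.loc["clusterA", "n_significant"]
                           + summary.loc["clusterB", "n_significant"])
        neg_in_clusters = (summary.loc["clusterA", "n_significant_negative"]
                           + summary.loc["clusterB", "n_significant_negative"])
        assert sig_in_clusters >= 0.5 * 36
        assert neg_in_clusters >= 0.9 * sig_in_clusters


class TestQPCRConcordance:
    def _setup(self, noise_sd=0.0):
        cfg = SimulationConfig(n_mirna=60, cluster_sizes=(5, 4),
                               effect_log2fc=-1.0, effect_fraction=1.0, seed=7)
        from plasmir.simulate import build_reference_bundle
        bundle = build_reference_bundle(cfg)
        truth = sample_truth(cfg, bundle)
        affected = list(truth.index[truth.disease_multiplier != 1.0][:5])
        stable = list(truth.index[(truth.disease_multiplier == 1.0)
                                  & (truth.cluster_label == "none")][:3])
        qres = simulate_qpcr(truth, cfg, features=affected + stable,
                             noise_sd=noise_sd)
        return cfg, truth, affected, stable, qres

    def test_noise_free_sign_agreement_and_fold_recovery(self):
        """Noise-free delta-delta-Ct recovers the planted fold change up to
        the case-pool renormalization shared by all features."""
        cfg, truth, affected, stable, qres = self._setup()
        seq_lfc = pd.DataFrame(
            {"log2fc": [-1.0] * len(affected) + [0.05] * len(stable)},
            index=pd.Index(affected + stable, name="feature_id"))
        table, n_agree = qpcr_concordance(seq_lfc, qres.ct, qres.sheet,
                                          qres.normalizer_id)
        got = table.loc[affected, "qpcr_log2fc"]
        assert np.allclose(got, -1.0, atol=1e-9)
        assert np.allclose(table.loc[stable, "qpcr_log2fc"], 0.0, atol=1e-9)
        assert table.loc[affected, "sign_agree"].all()

    def test_equal_ct_across_groups_gives_zero_fold(self):
        sheet = pd.DataFrame({"condition": ["case", "case", "control", "control"]},
                             index=pd.Index(list("abcd"), name="sample_id"))
        rows = [{"sample_id": s, "feature_id": f, "ct": 25.0 if f == "x" else 20.0}
                for s in "abcd" for f in ("x", "norm")]
        de = pd.DataFrame({"log2fc": [0.4]},
                          index=pd.Index(["x"], name="feature_id"))
        table, _ = qpcr_concordance(de, pd.DataFrame(rows), sheet, "norm")
        assert table.loc["x", "qpcr_log2fc"] == 0.0

    def test_missing_normalizer_rejected(self):
        sheet = pd.DataFrame({"condition": ["case", "control"]},
                             index=pd.Index(["a", "b"], name="sample_id"))
        ct = pd.DataFrame([{"sample_id": "a", "feature_id": "x", "ct": 20.0},
                           {"sample_id": "b", "feature_id": "x", "ct": 21.0}])
        de = pd.DataFrame({"log2fc": [1.0]},
                          index=pd.Index(["x"], name="feature_id"))
        with pytest.raises(ValueError, match="norm"):
            qpcr_concordance(de, ct, sheet, "norm")
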