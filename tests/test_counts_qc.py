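"""RPM scaling, guide exclusion rules and SSMD quality control."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oncodep.counts_qc import (CROSS_TARGETING_EXCLUSIONS, QCReport,
                               exclude_cross_targeting, filter_low_abundance,
                               mads, replicate_correlation, ssmd, to_rpm)
from oncodep.screen_io import CountMatrix, GuideLibrary


class TestRPM:
    def test_equal_counts_split_evenly(self, tiny_counts):
        rpm = to_rpm(pd.DataFrame({"s": [5, 5, 5, 5]}))
        assert (rpm["s"] == 250_000.0).all()

    def test_columns_sum_to_one_million(self, small_screen):
        rpm = to_rpm(small_screen)
        assert np.allclose(rpm.sum(axis=0), 1e6)

    def test_scale_invariance(self, tiny_counts):
        rpm1 = to_rpm(tiny_counts)
        scaled = tiny_counts.counts.copy()
        scaled["A_DMSO_1"] *= 7
        rpm2 = to_rpm(scaled)
        pd.testing.assert_frame_equal(rpm1, rpm2)


class TestLowAbundanceFilter:
    def _matrix(self, plasmid_counts):
        n = len(plasmid_counts)
        counts = pd.DataFrame({"plasmid": plasmid_counts,
                               "A_DMSO_1": [100] * n},
                              index=[f"g{i}" for i in range(n)])
        counts.index.name = "guide_id"
        from oncodep.screen_io import SampleMeta

        return CountMatrix(counts, [
            SampleMeta("plasmid", "other", "plasmid", 1),
            SampleMeta("A_DMSO_1", "control", "DMSO", 1)])

    def test_below_threshold_removed_and_counted(self):
        # guide g0 at 0.5 RPM in the plasmid: 1 read in ~2M total
        plasmid = [1] + [22221] * 90
        cm = self._matrix(plasmid)
        rpm0 = to_rpm(cm).loc["g0", "plasmid"]
        assert rpm0 < 1.0
        report = QCReport()
        out = filter_low_abundance(cm, report=report)
        assert "g0" not in out.guide_ids
        assert report.n_low_abundance_removed == 1

    def test_identity_when_all_pass(self, small_screen):
        out = filter_low_abundance(small_screen, threshold=0.0)
        assert out is small_screen

    def test_removal_count_matches_brute_force(self, small_screen):
        rpm = to_rpm(small_screen)[small_screen.plasmid_sample]
        threshold = float(rpm.quantile(0.1))
        expected = int((rpm < threshold).sum())
        report = QCReport()
        out = filter_low_abundance(small_screen, threshold, report)
        assert report.n_low_abundance_removed == expected
        assert len(out.guide_ids) == len(small_screen.guide_ids) - expected

    def test_idempotent(self, small_screen):
        once = filter_low_abundance(small_screen, threshold=2.0)
        twice = filter_low_abundance(once, threshold=2.0)
        assert list(once.guide_ids) == list(twice.guide_ids)


class TestCrossTargeting:
    def _library_with(self, sequences):
        rows = [{"guide_id": f"g{i}", "sequence": s, "gene": "KRAS",
                 "is_control": False} for i, s in enumerate(sequences)]
        rows.append({"guide_id": "x", "sequence": "A" * 20, "gene": "OTHER",
                     "is_control": False})
        return GuideLibrary(pd.DataFrame(rows))

    def test_kras_listed_sequence_removed(self):
        lib = self._library_with([CROSS_TARGETING_EXCLUSIONS["KRAS"][0],
                                  "C" * 20])
        out = exclude_cross_targeting(lib, "KRAS")
        assert "g0" not in set(out.guide_ids)
        assert "g1" in set(out.guide_ids)

    def test_control_line_is_identity(self):
        lib = self._library_with([CROSS_TARGETING_EXCLUSIONS["KRAS"][0]])
        out = exclude_cross_targeting(lib, "control")
        assert out is lib

    def test_both_rit1_sequences_removed(self):
        seqs = list(CROSS_TARGETING_EXCLUSIONS["RIT1"]) + ["G" * 20]
        lib = self._library_with(seqs)
        report = QCReport()
        out = exclude_cross_targeting(lib, "RIT1", report=report)
        assert len(lib.table) - len(out.table) == 2
        assert len(report.cross_targeting_removed) == 2


class TestReplicateCorrelation:
    def test_self_and_anticorrelated(self, rng):
        x = rng.normal(size=50)
        df = pd.DataFrame({"a": x, "b": x, "c": -x})
        table = replicate_correlation(df).set_index(["sample_a", "sample_b"])
        assert table.loc[("a", "b"), "r"] == pytest.approx(1.0)
        assert table.loc[("a", "c"), "r"] == pytest.approx(-1.0)

    def test_matches_covariance_formula(self, rng):
        x, y = rng.normal(size=30), rng.normal(size=30)
        table = replicate_correlation(pd.DataFrame({"x": x, "y": y}))
        cov = ((x - x.mean()) * (y - y.mean())).sum()
        r_direct = cov / np.sqrt(((x - x.mean()) ** 2).sum()
                                 * ((y - y.mean()) ** 2).sum())
        assert table["r"].iloc[0] == pytest.approx(r_direct, abs=1e-12)
        assert table["r2"].iloc[0] == pytest.approx(r_direct ** 2, abs=1e-12)

    def test_single_replicate_warns_empty(self, rng):
        with pytest.warns(UserWarning, match="fewer than 2"):
            out = replicate_correlation(pd.DataFrame({"a": rng.normal(size=5)}))
        assert out.empty


class TestSSMD:
    def _lfc(self, ess, ctrl):
        idx = [f"e{i}" for i in range(len(ess))] + \
              [f"c{i}" for i in range(len(ctrl))]
        return (pd.Series(list(ess) + list(ctrl), index=idx),
                [f"e{i}" for i in range(len(ess))],
                [f"c{i}" for i in range(len(ctrl))])

    def test_frozen_robust_statistics_example(self):
        """Independent oracle: medians -2 and 0, scaled MADs 1.4826 and
        0.7413 give SSMD = -2/sqrt(1.4826^2 + 0.7413^2) = -1.2066."""
        lfc, e, c = self._lfc([-3, -2, -1], [-0.5, 0, 0.5])
        assert ssmd(lfc, e, c) == pytest.approx(-1.2065657507, abs=1e-9)

    def test_identical_distributions_give_zero(self, rng):
        vals = rng.normal(size=40)
        lfc, e, c = self._lfc(vals[:20], vals[:20])
        assert abs(ssmd(lfc, e, c)) < 1e-12

    def test_shift_invariance_and_antisymmetry(self, rng):
        ess, ctrl = rng.normal(-2, 1, 30), rng.normal(0, 1, 30)
        lfc, e, c = self._lfc(ess, ctrl)
        shifted, _, _ = self._lfc(ess + 5, ctrl + 5)
        assert ssmd(lfc, e, c) == pytest.approx(ssmd(shifted, e, c), abs=1e-12)
        assert ssmd(lfc, e, c) == pytest.approx(-ssmd(lfc, c, e), abs=1e-12)

    @settings(max_examples=25, deadline=None)
    @given(shift=st.floats(-10, 10), scale=st.floats(0.1, 5))
    def test_ssmd_scales_like_an_effect_size(self, shift, scale, ):
        """Scaling both groups rescales nothing; shifting one group moves
        SSMD monotonically in the shift direction."""
        base_e = np.array([-2.0, -1.5, -1.0, -0.7, -2.2])
        base_c = np.array([-0.2, 0.0, 0.1, 0.3, -0.1])
        lfc, e, c = self._lfc(scale * base_e + shift, scale * base_c + shift)
        ref_lfc, _, _ = self._lfc(base_e, base_c)
        assert ssmd(lfc, e, c) == pytest.approx(ssmd(ref_lfc, e, c), rel=1e-9)

    def test_degenerate_inputs(self):
        lfc, e, c = self._lfc([1.0, 1.0, 1.0], [1.0, 1.0])
        assert ssmd(lfc, e, c) == 0.0
        lfc2, e2, c2 = self._lfc([1.0, 1.0], [0.0, 0.0])
        with pytest.warns(UserWarning, match="infinite"):
            assert ssmd(lfc2, e2, c2) == np.inf

    def test_synthetic_screen_passes_qc(self, small_screen, small_library,
                                        small_scenario):
        """Planted essential dropout at -0.25/doubling drives every endpoint
        replicate past the SSMD < -0.5 pass threshold."""
        from oncodep.counts_qc import qc_screen

        _, _, report = qc_screen(small_screen, small_library,
                                 small_scenario.registry()["qc_essential"])
        assert report.ssmd
        assert all(v < -0.5 for v in report.ssmd.values())
        assert all(report.ssmd_pass.values())

    def test_pass_flag_equals_threshold_rule(self):
        report = QCReport()
        report.record_ssmd("a", -0.501)
        report.record_ssmd("b", -0.5)
        report.record_ssmd("c", 1.0)
        assert report.ssmd_pass == {"a": True, "b": False, "c": False}
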