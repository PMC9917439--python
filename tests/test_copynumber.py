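"""Copy-number normalization, UR-domain calling, recovery and ΔΔCt."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mercikit import copynumber as cn
from mercikit.quant_io import CtTable

from conftest import make_track


class TestNormalizeToDiploid:
    def test_sample_equal_control_gives_ones(self):
        t = make_track({"2L": [10.0] * 100, "2R": [20.0] * 100},
                       bin_size=5000)
        out = cn.normalize_to_diploid(t, t, bin_size=5000)
        np.testing.assert_allclose(out.df["value"], 1.0)

    def test_half_depth_region(self):
        vals = [10.0] * 200
        sample = list(vals)
        for i in range(80, 120):  # 200 kb at half depth
            sample[i] = 5.0
        s = make_track({"3L": sample}, bin_size=5000)
        c = make_track({"3L": vals}, bin_size=5000)
        out = cn.normalize_to_diploid(s, c, bin_size=5000)
        v = out.df["value"].to_numpy()
        scale = 1.0 / np.mean(np.where(np.arange(200) // 40 == 2, 0.5, 1.0))
        np.testing.assert_allclose(v[80:120], 0.5 * scale, rtol=1e-9)
        np.testing.assert_allclose(v[:80], 1.0 * scale, rtol=1e-9)

    def test_rebinning_width_weighted(self):
        # two 50 bp bins -> one 100 bp bin with the width-weighted mean
        t = make_track({"X": [2.0, 4.0]}, bin_size=50)
        out = cn.rebin(t, 100)
        assert len(out) == 1
        assert out.df["value"].iloc[0] == pytest.approx(3.0)

    def test_zero_control_bins_dropped(self):
        s = make_track({"X": [1.0, 1.0]}, bin_size=50)
        c = make_track({"X": [1.0, 0.0]}, bin_size=50)
        with pytest.warns(UserWarning, match="zero control"):
            out = cn.normalize_to_diploid(s, c, bin_size=50, cpm=False)
        assert len(out) == 1


class TestCallURDomains:
    def test_flat_track_no_domains(self):
        t = make_track({"2L": [1.0] * 100}, bin_size=5000)
        assert cn.call_ur_domains(t) == []

    def test_planted_150kb_dip_single_domain(self):
        vals = np.ones(200)
        vals[60:90] = 0.5  # 30 bins x 5 kb = 150 kb
        t = make_track({"2L": vals}, bin_size=5000)
        doms = cn.call_ur_domains(t, min_length=100_000)
        assert len(doms) == 1
        d = doms[0]
        assert abs(d.start - 60 * 5000) <= 5000
        assert abs(d.end - 90 * 5000) <= 5000
        assert d.cn["control"] == pytest.approx(0.5, abs=0.01)

    def test_dip_below_min_length_not_called(self):
        vals = np.ones(200)
        vals[60:79] = 0.5  # 95 kb < 100 kb
        t = make_track({"2L": vals}, bin_size=5000)
        assert cn.call_ur_domains(t, min_length=100_000) == []

    def test_dip_exactly_at_min_length_called(self):
        vals = np.ones(200)
        vals[60:80] = 0.5  # 100 kb exactly
        t = make_track({"2L": vals}, bin_size=5000)
        assert len(cn.call_ur_domains(t, min_length=100_000)) == 1

    def test_gap_tolerance_merges_across_single_bin(self):
        vals = np.full(200, 0.99)
        vals[60:75] = 0.5
        vals[75] = 1.5  # single above-mean bin inside the dip
        vals[76:90] = 0.5
        t = make_track({"2L": vals}, bin_size=5000)
        assert len(cn.call_ur_domains(t, min_length=100_000, gap_tol=1)) == 1
        assert len(cn.call_ur_domains(t, min_length=100_000, gap_tol=0)) == 0

    def test_masked_region_not_called(self):
        vals = np.ones(200)
        vals[60:90] = 0.5
        t = make_track({"2L": vals}, bin_size=5000)
        mask = [("2L", 60 * 5000, 90 * 5000)]
        assert cn.call_ur_domains(t, mask=mask) == []

    def test_short_arm_warns(self):
        t = make_track({"4": [0.5, 1.0]}, bin_size=5000)
        with pytest.warns(UserWarning, match="min_length"):
            assert cn.call_ur_domains(t) == []


class TestRecovery:
    @pytest.mark.parametrize(
        "ctrl,mut,expected",
        [(0.51, 0.93, 86), (0.63, 0.93, 81), (0.63, 0.80, 46)],
    )
    def test_printed_table_rows(self, ctrl, mut, expected):
        assert round(cn.recovery(ctrl, mut)) == expected

    def test_no_change_is_zero(self):
        assert cn.recovery(0.37, 0.37) == 0.0

    def test_full_restoration_is_100(self):
        assert cn.recovery(0.2, 1.0) == pytest.approx(100.0)

    def test_control_without_deficit_rejected(self):
        with pytest.raises(ValueError, match="no deficit"):
            cn.recovery(1.0, 1.2)

    @settings(deadline=None, max_examples=50)
    @given(
        c=st.floats(0.01, 0.98),
        m1=st.floats(0.0, 1.5),
        m2=st.floats(0.0, 1.5),
        w=st.floats(0.0, 1.0),
    )
    def test_affine_in_mutant_cn(self, c, m1, m2, w):
        mix = w * m1 + (1 - w) * m2
        lhs = cn.recovery(c, mix)
        rhs = w * cn.recovery(c, m1) + (1 - w) * cn.recovery(c, m2)
        assert lhs == pytest.approx(rhs, abs=1e-8)


class TestSuppressionAndPerBinTest:
    def test_mean_p_and_flag(self):
        mean_p, flag = cn.call_suppression([0.001, 0.003, 0.002])
        assert mean_p == pytest.approx(0.002)
        assert flag is True

    def test_strictness_at_alpha(self):
        # mean p exactly 0.01 is NOT suppressed (strict inequality)
        _, flag = cn.call_suppression([0.01, 0.01])
        assert flag is False

    def test_uniform_half_not_suppressed(self):
        _, flag = cn.call_suppression([0.5] * 10)
        assert flag is False

    def test_no_pvalues_undefined(self):
        mean_p, flag = cn.call_suppression([])
        assert np.isnan(mean_p) and flag is None

    def test_identical_groups_p_one(self):
        assert cn.perbin_test([2.0, 2.0, 2.0], [2.0, 2.0, 2.0]) == 1.0

    def test_separated_groups_significant(self):
        p = cn.perbin_test([1.0, 1.01, 0.99], [2.0, 2.01, 1.99])
        assert p < 0.01

    def test_null_type_one_error_rate(self, rng):
        n, alpha = 4000, 0.01
        hits = 0
        for _ in range(n):
            a = rng.lognormal(0, 0.2, size=3)
            b = rng.lognormal(0, 0.2, size=3)
            hits += cn.perbin_test(a, b) < alpha
        # Welch t on log-values: type-I error near nominal alpha
        assert hits / n == pytest.approx(alpha, abs=0.008)


class TestSummarizeDomains:
    def test_single_domain_weighted_mean_is_itself(self):
        d = cn.URDomain("2L", 0, 100_000, cn={"w": 0.4})
        d.recovery_pct["m"] = 50.0
        d.mean_p["m"] = 0.001
        d.suppressed["m"] = True
        s = cn.summarize_domains([d], control="w")
        assert s["weighted_mean_cn"] == pytest.approx(0.4)
        assert s["mutants"]["m"]["weighted_mean_recovery_pct"] == 50.0

    def test_split_invariance(self):
        whole = cn.URDomain("2L", 0, 200_000, cn={"w": 0.3})
        half1 = cn.URDomain("2L", 0, 120_000, cn={"w": 0.3})
        half2 = cn.URDomain("2L", 120_000, 200_000, cn={"w": 0.3})
        s1 = cn.summarize_domains([whole], control="w")
        s2 = cn.summarize_domains([half1, half2], control="w")
        assert s1["weighted_mean_cn"] == pytest.approx(s2["weighted_mean_cn"])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cn.summarize_domains([], control="w")


class TestDdct:
    @staticmethod
    def _ct(cells):
        return CtTable({k: np.asarray(v, dtype=float)
                        for k, v in cells.items()})

    def test_equal_delta_ct_gives_cn_one(self):
        ct = self._ct({
            ("t", "SG"): [25, 25, 25], ("c", "SG"): [24, 24, 24],
            ("t", "emb"): [25, 25, 25], ("c", "emb"): [24, 24, 24],
        })
        (res,) = cn.ddct(ct, control_amplicon="c", control_group="emb")
        assert res.ddct == pytest.approx(0.0)
        assert res.copy_number == pytest.approx(1.0)

    def test_one_cycle_halves_copy_number(self):
        ct = self._ct({
            ("t", "SG"): [25.0], ("c", "SG"): [23.0],
            ("t", "emb"): [24.0], ("c", "emb"): [23.0],
        })
        (res,) = cn.ddct(ct, control_amplicon="c", control_group="emb")
        assert res.ddct == pytest.approx(1.0)
        assert res.copy_number == pytest.approx(0.5)

    def test_hand_worked_fixture_with_ci(self):
        # target SG <Ct>=25.0 sd 0.2; control SG <Ct>=24.0 sd 0.2;
        # embryo both 24.0 -> ddCt = 1, sigma = sqrt((0.04+0.04)/2) = 0.2
        ct = self._ct({
            ("t", "SG"): [24.8, 25.0, 25.2],
            ("c", "SG"): [23.8, 24.0, 24.2],
            ("t", "emb"): [24.0, 24.0, 24.0],
            ("c", "emb"): [24.0, 24.0, 24.0],
        })
        (res,) = cn.ddct(ct, control_amplicon="c", control_group="emb")
        assert res.ddct == pytest.approx(1.0)
        assert res.sigma == pytest.approx(0.2)
        assert res.copy_number == pytest.approx(0.5)
        assert res.ci[0] == pytest.approx(0.5 * 2 ** -0.2)
        assert res.ci[1] == pytest.approx(0.5 * 2 ** 0.2)
        assert res.ci[0] < res.copy_number < res.ci[1]

    def test_missing_control_amplicon(self):
        ct = self._ct({("t", "SG"): [25.0], ("t", "emb"): [24.0]})
        with pytest.raises(ValueError, match="control amplicon"):
            cn.ddct(ct, control_amplicon="c", control_group="emb")
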