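"""Normalisation, sex determination, relative copy number and QC windows."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mlpangs.cna import (
    CopyNumberProfile,
    PROBE_QC_DELETED_PASS,
    PROBE_QC_FAIL,
    PROBE_QC_PASS,
    determine_sex,
    qc_profile,
    relative_amplification,
    relative_copy_number,
)
from mlpangs.panel import ProbeCategory
from mlpangs.readcount import SampleCounts, count_sample
from mlpangs.simulate import SimConfig, simulate_panel, simulate_sample


def make_counts(panel, values, sample_id="s"):
    counts = {p.probe_id: values.get(p.probe_id, 0) for p in panel}
    return SampleCounts(sample_id, counts, total_reads=sum(counts.values()))


@pytest.fixture(scope="module")
def panel():
    return simulate_panel(n_dmd=6, n_internal_ref=4, seed=3)


@pytest.fixture(scope="module")
def kit_counts(kit_panel, presets):
    cfg = SimConfig(seed=21)
    out = {}
    for name, seed in (("normal_male", 100), ("normal_female", 101)):
        reads, _ = simulate_sample(kit_panel, presets[name], cfg, seed=seed)
        out[name] = count_sample([q for _, q in reads], kit_panel, name)
    return out


class TestRelativeAmplification:
    def test_uniform_refs(self, panel):
        values = {pid: 100 for pid in panel.internal_ref_ids}
        probe = panel.by_category(ProbeCategory.DMD_EXON)[0].probe_id
        values[probe] = 50
        rel = relative_amplification(make_counts(panel, values), panel)
        assert rel.rel[probe] == pytest.approx(0.5)
        refs_mean = sum(rel.rel[r] for r in panel.internal_ref_ids) / 4
        assert refs_mean == pytest.approx(1.0)

    def test_unequal_refs_use_mean(self, panel):
        refs = panel.internal_ref_ids
        values = {refs[0]: 100, refs[1]: 300, refs[2]: 200, refs[3]: 200}
        probe = panel.by_category(ProbeCategory.DMD_EXON)[0].probe_id
        values[probe] = 200
        rel = relative_amplification(make_counts(panel, values), panel)
        assert rel.rel[probe] == pytest.approx(1.0)

    _tiny_panel = simulate_panel(n_dmd=3, n_internal_ref=2, seed=5)

    @given(st.integers(min_value=2, max_value=1000))
    @settings(deadline=None, max_examples=20)
    def test_scale_invariance(self, k):
        panel = self._tiny_panel
        base = {pid: 100 + 13 * i for i, pid in enumerate(p.probe_id for p in panel)}
        rel1 = relative_amplification(make_counts(panel, base), panel)
        scaled = {pid: v * k for pid, v in base.items()}
        rel2 = relative_amplification(make_counts(panel, scaled), panel)
        for pid in base:
            assert rel1.rel[pid] == pytest.approx(rel2.rel[pid])

    def test_all_refs_zero_is_hard_error(self, panel):
        with pytest.raises(ValueError, match="unusable"):
            relative_amplification(make_counts(panel, {}), panel)


class TestDetermineSex:
    def _rel(self, panel, x, y):
        values = {pid: 100 for pid in panel.internal_ref_ids}
        for pid, v in zip([p.probe_id for p in panel.by_category(ProbeCategory.CHRX_SEX)], x):
            values[pid] = v
        for pid, v in zip([p.probe_id for p in panel.by_category(ProbeCategory.CHRY_SEX)], y):
            values[pid] = v
        return relative_amplification(make_counts(panel, values), panel)

    def test_absent_y_is_female(self, panel):
        call, ratio = determine_sex(self._rel(panel, (120, 100, 110), (0, 0, 0)), panel)
        assert call == "female" and ratio == 0.0

    def test_balanced_xy_is_male(self, panel):
        call, ratio = determine_sex(self._rel(panel, (50, 50, 50), (50, 50, 50)), panel)
        assert call == "male" and ratio == pytest.approx(1.0)

    def test_gap_is_indeterminate(self, panel):
        call, ratio = determine_sex(self._rel(panel, (100, 100, 100), (30, 30, 30)), panel)
        assert call == "indeterminate" and ratio == pytest.approx(0.3)

    def test_zero_x_signal_is_error(self, panel):
        with pytest.raises(ValueError, match="chrX"):
            determine_sex(self._rel(panel, (0, 0, 0), (10, 10, 10)), panel)


class TestRelativeCopyNumber:
    def test_self_comparison_yields_multiplier(self, kit_panel, kit_counts):
        """A male sample against itself: DMD rcn 1, SMN half-scale 2, refs 2."""
        rel = relative_amplification(kit_counts["normal_male"], kit_panel)
        profile = relative_copy_number(rel, rel, "male", kit_panel, "half")
        for p in kit_panel:
            if p.category is ProbeCategory.DMD_EXON:
                assert profile.rcn[p.probe_id] == pytest.approx(1.0)
            elif p.category is ProbeCategory.SMN_SHARED:
                assert profile.rcn[p.probe_id] == pytest.approx(2.0)
            elif p.category is ProbeCategory.INTERNAL_REF:
                assert profile.rcn[p.probe_id] == pytest.approx(2.0)

    def test_total_scale_doubles_shared_smn(self, kit_panel, kit_counts):
        rel = relative_amplification(kit_counts["normal_male"], kit_panel)
        half = relative_copy_number(rel, rel, "male", kit_panel, "half")
        total = relative_copy_number(rel, rel, "male", kit_panel, "total")
        for p in kit_panel.by_category(ProbeCategory.SMN_SHARED):
            assert total.rcn[p.probe_id] == pytest.approx(2 * half.rcn[p.probe_id])

    def test_normal_female_vs_male_control_doubles_dmd(self, kit_panel, kit_counts):
        rel_f = relative_amplification(kit_counts["normal_female"], kit_panel)
        rel_m = relative_amplification(kit_counts["normal_male"], kit_panel)
        profile = relative_copy_number(rel_f, rel_m, "male", kit_panel)
        dmd = [profile.rcn[p.probe_id] for p in kit_panel.by_category(ProbeCategory.DMD_EXON)]
        assert 1.6 < sum(dmd) / len(dmd) < 2.4
        assert profile.sex_call == "female"
        assert all(profile.theoretical[p.probe_id] == 2.0
                   for p in kit_panel.by_category(ProbeCategory.DMD_EXON))

    def test_count_scale_invariance_of_rcn(self, kit_panel, kit_counts):
        """Multiplying every count by a constant changes no rcn value."""
        sc = kit_counts["normal_female"]
        scaled = SampleCounts(
            sc.sample_id,
            {pid: 7 * v for pid, v in sc.counts.items()},
            total_reads=7 * sc.total_reads,
        )
        rel_m = relative_amplification(kit_counts["normal_male"], kit_panel)
        p1 = relative_copy_number(relative_amplification(sc, kit_panel), rel_m, "male", kit_panel)
        p2 = relative_copy_number(relative_amplification(scaled, kit_panel), rel_m, "male", kit_panel)
        for pid in p1.rcn:
            a, b = p1.rcn[pid], p2.rcn[pid]
            assert (math.isnan(a) and math.isnan(b)) or a == pytest.approx(b)

    def test_sum_vs_mean_aggregation_cancels_bitwise(self, kit_panel, kit_counts):
        rel_s_mean = relative_amplification(kit_counts["normal_female"], kit_panel, "mean")
        rel_c_mean = relative_amplification(kit_counts["normal_male"], kit_panel, "mean")
        rel_s_sum = relative_amplification(kit_counts["normal_female"], kit_panel, "sum")
        rel_c_sum = relative_amplification(kit_counts["normal_male"], kit_panel, "sum")
        p_mean = relative_copy_number(rel_s_mean, rel_c_mean, "male", kit_panel)
        p_sum = relative_copy_number(rel_s_sum, rel_c_sum, "male", kit_panel)
        for pid in p_mean.rcn:
            a, b = p_mean.rcn[pid], p_sum.rcn[pid]
            if p_mean.theoretical[pid] is None:
                # sex probes report raw rel, where the aggregate does not cancel
                continue
            assert (math.isnan(a) and math.isnan(b)) or a == b  # bit-identical

    def test_zero_control_probe_flagged_incomparable(self, panel):
        values = {pid: 100 for pid in panel.internal_ref_ids}
        for p in panel.by_category(ProbeCategory.CHRX_SEX):
            values[p.probe_id] = 100
        probe = panel.by_category(ProbeCategory.DMD_EXON)[0].probe_id
        sample_vals = dict(values, **{probe: 80})
        rel_s = relative_amplification(make_counts(panel, sample_vals, "s"), panel)
        rel_c = relative_amplification(make_counts(panel, values, "c"), panel)
        profile = relative_copy_number(rel_s, rel_c, "male", panel)
        assert probe in profile.incomparable
        assert math.isnan(profile.rcn[probe])


class TestQcWindows:
    def _profile(self, rcn, theoretical):
        return CopyNumberProfile(
            sample_id="s", control_id="c", sex_call="male", sex_ratio=1.0,
            rcn={"P": rcn}, theoretical={"P": theoretical}, smn_scale="half",
        )

    @pytest.mark.parametrize(
        "rcn,theo,expected",
        [
            (1.0, 1.0, PROBE_QC_PASS),
            (1.30, 1.0, PROBE_QC_PASS),   # inclusive boundary
            (1.31, 1.0, PROBE_QC_FAIL),
            (0.70, 1.0, PROBE_QC_PASS),
            (0.04, 1.0, PROBE_QC_DELETED_PASS),
            (0.05, 1.0, PROBE_QC_FAIL),   # residual rule is strict
            (2.2, 2.0, PROBE_QC_PASS),
        ],
    )
    def test_probe_windows(self, rcn, theo, expected):
        profile = qc_profile(self._profile(rcn, theo))
        assert profile.qc["P"] == expected

    def test_indeterminate_sex_fails_sample(self):
        p = self._profile(1.0, 1.0)
        p.sex_call = "indeterminate"
        assert qc_profile(p).sample_qc == "fail"
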