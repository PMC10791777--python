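"""Demultiplexing, detective-sequence read assignment and count statistics."""

import random

import numpy as np
import pytest

from mlpangs.panel import ProbeCategory
from mlpangs.readcount import (
    QC_AMPLIFICATION_FAILURE,
    QC_HYB_LIGATION_FAILURE,
    QC_OK,
    TOO_SHORT,
    UNASSIGNED,
    SampleCounts,
    assign_read,
    batch_stats,
    build_assignment_index,
    check_amplification_qc,
    count_sample,
    demultiplex,
)
from mlpangs.simulate import SimConfig, simulate_run, simulate_sample, write_fastq


class TestDemultiplex:
    def _write_run(self, tmp_path, panel, genotypes, cfg):
        reads, manifest = simulate_run(panel, genotypes, cfg)
        fq = tmp_path / "run.fastq"
        write_fastq(reads, fq)
        return fq, manifest, {g.index_barcode: g.sample_id for g in genotypes}

    def test_exact_indices_no_undetermined(self, tmp_path, small_panel, presets):
        fq, _, bm = self._write_run(
            tmp_path, small_panel,
            [presets["normal_male"], presets["normal_female"]],
            SimConfig(seed=1),
        )
        by_sample, undetermined = demultiplex(fq, bm)
        assert undetermined == 0
        assert set(by_sample) == set(bm.values())

    def test_one_mismatch_index_goes_undetermined(self, tmp_path):
        fq = tmp_path / "r.fastq"
        fq.write_text("@r1 1:N:0:AAAAAAAT\nACGT\n+\nIIII\n")
        by_sample, undetermined = demultiplex(fq, {"AAAAAAAA": "s1"})
        assert undetermined == 1
        assert by_sample["s1"] == []

    def test_conservation_against_truth_manifest(self, tmp_path, kit_panel, presets):
        gts = [presets[n] for n in ("normal_male", "normal_female", "dmd_del_30_44_male")]
        fq, manifest, bm = self._write_run(tmp_path, kit_panel, gts, SimConfig(seed=5))
        by_sample, undetermined = demultiplex(fq, bm)
        assert undetermined == 0
        total = sum(len(v) for v in by_sample.values())
        assert total == sum(1 for _ in open(fq)) / 4
        # every sample holds at least its manifest (non-junk) reads
        per_sample = manifest.groupby("sample_id").emitted_reads.sum()
        for sid, reads in by_sample.items():
            assert len(reads) >= per_sample[sid]

    def test_duplicate_barcode_rejected(self):
        with pytest.raises(ValueError, match="8 nt"):
            demultiplex([], {"AAA": "s"})

    def test_separate_index_fastq(self, tmp_path):
        (tmp_path / "r1.fastq").write_text("@r1\nACGTACGT\n+\nIIIIIIII\n")
        (tmp_path / "i1.fastq").write_text("@r1\nCCCCCCCC\n+\nIIIIIIII\n")
        by_sample, und = demultiplex(
            tmp_path / "r1.fastq", {"CCCCCCCC": "s1"}, index_fastq=tmp_path / "i1.fastq"
        )
        assert len(by_sample["s1"]) == 1 and und == 0


class TestAssignRead:
    def test_template_prefix_assigns(self, kit_panel):
        p = kit_panel.probes[0]
        assert assign_read(p.read_template, kit_panel) == p.probe_id

    def test_substitution_inside_window_unassigns(self, kit_panel):
        p = kit_panel.probes[0]
        read = list(p.read_template)
        read[17] = "A" if read[17] != "A" else "C"  # inside window 2
        assert assign_read("".join(read), kit_panel) == UNASSIGNED

    def test_substitution_outside_windows_still_assigns(self, kit_panel):
        p = kit_panel.probes[0]
        read = list(p.read_template)
        read[12] = "A" if read[12] != "A" else "C"  # between windows 1 and 2
        assert assign_read("".join(read), kit_panel) == p.probe_id

    def test_short_read_flagged(self, kit_panel):
        assert assign_read("ACGT" * 9, kit_panel) == TOO_SHORT

    def test_agrees_with_edit_distance_oracle(self, kit_panel, presets):
        """On error-free reads the exact detective match reproduces a
        minimum-edit-distance assignment over the probe templates."""
        edlib = pytest.importorskip("edlib")
        cfg = SimConfig(per_base_error=0.0, junk_read_fraction=0.0, seed=13)
        reads, _ = simulate_sample(kit_panel, presets["normal_female"], cfg)
        reads = reads[:2000]
        index = build_assignment_index(kit_panel)
        templates = [(p.probe_id, p.read_template) for p in kit_panel]
        for _, seq in reads:
            fast = assign_read(seq, index)
            dists = [(edlib.align(seq, t)["editDistance"], pid) for pid, t in templates]
            dists.sort()
            assert dists[0][0] == 0 and fast == dists[0][1]


class TestCountSample:
    def test_empty_stream(self, small_panel):
        sc = count_sample([], small_panel, "s")
        assert sc.no_reads
        assert sc.analyzable_proportion == 0.0
        assert all(v == 0 for v in sc.counts.values())

    def test_uniform_refs_zero_dispersion(self, small_panel):
        refs = small_panel.by_category(ProbeCategory.INTERNAL_REF)
        reads = [p.read_template for p in refs for _ in range(100)]
        sc = count_sample(reads, small_panel, "s")
        assert sc.internal_ref_mean == 100
        assert sc.dispersion_coefficient == 0.0

    def test_two_ref_dispersion_hand_computed(self):
        """Refs at 100 and 300: mean 200, sample sd 141.42, CV 0.7071."""
        from mlpangs.simulate import simulate_panel

        panel = simulate_panel(n_dmd=1, n_internal_ref=2, seed=2)
        refs = panel.by_category(ProbeCategory.INTERNAL_REF)
        reads = [refs[0].read_template] * 100 + [refs[1].read_template] * 300
        sc = count_sample(reads, panel, "s")
        assert sc.internal_ref_mean == pytest.approx(200)
        assert sc.internal_ref_sd == pytest.approx(141.4213, abs=1e-3)
        assert sc.dispersion_coefficient == pytest.approx(0.70710, abs=1e-4)

    def test_conservation_invariant(self, kit_panel, presets):
        reads, _ = simulate_sample(kit_panel, presets["normal_male"], SimConfig(seed=3))
        seqs = [seq for _, seq in reads]
        sc = count_sample(seqs, kit_panel, "s")
        assert sc.analyzable_reads + sc.unassigned + sc.too_short == sc.total_reads
        assert sc.total_reads == len(seqs)

    def test_order_independence(self, small_panel, presets):
        reads, _ = simulate_sample(small_panel, presets["normal_male"], SimConfig(seed=4))
        seqs = [seq for _, seq in reads]
        shuffled = seqs[:]
        random.Random(0).shuffle(shuffled)
        a = count_sample(seqs, small_panel, "s")
        b = count_sample(shuffled, small_panel, "s")
        assert a.counts == b.counts and a.total_reads == b.total_reads

    def test_error_free_counts_equal_manifest(self, kit_panel, presets):
        cfg = SimConfig(per_base_error=0.0, junk_read_fraction=0.0, seed=8)
        reads, manifest = simulate_sample(kit_panel, presets["dmd_del_30_44_male"], cfg)
        sc = count_sample([seq for _, seq in reads], kit_panel, "s")
        truth = dict(zip(manifest.probe_id, manifest.emitted_reads))
        assert sc.counts == truth


class TestBatchStats:
    def _sc(self, sid, analyzable, total):
        return SampleCounts(sid, {"P": analyzable}, total_reads=total)

    def test_identical_samples_correlation_not_applicable(self):
        samples = [self._sc(f"s{i}", 80, 100) for i in range(3)]
        out = batch_stats(samples, file_sizes=[100, 100, 100])
        assert out["proportion_size_correlation"] is None

    def test_linear_proportions_give_unit_correlation(self):
        samples = [self._sc(f"s{i}", 10 * (i + 1), 100) for i in range(4)]
        out = batch_stats(samples, file_sizes=[1000, 2000, 3000, 4000])
        assert out["proportion_size_correlation"] == pytest.approx(1.0)

    def test_simulated_batch_correlation_is_weak(self, small_panel, presets):
        """Junk fraction is size-independent, so proportion barely tracks size."""
        rng = np.random.default_rng(11)
        samples = []
        sizes = []
        g = presets["normal_male"]
        for i in range(36):
            reads, _ = simulate_sample(
                small_panel, g, SimConfig(seed=int(rng.integers(1 << 30)))
            )
            seqs = [seq for _, seq in reads]
            samples.append(count_sample(seqs, small_panel, f"s{i}"))
            sizes.append(sum(len(s) for s in seqs))
        out = batch_stats(samples, file_sizes=sizes)
        assert abs(out["proportion_size_correlation"]) < 0.5


class TestAmplificationQc:
    def test_normal_sample_ok(self, kit_panel, presets):
        reads, _ = simulate_sample(kit_panel, presets["normal_male"], SimConfig(seed=2))
        sc = count_sample([seq for _, seq in reads], kit_panel, "s")
        assert check_amplification_qc(sc, kit_panel) == QC_OK

    def test_external_only_flags_hybridization_failure(self, kit_panel):
        ext = kit_panel.by_category(ProbeCategory.EXTERNAL_REF)[0]
        reads = [ext.read_template] * 2000
        sc = count_sample(reads, kit_panel, "s")
        assert check_amplification_qc(sc, kit_panel) == QC_HYB_LIGATION_FAILURE

    def test_empty_fastq_flags_amplification_failure(self, kit_panel):
        sc = count_sample([], kit_panel, "s")
        assert check_amplification_qc(sc, kit_panel) == QC_AMPLIFICATION_FAILURE
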