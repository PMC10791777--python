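"""End-to-end convenience wrappers: FASTQ -> counts -> profile -> report."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

from . import calls, cna, readcount
from .calls import SampleReport
from .cna import CopyNumberProfile
from .panel import ProbePanel
from .readcount import SampleCounts

__all__ = ["call_sample", "run_pipeline"]


def call_sample(
    sample_counts: SampleCounts,
    control_counts: SampleCounts,
    panel: ProbePanel,
    control_sex: str = "male",
    smn_scale: str = "half",
) -> tuple[CopyNumberProfile, SampleReport]:
    """Counts for one sample + one control -> QC'd profile and report."""
    rel_s = cna.relative_amplification(sample_counts, panel)
    rel_c = cna.relative_amplification(control_counts, panel)
    profile = cna.relative_copy_number(rel_s, rel_c, control_sex, panel, smn_scale)
    report = calls.classify_and_report(profile)
    return profile, report


def run_pipeline(
    fastq: str | Path | Sequence[str | Path],
    panel: ProbePanel,
    barcode_map: Mapping[str, str],
    control_sample: str,
    control_sex: str = "male",
    smn_scale: str = "half",
    index_fastq: str | Path | None = None,
) -> dict[str, tuple[SampleCounts, CopyNumberProfile | None, SampleReport | None]]:
    """Demultiplex a run, count every sample and call all against one control.

    The control sample is identified by its sample_id in the barcode map;
    it is counted but not called against itself (its profile/report slots
    hold the self-comparison, useful as a sanity check).
    """
    if control_sample not in set(barcode_map.values()):
        raise ValueError(f"control sample {control_sample!r} not in barcode map")
    reads_by_sample, _undetermined = readcount.demultiplex(
        fastq, barcode_map, index_fastq=index_fastq
    )
    counts = {
        sid: readcount.count_sample(reads, panel, sample_id=sid)
        for sid, reads in reads_by_sample.items()
    }
    control_counts = counts[control_sample]
    out: dict = {}
    for sid, sc in counts.items():
        profile, report = call_sample(
            sc, control_counts, panel, control_sex, smn_scale
        )
        out[sid] = (sc, profile, report)
    return out
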