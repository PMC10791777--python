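"""Demultiplexing, read-to-probe assignment and per-sample count statistics.

A read is attributed to a probe when the three detective 10-mers of that
probe match the read exactly at their fixed window offsets; any mismatch
leaves the read unassigned.  Exact matching makes assignment a single
dictionary lookup per read and, because no detective 10-mer recurs within
a valid panel, the attribution is unambiguous by construction.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .panel import DETECTIVE_WINDOWS, ProbeCategory, ProbePanel

__all__ = [
    "SampleCounts",
    "demultiplex",
    "assign_read",
    "build_assignment_index",
    "count_sample",
    "count_reads",
    "batch_stats",
    "check_amplification_qc",
]

UNASSIGNED = "unassigned"
TOO_SHORT = "too_short"

#: Verdicts from amplification QC.
QC_OK = "ok"
QC_HYB_LIGATION_FAILURE = "hybridization_or_ligation_failure"
QC_AMPLIFICATION_FAILURE = "amplification_failure"


@dataclass
class SampleCounts:
    """Per-probe read counts and summary statistics for one sample.

    ``total_reads`` counts the reads examined for this sample after
    demultiplexing (undetermined-index reads belong to no sample);
    ``analyzable_reads`` is the subset attributed to a probe.  The
    dispersion coefficient is the coefficient of variation (sd/mean,
    sample sd with n-1 denominator) of the internal-reference counts.
    """

    sample_id: str
    counts: dict[str, int]
    total_reads: int = 0
    unassigned: int = 0
    too_short: int = 0
    internal_ref_mean: float = 0.0
    internal_ref_sd: float = 0.0

    @property
    def analyzable_reads(self) -> int:
        return sum(self.counts.values())

    @property
    def analyzable_proportion(self) -> float:
        """Fraction of examined reads attributed to a probe; 0 if no reads."""
        if self.total_reads == 0:
            return 0.0
        return self.analyzable_reads / self.total_reads

    @property
    def no_reads(self) -> bool:
        return self.total_reads == 0

    @property
    def dispersion_coefficient(self) -> float:
        if self.internal_ref_mean == 0:
            return float("nan")
        return self.internal_ref_sd / self.internal_ref_mean


def open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _fastq_records(paths: Sequence[str | Path]) -> Iterator[tuple[str, str]]:
    for path in paths:
        with open_text(path) as fh:
            for title, seq, _qual in FastqGeneralIterator(fh):
                yield title, seq


def _barcode_from_title(title: str) -> str | None:
    # Illumina convention: "<name> <read>:<filter>:<control>:<barcode>"
    parts = title.split()
    if len(parts) < 2:
        return None
    comment_fields = parts[-1].split(":")
    if len(comment_fields) < 4:
        return None
    return comment_fields[3] or None


def demultiplex(
    fastq: str | Path | Sequence[str | Path],
    barcode_map: Mapping[str, str],
    index_fastq: str | Path | Sequence[str | Path] | None = None,
) -> tuple[dict[str, list[str]], int]:
    """Split reads by exact 8 bp index match.

    The index is taken from the header comment (``1:N:0:BARCODE``) or, if
    ``index_fastq`` is given, from a parallel I1 file record by record.
    Reads whose index matches no sample exactly go to the undetermined
    tally; total conservation (sum of per-sample reads + undetermined =
    input reads) always holds.

    Returns ``(per-sample read-sequence lists, undetermined count)``.
    """
    _check_barcodes(barcode_map)
    if isinstance(fastq, (str, Path)):
        fastq = [fastq]
    reads_by_sample: dict[str, list[str]] = {s: [] for s in barcode_map.values()}
    undetermined = 0

    if index_fastq is not None:
        if isinstance(index_fastq, (str, Path)):
            index_fastq = [index_fastq]
        for (title, seq), (_, idx_seq) in zip(
            _fastq_records(fastq), _fastq_records(index_fastq), strict=True
        ):
            sample = barcode_map.get(idx_seq)
            if sample is None:
                undetermined += 1
            else:
                reads_by_sample[sample].append(seq)
    else:
        for title, seq in _fastq_records(fastq):
            barcode = _barcode_from_title(title)
            sample = barcode_map.get(barcode) if barcode else None
            if sample is None:
                undetermined += 1
            else:
                reads_by_sample[sample].append(seq)
    return reads_by_sample, undetermined


def _check_barcodes(barcode_map: Mapping[str, str]) -> None:
    for bc in barcode_map:
        if len(bc) != 8:
            raise ValueError(f"barcode {bc!r} is not 8 nt")
    if len(set(barcode_map)) != len(barcode_map):
        raise ValueError("duplicate barcodes in barcode map")


def load_barcode_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (barcode, sample_id), header optional."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            barcode, sample_id = line.split("\t")[:2]
            if barcode.lower() in ("barcode", "index"):
                continue
            if barcode in out:
                raise ValueError(f"duplicate barcode {barcode!r}")
            out[barcode] = sample_id
    return out


# ---------------------------------------------------------------------------
# Assignment


def build_assignment_index(
    panel: ProbePanel,
    windows: Sequence[tuple[int, int]] = DETECTIVE_WINDOWS,
) -> dict[str, str]:
    """Concatenated-detective lookup table: windows' content -> probe_id."""
    index: dict[str, str] = {}
    for probe in panel:
        key = "".join(probe.detective)
        if key in index:
            raise ValueError(
                f"panel not collision-free: {index[key]} and {probe.probe_id}"
            )
        index[key] = probe.probe_id
    return index


def assign_read(
    read: str,
    panel: ProbePanel | Mapping[str, str],
    windows: Sequence[tuple[int, int]] = DETECTIVE_WINDOWS,
) -> str:
    """Attribute one read: returns a probe_id, UNASSIGNED or TOO_SHORT.

    Only the first 40 nt are examined; a read shorter than the last window
    end is TOO_SHORT.  ``panel`` may be a ProbePanel or a prebuilt index
    from :func:`build_assignment_index`.
    """
    index = panel if isinstance(panel, Mapping) else build_assignment_index(panel, windows)
    if len(read) < max(end for _, end in windows):
        return TOO_SHORT
    key = "".join(read[start:end] for start, end in windows)
    return index.get(key.upper(), UNASSIGNED)


def count_reads(
    reads: Iterable[str],
    panel: ProbePanel,
    sample_id: str = "",
    windows: Sequence[tuple[int, int]] = DETECTIVE_WINDOWS,
) -> SampleCounts:
    """Count a stream of read sequences against a panel (zero-filled)."""
    index = build_assignment_index(panel, windows)
    counts = {p.probe_id: 0 for p in panel}
    total = unassigned = too_short = 0
    for read in reads:
        total += 1
        hit = assign_read(read, index, windows)
        if hit == TOO_SHORT:
            too_short += 1
        elif hit == UNASSIGNED:
            unassigned += 1
        else:
            counts[hit] += 1

    sc = SampleCounts(
        sample_id=sample_id,
        counts=counts,
        total_reads=total,
        unassigned=unassigned,
        too_short=too_short,
    )
    ref_counts = [counts[pid] for pid in panel.internal_ref_ids]
    if ref_counts:
        sc.internal_ref_mean = float(np.mean(ref_counts))
        sc.internal_ref_sd = (
            float(np.std(ref_counts, ddof=1)) if len(ref_counts) > 1 else 0.0
        )
    return sc


# count_sample is the public name used by the pipeline; count_reads is the
# same operation named for what it consumes.
count_sample = count_reads


# ---------------------------------------------------------------------------
# Batch statistics & QC


def batch_stats(
    samples: Sequence[SampleCounts],
    file_sizes: Sequence[int] | None = None,
) -> dict:
    """Run-level summary: totals, analyzable-proportion range and, when
    file sizes are given, the Pearson correlation of proportion vs size.

    The correlation is reported as None when fewer than two samples are
    present or either variable is constant.
    """
    totals = [s.total_reads for s in samples]
    props = [s.analyzable_proportion for s in samples]
    out = {
        "n_samples": len(samples),
        "min_total_reads": min(totals) if totals else 0,
        "max_total_reads": max(totals) if totals else 0,
        "min_analyzable_proportion": min(props) if props else None,
        "max_analyzable_proportion": max(props) if props else None,
        "proportion_size_correlation": None,
    }
    if file_sizes is not None and len(samples) >= 2:
        from scipy import stats

        sizes = np.asarray(file_sizes, dtype=float)
        p = np.asarray(props, dtype=float)
        if np.std(sizes) > 0 and np.std(p) > 0:
            r, _ = stats.pearsonr(p, sizes)
            out["proportion_size_correlation"] = float(r)
    return out


def check_amplification_qc(
    counts: SampleCounts,
    panel: ProbePanel,
    min_analyzable_reads: int = 1000,
    external_fraction_threshold: float = 0.5,
) -> str:
    """Diagnose assay failure modes from the count profile.

    External-reference probes amplify from pre-added template independent
    of the genomic DNA, so when they dominate the analyzable reads the
    hybridisation/ligation step failed (or no template was added); when
    next to nothing amplified at all, the PCR itself failed.
    """
    ext_ids = [
        p.probe_id for p in panel.by_category(ProbeCategory.EXTERNAL_REF)
    ]
    if not ext_ids:
        raise ValueError("panel has no external reference probe")
    analyzable = counts.analyzable_reads
    if analyzable > 0:
        ext_reads = sum(counts.counts.get(pid, 0) for pid in ext_ids)
        if ext_reads / analyzable > external_fraction_threshold:
            return QC_HYB_LIGATION_FAILURE
    if analyzable < min_analyzable_reads:
        return QC_AMPLIFICATION_FAILURE
    return QC_OK


# ---------------------------------------------------------------------------
# Tabular output


def counts_table(samples: Sequence[SampleCounts]) -> "pd.DataFrame":
    import pandas as pd

    rows = [
        {"sample_id": s.sample_id, "probe_id": pid, "count": n}
        for s in samples
        for pid, n in s.counts.items()
    ]
    return pd.DataFrame(rows)


def stats_table(samples: Sequence[SampleCounts]) -> "pd.DataFrame":
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "total_reads": s.total_reads,
                "analyzable_reads": s.analyzable_reads,
                "analyzable_proportion": s.analyzable_proportion,
                "unassigned": s.unassigned,
                "too_short": s.too_short,
                "internal_ref_mean": s.internal_ref_mean,
                "internal_ref_sd": s.internal_ref_sd,
                "dispersion_coefficient": s.dispersion_coefficient,
            }
            for s in samples
        ]
    )


def write_qc_json(verdicts: Mapping[str, str], path: str | Path) -> None:
    Path(path).write_text(json.dumps(dict(verdicts), indent=2) + "\n")
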