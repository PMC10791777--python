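"""Normalisation to relative copy number and the kit's QC windows.

The chain is: read counts -> relative amplification (count over the
internal-reference aggregate of the same sample) -> relative copy number
(sample-to-control ratio of relative amplification, scaled by a multiplier
reflecting the control's copy state at that locus class).

With a healthy male control the multipliers are 1 for DMD (the control
carries one X-linked copy), 4 for undiscriminated SMN on the total scale
(control carries SMN1+SMN2 = 4) or 2 on the half scale, 2 for the
SMN1/SMN2-discriminating probes and 2 for autosomal references.  Sex-probe
ratios are reported without control comparison.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .panel import ProbeCategory, ProbePanel
from .readcount import SampleCounts

__all__ = [
    "RelativeAmplification",
    "CopyNumberProfile",
    "relative_amplification",
    "determine_sex",
    "relative_copy_number",
    "qc_profile",
    "QC_WINDOW",
    "DELETED_RESIDUAL_MAX",
    "SEX_RATIO_FEMALE_MAX",
    "SEX_RATIO_MALE_MIN",
]

#: Per-probe QC: relative copy number must fall within 30% of the
#: theoretical value (inclusive), the same window as commercial MLPA kits.
QC_WINDOW = 0.30

#: A probe called at zero copies passes QC when its residual relative copy
#: number stays below 0.05 (error leakage only).
DELETED_RESIDUAL_MAX = 0.05

#: Y/X relative-amplification ratio thresholds for sex calling.
SEX_RATIO_FEMALE_MAX = 0.1
SEX_RATIO_MALE_MIN = 0.5

SmnScale = Literal["half", "total"]

PROBE_QC_PASS = "pass"
PROBE_QC_FAIL = "fail"
PROBE_QC_DELETED_PASS = "deleted_pass"
PROBE_QC_INCOMPARABLE = "incomparable"
PROBE_QC_NOT_EVALUATED = "not_evaluated"


@dataclass
class RelativeAmplification:
    """Per-probe counts normalised by the sample's internal-reference level."""

    sample_id: str
    rel: dict[str, float]
    aggregate: float  # the internal-reference aggregate used as denominator
    counts: dict[str, int] = field(default_factory=dict)  # raw counts
    ref_sum: int = 0  # raw internal-reference sum (aggregation-independent)


@dataclass
class CopyNumberProfile:
    sample_id: str
    control_id: str
    sex_call: str  # "male" | "female" | "indeterminate"
    sex_ratio: float
    rcn: dict[str, float]
    theoretical: dict[str, float | None]
    smn_scale: SmnScale
    rcn_se: dict[str, float] = field(default_factory=dict)
    qc: dict[str, str] = field(default_factory=dict)
    sample_qc: str = "pending"
    incomparable: list[str] = field(default_factory=list)
    panel: ProbePanel | None = None

    def to_json(self) -> str:
        payload = {
            "sample_id": self.sample_id,
            "control_id": self.control_id,
            "sex_call": self.sex_call,
            "sex_ratio": self.sex_ratio,
            "sample_qc": self.sample_qc,
            "smn_scale": self.smn_scale,
            "rcn": self.rcn,
            "theoretical": self.theoretical,
            "qc": self.qc,
            "incomparable": self.incomparable,
        }
        return json.dumps(payload, indent=2)


def relative_amplification(
    counts: SampleCounts,
    panel: ProbePanel,
    aggregate: Literal["mean", "sum"] = "mean",
) -> RelativeAmplification:
    """Normalise each probe's count by the internal-reference aggregate.

    With the default mean aggregation, a diploid reference locus sits near
    1.0.  The choice of mean vs sum is a constant factor that cancels in
    any sample-to-control ratio, so relative copy numbers are identical
    under either.
    """
    ref_ids = panel.internal_ref_ids
    if not ref_ids:
        raise ValueError("panel has no internal reference probes")
    ref_counts = [counts.counts.get(pid, 0) for pid in ref_ids]
    ref_sum = int(sum(ref_counts))
    denom = float(ref_sum) if aggregate == "sum" else ref_sum / len(ref_counts)
    if denom == 0:
        raise ValueError(
            f"sample {counts.sample_id}: all internal reference probes have "
            "zero reads; sample is unusable"
        )
    rel = {pid: n / denom for pid, n in counts.counts.items()}
    return RelativeAmplification(
        counts.sample_id, rel, denom, counts=dict(counts.counts), ref_sum=ref_sum
    )


def determine_sex(
    rel: RelativeAmplification, panel: ProbePanel
) -> tuple[str, float]:
    """Call sex from the Y-to-X relative-amplification ratio.

    ratio = mean(rel over chrY probes) / mean(rel over chrX probes);
    below 0.1 is female, above 0.5 is male, the gap is indeterminate
    (reported rather than guessed, and failed at sample QC).
    """
    x_ids = [p.probe_id for p in panel.by_category(ProbeCategory.CHRX_SEX)]
    y_ids = [p.probe_id for p in panel.by_category(ProbeCategory.CHRY_SEX)]
    if not x_ids or not y_ids:
        raise ValueError("panel lacks chrX or chrY sex probes")
    x_mean = float(np.mean([rel.rel[pid] for pid in x_ids]))
    y_mean = float(np.mean([rel.rel[pid] for pid in y_ids]))
    if x_mean == 0:
        raise ValueError(
            f"sample {rel.sample_id}: chrX probes show no amplification"
        )
    ratio = y_mean / x_mean
    if ratio < SEX_RATIO_FEMALE_MAX:
        return "female", ratio
    if ratio > SEX_RATIO_MALE_MIN:
        return "male", ratio
    return "indeterminate", ratio


def _multiplier(category: ProbeCategory, control_sex: str, smn_scale: SmnScale) -> float | None:
    """Control-copy-state multiplier turning a rel ratio into copies."""
    if category is ProbeCategory.DMD_EXON:
        return 2.0 if control_sex == "female" else 1.0
    if category is ProbeCategory.SMN_SHARED:
        return 4.0 if smn_scale == "total" else 2.0
    if category in (ProbeCategory.SMN1_SPECIFIC, ProbeCategory.SMN2_SPECIFIC):
        return 2.0
    if category is ProbeCategory.INTERNAL_REF:
        return 2.0
    return None  # sex probes, external refs: no control comparison


def _theoretical(category: ProbeCategory, sex_call: str, smn_scale: SmnScale) -> float | None:
    if category is ProbeCategory.DMD_EXON:
        if sex_call == "male":
            return 1.0
        if sex_call == "female":
            return 2.0
        return None
    if category is ProbeCategory.SMN_SHARED:
        return 4.0 if smn_scale == "total" else 2.0
    if category in (ProbeCategory.SMN1_SPECIFIC, ProbeCategory.SMN2_SPECIFIC):
        return 2.0
    if category is ProbeCategory.INTERNAL_REF:
        return 2.0
    return None


def relative_copy_number(
    sample: RelativeAmplification,
    control: RelativeAmplification,
    control_sex: str,
    panel: ProbePanel,
    smn_scale: SmnScale = "half",
) -> CopyNumberProfile:
    """Per-probe relative copy number of a sample against a single control.

    For each genomic probe, rcn = (rel_sample / rel_control) x multiplier;
    sex-chromosome probes are reported as the sample's own relative
    amplification without control comparison, and feed the sex call.
    A probe whose control signal is zero while the sample's is not cannot
    be compared and is flagged.
    """
    if control_sex not in ("male", "female"):
        raise ValueError("control_sex must be male or female")
    sex_call, sex_ratio = determine_sex(sample, panel)

    rcn: dict[str, float] = {}
    rcn_se: dict[str, float] = {}
    theoretical: dict[str, float | None] = {}
    incomparable: list[str] = []
    for probe in panel:
        pid = probe.probe_id
        m = _multiplier(probe.category, control_sex, smn_scale)
        if m is None:
            rcn[pid] = sample.rel.get(pid, 0.0)
            rcn_se[pid] = 0.0
            theoretical[pid] = None
            continue
        # Ratio from raw counts and reference sums: the reference-aggregation
        # constant (sum vs mean) cancels exactly, and integer products keep
        # the ratio bit-identical under any common count rescaling.
        n_s = sample.counts.get(pid, 0)
        n_c = control.counts.get(pid, 0)
        if n_c == 0 or control.ref_sum == 0:
            if n_s > 0:
                incomparable.append(pid)
            rcn[pid] = 0.0 if n_s == 0 else math.nan
            rcn_se[pid] = 0.0
        else:
            rcn[pid] = (n_s * control.ref_sum) / (n_c * sample.ref_sum) * m
            # delta-method counting error of the ratio (Poisson terms from
            # both counts and both reference aggregates)
            rcn_se[pid] = rcn[pid] * math.sqrt(
                (1.0 / n_s if n_s else 0.0)
                + 1.0 / n_c
                + 1.0 / sample.ref_sum
                + 1.0 / control.ref_sum
            )
        theoretical[pid] = _theoretical(probe.category, sex_call, smn_scale)

    profile = CopyNumberProfile(
        sample_id=sample.sample_id,
        control_id=control.sample_id,
        sex_call=sex_call,
        sex_ratio=sex_ratio,
        rcn=rcn,
        rcn_se=rcn_se,
        theoretical=theoretical,
        smn_scale=smn_scale,
        incomparable=incomparable,
        panel=panel,
    )
    return qc_profile(profile)


def qc_profile(profile: CopyNumberProfile) -> CopyNumberProfile:
    """Apply the per-probe and sample-level QC windows in place.

    A probe passes when its rcn lies within 30% of its theoretical value;
    a probe far below theoretical still passes (``deleted_pass``) when its
    residual is below 0.05, the leakage level expected at a truly deleted
    locus — both windows following the kit's acceptance rules.  Sample QC
    requires a determinate sex call and every internal-reference probe in
    its window; aberrant disease-gene probes are findings, not QC failures,
    and do not fail the sample.
    """
    qc: dict[str, str] = {}
    for pid, theo in profile.theoretical.items():
        rcn = profile.rcn[pid]
        if theo is None:
            qc[pid] = PROBE_QC_NOT_EVALUATED
            continue
        if math.isnan(rcn):
            qc[pid] = PROBE_QC_INCOMPARABLE
            continue
        # tiny epsilon keeps the inclusive "within 30%" boundary robust to
        # floating-point representation (|1.3 - 1| is not exactly 0.3)
        if abs(rcn - theo) <= QC_WINDOW * theo * (1 + 1e-9):
            qc[pid] = PROBE_QC_PASS
        elif rcn < DELETED_RESIDUAL_MAX:
            qc[pid] = PROBE_QC_DELETED_PASS
        else:
            qc[pid] = PROBE_QC_FAIL
    profile.qc = qc

    panel = profile.panel
    internal_ok = True
    if panel is not None:
        internal_ok = all(
            qc.get(pid) == PROBE_QC_PASS for pid in panel.internal_ref_ids
        )
    profile.sample_qc = (
        "pass" if internal_ok and profile.sex_call != "indeterminate" else "fail"
    )
    return profile


def profile_table(profile: CopyNumberProfile) -> "pd.DataFrame":
    import pandas as pd

    panel = profile.panel
    rows = []
    for pid, rcn in profile.rcn.items():
        probe = panel[pid] if panel is not None else None
        rows.append(
            {
                "probe_id": pid,
                "category": probe.category.value if probe else "",
                "exon": probe.exon_index if probe else None,
                "rcn": rcn,
                "theoretical": profile.theoretical[pid],
                "qc": profile.qc.get(pid, ""),
            }
        )
    return pd.DataFrame(rows)
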