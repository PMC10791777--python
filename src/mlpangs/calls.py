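"""Discrete copy-number events and the per-sample clinical-style report.

Continuous relative copy numbers are rounded to integer copies with a
confidence grade, contiguous aberrant DMD exons are merged into events,
and SMN1/SMN2 integer copies are cross-checked against the (more stable)
undiscriminated SMN total, which also flags the gene-conversion pattern:
SMN1 loss exactly balanced by SMN2 gain with the total unchanged.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .cna import CopyNumberProfile, DELETED_RESIDUAL_MAX
from .panel import ProbeCategory, ProbePanel

__all__ = [
    "CnaEvent",
    "SampleReport",
    "integerize",
    "segment_events",
    "interpret_smn",
    "classify_and_report",
    "ZERO_CALL_MAX_RCN",
    "CONFIDENCE_BAND",
]

#: An rcn below this may be called zero copies at all.
ZERO_CALL_MAX_RCN = 0.35
#: Nonzero integer calls are confident within this absolute band (the 30%
#: QC window evaluated at one copy).
CONFIDENCE_BAND = 0.30

CONFIDENT = "confident"
AMBIGUOUS = "ambiguous"

#: Evidence thresholds for event runs, in counting standard errors of the
#: run mean (|mean rcn - expected| / se).  The counting se deliberately
#: excludes residual probe-level wobble, so a run must clear a high apparent
#: z before it is called: a genuine one-copy change at the panel's design
#: depth (~600 reads per diploid probe) yields z of roughly 4-6 on a single
#: exon and 9+ on two or more, while coincident noise deviations large
#: enough to cross the rounding midpoint land near 3 (single) and 7 (pair).
#: Runs below threshold become review flags, not events.  Three or more
#: consecutive deviating exons are essentially never produced by noise, so
#: the bar drops again for long runs lest a genuine event that lost a
#: boundary exon to rounding be discarded wholesale.
SINGLE_EXON_MIN_Z = 4.0
TWO_EXON_MIN_Z = 8.0
LONG_RUN_MIN_Z = 5.0


def _run_min_z(n_exons: int) -> float:
    if n_exons == 1:
        return SINGLE_EXON_MIN_Z
    if n_exons == 2:
        return TWO_EXON_MIN_Z
    return LONG_RUN_MIN_Z


@dataclass(frozen=True)
class CnaEvent:
    gene: str  # "DMD" | "SMN1" | "SMN2" | "SMN_total"
    exon_start: int
    exon_end: int
    copies: int
    zygosity_label: str
    confidence: str = CONFIDENT

    def __post_init__(self) -> None:
        if self.exon_start > self.exon_end:
            raise ValueError("exon_start must not exceed exon_end")


@dataclass
class SampleReport:
    sample_id: str
    sex_call: str
    sample_qc: str
    events: list[CnaEvent] = field(default_factory=list)
    smn1_exon7_copies: int | None = None
    smn1_exon8_copies: int | None = None
    smn2_exon7_copies: int | None = None
    smn2_exon8_copies: int | None = None
    smn_total_copies: int | None = None
    smn_consistency: str = "consistent"
    clinical_annotation: list[str] = field(default_factory=list)
    review_flags: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        payload = {
            "sample_id": self.sample_id,
            "sex_call": self.sex_call,
            "sample_qc": self.sample_qc,
            "events": [
                {
                    "gene": e.gene,
                    "exon_start": e.exon_start,
                    "exon_end": e.exon_end,
                    "copies": e.copies,
                    "zygosity_label": e.zygosity_label,
                    "confidence": e.confidence,
                }
                for e in self.events
            ],
            "smn": {
                "smn1_exon7": self.smn1_exon7_copies,
                "smn1_exon8": self.smn1_exon8_copies,
                "smn2_exon7": self.smn2_exon7_copies,
                "smn2_exon8": self.smn2_exon8_copies,
                "smn_total": self.smn_total_copies,
                "consistency": self.smn_consistency,
            },
            "clinical_annotation": self.clinical_annotation,
            "review_flags": self.review_flags,
        }
        return json.dumps(payload, indent=2)


def integerize(rcn: float, theoretical: float | None = None) -> tuple[int, str]:
    """Round a relative copy number to integer copies with a confidence.

    Zero copies demand near-absence of signal: below 0.35 at all, and
    below 0.05 (the deletion-residual ceiling) to be confident.  Nonzero
    calls are confident within an absolute 0.3 band around the integer.
    Values in [0.35, 0.5) round up to one copy but are never confident.
    """
    if math.isnan(rcn):
        raise ValueError("cannot integerize an incomparable probe (NaN rcn)")
    if rcn < 0:
        raise ValueError("rcn must be non-negative")
    if rcn < ZERO_CALL_MAX_RCN:
        return 0, (CONFIDENT if rcn < DELETED_RESIDUAL_MAX else AMBIGUOUS)
    copies = max(1, math.floor(rcn + 0.5))
    conf = CONFIDENT if abs(rcn - copies) <= CONFIDENCE_BAND else AMBIGUOUS
    return copies, conf


_MULTIPLE_WORDS = {3: "threefold (3×)", 4: "fourfold (4×)", 5: "fivefold (5×)"}


def zygosity_label(sex: str, copies: int, expected: int) -> str:
    """Human-readable label for an aberrant X-linked copy state."""
    if copies == 0:
        return "hemizygous deletion" if expected == 1 else "homozygous deletion"
    if copies < expected:
        return "heterozygous deletion"
    word = _MULTIPLE_WORDS.get(copies, f"{copies}-fold ({copies}×)")
    return f"{word} duplication"


def segment_events(
    profile: CopyNumberProfile,
    panel: ProbePanel | None = None,
    with_flags: bool = False,
) -> list[CnaEvent] | tuple[list[CnaEvent], list[str]]:
    """Merge consecutive aberrant DMD exons into maximal events.

    Probes are ordered by exon number internally, so input order never
    matters.  Exon 1 carries two probes; a confident exon-1 state needs
    both to agree, otherwise the exon is treated as ambiguous and any
    event touching it is downgraded.

    Segmentation is run-aware rather than purely per-exon: two aberrant
    runs with the same integer copies separated by a single exon that
    deviates from the expected level in the same direction (by at least
    half the confidence band) are bridged into one event, and each event's
    copy number and confidence are re-estimated from the mean rcn over its
    exons.  At moderate depth a single mid-run exon wobbling across the
    rounding midpoint would otherwise split one contiguous aberration in
    two, which contradicts the contiguous-exon mechanism of these CNVs.

    An aberrant run confined to a single exon whose call is ambiguous is
    not reported as an event: isolated single-probe deviations are the
    signature of probe-level artefacts (e.g. a SNP under the probe) and
    always require orthogonal confirmation.  Such exons are returned as
    review flags when ``with_flags`` is true.
    """
    panel = panel or profile.panel
    if panel is None:
        raise ValueError("segment_events needs the probe panel")
    expected = 1 if profile.sex_call == "male" else 2
    if profile.sex_call == "indeterminate":
        expected = 2  # conservative; sample QC already failed

    # per-exon mean rcn and integer call; duplicate probes (exon 1) must agree
    per_exon: dict[int, list[tuple[float, float]]] = {}
    for probe in panel.by_category(ProbeCategory.DMD_EXON):
        rcn = profile.rcn[probe.probe_id]
        if math.isnan(rcn):
            continue
        se = profile.rcn_se.get(probe.probe_id, 0.0)
        per_exon.setdefault(probe.exon_index, []).append((rcn, se))

    exon_rcn: dict[int, float] = {}
    exon_se: dict[int, float] = {}
    exon_copies: dict[int, int] = {}
    exon_disputed: dict[int, bool] = {}
    for exon, vals in per_exon.items():
        rcns = [r for r, _ in vals]
        exon_rcn[exon] = sum(rcns) / len(rcns)
        exon_se[exon] = math.sqrt(sum(s * s for _, s in vals)) / len(vals)
        calls = [integerize(r)[0] for r in rcns]
        exon_copies[exon] = integerize(exon_rcn[exon])[0]
        exon_disputed[exon] = len(set(calls)) > 1

    # maximal contiguous runs of aberrant exons sharing a direction (gain or
    # loss); the run's integer copies are decided afterwards from its mean,
    # so one exon wobbling between adjacent integers cannot split an event
    runs: list[dict] = []
    for exon in sorted(exon_copies):
        copies = exon_copies[exon]
        if copies == expected:
            continue
        direction = 1 if copies > expected else -1
        if (
            runs
            and runs[-1]["direction"] == direction
            and exon == runs[-1]["exons"][-1] + 1
        ):
            runs[-1]["exons"].append(exon)
        else:
            runs.append({"direction": direction, "exons": [exon]})

    # bridge same-direction runs across a single-exon gap that leans their
    # way by at least half the confidence band
    half_band = CONFIDENCE_BAND / 2
    merged: list[dict] = []
    for run in runs:
        if merged:
            prev = merged[-1]
            gap = [
                e
                for e in range(prev["exons"][-1] + 1, run["exons"][0])
                if e in exon_rcn
            ]
            bridgeable = (
                run["direction"] == prev["direction"]
                and len(gap) == 1
                and run["direction"] * (exon_rcn[gap[0]] - expected) >= half_band
            )
            if bridgeable:
                prev["exons"].extend(gap + run["exons"])
                continue
        merged.append(run)

    # likelihood-based boundary refinement: absorb an adjacent exon into a
    # run when its value is better explained by the run's copy level than by
    # the expected level.  Noise is proportional to the copy level, so the
    # decision boundary is not the rounding midpoint: for a gain from 2 to 3
    # copies it sits slightly below 2.5.  Zero-copy runs are excluded (their
    # boundaries are crisp; a deleted exon has essentially no signal).
    claimed = {e for run in merged for e in run["exons"]}

    def _prefers_level(v: float, rel_err: float, level: float, exp: float) -> bool:
        if rel_err <= 0 or level <= 0:
            return False
        z_run = (v - level) / (rel_err * level)
        z_exp = (v - exp) / (rel_err * exp)
        return z_exp * z_exp - z_run * z_run > 2.0 * math.log(level / exp)

    for run in merged:
        level = integerize(sum(exon_rcn[e] for e in run["exons"]) / len(run["exons"]))[0]
        if level == 0 or level == expected:
            continue
        for step, edge in ((-1, 0), (1, -1)):
            while True:
                nxt = run["exons"][edge] + step
                if nxt not in exon_rcn or nxt in claimed:
                    break
                v = exon_rcn[nxt]
                rel_err = exon_se[nxt] / v if v > 0 else 0.0
                if not _prefers_level(v, rel_err, float(level), float(expected)):
                    break
                claimed.add(nxt)
                if step < 0:
                    run["exons"].insert(0, nxt)
                else:
                    run["exons"].append(nxt)

    events: list[CnaEvent] = []
    flags: list[str] = []
    for exon in sorted(exon_disputed):
        if exon_disputed[exon] and exon_copies[exon] == expected:
            flags.append(
                f"DMD exon {exon}: duplicate probes disagree on copy number"
            )
    for run in merged:
        exons = run["exons"]
        mean_rcn = sum(exon_rcn[e] for e in exons) / len(exons)
        copies, conf = integerize(mean_rcn)
        if copies == expected:
            continue  # run-level evidence washes out as noise
        if any(exon_disputed[e] for e in exons):
            conf = AMBIGUOUS
        run_se = math.sqrt(sum(exon_se[e] ** 2 for e in exons)) / len(exons)
        min_z = _run_min_z(len(exons))
        weak_evidence = run_se > 0 and abs(mean_rcn - expected) < min_z * run_se
        if weak_evidence or (len(exons) == 1 and conf == AMBIGUOUS):
            span = (
                f"exon {exons[0]}"
                if len(exons) == 1
                else f"exons {exons[0]}-{exons[-1]}"
            )
            flags.append(
                f"DMD {span}: deviation ({copies} copies) below evidence "
                "threshold, needs orthogonal confirmation"
            )
            continue
        events.append(
            CnaEvent(
                gene="DMD",
                exon_start=exons[0],
                exon_end=exons[-1],
                copies=copies,
                zygosity_label=zygosity_label(profile.sex_call, copies, expected),
                confidence=conf,
            )
        )
    if with_flags:
        return events, flags
    return events


def interpret_smn(
    profile: CopyNumberProfile, panel: ProbePanel | None = None
) -> dict:
    """Integer SMN1/SMN2 copies at exons 7-8 calibrated by the SMN total.

    The undiscriminated SMN probes measure SMN1+SMN2 and are the more
    stable signal; the exon-7/8 discriminating probes rest on a single
    terminal base and wobble more.  Consistency compares their sum to the
    total (on the 4-copy total scale): an exact match is consistent unless
    it shows the conversion pattern (SMN1 below two, SMN2 above two, total
    still four), which suggests exon conversion of one SMN1 allele rather
    than loss; a one-copy discrepancy is tolerated as probe wobble;
    anything larger is flagged inconsistent.
    """
    panel = panel or profile.panel
    if panel is None:
        raise ValueError("interpret_smn needs the probe panel")

    to_total = 2.0 if profile.smn_scale == "half" else 1.0

    def copies_of(category: ProbeCategory, exon: int) -> int | None:
        vals = [
            profile.rcn[p.probe_id]
            for p in panel.by_category(category)
            if p.exon_index == exon and not math.isnan(profile.rcn[p.probe_id])
        ]
        if not vals:
            return None
        return integerize(sum(vals) / len(vals))[0]

    smn1 = {e: copies_of(ProbeCategory.SMN1_SPECIFIC, e) for e in (7, 8)}
    smn2 = {e: copies_of(ProbeCategory.SMN2_SPECIFIC, e) for e in (7, 8)}

    shared = [
        profile.rcn[p.probe_id] * to_total
        for p in panel.by_category(ProbeCategory.SMN_SHARED)
        if not math.isnan(profile.rcn[p.probe_id])
    ]
    total = integerize(sum(shared) / len(shared))[0] if shared else None

    consistency = "consistent"
    for e in (7, 8):
        s1, s2 = smn1[e], smn2[e]
        if s1 is None or s2 is None or total is None:
            continue
        diff = abs((s1 + s2) - total)
        if s1 < 2 and s2 > 2 and total == 4:
            consistency = "conversion_suspected"
            break
        if diff > 1:
            consistency = "inconsistent"
            break
    return {
        "smn1_exon7_copies": smn1[7],
        "smn1_exon8_copies": smn1[8],
        "smn2_exon7_copies": smn2[7],
        "smn2_exon8_copies": smn2[8],
        "smn_total_copies": total,
        "smn_consistency": consistency,
    }


def classify_and_report(
    profile: CopyNumberProfile,
    events: Sequence[CnaEvent] | None = None,
    smn: dict | None = None,
    panel: ProbePanel | None = None,
) -> SampleReport:
    """Assemble the sample report with screening tags.

    Tags are string annotations, not diagnoses: SMA_affected (no SMN1
    exon 7), SMA_carrier (single SMN1 exon 7), DMD_affected (male with a
    zero-copy DMD event), DMD_carrier (female with a one- or three-copy
    DMD event).  A report is emitted even when sample QC failed, carrying
    the fail flag.
    """
    panel = panel or profile.panel
    flags: list[str] = []
    if events is None:
        events, flags = segment_events(profile, panel, with_flags=True)
    if smn is None:
        smn = interpret_smn(profile, panel)
    for e in events:
        if e.confidence == AMBIGUOUS:
            flags.append(
                f"{e.gene} exons {e.exon_start}-{e.exon_end}: event includes "
                "ambiguous probe calls"
            )

    tags: list[str] = []
    s1e7 = smn["smn1_exon7_copies"]
    if s1e7 == 0:
        tags.append("SMA_affected")
    elif s1e7 == 1:
        tags.append("SMA_carrier")
    if profile.sex_call == "male" and any(
        e.gene == "DMD" and e.copies == 0 for e in events
    ):
        tags.append("DMD_affected")
    if profile.sex_call == "female" and any(
        e.gene == "DMD" and e.copies in (1, 3) for e in events
    ):
        tags.append("DMD_carrier")

    return SampleReport(
        sample_id=profile.sample_id,
        sex_call=profile.sex_call,
        sample_qc=profile.sample_qc,
        events=list(events),
        clinical_annotation=tags,
        review_flags=flags,
        smn_consistency=smn["smn_consistency"],
        smn1_exon7_copies=smn["smn1_exon7_copies"],
        smn1_exon8_copies=smn["smn1_exon8_copies"],
        smn2_exon7_copies=smn["smn2_exon7_copies"],
        smn2_exon8_copies=smn["smn2_exon8_copies"],
        smn_total_copies=smn["smn_total_copies"],
    )


def write_report(report: SampleReport, path: str | Path) -> None:
    Path(path).write_text(report.to_json() + "\n")
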