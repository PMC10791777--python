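"""Probe-panel model for the DMD-SMA MLPA-NGS assay.

An MLPA probe pair consists of a left (L) and a right (R) oligo that
hybridise seamlessly adjacent on genomic DNA and are joined by ligation.
Only the gene-specific binding halves are stored here; the universal
primer tails (23 nt on the L 5' end, 24 nt on the R 3' end) are constant
across the panel and enter only into the expected amplicon length.

Reads are 40 bp of the ligated binding region sequenced from the L side.
Each probe is identified in a read by three 10-mer "detective" sequences
taken from fixed windows of that 40 bp region; together the three 10-mers
are unique to one probe in a valid panel.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from statistics import pstdev
from typing import Iterable, Mapping, Sequence

__all__ = [
    "ProbeCategory",
    "ProbePair",
    "ProbePanel",
    "PanelError",
    "DETECTIVE_WINDOWS",
    "READ_LENGTH",
    "derive_detective_sequences",
    "load_panel",
    "validate_panel",
    "expected_amplicon_length",
]

#: Windows (0-based, half-open) of the 40 bp read-facing region from which
#: the three detective 10-mers are taken.  The last window typically spans
#: the L/R ligation junction, making detection ligation-dependent.
DETECTIVE_WINDOWS: tuple[tuple[int, int], ...] = ((0, 10), (15, 25), (30, 40))

#: Genomic bases sequenced per read (the sample index is sequenced separately).
READ_LENGTH = 40

# Universal primer tails added to every oligo at synthesis.
LEFT_UNIVERSAL_TAIL = "CCTACACGACGCTCTTCCGATCT"  # 23 nt, L oligo 5'
RIGHT_UNIVERSAL_TAIL = "AGCCCCAAGGGATTCCCAACCTGA"  # 24 nt, R oligo 3'

# Amplification primers overlap the universal tails; the net addition to the
# amplicon beyond the two full oligos is (70 - 23) + (87 - 24) = 110 nt.
UPSTREAM_PRIMER_LEN = 70
DOWNSTREAM_PRIMER_LEN = 87
PRIMER_EXTENSION = (UPSTREAM_PRIMER_LEN - len(LEFT_UNIVERSAL_TAIL)) + (
    DOWNSTREAM_PRIMER_LEN - len(RIGHT_UNIVERSAL_TAIL)
)

_DNA = frozenset("ACGT")


class PanelError(ValueError):
    """Raised when a probe table cannot be assembled into a valid panel."""


class ProbeCategory(str, Enum):
    DMD_EXON = "DMD_exon"
    SMN_SHARED = "SMN_shared"
    SMN1_SPECIFIC = "SMN1_specific"
    SMN2_SPECIFIC = "SMN2_specific"
    CHRX_SEX = "chrX_sex"
    CHRY_SEX = "chrY_sex"
    INTERNAL_REF = "internal_ref"
    EXTERNAL_REF = "external_ref"


def derive_detective_sequences(
    ligated_binding: str,
    windows: Sequence[tuple[int, int]] = DETECTIVE_WINDOWS,
) -> tuple[str, ...]:
    """Cut the detective 10-mers out of a ligated binding sequence.

    Parameters
    ----------
    ligated_binding
        The L binding sequence concatenated with the R binding sequence
        (universal tails excluded).  Must be at least 40 nt so all three
        windows fit inside the sequenced region.
    windows
        0-based half-open windows; the assay default tiles the read
        as (0,10), (15,25), (30,40).

    Returns
    -------
    tuple of str
        One subsequence per window, in window order.
    """
    seq = ligated_binding.upper()
    need = max(end for _, end in windows)
    if len(seq) < need:
        raise PanelError(
            f"ligated binding sequence is {len(seq)} nt; "
            f"detective windows need at least {need} nt"
        )
    return tuple(seq[start:end] for start, end in windows)


@dataclass(frozen=True)
class ProbePair:
    """One L/R probe pair and its read-identification sequences."""

    probe_id: str
    category: ProbeCategory
    left_binding: str
    right_binding: str
    locus_label: str = ""
    exon_index: int | None = None
    detective: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "left_binding", self.left_binding.upper())
        object.__setattr__(self, "right_binding", self.right_binding.upper())
        for name in ("left_binding", "right_binding"):
            seq = getattr(self, name)
            bad = set(seq) - _DNA
            if bad:
                raise PanelError(
                    f"probe {self.probe_id}: non-ACGT characters {sorted(bad)} in {name}"
                )
        if len(self.ligated_binding) < READ_LENGTH:
            raise PanelError(
                f"probe {self.probe_id}: combined binding sequence is "
                f"{len(self.ligated_binding)} nt, must be >= {READ_LENGTH}"
            )
        if not self.detective:
            object.__setattr__(
                self, "detective", derive_detective_sequences(self.ligated_binding)
            )
        else:
            object.__setattr__(
                self, "detective", tuple(d.upper() for d in self.detective)
            )
        # Declared detective sequences must sit at their window offsets.
        for (start, end), kmer in zip(DETECTIVE_WINDOWS, self.detective):
            if self.ligated_binding[start:end] != kmer:
                raise PanelError(
                    f"probe {self.probe_id}: detective sequence {kmer} does not "
                    f"match binding sequence window [{start},{end})"
                )

    @property
    def ligated_binding(self) -> str:
        return self.left_binding + self.right_binding

    @property
    def read_template(self) -> str:
        """The error-free 40 bp read this probe's amplicon produces."""
        return self.ligated_binding[:READ_LENGTH]

    @property
    def amplicon_length(self) -> int:
        """Full PCR product length including universal tails and primers."""
        left_oligo = len(self.left_binding) + len(LEFT_UNIVERSAL_TAIL)
        right_oligo = len(self.right_binding) + len(RIGHT_UNIVERSAL_TAIL)
        return left_oligo + right_oligo + PRIMER_EXTENSION


@dataclass
class ProbePanel:
    """An ordered collection of probe pairs with collision-checked detectives."""

    probes: list[ProbePair] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [p.probe_id for p in self.probes]
        dup = [i for i, c in Counter(ids).items() if c > 1]
        if dup:
            raise PanelError(f"duplicate probe_id(s): {dup}")
        collisions = self.detective_collisions()
        if collisions:
            a, b, kmer = collisions[0]
            raise PanelError(
                f"detective 10-mer collision: {kmer!r} shared by probes {a} and {b}"
                + (f" (and {len(collisions) - 1} more)" if len(collisions) > 1 else "")
            )

    def __len__(self) -> int:
        return len(self.probes)

    def __iter__(self):
        return iter(self.probes)

    def __getitem__(self, probe_id: str) -> ProbePair:
        for p in self.probes:
            if p.probe_id == probe_id:
                return p
        raise KeyError(probe_id)

    def detective_collisions(self) -> list[tuple[str, str, str]]:
        """All (probe_a, probe_b, kmer) pairs sharing a detective 10-mer."""
        seen: dict[str, str] = {}
        out: list[tuple[str, str, str]] = []
        for p in self.probes:
            for kmer in p.detective:
                if kmer in seen and seen[kmer] != p.probe_id:
                    out.append((seen[kmer], p.probe_id, kmer))
                else:
                    seen[kmer] = p.probe_id
        return out

    def category_counts(self) -> dict[str, int]:
        return dict(Counter(p.category.value for p in self.probes))

    def by_category(self, *categories: ProbeCategory) -> list[ProbePair]:
        want = set(categories)
        return [p for p in self.probes if p.category in want]

    @property
    def internal_ref_ids(self) -> list[str]:
        return [p.probe_id for p in self.by_category(ProbeCategory.INTERNAL_REF)]

    def detective_index(self) -> dict[tuple[str, ...], str]:
        """Map each probe's detective triple to its probe_id."""
        return {p.detective: p.probe_id for p in self.probes}


# ---------------------------------------------------------------------------
# Loading


_CATEGORY_PREFIXES = (
    ("SMN1_", ProbeCategory.SMN1_SPECIFIC),
    ("SMN2_", ProbeCategory.SMN2_SPECIFIC),
    ("SMN_", ProbeCategory.SMN_SHARED),
    ("DMD_", ProbeCategory.DMD_EXON),
    ("CHRX_", ProbeCategory.CHRX_SEX),
    ("CHRY_", ProbeCategory.CHRY_SEX),
    ("EXTREF", ProbeCategory.EXTERNAL_REF),
    ("EXT_", ProbeCategory.EXTERNAL_REF),
)


def category_from_name(probe_id: str) -> ProbeCategory:
    """Infer a probe's category from its naming convention.

    DMD_* / SMN_* / SMN1_* / SMN2_* / ChrX_* / ChrY_* / ExtRef* follow the
    kit's conventions; anything else is treated as an autosomal internal
    reference locus (e.g. ATP8A1_E10).
    """
    upper = probe_id.upper()
    for prefix, cat in _CATEGORY_PREFIXES:
        if upper.startswith(prefix):
            return cat
    return ProbeCategory.INTERNAL_REF


def _exon_from_name(probe_id: str, category: ProbeCategory) -> int | None:
    if category not in (
        ProbeCategory.DMD_EXON,
        ProbeCategory.SMN_SHARED,
        ProbeCategory.SMN1_SPECIFIC,
        ProbeCategory.SMN2_SPECIFIC,
    ):
        return None
    tail = probe_id.rsplit("_E", 1)
    if len(tail) == 2:
        digits = "".join(ch for ch in tail[1] if ch.isdigit())
        if digits:
            return int(digits)
    return None


def load_panel(table_path: str | Path, dialect: str = "tsv") -> ProbePanel:
    """Load and validate a probe panel.

    Two dialects are supported:

    ``tsv``
        Canonical format: tab-separated, header row, one row per probe pair
        with columns ``probe_id``, ``category``, ``left_binding``,
        ``right_binding`` and optional ``locus_label``, ``exon_index``,
        ``detective`` (three comma-separated 10-mers).  Missing category is
        inferred from the probe name; missing detectives are derived from
        the binding sequence.

    ``xlsx``
        The two-rows-per-pair oligo layout: columns for the oligo name and
        sequence, L and R rows alternating, probe names ending in ``-L`` /
        ``-R`` (or ``_L`` / ``_R``).  Universal tails, if present on the
        sequences, must already be stripped.
    """
    table_path = Path(table_path)
    if dialect == "tsv":
        rows = _read_tsv_rows(table_path)
    elif dialect == "xlsx":
        rows = _read_xlsx_rows(table_path)
    else:
        raise ValueError(f"unknown panel dialect: {dialect!r}")

    probes = []
    for row in rows:
        probe_id = row["probe_id"].strip()
        cat_raw = (row.get("category") or "").strip()
        category = ProbeCategory(cat_raw) if cat_raw else category_from_name(probe_id)
        exon_raw = (str(row.get("exon_index") or "")).strip()
        exon = int(exon_raw) if exon_raw else _exon_from_name(probe_id, category)
        det_raw = (row.get("detective") or "").strip()
        detective = tuple(d.strip().upper() for d in det_raw.split(",")) if det_raw else ()
        probes.append(
            ProbePair(
                probe_id=probe_id,
                category=category,
                left_binding=row["left_binding"].strip(),
                right_binding=row["right_binding"].strip(),
                locus_label=(row.get("locus_label") or probe_id).strip(),
                exon_index=exon,
                detective=detective,
            )
        )
    return ProbePanel(probes)


def _read_tsv_rows(path: Path) -> list[dict[str, str]]:
    import csv

    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise PanelError(f"{path}: empty panel table")
        required = {"probe_id", "left_binding", "right_binding"}
        missing = required - set(reader.fieldnames)
        if missing:
            raise PanelError(f"{path}: missing columns {sorted(missing)}")
        return list(reader)


def _read_xlsx_rows(path: Path) -> list[dict[str, str]]:
    import pandas as pd

    df = pd.read_excel(path, dtype=str)
    cols = {c.strip().lower(): c for c in df.columns}
    name_col = next((cols[k] for k in ("name", "probe", "oligo", "probe name") if k in cols), None)
    seq_col = next((cols[k] for k in ("sequence", "seq", "binding sequence") if k in cols), None)
    if name_col is None or seq_col is None:
        raise PanelError(f"{path}: expected name and sequence columns")

    halves: dict[str, dict[str, str]] = {}
    order: list[str] = []
    for _, rec in df.iterrows():
        name = str(rec[name_col]).strip()
        seq = str(rec[seq_col]).strip().upper()
        if not name or name.lower() == "nan":
            continue
        side = name[-1].upper()
        if side not in "LR" or name[-2] not in "-_":
            raise PanelError(f"{path}: oligo name {name!r} does not end in -L/-R")
        pair_id = name[:-2]
        slot = halves.setdefault(pair_id, {})
        if pair_id not in order:
            order.append(pair_id)
        slot[side] = seq

    rows = []
    for pair_id in order:
        slot = halves[pair_id]
        if set(slot) != {"L", "R"}:
            raise PanelError(f"{path}: probe {pair_id} lacks an L or R oligo row")
        rows.append(
            {"probe_id": pair_id, "left_binding": slot["L"], "right_binding": slot["R"]}
        )
    return rows


# ---------------------------------------------------------------------------
# Validation & summary statistics


def validate_panel(panel: ProbePanel) -> dict:
    """Report-only panel health check.

    Returns a dict with the category census, detective collisions (none for
    a constructed ProbePanel, which rejects them), probes whose final
    detective window does not cross the L/R ligation junction (a warning:
    for such probes read assignment is not strictly ligation-dependent),
    and the count of internal reference probes.
    """
    junction_warnings = []
    for p in panel:
        start, end = DETECTIVE_WINDOWS[-1]
        junction = len(p.left_binding)
        if not (start < junction < end):
            junction_warnings.append(p.probe_id)
    report = {
        "n_probes": len(panel),
        "category_counts": panel.category_counts(),
        "collisions": [list(c) for c in panel.detective_collisions()],
        "junction_not_spanned": junction_warnings,
        "n_internal_ref": len(panel.internal_ref_ids),
        "ok": not panel.detective_collisions()
        and len(panel.internal_ref_ids) >= 1,
    }
    return report


def validation_report_text(report: Mapping) -> str:
    lines = [f"probes: {report['n_probes']}"]
    for cat, n in sorted(report["category_counts"].items()):
        lines.append(f"  {cat}: {n}")
    lines.append(f"collisions: {len(report['collisions'])}")
    for a, b, k in report["collisions"]:
        lines.append(f"  {a} / {b}: {k}")
    if report["junction_not_spanned"]:
        lines.append(
            "warning, third window inside one oligo (not ligation-dependent): "
            + ", ".join(report["junction_not_spanned"])
        )
    lines.append("status: " + ("ok" if report["ok"] else "INVALID"))
    return "\n".join(lines)


def write_validation_report(report: Mapping, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2) + "\n")


def expected_amplicon_length(panel: ProbePanel | Iterable[ProbePair]) -> tuple[float, float]:
    """Mean and (population) standard deviation of amplicon lengths, in bp.

    Per probe: full L oligo + full R oligo + 110 nt contributed by the
    amplification primers beyond their tail overlap.
    """
    lengths = [p.amplicon_length for p in panel]
    if not lengths:
        raise PanelError("empty panel")
    mean = sum(lengths) / len(lengths)
    return mean, pstdev(lengths)
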