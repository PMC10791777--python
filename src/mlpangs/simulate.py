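"""Synthetic MLPA-NGS data: panels, genotypes and barcoded FASTQ reads.

The generator emulates the assay's read structure — 40 bp of the ligated
probe binding region plus an 8 bp sample index carried in the header — and
its count statistics:

* each probe has a fixed lognormal amplification efficiency shared by every
  sample run against the same panel (probe-specific PCR/hybridisation bias);
* conditional on efficiency, the read count of a probe is negative binomial
  with mean proportional to the template copy number at its locus;
* reads carry i.i.d. substitution errors; a configurable fraction of reads
  is unassignable junk (uniform random 40-mers);
* external-reference probes amplify at a small constant level independent
  of genomic template.

A normal diploid locus averages ``mean_reads_per_probe`` reads, so a single
X-linked copy in a male averages half that.  Loci at zero copies emit no
reads of their own; any residual signal downstream arises solely from
sequencing errors converting another probe's read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .panel import (
    READ_LENGTH,
    PanelError,
    ProbeCategory,
    ProbePair,
    ProbePanel,
)

__all__ = [
    "GenotypeSpec",
    "SimConfig",
    "simulate_panel",
    "simulate_sample",
    "simulate_run",
    "preset_genotypes",
    "DMD_EXONS",
    "SMN_EXONS",
]

DMD_EXONS = range(1, 80)  # 79 exons; exon 1 carries two probes
SMN_EXONS = range(1, 9)

_BASES = np.frombuffer(b"ACGT", dtype="S1")

#: Copy number of a normal diploid template, the depth-normalisation anchor:
#: a locus at 2 copies yields ``mean_reads_per_probe`` expected reads.
DIPLOID_COPIES = 2

# Internal-reference and sex-probe names as used by the DMD-SMA kit.
INTERNAL_REF_NAMES = [
    "ATP8A1_E10", "IL13_IL4", "PKHD1_E61", "EYS_E23", "CCM2_E2",
    "EYA1_E15", "GLDC_E20", "ATP7B_E14", "BRIP1_E17", "TCF4_I13",
]
CHRX_NAMES = ["ChrX_AMOT_E2", "ChrX_NR0B1_CXorf21", "ChrX_PHEX_E9"]
CHRY_NAMES = ["ChrY_SRY_E1", "ChrY_UTY_TMSB4Y", "ChrY_UTY_E17"]

_BARCODE_ALPHABET = "ACGT"


@dataclass(frozen=True)
class GenotypeSpec:
    """Ground-truth copy numbers for one simulated individual."""

    sample_id: str
    sex: str  # "male" | "female"
    dmd_copies: dict[int, int] = field(default_factory=dict)
    smn1_copies: dict[int, int] = field(default_factory=dict)
    smn2_copies: dict[int, int] = field(default_factory=dict)
    index_barcode: str = "AAAAAAAA"

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be male or female, got {self.sex!r}")
        if len(self.index_barcode) != 8 or set(self.index_barcode) - set("ACGT"):
            raise ValueError("index_barcode must be an 8-mer over ACGT")

    def dmd_copy(self, exon: int) -> int:
        default = 1 if self.sex == "male" else 2
        return self.dmd_copies.get(exon, default)

    def smn1_copy(self, exon: int) -> int:
        return self.smn1_copies.get(exon, 2)

    def smn2_copy(self, exon: int) -> int:
        return self.smn2_copies.get(exon, 2)

    def copies_for(self, probe: ProbePair) -> int:
        """Template copy number seen by one probe."""
        cat = probe.category
        if cat is ProbeCategory.DMD_EXON:
            if probe.exon_index is None:
                raise ValueError(f"DMD probe {probe.probe_id} lacks an exon index")
            return self.dmd_copy(probe.exon_index)
        if cat is ProbeCategory.SMN_SHARED:
            exon = probe.exon_index or 1
            return self.smn1_copy(exon) + self.smn2_copy(exon)
        if cat is ProbeCategory.SMN1_SPECIFIC:
            return self.smn1_copy(probe.exon_index or 7)
        if cat is ProbeCategory.SMN2_SPECIFIC:
            return self.smn2_copy(probe.exon_index or 7)
        if cat is ProbeCategory.CHRX_SEX:
            return 1 if self.sex == "male" else 2
        if cat is ProbeCategory.CHRY_SEX:
            return 1 if self.sex == "male" else 0
        if cat is ProbeCategory.INTERNAL_REF:
            return 2
        return 0  # external_ref: no genomic template


@dataclass(frozen=True)
class SimConfig:
    """Noise and depth parameters of the simulated sequencing run.

    mean_reads_per_probe
        Expected reads for a probe at normal diploid dosage.  ~600 suffices
        for reliable copy-number calls; real runs average far deeper.
    efficiency_cv
        Coefficient of variation of the fixed per-probe lognormal
        amplification efficiency.  0.30 reproduces the within-sample
        dispersion observed across internal-reference probes (~0.26-0.36).
    count_dispersion
        Negative-binomial size parameter for per-draw count noise on top of
        the fixed efficiencies (variance = m + m^2/size).  Large values
        approach Poisson; the default 1000 adds mild extra-Poisson spread
        from pipetting/cluster variation.
    per_base_error
        Per-base substitution probability in emitted reads.
    junk_read_fraction
        Expected fraction of all reads that are unassignable junk
        (primer artefacts, low-quality clusters), modelled as uniform
        random 40-mers.
    external_ref_reads
        Expected reads per external-reference probe, template-independent.
    seed
        Base seed for count draws, errors and junk.
    efficiency_seed
        Seed for the per-probe efficiencies.  Held fixed across samples of
        a run so sample and control share the same probe bias, as in the
        physical assay where bias is a property of the probe, not the sample.
    """

    mean_reads_per_probe: float = 600.0
    efficiency_cv: float = 0.30
    count_dispersion: float = 1000.0
    per_base_error: float = 0.001
    junk_read_fraction: float = 0.15
    external_ref_reads: float = 100.0
    seed: int = 0
    efficiency_seed: int = 2024

    def __post_init__(self) -> None:
        if self.mean_reads_per_probe <= 0:
            raise ValueError("mean_reads_per_probe must be > 0")
        for name in ("junk_read_fraction", "per_base_error"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.efficiency_cv < 0 or self.count_dispersion <= 0:
            raise ValueError("efficiency_cv >= 0 and count_dispersion > 0 required")


# ---------------------------------------------------------------------------
# Panel simulation


def _random_binding(rng: np.random.Generator, length: int) -> str:
    """Random sequence of given length with GC content in [0.4, 0.6]."""
    while True:
        seq = rng.choice(_BASES, size=length).tobytes().decode()
        gc = (seq.count("G") + seq.count("C")) / length
        if 0.40 <= gc <= 0.60:
            return seq


def simulate_panel(
    n_dmd: int = 80,
    n_internal_ref: int = 10,
    seed: int = 0,
    max_retries: int = 200,
) -> ProbePanel:
    """Generate a synthetic collision-free probe panel.

    ``n_dmd`` DMD probes cover exons 1..n_dmd-1 with exon 1 probed twice
    (mirroring the kit's 80 probes on 79 exons), plus 8 SMN shared probes,
    4 SMN1/SMN2-discriminating probes (exons 7 and 8), 3 chrX and 3 chrY
    sex probes, ``n_internal_ref`` autosomal internal references and one
    external reference.  Binding sequences are random 50-70-mers with
    40-60% GC, resampled until no detective 10-mer recurs anywhere in the
    panel.
    """
    if n_dmd < 1:
        raise ValueError("n_dmd must be >= 1")
    if n_internal_ref < 1:
        raise PanelError("panel requires at least one internal reference probe")

    rng = np.random.default_rng(seed)
    used_kmers: set[str] = set()
    probes: list[ProbePair] = []

    def add(probe_id: str, category: ProbeCategory, exon: int | None = None) -> None:
        for _ in range(max_retries):
            total = int(rng.integers(50, 71))
            # the L/R junction falls inside the third detective window so
            # that read attribution requires successful ligation
            left_len = int(rng.integers(31, 40))
            lig = _random_binding(rng, total)
            kmers = (lig[0:10], lig[15:25], lig[30:40])
            if len(set(kmers)) == 3 and not used_kmers.intersection(kmers):
                used_kmers.update(kmers)
                probes.append(
                    ProbePair(
                        probe_id=probe_id,
                        category=category,
                        left_binding=lig[:left_len],
                        right_binding=lig[left_len:],
                        locus_label=probe_id,
                        exon_index=exon,
                    )
                )
                return
        raise PanelError(f"could not draw a collision-free sequence for {probe_id}")

    # DMD: exon 1 twice, then consecutive exons.
    dmd_exons = [1, 1] + list(range(2, n_dmd)) if n_dmd >= 2 else [1]
    seen_e1 = 0
    for exon in dmd_exons:
        if exon == 1:
            seen_e1 += 1
            pid = "DMD_E01" if seen_e1 == 1 else "DMD_E01b"
        else:
            pid = f"DMD_E{exon:02d}"
        add(pid, ProbeCategory.DMD_EXON, exon)

    for exon in SMN_EXONS:
        add(f"SMN_E{exon}", ProbeCategory.SMN_SHARED, exon)
    for exon in (7, 8):
        add(f"SMN1_E{exon}", ProbeCategory.SMN1_SPECIFIC, exon)
        add(f"SMN2_E{exon}", ProbeCategory.SMN2_SPECIFIC, exon)
    for name in CHRX_NAMES:
        add(name, ProbeCategory.CHRX_SEX)
    for name in CHRY_NAMES:
        add(name, ProbeCategory.CHRY_SEX)
    for i in range(n_internal_ref):
        name = (
            INTERNAL_REF_NAMES[i]
            if i < len(INTERNAL_REF_NAMES)
            else f"REF_{i + 1:02d}"
        )
        add(name, ProbeCategory.INTERNAL_REF)
    add("ExtRef_1", ProbeCategory.EXTERNAL_REF)

    return ProbePanel(probes)


# ---------------------------------------------------------------------------
# Read simulation


def probe_efficiencies(panel: ProbePanel, config: SimConfig) -> np.ndarray:
    """Fixed lognormal amplification efficiency per probe (mean 1)."""
    rng = np.random.default_rng(config.efficiency_seed)
    cv = config.efficiency_cv
    if cv == 0:
        return np.ones(len(panel))
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-sigma * sigma / 2, sigma=sigma, size=len(panel))


def _nbinom_draw(rng: np.random.Generator, mean: float, size_param: float) -> int:
    if mean <= 0:
        return 0
    p = size_param / (size_param + mean)
    return int(rng.negative_binomial(size_param, p))


def _emit_probe_reads(
    rng: np.random.Generator, template: str, n: int, per_base_error: float
) -> list[str]:
    """n copies of the template with i.i.d. substitution errors.

    The total number of errors is binomial over all n*len positions and
    error positions are drawn uniformly, which is equivalent to flipping
    each base independently with probability per_base_error.
    """
    reads = [template] * n
    if per_base_error <= 0 or n == 0:
        return reads
    length = len(template)
    k = rng.binomial(n * length, per_base_error)
    if k == 0:
        return reads
    positions = rng.choice(n * length, size=k, replace=False)
    for pos in positions:
        i, j = divmod(int(pos), length)
        read = reads[i]
        base = read[j]
        choices = [b for b in "ACGT" if b != base]
        reads[i] = read[:j] + choices[rng.integers(3)] + read[j + 1 :]
    return reads


def _emit_junk_reads(rng: np.random.Generator, n: int) -> list[str]:
    if n == 0:
        return []
    arr = _BASES[rng.integers(0, 4, size=(n, READ_LENGTH))]
    return [row.tobytes().decode() for row in arr]


def simulate_sample(
    panel: ProbePanel,
    genotype: GenotypeSpec,
    config: SimConfig,
    seed: int | None = None,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Simulate one sample's reads.

    Returns
    -------
    reads
        List of ``(header, sequence)`` pairs.  Headers follow the Illumina
        convention with the sample index in the comment field
        (``... 1:N:0:BARCODE``); sequences are 40 nt.
    manifest
        Truth manifest with columns sample_id, probe_id, true_copies,
        emitted_reads (exact counts drawn, before sequencing error).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    eff = probe_efficiencies(panel, config)

    counts: list[int] = []
    copies: list[int] = []
    per_copy = config.mean_reads_per_probe / DIPLOID_COPIES
    for probe, e in zip(panel, eff):
        c = genotype.copies_for(probe)
        if probe.category is ProbeCategory.EXTERNAL_REF:
            mean = config.external_ref_reads * e
        else:
            mean = per_copy * e * c
        counts.append(_nbinom_draw(rng, mean, config.count_dispersion))
        copies.append(c)

    n_real = int(sum(counts))
    f = config.junk_read_fraction
    n_junk = int(rng.poisson(n_real * f / (1.0 - f))) if f > 0 and n_real else 0

    sequences: list[str] = []
    for probe, n in zip(panel, counts):
        sequences.extend(
            _emit_probe_reads(rng, probe.read_template, n, config.per_base_error)
        )
    sequences.extend(_emit_junk_reads(rng, n_junk))

    order = rng.permutation(len(sequences))
    reads = [
        (_header(genotype, serial), sequences[i])
        for serial, i in enumerate(order, start=1)
    ]

    manifest = pd.DataFrame(
        {
            "sample_id": genotype.sample_id,
            "probe_id": [p.probe_id for p in panel],
            "true_copies": copies,
            "emitted_reads": counts,
        }
    )
    return reads, manifest


def _header(genotype: GenotypeSpec, serial: int) -> str:
    return f"SIM:{genotype.sample_id}:{serial} 1:N:0:{genotype.index_barcode}"


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path) -> int:
    """Write 4-line FASTQ records with a constant Q30 quality placeholder."""
    n = 0
    with open(path, "w") as fh:
        for header, seq in reads:
            fh.write(f"@{header}\n{seq}\n+\n{'?' * len(seq)}\n")
            n += 1
    return n


def write_index_fastq(reads: Iterable[tuple[str, str]], path: str | Path) -> int:
    """Write the 8 bp index reads (I1) for reads produced by simulate_sample."""
    n = 0
    with open(path, "w") as fh:
        for header, _ in reads:
            barcode = header.rsplit(":", 1)[1]
            fh.write(f"@{header}\n{barcode}\n+\n{'?' * len(barcode)}\n")
            n += 1
    return n


def simulate_run(
    panel: ProbePanel,
    genotypes: Sequence[GenotypeSpec],
    config: SimConfig,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Simulate a multiplexed run: several barcoded samples in one read pool.

    Per-sample seeds are spawned deterministically from ``config.seed``.
    """
    seeds = np.random.SeedSequence(config.seed).spawn(len(genotypes))
    all_reads: list[tuple[str, str]] = []
    manifests = []
    for genotype, ss in zip(genotypes, seeds):
        sub_seed = int(ss.generate_state(1)[0] % (2**31))
        reads, manifest = simulate_sample(panel, genotype, config, seed=sub_seed)
        all_reads.extend(reads)
        manifests.append(manifest)
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(all_reads))
    all_reads = [all_reads[i] for i in order]
    return all_reads, pd.concat(manifests, ignore_index=True)


# ---------------------------------------------------------------------------
# Preset genotypes mirroring the validated clinical cases


def _barcodes(n: int) -> list[str]:
    rng = np.random.default_rng(7)
    out: set[str] = set()
    while len(out) < n:
        out.add(rng.choice(_BASES, size=8).tobytes().decode())
    return sorted(out)


def preset_genotypes() -> dict[str, GenotypeSpec]:
    """Named ground-truth genotypes covering the kit's reference scenarios.

    * ``normal_male`` / ``normal_female`` — no aberration.
    * ``dmd_del_30_44_male`` — hemizygous deletion of DMD exons 30-44.
    * ``dmd_dup3x_3_7_female`` — threefold duplication of DMD exons 3-7.
    * ``dmd_carrier_female`` — heterozygous deletion of DMD exons 45-50.
    * ``sma_homozygous_female`` — SMN1 absent, two SMN2 copies.
    * ``sma_het_conversion_female`` — one SMN1, three SMN2 (gene-conversion
      pattern: total SMN dosage preserved at four copies).
    """
    bc = _barcodes(8)
    specs = [
        GenotypeSpec("normal_male", "male", index_barcode=bc[0]),
        GenotypeSpec("normal_female", "female", index_barcode=bc[1]),
        GenotypeSpec(
            "dmd_del_30_44_male",
            "male",
            dmd_copies={e: 0 for e in range(30, 45)},
            index_barcode=bc[2],
        ),
        GenotypeSpec(
            "dmd_dup3x_3_7_female",
            "female",
            dmd_copies={e: 3 for e in range(3, 8)},
            index_barcode=bc[3],
        ),
        GenotypeSpec(
            "dmd_carrier_female",
            "female",
            dmd_copies={e: 1 for e in range(45, 51)},
            index_barcode=bc[4],
        ),
        GenotypeSpec(
            "sma_homozygous_female",
            "female",
            smn1_copies={e: 0 for e in SMN_EXONS},
            smn2_copies={e: 2 for e in SMN_EXONS},
            index_barcode=bc[5],
        ),
        GenotypeSpec(
            "sma_het_conversion_female",
            "female",
            smn1_copies={e: 1 for e in SMN_EXONS},
            smn2_copies={e: 3 for e in SMN_EXONS},
            index_barcode=bc[6],
        ),
    ]
    return {s.sample_id: s for s in specs}


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    manifest.to_csv(path, sep="\t", index=False)
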