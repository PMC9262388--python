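"""Design of strain-unique molecular inversion probe (MIP) panels.

A MIP is an 80-nt single-stranded oligo whose two 20-nt arms hybridize to
reference sequence flanking a 100-nt capture window ("scan" sequence). After
gap fill and ligation the circularized probe is amplified and sequenced; a
10-nt unique molecular identifier (UMI) sits between the backbone and the
ligation arm. Each probe targets a biallelic SNV that is homozygous-alternative
in exactly one strain of the pool, so the alternative-read fraction at the
probe measures that strain's relative frequency.

Coordinate conventions: VCF positions are 1-based; all internal interval
arithmetic is 0-based half-open. ``snv_offset`` is the 1-based distance of the
SNV base from the end of the UMI in the sequencing read (the ligation arm
occupies offsets 1..20, the scan sequence follows), so a 50-nt read with a
10-nt UMI can carry offsets up to 40.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from cyvcf2 import VCF
from pyfaidx import Fasta

from .errors import FormatError, MissingStrainError, ProbeRejection

NUCLEOTIDES = frozenset("ACGT")

ARM_LENGTH = 20
UMI_LENGTH = 10
CAPTURE_SIZE = 100
OLIGO_LENGTH = 80

#: Default 30-nt linker joining the arms; carries the two amplification
#: landing sites. 80 = 2 x 20 (arms) + 10 (UMI) + 30 (backbone).
DEFAULT_BACKBONE = "CTTCAGCTTCCCGATATCCGACGGTAGTGT"


@dataclass(frozen=True)
class UniqueSnv:
    """A biallelic SNV homozygous-alternative in exactly one pool strain."""

    strain_id: str
    chrom: str
    pos: int  # 1-based, as in VCF
    ref_allele: str
    alt_allele: str

    def __post_init__(self):
        if self.ref_allele not in NUCLEOTIDES or self.alt_allele not in NUCLEOTIDES:
            raise ValueError(f"alleles must be single A/C/G/T bases, got "
                             f"{self.ref_allele!r}/{self.alt_allele!r}")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")


@dataclass(frozen=True)
class MipProbe:
    """One designed probe with its assembled 80-nt oligo.

    ``scan_seq`` is the reference-strand captured gap sequence;
    ``snv_offset`` the 1-based distance of the SNV from the UMI end in the
    sequencing read, so the SNV sits at ``scan_seq[snv_offset - ARM_LENGTH - 1]``.
    """

    probe_id: str
    target: UniqueSnv
    extension_arm: str
    ligation_arm: str
    scan_seq: str
    snv_offset: int
    umi_length: int = UMI_LENGTH
    capture_size: int = CAPTURE_SIZE
    backbone: str = DEFAULT_BACKBONE

    def __post_init__(self):
        if len(self.extension_arm) != ARM_LENGTH or len(self.ligation_arm) != ARM_LENGTH:
            raise ValueError("arms must be exactly 20 nt")
        if self.umi_length != UMI_LENGTH:
            raise ValueError("umi_length must be 10")
        if len(self.scan_seq) != self.capture_size:
            raise ValueError("scan_seq length must equal capture_size")
        if not (ARM_LENGTH < self.snv_offset <= 40):
            raise ValueError(f"snv_offset must lie in (20, 40], got {self.snv_offset}")
        scan_idx = self.snv_offset - ARM_LENGTH - 1
        if self.scan_seq[scan_idx] != self.target.ref_allele:
            raise ValueError("scan_seq does not carry the reference allele at the "
                             "position implied by snv_offset")
        if len(self.oligo_seq) != OLIGO_LENGTH:
            raise ValueError("assembled oligo must be 80 nt; check backbone length")

    @property
    def oligo_seq(self) -> str:
        """5'→3' assembled oligo: extension arm + backbone + UMI (N10) + ligation arm."""
        return self.extension_arm + self.backbone + "N" * self.umi_length + self.ligation_arm

    @property
    def scan_snv_index(self) -> int:
        """0-based index of the SNV within ``scan_seq``."""
        return self.snv_offset - ARM_LENGTH - 1


@dataclass
class PanelSpec:
    """A designed probe panel with per-strain shortfall bookkeeping."""

    probes_per_strain: int
    strains: list[str]
    probes: list[MipProbe]
    shortfall: dict[str, int] = field(default_factory=dict)  # strain -> probes obtained
    rejections: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self):
        ids = [p.probe_id for p in self.probes]
        if len(ids) != len(set(ids)):
            raise ValueError("probe_ids must be unique")
        per_strain = pd.Series([p.target.strain_id for p in self.probes]).value_counts()
        if (per_strain > self.probes_per_strain).any():
            raise ValueError("more probes than probes_per_strain for some strain")

    def probes_for(self, strain_id: str) -> list[MipProbe]:
        return [p for p in self.probes if p.target.strain_id == strain_id]


def find_unique_snvs(vcf_path, panel_strains: Sequence[str]) -> list[UniqueSnv]:
    """Parse strain-unique homozygous SNVs from a multi-sample VCF.

    A site qualifies when it is a biallelic SNV at which exactly one panel
    strain is homozygous-alternative and every other panel strain is
    homozygous-reference. Sites with any missing or heterozygous genotype
    among the panel strains are excluded, which keeps the downstream
    alternative-read-fraction interpretation exact.

    Returns records grouped by strain (panel order), sorted by coordinate
    within each strain.
    """
    try:
        vcf = VCF(str(vcf_path), gts012=True)
    except OSError as exc:
        raise FormatError(f"cannot read VCF {vcf_path}: {exc}") from exc
    samples = list(vcf.samples)
    absent = [s for s in panel_strains if s not in samples]
    if absent:
        raise MissingStrainError(absent)
    col_idx = [samples.index(s) for s in panel_strains]

    by_strain: dict[str, list[UniqueSnv]] = {s: [] for s in panel_strains}
    for var in vcf:
        if len(var.ALT) != 1:
            continue  # multi-allelic sites skipped
        ref, alt = var.REF, var.ALT[0]
        if len(ref) != 1 or len(alt) != 1 or ref not in NUCLEOTIDES or alt not in NUCLEOTIDES:
            continue
        gts = var.gt_types  # gts012: 0=hom-ref, 1=het, 2=hom-alt, 3=missing
        panel_gts = [gts[i] for i in col_idx]
        if any(g == 1 or g == 3 for g in panel_gts):
            continue
        carriers = [i for i, g in enumerate(panel_gts) if g == 2]
        if len(carriers) != 1:
            continue
        strain = panel_strains[carriers[0]]
        by_strain[strain].append(UniqueSnv(strain, var.CHROM, var.POS, ref, alt))

    out: list[UniqueSnv] = []
    for strain in panel_strains:
        out.extend(sorted(by_strain[strain], key=lambda s: (s.chrom, s.pos)))
    return out


def _contig_sequence(genome, chrom: str) -> str:
    if isinstance(genome, (str, Path)):
        genome = Fasta(str(genome))
    if isinstance(genome, Mapping):
        seq = genome.get(chrom)
        if seq is None:
            raise ProbeRejection("missing-contig", chrom)
        return str(seq).upper()
    if chrom not in genome:
        raise ProbeRejection("missing-contig", chrom)
    return str(genome[chrom][:]).upper()


def design_probe(genome, snv: UniqueSnv, read_length: int = 50, *,
                 capture_size: int = CAPTURE_SIZE,
                 backbone: str = DEFAULT_BACKBONE) -> MipProbe:
    """Place a 100-nt capture window over ``snv`` and assemble the probe.

    The window is slid left to right over every placement that keeps the SNV
    within the first ``read_length - umi_length - 20`` scan bases (so the SNV
    is no more than ``read_length - umi_length`` = 40 nt from the UMI in the
    read); the first placement whose arms fit on the contig and contain no
    ambiguous bases wins. Raises :class:`ProbeRejection` with a reason when no
    placement qualifies.

    ``genome`` may be a FASTA path, a ``pyfaidx.Fasta``, or a plain
    ``{chrom: sequence}`` mapping (useful in tests and simulations).
    """
    seq = _contig_sequence(genome, snv.chrom)
    pos0 = snv.pos - 1
    if pos0 >= len(seq):
        raise ProbeRejection("position-beyond-contig",
                             f"{snv.chrom}:{snv.pos} > contig length {len(seq)}")
    if seq[pos0] != snv.ref_allele:
        raise ProbeRejection("reference-mismatch",
                             f"genome has {seq[pos0]} at {snv.chrom}:{snv.pos}, "
                             f"VCF ref is {snv.ref_allele}")
    max_scan_idx = read_length - UMI_LENGTH - ARM_LENGTH - 1
    if max_scan_idx < 0:
        raise ProbeRejection("read-too-short",
                             f"read_length {read_length} cannot reach past the arm")
    max_scan_idx = min(max_scan_idx, capture_size - 1)

    reasons = set()
    for window_start in range(pos0 - max_scan_idx, pos0 + 1):
        scan_idx = pos0 - window_start
        if window_start < ARM_LENGTH or window_start + capture_size + ARM_LENGTH > len(seq):
            reasons.add("contig-end")
            continue
        ligation_arm = seq[window_start - ARM_LENGTH:window_start]
        extension_arm = seq[window_start + capture_size:window_start + capture_size + ARM_LENGTH]
        if "N" in ligation_arm or "N" in extension_arm:
            reasons.add("ambiguous-arm")
            continue
        scan = seq[window_start:window_start + capture_size]
        return MipProbe(
            probe_id=f"{snv.strain_id}_{snv.chrom}_{snv.pos}",
            target=snv,
            extension_arm=extension_arm,
            ligation_arm=ligation_arm,
            scan_seq=scan,
            snv_offset=ARM_LENGTH + scan_idx + 1,
            capture_size=capture_size,
            backbone=backbone,
        )
    raise ProbeRejection("no-valid-placement",
                         f"{snv.chrom}:{snv.pos} ({', '.join(sorted(reasons)) or 'offset constraint'})")


def _gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


def _arm_gc_rank(probe: MipProbe) -> float:
    gc = _gc_fraction(probe.extension_arm + probe.ligation_arm)
    return abs(gc - 0.5)


def build_panel(snvs: Sequence[UniqueSnv], genome, probes_per_strain: int = 4,
                read_length: int = 50, backbone: str = DEFAULT_BACKBONE) -> PanelSpec:
    """Select up to ``probes_per_strain`` accepted designs per strain.

    Candidates are designed deterministically, ranked by arm GC content
    closest to 50% (ties broken by genomic coordinate), and chosen in rank
    order while keeping ligation-arm assignment keys unique panel-wide.
    Strains falling short of the request are recorded in ``shortfall``;
    a strain with zero acceptable designs is not fatal.
    """
    by_strain: dict[str, list[UniqueSnv]] = {}
    for snv in snvs:
        by_strain.setdefault(snv.strain_id, []).append(snv)

    probes: list[MipProbe] = []
    shortfall: dict[str, int] = {}
    rejections: dict[str, list[str]] = {}
    used_keys: set[str] = set()
    for strain, cands in by_strain.items():
        designed = []
        for snv in sorted(cands, key=lambda s: (s.chrom, s.pos)):
            try:
                designed.append(design_probe(genome, snv, read_length, backbone=backbone))
            except ProbeRejection as rej:
                rejections.setdefault(strain, []).append(str(rej))
        designed.sort(key=lambda p: (_arm_gc_rank(p), p.target.chrom, p.target.pos))
        chosen = []
        for probe in designed:
            if probe.ligation_arm in used_keys:
                rejections.setdefault(strain, []).append(
                    f"duplicate-assignment-key: {probe.probe_id}")
                continue
            chosen.append(probe)
            used_keys.add(probe.ligation_arm)
            if len(chosen) == probes_per_strain:
                break
        probes.extend(sorted(chosen, key=lambda p: (p.target.chrom, p.target.pos)))
        if len(chosen) < probes_per_strain:
            shortfall[strain] = len(chosen)
            warnings.warn(f"strain {strain}: only {len(chosen)} of "
                          f"{probes_per_strain} requested probes designed")
    return PanelSpec(probes_per_strain=probes_per_strain,
                     strains=list(by_strain), probes=probes,
                     shortfall=shortfall, rejections=rejections)


def hybridization_input(panel_size: int, per_probe_amount: float = 0.0083) -> float:
    """Picomoles of pooled phosphorylated probe needed for one capture reaction.

    With the protocol's 0.0083 pmol per probe, a 412-probe panel takes
    3.42 pmol.
    """
    if panel_size < 1:
        raise ValueError("panel_size must be >= 1")
    if per_probe_amount <= 0:
        raise ValueError("per_probe_amount must be positive")
    return panel_size * per_probe_amount


# ---------------------------------------------------------------------------
# panel I/O

PANEL_COLUMNS = ["probe_id", "strain", "chrom", "pos", "ref", "alt",
                 "extension_arm", "ligation_arm", "scan_seq", "snv_offset",
                 "oligo_seq"]


def panel_to_frame(panel: PanelSpec) -> pd.DataFrame:
    rows = [{
        "probe_id": p.probe_id, "strain": p.target.strain_id,
        "chrom": p.target.chrom, "pos": p.target.pos,
        "ref": p.target.ref_allele, "alt": p.target.alt_allele,
        "extension_arm": p.extension_arm, "ligation_arm": p.ligation_arm,
        "scan_seq": p.scan_seq, "snv_offset": p.snv_offset,
        "oligo_seq": p.oligo_seq,
    } for p in panel.probes]
    return pd.DataFrame(rows, columns=PANEL_COLUMNS)


def write_panel_tsv(panel: PanelSpec, path) -> None:
    panel_to_frame(panel).to_csv(path, sep="\t", index=False)


def read_panel_tsv(path) -> PanelSpec:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    except Exception as exc:
        raise FormatError(f"cannot read panel TSV {path}: {exc}") from exc
    missing = set(PANEL_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"panel TSV {path} lacks columns: {sorted(missing)}")
    probes = []
    for row in df.itertuples(index=False):
        snv = UniqueSnv(row.strain, row.chrom, int(row.pos), row.ref, row.alt)
        backbone = row.oligo_seq[ARM_LENGTH:ARM_LENGTH + OLIGO_LENGTH - 2 * ARM_LENGTH - UMI_LENGTH]
        probes.append(MipProbe(
            probe_id=row.probe_id, target=snv,
            extension_arm=row.extension_arm, ligation_arm=row.ligation_arm,
            scan_seq=row.scan_seq, snv_offset=int(row.snv_offset),
            capture_size=len(row.scan_seq), backbone=backbone))
    strains = list(dict.fromkeys(df["strain"]))
    per_strain = df["strain"].value_counts().max() if len(df) else 0
    return PanelSpec(probes_per_strain=int(per_strain) or 1, strains=strains, probes=probes)


def write_probe_fasta(panel: PanelSpec, path) -> None:
    with open(path, "w") as fh:
        for p in panel.probes:
            fh.write(f">{p.probe_id}\n{p.oligo_seq}\n")
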