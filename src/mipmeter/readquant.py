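"""Read-to-probe assignment and SNV allele counting from single-end FASTQ.

Reads are laid out as ``UMI (10 nt) + ligation arm (20 nt) + captured scan
sequence``. A read is assigned to a probe by exact match of the probe's
20-nt ligation arm ("assignment key") at the post-UMI position; the allele is
the single base at ``umi_length + snv_offset`` (1-based offset from the UMI
end). Besides REF and ALT, the two remaining nucleotides map in lexicographic
order to OTHER_A / OTHER_B — their counts report substitution error and
off-target capture. UMI deduplication collapses reads sharing
(probe, UMI, allele class); it is off by default since it did not improve the
published analysis.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .errors import FormatError
from .panel import ARM_LENGTH, UMI_LENGTH, PanelSpec


class AlleleClass(str, Enum):
    REF = "REF"
    ALT = "ALT"
    OTHER_A = "OTHER_A"
    OTHER_B = "OTHER_B"


@dataclass(frozen=True)
class ReadLayout:
    """Geometry of the single-end sequencing read."""

    umi_length: int = UMI_LENGTH
    arm_length: int = ARM_LENGTH
    read_length: int = 50

    def __post_init__(self):
        if self.umi_length + self.arm_length >= self.read_length:
            raise ValueError("read too short to reach past the assignment key")

    @property
    def key_slice(self) -> slice:
        return slice(self.umi_length, self.umi_length + self.arm_length)


@dataclass
class AlleleCountRecord:
    """Per probe x sample allele counts."""

    probe_id: str
    sample_id: str
    n_ref: int = 0
    n_alt: int = 0
    n_other_a: int = 0
    n_other_b: int = 0

    @property
    def n_assigned(self) -> int:
        return self.n_ref + self.n_alt + self.n_other_a + self.n_other_b

    def __post_init__(self):
        if min(self.n_ref, self.n_alt, self.n_other_a, self.n_other_b) < 0:
            raise ValueError("counts must be non-negative")


def other_alleles(ref: str, alt: str) -> tuple[str, str]:
    """The two non-REF/non-ALT nucleotides, in lexicographic order."""
    a, b = sorted(set("ACGT") - {ref, alt})
    return a, b


@dataclass(frozen=True)
class _ProbeEntry:
    probe_id: str
    allele_index: int           # 0-based read index of the SNV base
    base_class: dict            # base -> AlleleClass
    expected_tail: str          # reference scan bases filling the read past the arm
    tail_snv_index: int         # index of the SNV slot within expected_tail


class PanelIndex:
    """Ligation-arm lookup table for read assignment."""

    def __init__(self, panel: PanelSpec, layout: ReadLayout = ReadLayout()):
        self.layout = layout
        self.entries: dict[str, _ProbeEntry] = {}
        for probe in panel.probes:
            if probe.ligation_arm in self.entries:
                raise ValueError(f"duplicate assignment key for {probe.probe_id}")
            snv = probe.target
            oa, ob = other_alleles(snv.ref_allele, snv.alt_allele)
            base_class = {snv.ref_allele: AlleleClass.REF, snv.alt_allele: AlleleClass.ALT,
                          oa: AlleleClass.OTHER_A, ob: AlleleClass.OTHER_B}
            tail_len = layout.read_length - layout.umi_length - layout.arm_length
            self.entries[probe.ligation_arm] = _ProbeEntry(
                probe_id=probe.probe_id,
                allele_index=layout.umi_length + probe.snv_offset - 1,
                base_class=base_class,
                expected_tail=probe.scan_seq[:tail_len],
                tail_snv_index=probe.scan_snv_index,
            )

    def probe_ids(self) -> list[str]:
        return [e.probe_id for e in self.entries.values()]


def _lookup(index: PanelIndex, key: str, max_mismatch: int) -> _ProbeEntry | None:
    entry = index.entries.get(key)
    if entry is not None or max_mismatch == 0:
        return entry
    best, best_d, ties = None, max_mismatch + 1, 0
    for arm, cand in index.entries.items():
        d = sum(a != b for a, b in zip(arm, key))
        if d < best_d:
            best, best_d, ties = cand, d, 1
        elif d == best_d:
            ties += 1
    if best_d > max_mismatch or ties > 1:  # unmatched or ambiguous
        return None
    return best


def assign_read(read_seq: str, index: PanelIndex, *, max_mismatch: int = 0,
                require_scan: bool = False):
    """Assign one read, returning ``(probe_id, AlleleClass)`` or ``None``.

    ``require_scan`` additionally demands that the read's tail match the
    probe's reference scan sequence outside the SNV slot (the stricter of the
    two published matching tiers).
    """
    layout = index.layout
    read_seq = read_seq.upper()
    if len(read_seq) < layout.umi_length + layout.arm_length + 1:
        return None
    entry = _lookup(index, read_seq[layout.key_slice], max_mismatch)
    if entry is None:
        return None
    if len(read_seq) <= entry.allele_index:
        return None
    if require_scan and not _scan_matches(read_seq, entry, layout):
        return None
    allele = entry.base_class.get(read_seq[entry.allele_index])
    if allele is None:
        return None  # ambiguous base (e.g. N) at the SNV slot
    return entry.probe_id, allele


def _scan_matches(read_seq: str, entry: _ProbeEntry, layout: ReadLayout) -> bool:
    start = layout.umi_length + layout.arm_length
    tail = read_seq[start:start + len(entry.expected_tail)]
    for i, (got, want) in enumerate(zip(tail, entry.expected_tail)):
        if i != entry.tail_snv_index and got != want:
            return False
    return True


def _open_maybe_gzip(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _iter_fastq(paths: Iterable) -> Iterable[tuple[int, str, str]]:
    i = 0
    for path in paths:
        with _open_maybe_gzip(path) as fh:
            try:
                for title, seq, _qual in FastqGeneralIterator(fh):
                    yield i, title, seq
                    i += 1
            except ValueError as exc:
                raise FormatError(f"malformed FASTQ record near index {i} "
                                  f"in {path}: {exc}") from exc


def count_alleles(fastq, panel: PanelSpec, layout: ReadLayout = ReadLayout(),
                  sample_id: str = "sample", *, dedup_umi: bool = False,
                  require_scan: bool = False, max_mismatch: int = 0):
    """Count allele classes per probe over one sample's FASTQ file(s).

    Returns ``(records, summary)`` where ``records`` has one
    :class:`AlleleCountRecord` per panel probe (zeros included) and
    ``summary`` reports total reads, the fraction matching the assignment key,
    and the fraction matching key plus scan sequence.
    """
    if not panel.probes:
        raise ValueError("panel is empty")
    paths = [fastq] if isinstance(fastq, (str, bytes)) or hasattr(fastq, "__fspath__") \
        else list(fastq)
    index = PanelIndex(panel, layout)
    counts = {p.probe_id: {c: 0 for c in AlleleClass} for p in panel.probes}
    seen_umis: set[tuple[str, str, AlleleClass]] = set()
    n_reads = n_key = n_scan = n_assigned = 0
    for _, _title, seq in _iter_fastq(paths):
        n_reads += 1
        seq = seq.upper()
        if len(seq) < layout.umi_length + layout.arm_length + 1:
            continue
        entry = _lookup(index, seq[layout.key_slice], max_mismatch)
        if entry is None:
            continue
        n_key += 1
        scan_ok = _scan_matches(seq, entry, layout)
        if scan_ok:
            n_scan += 1
        if require_scan and not scan_ok:
            continue
        if len(seq) <= entry.allele_index:
            continue
        allele = entry.base_class.get(seq[entry.allele_index])
        if allele is None:
            continue
        if dedup_umi:
            umi = seq[:layout.umi_length]
            dedup_key = (entry.probe_id, umi, allele)
            if dedup_key in seen_umis:
                continue
            seen_umis.add(dedup_key)
        counts[entry.probe_id][allele] += 1
        n_assigned += 1

    records = [AlleleCountRecord(
        probe_id=pid, sample_id=sample_id,
        n_ref=c[AlleleClass.REF], n_alt=c[AlleleClass.ALT],
        n_other_a=c[AlleleClass.OTHER_A], n_other_b=c[AlleleClass.OTHER_B],
    ) for pid, c in counts.items()]
    summary = {
        "sample_id": sample_id,
        "n_reads": n_reads,
        "n_key_matched": n_key,
        "n_key_scan_matched": n_scan,
        "n_assigned": n_assigned,
        "frac_key_matched": n_key / n_reads if n_reads else float("nan"),
        "frac_key_scan_matched": n_scan / n_reads if n_reads else float("nan"),
    }
    return records, summary


# ---------------------------------------------------------------------------
# counts I/O

COUNT_COLUMNS = ["probe_id", "sample_id", "n_ref", "n_alt", "n_other_a", "n_other_b"]


def records_to_frame(records: Sequence[AlleleCountRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "probe_id": r.probe_id, "sample_id": r.sample_id, "n_ref": r.n_ref,
        "n_alt": r.n_alt, "n_other_a": r.n_other_a, "n_other_b": r.n_other_b,
    } for r in records], columns=COUNT_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[AlleleCountRecord]:
    missing = set(COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"counts table lacks columns: {sorted(missing)}")
    return [AlleleCountRecord(r.probe_id, r.sample_id, int(r.n_ref), int(r.n_alt),
                              int(r.n_other_a), int(r.n_other_b))
            for r in df.itertuples(index=False)]


def write_counts_tsv(records: Sequence[AlleleCountRecord], path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)


def read_counts_tsv(path) -> list[AlleleCountRecord]:
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise FormatError(f"cannot read counts TSV {path}: {exc}") from exc
    return frame_to_records(df)
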