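"""Shared fixtures: synthetic genomes and multi-sample VCFs built at test time."""

from __future__ import annotations

import numpy as np
import pytest

VCF_HEADER = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}
"""


def write_vcf(path, samples, records):
    """records: iterable of (chrom, pos, ref, alt, genotypes) with genotypes
    like '0/0'; alt may contain commas for multi-allelic sites."""
    with open(path, "w") as fh:
        fh.write(VCF_HEADER.format(samples="\t".join(samples)))
        for chrom, pos, ref, alt, gts in records:
            row = [chrom, str(pos), ".", ref, alt, ".", "PASS", ".", "GT"] + list(gts)
            fh.write("\t".join(row) + "\n")


def write_fasta(path, contigs):
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n{seq}\n")


def random_contig(length, rng, forced=None):
    """Random ACGT sequence with ``forced`` = {1-based position: base}."""
    seq = list(rng.choice(list("ACGT"), size=length))
    for pos, base in (forced or {}).items():
        seq[pos - 1] = base
    return "".join(seq)


# Six-site toy panel: strains A, B, C on one 400-nt contig.
# Hand enumeration of the uniqueness rule:
#   pos 150 (A/G): only B hom-alt          -> unique SNV of B
#   pos 180 (C/T): A and C hom-alt         -> excluded (not unique)
#   pos 210 (G/A): B heterozygous          -> excluded (het)
#   pos 240 (T/C): C missing genotype      -> excluded (missing)
#   pos 270 (A/C): only A hom-alt          -> unique SNV of A
#   pos 300 (G,"A,T"): multi-allelic       -> excluded
TOY_STRAINS = ["A", "B", "C"]
TOY_RECORDS = [
    ("chrI", 150, "A", "G", ["0/0", "1/1", "0/0"]),
    ("chrI", 180, "C", "T", ["1/1", "0/0", "1/1"]),
    ("chrI", 210, "G", "A", ["0/0", "0/1", "0/0"]),
    ("chrI", 240, "T", "C", ["0/0", "1/1", "./."]),
    ("chrI", 270, "A", "C", ["1/1", "0/0", "0/0"]),
    ("chrI", 300, "G", "A,T", ["0/0", "1/1", "2/2"]),
]
TOY_EXPECTED = {"A": [("chrI", 270, "A", "C")], "B": [("chrI", 150, "A", "G")]}


@pytest.fixture(scope="session")
def toy_genome_seq():
    rng = np.random.default_rng(20220621)
    forced = {pos: rec[2] for rec in TOY_RECORDS for pos in [rec[1]]}
    return random_contig(400, rng, forced)


@pytest.fixture(scope="session")
def toy_genome(tmp_path_factory, toy_genome_seq):
    path = tmp_path_factory.mktemp("toy") / "genome.fa"
    write_fasta(path, {"chrI": toy_genome_seq})
    return path


@pytest.fixture(scope="session")
def toy_vcf(tmp_path_factory):
    path = tmp_path_factory.mktemp("toy") / "strains.vcf"
    write_vcf(path, TOY_STRAINS, TOY_RECORDS)
    return path


def make_cohort(n_strains, snvs_per_strain, rng, spacing=250, chrom="chrI"):
    """A cohort genome + VCF records where each strain owns
    ``snvs_per_strain`` unique homozygous-alt SNVs, evenly spaced."""
    strains = [f"W{i:03d}" for i in range(n_strains)]
    records, forced = [], {}
    pos = 200
    for i in range(n_strains):
        for _ in range(snvs_per_strain):
            ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
            gts = ["0/0"] * n_strains
            gts[i] = "1/1"
            records.append((chrom, pos, str(ref), str(alt), gts))
            forced[pos] = str(ref)
            pos += spacing
    genome = {chrom: random_contig(pos + 300, rng, forced)}
    return strains, records, genome


@pytest.fixture(scope="session")
def cohort_103(tmp_path_factory):
    """103 strains x 5 candidate SNVs each, on disk (VCF + FASTA)."""
    rng = np.random.default_rng(103)
    strains, records, genome = make_cohort(103, 5, rng)
    d = tmp_path_factory.mktemp("cohort103")
    vcf_path, fa_path = d / "cohort.vcf", d / "cohort.fa"
    write_vcf(vcf_path, strains, records)
    write_fasta(fa_path, genome)
    return {"strains": strains, "vcf": vcf_path, "fasta": fa_path,
            "genome": genome, "records": records}
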