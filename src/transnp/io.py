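"""Readers and writers for the plain-text formats the pipeline consumes and emits.

FASTA/FASTQ go through Bio.SeqIO; tabular local-alignment records (BLAST
``-outfmt 6`` dialect, optionally with a query-frame column) and genotype
matrices go through pandas. A minimal Genepop reader is provided for panel
genotypes exported by other tools.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclass
class Read:
    """One sequencing read held in memory.

    ``qual`` is a numpy array of phred scores (Sanger scale), same length as
    ``seq``. ``barcode`` and ``individual`` are filled by demultiplexing.
    """

    id: str
    seq: str
    qual: np.ndarray
    barcode: str | None = None
    individual: str | None = None

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValueError(f"read {self.id}: sequence/quality length mismatch")

    @property
    def error_probs(self) -> np.ndarray:
        return 10.0 ** (-self.qual / 10.0)


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path) -> list[Read]:
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = np.asarray(rec.letter_annotations["phred_quality"], dtype=np.int32)
        reads.append(Read(rec.id, str(rec.seq).upper(), qual))
    return reads


def write_fastq(reads: Iterable[Read], path) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.seq), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = [int(q) for q in r.qual]
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


BLAST6_COLUMNS = [
    "query_id", "subject_id", "pct_identity", "align_length", "mismatches",
    "gap_opens", "q_start", "q_end", "s_start", "s_end", "e_value", "bit_score",
]


def read_blast_tab(path, with_frames: bool = False) -> pd.DataFrame:
    """Read tabular local-alignment records (BLAST ``-outfmt 6`` dialect).

    With ``with_frames=True`` a trailing ``frame`` column (signed query frame,
    the ``qframe`` field) is expected, as emitted by translated searches.
    """
    cols = BLAST6_COLUMNS + (["frame"] if with_frames else [])
    df = pd.read_csv(str(path), sep="\t", names=cols, comment="#")
    return df


def write_blast_tab(df: pd.DataFrame, path, with_frames: bool = False) -> None:
    cols = BLAST6_COLUMNS + (["frame"] if with_frames else [])
    df.to_csv(str(path), sep="\t", header=False, index=False, columns=cols)


def read_genotype_tsv(path) -> tuple[pd.DataFrame, pd.Series]:
    """Read a samples x loci genotype matrix from TSV.

    First column: sample id; second column: population label; remaining
    columns: loci with genotypes coded as minor-allele dosage 0/1/2, empty or
    NA for missing.
    """
    df = pd.read_csv(str(path), sep="\t", index_col=0)
    pops = df.iloc[:, 0].astype(str)
    genos = df.iloc[:, 1:].astype(float)
    return genos, pops


def write_genotype_tsv(genos: pd.DataFrame, pops: pd.Series, path) -> None:
    out = pd.concat([pops.rename("population"), genos], axis=1)
    out.to_csv(str(path), sep="\t", index_label="sample")


def read_genepop(path) -> tuple[pd.DataFrame, pd.Series]:
    """Minimal Genepop reader for biallelic loci (2- or 3-digit allele codes).

    Returns the (samples x loci) dosage matrix (count of the numerically
    larger allele; NaN for missing) and a population label series. Population
    labels are ``pop1`` ... ``popK`` in file order.
    """
    with open(str(path)) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines:
        raise ValueError("empty genepop file")
    body = lines[1:]  # first line is a title/comment
    loci: list[str] = []
    i = 0
    while i < len(body) and body[i].strip().lower() != "pop":
        # locus names: one per line, or comma separated
        loci.extend(x.strip() for x in body[i].split(",") if x.strip())
        i += 1
    allele_rows, pops, sample_ids = [], [], []
    pop_idx = 0
    while i < len(body):
        if body[i].strip().lower() == "pop":
            pop_idx += 1
            i += 1
            continue
        line = body[i].strip()
        i += 1
        if not line:
            continue
        name, _, geno_part = line.partition(",")
        codes = geno_part.split()
        if len(codes) != len(loci):
            raise ValueError(f"genepop line for {name.strip()}: expected {len(loci)} loci")
        row = []
        for code in codes:
            w = len(code) // 2
            a1, a2 = int(code[:w]), int(code[w:])
            row.append((a1, a2) if a1 != 0 and a2 != 0 else None)
        allele_rows.append(row)
        sample_ids.append(name.strip())
        pops.append(f"pop{pop_idx}")
    # dosage of the numerically larger allele code observed at each locus
    data = np.full((len(allele_rows), len(loci)), np.nan)
    for j in range(len(loci)):
        observed = {a for row in allele_rows if row[j] for a in row[j]}
        if not observed:
            continue
        if len(observed) > 2:
            raise ValueError(f"locus {loci[j]} has more than two alleles")
        hi = max(observed)
        for k, row in enumerate(allele_rows):
            if row[j] is not None:
                data[k, j] = (row[j][0] == hi) + (row[j][1] == hi)
    genos = pd.DataFrame(data, index=sample_ids, columns=loci)
    return genos, pd.Series(pops, index=sample_ids, name="population")


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def write_vcf(snps: pd.DataFrame, path) -> None:
    """Write candidate SNPs as a minimal VCF (site records only).

    INFO carries read depth (DP), minor-allele read count (MC), number of
    individuals with the minor allele (NIND) and the polymorphism posterior
    (PP).
    """
    with open(str(path), "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##INFO=<ID=MC,Number=1,Type=Integer,Description="Minor allele read count">\n')
        fh.write('##INFO=<ID=NIND,Number=1,Type=Integer,Description="Individuals with minor allele">\n')
        fh.write('##INFO=<ID=PP,Number=1,Type=Float,Description="Polymorphism posterior">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for _, row in snps.iterrows():
            info = (
                f"DP={int(row.depth)};MC={int(row.minor_count)};"
                f"NIND={int(row.individuals_with_minor)};PP={row.posterior:.6g}"
            )
            fh.write(
                f"{row.contig_id}\t{int(row.position)}\t.\t{row.major_allele}\t"
                f"{row.minor_allele}\t.\tPASS\t{info}\n"
            )


def parse_bracketed_assay(text: str) -> tuple[str, str]:
    """Expand ``flank[A/G]flank`` into the two full allele sequences."""
    m = re.fullmatch(r"([ACGTNacgtn]*)\[([ACGT])/([ACGT])\]([ACGTNacgtn]*)", text)
    if m is None:
        raise ValueError(f"not a bracketed assay sequence: {text!r}")
    up, a1, a2, down = m.groups()
    return up + a1 + down, up + a2 + down


def format_bracketed_assay(assay_region: str, allele1: str, allele2: str) -> str:
    """Format a 121-bp assay window as ``flank[allele1/allele2]flank``."""
    center = len(assay_region) // 2
    return f"{assay_region[:center]}[{allele1}/{allele2}]{assay_region[center + 1:]}"
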