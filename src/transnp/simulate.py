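"""Synthetic transcriptomes, diploid genotypes and barcoded 454-like reads.

The generator is the test bed for every downstream stage: it writes a truth
table of planted SNPs (positions, alleles, per-population frequencies,
per-individual genotypes) and a read-origin table, so recall, demultiplexing
accuracy and filter behaviour can be scored against known truth.

The study conditions it emulates: a non-normalised cDNA library from eight
diploid individuals drawn from four locations, each fish tagged with a 10-mer
5' barcode, sequenced to ~20x pooled depth with ~205 bp reads, with
substitution errors and occasional +/-1 homopolymer-length errors (the
dominant pyrosequencing error mode). Reads are sampled uniformly along
transcripts (no 3' bias) and truth SNPs are biallelic substitutions only;
indel variants are never planted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .io import Read, revcomp

BASES = "ACGT"


def uniform_maf(low: float = 0.05, high: float = 0.5) -> Callable[[np.random.Generator], float]:
    """Uniform minor-allele-frequency sampler on [low, high]."""
    def sample(rng: np.random.Generator) -> float:
        return float(rng.uniform(low, high))
    return sample


def neutral_maf(low: float = 0.02, high: float = 0.5) -> Callable[[np.random.Generator], float]:
    """Neutral-spectrum sampler: density proportional to 1/x, folded at 0.5.

    Produces the L-shaped spectrum expected of an unascertained panel.
    """
    def sample(rng: np.random.Generator) -> float:
        return float(low * (high / low) ** rng.uniform())
    return sample


@dataclass
class SimConfig:
    """Configuration of one simulated sequencing experiment.

    mean_depth is pooled reads per base over all individuals (the library is
    multiplexed, so each of the ``2 * n_individuals`` haplotypes receives
    roughly ``mean_depth / (2 * n_individuals)`` fold coverage).
    """

    n_transcripts: int = 50
    transcript_length_range: tuple[int, int] = (1000, 1000)
    n_individuals: int = 8
    n_populations: int = 4
    snp_density: float = 2.0           # SNPs per kb
    maf_distribution: Callable[[np.random.Generator], float] = field(default_factory=uniform_maf)
    mean_depth: float = 20.0           # reads per base, pooled
    read_length_mean: float = 205.0
    read_length_sd: float = 30.0
    per_base_error: float = 0.01
    homopolymer_indel_rate: float = 5e-4
    barcode_length: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.per_base_error, self.homopolymer_indel_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("error rates must lie in [0, 1]")
        if self.read_length_mean < 50:
            raise ValueError("read_length_mean must be >= 50")
        if self.n_individuals % 2 or self.n_individuals % self.n_populations:
            raise ValueError("n_individuals must be even and divisible by n_populations")
        lo, hi = self.transcript_length_range
        if lo > hi or lo < 1:
            raise ValueError("invalid transcript_length_range")
        if self.snp_density < 0 or self.mean_depth < 0:
            raise ValueError("snp_density and mean_depth must be non-negative")

    @property
    def individuals(self) -> list[str]:
        return [f"ind{i}" for i in range(self.n_individuals)]

    @property
    def populations(self) -> list[str]:
        return [f"pop{i}" for i in range(self.n_populations)]

    def individual_population(self) -> dict[str, str]:
        per = self.n_individuals // self.n_populations
        return {f"ind{i}": f"pop{i // per}" for i in range(self.n_individuals)}

    def barcodes(self) -> dict[str, str]:
        """Deterministic per-individual 10-mer tags, pairwise Hamming >= 3."""
        rng = np.random.default_rng((self.seed * 1_000_003 + 17) % 2**31)
        chosen: list[str] = []
        while len(chosen) < self.n_individuals:
            cand = "".join(BASES[b] for b in rng.integers(0, 4, size=self.barcode_length))
            if all(_hamming(cand, c) >= 3 for c in chosen):
                chosen.append(cand)
        return dict(zip(self.individuals, chosen))


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[b] for b in rng.integers(0, 4, size=length))


def generate_transcriptome(config: SimConfig) -> tuple[dict[str, str], pd.DataFrame]:
    """Generate reference transcripts and the truth table of planted SNPs.

    The number of SNPs per transcript is ``snp_density * length / 1000``
    (fractional parts resolved by a Bernoulli draw, so integral expectations
    are exact). Returns (transcripts, truth). Truth columns: transcript,
    position (0-based), ref, alt, maf, per-population alt frequencies
    (pop0..popK), per-individual alt dosages (ind0..indN in {0,1,2}).
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.transcript_length_range
    transcripts: dict[str, str] = {}
    records = []
    pop_of = config.individual_population()
    for t in range(config.n_transcripts):
        length = int(rng.integers(lo, hi + 1))
        name = f"tx{t:04d}"
        seq = _random_seq(rng, length)
        transcripts[name] = seq
        expected = config.snp_density * length / 1000.0
        n_snps = int(expected) + (1 if rng.uniform() < expected - int(expected) else 0)
        if n_snps > length:
            raise ValueError(
                f"snp_density {config.snp_density}/kb yields {n_snps} SNPs for a "
                f"{length} bp transcript; too dense"
            )
        if n_snps == 0:
            continue
        positions = np.sort(rng.choice(length, size=n_snps, replace=False))
        for pos in positions:
            ref = seq[pos]
            alt = BASES[(BASES.index(ref) + int(rng.integers(1, 4))) % 4]
            maf = config.maf_distribution(rng)
            pop_freqs = {p: maf for p in config.populations}
            genos = {
                ind: int(rng.binomial(2, pop_freqs[pop_of[ind]]))
                for ind in config.individuals
            }
            records.append(
                {"transcript": name, "position": int(pos), "ref": ref, "alt": alt,
                 "maf": maf, **{f"freq_{p}": pop_freqs[p] for p in config.populations},
                 **genos}
            )
    columns = (
        ["transcript", "position", "ref", "alt", "maf"]
        + [f"freq_{p}" for p in config.populations]
        + config.individuals
    )
    truth = pd.DataFrame(records, columns=columns)
    return transcripts, truth


def _haplotypes(transcripts: dict[str, str], truth: pd.DataFrame, config: SimConfig,
                rng: np.random.Generator) -> dict[tuple[str, str, int], str]:
    """Phase genotypes into two haplotype sequences per (transcript, individual)."""
    haps: dict[tuple[str, str, int], str] = {}
    for name, seq in transcripts.items():
        rows = truth[truth.transcript == name]
        for ind in config.individuals:
            pair = [list(seq), list(seq)]
            for _, row in rows.iterrows():
                g = int(row[ind])
                if g == 2:
                    carriers = (0, 1)
                elif g == 1:
                    carriers = (int(rng.integers(0, 2)),)
                else:
                    carriers = ()
                for h in carriers:
                    pair[h][int(row.position)] = row.alt
            haps[(name, ind, 0)] = "".join(pair[0])
            haps[(name, ind, 1)] = "".join(pair[1])
    return haps


def _apply_homopolymer_indels(seq: str, rate: float, rng: np.random.Generator) -> tuple[str, int]:
    """Expand or contract homopolymer runs of length >= 3 by one base."""
    if rate <= 0:
        return seq, 0
    out: list[str] = []
    i = 0
    n_events = 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        run = seq[i:j]
        if j - i >= 3 and rng.uniform() < rate:
            n_events += 1
            run = run + seq[i] if rng.uniform() < 0.5 else run[:-1]
        out.append(run)
        i = j
    return "".join(out), n_events


def _apply_substitutions(seq: str, rate: float, rng: np.random.Generator) -> tuple[str, int]:
    if rate <= 0:
        return seq, 0
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.uniform(size=len(arr)) < rate)[0]
    for i in hits:
        base = chr(arr[i])
        arr[i] = ord(BASES[(BASES.index(base) + int(rng.integers(1, 4))) % 4])
    return arr.tobytes().decode(), len(hits)


def simulate_reads(transcripts: dict[str, str], truth: pd.DataFrame, config: SimConfig,
                   ) -> tuple[list[Read], pd.DataFrame]:
    """Simulate barcoded reads and the read-origin truth table.

    Each read: a fragment drawn uniformly along one haplotype of one
    individual, possibly reverse-complemented, with homopolymer +/-1 indels
    then substitution errors applied, the individual's 10-mer barcode
    prepended, and flat Sanger qualities encoding the substitution rate.
    Origin columns: read_id, individual, transcript, strand, offset
    (0-based on the transcript), haplotype, length, n_subs, n_indels.
    """
    rng = np.random.default_rng(config.seed + 1)
    barcodes = config.barcodes()
    haps = _haplotypes(transcripts, truth, config, rng)
    q = int(min(40, round(-10 * np.log10(config.per_base_error)))) if config.per_base_error > 0 else 40
    reads: list[Read] = []
    origins = []
    counter = 0
    for name, seq in transcripts.items():
        length = len(seq)
        n_reads = int(round(config.mean_depth * length / config.read_length_mean))
        for _ in range(n_reads):
            ind = config.individuals[int(rng.integers(0, config.n_individuals))]
            hap = int(rng.integers(0, 2))
            rl = int(np.clip(round(rng.normal(config.read_length_mean, config.read_length_sd)),
                             50, length))
            start = int(rng.integers(0, length - rl + 1))
            frag = haps[(name, ind, hap)][start:start + rl]
            strand = "+" if rng.uniform() < 0.5 else "-"
            if strand == "-":
                frag = revcomp(frag)
            frag, n_ind = _apply_homopolymer_indels(frag, config.homopolymer_indel_rate, rng)
            frag, n_sub = _apply_substitutions(frag, config.per_base_error, rng)
            barcode, _ = _apply_substitutions(barcodes[ind], config.per_base_error, rng)
            read_id = f"read{counter:07d}"
            counter += 1
            full = barcode + frag
            reads.append(Read(read_id, full, np.full(len(full), q, dtype=np.int32)))
            origins.append(
                {"read_id": read_id, "individual": ind, "transcript": name,
                 "strand": strand, "offset": start, "haplotype": hap,
                 "length": rl, "n_subs": n_sub, "n_indels": n_ind}
            )
    origin = pd.DataFrame(
        origins,
        columns=["read_id", "individual", "transcript", "strand", "offset",
                 "haplotype", "length", "n_subs", "n_indels"],
    )
    return reads, origin


def simulate_genotype_matrix(n_samples_per_pop: int, truth: pd.DataFrame, config: SimConfig,
                             missing_rate: float = 0.02, seed: int | None = None,
                             ) -> tuple[pd.DataFrame, pd.Series]:
    """Draw an independent genotyping panel at the truth SNPs' frequencies.

    Emulates typing the discovered panel in fresh samples from the same
    populations: dosages are binomial(2, freq) per sample, with genotypes
    missing completely at random at ``missing_rate``.
    """
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    loci = [f"{r.transcript}:{r.position + 1}" for r in truth.itertuples()]
    samples, pops = [], []
    data = []
    for p in config.populations:
        freqs = truth[f"freq_{p}"].to_numpy()
        for s in range(n_samples_per_pop):
            g = rng.binomial(2, freqs).astype(float)
            g[rng.uniform(size=len(g)) < missing_rate] = np.nan
            data.append(g)
            samples.append(f"{p}_s{s}")
            pops.append(p)
    genos = pd.DataFrame(data, index=samples, columns=loci)
    return genos, pd.Series(pops, index=samples, name="population")
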