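"""Gapless placement of cleaned reads onto contig consensus sequences.

The mapper is deliberately simple: exact k-mer seeds nominate gapless
diagonals on both strands, a read is placed at its best full-length
location if identity >= 90%, and ties break deterministically (first
contig in input order, then leftmost coordinate, plus strand before
minus). Reads carrying homopolymer-length errors that no longer fit any
gapless diagonal are reported unplaced. Internally everything is 0-based
half-open; emitted tables are 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Read, revcomp


@dataclass(frozen=True)
class Placement:
    read_id: str
    contig_id: str
    strand: str            # '+' or '-'
    start: int             # 0-based on the contig
    length: int
    mismatches: int
    individual: str | None

    @property
    def identity(self) -> float:
        return 1.0 - self.mismatches / self.length


class ContigPileup:
    """Per-position read-base columns over one contig consensus.

    Column entries are stored as flat arrays (position, base, error
    probability, read index, individual index) for speed; ``column(i)``
    materialises one column. All read bases are oriented to the consensus
    strand before stacking.
    """

    def __init__(self, contig_id: str, consensus: str, positions: np.ndarray,
                 bases: np.ndarray, eprobs: np.ndarray, read_ids: np.ndarray,
                 individuals: np.ndarray):
        self.contig_id = contig_id
        self.consensus = consensus
        order = np.argsort(positions, kind="stable")
        self.positions = positions[order]
        self.bases = bases[order]
        self.eprobs = eprobs[order]
        self.read_ids = read_ids[order]
        self.individuals = individuals[order]
        if len(self.positions) and (self.positions.min() < 0
                                    or self.positions.max() >= len(consensus)):
            raise ValueError(f"{contig_id}: pileup column outside consensus")
        if np.any(self.eprobs <= 0) or np.any(self.eprobs >= 1):
            raise ValueError(f"{contig_id}: error probabilities must lie in (0,1)")
        self._starts = np.searchsorted(self.positions, np.arange(len(consensus) + 1))

    @property
    def depth(self) -> np.ndarray:
        return np.diff(self._starts)

    def column(self, pos: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(bases, error_probs, read_ids, individuals) stacked at ``pos``."""
        lo, hi = self._starts[pos], self._starts[pos + 1]
        return (self.bases[lo:hi], self.eprobs[lo:hi],
                self.read_ids[lo:hi], self.individuals[lo:hi])


def _seq_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def _index_contigs(contigs: dict[str, str], k: int):
    index: dict[str, list[tuple[int, int]]] = {}
    order = list(contigs)
    for ci, name in enumerate(order):
        seq = contigs[name]
        for i in range(len(seq) - k + 1):
            index.setdefault(seq[i:i + k], []).append((ci, i))
    return index, order


def map_reads(reads: list[Read], contigs: dict[str, str], min_identity: float = 0.9,
              k: int = 16) -> tuple[list[Placement], list[Read]]:
    """Place each read at its best gapless location, or report it unplaced.

    Requires full-read identity >= ``min_identity`` on one strand of one
    contig. Best placement = fewest mismatches; ties resolved by contig
    input order, then leftmost start, then '+' strand.
    """
    if not contigs:
        raise ValueError("no contigs to map against")
    index, order = _index_contigs(contigs, k)
    arrs = [_seq_array(contigs[name]) for name in order]
    placements: list[Placement] = []
    unplaced: list[Read] = []
    for read in reads:
        best: tuple | None = None
        for strand, seq in (("+", read.seq), ("-", revcomp(read.seq))):
            if len(seq) < k:
                continue
            arr = _seq_array(seq)
            n = len(arr)
            seen: set[tuple[int, int]] = set()
            for off in range(0, n - k + 1):
                for ci, pos in index.get(seq[off:off + k], ()):
                    start = pos - off
                    if start < 0 or start + n > len(arrs[ci]) or (ci, start) in seen:
                        continue
                    seen.add((ci, start))
                    mm = int(np.count_nonzero(arr != arrs[ci][start:start + n]))
                    if mm > (1.0 - min_identity) * n:
                        continue
                    key = (mm, ci, start, 0 if strand == "+" else 1)
                    if best is None or key < best[0]:
                        best = (key, Placement(read.id, order[ci], strand, start, n,
                                               mm, read.individual))
        if best is None:
            unplaced.append(read)
        else:
            placements.append(best[1])
    return placements, unplaced


_BASE_BYTES = {b: ord(b) for b in "ACGTN"}


def build_pileup(placements: list[Placement], contigs: dict[str, str],
                 reads: dict[str, Read]) -> dict[str, ContigPileup]:
    """Stack placed reads into per-contig pileups.

    Reverse-strand reads are reverse-complemented (bases and qualities) onto
    the consensus strand; per-base error probabilities come from the phred
    qualities, clipped into (0, 1).
    """
    per_contig: dict[str, list] = {name: [] for name in contigs}
    for pl in placements:
        if pl.contig_id not in contigs:
            raise ValueError(f"placement on unknown contig {pl.contig_id}")
        if pl.start < 0 or pl.start + pl.length > len(contigs[pl.contig_id]):
            raise ValueError(f"placement of {pl.read_id} outside {pl.contig_id}")
        per_contig[pl.contig_id].append(pl)
    pileups: dict[str, ContigPileup] = {}
    for name, seq in contigs.items():
        pos_parts, base_parts, ep_parts, rid_parts, ind_parts = [], [], [], [], []
        for pl in per_contig[name]:
            read = reads[pl.read_id]
            if pl.strand == "+":
                bases = _seq_array(read.seq)
                eprobs = read.error_probs
            else:
                bases = _seq_array(revcomp(read.seq))
                eprobs = read.error_probs[::-1]
            pos_parts.append(np.arange(pl.start, pl.start + pl.length))
            base_parts.append(bases)
            ep_parts.append(np.clip(eprobs, 1e-6, 1 - 1e-6))
            rid_parts.append(np.repeat(pl.read_id, pl.length))
            ind_parts.append(np.repeat(pl.individual or "", pl.length))
        if pos_parts:
            pileups[name] = ContigPileup(
                name, seq,
                np.concatenate(pos_parts).astype(np.int64),
                np.concatenate(base_parts),
                np.concatenate(ep_parts),
                np.concatenate(rid_parts),
                np.concatenate(ind_parts),
            )
        else:
            empty_s = np.array([], dtype="U1")
            pileups[name] = ContigPileup(name, seq, np.array([], dtype=np.int64),
                                         np.array([], dtype=np.uint8),
                                         np.array([], dtype=float), empty_s, empty_s)
    return pileups


def placements_table(placements: list[Placement], unplaced: list[Read]) -> pd.DataFrame:
    """Placement summary, 1-based coordinates."""
    rows = [
        {"read_id": p.read_id, "contig_id": p.contig_id, "strand": p.strand,
         "start": p.start + 1, "end": p.start + p.length, "mismatches": p.mismatches,
         "identity": round(p.identity, 4), "individual": p.individual or ""}
        for p in placements
    ]
    rows += [
        {"read_id": r.id, "contig_id": "", "strand": "", "start": 0, "end": 0,
         "mismatches": -1, "identity": 0.0, "individual": r.individual or ""}
        for r in unplaced
    ]
    return pd.DataFrame(rows, columns=["read_id", "contig_id", "strand", "start",
                                       "end", "mismatches", "identity", "individual"])


def import_placements(path, reads: dict[str, Read]) -> list[Placement]:
    """Import existing placements from an ace-like TSV
    (read_id, contig_id, strand, offset; offset 0-based)."""
    df = pd.read_csv(str(path), sep="\t",
                     names=["read_id", "contig_id", "strand", "offset"])
    out = []
    for row in df.itertuples():
        read = reads[row.read_id]
        out.append(Placement(row.read_id, row.contig_id, row.strand, int(row.offset),
                             len(read.seq), 0, read.individual))
    return out
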