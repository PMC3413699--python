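"""Read preparation: demultiplexing and the cleaning filters.

Stages mirror a pooled-library cDNA cleaning workflow: assign each read to
its individual by the 5' barcode, drop reads matching a contaminant
reference (mitochondrial transcripts, for a muscle cDNA library), drop
reads below a minimum length, and soft-mask low-complexity sequence with a
DUST-style triplet-entropy score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import Read, revcomp


@dataclass
class StageCounts:
    """Accounting for one filter stage: input = kept + sum(removed)."""

    stage: str
    n_in: int
    n_kept: int
    removed: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_in != self.n_kept + sum(self.removed.values()):
            raise ValueError(f"stage {self.stage}: counts do not conserve")


def _hamming_prefix(seq: str, barcode: str) -> int:
    if len(seq) < len(barcode):
        return len(barcode)
    return sum(a != b for a, b in zip(seq, barcode))


def demultiplex(reads: list[Read], barcode_map: dict[str, str], max_mismatch: int = 0,
                ) -> tuple[list[Read], list[tuple[Read, str]], StageCounts]:
    """Assign reads to individuals by their 5' barcode and trim it.

    ``barcode_map`` maps barcode sequence -> individual. A read is assigned
    iff exactly one barcode matches its prefix within ``max_mismatch``
    substitutions; ties go to the unassigned pile with reason ``ambiguous``,
    everything else with ``no_match``. Default 0 mismatches: with tags at
    pairwise Hamming distance >= 3 this keeps assignment unambiguous and
    matches the strictness implied by the study design.
    """
    barcodes = list(barcode_map)
    lens = {len(b) for b in barcodes}
    if len(lens) != 1:
        raise ValueError("barcodes must share one length")
    min_dist = min(
        (_hamming_prefix(a, b) for i, a in enumerate(barcodes) for b in barcodes[i + 1:]),
        default=len(barcodes[0]),
    )
    if max_mismatch >= min_dist / 2:
        raise ValueError("max_mismatch must be < half the minimum barcode distance")
    blen = lens.pop()
    assigned, unassigned = [], []
    reasons = {"ambiguous": 0, "no_match": 0}
    for read in reads:
        dists = [(_hamming_prefix(read.seq, b), b) for b in barcodes]
        best = min(d for d, _ in dists)
        hits = [b for d, b in dists if d == best]
        if best > max_mismatch:
            reasons["no_match"] += 1
            unassigned.append((read, "no_match"))
        elif len(hits) > 1:
            reasons["ambiguous"] += 1
            unassigned.append((read, "ambiguous"))
        else:
            trimmed = Read(read.id, read.seq[blen:], read.qual[blen:],
                           barcode=hits[0], individual=barcode_map[hits[0]])
            assigned.append(trimmed)
    counts = StageCounts("demultiplex", len(reads), len(assigned),
                         {k: v for k, v in reasons.items() if v})
    return assigned, unassigned, counts


def _kmer_index(seqs: dict[str, str], k: int) -> dict[str, list[tuple[str, int]]]:
    index: dict[str, list[tuple[str, int]]] = {}
    for name, seq in seqs.items():
        for i in range(len(seq) - k + 1):
            index.setdefault(seq[i:i + k], []).append((name, i))
    return index


def _seq_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def _diagonal_hit(read_arr: np.ndarray, ref_arr: np.ndarray, diag: int,
                  min_identity: float, min_span: int) -> bool:
    """Does any window of span >= min_span on this gapless diagonal reach
    identity >= min_identity? diag = ref_pos - read_pos."""
    r0 = max(0, -diag)
    r1 = min(len(read_arr), len(ref_arr) - diag)
    if r1 - r0 < min_span:
        return False
    matches = (read_arr[r0:r1] == ref_arr[r0 + diag:r1 + diag]).astype(np.int64)
    prefix = np.concatenate([[0], np.cumsum(matches)])
    n = len(matches)
    # Test every window length >= min_span (a long span can qualify even when
    # no 60-mer does); reads are short so the O(n^2) scan is cheap.
    for length in range(min_span, n + 1):
        window = prefix[length:] - prefix[:-length]
        if window.size and window.max() >= min_identity * length:
            return True
    return False


def contaminant_screen(reads: list[Read], contaminant_reference: dict[str, str],
                       min_identity: float = 0.94, min_span: int = 60, k: int = 16,
                       ) -> tuple[list[Read], list[Read], StageCounts]:
    """Remove reads with an ungapped local match to the contaminant reference.

    A read is removed iff some gapless local alignment (either strand)
    reaches ``min_identity`` over a span of at least ``min_span`` bases, the
    criterion used for the mitochondrial screen (94% over 60 bp). Candidate
    diagonals are located by exact ``k``-mer seeds.
    """
    if not contaminant_reference:
        raise ValueError("contaminant reference is empty")
    index = _kmer_index(contaminant_reference, k)
    ref_arrs = {name: _seq_array(seq) for name, seq in contaminant_reference.items()}
    kept, removed = [], []
    for read in reads:
        if _matches_reference(read.seq, index, ref_arrs, k, min_identity, min_span):
            removed.append(read)
        else:
            kept.append(read)
    counts = StageCounts("contaminant_screen", len(reads), len(kept),
                         {"contaminant": len(removed)} if removed else {})
    return kept, removed, counts


def _matches_reference(seq: str, index, ref_arrs, k: int, min_identity: float,
                       min_span: int) -> bool:
    for oriented in (seq, revcomp(seq)):
        if len(oriented) < min_span:
            continue
        arr = _seq_array(oriented)
        seen: set[tuple[str, int]] = set()
        for i in range(0, len(oriented) - k + 1):
            for name, pos in index.get(oriented[i:i + k], ()):
                key = (name, pos - i)
                if key in seen:
                    continue
                seen.add(key)
                if _diagonal_hit(arr, ref_arrs[name], pos - i, min_identity, min_span):
                    return True
    return False


def length_quality_filter(reads: list[Read], min_length: int = 50,
                          ) -> tuple[list[Read], list[Read], StageCounts]:
    """Drop reads shorter than ``min_length`` bases (default 50)."""
    kept = [r for r in reads if len(r.seq) >= min_length]
    removed = [r for r in reads if len(r.seq) < min_length]
    counts = StageCounts("length_filter", len(reads), len(kept),
                         {"short": len(removed)} if removed else {})
    return kept, removed, counts


def dust_score(triplet_window: str) -> float:
    """DUST score of a window: sum over triplet types of c*(c-1)/2, divided
    by (number of triplets - 1). High scores flag low-complexity sequence."""
    counts: dict[str, int] = {}
    n = len(triplet_window) - 2
    if n < 2:
        return 0.0
    for i in range(n):
        t = triplet_window[i:i + 3]
        counts[t] = counts.get(t, 0) + 1
    return sum(c * (c - 1) / 2 for c in counts.values()) / (n - 1)


def mask_low_complexity(seqs: dict[str, str], window: int = 64, threshold: float = 2.0,
                        ) -> tuple[dict[str, str], float]:
    """Soft-mask (lower-case) low-complexity regions, DUST-style.

    Every window whose triplet score exceeds ``threshold`` is masked in
    full. Masking changes case only, never length, and is idempotent (the
    score is computed on the upper-cased sequence). Returns the masked
    sequences and the overall masked fraction. Stands in for a repeat
    masker with a species repeat library, which needs external data; the
    masked fraction makes the stand-in auditable.
    """
    if window < 8:
        raise ValueError("window must be >= 8")
    masked_out: dict[str, str] = {}
    total = masked_total = 0
    for name, seq in seqs.items():
        upper = seq.upper()
        n = len(upper)
        mask = np.zeros(n, dtype=bool)
        if n <= window:
            if dust_score(upper) > threshold:
                mask[:] = True
        else:
            for start in range(0, n - window + 1):
                if dust_score(upper[start:start + window]) > threshold:
                    mask[start:start + window] = True
        out = "".join(c.lower() if m else c for c, m in zip(upper, mask))
        masked_out[name] = out
        total += n
        masked_total += int(mask.sum())
    fraction = masked_total / total if total else 0.0
    return masked_out, fraction


def mask_reads(reads: list[Read], window: int = 64, threshold: float = 2.0,
               ) -> tuple[list[Read], float]:
    """Apply the low-complexity masker to reads, preserving qualities."""
    seqs = {r.id: r.seq for r in reads}
    masked, fraction = mask_low_complexity(seqs, window=window, threshold=threshold)
    out = [Read(r.id, masked[r.id], r.qual, r.barcode, r.individual) for r in reads]
    return out, fraction
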