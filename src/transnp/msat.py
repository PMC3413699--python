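"""Perfect microsatellite detection in contigs and primer-flank screening.

Finds maximal perfect tandem repeats of primitive 2–6-mer motifs with at
least four units, collapses phase-shifted duplicates to the leftmost
maximal run, canonicalizes motifs to their lexicographically minimal
rotation, and excludes homopolymers. Flank sufficiency (both flanks at
least ``min_flank`` bases of non-repeat sequence) is a proxy for
primer-design feasibility; actual primer design is external.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


@dataclass
class MsatLocus:
    contig_id: str
    start: int          # 1-based inclusive
    end: int            # 1-based inclusive
    motif: str          # canonical (lexicographically minimal rotation)
    n_units: int
    left_flank_len: int = 0
    right_flank_len: int = 0
    primer_ready: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _is_primitive(motif: str) -> bool:
    m = len(motif)
    for d in range(1, m):
        if m % d == 0 and motif == motif[:d] * (m // d):
            return False
    return True


def canonical_motif(motif: str) -> str:
    """Lexicographically minimal rotation of the motif."""
    return min(motif[i:] + motif[:i] for i in range(len(motif)))


def find_repeats(contigs: dict[str, str], min_units: int = 4,
                 motif_lengths: range = range(2, 7)) -> list[MsatLocus]:
    """Locate maximal perfect tandem repeats.

    Within a contig, candidate runs for every motif length are collected and
    overlapping candidates collapsed: runs are taken greedily by start
    coordinate (longer run first on ties), so reported loci never overlap
    and phase-shifted duplicates resolve to the leftmost maximal run.
    """
    loci: list[MsatLocus] = []
    for name, raw in contigs.items():
        seq = raw.upper()
        n = len(seq)
        candidates: list[tuple[int, int, int, str, int]] = []
        for m in motif_lengths:
            i = 0
            while i + m <= n:
                # maximal run of period m starting at i (leftmost alignment)
                j = i
                while j + m < n and seq[j + m] == seq[j]:
                    j += 1
                run_len = j - i + m          # length of the periodic region
                units = run_len // m
                motif = seq[i:i + m]
                if units >= min_units and _is_primitive(motif):
                    end = i + units * m       # trim partial unit
                    candidates.append((i, end - i, m, motif, units))
                    i = end                   # maximal: nothing overlapping starts inside
                else:
                    i = i + 1 if units < 2 else i + run_len - m + 1
            # note: scanning restarts per motif length; cross-length overlaps
            # are resolved below
        candidates.sort(key=lambda c: (c[0], -c[1], c[2]))
        taken_until = -1
        for start, length, m, motif, units in candidates:
            if start <= taken_until:
                continue
            loci.append(MsatLocus(name, start + 1, start + length,
                                  canonical_motif(motif), units))
            taken_until = start + length - 1
    return loci


def flank_check(loci: list[MsatLocus], contigs: dict[str, str],
                min_flank: int = 50) -> tuple[list[MsatLocus], dict]:
    """Flag loci with sufficient clean flanking sequence for primer design.

    primer_ready iff both flanks are at least ``min_flank`` bases long and
    no other repeat locus lies within ``min_flank`` bases of this one.
    """
    by_contig: dict[str, list[MsatLocus]] = {}
    for locus in loci:
        by_contig.setdefault(locus.contig_id, []).append(locus)
    n_ready = 0
    for locus in loci:
        contig_len = len(contigs[locus.contig_id])
        locus.left_flank_len = locus.start - 1
        locus.right_flank_len = contig_len - locus.end
        clear = all(
            other is locus
            or other.end < locus.start - min_flank
            or other.start > locus.end + min_flank
            for other in by_contig[locus.contig_id]
        )
        locus.primer_ready = (locus.left_flank_len >= min_flank
                              and locus.right_flank_len >= min_flank and clear)
        n_ready += locus.primer_ready
    summary = {"n_loci": len(loci), "primer_ready": n_ready,
               "fraction_ready": n_ready / len(loci) if loci else 0.0}
    return loci, summary


_UNIT_BINS = [(4, 9), (10, 14), (15, 19), (20, None)]
_BIN_LABELS = ["4-9", "10-14", "15-19", ">19"]
_TYPE_NAMES = {2: "Dinucleotide", 3: "Trinucleotide", 4: "Tetranucleotide",
               5: "Pentanucleotide", 6: "Hexanucleotide"}


def repeat_summary(loci: list[MsatLocus]) -> pd.DataFrame:
    """Motif-length x unit-count-bin census of detected repeats.

    Bins follow the conventional 4-9 / 10-14 / 15-19 / >19 partition (the
    overlapping 14-19 label sometimes seen in print is normalised to
    15-19). Rows report the per-type maximum unit count and totals, plus a
    grand-total row.
    """
    rows = []
    for m in range(2, 7):
        subset = [l for l in loci if len(l.motif) == m]
        counts = []
        for lo, hi in _UNIT_BINS:
            counts.append(sum(1 for l in subset
                              if l.n_units >= lo and (hi is None or l.n_units <= hi)))
        rows.append({
            "type": _TYPE_NAMES[m],
            **dict(zip(_BIN_LABELS, counts)),
            "max_units": max((l.n_units for l in subset), default=0),
            "total": len(subset),
        })
    total_row = {"type": "Total",
                 **{lab: sum(r[lab] for r in rows) for lab in _BIN_LABELS},
                 "max_units": max((r["max_units"] for r in rows), default=0),
                 "total": sum(r["total"] for r in rows)}
    rows.append(total_row)
    return pd.DataFrame(rows)


def loci_table(loci: list[MsatLocus], contigs: dict[str, str],
               flank_out: int = 200) -> pd.DataFrame:
    """Locus table with up to ``flank_out`` bases of flanking sequence."""
    rows = []
    for l in loci:
        seq = contigs[l.contig_id]
        rows.append({
            "contig_id": l.contig_id, "start": l.start, "end": l.end,
            "motif": l.motif, "n_units": l.n_units,
            "left_flank_len": l.left_flank_len, "right_flank_len": l.right_flank_len,
            "primer_ready": l.primer_ready,
            "left_flank": seq[max(0, l.start - 1 - flank_out): l.start - 1],
            "right_flank": seq[l.end: l.end + flank_out],
        })
    return pd.DataFrame(rows)
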