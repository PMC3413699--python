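"""Synonymous / non-synonymous classification of selected SNPs.

The reading frame of a SNP-containing contig is projected from its best
protein alignment (translated-search tabular records carrying a signed
query frame). The codon containing the SNP is then translated for both
allele versions of the 121-bp assay window under the standard genetic
code; identical amino acids give S, different (including stop gain/loss)
give NS, and SNPs without a qualifying protein hit — or whose codon runs
off the window — are NA.

Frame convention (translated-search dialect): frame +k means translation
of the plus strand starting at query base k (1-based); frame -k means
translation of the reverse complement starting at base k of the
reverse-complemented query. Minus-strand codon phase is therefore computed
in reverse-complement coordinates, which requires the contig length.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio.Seq import Seq

from .io import revcomp

FLANK = 60


@dataclass
class EffectCall:
    contig_id: str
    position: int
    frame: int | None
    ref_codon: str | None
    alt_codon: str | None
    ref_aa: str | None
    alt_aa: str | None
    call: str                      # 'S', 'NS' or 'NA'
    reason: str | None = None


def best_protein_frame(protein_hits: pd.DataFrame, evalue_cutoff: float = 1e-3,
                       ) -> tuple[int, int, int] | None:
    """Best protein hit's (frame, q_start, q_end), or None below cutoff.

    Best = minimum e-value, ties broken by maximum bit score; stable under
    record order.
    """
    sig = protein_hits[protein_hits.e_value < evalue_cutoff]
    if sig.empty:
        return None
    order = sig.sort_values(by=["e_value", "bit_score"], ascending=[True, False],
                            kind="stable")
    best = order.iloc[0]
    return int(best.frame), int(best.q_start), int(best.q_end)


def allele_sequences(assay_region: str, major: str, minor: str) -> tuple[str, str]:
    """The two allele versions of the 121-bp window (major first)."""
    center = len(assay_region) // 2
    return (assay_region[:center] + major + assay_region[center + 1:],
            assay_region[:center] + minor + assay_region[center + 1:])


def _codon_at(seq: str, window_start: int, target: int, frame_start: int,
              ) -> tuple[str, int] | None:
    """Codon (in ``seq`` coordinates) containing position ``target``.

    All positions 1-based on the same strand; ``window_start`` is the
    coordinate of seq[0]; codons begin at frame_start, frame_start+3, ...
    Returns (codon, phase) or None when the codon is incomplete within seq.
    """
    if target < frame_start:
        return None
    codon_start = frame_start + 3 * ((target - frame_start) // 3)
    i = codon_start - window_start
    if i < 0 or i + 3 > len(seq):
        return None
    return seq[i:i + 3], target - codon_start


def classify_effect(contig_id: str, position: int, assay_pair: tuple[str, str],
                    frame: int | None, contig_length: int,
                    confirmation_hits: pd.DataFrame | None = None,
                    confirm_cutoff: float = 1e-10) -> EffectCall:
    """Classify one SNP as S / NS / NA.

    ``position`` is the 1-based SNP coordinate on the contig; the assay
    pair are the two 121-bp allele windows centred on it. When
    ``confirmation_hits`` (translated-search records of the allele windows)
    are supplied and neither window has a hit below ``confirm_cutoff``, the
    call degrades to NA — mirroring a second-pass confirmation search.
    """
    if frame is None:
        return EffectCall(contig_id, position, None, None, None, None, None, "NA",
                          "no_frame")
    if confirmation_hits is not None:
        if not (confirmation_hits.e_value < confirm_cutoff).any():
            return EffectCall(contig_id, position, frame, None, None, None, None,
                              "NA", "unconfirmed")
    ref_seq, alt_seq = assay_pair
    window_start = position - FLANK   # 1-based coordinate of window[0]
    if frame > 0:
        codons = [_codon_at(s, window_start, position, frame)
                  for s in (ref_seq, alt_seq)]
    else:
        # reverse-complement coordinates: base p maps to L - p + 1
        rc_pos = contig_length - position + 1
        rc_window_start = contig_length - (window_start + len(ref_seq) - 1) + 1
        codons = [_codon_at(revcomp(s), rc_window_start, rc_pos, -frame)
                  for s in (ref_seq, alt_seq)]
    if codons[0] is None or codons[1] is None:
        return EffectCall(contig_id, position, frame, None, None, None, None, "NA",
                          "partial_codon")
    ref_codon, alt_codon = codons[0][0], codons[1][0]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    call = "S" if ref_aa == alt_aa else "NS"
    return EffectCall(contig_id, position, frame, ref_codon, alt_codon,
                      ref_aa, alt_aa, call)


def effect_table(calls: list[EffectCall]) -> pd.DataFrame:
    df = pd.DataFrame([vars(c) for c in calls])
    return df


def ns_s_ratio(calls: list[EffectCall] | pd.DataFrame) -> float:
    """count(NS) / count(S) over a set of effect calls."""
    if isinstance(calls, pd.DataFrame):
        labels = calls["call"]
    else:
        labels = pd.Series([c.call for c in calls])
    n_s = int((labels == "S").sum())
    n_ns = int((labels == "NS").sum())
    if n_s == 0:
        return float("nan")
    return n_ns / n_s
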