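"""Selection of genotyping-assay candidates.

A candidate SNP becomes an assay candidate only if a full 121-bp window
(SNP +/- 60 bp) fits inside its contig — the window the assay oligos are
designed on. Candidates are then gated on the externally supplied Assay
Design Score (discard < 0.4, prefer > 0.7), screened for intron–exon
boundaries inside the window with two alignment-based pipelines (direct
contig-vs-genome, and contig-vs-transcript projected onto
transcript-vs-genome exon segments), scored for neighbourhood sequence
quality (extra variant columns in the window flag paralog co-assembly),
and ranked so that at most two SNPs per contig enter the panel.

All alignment coordinates follow the tabular BLAST dialect: 1-based,
inclusive; subject start > end encodes the minus strand. Containment tests
use inclusive interval logic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .mapping import ContigPileup
from .io import revcomp


class Boundary(str, Enum):
    SINGLE_EXON = "single_exon"
    BOUNDARY = "boundary"
    NO_MATCH = "no_match"


@dataclass
class BoundaryCall:
    call: Boundary
    supporting_species: int
    evidence: list[tuple[str, str, str]] = field(default_factory=list)  # (source, species, call)


FLANK = 60
ASSAY_LEN = 2 * FLANK + 1


def extract_flanks(position: int, consensus: str, major: str, minor: str,
                   flank: int = FLANK) -> dict | None:
    """Extract the assay window for a SNP at 1-based ``position``.

    Returns None (rejection reason "terminal") when either flank would run
    off the contig; otherwise a dict with flank_up, flank_down and the
    121-bp assay_region carrying the major allele at its centre.
    """
    if position - flank < 1 or position + flank > len(consensus):
        return None
    window = consensus[position - flank - 1: position + flank]
    assay = window[:flank] + major + window[flank + 1:]
    return {"flank_up": window[:flank], "flank_down": window[flank + 1:],
            "assay_region": assay}


def ads_tier(ads: float | None, reject_below: float = 0.4,
             prefer_above: float = 0.7) -> str | None:
    """Tier an Assay Design Score: reject < 0.4 <= acceptable <= 0.7 < preferred."""
    if ads is None or (isinstance(ads, float) and np.isnan(ads)):
        return None
    if ads < reject_below:
        return "reject"
    if ads > prefer_above:
        return "preferred"
    return "acceptable"


def ads_filter(candidates: pd.DataFrame, ads_table: pd.DataFrame,
               reject_below: float = 0.4, prefer_above: float = 0.7) -> pd.DataFrame:
    """Join an ADS column onto candidates and tier it.

    ``ads_table`` columns: contig_id, position, ads. Missing scores give a
    null tier: such rows stay in the table but are never selected.
    """
    merged = candidates.merge(ads_table, on=["contig_id", "position"], how="left")
    merged["ads_tier"] = [
        ads_tier(a, reject_below, prefer_above) for a in merged["ads"]
    ]
    return merged


def ads_proxy(assay_region: str) -> float:
    """Crude, non-Illumina design-score proxy for synthetic runs.

    Combines GC balance and flank self-complementarity into [0, 1]. This is
    NOT the proprietary Assay Design Score; it exists so synthetic
    pipelines have a score column with realistic spread.
    """
    seq = assay_region.upper()
    gc = (seq.count("G") + seq.count("C")) / len(seq)
    gc_term = max(0.0, 1.0 - 3.0 * abs(gc - 0.45))
    up, down = seq[:FLANK], seq[FLANK + 1:]
    rc_down = revcomp(down)
    k = 8
    kmers = {up[i:i + k] for i in range(len(up) - k + 1)}
    hits = sum(rc_down[i:i + k] in kmers for i in range(len(rc_down) - k + 1))
    selfcomp = min(1.0, hits / 10.0)
    return round(0.75 * gc_term + 0.25 * (1.0 - selfcomp), 3)


def _best_hit(hits: pd.DataFrame, evalue_cutoff: float) -> pd.Series | None:
    """Best positive match: max aligned query span, then min e-value, then
    max bit score."""
    sig = hits[hits.e_value < evalue_cutoff]
    if sig.empty:
        return None
    span = sig.q_end - sig.q_start + 1
    order = sig.assign(_span=span).sort_values(
        by=["_span", "e_value", "bit_score"], ascending=[False, True, False],
        kind="stable")
    return order.iloc[0]


def boundary_direct(position: int, genome_hits: pd.DataFrame, flank: int = FLANK,
                    evalue_cutoff: float = 1e-5) -> dict[str, Boundary]:
    """Direct pipeline: contig vs reference genomes, one call per species.

    single_exon iff the best hit's query range contains [pos-60, pos+60];
    boundary if it overlaps the window without containing it; no_match if
    there is no qualifying hit (or the best hit misses the window entirely).
    """
    calls: dict[str, Boundary] = {}
    lo, hi = position - flank, position + flank
    for species, hits in genome_hits.groupby("species"):
        best = _best_hit(hits, evalue_cutoff)
        if best is None:
            calls[str(species)] = Boundary.NO_MATCH
        elif best.q_start <= lo and hi <= best.q_end:
            calls[str(species)] = Boundary.SINGLE_EXON
        elif best.q_start <= hi and best.q_end >= lo:
            calls[str(species)] = Boundary.BOUNDARY
        else:
            calls[str(species)] = Boundary.NO_MATCH
    return calls


def _project(position: int, hit: pd.Series) -> int | None:
    """Project a contig coordinate into transcript coordinates through a hit."""
    if not (hit.q_start <= position <= hit.q_end):
        return None
    offset = position - hit.q_start
    if hit.s_start <= hit.s_end:
        return int(hit.s_start + offset)
    return int(hit.s_start - offset)


def boundary_projected(position: int, contig_tx_hits: pd.DataFrame,
                       tx_genome_hits: pd.DataFrame, flank: int = FLANK,
                       evalue_cutoff: float = 1e-5) -> dict[str, Boundary]:
    """Projected pipeline: contig -> transcript -> genome exon segments.

    Per species: the best contig-vs-transcriptome hit projects the SNP into
    transcript coordinates; the transcript-vs-own-genome hits' query ranges
    act as exon segments in those coordinates. single_exon iff the 121-bp
    window lies inside one segment; boundary if it overlaps segments but
    crosses an edge; no_match when projection or segments are unavailable.
    """
    calls: dict[str, Boundary] = {}
    for species, hits in contig_tx_hits.groupby("species"):
        best = _best_hit(hits, evalue_cutoff)
        if best is None:
            calls[str(species)] = Boundary.NO_MATCH
            continue
        projected = _project(position, best)
        if projected is None:
            calls[str(species)] = Boundary.NO_MATCH  # reason: unprojected
            continue
        segs = tx_genome_hits[
            (tx_genome_hits.species == species)
            & (tx_genome_hits.query_id == best.subject_id)
            & (tx_genome_hits.e_value < evalue_cutoff)
        ]
        if segs.empty:
            calls[str(species)] = Boundary.NO_MATCH
            continue
        lo, hi = projected - flank, projected + flank
        contained = ((segs.q_start <= lo) & (hi <= segs.q_end)).any()
        overlaps = ((segs.q_start <= hi) & (segs.q_end >= lo)).any()
        if contained:
            calls[str(species)] = Boundary.SINGLE_EXON
        elif overlaps:
            calls[str(species)] = Boundary.BOUNDARY
        else:
            calls[str(species)] = Boundary.NO_MATCH
    return calls


def boundary_consensus(direct_calls: dict[str, Boundary],
                       projected_calls: dict[str, Boundary]) -> BoundaryCall:
    """Conservative consensus: any boundary evidence rejects the SNP.

    Otherwise one single_exon call suffices for single_exon; else no_match.
    supporting_species counts distinct species with a call (from either
    pipeline) equal to the consensus label.
    """
    evidence = [("direct", sp, c.value) for sp, c in sorted(direct_calls.items())]
    evidence += [("projected", sp, c.value) for sp, c in sorted(projected_calls.items())]
    all_calls = list(direct_calls.values()) + list(projected_calls.values())
    if any(c == Boundary.BOUNDARY for c in all_calls):
        label = Boundary.BOUNDARY
    elif any(c == Boundary.SINGLE_EXON for c in all_calls):
        label = Boundary.SINGLE_EXON
    else:
        label = Boundary.NO_MATCH
    species = set(direct_calls) | set(projected_calls)
    support = sum(
        1 for sp in species
        if direct_calls.get(sp) == label or projected_calls.get(sp) == label
    )
    if label == Boundary.NO_MATCH and all(c == Boundary.NO_MATCH for c in all_calls):
        evidence_out = []  # no_match with no positive evidence anywhere
    else:
        evidence_out = evidence
    return BoundaryCall(label, support, evidence_out)


def neighborhood_quality(position: int, pileup: ContigPileup, flank: int = FLANK,
                         min_minor: int = 2) -> int:
    """Count extra variant columns in the assay window.

    nsq = number of non-target columns within [pos-60, pos+60] whose
    second-most-frequent base is seen in >= ``min_minor`` reads. A
    countable surrogate for visual alignment inspection; high values
    suggest paralog co-assembly.
    """
    lo = max(0, position - 1 - flank)
    hi = min(len(pileup.consensus) - 1, position - 1 + flank)
    nsq = 0
    for pos in range(lo, hi + 1):
        if pos == position - 1:
            continue
        bases, _, _, _ = pileup.column(pos)
        if len(bases) < min_minor + 1:
            continue
        vals, counts = np.unique(bases, return_counts=True)
        if len(vals) >= 2 and np.sort(counts)[-2] >= min_minor:
            nsq += 1
    return nsq


_TIER_RANK = {"preferred": 0, "acceptable": 1}


def rank_candidates(candidates: pd.DataFrame, per_contig_max: int = 2,
                    ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Rank within contigs and keep at most ``per_contig_max`` per contig.

    Expects columns: contig_id, position, depth, ads_tier, boundary, nsq.
    Eligible rows need a full window (flank_ok), a non-reject non-null ADS
    tier and no boundary call. Order: preferred ADS before acceptable, then
    ascending nsq, then descending depth, then ascending position. Returns
    (table with 'stage' column, funnel counts). Stages partition the input:
    terminal, ads_missing, ads_reject, boundary_reject, not_ranked, selected.
    """
    df = candidates.copy()
    stage = np.full(len(df), "", dtype=object)
    flank_ok = df["flank_ok"].to_numpy(dtype=bool)
    stage[~flank_ok] = "terminal"
    tier = df["ads_tier"].to_numpy(dtype=object)
    live = flank_ok
    stage[live & pd.isna(tier)] = "ads_missing"
    stage[live & (tier == "reject")] = "ads_reject"
    live = live & ~pd.isna(tier) & (tier != "reject")
    boundary = df["boundary"].astype(str).to_numpy()
    stage[live & (boundary == Boundary.BOUNDARY.value)] = "boundary_reject"
    live = live & (boundary != Boundary.BOUNDARY.value)
    df["_live"] = live
    selected_idx: list[int] = []
    for _, group in df[df["_live"]].groupby("contig_id", sort=False):
        order = group.assign(
            _tier=[_TIER_RANK[t] for t in group.ads_tier],
        ).sort_values(by=["_tier", "nsq", "depth", "position"],
                      ascending=[True, True, False, True], kind="stable")
        selected_idx.extend(order.index[:per_contig_max])
    is_sel = df.index.isin(selected_idx)
    stage[df["_live"].to_numpy() & is_sel] = "selected"
    stage[df["_live"].to_numpy() & ~is_sel] = "not_ranked"
    df = df.drop(columns="_live")
    df["stage"] = stage
    funnel = {s: int((stage == s).sum())
              for s in ["terminal", "ads_missing", "ads_reject", "boundary_reject",
                        "not_ranked", "selected"]}
    return df, funnel


def panel_table(selected: pd.DataFrame) -> pd.DataFrame:
    """Selected panel with the assay window in bracketed-allele style."""
    from .io import format_bracketed_assay

    rows = []
    for row in selected.itertuples():
        rows.append({
            "contig_id": row.contig_id, "position": row.position,
            "alleles": f"{row.major_allele}/{row.minor_allele}",
            "assay_sequence": format_bracketed_assay(
                row.assay_region, row.major_allele, row.minor_allele),
            "ads": row.ads, "ads_tier": row.ads_tier, "boundary": row.boundary,
            "nsq": row.nsq, "depth": row.depth,
        })
    return pd.DataFrame(rows)
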