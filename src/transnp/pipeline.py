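"""End-to-end orchestration and the funnel accounting report.

The funnel report records, for every stage, how many items entered, how
many left, and why the rest were removed; stage chains must be contiguous
(one stage's output count is the next one's input) so the report can be
audited by pure arithmetic. Percentages are always recomputed from the
stored integer counts — truncation at one decimal by default, half-up
rounding as an option — and raw counts are always printed alongside so the
style never hides data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import pandas as pd

from . import readprep, mapping, snpcall, assaydesign, msat as msat_mod
from .simulate import SimConfig, generate_transcriptome, simulate_reads


@dataclass
class FunnelStage:
    stage: str
    n_in: int
    n_out: int
    removed: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_in != self.n_out + sum(self.removed.values()):
            raise ValueError(f"stage {self.stage}: in != out + removed")


class FunnelReport:
    """Ordered, conservation-checked stage accounting."""

    def __init__(self, seed: int | None = None):
        self.seed = seed
        self.stages: list[FunnelStage] = []
        self._chains: dict[str, list[FunnelStage]] = {}

    def add(self, stage: str, n_in: int, n_out: int,
            removed: dict[str, int] | None = None, chain: str = "main") -> None:
        st = FunnelStage(stage, n_in, n_out, dict(removed or {}))
        prev = self._chains.get(chain)
        if prev and prev[-1].n_out != n_in:
            raise ValueError(
                f"funnel chain '{chain}' broken at {stage}: "
                f"{prev[-1].n_out} != {n_in}")
        self._chains.setdefault(chain, []).append(st)
        self.stages.append(st)

    def percentage(self, numerator_stage: str, denominator_stage: str,
                   mode: str = "truncate", what: str = "removed") -> float:
        num_stage = self._find(numerator_stage)
        den_stage = self._find(denominator_stage)
        num = (sum(num_stage.removed.values()) if what == "removed"
               else num_stage.n_out)
        return funnel_percentage(num, den_stage.n_in, mode=mode)

    def _find(self, name: str) -> FunnelStage:
        for st in self.stages:
            if st.stage == name:
                return st
        raise KeyError(name)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "stages": [
                {"stage": s.stage, "in": s.n_in, "out": s.n_out,
                 "removed": s.removed}
                for s in self.stages
            ],
        }

    def to_json(self, path) -> None:
        with open(str(path), "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"stage": s.stage, "in": s.n_in, "out": s.n_out,
                 "removed": sum(s.removed.values()),
                 "reasons": ";".join(f"{k}={v}" for k, v in s.removed.items())}
                for s in self.stages]
        return pd.DataFrame(rows)


def funnel_percentage(numerator: int, denominator: int, mode: str = "truncate",
                      decimals: int = 1) -> float:
    """100 * numerator / denominator at fixed precision.

    ``truncate`` cuts toward zero at ``decimals`` places (the style that
    reproduces most of the published worked examples); ``half_up`` is
    conventional commercial rounding. Integer arithmetic, no cached floats.
    """
    if denominator == 0:
        raise ZeroDivisionError("empty denominator stage")
    scale = 10 ** decimals
    if mode == "truncate":
        return (100 * scale * numerator // denominator) / scale
    if mode == "half_up":
        frac = Decimal(100 * numerator) / Decimal(denominator)
        q = Decimal(1).scaleb(-decimals)
        return float(frac.quantize(q, rounding=ROUND_HALF_UP))
    raise ValueError("mode must be 'truncate' or 'half_up'")


def run_discovery(config: SimConfig,
                  params: snpcall.SiteModelParams | None = None,
                  max_mismatch: int = 0, run_msat: bool = True) -> dict:
    """Synthetic end-to-end discovery run: simulate -> prep -> map -> call ->
    select (with the non-Illumina proxy design score) -> repeat screen.

    Returns a dict with the intermediate products, the candidate and
    selected-panel tables, and the funnel report. Deterministic given the
    config seed.
    """
    params = params or snpcall.SiteModelParams()
    report = FunnelReport(seed=config.seed)
    transcripts, truth = generate_transcriptome(config)
    reads, origin = simulate_reads(transcripts, truth, config)
    barcode_map = {bc: ind for ind, bc in config.barcodes().items()}

    assigned, unassigned, demux_counts = readprep.demultiplex(
        reads, barcode_map, max_mismatch=max_mismatch)
    report.add("demultiplex", demux_counts.n_in, demux_counts.n_kept,
               demux_counts.removed)
    kept, removed_short, len_counts = readprep.length_quality_filter(assigned)
    report.add("length_filter", len_counts.n_in, len_counts.n_kept,
               len_counts.removed)

    placements, unplaced = mapping.map_reads(kept, transcripts)
    report.add("mapping", len(kept), len(placements),
               {"unplaced": len(unplaced)} if unplaced else {})
    pileups = mapping.build_pileup(placements, transcripts,
                                   {r.id: r for r in kept})
    candidates, call_summary = snpcall.call_snps(pileups, params)
    report.add("snp_call", call_summary["sites_scanned"], len(candidates),
               {"depth": call_summary["fail_depth"],
                "minor_count": call_summary["fail_minor_count"],
                "posterior": call_summary["fail_posterior"],
                "single_individual": call_summary["fail_single_individual"]},
               chain="sites")

    enriched = candidates.copy()
    flank_ok, regions, ads_scores, nsqs = [], [], [], []
    for row in candidates.itertuples():
        flanks = assaydesign.extract_flanks(
            row.position, transcripts[row.contig_id], row.major_allele,
            row.minor_allele)
        flank_ok.append(flanks is not None)
        regions.append(flanks["assay_region"] if flanks else "")
        ads_scores.append(assaydesign.ads_proxy(flanks["assay_region"])
                          if flanks else float("nan"))
        nsqs.append(assaydesign.neighborhood_quality(
            row.position, pileups[row.contig_id]))
    enriched["flank_ok"] = flank_ok
    enriched["assay_region"] = regions
    enriched["ads"] = ads_scores
    enriched["ads_tier"] = [assaydesign.ads_tier(a) for a in ads_scores]
    enriched["boundary"] = assaydesign.Boundary.NO_MATCH.value
    enriched["supporting_species"] = 0
    enriched["nsq"] = nsqs
    ranked, funnel_counts = assaydesign.rank_candidates(enriched)
    n_cand = len(ranked)
    report.add("assay_selection", n_cand, funnel_counts["selected"],
               {k: v for k, v in funnel_counts.items() if k != "selected" and v},
               chain="candidates")

    result = {
        "transcripts": transcripts, "truth": truth, "origin": origin,
        "reads": reads, "assigned": assigned, "unassigned": unassigned,
        "placements": placements, "unplaced": unplaced, "pileups": pileups,
        "candidates": candidates, "call_summary": call_summary,
        "ranked": ranked,
        "selected": ranked[ranked.stage == "selected"].reset_index(drop=True),
        "report": report,
    }
    if run_msat:
        loci = msat_mod.find_repeats(transcripts)
        loci, msat_summary = msat_mod.flank_check(loci, transcripts)
        result["msat_loci"] = loci
        result["msat_summary"] = msat_summary
    return result
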