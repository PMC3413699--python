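"""Intron-exon boundary screening and per-contig candidate ranking.

Builds toy alignment records for one SNP-bearing contig: against one
reference genome the best hit truncates inside the 121-bp assay window
(boundary), against another it contains the window (single exon). The
conservative consensus rejects on any boundary evidence — a splice
junction inside the window would break genomic-DNA genotyping of a
cDNA-derived marker.
"""

import pandas as pd

from transnp import boundary_consensus, boundary_direct, extract_flanks

COLUMNS = ["query_id", "subject_id", "pct_identity", "align_length", "mismatches",
           "gap_opens", "q_start", "q_end", "s_start", "s_end", "e_value",
           "bit_score", "species"]


def hit(species, q_start, q_end, e_value=1e-30):
    return dict(zip(COLUMNS, ["contig1", "chr5", 96.0, q_end - q_start + 1, 3, 0,
                              q_start, q_end, 1000, 1000 + q_end - q_start,
                              e_value, 250.0, species]))


snp_position = 250
hits = pd.DataFrame([
    hit("stickleback", 1, 280),       # ends 30 bp past the SNP: boundary
    hit("medaka", 150, 500),          # contains [190, 310]: single exon
    hit("zebrafish", 1, 500, 0.01),   # not significant at 1e-5: no match
])

calls = boundary_direct(snp_position, hits)
for species, call in sorted(calls.items()):
    print(f"{species:12s} -> {call.value}")

consensus = boundary_consensus(calls, {})
print(f"\nconsensus: {consensus.call.value} "
      f"({consensus.supporting_species} supporting species)")
print("any boundary evidence rejects the SNP from the panel\n")

contig = "ACGT" * 200
flanks = extract_flanks(snp_position, contig, "A", "G")
print(f"assay window: {len(flanks['assay_region'])} bp, "
      f"SNP at the central position")
print(f"terminal check: SNP at position 60 -> "
      f"{extract_flanks(60, contig, 'A', 'G')} (rejected, flank too short)")
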