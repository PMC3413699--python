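"""Screening contigs for microsatellites and primer-ready flanks.

Plants perfect tandem repeats of different motif sizes into random
contigs, detects them (primitive motifs, >= 4 units, homopolymers
excluded), checks flank sufficiency for primer design, and prints the
motif-length by unit-count census.
"""

import numpy as np

from transnp import find_repeats, flank_check, repeat_summary

rng = np.random.default_rng(11)


def random_seq(n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


contigs = {}
for i, (motif, units) in enumerate([("AC", 6), ("AGC", 12), ("GATA", 4),
                                    ("AAGGC", 5), ("ACGTAG", 21)]):
    contigs[f"contig{i}"] = random_seq(150) + motif * units + random_seq(150)
contigs["edge"] = "AT" * 8 + random_seq(300)          # repeat at the contig end
contigs["plain"] = random_seq(400)                    # no repeat planted

loci = find_repeats(contigs)
loci, summary = flank_check(loci, contigs, min_flank=50)
for l in loci:
    print(f"{l.contig_id:8s} {l.start:4d}-{l.end:<4d} ({l.motif})x{l.n_units}"
          f"  primer_ready={l.primer_ready}")

print(f"\n{summary['n_loci']} loci, {summary['primer_ready']} primer-ready "
      f"({100 * summary['fraction_ready']:.0f}%)")
print("\ncensus (motif length x unit-count bin):")
print(repeat_summary(loci).to_string(index=False))
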