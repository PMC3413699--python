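"""The Bayesian polymorphism posterior on hand-built pileup columns.

Shows how the posterior responds to minor-allele support at a fixed
depth: with a per-site polymorphism prior of 0.003, two discordant reads
out of twenty are still best explained as sequencing error, while three
or more flip the verdict.
"""

import numpy as np

from transnp import polymorphism_posterior

for n_minor in range(0, 6):
    column = "A" * (20 - n_minor) + "G" * n_minor
    bases = np.frombuffer(column.encode(), dtype=np.uint8)
    eprobs = np.full(20, 0.01)
    post, pair, _ = polymorphism_posterior(bases, eprobs)
    verdict = "called" if post >= 0.5 and n_minor >= 2 else "not called"
    print(f"{20 - n_minor:2d} x A + {n_minor} x G (e=0.01): "
          f"posterior = {post:8.3g}  -> {verdict}")

print("\nAt shallow depth the same minor count is stronger evidence:")
bases = np.frombuffer(b"AAGG", dtype=np.uint8)
post, pair, _ = polymorphism_posterior(bases, np.full(4, 0.01))
print(f" 2 x A + 2 x G at depth 4: posterior = {post:.3f} (alleles {pair})")
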