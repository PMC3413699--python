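"""Predicting assay success with the two-step logistic validation model.

Simulates a validated panel whose conversion depends positively on the
design score and whose polymorphism degrades with neighbourhood sequence
noise, then recovers both with backward-eliminated binomial logistic
regressions (terms with Wald p >= 0.10 are dropped sequentially).
"""

import numpy as np
import pandas as pd

from transnp import PREDICTOR_TERMS, backward_eliminate
from transnp.valmodel import simulate_validation_outcomes

rng = np.random.default_rng(7)
n = 1536   # one genotyping plate worth of assays
table = pd.DataFrame({
    "asc_ind_reads": rng.integers(2, 9, n).astype(float),
    "n_reads_at_snp": rng.integers(4, 40, n).astype(float),
    "n_minor_reads": rng.integers(2, 12, n).astype(float),
    "asc_ind_minor": rng.integers(2, 8, n).astype(float),
    "ads": rng.uniform(0.4, 1.0, n),
    "boundary_single": rng.binomial(1, 0.2, n).astype(float),
    # a handful of boundary-flagged assays slipped through manual review
    "boundary_intron": rng.binomial(1, 0.05, n).astype(float),
    "n_supporting_species": rng.integers(0, 5, n).astype(float),
    "nsq": rng.integers(0, 12, n).astype(float),
})
table["minor_freq"] = table.n_minor_reads / table.n_reads_at_snp
table = simulate_validation_outcomes(table, seed=7)

conv_fit, conv_trace = backward_eliminate(table, "conversion", PREDICTOR_TERMS)
print("conversion model (B, Wald, df, P):")
print(conv_fit.table().to_string())
print(f"model chi2 = {conv_fit.model_chi2:.2f}, df = {conv_fit.model_df}, "
      f"p = {conv_fit.model_p:.3g}; removed {len(conv_trace)} terms\n")

poly = table[table.conversion == 1]
poly_fit, _ = backward_eliminate(poly, "polymorphism", PREDICTOR_TERMS)
print("polymorphism model (converted assays only):")
print(poly_fit.table().to_string())
print("\nexpected recovery: positive design-score effect on conversion, "
      "negative neighbourhood-noise effect on polymorphism")
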