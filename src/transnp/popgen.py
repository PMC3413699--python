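"""Panel-evaluation statistics for a genotyped biallelic SNP panel.

Covers the minor-allele-frequency spectrum (with the L-shape diagnostic
for ascertainment bias), observed and expected heterozygosity, exact and
Monte-Carlo Hardy–Weinberg tests, permutation tests of genotypic linkage
disequilibrium, and Benjamini–Yekutieli FDR control (valid under arbitrary
dependence).

Genotypes are minor/alt-allele dosages 0/1/2 with NaN for missing; tests
drop missing data test-wise. Samples with call rate below 0.8 are flagged
rather than silently removed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln


@dataclass
class GenotypeMatrix:
    """Samples x biallelic loci with population labels.

    ``genotypes``: DataFrame of dosages (0/1/2, NaN missing); ``populations``:
    per-sample labels aligned to the index.
    """

    genotypes: pd.DataFrame
    populations: pd.Series

    def __post_init__(self) -> None:
        if not self.genotypes.index.equals(self.populations.index):
            raise ValueError("population labels must align with sample index")
        vals = self.genotypes.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("genotypes must be dosages 0/1/2 or missing")

    @property
    def call_rate(self) -> pd.Series:
        return self.genotypes.notna().mean(axis=1)

    def low_call_samples(self, threshold: float = 0.8) -> list[str]:
        cr = self.call_rate
        return list(cr.index[cr < threshold])

    def locus_counts(self, locus: str, population: str | None = None,
                     ) -> tuple[int, int, int]:
        g = self.genotypes[locus]
        if population is not None:
            g = g[self.populations == population]
        g = g.dropna()
        return (int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum()))


def maf_spectrum(matrix: GenotypeMatrix, bin_width: float = 0.05,
                 ) -> tuple[pd.DataFrame, bool]:
    """Binned minor-allele-frequency spectrum and the L-shape flag.

    MAF per locus = min(p, 1-p) over non-missing genotypes. Bins are
    [0, 0.05), ..., [0.45, 0.5]. The flag is True iff the lowest bin is
    modal — the signature of a panel that has retained its rare variants.
    """
    g = matrix.genotypes.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        p = np.nanmean(g, axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    maf = maf[~np.isnan(maf)]
    edges = np.arange(0.0, 0.5 + bin_width, bin_width)
    # clip folds exact-0.5 values into the top bin
    counts, _ = np.histogram(np.clip(maf, 0, 0.5 - 1e-12), bins=edges)
    labels = [f"[{edges[i]:.2f},{edges[i+1]:.2f})" for i in range(len(edges) - 1)]
    spectrum = pd.DataFrame({"bin": labels, "count": counts})
    l_shape = bool(counts.size and counts[0] == counts.max() and counts[0] > 0)
    return spectrum, l_shape


def heterozygosity(matrix: GenotypeMatrix, by_population: bool = False,
                   unbiased: bool = False) -> pd.DataFrame:
    """Observed (H_O) and expected (H_E = 2p(1-p)) heterozygosity per locus.

    ``unbiased=True`` applies the small-sample factor n/(n-1) to H_E
    (off by default). With ``by_population`` one row per (locus,
    population).
    """
    frames = []
    groups = ([(None, matrix.genotypes)] if not by_population else
              [(p, matrix.genotypes[matrix.populations == p])
               for p in sorted(matrix.populations.unique())])
    for pop, genos in groups:
        g = genos.to_numpy(dtype=float)
        n = np.sum(~np.isnan(g), axis=0).astype(float)
        with np.errstate(invalid="ignore"):
            p_freq = np.nansum(g, axis=0) / (2.0 * np.where(n > 0, n, np.nan))
            h_o = np.nansum(g == 1, axis=0) / np.where(n > 0, n, np.nan)
        h_e = 2.0 * p_freq * (1.0 - p_freq)
        if unbiased:
            with np.errstate(invalid="ignore", divide="ignore"):
                h_e = np.where(n > 1, h_e * n / (n - 1.0), np.nan)
        df = pd.DataFrame({"locus": genos.columns, "n": n.astype(int),
                           "H_O": h_o, "H_E": h_e})
        if pop is not None:
            df.insert(0, "population", pop)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def _levene_log_prob(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Log conditional probability of a genotype table given n and allele
    counts (Levene distribution)."""
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    return (gammaln(n + 1) - gammaln(n_aa + 1) - gammaln(n_ab + 1) - gammaln(n_bb + 1)
            + n_ab * np.log(2.0)
            + gammaln(n_a + 1) + gammaln(n_b + 1) - gammaln(2 * n + 1))


def hwe_exact(n_aa: int, n_ab: int, n_bb: int, mode: str = "exact",
              iterations: int = 10_000, batches: int = 20,
              seed: int | None = None) -> dict:
    """Exact (or Monte-Carlo) test of Hardy–Weinberg proportions.

    Exact mode enumerates every heterozygote count compatible with the
    allele counts (Levene conditional distribution) and sums the
    probabilities of tables no more probable than the observed one
    (two-sided). MC mode estimates the same tail by shuffling the alleles
    into random diploids, in ``batches`` batches whose spread gives a
    standard error. Monomorphic tables are skipped (p None, skipped True).
    """
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    if n == 0 or n_a == 0 or n_a == 2 * n:
        return {"p": None, "skipped": True, "reason": "monomorphic"}
    obs_logp = _levene_log_prob(n_aa, n_ab, n_bb)
    if mode == "exact":
        p = 0.0
        for h in _het_range(n, n_a):
            aa = (n_a - h) // 2
            bb = n - aa - h
            lp = _levene_log_prob(aa, h, bb)
            if lp <= obs_logp + 1e-12:
                p += float(np.exp(lp))
        return {"p": min(p, 1.0), "skipped": False, "se": 0.0}
    if mode != "mc":
        raise ValueError("mode must be 'exact' or 'mc'")
    rng = np.random.default_rng(seed)
    alleles = np.concatenate([np.ones(n_a, dtype=np.int8),
                              np.zeros(2 * n - n_a, dtype=np.int8)])
    per_batch = iterations // batches
    batch_ps = []
    for _ in range(batches):
        hits = 0
        for _ in range(per_batch):
            rng.shuffle(alleles)
            pairs = alleles.reshape(-1, 2).sum(axis=1)
            h = int((pairs == 1).sum())
            aa = (n_a - h) // 2
            bb = n - aa - h
            if _levene_log_prob(aa, h, bb) <= obs_logp + 1e-12:
                hits += 1
        batch_ps.append(hits / per_batch)
    batch_ps = np.asarray(batch_ps)
    se = float(batch_ps.std(ddof=1) / np.sqrt(batches))
    return {"p": float(batch_ps.mean()), "skipped": False, "se": se}


def _het_range(n: int, n_a: int):
    """All heterozygote counts compatible with n diploids and n_a copies."""
    n_b = 2 * n - n_a
    h_max = min(n_a, n_b)
    h_min = n_a % 2
    return range(h_min, h_max + 1, 2)


def hwe_enumeration_total(n: int, n_a: int) -> float:
    """Sum of the Levene distribution over all tables (should be 1)."""
    total = 0.0
    for h in _het_range(n, n_a):
        aa = (n_a - h) // 2
        bb = n - aa - h
        total += float(np.exp(_levene_log_prob(aa, h, bb)))
    return total


def _g_statistic(table: np.ndarray) -> float:
    """Log-likelihood-ratio statistic of independence on a contingency table."""
    table = table.astype(float)
    total = table.sum()
    if total == 0:
        return 0.0
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(table > 0, table * np.log(table / expected), 0.0)
    return float(2.0 * terms.sum())


def ld_test(g1: pd.Series | np.ndarray, g2: pd.Series | np.ndarray,
            populations: pd.Series | None = None, mc_iterations: int = 10_000,
            batches: int = 20, seed: int = 0) -> dict:
    """Permutation test of genotypic linkage disequilibrium for a locus pair.

    The G statistic of the 3x3 genotype contingency table (summed over
    populations when labels are given) is compared with its null
    distribution obtained by permuting one locus's genotypes across samples
    within population. The pair is canonicalized before drawing the seeded
    permutation stream, so the p-value is exactly invariant to swapping the
    loci. p uses the add-one rule (count + 1) / (N + 1); batching yields a
    standard error.
    """
    a = np.asarray(g1, dtype=float)
    b = np.asarray(g2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("loci must be typed on the same samples")
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    pops = (np.asarray(populations)[keep] if populations is not None
            else np.zeros(len(a), dtype=int))
    # canonical order: permutation stream must not depend on argument order
    if tuple(b) < tuple(a):
        a, b = b, a
    groups = [np.nonzero(pops == p)[0] for p in np.unique(pops)]

    def observed_g(bb: np.ndarray) -> float:
        g = 0.0
        for idx in groups:
            table = np.zeros((3, 3))
            np.add.at(table, (a[idx].astype(int), bb[idx].astype(int)), 1)
            g += _g_statistic(table)
        return g

    g_obs = observed_g(b)
    rng = np.random.default_rng(seed)
    per_batch = mc_iterations // batches
    batch_hits = []
    b_perm = b.copy()
    for _ in range(batches):
        hits = 0
        for _ in range(per_batch):
            for idx in groups:
                b_perm[idx] = b[idx][rng.permutation(len(idx))]
            if observed_g(b_perm) >= g_obs - 1e-12:
                hits += 1
        batch_hits.append(hits)
    total = int(np.sum(batch_hits))
    n_perm = per_batch * batches
    p = (total + 1) / (n_perm + 1)
    fracs = np.asarray(batch_hits) / per_batch
    se = float(fracs.std(ddof=1) / np.sqrt(batches))
    return {"p": float(p), "g": g_obs, "se": se, "n_permutations": n_perm}


def by_fdr(p_values, alpha: float = 0.05) -> np.ndarray:
    """Benjamini–Yekutieli step-up FDR control under arbitrary dependence.

    Sort p ascending; with c(m) = sum_{i=1}^m 1/i, reject all p_(k) for
    k <= max{k : p_(k) <= k * alpha / (m * c(m))}. Returns a boolean flag
    array aligned with the input order.
    """
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    if m == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    c_m = np.sum(1.0 / np.arange(1, m + 1))
    order = np.argsort(p, kind="stable")
    thresholds = np.arange(1, m + 1) * alpha / (m * c_m)
    passing = np.nonzero(p[order] <= thresholds)[0]
    flags = np.zeros(m, dtype=bool)
    if passing.size:
        k_max = passing.max()
        flags[order[: k_max + 1]] = True
    return flags


def hwe_table(matrix: GenotypeMatrix, alpha: float = 0.05, mode: str = "exact",
              seed: int = 0) -> pd.DataFrame:
    """Per-locus, per-population HWE tests with BY-FDR flags.

    Population-monomorphic loci are skipped, so the number of performed
    tests is data dependent.
    """
    rows = []
    for pop in sorted(matrix.populations.unique()):
        for locus in matrix.genotypes.columns:
            n_aa, n_ab, n_bb = matrix.locus_counts(locus, pop)
            res = hwe_exact(n_aa, n_ab, n_bb, mode=mode, seed=seed)
            if res.get("skipped"):
                continue
            rows.append({"locus": locus, "population": pop, "p_value": res["p"]})
    df = pd.DataFrame(rows, columns=["locus", "population", "p_value"])
    if len(df):
        df["fdr_significant"] = by_fdr(df.p_value.to_numpy(), alpha)
    else:
        df["fdr_significant"] = pd.Series(dtype=bool)
    return df
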