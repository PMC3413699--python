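"""Bayesian detection of candidate SNPs from read pileups.

Site model
----------
Each pileup column is scored for polymorphism with a Bayesian two-allele
model. Per-read likelihoods use the phred-derived error probability e_i:
P(b_i | true base a) = 1 - e_i if b_i == a, else e_i / 3. The monomorphic
hypothesis puts prior (1 - theta) / 4 on each base a with likelihood
prod_i P(b_i | a). The polymorphic hypothesis puts prior theta / 6 on each
unordered base pair {a1, a2}, with the allele fraction f marginalised over
a uniform grid {0.05, 0.10, ..., 0.95}:

    L({a1,a2}) = mean_f prod_i [ f P(b_i|a1) + (1-f) P(b_i|a2) ].

The posterior probability of polymorphism is the ratio of the summed
polymorphic terms to the total. theta defaults to 0.003, the per-site
prior polymorphism probability used for the discovery run.

Candidate sites must then pass hard filters, in order: total depth >= 4,
minor-allele reads >= 2, posterior >= 0.5 (a MAP decision rule), and the
minor allele must be seen in reads from at least two individuals
(single-individual variants are likely errors or private noise and would
bias the panel).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mapping import ContigPileup

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_PAIRS = [(i, j) for i in range(4) for j in range(i + 1, 4)]


@dataclass
class SiteModelParams:
    theta: float = 0.003
    posterior_threshold: float = 0.5
    min_depth: int = 4
    min_minor_reads: int = 2
    min_individuals_with_minor: int = 2
    f_grid: np.ndarray = field(default_factory=lambda: np.arange(1, 20) * 0.05)

    def __post_init__(self) -> None:
        if not 0.0 < self.theta < 1.0:
            raise ValueError("theta must lie in (0, 1)")
        if min(self.posterior_threshold, self.min_depth, self.min_minor_reads,
               self.min_individuals_with_minor) <= 0:
            raise ValueError("thresholds must be positive")


def _column_base_idx(bases: np.ndarray) -> tuple[np.ndarray, int]:
    """Map an ASCII uint8 base column to indices 0..3, dropping non-ACGT."""
    if bases.dtype.kind == "U":
        bases = np.frombuffer("".join(bases).encode(), dtype=np.uint8)
    idx = np.full(len(bases), -1, dtype=np.int64)
    for i, b in enumerate(_BASES):
        idx[bases == b] = i
    skipped = int(np.count_nonzero(idx < 0))
    return idx[idx >= 0], skipped


def polymorphism_posterior(bases: np.ndarray, eprobs: np.ndarray,
                           params: SiteModelParams | None = None,
                           ) -> tuple[float, tuple[str, str], int]:
    """Posterior probability that a column is polymorphic.

    ``bases``: ASCII uint8 (or single-char unicode) array; ``eprobs``:
    matching per-read error probabilities in (0, 1). Returns (posterior,
    best unordered allele pair as characters, number of skipped non-ACGT
    entries). The best pair is the maximum-likelihood polymorphic pair.
    """
    params = params or SiteModelParams()
    raw = np.asarray(bases)
    if raw.dtype.kind == "U":
        raw = np.frombuffer("".join(raw).encode(), dtype=np.uint8)
    eprobs = np.asarray(eprobs, dtype=float)
    usable = np.isin(raw, _BASES)
    skipped = int(np.count_nonzero(~usable))
    idx, _ = _column_base_idx(raw[usable])
    eprobs = eprobs[usable]
    if len(idx) == 0:
        raise ValueError("column has no usable bases")
    if np.any(eprobs <= 0) or np.any(eprobs >= 1):
        raise ValueError("error probabilities must lie in (0, 1)")
    # P[i, a]: linear per-read likelihoods
    p = np.where(idx[:, None] == np.arange(4)[None, :],
                 (1.0 - eprobs)[:, None], (eprobs / 3.0)[:, None])
    logp = np.log(p)
    mono_loglik = logp.sum(axis=0)                       # (4,)
    fg = params.f_grid[None, :]                          # (1, F)
    pair_logliks = np.empty(len(_PAIRS))
    for k, (a1, a2) in enumerate(_PAIRS):
        mix = fg * p[:, a1, None] + (1.0 - fg) * p[:, a2, None]  # (n, F)
        per_f = np.log(mix).sum(axis=0)                  # (F,)
        pair_logliks[k] = _logsumexp(per_f) - np.log(len(params.f_grid))
    log_mono = _logsumexp(mono_loglik) + np.log((1.0 - params.theta) / 4.0)
    log_poly = _logsumexp(pair_logliks) + np.log(params.theta / 6.0)
    posterior = float(np.exp(log_poly - np.logaddexp(log_poly, log_mono)))
    best = _PAIRS[int(np.argmax(pair_logliks))]
    pair = (chr(_BASES[best[0]]), chr(_BASES[best[1]]))
    return posterior, pair, skipped


def _logsumexp(x: np.ndarray) -> float:
    m = np.max(x)
    return float(m + np.log(np.sum(np.exp(x - m))))


def apply_hard_filters(depth: int, minor_count: int, posterior: float,
                       params: SiteModelParams) -> tuple[bool, str | None]:
    """Ordered hard filters; first failing reason wins."""
    if depth < params.min_depth:
        return False, "depth"
    if minor_count < params.min_minor_reads:
        return False, "minor_count"
    if posterior < params.posterior_threshold:
        return False, "posterior"
    return True, None


def individual_filter(candidates: pd.DataFrame,
                      params: SiteModelParams | None = None) -> pd.DataFrame:
    """Drop candidates whose minor allele was seen in < 2 individuals."""
    params = params or SiteModelParams()
    keep = candidates.individuals_with_minor >= params.min_individuals_with_minor
    return candidates[keep].reset_index(drop=True)


def _column_counts(bases_idx: np.ndarray) -> np.ndarray:
    return np.bincount(bases_idx, minlength=4)


def call_snps(pileups: dict[str, ContigPileup], params: SiteModelParams | None = None,
              ) -> tuple[pd.DataFrame, dict]:
    """Scan every pileup column and emit the candidate-SNP table.

    Returns (candidates, summary). Candidate columns: contig_id, position
    (1-based), major_allele, minor_allele, depth, minor_count,
    individuals_covering, individuals_with_minor, posterior. The summary
    counts sites scanned, per-reason hard-filter failures, the
    single-individual exclusions and skipped non-ACGT entries.
    """
    params = params or SiteModelParams()
    rows = []
    summary = {"sites_scanned": 0, "fail_depth": 0, "fail_minor_count": 0,
               "fail_posterior": 0, "fail_single_individual": 0,
               "skipped_non_acgt": 0, "called": 0}
    for name, pile in pileups.items():
        depth_arr = pile.depth
        covered = np.nonzero(depth_arr > 0)[0]
        summary["sites_scanned"] += int(len(covered))
        for pos in covered:
            bases, eprobs, _, individuals = pile.column(int(pos))
            idx, skipped = _column_base_idx(bases)
            summary["skipped_non_acgt"] += skipped
            if skipped:
                usable = np.isin(bases, _BASES)
                eprobs = eprobs[usable]
                individuals = individuals[usable]
            depth = len(idx)
            counts = _column_counts(idx)
            order = np.argsort(-counts, kind="stable")
            major_i, minor_i = int(order[0]), int(order[1])
            minor_count = int(counts[minor_i])
            if depth < params.min_depth:
                summary["fail_depth"] += 1
                continue
            if minor_count < params.min_minor_reads:
                summary["fail_minor_count"] += 1
                continue
            posterior, _, _ = polymorphism_posterior(
                bases[np.isin(bases, _BASES)] if skipped else bases, eprobs, params)
            if posterior < params.posterior_threshold:
                summary["fail_posterior"] += 1
                continue
            minor_mask = idx == minor_i
            inds_minor = set(individuals[minor_mask]) - {""}
            inds_cover = set(individuals) - {""}
            rows.append({
                "contig_id": name, "position": int(pos) + 1,
                "major_allele": chr(_BASES[major_i]),
                "minor_allele": chr(_BASES[minor_i]),
                "depth": depth, "minor_count": minor_count,
                "individuals_covering": len(inds_cover),
                "individuals_with_minor": len(inds_minor),
                "posterior": posterior,
            })
    candidates = pd.DataFrame(rows, columns=[
        "contig_id", "position", "major_allele", "minor_allele", "depth",
        "minor_count", "individuals_covering", "individuals_with_minor", "posterior"])
    kept = individual_filter(candidates, params)
    summary["fail_single_individual"] = len(candidates) - len(kept)
    summary["called"] = len(kept)
    return kept, summary
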