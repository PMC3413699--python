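"""Independent brute-force oracles used by the tests.

Everything here is deliberately written in the most naive way possible —
plain loops, linear-scale arithmetic, no sharing of code with the package —
so it can serve as an independent check of the optimised implementations.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"


def posterior_bruteforce(bases: str, eprobs: list[float], theta: float = 0.003,
                         f_grid=None) -> float:
    """Direct evaluation of the polymorphism posterior (linear scale)."""
    if f_grid is None:
        f_grid = [0.05 * i for i in range(1, 20)]

    def p_read(b: str, a: str, e: float) -> float:
        return 1.0 - e if b == a else e / 3.0

    mono = 0.0
    for a in BASES:
        lik = 1.0
        for b, e in zip(bases, eprobs):
            lik *= p_read(b, a, e)
        mono += (1.0 - theta) / 4.0 * lik
    poly = 0.0
    for i in range(4):
        for j in range(i + 1, 4):
            a1, a2 = BASES[i], BASES[j]
            marg = 0.0
            for f in f_grid:
                lik = 1.0
                for b, e in zip(bases, eprobs):
                    lik *= f * p_read(b, a1, e) + (1 - f) * p_read(b, a2, e)
                marg += lik
            poly += theta / 6.0 * marg / len(f_grid)
    return poly / (poly + mono)


def by_fdr_bruteforce(p_values, alpha: float = 0.05) -> np.ndarray:
    """Benjamini–Yekutieli by literal definition, checking every k."""
    p = list(p_values)
    m = len(p)
    if m == 0:
        return np.zeros(0, dtype=bool)
    c_m = sum(1.0 / i for i in range(1, m + 1))
    indexed = sorted(range(m), key=lambda i: p[i])
    k_star = 0
    for rank, i in enumerate(indexed, start=1):
        if p[i] <= rank * alpha / (m * c_m):
            k_star = rank
    flags = np.zeros(m, dtype=bool)
    for rank, i in enumerate(indexed, start=1):
        if rank <= k_star:
            flags[i] = True
    return flags


def find_repeats_bruteforce(seq: str, min_units: int = 4,
                            motif_lengths=range(2, 7)) -> list[tuple[int, int, str, int]]:
    """Naive maximal-perfect-repeat scan; returns (start0, end0_excl, canonical
    motif, units), collapsed greedily by start (longest first) so no two
    reported loci overlap."""
    seq = seq.upper()
    n = len(seq)

    def canonical(m: str) -> str:
        return min(m[i:] + m[:i] for i in range(len(m)))

    def primitive(m: str) -> bool:
        return all(not (len(m) % d == 0 and m == m[:d] * (len(m) // d))
                   for d in range(1, len(m)))

    candidates = []
    for m in motif_lengths:
        for i in range(n - m * min_units + 1):
            motif = seq[i:i + m]
            if not primitive(motif):
                continue
            # leftmost: reject if the run extends to the left
            if i >= 1 and seq[i - 1] == seq[i - 1 + m]:
                continue
            units = 1
            while seq[i + units * m: i + (units + 1) * m] == motif:
                units += 1
            if units >= min_units:
                candidates.append((i, i + units * m, motif, units))
    candidates.sort(key=lambda c: (c[0], -(c[1] - c[0]), len(c[2])))
    out = []
    taken_until = -1
    for start, end, motif, units in candidates:
        if start <= taken_until:
            continue
        out.append((start, end, canonical(motif), units))
        taken_until = end - 1
    return out


def hwe_exact_bruteforce(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact HWE p by enumerating heterozygote counts with factorials."""
    from math import factorial

    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n - n_a

    def prob(h: int) -> float:
        aa = (n_a - h) // 2
        bb = n - aa - h
        return (factorial(n) / (factorial(aa) * factorial(h) * factorial(bb))
                * 2 ** h * factorial(n_a) * factorial(n_b) / factorial(2 * n))

    obs = prob(n_ab)
    total = 0.0
    for h in range(n_a % 2, min(n_a, n_b) + 1, 2):
        p_h = prob(h)
        if p_h <= obs * (1 + 1e-12):
            total += p_h
    return min(total, 1.0)


def six_frame_translate(seq: str) -> dict[int, str]:
    """All six translation frames of a sequence, standard code."""
    from Bio.Seq import Seq

    out = {}
    rc = str(Seq(seq).reverse_complement())
    for k in (1, 2, 3):
        sub = seq[k - 1:]
        out[k] = str(Seq(sub[: len(sub) - len(sub) % 3]).translate())
        sub = rc[k - 1:]
        out[-k] = str(Seq(sub[: len(sub) - len(sub) % 3]).translate())
    return out
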