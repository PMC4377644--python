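"""Independent brute-force oracles used only by the test suite.

Each oracle re-derives a quantity by direct enumeration so the production
code path (scipy tails, Biopython alignment, vectorized EM) can be checked
against an implementation that shares no code with it.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb, inf

import numpy as np

MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 2, -1, -3, -1


def gotoh_local_alignments(
    target: str, query: str
) -> tuple[float, list[dict[int, int]]]:
    """All optimal local alignments under affine-gap scoring.

    Returns the best score and, for every co-optimal alignment, the mapping
    of aligned target positions to query positions. Suitable for short
    fixtures only (full traceback enumeration).
    """
    nt, nq = len(target), len(query)
    M = np.full((nt + 1, nq + 1), -inf)
    X = np.full((nt + 1, nq + 1), -inf)  # gap in query (target consumed)
    Y = np.full((nt + 1, nq + 1), -inf)  # gap in target (query consumed)
    for i in range(1, nt + 1):
        for j in range(1, nq + 1):
            s = MATCH if target[i - 1] == query[j - 1] else MISMATCH
            M[i, j] = s + max(
                0.0, M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]
            )
            X[i, j] = max(M[i - 1, j] + GAP_OPEN, X[i - 1, j] + GAP_EXTEND)
            Y[i, j] = max(M[i, j - 1] + GAP_OPEN, Y[i, j - 1] + GAP_EXTEND)
    best = float(M.max())
    if best <= 0:
        return 0.0, []
    alignments: list[dict[int, int]] = []

    def walk(i: int, j: int, state: str, pairs: list[tuple[int, int]]):
        if state == "M":
            pairs = pairs + [(i - 1, j - 1)]
            prev = max(0.0, M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            if prev == 0.0:
                alignments.append(dict(pairs))
            for st, val in (("M", M[i - 1, j - 1]), ("X", X[i - 1, j - 1]),
                            ("Y", Y[i - 1, j - 1])):
                if val == prev and prev > 0.0:
                    walk(i - 1, j - 1, st, pairs)
        elif state == "X":
            if M[i - 1, j] + GAP_OPEN == X[i, j]:
                walk(i - 1, j, "M", pairs)
            if X[i - 1, j] + GAP_EXTEND == X[i, j]:
                walk(i - 1, j, "X", pairs)
        else:
            if M[i, j - 1] + GAP_OPEN == Y[i, j]:
                walk(i, j - 1, "M", pairs)
            if Y[i, j - 1] + GAP_EXTEND == Y[i, j]:
                walk(i, j - 1, "Y", pairs)

    for i in range(1, nt + 1):
        for j in range(1, nq + 1):
            if M[i, j] == best:
                walk(i, j, "M", [])
    # de-duplicate mappings reached via different traceback orders
    unique = {tuple(sorted(a.items())) for a in alignments}
    return best, [dict(u) for u in unique]


def oracle_realign(read: str, reference: str, site: int) -> str:
    """Exhaustive-enumeration counterpart of realign_read."""
    best, alns = gotoh_local_alignments(reference.upper(), read.upper())
    if not alns:
        return "wildtype"
    ref_base = reference[site].upper()
    for mapping in alns:
        q = mapping.get(site)
        if q is None or read[q].upper() == ref_base:
            return "wildtype"
    return "supports_mutant"


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact P by hypergeometric enumeration, in exact
    rational arithmetic (sum of tables no more probable than observed)."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)

    def pmf(x: int) -> Fraction:
        return Fraction(comb(r1, x) * comb(r2, c1 - x), denom)

    p_obs = pmf(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    total = sum(pmf(x) for x in range(lo, hi + 1) if pmf(x) <= p_obs)
    return float(total)


def grid_mixture_loglik(
    x: np.ndarray, n: np.ndarray, K: int, n_grid: int = 60
) -> float:
    """Best binomial-mixture log-likelihood over a dense parameter grid."""
    from scipy.special import gammaln, logsumexp

    x = np.asarray(x, dtype=float)
    n = np.asarray(n, dtype=float)
    const = gammaln(n + 1) - gammaln(x + 1) - gammaln(n - x + 1)
    ps = np.linspace(0.005, 0.995, n_grid)

    def loglik(p: np.ndarray, lam: np.ndarray) -> float:
        logpmf = (
            const[:, None]
            + x[:, None] * np.log(p)[None, :]
            + (n - x)[:, None] * np.log1p(-p)[None, :]
        )
        return float(logsumexp(logpmf + np.log(lam)[None, :], axis=1).sum())

    if K == 1:
        return max(loglik(np.array([p]), np.array([1.0])) for p in ps)
    if K != 2:
        raise ValueError("grid oracle supports K in {1, 2}")
    lams = np.linspace(0.05, 0.95, 19)
    best = -np.inf
    for p1 in ps:
        for p2 in ps:
            if p2 < p1:
                continue
            for lam in lams:
                ll = loglik(np.array([p1, p2]), np.array([lam, 1 - lam]))
                if ll > best:
                    best = ll
    return best


def binom_sf_direct(k: int, n: int, p: float) -> float:
    """P(X >= k) by direct summation of exact rational pmf terms."""
    total = Fraction(0)
    pf = Fraction(p).limit_denominator(10**12)
    for x in range(k, n + 1):
        total += comb(n, x) * pf**x * (1 - pf) ** (n - x)
    return float(total)
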