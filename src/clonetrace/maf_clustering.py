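"""Coverage-aware binomial mixture clustering of mutant-allele fractions.

Two models are fitted by EM. The *specific* model clusters variants private
to one timepoint: mutant counts X_i ~ Binomial(N_i, p_k) with cluster
centres p_k and mixing weights lambda_k. The *shared* (multiplicative)
model clusters variants present at both timepoints: each cluster has an
independent diagnosis centre and relapse centre and a variant's likelihood
is the product of the two binomial terms. Unlike clustering raw MAF values,
the binomial likelihood weighs each variant by its depth, so a 0.01-MAF
cluster at 800-fold coverage is resolvable from the founder cluster.

The number of clusters K is selected by AIC = 2k - 2 ln L with free
parameter counts k = 2K-1 (specific: K centres, K-1 weights) and
k = 3K-1 (shared: 2K centres, K-1 weights).

Tumour purity is estimated from one timepoint's diploid coding SNVs as
twice the highest cluster centre among centres <= 0.5 — a clonal
heterozygous cluster in a sample of purity rho sits at MAF rho/2, and
centres above 0.5 indicate loci that are not copy-neutral.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

__all__ = [
    "MixtureFit",
    "PuritySummary",
    "fit_specific_mixture",
    "fit_shared_mixture",
    "select_model",
    "estimate_purity",
]

_EPS_P = 1e-6  # centre clamp avoiding degenerate likelihoods
_TOL = 1e-8
_MAX_ITER = 500
_N_RESTARTS = 10


@dataclass(frozen=True)
class MixtureFit:
    """A fitted binomial mixture.

    ``centers`` has shape (K,) for the specific model and (K, 2) —
    diagnosis and relapse columns — for the shared model; clusters are
    ordered by descending (diagnosis) centre. ``responsibilities`` are the
    soft membership probabilities Z_ik; ``assignments`` the hard argmax
    labels. ``loglik_trace`` records the EM objective per iteration of the
    winning restart (non-decreasing by construction of EM).
    """

    model: str
    K: int
    centers: np.ndarray
    weights: np.ndarray
    responsibilities: np.ndarray
    assignments: np.ndarray
    loglik: float
    aic: float
    n_variants: int
    loglik_trace: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("mixing weights must sum to 1")
        row_sums = self.responsibilities.sum(axis=1)
        if np.any(np.abs(row_sums - 1.0) > 1e-9):
            raise ValueError("responsibilities must sum to 1 per variant")

    def summary(self) -> dict:
        return {
            "model": self.model,
            "K": self.K,
            "centers": np.asarray(self.centers).tolist(),
            "weights": self.weights.tolist(),
            "loglik": self.loglik,
            "aic": self.aic,
            "n_variants": self.n_variants,
        }


@dataclass(frozen=True)
class PuritySummary:
    """Tumour purity estimated from MAF cluster centres at one timepoint."""

    sample: str
    cluster_centers: tuple[float, ...]
    purity: float

    def __post_init__(self) -> None:
        if not (0.0 < self.purity <= 1.0):
            raise ValueError("purity must lie in (0, 1]")


def _n_params(model: str, K: int) -> int:
    return 2 * K - 1 if model == "specific" else 3 * K - 1


def _check_counts(x: np.ndarray, n: np.ndarray) -> None:
    if x.size == 0:
        raise ValueError("empty input: no variants to cluster")
    if np.any(n < 1):
        raise ValueError("all total read counts must be >= 1")
    if np.any((x < 0) | (x > n)):
        raise ValueError("mutant counts must lie in [0, total]")


def _log_binom_const(x: np.ndarray, n: np.ndarray) -> np.ndarray:
    return gammaln(n + 1) - gammaln(x + 1) - gammaln(n - x + 1)


def _init_centers(
    maf: np.ndarray, K: int, rng: np.random.Generator, restart: int
) -> np.ndarray:
    """Quantile-based centres; restarts beyond the first are jittered."""
    qs = (np.arange(K) + 0.5) / K
    centers = np.quantile(maf, qs)
    if restart > 0:
        centers = centers + rng.normal(0.0, 0.03, size=K)
    return np.clip(centers, _EPS_P, 1.0 - _EPS_P)


def _em_specific_batch(
    x: np.ndarray,
    n: np.ndarray,
    p0: np.ndarray,  # (R, K): one centre vector per restart
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[float]]:
    """Run R jittered EM restarts simultaneously; return the best one."""
    R, K = p0.shape
    const = _log_binom_const(x, n)[None, :, None]
    p = p0.copy()
    lam = np.full((R, K), 1.0 / K)
    traces: list[np.ndarray] = []
    prev = np.full(R, -np.inf)
    for _ in range(_MAX_ITER):
        joint = (
            const
            + x[None, :, None] * np.log(p)[:, None, :]
            + (n - x)[None, :, None] * np.log1p(-p)[:, None, :]
            + np.log(lam)[:, None, :]
        )
        row_ll = logsumexp(joint, axis=2)  # (R, n)
        ll = row_ll.sum(axis=1)  # (R,)
        traces.append(ll)
        z = np.exp(joint - row_ll[:, :, None])
        lam = np.maximum(z.mean(axis=1), 1e-12)
        lam /= lam.sum(axis=1, keepdims=True)
        denom = np.einsum("rnk,n->rk", z, n)
        num = np.einsum("rnk,n->rk", z, x)
        p = np.where(denom > 0, num / np.maximum(denom, 1e-300), p)
        p = np.clip(p, _EPS_P, 1.0 - _EPS_P)
        if np.all(np.abs(ll - prev) < _TOL):
            break
        prev = ll
    best = int(np.argmax(traces[-1]))
    pb, lamb = p[best], lam[best]
    z = _posterior_specific(x, n, pb, lamb)
    trace = [float(t[best]) for t in traces]
    return pb, lamb, z, trace


def _posterior_specific(x, n, p, lam):
    const = _log_binom_const(x, n)[:, None]
    logpmf = (
        const
        + x[:, None] * np.log(p)[None, :]
        + (n - x)[:, None] * np.log1p(-p)[None, :]
    )
    joint = logpmf + np.log(lam)[None, :]
    return np.exp(joint - logsumexp(joint, axis=1)[:, None])


def _loglik_specific(x, n, p, lam) -> float:
    const = _log_binom_const(x, n)[:, None]
    logpmf = (
        const
        + x[:, None] * np.log(p)[None, :]
        + (n - x)[:, None] * np.log1p(-p)[None, :]
    )
    return float(logsumexp(logpmf + np.log(lam)[None, :], axis=1).sum())


def _em_shared_batch(
    x: np.ndarray,  # (n, 2) mutant counts at dx, rel
    n: np.ndarray,  # (n, 2) depths
    p0: np.ndarray,  # (R, K, 2)
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[float]]:
    """As :func:`_em_specific_batch` for the multiplicative model."""
    R, K, _ = p0.shape
    const = _log_binom_const(x, n).sum(axis=1)[None, :, None]
    p = p0.copy()
    lam = np.full((R, K), 1.0 / K)
    traces: list[np.ndarray] = []
    prev = np.full(R, -np.inf)
    for _ in range(_MAX_ITER):
        kernel = np.zeros((R, x.shape[0], K))
        for t in range(2):
            kernel += (
                x[None, :, t, None] * np.log(p[:, :, t])[:, None, :]
                + (n[:, t] - x[:, t])[None, :, None]
                * np.log1p(-p[:, :, t])[:, None, :]
            )
        joint = const + kernel + np.log(lam)[:, None, :]
        row_ll = logsumexp(joint, axis=2)
        ll = row_ll.sum(axis=1)
        traces.append(ll)
        z = np.exp(joint - row_ll[:, :, None])
        lam = np.maximum(z.mean(axis=1), 1e-12)
        lam /= lam.sum(axis=1, keepdims=True)
        for t in range(2):
            denom = np.einsum("rnk,n->rk", z, n[:, t])
            num = np.einsum("rnk,n->rk", z, x[:, t])
            p[:, :, t] = np.where(
                denom > 0, num / np.maximum(denom, 1e-300), p[:, :, t]
            )
        p = np.clip(p, _EPS_P, 1.0 - _EPS_P)
        if np.all(np.abs(ll - prev) < _TOL):
            break
        prev = ll
    best = int(np.argmax(traces[-1]))
    pb, lamb = p[best], lam[best]
    z = _posterior_shared(x, n, pb, lamb)
    trace = [float(t[best]) for t in traces]
    return pb, lamb, z, trace


def _shared_kernel(x, n, p):
    """Sum over timepoints of x log p + (n-x) log(1-p), shape (n, K)."""
    out = np.zeros((x.shape[0], p.shape[0]))
    for t in range(2):
        out += (
            x[:, t][:, None] * np.log(p[:, t])[None, :]
            + (n[:, t] - x[:, t])[:, None] * np.log1p(-p[:, t])[None, :]
        )
    return out


def _posterior_shared(x, n, p, lam):
    const = _log_binom_const(x, n).sum(axis=1)[:, None]
    joint = const + _shared_kernel(x, n, p) + np.log(lam)[None, :]
    return np.exp(joint - logsumexp(joint, axis=1)[:, None])


def _loglik_shared(x, n, p, lam) -> float:
    const = _log_binom_const(x, n).sum(axis=1)[:, None]
    joint = const + _shared_kernel(x, n, p) + np.log(lam)[None, :]
    return float(logsumexp(joint, axis=1).sum())


def _finalize(
    model: str,
    p: np.ndarray,
    lam: np.ndarray,
    z: np.ndarray,
    ll: float,
    trace: list[float],
    n_variants: int,
) -> MixtureFit:
    # Order clusters by descending (diagnosis) centre; hard assignment is
    # argmax responsibility with ties to the smaller index after sorting.
    key = p if p.ndim == 1 else p[:, 0]
    order = np.argsort(-key, kind="stable")
    p = p[order]
    lam = lam[order]
    z = z[:, order]
    K = len(lam)
    aic = 2.0 * _n_params(model, K) - 2.0 * ll
    return MixtureFit(
        model=model,
        K=K,
        centers=p,
        weights=lam,
        responsibilities=z,
        assignments=np.argmax(z, axis=1),
        loglik=ll,
        aic=aic,
        n_variants=n_variants,
        loglik_trace=tuple(trace),
    )


def fit_specific_mixture(
    variants: Sequence[tuple[int, int]] | np.ndarray,
    K: int,
    seed: int = 0,
    n_restarts: int = _N_RESTARTS,
) -> MixtureFit:
    """Fit the timepoint-specific binomial mixture with K clusters.

    ``variants`` are (mutant reads, total reads) pairs restricted to
    diploid loci. EM is run from quantile-initialised centres plus jittered
    restarts from a seeded generator; the best-likelihood restart is kept.
    """
    arr = np.asarray(variants, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("variants must be (mut_reads, total_reads) pairs")
    x, n = arr[:, 0], arr[:, 1]
    _check_counts(x, n)
    if K < 1 or K > len(x):
        raise ValueError(f"K must lie in [1, n={len(x)}]")
    rng = np.random.default_rng(seed)
    maf = x / n
    p0 = np.stack([_init_centers(maf, K, rng, r) for r in range(n_restarts)])
    p, lam, z, trace = _em_specific_batch(x, n, p0)
    ll = _loglik_specific(x, n, p, lam)
    return _finalize("specific", p, lam, z, ll, trace, len(x))


def fit_shared_mixture(
    variants: Sequence[tuple[int, int, int, int]] | np.ndarray,
    K: int,
    seed: int = 0,
    n_restarts: int = _N_RESTARTS,
) -> MixtureFit:
    """Fit the shared (multiplicative) binomial mixture with K clusters.

    ``variants`` are (X_dx, N_dx, X_rel, N_rel) tuples; each cluster is
    parameterised by an independent diagnosis and relapse centre and the
    per-variant likelihood is the product of the two binomial terms.
    """
    arr = np.asarray(variants, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 4:
        raise ValueError(
            "variants must be (X_dx, N_dx, X_rel, N_rel) tuples"
        )
    x = arr[:, [0, 2]]
    n = arr[:, [1, 3]]
    _check_counts(x, n)
    if K < 1 or K > len(x):
        raise ValueError(f"K must lie in [1, n={len(x)}]")
    rng = np.random.default_rng(seed)
    maf = x / n
    p0 = np.stack(
        [
            np.column_stack(
                [_init_centers(maf[:, 0], K, rng, r),
                 _init_centers(maf[:, 1], K, rng, r)]
            )
            for r in range(n_restarts)
        ]
    )
    p, lam, z, trace = _em_shared_batch(x, n, p0)
    ll = _loglik_shared(x, n, p, lam)
    return _finalize("shared", p, lam, z, ll, trace, x.shape[0])


def select_model(
    variants,
    K_max: int,
    model: str = "specific",
    seed: int = 0,
    n_restarts: int = _N_RESTARTS,
    curve_out: list | None = None,
) -> MixtureFit:
    """Fit K = 1..K_max and return the fit minimising AIC.

    Ties (and candidate K exceeding the number of variants) resolve toward
    smaller K. When ``curve_out`` is a list, (K, loglik, aic) triples for
    every candidate K are appended to it.
    """
    if model not in ("specific", "shared"):
        raise ValueError(f"unknown model: {model!r}")
    if K_max < 1:
        raise ValueError("K_max must be >= 1")
    fit_fn = fit_specific_mixture if model == "specific" else fit_shared_mixture
    n = len(variants)
    best: MixtureFit | None = None
    for K in range(1, min(K_max, n) + 1):
        fit = fit_fn(variants, K, seed=seed, n_restarts=n_restarts)
        if curve_out is not None:
            curve_out.append((K, fit.loglik, fit.aic))
        if best is None or fit.aic < best.aic - 1e-9:
            best = fit
    return best


def estimate_purity(
    variants: Sequence[tuple[int, int]] | np.ndarray,
    K_max: int = 6,
    seed: int = 0,
    sample: str = "",
    n_restarts: int = _N_RESTARTS,
) -> PuritySummary:
    """Estimate tumour purity from diploid coding-SNV MAFs at one timepoint.

    The MAFs are clustered (coverage-aware binomial mixture, K by AIC) and
    purity is twice the highest cluster centre among centres <= 0.5, capped
    at 1. A small boundary tolerance (0.02) keeps a clonal heterozygous
    cluster whose centre drifts just above 0.5 by sampling noise eligible;
    centres clearly above 0.5 indicate the loci are not copy-neutral
    heterozygous and no purity can be derived.
    """
    fit = select_model(
        variants, K_max=K_max, model="specific", seed=seed,
        n_restarts=n_restarts,
    )
    centers = np.asarray(fit.centers, dtype=float)
    eligible = centers[centers <= 0.52]
    if eligible.size == 0:
        raise ValueError(
            "no cluster centre <= 0.5: loci inconsistent with diploid "
            "heterozygous mutations (possible copy-number contamination)"
        )
    purity = min(1.0, 2.0 * float(eligible.max()))
    return PuritySummary(
        sample=sample,
        cluster_centers=tuple(float(c) for c in centers),
        purity=purity,
    )
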