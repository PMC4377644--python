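"""Coverage-aware statistics for subclonal analysis of deep-sequencing data.

Implements the detection-power calculation for low-frequency mutations, the
per-site misclassification probability for an allele absent from a sample,
the compound binomial test used to decide whether a relapse mutation cluster
is genuinely distinct from a low-frequency diagnosis cluster, and
transition/transversion mutation-spectrum summaries with an exact 2x2 test.

All binomial tails are computed through :mod:`scipy.stats` survival
functions, which remain accurate for P values far below float underflow of
the naive sum.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "DistinctnessResult",
    "SpectrumSummary",
    "detection_power",
    "misclassification_p",
    "compound_distinctness_p",
    "cluster_distinct_from",
    "transition_fraction",
    "spectrum_test",
    "is_transition",
]

#: Purine<->purine and pyrimidine<->pyrimidine substitutions.
TRANSITIONS = frozenset({("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")})

_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class DistinctnessResult:
    """Outcome of the compound cluster-distinctness test.

    ``n_unlikely`` is the number of sites whose individual misclassification
    probability falls at or below ``threshold``; ``compound_p`` is the
    upper-tail binomial probability of observing at least that many such
    sites by chance.
    """

    n_snvs: int
    n_unlikely: int
    per_snv_p: tuple[float, ...]
    threshold: float
    compound_p: float
    alpha: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.n_unlikely <= self.n_snvs):
            raise ValueError("n_unlikely must lie in [0, n_snvs]")
        if not (0.0 <= self.compound_p <= 1.0):
            raise ValueError("compound_p must be a probability")


@dataclass(frozen=True)
class SpectrumSummary:
    """Transition/transversion composition of a set of SNVs."""

    label: str
    transitions: int
    transversions: int

    def __post_init__(self) -> None:
        if self.transitions < 0 or self.transversions < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_snvs(self) -> int:
        return self.transitions + self.transversions

    @property
    def transition_fraction(self) -> float:
        if self.n_snvs == 0:
            raise ValueError(f"spectrum {self.label!r} is empty")
        return self.transitions / self.n_snvs


def detection_power(coverage: int, maf: float, min_reads: int = 3) -> float:
    """Probability of observing >= ``min_reads`` mutant reads.

    For a site sequenced to depth ``coverage`` where the mutant allele is at
    frequency ``maf``, the mutant read count is Binomial(coverage, maf) and
    the mutation is detectable when at least ``min_reads`` non-duplicate
    mutant reads are observed.
    """
    if coverage < 1:
        raise ValueError("coverage must be >= 1")
    if not (0.0 <= maf <= 1.0):
        raise ValueError("maf must lie in [0, 1]")
    if min_reads < 0:
        raise ValueError("min_reads must be non-negative")
    if maf == 0.0:
        warnings.warn("maf=0: detection power is zero", stacklevel=2)
        return 0.0
    if min_reads == 0:
        return 1.0
    return float(stats.binom.sf(min_reads - 1, coverage, maf))


def misclassification_p(coverage: int, alpha: float) -> float:
    """P(X = 0 | Binomial(coverage, alpha)): chance of seeing no mutant read.

    Used to ask whether a site with zero mutant reads could nonetheless
    belong to a clone present at allele frequency ``alpha``.
    """
    if coverage < 1:
        raise ValueError("coverage must be >= 1")
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    if alpha == 1.0:
        return 0.0
    return math.exp(coverage * math.log1p(-alpha))


def compound_distinctness_p(
    per_snv_p: Sequence[float],
    threshold: float = 0.05,
    alpha: float | None = None,
) -> DistinctnessResult:
    """Compound upper-tail binomial test over per-site probabilities.

    A site with individual probability <= ``threshold`` is deemed unlikely
    to be misclassified; with x such sites out of n, the compound P value is
    P(X >= x | Binomial(n, threshold)), inclusive. x = 0 yields 1.
    """
    ps = tuple(float(p) for p in per_snv_p)
    if not ps:
        raise ValueError("at least one per-SNV probability is required")
    if any(not (0.0 <= p <= 1.0) for p in ps):
        raise ValueError("per-SNV values must be probabilities")
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    n = len(ps)
    x = sum(p <= threshold for p in ps)
    compound = 1.0 if x == 0 else float(stats.binom.sf(x - 1, n, threshold))
    return DistinctnessResult(
        n_snvs=n,
        n_unlikely=x,
        per_snv_p=ps,
        threshold=threshold,
        compound_p=compound,
        alpha=alpha,
    )


def cluster_distinct_from(
    parent_alpha: float,
    child_variants: Iterable[tuple[int, int] | int],
    threshold: float = 0.05,
) -> DistinctnessResult:
    """Test whether a cluster of alleles absent at one timepoint is distinct
    from a putative parent cluster at allele frequency ``parent_alpha``.

    ``child_variants`` holds the coverages (or ``(mut_reads, coverage)``
    pairs, where mut_reads must be 0) of the child-cluster sites in the
    sample where they were not observed. Composes the per-site
    misclassification probability with the compound test.
    """
    coverages: list[int] = []
    for v in child_variants:
        if isinstance(v, tuple):
            x, n = v
            if x != 0:
                raise ValueError(
                    "distinctness test is defined for absent alleles (X=0); "
                    f"got X={x}"
                )
        else:
            n = int(v)
        coverages.append(n)
    per_p = [misclassification_p(n, parent_alpha) for n in coverages]
    return compound_distinctness_p(per_p, threshold=threshold, alpha=parent_alpha)


def _parse_substitution(s: str) -> tuple[str, str]:
    parts = s.strip().upper().split(">")
    if len(parts) != 2:
        raise ValueError(f"not a base substitution: {s!r}")
    ref, alt = parts
    if ref not in _BASES or alt not in _BASES:
        raise ValueError(f"not a single-base substitution: {s!r}")
    if ref == alt:
        raise ValueError(f"ref and alt alleles are identical: {s!r}")
    return ref, alt


def is_transition(substitution: str | tuple[str, str]) -> bool:
    """True for A<->G / C<->T changes, False for transversions."""
    if isinstance(substitution, str):
        ref, alt = _parse_substitution(substitution)
    else:
        ref, alt = (b.upper() for b in substitution)
        _parse_substitution(f"{ref}>{alt}")
    return (ref, alt) in TRANSITIONS


def transition_fraction(
    snvs: Iterable[str | tuple[str, str]], label: str = ""
) -> SpectrumSummary:
    """Summarize the transition/transversion spectrum of substitutions."""
    ti = tv = 0
    for s in snvs:
        if is_transition(s):
            ti += 1
        else:
            tv += 1
    if ti + tv == 0:
        raise ValueError("no substitutions supplied")
    return SpectrumSummary(label=label, transitions=ti, transversions=tv)


def spectrum_test(set_a: SpectrumSummary, set_b: SpectrumSummary) -> float:
    """Two-sided Fisher exact P value comparing two mutation spectra.

    The 2x2 table is (transitions, transversions) x (set_a, set_b). Used to
    decide whether two mutation clusters could plausibly share a mutational
    process (e.g. a mismatch-repair-deficient hypermutator lineage).
    """
    if set_a.n_snvs == 0 or set_b.n_snvs == 0:
        raise ValueError("both spectra must be non-empty")
    table = np.array(
        [
            [set_a.transitions, set_a.transversions],
            [set_b.transitions, set_b.transversions],
        ]
    )
    return float(stats.fisher_exact(table, alternative="two-sided")[1])
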