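"""Synthetic clonal architectures and read-count tables for paired
diagnosis/relapse tumour samples.

The generator emulates the statistical structure the downstream analysis
assumes: a rooted clone tree whose founder carries mutations present in all
tumour cells, sibling subclones nested under it at diagnosis, a single
designated surviving clone whose descendants constitute the relapse, and
per-variant read counts drawn as

    N ~ Poisson(mean_coverage),   X ~ Binomial(N, purity * cell_fraction / 2)

for diploid heterozygous SNVs. Each mutation cluster belongs to exactly one
clone; its cell fraction at a timepoint is the total (self + descendants)
fraction of that clone. The emitted :class:`SimTruth` carries everything
needed to score recovery of clusters, purity and tree topology.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .clonal_stats import TRANSITIONS
from .variant_table import TSV_COLUMNS

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_lineage",
    "simulate_reads",
    "simulate_spectrum",
    "simulate_mixture_counts",
    "InfeasibleConfigError",
]


class InfeasibleConfigError(ValueError):
    """Requested clone fractions cannot be nested under their parents."""


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated diagnosis/relapse pair.

    Defaults follow the sequencing design the analysis targets: combined
    deep coverage of ~883-fold, tumour purity ~0.9 so clonal heterozygous
    MAFs centre near 0.45, 8-20 mutations per cluster, a relapse seeded by
    a minor diagnosis subclone (2-20% of cells), and a transition fraction
    of 0.77 for the normal mutational process versus 0.99 under
    mismatch-repair-deficient hypermutation.
    """

    n_clones_dx: int = 3
    n_clones_rel: int = 2
    purity_dx: float = 0.9
    purity_rel: float = 0.9
    mean_coverage: float = 883.0
    muts_per_cluster: tuple[int, int] = (8, 20)
    surviving_clone_rank: str | int = "minor"
    hypermutator: bool = False
    transition_prob_normal: float = 0.77
    transition_prob_hyper: float = 0.99
    maf_separation: float = 0.05
    residual_disease_maf: float = 0.0
    case_id: str = "SIM"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clones_dx < 1 or self.n_clones_rel < 1:
            raise ValueError("need at least one clone per timepoint")
        for name in ("purity_dx", "purity_rel"):
            p = getattr(self, name)
            if not (0.0 < p <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.mean_coverage < 0:
            raise ValueError("mean_coverage must be non-negative")
        lo, hi = self.muts_per_cluster
        if not (1 <= lo <= hi):
            raise ValueError("muts_per_cluster must be a range with low >= 1")
        for name in (
            "transition_prob_normal",
            "transition_prob_hyper",
            "residual_disease_maf",
        ):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["muts_per_cluster"] = list(self.muts_per_cluster)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        if "muts_per_cluster" in d:
            d["muts_per_cluster"] = tuple(d["muts_per_cluster"])
        return cls(**d)


@dataclass(frozen=True)
class SimTruth:
    """Ground truth emitted by :func:`simulate_lineage`.

    ``cell_fraction_dx``/``cell_fraction_rel`` are *total* fractions
    (clone plus descendants); the invariant that a child's total never
    exceeds its parent's makes the pigeonhole sum rule hold by
    construction.
    """

    clone_tree: dict[str, str | None]
    cell_fraction_dx: dict[str, float]
    cell_fraction_rel: dict[str, float]
    cluster_of_clone: dict[str, str]
    cluster_of_variant: dict[str, str]
    category_of_cluster: dict[str, str]
    surviving_clone: str

    def __post_init__(self) -> None:
        roots = [c for c, p in self.clone_tree.items() if p is None]
        if len(roots) != 1:
            raise ValueError("clone tree must have exactly one root")
        for child, parent in self.clone_tree.items():
            if parent is None:
                continue
            for cf in (self.cell_fraction_dx, self.cell_fraction_rel):
                if cf[child] > cf[parent] + 1e-9:
                    raise ValueError(
                        f"clone {child} total fraction exceeds parent "
                        f"{parent}'s"
                    )

    @property
    def founder(self) -> str:
        return next(c for c, p in self.clone_tree.items() if p is None)

    def children(self, clone: str) -> list[str]:
        return [c for c, p in self.clone_tree.items() if p == clone]

    def residual_fractions(self, timepoint: str) -> dict[str, float]:
        """Total minus the sum of direct children's totals, per clone."""
        total = (
            self.cell_fraction_dx
            if timepoint == "diagnosis"
            else self.cell_fraction_rel
        )
        return {
            c: total[c] - sum(total[ch] for ch in self.children(c))
            for c in self.clone_tree
        }

    def cluster_fractions(self, timepoint: str) -> dict[str, float]:
        total = (
            self.cell_fraction_dx
            if timepoint == "diagnosis"
            else self.cell_fraction_rel
        )
        return {
            cluster: total[clone]
            for clone, cluster in self.cluster_of_clone.items()
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        return cls(**json.loads(Path(path).read_text()))


#: Smallest simulated clone fraction (the study's minor rising clones sat
#: at 2-20% of cells; below ~3% clusters fall off the detection floor).
_MIN_CF = 0.03


def _sibling_fractions(
    rng: np.random.Generator,
    n_siblings: int,
    purity: float,
    maf_separation: float,
) -> list[float]:
    """Descending sibling cell fractions nested under a clonal parent.

    MAF centres (purity * cf / 2) of the resulting clusters are separated
    by at least ``maf_separation`` from each other and from the parent's
    clonal centre, and sibling totals sum to < 1 so the tree nests. The
    first sibling is the predominant subclone; the last (the default
    surviving clone under the "minor" rank) is kept at <= 20% of cells.
    """
    if n_siblings == 0:
        return []
    sep = 2.0 * maf_separation / purity  # separation on the CF scale
    budget = 1.0 - sep  # parent keeps its own centre separated
    fractions: list[float] = []
    prev = None
    for i in range(n_siblings):
        k = n_siblings - i - 1  # siblings still to place
        rest_min = k * _MIN_CF + sep * k * (k - 1) / 2.0
        hi = budget - sum(fractions) - rest_min
        if prev is not None:
            hi = min(hi, prev - sep)
        lo = _MIN_CF + k * sep
        if i == 0:
            lo = max(lo, min(0.55, hi))  # predominant subclone
        if k == 0:
            hi = min(hi, 0.20)  # minor terminal sibling
        if hi < lo - 1e-12:
            raise InfeasibleConfigError(
                f"cannot nest {n_siblings} separated siblings at purity "
                f"{purity} with MAF separation {maf_separation}"
            )
        frac = float(rng.uniform(lo, max(lo, hi)))
        fractions.append(frac)
        prev = frac
    return fractions


def _chain_fractions(
    rng: np.random.Generator,
    n: int,
    purity: float,
    maf_separation: float,
) -> list[float]:
    """Descending totals for a nested chain, head clonal at 1.0."""
    sep = 2.0 * maf_separation / purity
    fracs = [1.0]
    for i in range(1, n):
        k = n - i - 1  # clones still to place below this one
        hi = fracs[-1] - sep
        lo = _MIN_CF + k * sep
        if hi < lo - 1e-12:
            raise InfeasibleConfigError(
                f"cannot nest a chain of {n} separated clones at purity "
                f"{purity} with MAF separation {maf_separation}"
            )
        fracs.append(float(rng.uniform(lo, max(lo, hi))))
    return fracs


def simulate_lineage(config: SimConfig) -> SimTruth:
    """Draw a ground-truth clone tree with cell fractions at both timepoints.

    Diagnosis: a clonal founder (its mutation cluster is shared, being
    ancestral to the relapse) with ``n_clones_dx - 1`` sibling subclones.
    Exactly one diagnosis clone — chosen by ``surviving_clone_rank`` —
    survives therapy: its cluster is also shared, and the relapse is a
    nested chain of ``n_clones_rel`` new clones descending from it, each
    carrying a relapse-specific cluster. Every clone carries exactly one
    lineage-specific cluster.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.muts_per_cluster

    clone_tree: dict[str, str | None] = {"D1": None}
    cf_dx: dict[str, float] = {"D1": 1.0}
    cf_rel: dict[str, float] = {"D1": 1.0}
    cluster_of_clone: dict[str, str] = {"D1": "s0"}
    category: dict[str, str] = {"s0": "shared"}

    n_sib = config.n_clones_dx - 1
    sib_fracs = _sibling_fractions(
        rng, n_sib, config.purity_dx, config.maf_separation
    )
    sib_ids = [f"D{i + 2}" for i in range(n_sib)]
    for cid, frac in zip(sib_ids, sib_fracs):
        clone_tree[cid] = "D1"
        cf_dx[cid] = frac
        cf_rel[cid] = 0.0

    # Which diagnosis clone seeds the relapse.
    rank = config.surviving_clone_rank
    if n_sib == 0:
        surviving = "D1"
    elif rank == "minor":
        surviving = sib_ids[-1]  # smallest sibling fraction
    elif rank == "major":
        surviving = sib_ids[0]
    elif rank == "founder":
        surviving = "D1"
    elif isinstance(rank, int):
        if not (0 <= rank < len(sib_ids)):
            raise InfeasibleConfigError(
                f"surviving_clone_rank {rank} out of range for "
                f"{len(sib_ids)} subclones"
            )
        surviving = sib_ids[rank]
    else:
        raise ValueError(f"unknown surviving_clone_rank: {rank!r}")

    # Lineage-specific clusters of diagnosis subclones: the survivor's is
    # shared (it persists), the others are diagnosis-specific.
    d_idx = 1
    s_idx = 1
    for cid in sib_ids:
        if cid == surviving:
            label = f"s{s_idx}"
            s_idx += 1
            category[label] = "shared"
        else:
            label = f"d{d_idx}"
            d_idx += 1
            category[label] = "dx_specific"
        cluster_of_clone[cid] = label

    # The surviving lineage is clonal at relapse (its mutations are carried
    # by every relapse cell); ancestors of the survivor likewise.
    node = surviving
    while node is not None:
        cf_rel[node] = 1.0
        node = clone_tree[node]

    rel_fracs = _chain_fractions(
        rng, config.n_clones_rel, config.purity_rel, config.maf_separation
    )
    parent = surviving
    for i, frac in enumerate(rel_fracs):
        cid = f"R{i + 1}"
        clone_tree[cid] = parent
        cf_dx[cid] = 0.0
        cf_rel[cid] = frac
        label = f"r{i}"
        cluster_of_clone[cid] = label
        category[label] = "rel_specific"
        parent = cid

    # Mutation counts per cluster; a hypermutator relapse founder carries a
    # greatly elevated load (the study's hypermutators had >100
    # relapse-specific coding SNVs).
    cluster_of_variant: dict[str, str] = {}
    i_var = 0
    for clone in clone_tree:
        label = cluster_of_clone[clone]
        if config.hypermutator and label == "r0":
            n_mut = int(rng.integers(150, 301))
        else:
            n_mut = int(rng.integers(lo, hi + 1))
        for _ in range(n_mut):
            cluster_of_variant[f"v{i_var:06d}"] = label
            i_var += 1

    return SimTruth(
        clone_tree=clone_tree,
        cell_fraction_dx=cf_dx,
        cell_fraction_rel=cf_rel,
        cluster_of_clone=cluster_of_clone,
        cluster_of_variant=cluster_of_variant,
        category_of_cluster=category,
        surviving_clone=surviving,
    )


def simulate_spectrum(
    n_snvs: int,
    transition_prob: float,
    seed: int | np.random.Generator = 0,
) -> list[str]:
    """Draw ``ref>alt`` single-base substitutions.

    Each SNV is a transition (A<->G, C<->T) with probability
    ``transition_prob``, otherwise a transversion; the reference base is
    uniform over ACGT and transversion targets are uniform over the two
    candidates.
    """
    if not (0.0 <= transition_prob <= 1.0):
        raise ValueError("transition_prob must lie in [0, 1]")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    ti_partner = dict(TRANSITIONS)
    tv_partners = {
        "A": ("C", "T"), "G": ("C", "T"), "C": ("A", "G"), "T": ("A", "G"),
    }
    bases = np.array(list("ACGT"))
    out = []
    for _ in range(n_snvs):
        ref = str(rng.choice(bases))
        if rng.random() < transition_prob:
            alt = ti_partner[ref]
        else:
            alt = tv_partners[ref][int(rng.integers(2))]
        out.append(f"{ref}>{alt}")
    return out


def simulate_reads(truth: SimTruth, config: SimConfig) -> pd.DataFrame:
    """Draw the per-variant read-count table implied by a ground truth.

    Depth per variant and timepoint is Poisson(mean_coverage); mutant reads
    are Binomial(N, purity * cell_fraction / 2), the MAF of a diploid
    heterozygous mutation carried by the cluster's clone and its
    descendants. Remission counts use ``residual_disease_maf`` (default 0)
    for clusters ancestral to the relapse, else 0.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 0x5EAD]).generate_state(1)[0]
    )
    cf = {
        "diagnosis": truth.cluster_fractions("diagnosis"),
        "relapse": truth.cluster_fractions("relapse"),
    }
    # Clusters carried by the relapse founder lineage can leave a residual
    # disease trace in the remission sample.
    relapse_carried = {
        cl for cl, f in cf["relapse"].items() if f > 0
    }

    variant_ids = sorted(truth.cluster_of_variant)
    clusters = [truth.cluster_of_variant[v] for v in variant_ids]
    n = len(variant_ids)

    # Per-cluster substitution spectra (hypermutator relapse founder gets
    # the elevated transition fraction).
    spectrum_by_cluster: dict[str, list[str]] = {}
    for label in sorted(set(clusters)):
        count = clusters.count(label)
        p_ti = (
            config.transition_prob_hyper
            if config.hypermutator and label == "r0"
            else config.transition_prob_normal
        )
        spectrum_by_cluster[label] = simulate_spectrum(count, p_ti, rng)

    def draw(maf: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if config.mean_coverage == 0:
            depth = np.zeros(n, dtype=int)
        else:
            depth = rng.poisson(config.mean_coverage, size=n)
        mut = rng.binomial(depth, np.clip(maf, 0.0, 1.0))
        return mut, depth

    maf_dx = np.array(
        [config.purity_dx * cf["diagnosis"][c] / 2.0 for c in clusters]
    )
    maf_rel = np.array(
        [config.purity_rel * cf["relapse"][c] / 2.0 for c in clusters]
    )
    maf_rem = np.array(
        [
            config.residual_disease_maf if c in relapse_carried else 0.0
            for c in clusters
        ]
    )
    dx_mut, dx_tot = draw(maf_dx)
    rel_mut, rel_tot = draw(maf_rel)
    rem_mut, rem_tot = draw(maf_rem)

    spectrum_iters = {c: iter(s) for c, s in spectrum_by_cluster.items()}
    refs, alts = [], []
    for c in clusters:
        ref, alt = next(spectrum_iters[c]).split(">")
        refs.append(ref)
        alts.append(alt)

    df = pd.DataFrame(
        {
            "case_id": config.case_id,
            "chrom": "chr1",
            "pos": np.arange(1, n + 1) * 1000,
            "ref": refs,
            "alt": alts,
            "dx_mut": dx_mut, "dx_tot": dx_tot,
            "rel_mut": rel_mut, "rel_tot": rel_tot,
            "rem_mut": rem_mut, "rem_tot": rem_tot,
            "diploid": True,
            "gene": "", "effect": "", "pathway": "",
        },
        columns=TSV_COLUMNS,
    )
    df["variant_id"] = variant_ids
    df["true_cluster"] = clusters
    return df


def simulate_mixture_counts(
    centers: np.ndarray | list[float],
    weights: np.ndarray | list[float] | None,
    n_variants: int,
    mean_depth: float,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw (X, N, labels) directly from a binomial mixture.

    Convenience generator for clustering experiments where no lineage
    structure is needed: component labels are multinomial on ``weights``,
    depths Poisson, mutant counts binomial at the component centre.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    centers = np.asarray(centers, dtype=float)
    k = len(centers)
    if weights is None:
        weights = np.full(k, 1.0 / k)
    weights = np.asarray(weights, dtype=float)
    weights = weights / weights.sum()
    labels = rng.choice(k, size=n_variants, p=weights)
    depth = rng.poisson(mean_depth, size=n_variants)
    depth = np.maximum(depth, 1)
    x = rng.binomial(depth, centers[labels])
    return x, depth, labels
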