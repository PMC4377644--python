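"""Shared fixtures: programmatically generated variant tables mimicking the
cluster geometries of well-characterized diagnosis/relapse cases."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from clonetrace.variant_table import VariantCall

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@dataclass(frozen=True)
class ClusterSpec:
    """One simulated mutation cluster for building fixture tables."""

    label: str
    n: int
    maf_dx: float
    maf_rel: float
    pathways: tuple[str, ...] = ()  # assigned to the first variants
    transition_prob: float = 0.77


def make_cluster_table(
    specs: list[ClusterSpec],
    depth: float = 883.0,
    seed: int = 0,
    case_id: str = "CASE",
) -> list[VariantCall]:
    """Draw a variant table with binomial counts at the given MAF centres."""
    rng = np.random.default_rng(seed)
    ti_partner = {"A": "G", "G": "A", "C": "T", "T": "C"}
    tv_partner = {"A": "C", "G": "C", "C": "A", "T": "A"}
    variants = []
    pos = 1000
    for spec in specs:
        for i in range(spec.n):
            ref = str(rng.choice(list("ACGT")))
            alt = (
                ti_partner[ref]
                if rng.random() < spec.transition_prob
                else tv_partner[ref]
            )
            counts = {}
            for tp, maf in (("dx", spec.maf_dx), ("rel", spec.maf_rel),
                            ("rem", 0.0)):
                n_tot = int(rng.poisson(depth))
                counts[f"{tp}_tot"] = n_tot
                counts[f"{tp}_mut"] = int(rng.binomial(n_tot, maf))
            variants.append(
                VariantCall(
                    case_id=case_id,
                    chrom="chr1",
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    pathway=spec.pathways[i] if i < len(spec.pathways) else "",
                    gene=spec.pathways[i] if i < len(spec.pathways) else "",
                    **counts,
                )
            )
            pos += 1000
    return variants


@pytest.fixture
def papspn_like_table() -> list[VariantCall]:
    """Six-cluster geometry: a clonal shared founder cluster, a minor
    shared cluster that seeds the relapse, one clonal and one minor
    diagnosis-specific cluster, and two nested relapse-specific clusters.
    Three JAK-pathway hotspot mutations sit in three different minor/major
    clusters (mutually exclusive activating drivers)."""
    specs = [
        ClusterSpec("c_founder", 12, 0.45, 0.45),
        ClusterSpec("d_shared_minor", 10, 0.02, 0.45, pathways=("JAK",)),
        ClusterSpec("a_dx_clonal", 12, 0.45, 0.0, pathways=("JAK",)),
        ClusterSpec("b_dx_minor", 6, 0.02, 0.0, pathways=("JAK",)),
        ClusterSpec("e_rel_clonal", 38, 0.0, 0.45),
        ClusterSpec("f_rel_sub", 8, 0.0, 0.30),
    ]
    return make_cluster_table(specs, seed=11)


@pytest.fixture
def parjzz_like_table() -> list[VariantCall]:
    """Five-cluster dual-lineage geometry: an ancestral shared cluster and
    two sibling shared clusters that both persist with reversed dominance
    (75% -> 8% of cells vs 12.5% -> 92%), plus nested relapse-specific
    clusters under the rising sibling. Purity 0.8 at both timepoints."""
    specs = [
        ClusterSpec("a_ancestral", 14, 0.40, 0.40),
        ClusterSpec("b_falling", 12, 0.30, 0.032, pathways=("RAS",)),
        ClusterSpec("c_rising", 12, 0.05, 0.368, pathways=("RAS",)),
        ClusterSpec("d_rel", 10, 0.0, 0.22),
        ClusterSpec("e_rel", 8, 0.0, 0.12),
    ]
    return make_cluster_table(specs, seed=23)
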