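"""Clonal lineage reconstruction from mutation clusters.

Each mutation cluster, with a cell fraction at diagnosis and relapse
(2 x MAF / purity for diploid heterozygous variants), defines one clone.
Trees are built greedily under the pigeonhole sum rule: shared clusters
first, in descending diagnosis fraction — the largest is the founder —
each new cluster attaching to the existing clone with the largest residual
(unallocated) population, which is then reduced by the newcomer's fraction.
Diagnosis-specific clusters follow by the same rule. At relapse, shared
clusters keep the nesting established at diagnosis (clones persist across
timepoints); relapse residuals are recomputed from relapse fractions and
relapse-specific clusters then attach greedily on those residuals.

Surviving diagnosis clones are mapped to the relapse founders they seed;
multiple surviving clones give a dual-lineage relapse. Ambiguous parental
assignments (several clones could accommodate a cluster within the
tolerance epsilon) are recorded and can be resolved by biological
constraints: mutual exclusivity of activating driver mutations in the same
gene/pathway, and consistency of transition/transversion mutation spectra.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .clonal_stats import SpectrumSummary, spectrum_test

__all__ = [
    "ClusterSummary",
    "Clone",
    "Ambiguity",
    "LineageTree",
    "SvCnvEvent",
    "InfeasibleLineageError",
    "cluster_cell_fraction",
    "build_lineage",
    "map_relapse_founders",
    "resolve_ambiguity",
    "place_sv_cnv",
]

#: Detection floor for a clonal population (fraction of cells).
DETECTION_LEVEL = 0.01


class InfeasibleLineageError(ValueError):
    """No clone can accommodate a cluster's population fraction."""


def cluster_cell_fraction(center_maf: float, purity: float) -> float:
    """Cell fraction carrying a cluster: 2 x MAF / purity, capped at 1.

    Valid for diploid heterozygous mutations; a centre implying a fraction
    more than 10% above 1 is flagged as super-clonal before capping.
    """
    if not (0.0 < purity <= 1.0):
        raise ValueError("purity must lie in (0, 1]")
    if center_maf < 0.0:
        raise ValueError("MAF centre must be non-negative")
    cf = 2.0 * center_maf / purity
    if cf > 1.1:
        warnings.warn(
            f"super-clonal cluster: MAF {center_maf:.3f} at purity "
            f"{purity:.2f} implies cell fraction {cf:.2f}; capped at 1",
            stacklevel=2,
        )
    return min(1.0, cf)


@dataclass(frozen=True)
class ClusterSummary:
    """A mutation cluster ready for lineage placement."""

    label: str
    category: str  # dx_specific | rel_specific | shared
    cell_fraction_dx: float
    cell_fraction_rel: float
    n_variants: int = 0
    drivers: frozenset[str] = frozenset()
    transitions: int = 0
    transversions: int = 0

    def __post_init__(self) -> None:
        if self.category not in ("dx_specific", "rel_specific", "shared"):
            raise ValueError(f"bad category: {self.category!r}")
        for f in (self.cell_fraction_dx, self.cell_fraction_rel):
            if not (0.0 <= f <= 1.0):
                raise ValueError("cell fractions must lie in [0, 1]")

    @property
    def spectrum(self) -> SpectrumSummary | None:
        if self.transitions + self.transversions == 0:
            return None
        return SpectrumSummary(
            label=self.label,
            transitions=self.transitions,
            transversions=self.transversions,
        )


@dataclass
class Clone:
    """A clone: the set of mutation clusters on its path from the founder.

    ``total_fraction_*`` is the fraction of cells carrying the clone's own
    cluster (clone plus descendants); ``residual_fraction_*`` subtracts the
    direct children, i.e. cells belonging to this clone and no descendant.
    """

    clone_id: str
    own_cluster: str
    clusters: frozenset[str]
    total_fraction_dx: float
    total_fraction_rel: float
    residual_fraction_dx: float
    residual_fraction_rel: float
    inferred: bool = False

    @property
    def at_diagnosis(self) -> bool:
        return self.total_fraction_dx > 0.0

    @property
    def at_relapse(self) -> bool:
        return self.total_fraction_rel > 0.0


@dataclass
class Ambiguity:
    """A cluster that several parents could accommodate within epsilon."""

    cluster: str
    timepoint: str
    chosen_parent: str
    alternatives: tuple[str, ...]
    resolved_by: str | None = None
    note: str = ""


@dataclass
class LineageTree:
    """Clones with parent edges per timepoint plus relapse-founder edges."""

    clones: dict[str, Clone]
    parent_dx: dict[str, str]
    parent_rel: dict[str, str]
    founder_edges: list[tuple[str, str]]
    ambiguities: list[Ambiguity]
    clusters: dict[str, ClusterSummary]
    epsilon: float = 0.05

    # -- structure helpers -------------------------------------------------
    def children(self, clone_id: str, timepoint: str) -> list[str]:
        parents = self.parent_dx if timepoint == "diagnosis" else self.parent_rel
        return [c for c, p in parents.items() if p == clone_id]

    def depth(self, clone_id: str, timepoint: str) -> int:
        parents = self.parent_dx if timepoint == "diagnosis" else self.parent_rel
        d = 0
        while clone_id in parents:
            clone_id = parents[clone_id]
            d += 1
        return d

    def founder_clone(self) -> Clone:
        roots = [
            c for c in self.clones.values()
            if c.at_diagnosis and c.clone_id not in self.parent_dx
        ]
        if len(roots) != 1:
            raise ValueError("diagnosis tree must have a single founder")
        return roots[0]

    def clone_by_cluster(self, label: str) -> Clone:
        for c in self.clones.values():
            if c.own_cluster == label:
                return c
        raise KeyError(label)

    def _recompute(self) -> None:
        """Re-derive carried cluster sets, residuals and inferred flags
        from the parent maps and per-clone totals."""
        for tp, parents in (
            ("diagnosis", self.parent_dx), ("relapse", self.parent_rel)
        ):
            for clone in self.clones.values():
                total = (
                    clone.total_fraction_dx
                    if tp == "diagnosis"
                    else clone.total_fraction_rel
                )
                child_sum = sum(
                    (
                        self.clones[c].total_fraction_dx
                        if tp == "diagnosis"
                        else self.clones[c].total_fraction_rel
                    )
                    for c in self.children(clone.clone_id, tp)
                )
                if tp == "diagnosis":
                    clone.residual_fraction_dx = total - child_sum
                else:
                    clone.residual_fraction_rel = total - child_sum
        # carried sets follow the diagnosis tree for clones present there,
        # the relapse tree otherwise
        def carried(cid: str) -> frozenset[str]:
            clone = self.clones[cid]
            parents = (
                self.parent_dx if clone.at_diagnosis else self.parent_rel
            )
            if cid in parents:
                return carried(parents[cid]) | {clone.own_cluster}
            return frozenset({clone.own_cluster})

        for cid, clone in self.clones.items():
            clone.clusters = carried(cid)
            clone.inferred = (
                clone.at_diagnosis
                and clone.residual_fraction_dx < DETECTION_LEVEL
                and bool(self.children(cid, "diagnosis"))
            )

    def to_dict(self) -> dict:
        return {
            "epsilon": self.epsilon,
            "clones": {
                cid: {
                    "own_cluster": c.own_cluster,
                    "clusters": sorted(c.clusters),
                    "total_fraction_dx": c.total_fraction_dx,
                    "total_fraction_rel": c.total_fraction_rel,
                    "residual_fraction_dx": c.residual_fraction_dx,
                    "residual_fraction_rel": c.residual_fraction_rel,
                    "inferred": c.inferred,
                }
                for cid, c in self.clones.items()
            },
            "parent_dx": dict(self.parent_dx),
            "parent_rel": dict(self.parent_rel),
            "founder_edges": [list(e) for e in self.founder_edges],
            "ambiguities": [
                {
                    "cluster": a.cluster,
                    "timepoint": a.timepoint,
                    "chosen_parent": a.chosen_parent,
                    "alternatives": list(a.alternatives),
                    "resolved_by": a.resolved_by,
                    "note": a.note,
                }
                for a in self.ambiguities
            ],
            "clusters": {
                lab: {
                    "category": cl.category,
                    "cell_fraction_dx": cl.cell_fraction_dx,
                    "cell_fraction_rel": cl.cell_fraction_rel,
                    "n_variants": cl.n_variants,
                    "drivers": sorted(cl.drivers),
                    "transitions": cl.transitions,
                    "transversions": cl.transversions,
                }
                for lab, cl in self.clusters.items()
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "LineageTree":
        clones = {
            cid: Clone(
                clone_id=cid,
                own_cluster=cd["own_cluster"],
                clusters=frozenset(cd["clusters"]),
                total_fraction_dx=cd["total_fraction_dx"],
                total_fraction_rel=cd["total_fraction_rel"],
                residual_fraction_dx=cd["residual_fraction_dx"],
                residual_fraction_rel=cd["residual_fraction_rel"],
                inferred=cd["inferred"],
            )
            for cid, cd in d["clones"].items()
        }
        clusters = {
            lab: ClusterSummary(
                label=lab,
                category=cd["category"],
                cell_fraction_dx=cd["cell_fraction_dx"],
                cell_fraction_rel=cd["cell_fraction_rel"],
                n_variants=cd["n_variants"],
                drivers=frozenset(cd["drivers"]),
                transitions=cd["transitions"],
                transversions=cd["transversions"],
            )
            for lab, cd in d["clusters"].items()
        }
        return cls(
            clones=clones,
            parent_dx=dict(d["parent_dx"]),
            parent_rel=dict(d["parent_rel"]),
            founder_edges=[tuple(e) for e in d["founder_edges"]],
            ambiguities=[Ambiguity(**a) for a in d["ambiguities"]],
            clusters=clusters,
            epsilon=d["epsilon"],
        )


def _pick_parent(
    candidates: list[tuple[float, Clone]], tree: LineageTree, timepoint: str
) -> Clone:
    """Largest residual wins; exact residual ties go to the deeper clone
    (equal-fraction clusters nest into chains), then to the
    lexicographically smaller id."""
    def key(item):
        residual, clone = item
        return (
            -residual, -tree.depth(clone.clone_id, timepoint), clone.clone_id
        )

    return sorted(candidates, key=key)[0][1]


def build_lineage(
    clusters: Iterable[ClusterSummary], epsilon: float = 0.05
) -> LineageTree:
    """Greedy construction of the diagnosis and relapse lineage trees.

    Residuals may dip as low as -epsilon (sampling noise on fractions); a
    cluster no clone can accommodate within epsilon raises
    :class:`InfeasibleLineageError`. Ambiguous placements (more than one
    admissible parent) are recorded on the returned tree.
    """
    clusters = list(clusters)
    by_cat = {"shared": [], "dx_specific": [], "rel_specific": []}
    for cl in clusters:
        by_cat[cl.category].append(cl)
    if not by_cat["shared"]:
        raise ValueError(
            "at least one shared cluster is required: diagnosis and relapse "
            "must descend from a common ancestral clone"
        )

    def dx_order(cl: ClusterSummary):
        return (-cl.cell_fraction_dx, -cl.cell_fraction_rel, cl.label)

    def rel_order(cl: ClusterSummary):
        return (-cl.cell_fraction_rel, cl.label)

    tree = LineageTree(
        clones={}, parent_dx={}, parent_rel={}, founder_edges=[],
        ambiguities=[], clusters={c.label: c for c in clusters},
        epsilon=epsilon,
    )
    next_id = 1

    def new_clone(cl: ClusterSummary) -> Clone:
        nonlocal next_id
        clone = Clone(
            clone_id=str(next_id),
            own_cluster=cl.label,
            clusters=frozenset({cl.label}),
            total_fraction_dx=cl.cell_fraction_dx,
            total_fraction_rel=cl.cell_fraction_rel,
            residual_fraction_dx=cl.cell_fraction_dx,
            residual_fraction_rel=cl.cell_fraction_rel,
        )
        next_id += 1
        tree.clones[clone.clone_id] = clone
        return clone

    # ---- diagnosis tree: shared clusters, then diagnosis-specific --------
    # A shared cluster's clone persists to relapse, so its parent must have
    # room for it at both timepoints; a diagnosis-specific cluster only
    # constrains the diagnosis residual.
    shared_sorted = sorted(by_cat["shared"], key=dx_order)
    founder = new_clone(shared_sorted[0])
    for cl in shared_sorted[1:] + sorted(by_cat["dx_specific"], key=dx_order):
        frac = cl.cell_fraction_dx
        candidates = [
            (c.residual_fraction_dx, c)
            for c in tree.clones.values()
            if c.at_diagnosis
            and c.residual_fraction_dx >= frac - epsilon
            and (
                cl.category != "shared"
                or c.residual_fraction_rel >= cl.cell_fraction_rel - epsilon
            )
        ]
        if not candidates:
            raise InfeasibleLineageError(
                f"cluster {cl.label!r} (fraction {frac:.3f}) exceeds every "
                f"clone's residual population at diagnosis by more than "
                f"epsilon={epsilon}"
            )
        parent = _pick_parent(candidates, tree, "diagnosis")
        clone = new_clone(cl)
        clone.clusters = parent.clusters | {cl.label}
        tree.parent_dx[clone.clone_id] = parent.clone_id
        parent.residual_fraction_dx -= frac
        if cl.category == "shared":
            parent.residual_fraction_rel -= cl.cell_fraction_rel
        if len(candidates) > 1:
            tree.ambiguities.append(
                Ambiguity(
                    cluster=cl.label,
                    timepoint="diagnosis",
                    chosen_parent=parent.clone_id,
                    alternatives=tuple(
                        sorted(
                            c.clone_id
                            for _, c in candidates
                            if c.clone_id != parent.clone_id
                        )
                    ),
                )
            )

    # ---- relapse tree: persisting clones keep the diagnosis nesting ------
    persisting = [c for c in tree.clones.values() if c.at_relapse]
    for clone in persisting:
        anc = tree.parent_dx.get(clone.clone_id)
        while anc is not None and not tree.clones[anc].at_relapse:
            anc = tree.parent_dx.get(anc)
        if anc is not None:
            tree.parent_rel[clone.clone_id] = anc
    for clone in persisting:
        clone.residual_fraction_rel = clone.total_fraction_rel - sum(
            tree.clones[c].total_fraction_rel
            for c in tree.children(clone.clone_id, "relapse")
        )

    # ---- relapse-specific clusters ---------------------------------------
    for cl in sorted(by_cat["rel_specific"], key=rel_order):
        frac = cl.cell_fraction_rel
        candidates = [
            (c.residual_fraction_rel, c)
            for c in tree.clones.values()
            if c.at_relapse and c.residual_fraction_rel >= frac - epsilon
        ]
        if not candidates:
            raise InfeasibleLineageError(
                f"cluster {cl.label!r} (fraction {frac:.3f}) exceeds every "
                f"clone's residual population at relapse by more than "
                f"epsilon={epsilon}"
            )
        parent = _pick_parent(candidates, tree, "relapse")
        clone = new_clone(cl)
        clone.clusters = parent.clusters | {cl.label}
        tree.parent_rel[clone.clone_id] = parent.clone_id
        parent.residual_fraction_rel -= frac
        if len(candidates) > 1:
            tree.ambiguities.append(
                Ambiguity(
                    cluster=cl.label,
                    timepoint="relapse",
                    chosen_parent=parent.clone_id,
                    alternatives=tuple(
                        sorted(
                            c.clone_id
                            for _, c in candidates
                            if c.clone_id != parent.clone_id
                        )
                    ),
                )
            )

    tree._recompute()
    return tree


def map_relapse_founders(tree: LineageTree) -> list[tuple[str, str]]:
    """Link surviving diagnosis clones to the relapse founders they seed.

    An anchor is a persisting (shared-cluster) clone that either carries a
    relapse-specific child or retains a relapse population above the
    tree's noise tolerance epsilon (cluster-centre noise at realistic
    depths makes residuals below epsilon uninformative). One
    diagnosis->relapse edge is emitted per anchor: to
    its largest relapse-specific child (the relapse founder clone), or to
    itself when it persists without new mutations. Edges are stored on the
    tree and returned; >= 2 anchors constitute a dual-lineage relapse.
    """
    rel_specific = {
        c.clone_id
        for c in tree.clones.values()
        if tree.clusters[c.own_cluster].category == "rel_specific"
    }
    edges: list[tuple[str, str]] = []
    for clone in tree.clones.values():
        if not clone.at_relapse or clone.clone_id in rel_specific:
            continue
        rel_children = [
            cid
            for cid in tree.children(clone.clone_id, "relapse")
            if cid in rel_specific
        ]
        if rel_children:
            target = max(
                rel_children,
                key=lambda cid: tree.clones[cid].total_fraction_rel,
            )
            edges.append((clone.clone_id, target))
        elif clone.residual_fraction_rel > max(DETECTION_LEVEL, tree.epsilon):
            edges.append((clone.clone_id, clone.clone_id))
    if not edges:
        raise ValueError(
            "no relapse founder maps to a diagnosis clone via shared "
            "clusters; diagnosis and relapse lack a common origin"
        )
    tree.founder_edges = sorted(edges)
    return tree.founder_edges


def resolve_ambiguity(
    tree: LineageTree,
    drivers: Mapping[str, Iterable[str]] | None = None,
    spectra: Mapping[str, SpectrumSummary] | None = None,
    alpha: float = 0.05,
) -> LineageTree:
    """Resolve recorded parental ambiguities with biological constraints.

    Rule 1 (mutual exclusivity): a candidate parent is rejected when its
    lineage path would stack two activating mutations of the same
    gene/pathway (``drivers`` maps cluster label -> driver keys). Rule 2
    (spectrum consistency): among survivors, parents whose own cluster's
    transition/transversion spectrum is NOT significantly different from
    the child's (two-sided exact test, P >= ``alpha``) are preferred. A
    unique survivor is adopted (the subtree is re-parented); otherwise the
    default stands and the alternatives remain annotated.
    """
    if drivers is None:
        drivers = {lab: cl.drivers for lab, cl in tree.clusters.items()}
    drivers = {k: frozenset(v) for k, v in drivers.items()}
    if spectra is None:
        spectra = {
            lab: cl.spectrum
            for lab, cl in tree.clusters.items()
            if cl.spectrum is not None
        }

    for amb in tree.ambiguities:
        child_clone = tree.clone_by_cluster(amb.cluster)
        candidate_ids = [amb.chosen_parent, *amb.alternatives]
        child_drivers = drivers.get(amb.cluster, frozenset())

        surviving = []
        for cid in candidate_ids:
            path_drivers = frozenset().union(
                *(drivers.get(lab, frozenset())
                  for lab in tree.clones[cid].clusters)
            )
            if child_drivers & path_drivers:
                continue
            surviving.append(cid)

        rule = None
        if not surviving:
            amb.note = (
                "all candidate parents conflict with driver mutual "
                "exclusivity; default retained"
            )
            continue
        if len(surviving) < len(candidate_ids):
            rule = "driver_exclusivity"

        if len(surviving) > 1:
            child_spec = spectra.get(amb.cluster)
            consistent = []
            for cid in surviving:
                parent_spec = spectra.get(tree.clones[cid].own_cluster)
                if child_spec is None or parent_spec is None:
                    consistent.append(cid)  # no evidence either way
                    continue
                if spectrum_test(child_spec, parent_spec) >= alpha:
                    consistent.append(cid)
            if consistent and len(consistent) < len(surviving):
                surviving = consistent
                rule = (
                    "driver_exclusivity+spectrum"
                    if rule
                    else "spectrum"
                )

        if len(surviving) == 1:
            choice = surviving[0]
            amb.resolved_by = rule or "default"
            if choice != amb.chosen_parent:
                _reattach(tree, child_clone, choice, amb.timepoint)
                amb.note = f"re-parented from {amb.chosen_parent} to {choice}"
                amb.chosen_parent = choice
        else:
            # keep the greedy default among the surviving candidates
            if amb.chosen_parent not in surviving:
                choice = max(
                    surviving,
                    key=lambda cid: (
                        tree.clones[cid].residual_fraction_dx
                        if amb.timepoint == "diagnosis"
                        else tree.clones[cid].residual_fraction_rel
                    ),
                )
                _reattach(tree, child_clone, choice, amb.timepoint)
                amb.note = f"re-parented from {amb.chosen_parent} to {choice}"
                amb.chosen_parent = choice
                amb.resolved_by = rule
            amb.alternatives = tuple(
                cid for cid in surviving if cid != amb.chosen_parent
            )
            if amb.alternatives:
                amb.note = (amb.note + "; " if amb.note else "") + (
                    "unresolved: alternatives retained"
                )
    tree._recompute()
    return tree


def _reattach(
    tree: LineageTree, clone: Clone, new_parent: str, timepoint: str
) -> None:
    if timepoint == "diagnosis":
        tree.parent_dx[clone.clone_id] = new_parent
        if clone.at_relapse:
            # keep the relapse mirror of the persisting topology in sync
            anc = new_parent
            while anc is not None and not tree.clones[anc].at_relapse:
                anc = tree.parent_dx.get(anc)
            if anc is not None:
                tree.parent_rel[clone.clone_id] = anc
    else:
        tree.parent_rel[clone.clone_id] = new_parent
    tree._recompute()


# ---------------------------------------------------------------------------
# Qualitative SV/CNV placement
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SvCnvEvent:
    """A structural variant or copy-number event with per-assay detection.

    ``detected_dx``/``detected_rel`` map assay names (e.g. ``wgs``,
    ``capture``, ``snp_array``) to detection status at each timepoint.
    """

    event_id: str
    genes: tuple[str, ...]
    type: str  # "SV" | "CNV"
    detected_dx: Mapping[str, bool]
    detected_rel: Mapping[str, bool]
    manual_review_subclonal_dx: bool = False
    placement: str | None = None


def place_sv_cnv(event: SvCnvEvent) -> SvCnvEvent:
    """Assign a qualitative clonal placement to an SV/CNV.

    Events present at both timepoints sit in the ancestral/predominant
    clone by default, with two exceptions: (1) detection by deep capture
    but not WGS at diagnosis indicates a diagnosis subclone; (2) an
    automated relapse-specific call overridden as subclonal at diagnosis by
    manual array review. Events with evidence at only one timepoint are
    timepoint-specific; no evidence anywhere is contradictory.
    """
    if event.type not in ("SV", "CNV"):
        raise ValueError(f"bad event type: {event.type!r}")
    dx = any(event.detected_dx.values())
    rel = any(event.detected_rel.values())
    if not dx and not rel:
        if event.manual_review_subclonal_dx:
            placement = "subclonal_dx"
        else:
            raise ValueError(
                f"event {event.event_id!r}: no detection at any "
                "assay/timepoint"
            )
    elif dx and rel:
        capture_pos = event.detected_dx.get("capture", False)
        wgs_neg = "wgs" in event.detected_dx and not event.detected_dx["wgs"]
        placement = "subclonal_dx" if (capture_pos and wgs_neg) else "ancestral"
    elif rel:
        placement = (
            "subclonal_dx"
            if event.manual_review_subclonal_dx
            else "rel_specific"
        )
    else:
        placement = "dx_specific"
    return replace(event, placement=placement)
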