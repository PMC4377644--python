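"""Lineage construction: greedy nesting, founder mapping, ambiguity rules,
SV/CNV placement."""

import pytest

from clonetrace.lineage import (
    Ambiguity,
    ClusterSummary,
    InfeasibleLineageError,
    SvCnvEvent,
    build_lineage,
    cluster_cell_fraction,
    map_relapse_founders,
    place_sv_cnv,
    resolve_ambiguity,
)


def CS(label, category, dx, rel, **kw):
    return ClusterSummary(
        label=label, category=category, cell_fraction_dx=dx,
        cell_fraction_rel=rel, **kw
    )


class TestCellFraction:
    def test_clonal_het_pure_tumour(self):
        assert cluster_cell_fraction(0.5, 1.0) == 1.0

    def test_half_of_low_purity_sample(self):
        assert cluster_cell_fraction(0.06, 0.24) == pytest.approx(0.5)

    def test_hotspot_at_maf_0233(self):
        # a 0.233-MAF subclonal hotspot in a pure sample sits in ~47% of cells
        assert cluster_cell_fraction(0.233, 1.0) == pytest.approx(0.466)

    def test_superclonal_warns_and_caps(self):
        with pytest.warns(UserWarning, match="super-clonal"):
            assert cluster_cell_fraction(0.58, 1.0) == 1.0

    def test_invalid_purity(self):
        with pytest.raises(ValueError):
            cluster_cell_fraction(0.2, 0.0)


class TestBuildLineage:
    def test_single_shared_cluster_single_founder(self):
        tree = build_lineage([CS("s", "shared", 1.0, 1.0)])
        assert len(tree.clones) == 1
        founder = tree.founder_clone()
        assert founder.own_cluster == "s"
        assert not tree.children(founder.clone_id, "diagnosis")

    def test_nested_chain_residuals(self):
        tree = build_lineage(
            [
                CS("a", "shared", 1.0, 1.0),
                CS("b", "shared", 0.5, 0.5),
                CS("c", "shared", 0.2, 0.2),
            ]
        )
        by_cluster = {c.own_cluster: c for c in tree.clones.values()}
        assert tree.parent_dx[by_cluster["b"].clone_id] == by_cluster["a"].clone_id
        assert tree.parent_dx[by_cluster["c"].clone_id] == by_cluster["b"].clone_id
        assert by_cluster["a"].residual_fraction_dx == pytest.approx(0.5)
        assert by_cluster["b"].residual_fraction_dx == pytest.approx(0.3)
        assert by_cluster["c"].residual_fraction_dx == pytest.approx(0.2)

    def test_no_shared_cluster_rejected(self):
        with pytest.raises(ValueError, match="shared"):
            build_lineage([CS("a", "dx_specific", 0.9, 0.0)])

    def test_infeasible_fraction_raises_naming_cluster(self):
        with pytest.raises(InfeasibleLineageError, match="big"):
            build_lineage(
                [
                    CS("s", "shared", 0.3, 1.0),
                    CS("big", "dx_specific", 0.9, 0.0),
                ]
            )

    def test_carried_sets_accumulate_along_paths(self):
        tree = build_lineage(
            [
                CS("s", "shared", 1.0, 1.0),
                CS("t", "shared", 0.4, 1.0),
                CS("r", "rel_specific", 0.0, 0.8),
            ]
        )
        rel_clone = tree.clone_by_cluster("r")
        assert rel_clone.clusters == {"s", "t", "r"}

    def test_pigeonhole_conservation_at_every_node(self):
        tree = build_lineage(
            [
                CS("s", "shared", 1.0, 1.0),
                CS("u", "shared", 0.35, 0.6),
                CS("a", "dx_specific", 0.55, 0.0),
                CS("b", "dx_specific", 0.2, 0.0),
                CS("r1", "rel_specific", 0.0, 0.55),
                CS("r2", "rel_specific", 0.0, 0.3),
            ]
        )
        for tp in ("diagnosis", "relapse"):
            for clone in tree.clones.values():
                total = (
                    clone.total_fraction_dx
                    if tp == "diagnosis"
                    else clone.total_fraction_rel
                )
                child_sum = sum(
                    (
                        tree.clones[c].total_fraction_dx
                        if tp == "diagnosis"
                        else tree.clones[c].total_fraction_rel
                    )
                    for c in tree.children(clone.clone_id, tp)
                )
                assert child_sum <= total + tree.epsilon

    def test_determinism(self):
        clusters = [
            CS("s", "shared", 1.0, 1.0),
            CS("u", "shared", 0.3, 0.9),
            CS("a", "dx_specific", 0.6, 0.0),
            CS("r", "rel_specific", 0.0, 0.7),
        ]
        t1 = build_lineage(clusters)
        t2 = build_lineage(list(reversed(clusters)))
        assert t1.to_dict() == t2.to_dict()


class TestPapspnStructure:
    """Founder + clonal diagnosis cluster geometry: the founder is fully
    consumed by its children and survives only as an inferred clone."""

    def clusters(self):
        return [
            CS("c", "shared", 1.0, 1.0),
            CS("d", "shared", 0.03, 1.0, drivers=frozenset({"JAK"})),
            CS("a", "dx_specific", 0.95, 0.0, drivers=frozenset({"JAK"})),
            CS("b", "dx_specific", 0.03, 0.0, drivers=frozenset({"JAK"})),
            CS("e", "rel_specific", 0.0, 1.0),
            CS("f", "rel_specific", 0.0, 0.67),
        ]

    def test_structure_and_survivor(self):
        tree = build_lineage(self.clusters())
        map_relapse_founders(tree)
        tree = resolve_ambiguity(tree)
        by_cluster = {c.own_cluster: c for c in tree.clones.values()}
        founder = tree.founder_clone()
        assert founder.own_cluster == "c"
        # founder consumed below detection -> inferred ancestral node
        assert founder.inferred
        # three real diagnosis clones
        real_dx = [
            c for c in tree.clones.values()
            if c.at_diagnosis and not c.inferred
        ]
        assert len(real_dx) == 3
        # mutually exclusive JAK drivers force b out of the a/d lineages
        assert tree.parent_dx[by_cluster["b"].clone_id] == founder.clone_id
        # the minor shared cluster d seeds the relapse
        assert tree.founder_edges == [
            (by_cluster["d"].clone_id, by_cluster["e"].clone_id)
        ]
        # nested relapse clones: e under d, f under e
        assert tree.parent_rel[by_cluster["e"].clone_id] == by_cluster["d"].clone_id
        assert tree.parent_rel[by_cluster["f"].clone_id] == by_cluster["e"].clone_id

    def test_driver_exclusivity_is_recorded(self):
        tree = build_lineage(self.clusters())
        tree = resolve_ambiguity(tree)
        amb = next(a for a in tree.ambiguities if a.cluster == "b")
        assert amb.resolved_by == "driver_exclusivity"


class TestDualLineage:
    """Two sibling diagnosis clones both persist to relapse with reversed
    dominance; both map as relapse founders."""

    def clusters(self):
        return [
            CS("a", "shared", 1.0, 1.0),
            CS("b", "shared", 0.75, 0.08, drivers=frozenset({"RAS"})),
            CS("c", "shared", 0.125, 0.92, drivers=frozenset({"RAS"})),
            CS("d", "rel_specific", 0.0, 0.55),
            CS("e", "rel_specific", 0.0, 0.30),
        ]

    def test_siblings_not_nested(self):
        tree = build_lineage(self.clusters())
        by_cluster = {c.own_cluster: c for c in tree.clones.values()}
        a = by_cluster["a"].clone_id
        assert tree.parent_dx[by_cluster["b"].clone_id] == a
        # c cannot nest under b: b has no relapse room for c's 92%
        assert tree.parent_dx[by_cluster["c"].clone_id] == a

    def test_dual_founder_mapping_with_dominance_reversal(self):
        tree = build_lineage(self.clusters())
        edges = map_relapse_founders(tree)
        by_cluster = {c.own_cluster: c for c in tree.clones.values()}
        anchors = {dx for dx, _ in edges}
        assert anchors == {
            by_cluster["b"].clone_id, by_cluster["c"].clone_id
        }
        b, c = by_cluster["b"], by_cluster["c"]
        assert b.total_fraction_dx > c.total_fraction_dx
        assert b.total_fraction_rel < c.total_fraction_rel


class TestSpectrumResolution:
    """A hypermutated relapse cluster chooses the parent whose mutation
    spectrum it shares; a non-hypermutated cluster avoids the
    hypermutated lineage."""

    def clusters(self):
        return [
            CS("a", "shared", 1.0, 1.0, transitions=15, transversions=5),
            CS("b", "shared", 0.03, 1.0, transitions=8, transversions=2),
            # non-hypermutated relapse cluster (60% transitions)
            CS("c", "rel_specific", 0.0, 1.0, transitions=3, transversions=2),
            # hypermutated: 239 SNVs, 99% transitions
            CS("d", "rel_specific", 0.0, 0.52, transitions=237,
               transversions=2),
            # 98 SNVs, 99% transitions: could sit under c or d by fractions
            CS("e", "rel_specific", 0.0, 0.30, transitions=97,
               transversions=1),
            # 21 SNVs, ~76% transitions: could sit under c, d or e
            CS("f", "rel_specific", 0.0, 0.10, transitions=16,
               transversions=5),
        ]

    def test_hypermutated_cluster_placed_under_hypermutated_parent(self):
        tree = build_lineage(self.clusters())
        tree = resolve_ambiguity(tree)
        by_cluster = {c.own_cluster: c for c in tree.clones.values()}
        assert (
            tree.parent_rel[by_cluster["e"].clone_id]
            == by_cluster["d"].clone_id
        )
        amb = next(a for a in tree.ambiguities if a.cluster == "e")
        assert amb.resolved_by == "spectrum"

    def test_normal_spectrum_cluster_avoids_hypermutated_lineage(self):
        tree = build_lineage(self.clusters())
        tree = resolve_ambiguity(tree)
        by_cluster = {c.own_cluster: c for c in tree.clones.values()}
        assert (
            tree.parent_rel[by_cluster["f"].clone_id]
            == by_cluster["c"].clone_id
        )

    def test_no_evidence_keeps_ambiguity_annotated(self):
        clusters = [
            CS("s", "shared", 1.0, 1.0),
            CS("p", "rel_specific", 0.0, 0.5),
            CS("q", "rel_specific", 0.0, 0.3),
            CS("r", "rel_specific", 0.0, 0.2),
        ]
        tree = build_lineage(clusters)
        tree = resolve_ambiguity(tree)
        unresolved = [a for a in tree.ambiguities if a.alternatives]
        assert unresolved
        assert all("unresolved" in a.note for a in unresolved)


class TestMapRelapseFounders:
    def test_single_minor_survivor_single_edge(self):
        tree = build_lineage(
            [
                CS("s", "shared", 1.0, 1.0),
                CS("t", "shared", 0.07, 1.0),
                CS("a", "dx_specific", 0.9, 0.0),
                CS("r", "rel_specific", 0.0, 1.0),
            ]
        )
        edges = map_relapse_founders(tree)
        t = tree.clone_by_cluster("t").clone_id
        r = tree.clone_by_cluster("r").clone_id
        assert edges == [(t, r)]


class TestPlaceSvCnv:
    def make_event(self, **kw):
        base = dict(
            event_id="ev1", genes=("CDKN2A",), type="CNV",
            detected_dx={"wgs": True, "capture": True},
            detected_rel={"wgs": True, "capture": True},
        )
        base.update(kw)
        return SvCnvEvent(**base)

    def test_detected_everywhere_is_ancestral(self):
        assert place_sv_cnv(self.make_event()).placement == "ancestral"

    def test_capture_only_at_diagnosis_is_subclonal(self):
        ev = self.make_event(
            detected_dx={"wgs": False, "capture": True},
            detected_rel={"wgs": True, "capture": True},
        )
        assert place_sv_cnv(ev).placement == "subclonal_dx"

    def test_relapse_only_event(self):
        ev = self.make_event(
            detected_dx={"wgs": False, "capture": False},
            detected_rel={"wgs": True, "capture": True},
        )
        assert place_sv_cnv(ev).placement == "rel_specific"

    def test_manual_review_overrides_relapse_specific_call(self):
        ev = self.make_event(
            detected_dx={"wgs": False, "capture": False},
            detected_rel={"wgs": True},
            manual_review_subclonal_dx=True,
        )
        assert place_sv_cnv(ev).placement == "subclonal_dx"

    def test_diagnosis_only_event(self):
        ev = self.make_event(
            detected_dx={"wgs": True}, detected_rel={"wgs": False}
        )
        assert place_sv_cnv(ev).placement == "dx_specific"

    def test_no_detection_anywhere_rejected(self):
        ev = self.make_event(
            detected_dx={"wgs": False}, detected_rel={"wgs": False}
        )
        with pytest.raises(ValueError, match="no detection"):
            place_sv_cnv(ev)
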