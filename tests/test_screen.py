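"""Family-specific homolog screens on constructed genomes."""

from __future__ import annotations

import pandas as pd
import pytest

from motortrace.context import OperonIndex, find_marker_clusters, group_operons
from motortrace.models import FeatureTable, ProteinFeature, ValidationError
from motortrace.screen import (
    PROFILE_MGTE_N,
    PROFILE_PILN,
    PROFILE_TPR,
    best_hit,
    best_hit_screen,
    detect_t4p,
    screen_fcpmno,
    screen_flgy,
    screen_tpr_scaffolds,
)

from conftest import dom_row, dom_table, make_genome, seq_row, seq_table


def locus(i: int, genome_id: str = "g1") -> str:
    return f"{genome_id}_{i:05d}"


def features_for(genome, **overrides: ProteinFeature) -> FeatureTable:
    table = FeatureTable()
    for gene in genome:
        table.add(ProteinFeature(protein_id=gene.protein_id, length=400))
    for feat in overrides.values():
        table.add(feat)
    return table


class TestBestHit:
    def test_lowest_evalue_wins(self):
        hits = seq_table(
            [seq_row("FlgY", "g1_1", 1e-5), seq_row("FlgY", "g1_2", 1e-8)]
        )
        assert best_hit(hits, "FlgY").locus_tag == "g1_2"

    def test_threshold_is_strict(self):
        assert best_hit(seq_table([seq_row("FlgY", "g1_1", 1e-2)]), "FlgY") is None
        assert best_hit(seq_table([seq_row("FlgY", "g1_1", 1e-3)]), "FlgY") is None

    def test_empty_table(self):
        assert best_hit(seq_table([]), "FlgY") is None

    def test_tiebreak_matches_brute_force_ordering(self):
        rows = [
            seq_row("FcpO", "g1_b", 1e-6, bitscore=50.0),
            seq_row("FcpO", "g1_a", 1e-6, bitscore=50.0),
            seq_row("FcpO", "g1_c", 1e-6, bitscore=70.0),
            seq_row("FcpO", "g1_d", 1e-5, bitscore=99.0),
        ]
        table = seq_table(rows)
        expected = min(rows, key=lambda r: (r["evalue"], -r["bitscore"], r["sseqid"]))
        assert best_hit(table, "FcpO").locus_tag == expected["sseqid"]

    def test_malformed_row_errors(self):
        bad = seq_table([seq_row("FlgY", "g1_1", evalue=-1.0)])
        with pytest.raises(ValidationError, match="malformed"):
            best_hit(bad, "FlgY")

    def test_weaker_cutoff_never_loses_a_hit(self):
        hits = seq_table([seq_row("FlgY", "g1_1", 1e-4)])
        assert best_hit(hits, "FlgY", evalue_max=1e-3) is not None
        assert best_hit(hits, "FlgY", evalue_max=1e-5) is None


@pytest.fixture()
def clustered_genome():
    """40-gene genome with a flagellar marker cluster at indices 5..10."""
    genome = make_genome(40)
    markers = [locus(i) for i in range(5, 11)]
    clusters = find_marker_clusters(genome, markers, max_gap=5)
    return genome, clusters


class TestFlgyScreen:
    def test_hit_near_cluster_is_context_validated(self, clustered_genome):
        genome, clusters = clustered_genome
        dom = dom_table([dom_row(locus(13), PROFILE_MGTE_N)])  # 2 genes away
        calls, discards = screen_flgy(
            dom, genome, clusters, flagellated=True,
            features=features_for(genome),
        )
        assert [c.tier for c in calls] == ["context_validated"]
        assert calls[0].locus_tag == locus(13) and not discards

    def test_distant_hit_discarded_for_context(self, clustered_genome):
        genome, clusters = clustered_genome
        dom = dom_table([dom_row(locus(35), PROFILE_MGTE_N)])
        calls, discards = screen_flgy(
            dom, genome, clusters, flagellated=False,
            features=features_for(genome),
        )
        assert not calls and discards[0].reason == "context"

    def test_rescue_candidates_near_flijk(self, clustered_genome):
        genome, clusters = clustered_genome
        calls, _ = screen_flgy(
            dom_table([]), genome, clusters, flagellated=True,
            features=features_for(genome), flijk_loci=[locus(20)],
            rescue_window=2,
        )
        assert calls and all(c.tier == "rescue_candidate" for c in calls)
        assert {c.locus_tag for c in calls} == {
            locus(i) for i in (18, 19, 21, 22)
        }

    def test_no_rescue_when_validated_call_exists(self, clustered_genome):
        genome, clusters = clustered_genome
        dom = dom_table([dom_row(locus(13), PROFILE_MGTE_N)])
        calls, _ = screen_flgy(
            dom, genome, clusters, flagellated=True,
            features=features_for(genome), flijk_loci=[locus(20)],
        )
        assert all(c.tier == "context_validated" for c in calls)

    def test_hit_on_unknown_protein_errors(self, clustered_genome):
        genome, clusters = clustered_genome
        dom = dom_table([dom_row("nope_1", PROFILE_MGTE_N)])
        with pytest.raises(ValidationError, match="absent"):
            screen_flgy(
                dom, genome, clusters, flagellated=False,
                features=features_for(genome),
            )


def tpr_motifs(pid: str, n: int, gap: int = 2, start: int = 10) -> list[dict]:
    rows, pos = [], start
    for _ in range(n):
        rows.append(dom_row(pid, PROFILE_TPR, pos, pos + 33, 1e-8))
        pos += 34 + gap
    return rows


class TestTprScreen:
    def test_clean_candidate_near_cluster_called_pfla(self, clustered_genome):
        genome, clusters = clustered_genome
        dom = dom_table(tpr_motifs(locus(12), 5))
        calls, _ = screen_tpr_scaffolds(
            dom, genome, clusters, features_for(genome)
        )
        assert [c.family for c in calls] == ["PflA_like"]

    def test_tm_plus_beta_pair_is_pflb(self, clustered_genome):
        genome, clusters = clustered_genome
        feats = features_for(
            genome,
            x=ProteinFeature(locus(12), 800, has_tm=True, has_beta_pair=True),
        )
        calls, _ = screen_tpr_scaffolds(
            dom_table(tpr_motifs(locus(12), 6)), genome, clusters, feats
        )
        assert [c.family for c in calls] == ["PflB_like"]

    def test_blacklisted_enzyme_excluded(self, clustered_genome):
        genome, clusters = clustered_genome
        feats = features_for(
            genome,
            x=ProteinFeature(
                locus(12), 800,
                blacklist_domains=frozenset({"glycosyltransferase"}),
            ),
        )
        calls, discards = screen_tpr_scaffolds(
            dom_table(tpr_motifs(locus(12), 8)), genome, clusters, feats
        )
        assert not calls and "blacklist" in discards[0].reason

    def test_too_few_sequential_motifs_excluded(self, clustered_genome):
        genome, clusters = clustered_genome
        calls, discards = screen_tpr_scaffolds(
            dom_table(tpr_motifs(locus(12), 2)), genome, clusters,
            features_for(genome),
        )
        assert not calls and "sequential_motifs" in discards[0].reason

    def test_large_motif_gap_breaks_the_run(self, clustered_genome):
        genome, clusters = clustered_genome
        rows = tpr_motifs(locus(12), 2) + tpr_motifs(locus(12), 2, start=500)
        calls, discards = screen_tpr_scaffolds(
            dom_table(rows), genome, clusters, features_for(genome),
            min_sequential=3, max_motif_gap_aa=50,
        )
        assert not calls and "sequential_motifs" in discards[0].reason

    def test_decoy_far_from_cluster_excluded(self, clustered_genome):
        genome, clusters = clustered_genome
        calls, discards = screen_tpr_scaffolds(
            dom_table(tpr_motifs(locus(30), 6)), genome, clusters,
            features_for(genome),
        )
        assert not calls and "context" in discards[0].reason


def fcp_genome(with_tff: bool = False, with_mia: bool = True):
    """Genome with a contiguous same-strand M,N,O triplet at 20..22."""
    products = {}
    genome = make_genome(40, gaps={i: 50 for i in range(40)}, products=products)
    dom = dom_table([dom_row(locus(21), PROFILE_PILN, 10, 150, 1e-9)])
    seq_rows = [
        seq_row("FcpM", locus(20), 1e-9),
        seq_row("FcpO", locus(22), 1e-9),
    ]
    tff = {}
    if with_tff:
        tff = {locus(23): "PilP", locus(24): "PilQ"}
    mia = [locus(19)] if with_mia else []
    operons = OperonIndex(group_operons(genome))
    return genome, dom, seq_table(seq_rows), operons, tff, mia


class TestFcpScreen:
    def test_triplet_with_miab_upstream_called_fcp(self):
        genome, dom, seq, operons, tff, mia = fcp_genome()
        calls, discards, review = screen_fcpmno(
            dom, seq, genome, operons, tff_markers=tff, mia_loci=mia
        )
        assert sorted(c.family for c in calls) == ["FcpM", "FcpN", "FcpO"]
        assert all("miaB_upstream" in c.evidence for c in calls)
        assert not discards and not review

    def test_triplet_next_to_pilpq_called_pil(self):
        genome, dom, seq, operons, tff, mia = fcp_genome(with_tff=True)
        calls, _, review = screen_fcpmno(
            dom, seq, genome, operons, tff_markers=tff, mia_loci=mia
        )
        assert sorted(c.family for c in calls) == ["PilM", "PilN", "PilO"]
        assert not review

    def test_lone_anchor_is_incomplete_triplet(self):
        genome = make_genome(40, gaps={i: 50 for i in range(40)})
        dom = dom_table([dom_row(locus(21), PROFILE_PILN, 10, 150, 1e-9)])
        calls, discards, _ = screen_fcpmno(
            dom, seq_table([]), genome, OperonIndex(group_operons(genome))
        )
        assert not calls and discards[0].reason == "incomplete_triplet"

    def test_ambiguous_tff_adjacency_goes_to_review(self):
        genome, dom, seq, operons, _, mia = fcp_genome()
        tff = {locus(25): "PilT"}  # a motor gene nearby, but no pilP/pilQ
        calls, _, review = screen_fcpmno(
            dom, seq, genome, operons, tff_markers=tff, mia_loci=mia
        )
        assert not calls and review and "ambiguous" in review[0].reason

    def test_no_gene_gets_both_fcp_and_pil_call(self):
        for with_tff in (False, True):
            genome, dom, seq, operons, tff, mia = fcp_genome(with_tff=with_tff)
            calls, _, _ = screen_fcpmno(
                dom, seq, genome, operons, tff_markers=tff, mia_loci=mia
            )
            per_locus = {}
            for c in calls:
                per_locus.setdefault(c.locus_tag, set()).add(c.family[:3])
            assert all(len(v) == 1 for v in per_locus.values())


def t4p_components(genome_id: str = "g1", fused: bool = False):
    if fused:
        comp = {
            "PilM": {locus(10)}, "PilN": {locus(10)},
            "PilO": {locus(11)}, "PilP": {locus(12)}, "PilQ": {locus(13)},
        }
    else:
        comp = {
            "PilM": {locus(10)}, "PilN": {locus(11)}, "PilO": {locus(12)},
            "PilP": {locus(13)}, "PilQ": {locus(14)},
        }
    comp.update({"PilB": {locus(30)}, "PilC": set(), "PilT": {locus(31)}, "PilU": set()})
    return comp


class TestT4P:
    def test_canonical_cluster_present_unfused(self):
        genome = make_genome(40)
        verdict = detect_t4p(t4p_components(), genome, dom_table([]))
        assert verdict.present and not verdict.fused_pilMN
        assert verdict.order == ("PilM", "PilN", "PilO", "PilP", "PilQ")

    def test_fused_cluster_present_with_flag(self):
        genome = make_genome(40)
        dom = dom_table(
            [
                dom_row(locus(10), "PilM", 5, 140, 1e-9),
                dom_row(locus(10), PROFILE_PILN, 165, 310, 1e-9),
            ]
        )
        verdict = detect_t4p(t4p_components(fused=True), genome, dom)
        assert verdict.present and verdict.fused_pilMN
        assert verdict.order == ("PilMN", "PilO", "PilP", "PilQ")

    def test_lonely_pilt_is_absent_with_missing_list(self):
        genome = make_genome(40)
        comp = {f: set() for f in t4p_components()}
        comp["PilT"] = {locus(31)}
        verdict = detect_t4p(comp, genome, dom_table([]))
        assert not verdict.present
        assert "PilM" in verdict.missing and "PilQ" in verdict.missing

    def test_wrong_order_not_called(self):
        genome = make_genome(40)
        comp = t4p_components()
        comp["PilM"], comp["PilQ"] = comp["PilQ"], comp["PilM"]  # swap ends
        verdict = detect_t4p(comp, genome, dom_table([]))
        assert not verdict.present

    def test_fewer_than_two_motor_genes_not_called(self):
        genome = make_genome(40)
        comp = t4p_components()
        comp["PilB"] = set()
        verdict = detect_t4p(comp, genome, dom_table([]))
        assert not verdict.present

    def test_reverse_strand_cluster_detected(self):
        genome = make_genome(40, strands={i: "-" for i in range(40)})
        comp = {
            "PilM": {locus(14)}, "PilN": {locus(13)}, "PilO": {locus(12)},
            "PilP": {locus(11)}, "PilQ": {locus(10)},
            "PilB": {locus(30)}, "PilC": set(), "PilT": {locus(31)}, "PilU": set(),
        }
        verdict = detect_t4p(comp, genome, dom_table([]))
        assert verdict.present


class TestBestHitScreen:
    def test_all_seven_families_called(self):
        rows = [
            seq_row(q, locus(i), 1e-9)
            for i, q in enumerate(
                ("FlgY", "PflA", "PflB", "PflD", "FcpM", "FcpN", "FcpO")
            )
        ]
        calls = best_hit_screen(
            seq_table(rows), "g1",
            query_families=("FlgY", "PflA", "PflB", "PflD", "FcpM", "FcpN", "FcpO"),
        )
        assert len(calls) == 7 and all(c.tier == "best_hit" for c in calls)
        assert {c.family for c in calls} == {
            "FlgY", "PflA_like", "PflB_like", "PflD", "FcpM", "FcpN", "FcpO"
        }

    def test_family_without_qualifying_hit_not_called(self):
        rows = [seq_row("FcpM", locus(1), 1e-2)]
        calls = best_hit_screen(seq_table(rows), "g1", query_families=("FcpM",))
        assert calls == []

    def test_struct_confirmed_recorded_as_evidence(self):
        feats = FeatureTable(
            [ProteinFeature(locus(1), 400, struct_confirmed=True)]
        )
        calls = best_hit_screen(
            seq_table([seq_row("PflD", locus(1), 1e-9)]), "g1",
            query_families=("PflD",), features=feats,
        )
        assert "struct_confirmed" in calls[0].evidence
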