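"""End-to-end orchestration: simulate/load -> curate -> census -> screen -> profile.

A :class:`RunConfig` holds every threshold in one serializable place; a
run produces a :class:`RunReport` whose JSON form is a pure function of
config plus inputs (re-running an identical configuration yields a
byte-identical report, which is how determinism is checked).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import pandas as pd

from . import __version__
from .census import (
    CORE_FAMILIES,
    CensusResult,
    census_core_genes,
    census_table,
)
from .context import OperonIndex, find_marker_clusters, group_operons
from .curation import balance_taxa, filter_quality
from .models import Discard, FeatureTable, GenomeAnnotation, HomologCall, ValidationError
from .profiling import (
    PresenceMatrix,
    build_matrix,
    cooccurrence,
    export_tree_annotations,
    fitch_ancestral,
    prevalence,
)
from .screen import (
    T4PVerdict,
    best_hit_screen,
    calls_table,
    detect_t4p,
    screen_fcpmno,
    screen_flgy,
    screen_tpr_scaffolds,
)
from .simulate import (
    QUERY_FAMILIES,
    SynthConfig,
    SynthDataset,
    load_dataset,
    simulate_dataset,
)

TRAIT_LIST = (
    "flagellar_gene_set",
    "FlgY",
    "PflA_like",
    "PflB_like",
    "PflD",
    "FcpM",
    "FcpN",
    "FcpO",
    "FcpMNO",
    "T4P",
)

#: T4P component evidence channels: sequence query families and domain
#: profiles that identify each core/motor component
T4P_COMPONENT_QUERIES: dict[str, tuple[str, ...]] = {
    "PilM": ("PilM", "FcpM"),
    "PilN": ("PilN", "FcpN"),
    "PilO": ("PilO", "FcpO"),
    "PilP": ("PilP",),
    "PilQ": ("PilQ",),
    "PilB": ("PilB",),
    "PilC": ("PilC",),
    "PilT": ("PilT",),
    "PilU": ("PilU",),
}

T4P_COMPONENT_PROFILES: dict[str, tuple[str, ...]] = {
    "PilM": ("PilM",),
    "PilN": ("COG3166",),
    "PilO": ("PilO",),
    "PilP": ("PilP",),
    "PilQ": ("PilQ",),
    "PilB": ("PilB",),
    "PilC": ("PilC",),
    "PilT": ("PilT",),
    "PilU": ("PilU",),
}


@dataclass(frozen=True)
class RunConfig:
    """All pipeline thresholds plus the data source."""

    synth: SynthConfig = field(default_factory=SynthConfig)
    input_dir: str | None = None

    # curation
    min_completeness: float = 70.0
    max_contamination: float = 10.0
    size_threshold: int = 200
    balancing_rank: str = "phylum"
    curation_order: str = "balance_then_filter"  # or "filter_then_balance"

    # census
    min_core: int = 20
    census_evalue: float = 1e-5

    # genomic context
    context_n: int = 5
    cluster_max_gap: int = 5
    operon_max_intergenic_bp: int = 150

    # screens
    screen_evalue: float = 1e-3
    t4p_evalue: float = 1e-5
    t4p_max_gap: int = 3
    min_sequential: int = 3
    max_motif_gap_aa: int = 50
    rescue_window: int = 2
    fusion_max_overlap_frac: float = 0.1
    best_hit_families: tuple[str, ...] = ("PflD",)

    def __post_init__(self) -> None:
        if not 0 <= self.min_core <= len(CORE_FAMILIES):
            raise ValidationError(
                f"min_core must be in [0, {len(CORE_FAMILIES)}]"
            )
        if not 0.0 <= self.min_completeness <= 100.0:
            raise ValidationError("min_completeness must be in [0, 100]")
        if self.max_contamination < 0:
            raise ValidationError("max_contamination must be >= 0")
        for name in ("census_evalue", "screen_evalue", "t4p_evalue"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        for name in (
            "context_n",
            "cluster_max_gap",
            "t4p_max_gap",
            "rescue_window",
            "size_threshold",
            "operon_max_intergenic_bp",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.min_sequential < 1:
            raise ValidationError("min_sequential must be >= 1")
        if self.curation_order not in ("balance_then_filter", "filter_then_balance"):
            raise ValidationError(
                f"unknown curation_order {self.curation_order!r}"
            )

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()


@dataclass
class RunReport:
    """Machine-readable summary of one pipeline run."""

    payload: dict

    def to_json(self) -> str:
        return json.dumps(self.payload, indent=1, sort_keys=True)

    @property
    def hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()


def _evidence_tables(dataset: SynthDataset) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Attach query_family / genome_id columns to the raw hit tables."""
    locus_to_genome: dict[str, str] = {}
    for gid, genome in dataset.genomes.items():
        for gene in genome:
            locus_to_genome[gene.locus_tag] = gid

    seq = dataset.sequence_hits.copy()
    if len(seq):
        mapping = dict(QUERY_FAMILIES)
        seq["query_family"] = seq["qseqid"].map(mapping).fillna(seq["qseqid"])
        seq["genome_id"] = seq["sseqid"].map(locus_to_genome)
        unknown = seq["genome_id"].isna()
        if unknown.any():
            bad = sorted(seq.loc[unknown, "sseqid"].unique())[:5]
            raise ValidationError(f"hit targets not in any genome: {bad}")
    else:
        seq["query_family"] = pd.Series(dtype=object)
        seq["genome_id"] = pd.Series(dtype=object)

    dom = dataset.domain_hits.copy()
    if len(dom):
        dom["genome_id"] = dom["protein_id"].map(locus_to_genome)
        unknown = dom["genome_id"].isna()
        if unknown.any():
            bad = sorted(dom.loc[unknown, "protein_id"].unique())[:5]
            raise ValidationError(f"domain hits on unknown proteins: {bad}")
    else:
        dom["genome_id"] = pd.Series(dtype=object)
    return dom, seq


def _qualifying_loci(
    seq: pd.DataFrame,
    dom: pd.DataFrame,
    queries: tuple[str, ...],
    profiles: tuple[str, ...],
    evalue_max: float,
) -> set[str]:
    loci: set[str] = set()
    if len(seq):
        sub = seq[seq["query_family"].isin(queries) & (seq["evalue"] < evalue_max)]
        loci.update(sub["sseqid"].astype(str))
    if len(dom) and profiles:
        sub = dom[dom["profile_id"].isin(profiles) & (dom["evalue"] < evalue_max)]
        loci.update(sub["protein_id"].astype(str))
    return loci


def run_pipeline(
    config: RunConfig,
    dataset: SynthDataset | None = None,
    out_dir: str | Path | None = None,
) -> RunReport:
    """Execute all stages and assemble the run report.

    ``dataset`` defaults to a fresh simulation from ``config.synth`` (or
    a load from ``config.input_dir``); passing one explicitly lets the
    caller reuse inputs across runs.
    """
    if dataset is None:
        if config.input_dir is not None:
            dataset = load_dataset(config.input_dir)
        else:
            dataset = simulate_dataset(config.synth)

    # --- curation ------------------------------------------------------
    n_input = len(dataset.metas)
    if config.curation_order == "balance_then_filter":
        balanced = balance_taxa(
            dataset.metas,
            balancing_rank=config.balancing_rank,
            size_threshold=config.size_threshold,
        )
        curated_metas, removals = filter_quality(
            balanced,
            min_completeness=config.min_completeness,
            max_contamination=config.max_contamination,
        )
    else:
        passed, removals = filter_quality(
            dataset.metas,
            min_completeness=config.min_completeness,
            max_contamination=config.max_contamination,
        )
        curated_metas = balance_taxa(
            passed,
            balancing_rank=config.balancing_rank,
            size_threshold=config.size_threshold,
        )
    curated = sorted(
        m.genome_id for m in curated_metas if m.genome_id in dataset.genomes
    )

    dom_all, seq_all = _evidence_tables(dataset)
    dom_by_genome = {gid: g for gid, g in dom_all.groupby("genome_id")} if len(dom_all) else {}
    seq_by_genome = {gid: g for gid, g in seq_all.groupby("genome_id")} if len(seq_all) else {}
    empty_dom = dom_all.iloc[0:0]
    empty_seq = seq_all.iloc[0:0]

    # --- census --------------------------------------------------------
    census_results: list[CensusResult] = []
    for sp in curated:
        sp_hits = seq_by_genome.get(sp, empty_seq)
        core_hits = sp_hits[sp_hits["query_family"].isin(CORE_FAMILIES)]
        census_results.append(
            census_core_genes(
                core_hits,
                sp,
                evalue_max=config.census_evalue,
                min_core=config.min_core,
            )
        )
    census_by_sp = {c.species_id: c for c in census_results}

    # --- screens -------------------------------------------------------
    calls: list[HomologCall] = []
    discards: list[Discard] = []
    review: list[Discard] = []
    t4p_verdicts: dict[str, T4PVerdict] = {}
    for sp in curated:
        genome = dataset.genomes[sp]
        dom = dom_by_genome.get(sp, empty_dom)
        seq = seq_by_genome.get(sp, empty_seq)

        core_marker_loci = _qualifying_loci(
            seq, empty_dom, CORE_FAMILIES, (), config.census_evalue
        )
        clusters = (
            find_marker_clusters(
                genome, sorted(core_marker_loci), max_gap=config.cluster_max_gap,
                label="flagellar",
            )
            if core_marker_loci
            else []
        )
        operons = OperonIndex(
            group_operons(genome, max_intergenic_bp=config.operon_max_intergenic_bp)
        )
        flijk = _qualifying_loci(
            seq, empty_dom, ("FliJ", "FliK"), (), config.screen_evalue
        )
        mia = _qualifying_loci(seq, empty_dom, ("miaB",), (), config.screen_evalue)

        flgy_calls, flgy_disc = screen_flgy(
            dom,
            genome,
            clusters,
            flagellated=census_by_sp[sp].is_flagellated,
            features=dataset.features,
            flijk_loci=flijk,
            evalue_max=config.screen_evalue,
            context_n=config.context_n,
            rescue_window=config.rescue_window,
        )
        tpr_calls, tpr_disc = screen_tpr_scaffolds(
            dom,
            genome,
            clusters,
            dataset.features,
            min_sequential=config.min_sequential,
            max_motif_gap_aa=config.max_motif_gap_aa,
            evalue_max=config.screen_evalue,
            context_n=config.context_n,
        )

        tff_markers: dict[str, str] = {}
        for fam in ("PilP", "PilQ", "PilB", "PilC", "PilT", "PilU"):
            for locus in _qualifying_loci(
                seq, dom, T4P_COMPONENT_QUERIES[fam],
                T4P_COMPONENT_PROFILES[fam], config.t4p_evalue,
            ):
                tff_markers[locus] = fam
        fcp_calls, fcp_disc, fcp_review = screen_fcpmno(
            dom,
            seq,
            genome,
            operons,
            tff_markers=tff_markers,
            mia_loci=mia,
            evalue_max=config.screen_evalue,
            adjacency_n=config.context_n,
        )

        component_loci = {
            fam: _qualifying_loci(
                seq, dom, T4P_COMPONENT_QUERIES[fam],
                T4P_COMPONENT_PROFILES[fam], config.t4p_evalue,
            )
            for fam in T4P_COMPONENT_QUERIES
        }
        component_loci = {
            fam: {l for l in loci if l in genome}
            for fam, loci in component_loci.items()
        }
        t4p_verdicts[sp] = detect_t4p(
            component_loci,
            genome,
            dom,
            max_gap=config.t4p_max_gap,
            max_overlap_frac=config.fusion_max_overlap_frac,
            fusion_evalue_max=config.t4p_evalue,
        )

        bh_calls = best_hit_screen(
            seq,
            sp,
            query_families=config.best_hit_families,
            evalue_max=config.screen_evalue,
            features=dataset.features,
        )
        existing = {(c.family, c.genome_id, c.locus_tag) for c in calls}
        for group in (flgy_calls, tpr_calls, fcp_calls, bh_calls):
            for c in group:
                key = (c.family, c.genome_id, c.locus_tag)
                if key not in existing:
                    existing.add(key)
                    calls.append(c)
        discards.extend(flgy_disc + tpr_disc + fcp_disc)
        review.extend(fcp_review)

    # --- profiling -----------------------------------------------------
    matrix = build_matrix(
        calls,
        census_results,
        curated,
        traits=TRAIT_LIST,
        extra_traits={
            "T4P": {sp: v.present for sp, v in t4p_verdicts.items()}
        },
    )
    flagellated = sorted(
        sp for sp in curated if census_by_sp[sp].is_flagellated
    )
    prevalence_block: dict[str, dict] = {}
    cooccurrence_block: dict[str, dict] = {}
    if flagellated:
        for trait in TRAIT_LIST:
            if trait == "flagellar_gene_set":
                continue
            frac, num, den = prevalence(matrix, trait, flagellated)
            prevalence_block[trait] = {
                "fraction": round(frac, 6),
                "numerator": num,
                "denominator": den,
            }
    for trait in TRAIT_LIST:
        if trait == "flagellar_gene_set":
            continue
        co = cooccurrence(matrix, trait, "flagellar_gene_set")
        cooccurrence_block[trait] = {
            "jaccard": round(co.jaccard, 6),
            "both": co.both,
            "a_only": co.a_only,
            "b_only": co.b_only,
            "neither": co.neither,
            "p_enrichment": float(f"{co.p_enrichment:.6e}"),
        }

    ancestral_block: dict[str, dict] = {}
    if len(curated) >= 2:
        subtree = dataset.tree.extract_tree_with_taxa_labels(labels=curated)
        subtree.is_rooted = True
        for trait in TRAIT_LIST:
            col = matrix.column(trait)
            rec = fitch_ancestral(subtree, {sp: int(col.loc[sp]) for sp in curated})
            ancestral_block[trait] = {
                "changes": rec.changes,
                "root_states": sorted(rec.root_states),
            }

    recovery_block = None
    if dataset.truth is not None and dataset.truth.traits:
        recovery_block = _recovery(matrix, dataset, t4p_verdicts, calls, curated)

    payload = {
        "tool": {"name": "motortrace", "version": __version__},
        "config_hash": config.config_hash(),
        "stages": {
            "input_genomes": n_input,
            "curated_genomes": len(curated),
            "removed_by_quality": len(removals),
            "flagellated_species": len(flagellated),
            "homolog_calls": len(calls),
            "discarded_candidates": len(discards),
            "review_items": len(review),
            "t4p_positive": sum(v.present for v in t4p_verdicts.values()),
        },
        "census": {
            c.species_id: {
                "core_count": c.core_count,
                "is_flagellated": c.is_flagellated,
            }
            for c in census_results
        },
        "prevalence_in_flagellated": prevalence_block,
        "cooccurrence_with_flagellar_set": cooccurrence_block,
        "ancestral": ancestral_block,
        "recovery": recovery_block,
    }
    report = RunReport(payload=payload)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(report.to_json())
        census_table(census_results).to_csv(out / "census.tsv", sep="\t", index=False)
        calls_table(calls).to_csv(out / "calls.tsv", sep="\t", index=False)
        pd.DataFrame(
            [dataclasses.asdict(d) for d in discards + review]
        ).to_csv(out / "discards.tsv", sep="\t", index=False)
        matrix.data.to_csv(out / "matrix.tsv", sep="\t", index_label="species")
        if len(curated) >= 2:
            subtree = dataset.tree.extract_tree_with_taxa_labels(labels=curated)
            groups = {
                m.genome_id: m.lineage.get("phylum", "unknown")
                for m in curated_metas
                if m.genome_id in dataset.genomes
            }
            export_tree_annotations(
                matrix, subtree, out / "itol", taxon_groups=groups
            )
    return report


def _recovery(
    matrix: PresenceMatrix,
    dataset: SynthDataset,
    t4p_verdicts: dict[str, T4PVerdict],
    calls: list[HomologCall],
    curated: list[str],
) -> dict:
    """Per-trait precision/recall versus planted truth, on analyzed species."""
    truth = dataset.truth
    block: dict[str, dict] = {"traits": {}}
    for trait in (
        "flagellar_gene_set", "FlgY", "PflA_like", "PflB_like",
        "PflD", "FcpM", "FcpN", "FcpO", "T4P",
    ):
        tp = fp = fn = tn = 0
        col = matrix.column(trait)
        for sp in curated:
            if trait == "flagellar_gene_set":
                true = truth.flagellated[sp]
            else:
                true = truth.traits[sp][trait]
            pred = bool(col.loc[sp])
            if pred and true:
                tp += 1
            elif pred and not true:
                fp += 1
            elif true:
                fn += 1
            else:
                tn += 1
        precision = tp / (tp + fp) if (tp + fp) else 1.0
        recall = tp / (tp + fn) if (tp + fn) else 1.0
        block["traits"][trait] = {
            "tp": tp, "fp": fp, "fn": fn, "tn": tn,
            "precision": round(precision, 6),
            "recall": round(recall, 6),
        }
    decoy_calls = sum(
        1
        for c in calls
        if truth.family_of(c.genome_id, c.locus_tag) == "decoy_tpr"
        and c.tier != "rescue_candidate"
    )
    fusion_mismatch = sum(
        1
        for sp in curated
        if t4p_verdicts[sp].present
        and truth.traits[sp]["T4P"]
        and t4p_verdicts[sp].fused_pilMN != truth.pilMN_fused.get(sp, False)
    )
    fcp_loci = {
        (c.genome_id, c.locus_tag)
        for c in calls
        if c.family in ("FcpM", "FcpN", "FcpO")
    }
    pil_loci = {
        (c.genome_id, c.locus_tag)
        for c in calls
        if c.family.startswith("Pil")
    }
    block["decoy_calls"] = decoy_calls
    block["fusion_mismatches"] = fusion_mismatch
    block["fcp_pil_overlap"] = len(fcp_loci & pil_loci)
    return block
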