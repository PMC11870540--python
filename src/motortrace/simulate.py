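"""Synthetic pangenome generator with ground truth.

Downstream stages (census, neighborhood screens, profiling) are exercised
against simulated genome annotations and noisy evidence tables whose true
gene families are known.  The generator emulates the genomic structures
the screens assume:

* flagellar core genes grouped into a few contiguous clusters, with
  scaffold genes (FlgY, TPR scaffolds, PflD) planted within a bounded
  gene distance of a cluster and *fliJ*/*fliK* adjacent to one cluster;
* an *fcpMNO* operon: contiguous same-strand triplet with *miaB*
  immediately upstream, placed away from any type-IV-filament genes;
* an optional type IV pilus cluster in canonical *pilMNOPQ* order (with
  the *pilM*–*pilN* fusion at a configurable probability) plus the
  PilB/PilC/PilT/PilU genes elsewhere in the genome;
* decoy TPR-repeat enzymes (glycosyltransferases and friends) placed
  strictly farther from flagellar clusters than the context rule allows;
* per-domain and pairwise hit tables with true hits far below the screen
  thresholds, plus configurable false-negative / false-positive noise
  whose spurious E-values straddle the 1e-3 / 1e-5 cutoffs.

Sequence content is deliberately unrealistic (random residues): all
evidence flows through hit tables, so the pipeline never depends on a
live search tool.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from . import io as mtio
from .census import CORE_FAMILIES
from .models import (
    DOMHIT_COLUMNS,
    FeatureTable,
    GeneRecord,
    GenomeAnnotation,
    GenomeMeta,
    ProteinFeature,
    SEQHIT_COLUMNS,
    ValidationError,
)

# profile identifiers used in simulated domain-hit tables
PROFILE_MGTE_N = "PF03448"   # MgtE_N / FlgY ARM-like domain
PROFILE_TPR = "PF00515"      # tetratricopeptide repeat motif
PROFILE_PILN = "COG3166"     # PilN / FcpN coiled-coil profile
PROFILE_PILM = "PilM"        # PilM actin-like domain

#: species-level traits tracked in the truth labels
TRUTH_TRAITS = (
    "FlgY",
    "PflA_like",
    "PflB_like",
    "PflD",
    "FcpM",
    "FcpN",
    "FcpO",
    "T4P",
)

SCAFFOLD_TRAITS = ("FlgY", "PflA_like", "PflB_like", "PflD", "FcpM", "FcpN", "FcpO")

#: enzymatic domain labels that disqualify a TPR protein as a scaffold
DEFAULT_BLACKLIST = (
    "glycosyltransferase",
    "methyltransferase",
    "acetyltransferase",
    "sulfotransferase",
    "metalloprotease",
)

_PRODUCTS = {
    "FlgY": "flagellar E-ring protein FlgY",
    "PflA_like": "flagellar TPR scaffold protein",
    "PflB_like": "flagellar TPR rim protein",
    "PflD": "flagellar cage protein PflD",
    "FcpM": "flagellar cage protein FcpM",
    "FcpN": "flagellar cage protein FcpN",
    "FcpO": "flagellar cage protein FcpO",
    "miaB": "tRNA methylthiotransferase MiaB",
    "FliJ": "flagellar export chaperone FliJ",
    "FliK": "flagellar hook-length control protein FliK",
    "decoy_tpr": "TPR-containing enzyme",
}


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the simulated study conditions."""

    seed: int = 0
    n_species: int = 50
    n_phyla: int = 4
    n_genera: int = 12
    frac_flagellated: float = 0.6
    trait_mode: str = "clade_planted"  # or "markov"
    root_state: int = 1
    gain_rate: float = 0.05
    loss_rate: float = 0.05
    genes_per_genome: int = 1000
    n_flagellar_clusters: int = 3
    scaffold_context_distance: int = 5
    decoy_tpr_count: int = 3
    t4p_probability: float = 0.5
    pilMN_fusion_probability: float = 0.5
    hit_fp_rate: float = 0.0
    hit_fn_rate: float = 0.0
    completeness_range: tuple[float, float] = (50.0, 100.0)
    contamination_range: tuple[float, float] = (0.0, 20.0)
    frac_complete_assembly: float = 0.6

    def __post_init__(self) -> None:
        for name in (
            "frac_flagellated",
            "t4p_probability",
            "pilMN_fusion_probability",
            "hit_fp_rate",
            "hit_fn_rate",
            "gain_rate",
            "loss_rate",
            "frac_complete_assembly",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "n_species",
            "genes_per_genome",
            "n_flagellar_clusters",
        ):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        for name in ("decoy_tpr_count", "scaffold_context_distance", "n_phyla", "n_genera"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.trait_mode not in ("clade_planted", "markov"):
            raise ValidationError(f"unknown trait_mode {self.trait_mode!r}")
        if self.root_state not in (0, 1):
            raise ValidationError("root_state must be 0 or 1")

    def rng(self, stage: int) -> np.random.Generator:
        """Independent deterministic stream for one simulation stage."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, stage]))


@dataclass
class TruthLabels:
    """Ground truth for a simulated dataset."""

    species: tuple[str, ...]
    flagellated: dict[str, bool]
    traits: dict[str, dict[str, bool]]  # species -> trait -> present
    gene_families: dict[str, dict[str, str]] = field(default_factory=dict)
    pilMN_fused: dict[str, bool] = field(default_factory=dict)

    def family_of(self, genome_id: str, locus_tag: str) -> str:
        return self.gene_families.get(genome_id, {}).get(locus_tag, "background")

    def matrix(self) -> pd.DataFrame:
        """Species x trait truth as a 0/1 DataFrame (flagellation included)."""
        rows = {}
        for sp in self.species:
            row = {"flagellar_gene_set": int(self.flagellated[sp])}
            row.update({t: int(self.traits[sp][t]) for t in TRUTH_TRAITS})
            rows[sp] = row
        return pd.DataFrame.from_dict(rows, orient="index").sort_index()

    def to_json(self) -> str:
        payload = {
            "species": list(self.species),
            "flagellated": self.flagellated,
            "traits": self.traits,
            "gene_families": self.gene_families,
            "pilMN_fused": self.pilMN_fused,
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthLabels":
        d = json.loads(text)
        return cls(
            species=tuple(d["species"]),
            flagellated=d["flagellated"],
            traits=d["traits"],
            gene_families=d["gene_families"],
            pilMN_fused=d["pilMN_fused"],
        )


@dataclass
class SynthDataset:
    """A complete simulated dataset: inputs plus ground truth."""

    config: SynthConfig
    tree: dendropy.Tree
    truth: TruthLabels
    genomes: dict[str, GenomeAnnotation]
    features: FeatureTable
    metas: list[GenomeMeta]
    domain_hits: pd.DataFrame
    sequence_hits: pd.DataFrame


# ---------------------------------------------------------------------------
# tree and trait simulation


def species_ids(config: SynthConfig) -> list[str]:
    return [f"sp{i + 1:04d}" for i in range(config.n_species)]


def simulate_tree(config: SynthConfig) -> dendropy.Tree:
    """Random rooted tree by sequential joins with unit branch lengths.

    Topology, not branch length, drives every downstream computation, so
    no attempt is made at realistic divergence times.
    """
    if config.n_species < 1:
        raise ValidationError("empty taxon set")
    rng = config.rng(1)
    species = species_ids(config)
    tns = dendropy.TaxonNamespace(species)
    nodes = []
    for sp in species:
        node = dendropy.Node(taxon=tns.get_taxon(sp))
        node.edge.length = 1.0
        nodes.append(node)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.edge.length = 1.0
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(parent)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=nodes[0])
    tree.is_rooted = True
    return tree


def simulate_traits(tree: dendropy.Tree, config: SynthConfig) -> TruthLabels:
    """Assign flagellation and trait presence to the leaves.

    ``clade_planted``: one clade whose size best matches the flagellated
    fraction is flagellated; scaffold traits are present exactly in
    flagellated species (perfect co-occurrence).  ``markov``: the
    flagellation state evolves along branches with the configured
    gain/loss flip probabilities from the root state, and scaffold traits
    mirror the resulting flagellation (co-occurrence is preserved so
    planted genomes remain internally consistent).  T4P presence is an
    independent per-species Bernoulli draw in both modes.
    """
    species = tuple(
        sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    )
    rng = config.rng(2)
    if config.trait_mode == "clade_planted":
        flagellated = _plant_clade(tree, species, config.frac_flagellated)
    elif config.trait_mode == "markov":
        flagellated = _evolve_markov(
            tree, config.root_state, config.gain_rate, config.loss_rate, rng
        )
    else:  # pragma: no cover - blocked by config validation
        raise ValidationError(f"unknown trait_mode {config.trait_mode!r}")

    traits: dict[str, dict[str, bool]] = {}
    fused: dict[str, bool] = {}
    for sp in species:
        has_t4p = bool(rng.random() < config.t4p_probability)
        traits[sp] = {t: flagellated[sp] for t in SCAFFOLD_TRAITS}
        traits[sp]["T4P"] = has_t4p
        fused[sp] = bool(
            has_t4p and rng.random() < config.pilMN_fusion_probability
        )
    return TruthLabels(
        species=species, flagellated=flagellated, traits=traits, pilMN_fused=fused
    )


def _plant_clade(
    tree: dendropy.Tree, species: tuple[str, ...], frac: float
) -> dict[str, bool]:
    target = round(frac * len(species))
    if target <= 0:
        return {sp: False for sp in species}
    if target >= len(species):
        return {sp: True for sp in species}
    best_node, best_gap = None, None
    for node in tree.postorder_node_iter():
        count = sum(1 for _ in node.leaf_iter())
        gap = abs(count - target)
        if best_gap is None or gap < best_gap:
            best_node, best_gap = node, gap
    chosen = {leaf.taxon.label for leaf in best_node.leaf_iter()}
    return {sp: sp in chosen for sp in species}


def _evolve_markov(
    tree: dendropy.Tree,
    root_state: int,
    gain: float,
    loss: float,
    rng: np.random.Generator,
) -> dict[str, bool]:
    states: dict[int, int] = {id(tree.seed_node): root_state}
    out: dict[str, bool] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            state = root_state
        else:
            parent_state = states[id(node.parent_node)]
            flip = rng.random() < (loss if parent_state == 1 else gain)
            state = (1 - parent_state) if flip else parent_state
            states[id(node)] = state
        if node.is_leaf():
            out[node.taxon.label] = bool(state)
    return out


# ---------------------------------------------------------------------------
# genome construction

#: (family, role) entries; role controls products/features downstream
_Entry = tuple[str | None, str]


def _cluster_block(
    rng: np.random.Generator,
    core_chunk: tuple[str, ...],
    before: list[str],
    after: list[str],
    include_flijk: bool,
    ctx: int,
) -> list[_Entry]:
    """One flagellar gene cluster with attached scaffold genes.

    Scaffold genes in ``before``/``after`` are separated from the nearest
    core (marker) gene by a drawn number of background genes such that
    their intervening-gene distance never exceeds ``ctx``.
    """
    entries: list[_Entry] = [(fam, "core") for fam in core_chunk]

    def attach(chain: list[str], initial_load: int) -> list[_Entry]:
        out: list[_Entry] = []
        load = initial_load
        for fam in chain:
            budget = ctx - load
            if budget < 0:
                raise ValidationError(
                    "scaffold_context_distance too small to attach scaffold "
                    f"genes to {len(core_chunk)}-gene cluster"
                )
            d = int(rng.integers(0, min(2, budget) + 1))
            out.extend([(None, "bg")] * d)
            out.append((fam, "scaffold"))
            load += d + 1
        return out

    tail: list[_Entry] = []
    tail_load = 0
    if include_flijk:
        tail.extend([("FliJ", "aux"), ("FliK", "aux")])
        tail_load = 2
    tail.extend(attach(after, tail_load))
    head = attach(before, 0)
    head.reverse()
    return head + entries + tail


def _plan_elements(
    rng: np.random.Generator, config: SynthConfig, sp_traits: dict[str, bool],
    flagellated: bool, fused: bool,
) -> list[tuple[str, list[_Entry], str]]:
    """Plan planted blocks for one genome: (kind, entries, strand)."""
    ctx = config.scaffold_context_distance
    elements: list[tuple[str, list[_Entry], str]] = []

    def strand() -> str:
        return "+" if rng.random() < 0.5 else "-"

    if flagellated:
        k = config.n_flagellar_clusters
        chunks = [tuple(CORE_FAMILIES[i::k]) for i in range(k)]
        # spread scaffold attachments over clusters; fliJ/fliK next to cluster 0
        sides: list[list[str]] = [[] for _ in range(2 * k)]  # (block, after/before)
        loads = [0] * (2 * k)
        loads[0] = 2  # fliJ/fliK occupy the 'after' side of cluster 0
        order = ["FlgY", "PflA_like", "PflB_like", "PflD"]
        for fam in order:
            side = min(range(2 * k), key=lambda s: (loads[s], s))
            if loads[side] > ctx:
                raise ValidationError(
                    "cannot place scaffold genes within "
                    f"scaffold_context_distance={ctx} of "
                    f"{k} flagellar clusters; increase either parameter"
                )
            sides[side].append(fam)
            loads[side] += 1
        for b in range(k):
            entries = _cluster_block(
                rng,
                chunks[b],
                before=sides[2 * b + 1],
                after=sides[2 * b],
                include_flijk=(b == 0),
                ctx=ctx,
            )
            elements.append(("flagellar_cluster", entries, strand()))
        # fcpMNO operon with miaB immediately upstream (strand-aware)
        fcp = [("miaB", "aux"), ("FcpM", "fcp"), ("FcpN", "fcp"), ("FcpO", "fcp")]
        s = strand()
        if s == "-":
            fcp = list(reversed(fcp))
        elements.append(("fcp_operon", fcp, s))
    else:
        n_core = int(rng.integers(0, 13))
        if n_core:
            fams = list(rng.choice(len(CORE_FAMILIES), size=n_core, replace=False))
            entries = [(CORE_FAMILIES[i], "core") for i in sorted(fams)]
            elements.append(("partial_core", entries, strand()))

    if sp_traits["T4P"]:
        if fused:
            pil = [("PilMN", "t4p"), ("PilO", "t4p"), ("PilP", "t4p"), ("PilQ", "t4p")]
        else:
            pil = [("PilM", "t4p"), ("PilN", "t4p"), ("PilO", "t4p"),
                   ("PilP", "t4p"), ("PilQ", "t4p")]
        s = strand()
        if s == "-":
            pil = list(reversed(pil))
        elements.append(("t4p_cluster", pil, s))
        atp = [("PilB", "t4p"), ("PilC", "t4p"), ("PilT", "t4p"), ("PilU", "t4p")]
        elements.append(("t4p_motor", atp, strand()))

    if config.decoy_tpr_count:
        decoys = [("decoy_tpr", "decoy")] * config.decoy_tpr_count
        elements.append(("decoys", decoys, strand()))
    return elements


def required_genes_per_genome(config: SynthConfig) -> int:
    """Minimum genes_per_genome that can host all planted blocks."""
    k = config.n_flagellar_clusters
    ctx = config.scaffold_context_distance
    max_cluster = -(-len(CORE_FAMILIES) // k) + 2 + 4 + 4 * min(2, ctx)
    max_block = max(max_cluster, 5, 4, max(config.decoy_tpr_count, 1))
    n_elements = k + 3 + 1  # clusters + fcp + t4p + motor + decoys
    return n_elements * (max_block + 2 * (ctx + 1))


def simulate_genomes(
    truth: TruthLabels, config: SynthConfig
) -> tuple[dict[str, GenomeAnnotation], FeatureTable, list[GenomeMeta]]:
    """Build annotated genomes, protein features and metadata from truth.

    Fills ``truth.gene_families`` with the per-gene family label of every
    planted gene (background genes are implicit).
    """
    minimum = required_genes_per_genome(config)
    if config.genes_per_genome < minimum:
        raise ValidationError(
            f"genes_per_genome={config.genes_per_genome} too small to host the "
            f"requested clusters; need at least {minimum}"
        )
    rng = config.rng(3)
    genomes: dict[str, GenomeAnnotation] = {}
    features = FeatureTable()
    blacklist_cycle = list(DEFAULT_BLACKLIST)

    for sp in truth.species:
        elements = _plan_elements(
            rng, config, truth.traits[sp], truth.flagellated[sp],
            truth.pilMN_fused.get(sp, False),
        )
        G = config.genes_per_genome
        ctx = config.scaffold_context_distance
        n_seg = max(len(elements), 1)
        seg_len = G // n_seg
        # (slot index -> (family, role, strand)) for planted genes
        planted: dict[int, tuple[str | None, str, str]] = {}
        for e, (kind, entries, strand) in enumerate(elements):
            margin = ctx + 1
            slack = seg_len - len(entries) - 2 * margin
            if slack < 0:
                raise ValidationError(
                    f"genes_per_genome={G} too small to host the requested "
                    f"clusters; need at least {required_genes_per_genome(config)}"
                )
            offset = int(rng.integers(0, slack + 1))
            start = e * seg_len + margin + offset
            for i, (fam, role) in enumerate(entries):
                planted[start + i] = (fam, role, strand)

        genes: list[GeneRecord] = []
        fam_labels: dict[str, str] = {}
        lengths = rng.integers(300, 2400, size=G)
        gaps = rng.integers(5, 180, size=G)
        bg_strands = rng.random(size=G) < 0.5
        bg_tm = rng.random(size=G) < 0.1
        pos = 1
        for i in range(G):
            locus = f"{sp}_{i + 1:05d}"
            fam, role, strand = planted.get(
                i, (None, "bg", "+" if bg_strands[i] else "-")
            )
            length = int(lengths[i])
            gap = int(gaps[i])
            if role in ("fcp", "t4p", "core", "aux") or (i + 1) in planted:
                gap = int(gap % 100) + 5  # keep operon-critical gaps tight
            start = pos + gap
            end = start + length - 1
            pos = end
            product = "hypothetical protein"
            if fam is not None:
                product = _PRODUCTS.get(fam, f"{fam} family protein")
                if fam in CORE_FAMILIES:
                    product = f"flagellar protein {fam}"
                fam_labels[locus] = fam
            genes.append(
                GeneRecord(
                    genome_id=sp,
                    replicon_id=f"{sp}_chr",
                    index=i,
                    start=start,
                    end=end,
                    strand=strand,
                    locus_tag=locus,
                    protein_id=locus,
                    product=product,
                )
            )
            features.add(
                _feature_for(locus, fam, length, bool(bg_tm[i]), blacklist_cycle, i)
            )
        genomes[sp] = GenomeAnnotation(sp, genes)
        truth.gene_families[sp] = fam_labels

    metas = _simulate_metadata(truth, config)
    return genomes, features, metas


def _feature_for(
    locus: str,
    fam: str | None,
    length_nt: int,
    bg_tm: bool,
    blacklist_cycle: list[str],
    i: int,
) -> ProteinFeature:
    length_aa = max(length_nt // 3, 50)
    kwargs: dict = {}
    if fam == "FlgY":
        kwargs = dict(has_signal_peptide=True)
    elif fam == "PflB_like":
        kwargs = dict(has_tm=True, has_beta_pair=True)
    elif fam in ("FcpN", "FcpO", "PflD", "PilN", "PilMN"):
        kwargs = dict(has_tm=True)
    elif fam == "decoy_tpr":
        kwargs = dict(
            blacklist_domains=frozenset({blacklist_cycle[i % len(blacklist_cycle)]})
        )
    elif fam is None and bg_tm:
        kwargs = dict(has_tm=bg_tm)
    return ProteinFeature(protein_id=locus, length=length_aa, **kwargs)


def _simulate_metadata(truth: TruthLabels, config: SynthConfig) -> list[GenomeMeta]:
    rng = config.rng(4)
    metas = []
    n_phyla = max(config.n_phyla, 1)
    n_genera = max(config.n_genera, 1)
    genus_of = rng.integers(0, n_genera, size=len(truth.species))
    phylum_of_genus = rng.integers(0, n_phyla, size=n_genera)
    lo_c, hi_c = config.completeness_range
    lo_x, hi_x = config.contamination_range
    for i, sp in enumerate(truth.species):
        genus = int(genus_of[i])
        level = (
            "complete"
            if rng.random() < config.frac_complete_assembly
            else ["chromosome", "scaffold", "contig"][int(rng.integers(0, 3))]
        )
        metas.append(
            GenomeMeta(
                genome_id=sp,
                lineage={
                    "phylum": f"phy{phylum_of_genus[genus] + 1:02d}",
                    "class": "cls01",
                    "order": "ord01",
                    "family": "fam01",
                    "genus": f"gen{genus + 1:02d}",
                    "species": sp,
                },
                assembly_level=level,
                completeness=round(float(rng.uniform(lo_c, hi_c)), 2),
                contamination=round(float(rng.uniform(lo_x, hi_x)), 2),
                model_priority=int(rng.integers(0, 3)) if rng.random() < 0.1 else 0,
            )
        )
    return metas


# ---------------------------------------------------------------------------
# hit table simulation

#: sequence-search queries that hit each planted family (cross-homology
#: between Fcp and Pil reflects their shared ancestry)
_SEQ_QUERIES: dict[str, tuple[str, ...]] = {
    "FlgY": ("FlgY",),
    "PflA_like": ("PflA",),
    "PflB_like": ("PflB",),
    "PflD": ("PflD",),
    "FcpM": ("FcpM", "PilM"),
    "FcpN": ("FcpN", "PilN"),
    "FcpO": ("FcpO", "PilO"),
    "PilM": ("PilM", "FcpM"),
    "PilN": ("PilN", "FcpN"),
    "PilO": ("PilO", "FcpO"),
    "PilMN": ("PilM", "PilN"),
    "PilP": ("PilP",),
    "PilQ": ("PilQ",),
    "PilB": ("PilB",),
    "PilC": ("PilC",),
    "PilT": ("PilT",),
    "PilU": ("PilU",),
    "miaB": ("miaB",),
    "FliJ": ("FliJ",),
    "FliK": ("FliK",),
}

#: map of sequence query id -> family used for presence logic downstream
QUERY_FAMILIES: dict[str, str] = {
    q: q for fams in _SEQ_QUERIES.values() for q in fams
}
QUERY_FAMILIES.update({fam: fam for fam in CORE_FAMILIES})

_ALL_QUERIES = tuple(sorted(QUERY_FAMILIES))
_ALL_PROFILES = (
    PROFILE_MGTE_N, PROFILE_TPR, PROFILE_PILN, PROFILE_PILM,
    "PilO", "PilP", "PilQ", "PilB", "PilC", "PilT", "PilU",
)


def _true_evalue(rng: np.random.Generator) -> float:
    return float(f"{10.0 ** -rng.uniform(6, 50):.3e}")


def _spurious_evalue(rng: np.random.Generator) -> float:
    return float(f"{10.0 ** -rng.uniform(1, 4):.3e}")


def _bitscore(evalue: float, rng: np.random.Generator) -> float:
    return round(-2.0 * np.log10(evalue) + float(rng.uniform(25, 60)), 1)


def simulate_hits(
    genomes: dict[str, GenomeAnnotation],
    truth: TruthLabels,
    config: SynthConfig,
    features: FeatureTable | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit domain- and sequence-hit tables consistent with the truth.

    True hits carry E-values far below the screening thresholds
    (10^-U(6,50)); each true row is dropped independently with
    probability ``hit_fn_rate``; spurious rows hit random background
    genes at ``hit_fp_rate`` per background gene with E-values of
    10^-U(1,4), exercising both sides of the 1e-3 / 1e-5 cutoffs.
    """
    rng = config.rng(5)
    dom_rows: list[dict] = []
    seq_rows: list[dict] = []

    for sp in truth.species:
        genome = genomes[sp]
        fam_labels = truth.gene_families.get(sp, {})
        background = [g.locus_tag for g in genome if g.locus_tag not in fam_labels]
        for gene in genome:
            fam = fam_labels.get(gene.locus_tag)
            if fam is None:
                continue
            length_aa = (
                features.get(gene.locus_tag).length
                if features is not None and gene.locus_tag in features
                else max((gene.end - gene.start + 1) // 3, 60)
            )
            dom_rows.extend(_domain_rows_for(gene, fam, length_aa, rng))
            for query in _seq_queries_for(fam):
                e = _true_evalue(rng)
                seq_rows.append(_seq_row(query, gene.locus_tag, length_aa, e, rng))

        # false negatives: drop true rows independently
        if config.hit_fn_rate > 0:
            dom_rows = [r for r in dom_rows if not (
                r["_genome"] == sp and rng.random() < config.hit_fn_rate)]
            seq_rows = [r for r in seq_rows if not (
                r["_genome"] == sp and rng.random() < config.hit_fn_rate)]

        # false positives: spurious rows on random background genes
        if config.hit_fp_rate > 0 and background:
            n_fp_seq = int(rng.binomial(len(background), config.hit_fp_rate))
            n_fp_dom = int(rng.binomial(len(background), config.hit_fp_rate))
            for _ in range(n_fp_seq):
                locus = background[int(rng.integers(0, len(background)))]
                query = _ALL_QUERIES[int(rng.integers(0, len(_ALL_QUERIES)))]
                e = _spurious_evalue(rng)
                seq_rows.append(_seq_row(query, locus, 300, e, rng))
            for _ in range(n_fp_dom):
                locus = background[int(rng.integers(0, len(background)))]
                profile = _ALL_PROFILES[int(rng.integers(0, len(_ALL_PROFILES)))]
                e = _spurious_evalue(rng)
                start = int(rng.integers(5, 200))
                dom_rows.append(
                    {
                        "protein_id": locus,
                        "profile_id": profile,
                        "env_start": start,
                        "env_end": start + 40,
                        "evalue": e,
                        "bitscore": _bitscore(e, rng),
                        "_genome": locus.rsplit("_", 1)[0],
                    }
                )

    dom = pd.DataFrame(dom_rows, columns=list(DOMHIT_COLUMNS) + ["_genome"])
    seq = pd.DataFrame(seq_rows, columns=list(SEQHIT_COLUMNS) + ["_genome"])
    dom = dom.drop(columns="_genome")
    seq = seq.drop(columns="_genome")
    dom = dom.sort_values(
        ["profile_id", "protein_id", "env_start", "evalue"], kind="mergesort"
    ).reset_index(drop=True)
    seq = seq.sort_values(
        ["qseqid", "sseqid", "evalue", "bitscore"], kind="mergesort"
    ).reset_index(drop=True)
    return dom, seq


def _seq_queries_for(fam: str) -> tuple[str, ...]:
    if fam in CORE_FAMILIES:
        return (fam,)
    return _SEQ_QUERIES.get(fam, ())


def _domain_rows_for(
    gene: GeneRecord, fam: str, length_aa: int, rng: np.random.Generator
) -> list[dict]:
    rows: list[dict] = []

    def add(profile: str, start: int, end: int) -> None:
        e = _true_evalue(rng)
        rows.append(
            {
                "protein_id": gene.locus_tag,
                "profile_id": profile,
                "env_start": start,
                "env_end": end,
                "evalue": e,
                "bitscore": _bitscore(e, rng),
                "_genome": gene.genome_id,
            }
        )

    if fam == "FlgY":
        add(PROFILE_MGTE_N, 90, 170)
    elif fam in ("PflA_like", "PflB_like", "decoy_tpr"):
        n_motifs = int(rng.integers(4, 9))
        pos = int(rng.integers(5, 30))
        for _ in range(n_motifs):
            add(PROFILE_TPR, pos, pos + 33)
            pos += 34 + int(rng.integers(0, 9))
    elif fam in ("FcpN", "PilN"):
        add(PROFILE_PILN, 10, 160)
    elif fam == "PilM":
        add(PROFILE_PILM, 10, 150)
    elif fam == "PilMN":
        add(PROFILE_PILM, 5, 140)
        add(PROFILE_PILN, 165, 310)
    elif fam in ("PilO", "PilP", "PilQ", "PilB", "PilC", "PilT", "PilU"):
        add(fam, 10, 150)
    return rows


def _seq_row(
    query: str, locus: str, length_aa: int, evalue: float, rng: np.random.Generator
) -> dict:
    aln = max(int(length_aa * float(rng.uniform(0.5, 0.95))), 30)
    return {
        "qseqid": query,
        "sseqid": locus,
        "pident": round(float(rng.uniform(28, 95)), 1),
        "length": aln,
        "mismatch": int(rng.integers(0, aln)),
        "gapopen": int(rng.integers(0, 5)),
        "qstart": 1,
        "qend": aln,
        "sstart": 1,
        "send": aln,
        "evalue": evalue,
        "bitscore": _bitscore(evalue, rng),
        "_genome": locus.rsplit("_", 1)[0],
    }


# ---------------------------------------------------------------------------
# top-level API


def simulate_dataset(config: SynthConfig) -> SynthDataset:
    """Run all simulation stages for one configuration."""
    tree = simulate_tree(config)
    truth = simulate_traits(tree, config)
    genomes, features, metas = simulate_genomes(truth, config)
    dom, seq = simulate_hits(genomes, truth, config, features)
    return SynthDataset(
        config=config,
        tree=tree,
        truth=truth,
        genomes=genomes,
        features=features,
        metas=metas,
        domain_hits=dom,
        sequence_hits=seq,
    )


def emit_dataset(dataset: SynthDataset, out_dir: str | Path) -> dict[str, str]:
    """Write a dataset to disk; returns {relative path: sha256} manifest.

    Layout: ``tree.nwk``, ``metadata.tsv``, ``features.tsv``,
    ``truth.json``, ``genomes/<sp>.gff3``, ``proteins/<sp>.faa``,
    ``hits/domain_hits.domtblout``, ``hits/sequence_hits.tsv``,
    ``hits/query_families.tsv`` and ``manifest.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "genomes").mkdir(exist_ok=True)
    (out / "proteins").mkdir(exist_ok=True)
    (out / "hits").mkdir(exist_ok=True)

    files: dict[str, str] = {}

    def write(rel: str, text: str) -> None:
        path = out / rel
        path.write_text(text)
        files[rel] = hashlib.sha256(text.encode()).hexdigest()

    write(
        "tree.nwk",
        dataset.tree.as_string(schema="newick", suppress_rooting=True),
    )
    write("metadata.tsv", mtio.metadata_to_tsv(dataset.metas))
    write("features.tsv", mtio.features_to_tsv(dataset.features))
    write("truth.json", dataset.truth.to_json())
    write(
        "hits/domain_hits.domtblout",
        mtio.domain_hits_to_domtblout(dataset.domain_hits, dataset.features),
    )
    write("hits/sequence_hits.tsv", mtio.sequence_hits_to_tsv(dataset.sequence_hits))
    write(
        "hits/query_families.tsv",
        "query\tfamily\n"
        + "".join(f"{q}\t{QUERY_FAMILIES[q]}\n" for q in sorted(QUERY_FAMILIES)),
    )
    seq_rng = np.random.default_rng(
        np.random.SeedSequence([dataset.config.seed, 6])
    )
    for sp in dataset.truth.species:
        genome = dataset.genomes[sp]
        write(f"genomes/{sp}.gff3", mtio.genome_to_gff3(genome))
        write(
            f"proteins/{sp}.faa",
            mtio.stub_protein_fasta(genome, dataset.features, seq_rng),
        )
    manifest = {
        "config": dataclasses.asdict(dataset.config),
        "files": files,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return files


def load_dataset(in_dir: str | Path) -> SynthDataset:
    """Re-read an emitted dataset through the pipeline's own readers."""
    d = Path(in_dir)
    manifest = json.loads((d / "manifest.json").read_text())
    cfg_dict = manifest["config"]
    for key in ("completeness_range", "contamination_range"):
        cfg_dict[key] = tuple(cfg_dict[key])
    config = SynthConfig(**cfg_dict)
    tree = dendropy.Tree.get(path=str(d / "tree.nwk"), schema="newick")
    tree.is_rooted = True
    truth = TruthLabels.from_json((d / "truth.json").read_text())
    metas = mtio.read_metadata_tsv(d / "metadata.tsv")
    features = mtio.read_features_tsv(d / "features.tsv")
    genomes = {
        sp: mtio.read_gff3(d / "genomes" / f"{sp}.gff3", genome_id=sp)
        for sp in truth.species
    }
    dom = mtio.read_domtblout(d / "hits" / "domain_hits.domtblout")
    seq = mtio.read_blast_tab(d / "hits" / "sequence_hits.tsv")
    return SynthDataset(
        config=config,
        tree=tree,
        truth=truth,
        genomes=genomes,
        features=features,
        metas=metas,
        domain_hits=dom,
        sequence_hits=seq,
    )
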