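"""Family-specific homolog calling procedures.

Each screen turns raw hit tables into :class:`~motortrace.models.HomologCall`
verdicts by combining evidence quality (E-value thresholds) with genomic
context:

* **FlgY** — MgtE_N (PF03448) profile hits accepted only within five
  genes of a flagellar gene cluster, with a *fliJ*/*fliK* neighborhood
  rescue path for flagellated genomes the profile search missed;
* **TPR scaffolds** — TPR (PF00515) hits requiring at least three
  sequential motifs, flagellar-cluster context, and no known enzymatic
  domain; candidates split into PflB-like (transmembrane motif plus
  antiparallel beta-pair) versus PflA-like;
* **FcpMNO** — PilN-profile (COG3166) anchors whose operon carries
  M-like and O-like partners, discriminated from genuine type-IV-filament
  clusters by gene neighborhood;
* **T4P** — the canonical ordered *pilMNOPQ* cluster (allowing the
  *pilM–pilN* fusion) plus at least two of the PilB/PilC/PilT/PilU genes;
* **best-hit screens** — single best BLAST hit below 1e-3 per query
  family per genome, as used for close-range searches within a phylum.

Thresholds follow the strict-inequality convention of the search rules
they implement (a hit at exactly the cutoff does not qualify).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd

from .context import (
    GeneCluster,
    OperonIndex,
    detect_fusion,
    within_context,
)
from .models import (
    Discard,
    FeatureTable,
    GenomeAnnotation,
    HomologCall,
    ValidationError,
)

PROFILE_MGTE_N = "PF03448"
PROFILE_TPR = "PF00515"
PROFILE_PILN = "COG3166"
PROFILE_PILM = "PilM"

DEFAULT_BLACKLIST = frozenset(
    {
        "glycosyltransferase",
        "methyltransferase",
        "acetyltransferase",
        "sulfotransferase",
        "metalloprotease",
    }
)

#: T4P components whose presence near a triplet marks it as a pilus system
TFF_DISCRIMINATOR_FAMILIES = ("PilP", "PilQ", "PilB", "PilC", "PilT", "PilU")

T4P_CORE_ORDER = ("PilM", "PilN", "PilO", "PilP", "PilQ")
T4P_MOTOR_FAMILIES = ("PilB", "PilC", "PilT", "PilU")


class BestHit(NamedTuple):
    locus_tag: str
    evalue: float
    bitscore: float


def best_hit(
    hits: pd.DataFrame,
    query_family: str,
    *,
    evalue_max: float = 1e-3,
) -> BestHit | None:
    """Best qualifying hit for one query family, or None.

    Qualifying rows have E strictly below ``evalue_max``; ties on E-value
    break by higher bit score, then smallest target locus.
    """
    if len(hits) == 0:
        return None
    sub = hits[hits["query_family"] == query_family] if "query_family" in hits else hits
    bad = sub["evalue"].isna() | (sub["evalue"] <= 0) | sub["sseqid"].isna()
    if bad.any():
        lines = [str(i) for i in sub.index[bad][:5]]
        raise ValidationError(
            f"malformed hit rows (non-positive E-value or missing target) "
            f"at table rows {', '.join(lines)}"
        )
    sub = sub[sub["evalue"] < evalue_max]
    if sub.empty:
        return None
    sub = sub.sort_values(
        ["evalue", "bitscore", "sseqid"],
        ascending=[True, False, True],
        kind="mergesort",
    )
    row = sub.iloc[0]
    return BestHit(str(row["sseqid"]), float(row["evalue"]), float(row["bitscore"]))


# ---------------------------------------------------------------------------
# FlgY


def screen_flgy(
    domain_hits: pd.DataFrame,
    genome: GenomeAnnotation,
    clusters: Sequence[GeneCluster],
    *,
    flagellated: bool,
    features: FeatureTable,
    flijk_loci: Iterable[str] = (),
    profile: str = PROFILE_MGTE_N,
    evalue_max: float = 1e-3,
    context_n: int = 5,
    rescue_window: int = 2,
    blacklist: frozenset[str] = DEFAULT_BLACKLIST,
) -> tuple[list[HomologCall], list[Discard]]:
    """Call FlgY homologs in one genome from MgtE_N profile hits.

    Profile hits are context-validated against flagellar gene clusters;
    for flagellated genomes with no validated call, genes within
    ``rescue_window`` of a *fliJ*/*fliK* gene and carrying no blacklist
    domain are flagged as rescue candidates (never auto-promoted).
    """
    calls: list[HomologCall] = []
    discards: list[Discard] = []
    cand = domain_hits[domain_hits["profile_id"] == profile]
    seen: set[str] = set()
    for row in cand.sort_values(["protein_id", "evalue"]).itertuples():
        try:
            gene = genome.by_protein(str(row.protein_id))
        except KeyError:
            raise ValidationError(
                f"domain hit on protein {row.protein_id!r} absent from "
                f"genome {genome.genome_id}"
            ) from None
        if gene.locus_tag in seen:
            continue
        seen.add(gene.locus_tag)
        if not row.evalue < evalue_max:
            discards.append(
                Discard("FlgY", genome.genome_id, gene.locus_tag, "evalue")
            )
            continue
        ok, dist = within_context(gene, clusters, genome, n=context_n)
        if not ok:
            discards.append(
                Discard("FlgY", genome.genome_id, gene.locus_tag, "context")
            )
            continue
        calls.append(
            HomologCall(
                family="FlgY",
                genome_id=genome.genome_id,
                locus_tag=gene.locus_tag,
                tier="context_validated",
                evidence=(f"profile:{profile}", f"cluster_distance:{int(dist)}"),
            )
        )
    if flagellated and not calls:
        calls.extend(
            _flgy_rescue(genome, flijk_loci, features, rescue_window, blacklist)
        )
    return calls, discards


def _flgy_rescue(
    genome: GenomeAnnotation,
    flijk_loci: Iterable[str],
    features: FeatureTable,
    rescue_window: int,
    blacklist: frozenset[str],
) -> list[HomologCall]:
    rescues: list[HomologCall] = []
    anchor_loci = sorted(set(flijk_loci))
    seen: set[str] = set()
    for locus in anchor_loci:
        if locus not in genome:
            continue
        anchor = genome.by_locus(locus)
        recs = genome.genes_on(anchor.replicon_id)
        lo = max(anchor.index - rescue_window, 0)
        hi = min(anchor.index + rescue_window, len(recs) - 1)
        for i in range(lo, hi + 1):
            gene = recs[i]
            if gene.locus_tag == locus or gene.locus_tag in anchor_loci:
                continue
            if gene.locus_tag in seen:
                continue
            if gene.protein_id in features:
                if features.get(gene.protein_id).blacklist_domains & blacklist:
                    continue
            seen.add(gene.locus_tag)
            rescues.append(
                HomologCall(
                    family="FlgY",
                    genome_id=genome.genome_id,
                    locus_tag=gene.locus_tag,
                    tier="rescue_candidate",
                    evidence=(f"neighbor_of:{locus}",),
                )
            )
    return rescues


# ---------------------------------------------------------------------------
# PflA/PflB-like TPR scaffolds


def sequential_motif_count(
    hits: pd.DataFrame, *, max_motif_gap_aa: int = 50
) -> int:
    """Longest run of motif hits (sorted by start) with bounded gaps.

    The gap between consecutive motifs is the number of residues between
    the end of one envelope and the start of the next.
    """
    if len(hits) == 0:
        return 0
    ordered = hits.sort_values(["env_start", "env_end"])
    best = run = 1
    prev_end = None
    for row in ordered.itertuples():
        if prev_end is None:
            prev_end = row.env_end
            continue
        gap = row.env_start - prev_end - 1
        run = run + 1 if gap <= max_motif_gap_aa else 1
        best = max(best, run)
        prev_end = max(prev_end, row.env_end) if gap <= max_motif_gap_aa else row.env_end
    return best


def screen_tpr_scaffolds(
    domain_hits: pd.DataFrame,
    genome: GenomeAnnotation,
    clusters: Sequence[GeneCluster],
    features: FeatureTable,
    *,
    blacklist: frozenset[str] = DEFAULT_BLACKLIST,
    min_sequential: int = 3,
    max_motif_gap_aa: int = 50,
    profile: str = PROFILE_TPR,
    evalue_max: float = 1e-3,
    context_n: int = 5,
) -> tuple[list[HomologCall], list[Discard]]:
    """Call PflA/PflB-like TPR scaffolds in one genome.

    A protein is called when its longest sequential TPR motif run reaches
    ``min_sequential``, its gene lies within ``context_n`` genes of a
    flagellar gene cluster, and it carries no blacklisted enzymatic
    domain.  Calls are labelled PflB-like when the protein has both a
    transmembrane motif and the antiparallel beta-pair flag, PflA-like
    otherwise.
    """
    calls: list[HomologCall] = []
    discards: list[Discard] = []
    cand = domain_hits[
        (domain_hits["profile_id"] == profile)
        & (domain_hits["evalue"] < evalue_max)
    ]
    for pid in sorted(cand["protein_id"].unique()):
        try:
            gene = genome.by_protein(str(pid))
        except KeyError:
            raise ValidationError(
                f"domain hit on protein {pid!r} absent from genome "
                f"{genome.genome_id}"
            ) from None
        if pid not in features:
            raise ValidationError(
                f"no feature record for TPR candidate {pid!r}"
            )
        feat = features.get(str(pid))
        run = sequential_motif_count(
            cand[cand["protein_id"] == pid], max_motif_gap_aa=max_motif_gap_aa
        )
        failed: list[str] = []
        if run < min_sequential:
            failed.append("sequential_motifs")
        if feat.blacklist_domains & blacklist:
            failed.append("blacklist")
        ok, dist = within_context(gene, clusters, genome, n=context_n)
        if not ok:
            failed.append("context")
        if failed:
            discards.append(
                Discard(
                    "PflA_like", genome.genome_id, gene.locus_tag,
                    ",".join(failed),
                )
            )
            continue
        family = (
            "PflB_like" if feat.has_tm and feat.has_beta_pair else "PflA_like"
        )
        calls.append(
            HomologCall(
                family=family,
                genome_id=genome.genome_id,
                locus_tag=gene.locus_tag,
                tier="context_validated",
                evidence=(
                    f"profile:{profile}",
                    f"sequential_motifs:{run}",
                    f"cluster_distance:{int(dist)}",
                ),
            )
        )
    return calls, discards


# ---------------------------------------------------------------------------
# FcpMNO vs PilMNO


def _neighbor(
    genome: GenomeAnnotation, gene, offset: int
):
    recs = genome.genes_on(gene.replicon_id)
    i = gene.index + offset
    if 0 <= i < len(recs):
        return recs[i]
    return None


def screen_fcpmno(
    domain_hits: pd.DataFrame,
    seq_hits: pd.DataFrame,
    genome: GenomeAnnotation,
    operons: OperonIndex,
    *,
    tff_markers: Mapping[str, str] = (),
    mia_loci: Iterable[str] = (),
    profile: str = PROFILE_PILN,
    evalue_max: float = 1e-3,
    adjacency_n: int = 5,
) -> tuple[list[HomologCall], list[Discard], list[Discard]]:
    """Call FcpM/FcpN/FcpO triplets anchored on PilN-profile hits.

    Each qualifying anchor must sit in an operon with M-like and O-like
    neighbors (by domain or sequence-hit evidence).  The triplet is
    called Fcp iff no type-IV-filament marker gene lies within
    ``adjacency_n`` intervening genes; triplets adjacent to *pilP*/*pilQ*
    are labelled PilM/PilN/PilO instead, and other ambiguous adjacency is
    emitted to the review report.  An immediately upstream *miaB* gene is
    recorded as supporting evidence but not required.

    Returns ``(calls, discards, review)``.
    """
    calls: list[HomologCall] = []
    discards: list[Discard] = []
    review: list[Discard] = []
    tff_markers = dict(tff_markers)
    mia = set(mia_loci)

    anchors = domain_hits[
        (domain_hits["profile_id"] == profile)
        & (domain_hits["evalue"] < evalue_max)
    ]
    m_evid = _evidence_loci(seq_hits, domain_hits, ("FcpM", "PilM"), (PROFILE_PILM,), evalue_max)
    o_evid = _evidence_loci(seq_hits, domain_hits, ("FcpO", "PilO"), (), evalue_max)

    claimed: set[str] = set()
    for pid in sorted(anchors["protein_id"].unique()):
        try:
            gene = genome.by_protein(str(pid))
        except KeyError:
            raise ValidationError(
                f"domain hit on protein {pid!r} absent from genome "
                f"{genome.genome_id}"
            ) from None
        if gene.locus_tag in claimed:
            continue
        operon = operons.operon_of(gene.locus_tag)
        up = -1 if gene.strand == "+" else +1
        m_gene = _neighbor(genome, gene, up)
        o_gene = _neighbor(genome, gene, -up)
        ok = (
            m_gene is not None
            and o_gene is not None
            and m_gene.index in operon.member_indices
            and o_gene.index in operon.member_indices
            and m_gene.locus_tag in m_evid
            and o_gene.locus_tag in o_evid
        )
        if not ok:
            discards.append(
                Discard("FcpN", genome.genome_id, gene.locus_tag,
                        "incomplete_triplet")
            )
            continue
        triplet = (m_gene, gene, o_gene)
        triplet_loci = {g.locus_tag for g in triplet}
        near_tff = _tff_near(
            genome, triplet, tff_markers, triplet_loci, adjacency_n
        )
        evidence = [f"profile:{profile}", "operon_triplet"]
        mia_gene = _neighbor(genome, m_gene, up)
        has_mia = mia_gene is not None and mia_gene.locus_tag in mia
        if not near_tff:
            if has_mia:
                evidence.append("miaB_upstream")
            fams = ("FcpM", "FcpN", "FcpO")
        elif {"PilP", "PilQ"} & set(near_tff.values()):
            evidence.append("tff_adjacent:" + ",".join(sorted(set(near_tff.values()))))
            fams = ("PilM", "PilN", "PilO")
        else:
            review.append(
                Discard(
                    "FcpN", genome.genome_id, gene.locus_tag,
                    "ambiguous_tff_adjacency:"
                    + ",".join(sorted(set(near_tff.values()))),
                )
            )
            continue
        for fam, g in zip(fams, triplet):
            claimed.add(g.locus_tag)
            calls.append(
                HomologCall(
                    family=fam,
                    genome_id=genome.genome_id,
                    locus_tag=g.locus_tag,
                    tier="context_validated",
                    evidence=tuple(evidence),
                )
            )
    return calls, discards, review


def _evidence_loci(
    seq_hits: pd.DataFrame,
    domain_hits: pd.DataFrame,
    query_families: tuple[str, ...],
    profiles: tuple[str, ...],
    evalue_max: float,
) -> set[str]:
    loci: set[str] = set()
    if len(seq_hits) and "query_family" in seq_hits:
        sub = seq_hits[
            seq_hits["query_family"].isin(query_families)
            & (seq_hits["evalue"] < evalue_max)
        ]
        loci.update(sub["sseqid"].astype(str))
    if profiles and len(domain_hits):
        sub = domain_hits[
            domain_hits["profile_id"].isin(profiles)
            & (domain_hits["evalue"] < evalue_max)
        ]
        loci.update(sub["protein_id"].astype(str))
    return loci


def _tff_near(
    genome: GenomeAnnotation,
    triplet,
    tff_markers: Mapping[str, str],
    exclude: set[str],
    n: int,
) -> dict[str, str]:
    from .context import intervening_distance

    near: dict[str, str] = {}
    for locus, fam in tff_markers.items():
        if locus in exclude or locus not in genome:
            continue
        marker = genome.by_locus(locus)
        for g in triplet:
            circular = genome.is_circular(g.replicon_id)
            size = genome.replicon_size(g.replicon_id) if circular else None
            d = intervening_distance(
                g, marker, circular=circular, replicon_size=size
            )
            if d <= n:
                near[locus] = fam
                break
    return near


# ---------------------------------------------------------------------------
# type IV pilus detection


@dataclass(frozen=True)
class T4PVerdict:
    genome_id: str
    present: bool
    cluster_loci: tuple[str, ...] = ()
    order: tuple[str, ...] = ()
    fused_pilMN: bool = False
    missing: tuple[str, ...] = ()


def detect_t4p(
    component_loci: Mapping[str, Iterable[str]],
    genome: GenomeAnnotation,
    domain_hits: pd.DataFrame,
    *,
    max_gap: int = 3,
    max_overlap_frac: float = 0.1,
    fusion_evalue_max: float = 1e-5,
) -> T4PVerdict:
    """Decide whether one genome encodes a type IV pilus system.

    ``component_loci`` maps each of the nine core component families to
    the loci with qualifying hits (already thresholded at E < 1e-5).
    The system is present iff a single marker cluster (consecutive-member
    gap <= ``max_gap``) contains PilM, PilN, PilO, PilP, PilQ in that
    genomic order on one strand — a *pilM–pilN* fusion gene satisfying
    both M and N — and at least two of PilB/PilC/PilT/PilU are hit
    anywhere in the genome.
    """
    from .context import find_marker_clusters

    loci_of = {fam: set(component_loci.get(fam, ())) for fam in
               T4P_CORE_ORDER + T4P_MOTOR_FAMILIES}
    missing = tuple(
        fam for fam in T4P_CORE_ORDER + T4P_MOTOR_FAMILIES if not loci_of[fam]
    )
    core_loci = sorted(set().union(*(loci_of[f] for f in T4P_CORE_ORDER)))
    core_loci = [l for l in core_loci if l in genome]
    n_motor = sum(1 for fam in T4P_MOTOR_FAMILIES if loci_of[fam])
    if not core_loci or n_motor < 2:
        return T4PVerdict(genome.genome_id, False, missing=missing)

    clusters = find_marker_clusters(genome, core_loci, max_gap=max_gap)
    for cluster in clusters:
        result = _ordered_mnopq(cluster, genome, loci_of, domain_hits,
                                max_overlap_frac, fusion_evalue_max)
        if result is not None:
            order, fused, loci = result
            return T4PVerdict(
                genome_id=genome.genome_id,
                present=True,
                cluster_loci=tuple(loci),
                order=tuple(order),
                fused_pilMN=fused,
                missing=missing,
            )
    return T4PVerdict(genome.genome_id, False, missing=missing)


def _ordered_mnopq(
    cluster: GeneCluster,
    genome: GenomeAnnotation,
    loci_of: Mapping[str, set[str]],
    domain_hits: pd.DataFrame,
    max_overlap_frac: float,
    fusion_evalue_max: float,
) -> tuple[list[str], bool, list[str]] | None:
    recs = genome.genes_on(cluster.replicon_id)
    members = [recs[i] for i in cluster.member_indices]
    for oriented in (members, list(reversed(members))):
        # read along the strand of the first matched gene
        i = 0
        fused = False
        matched: list[str] = []
        order: list[str] = []
        strand: str | None = None
        for gene in oriented:
            if i >= len(T4P_CORE_ORDER):
                break
            fams = {f for f in T4P_CORE_ORDER if gene.locus_tag in loci_of[f]}
            expected = T4P_CORE_ORDER[i]
            if expected not in fams:
                continue
            if strand is None:
                strand = gene.strand
            if gene.strand != strand:
                break
            if expected == "PilM" and "PilN" in fams:
                gene_hits = domain_hits[
                    domain_hits["protein_id"] == gene.protein_id
                ]
                if detect_fusion(
                    gene_hits,
                    PROFILE_PILM,
                    PROFILE_PILN,
                    max_overlap_frac=max_overlap_frac,
                    evalue_max=fusion_evalue_max,
                ):
                    matched.append(gene.locus_tag)
                    order.append("PilMN")
                    fused = True
                    i += 2
                    continue
            matched.append(gene.locus_tag)
            order.append(expected)
            i += 1
        if i == len(T4P_CORE_ORDER):
            return order, fused, matched
    return None


# ---------------------------------------------------------------------------
# close-range best-hit screens

BEST_HIT_FAMILY_MAP = {
    "FlgY": "FlgY",
    "PflA": "PflA_like",
    "PflB": "PflB_like",
    "PflD": "PflD",
    "FcpM": "FcpM",
    "FcpN": "FcpN",
    "FcpO": "FcpO",
}


def best_hit_screen(
    seq_hits: pd.DataFrame,
    genome_id: str,
    *,
    query_families: tuple[str, ...] = tuple(BEST_HIT_FAMILY_MAP),
    evalue_max: float = 1e-3,
    features: FeatureTable | None = None,
) -> list[HomologCall]:
    """Best-hit calls for close-range searches within a phylum.

    ``seq_hits`` must be restricted to the genome's own genes and carry a
    ``query_family`` column.  One call at most per family, at tier
    ``best_hit``; a ``struct_confirmed`` feature flag on the target
    protein is recorded as supporting evidence when present.
    """
    calls: list[HomologCall] = []
    for query in query_families:
        hit = best_hit(seq_hits, query, evalue_max=evalue_max)
        if hit is None:
            continue
        evidence = [f"best_hit:{query}", f"evalue:{hit.evalue:.3e}"]
        if (
            features is not None
            and hit.locus_tag in features
            and features.get(hit.locus_tag).struct_confirmed
        ):
            evidence.append("struct_confirmed")
        calls.append(
            HomologCall(
                family=BEST_HIT_FAMILY_MAP.get(query, query),
                genome_id=genome_id,
                locus_tag=hit.locus_tag,
                tier="best_hit",
                evidence=tuple(evidence),
            )
        )
    return calls


def calls_table(calls: Iterable[HomologCall]) -> pd.DataFrame:
    """Homolog calls as a sorted DataFrame (family, genome, locus, tier)."""
    rows = [
        {
            "family": c.family,
            "genome_id": c.genome_id,
            "locus_tag": c.locus_tag,
            "tier": c.tier,
            "evidence": ";".join(c.evidence),
        }
        for c in calls
    ]
    df = pd.DataFrame(
        rows, columns=["family", "genome_id", "locus_tag", "tier", "evidence"]
    )
    return df.sort_values(["family", "genome_id", "locus_tag"]).reset_index(
        drop=True
    )
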