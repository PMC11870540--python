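"""Gene-neighborhood computations.

Distances between genes are counted as *intervening genes* (strand
agnostic), not base pairs: a context rule such as "within five genes of a
flagellar gene cluster" asks how many genes lie strictly between the
candidate and the nearest cluster member.  Operon grouping, by contrast,
works on nucleotide gaps because transcriptional read-through depends on
physical spacing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .models import GeneRecord, GenomeAnnotation, ValidationError

#: sentinel distance for genes on different replicons
UNLINKED = math.inf


@dataclass(frozen=True)
class GeneCluster:
    """A maximal run of marker genes on one replicon."""

    genome_id: str
    replicon_id: str
    member_indices: tuple[int, ...]
    member_loci: tuple[str, ...]
    marker_families: tuple[str, ...] = ()
    label: str = "other"

    def __post_init__(self) -> None:
        if tuple(sorted(self.member_indices)) != tuple(self.member_indices):
            object.__setattr__(
                self, "member_indices", tuple(sorted(self.member_indices))
            )

    def __len__(self) -> int:
        return len(self.member_indices)


@dataclass(frozen=True)
class Operon:
    """Run of adjacent same-strand genes treated as one transcriptional unit."""

    genome_id: str
    replicon_id: str
    strand: str
    member_indices: tuple[int, ...]
    member_loci: tuple[str, ...]


def intervening_distance(
    a: GeneRecord,
    b: GeneRecord,
    *,
    circular: bool = False,
    replicon_size: int | None = None,
) -> float:
    """Number of genes strictly between ``a`` and ``b`` along the replicon.

    Adjacent or identical genes are at distance 0.  Genes on different
    replicons (or genomes) return the :data:`UNLINKED` sentinel.  On a
    circular replicon the minimum over both arcs is taken, which requires
    ``replicon_size`` (total gene count on the replicon).
    """
    if a.genome_id != b.genome_id or a.replicon_id != b.replicon_id:
        return UNLINKED
    d = abs(a.index - b.index)
    linear = max(d - 1, 0)
    if not circular:
        return linear
    if replicon_size is None:
        raise ValueError("circular distance requires replicon_size")
    if d == 0:
        return 0
    other_arc = replicon_size - d - 1
    return min(linear, max(other_arc, 0))


def _record_distance(
    genome: GenomeAnnotation, a: GeneRecord, b: GeneRecord
) -> float:
    circular = (
        a.replicon_id == b.replicon_id and genome.is_circular(a.replicon_id)
    )
    size = genome.replicon_size(a.replicon_id) if circular else None
    return intervening_distance(a, b, circular=circular, replicon_size=size)


def find_marker_clusters(
    genome: GenomeAnnotation,
    marker_loci: Iterable[str],
    *,
    max_gap: int = 5,
    marker_families: dict[str, str] | None = None,
    label: str = "other",
) -> list[GeneCluster]:
    """Group marker genes into maximal runs with inter-marker gaps <= max_gap.

    Consecutive markers along a replicon are chained while the number of
    intervening genes between them is at most ``max_gap``; singleton
    markers form singleton clusters.  Clusters never span replicons.
    """
    markers = sorted(set(marker_loci))
    records: dict[str, list[GeneRecord]] = {}
    for locus in markers:
        if locus not in genome:
            raise ValidationError(
                f"marker gene {locus!r} not found in genome {genome.genome_id}"
            )
        rec = genome.by_locus(locus)
        records.setdefault(rec.replicon_id, []).append(rec)

    clusters: list[GeneCluster] = []
    for replicon_id in sorted(records):
        recs = sorted(records[replicon_id], key=lambda g: g.index)
        run: list[GeneRecord] = [recs[0]]
        for rec in recs[1:]:
            gap = rec.index - run[-1].index - 1
            if gap <= max_gap:
                run.append(rec)
            else:
                clusters.append(_make_cluster(genome, run, marker_families, label))
                run = [rec]
        clusters.append(_make_cluster(genome, run, marker_families, label))
        # circular wrap: merge first and last cluster if the wrap gap closes
        if (
            genome.is_circular(replicon_id)
            and len(clusters) >= 2
            and clusters[-1].replicon_id == replicon_id
        ):
            first = next(c for c in clusters if c.replicon_id == replicon_id)
            last = clusters[-1]
            if first is not last:
                size = genome.replicon_size(replicon_id)
                wrap_gap = size - last.member_indices[-1] - 1 + first.member_indices[0]
                if wrap_gap <= max_gap:
                    merged = _make_cluster(
                        genome,
                        [genome.genes_on(replicon_id)[i]
                         for i in first.member_indices + last.member_indices],
                        marker_families,
                        label,
                    )
                    clusters.remove(first)
                    clusters.remove(last)
                    clusters.append(merged)
    return clusters


def _make_cluster(
    genome: GenomeAnnotation,
    run: Sequence[GeneRecord],
    marker_families: dict[str, str] | None,
    label: str,
) -> GeneCluster:
    fams: tuple[str, ...] = ()
    if marker_families:
        fams = tuple(
            sorted({marker_families[g.locus_tag]
                    for g in run if g.locus_tag in marker_families})
        )
    return GeneCluster(
        genome_id=genome.genome_id,
        replicon_id=run[0].replicon_id,
        member_indices=tuple(g.index for g in run),
        member_loci=tuple(g.locus_tag for g in run),
        marker_families=fams,
        label=label,
    )


def within_context(
    gene: GeneRecord,
    clusters: Sequence[GeneCluster],
    genome: GenomeAnnotation,
    *,
    n: int = 5,
) -> tuple[bool, float]:
    """Is ``gene`` within ``n`` intervening genes of any cluster member?

    Returns ``(verdict, nearest_distance)``; a cluster member itself is at
    distance 0.  With no clusters the distance is the unlinked sentinel.
    """
    best = UNLINKED
    for cluster in clusters:
        if cluster.replicon_id != gene.replicon_id:
            continue
        recs = genome.genes_on(cluster.replicon_id)
        for idx in cluster.member_indices:
            d = _record_distance(genome, gene, recs[idx])
            if d < best:
                best = d
            if best == 0:
                return True, 0
    return best <= n, best


def group_operons(
    genome: GenomeAnnotation, *, max_intergenic_bp: int = 150
) -> list[Operon]:
    """Partition each replicon into putative operons.

    Maximal runs of same-strand, index-consecutive genes whose inter-gene
    nucleotide gap is at most ``max_intergenic_bp``; overlapping genes
    (negative gap) are always grouped.
    """
    operons: list[Operon] = []
    for replicon_id in genome.replicons:
        recs = genome.genes_on(replicon_id)
        if not recs:
            continue
        run = [recs[0]]
        for prev, cur in zip(recs, recs[1:]):
            gap = cur.start - prev.end - 1
            if cur.strand == prev.strand and gap <= max_intergenic_bp:
                run.append(cur)
            else:
                operons.append(_make_operon(genome, run))
                run = [cur]
        operons.append(_make_operon(genome, run))
    return operons


def _make_operon(genome: GenomeAnnotation, run: Sequence[GeneRecord]) -> Operon:
    return Operon(
        genome_id=genome.genome_id,
        replicon_id=run[0].replicon_id,
        strand=run[0].strand,
        member_indices=tuple(g.index for g in run),
        member_loci=tuple(g.locus_tag for g in run),
    )


class OperonIndex:
    """Locus -> operon lookup built from :func:`group_operons` output."""

    def __init__(self, operons: Iterable[Operon]) -> None:
        self.operons = list(operons)
        self._by_locus: dict[str, Operon] = {}
        for op in self.operons:
            for locus in op.member_loci:
                self._by_locus[locus] = op

    def operon_of(self, locus_tag: str) -> Operon:
        try:
            return self._by_locus[locus_tag]
        except KeyError:
            raise ValidationError(
                f"locus {locus_tag!r} has no operon assignment"
            ) from None


def detect_fusion(
    hits_for_protein,
    profile_a: str,
    profile_b: str,
    *,
    max_overlap_frac: float = 0.1,
    evalue_max: float = 1e-5,
) -> bool:
    """Does one protein carry essentially non-overlapping hits to two profiles?

    ``hits_for_protein`` is a domain-hit DataFrame restricted to a single
    protein.  The protein is called a fusion iff it has at least one
    qualifying hit (E <= ``evalue_max``) to each profile and the best hit
    pair overlaps by at most ``max_overlap_frac`` of the shorter hit span.
    """
    if len(hits_for_protein) == 0:
        return False
    ok = hits_for_protein[hits_for_protein["evalue"] <= evalue_max]
    hits_a = ok[ok["profile_id"] == profile_a]
    hits_b = ok[ok["profile_id"] == profile_b]
    if hits_a.empty or hits_b.empty:
        return False
    best_a = hits_a.sort_values(["evalue", "env_start"]).iloc[0]
    best_b = hits_b.sort_values(["evalue", "env_start"]).iloc[0]
    overlap = (
        min(best_a["env_end"], best_b["env_end"])
        - max(best_a["env_start"], best_b["env_start"])
        + 1
    )
    if overlap <= 0:
        return True
    shorter = min(
        best_a["env_end"] - best_a["env_start"] + 1,
        best_b["env_end"] - best_b["env_start"] + 1,
    )
    return bool(overlap <= max_overlap_frac * shorter)
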