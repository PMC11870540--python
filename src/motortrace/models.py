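"""Core data structures shared across the pipeline.

Conventions
-----------
* Nucleotide coordinates are 1-based inclusive (GFF3).
* Gene ordinals (``index``) are 0-based and contiguous along each replicon
  in coordinate order.
* Amino-acid envelope coordinates on domain hits are 1-based inclusive.

Tabular evidence (sequence hits, domain hits) is carried as pandas
DataFrames with the column schemas declared here; gene models and genome
metadata are dataclasses because the neighborhood logic needs ordered,
validated records rather than rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping

STRANDS = ("+", "-")

ASSEMBLY_LEVELS = ("complete", "chromosome", "scaffold", "contig")

LINEAGE_RANKS = ("phylum", "class", "order", "family", "genus", "species")

#: column schema for pairwise sequence hit tables (BLAST outfmt-6 dialect)
SEQHIT_COLUMNS = (
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
)

#: column schema for per-domain profile hit tables (domtblout dialect)
DOMHIT_COLUMNS = (
    "protein_id",
    "profile_id",
    "env_start",
    "env_end",
    "evalue",
    "bitscore",
)


class ValidationError(ValueError):
    """Raised when an input record violates a documented invariant."""


@dataclass(frozen=True)
class GeneRecord:
    """One protein-coding gene on a replicon."""

    genome_id: str
    replicon_id: str
    index: int
    start: int
    end: int
    strand: str
    locus_tag: str
    protein_id: str = ""
    product: str = "hypothetical protein"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"gene {self.locus_tag}: start {self.start} > end {self.end}"
            )
        if self.strand not in STRANDS:
            raise ValidationError(
                f"gene {self.locus_tag}: strand must be one of {STRANDS}"
            )
        if self.index < 0:
            raise ValidationError(f"gene {self.locus_tag}: negative index")
        if not self.protein_id:
            object.__setattr__(self, "protein_id", self.locus_tag)


class GenomeAnnotation:
    """Ordered, stranded gene table for one genome.

    Genes are validated on construction: indices must be contiguous
    ``0..n-1`` per replicon in coordinate order and locus tags unique
    within the genome.
    """

    def __init__(
        self,
        genome_id: str,
        genes: Iterable[GeneRecord],
        circular_replicons: Iterable[str] = (),
    ) -> None:
        self.genome_id = genome_id
        self.circular_replicons = frozenset(circular_replicons)
        by_replicon: dict[str, list[GeneRecord]] = {}
        for g in genes:
            if g.genome_id != genome_id:
                raise ValidationError(
                    f"gene {g.locus_tag} belongs to {g.genome_id}, not {genome_id}"
                )
            by_replicon.setdefault(g.replicon_id, []).append(g)
        self._by_replicon: dict[str, list[GeneRecord]] = {}
        self._by_locus: dict[str, GeneRecord] = {}
        self._by_protein: dict[str, GeneRecord] = {}
        for replicon_id, recs in by_replicon.items():
            recs.sort(key=lambda g: g.index)
            for i, g in enumerate(recs):
                if g.index != i:
                    raise ValidationError(
                        f"{genome_id}/{replicon_id}: gene indices not contiguous "
                        f"(expected {i}, found {g.index} at {g.locus_tag})"
                    )
                if i and recs[i - 1].start > g.start:
                    raise ValidationError(
                        f"{genome_id}/{replicon_id}: indices not in coordinate order "
                        f"at {g.locus_tag}"
                    )
                if g.locus_tag in self._by_locus:
                    raise ValidationError(
                        f"{genome_id}: duplicate locus_tag {g.locus_tag}"
                    )
                self._by_locus[g.locus_tag] = g
                self._by_protein[g.protein_id] = g
            self._by_replicon[replicon_id] = recs

    @property
    def replicons(self) -> tuple[str, ...]:
        return tuple(sorted(self._by_replicon))

    def genes_on(self, replicon_id: str) -> list[GeneRecord]:
        return self._by_replicon[replicon_id]

    def replicon_size(self, replicon_id: str) -> int:
        return len(self._by_replicon[replicon_id])

    def is_circular(self, replicon_id: str) -> bool:
        return replicon_id in self.circular_replicons

    def by_locus(self, locus_tag: str) -> GeneRecord:
        try:
            return self._by_locus[locus_tag]
        except KeyError:
            raise KeyError(
                f"locus_tag {locus_tag!r} not in genome {self.genome_id}"
            ) from None

    def by_protein(self, protein_id: str) -> GeneRecord:
        try:
            return self._by_protein[protein_id]
        except KeyError:
            raise KeyError(
                f"protein_id {protein_id!r} not in genome {self.genome_id}"
            ) from None

    def __contains__(self, locus_tag: str) -> bool:
        return locus_tag in self._by_locus

    def __len__(self) -> int:
        return len(self._by_locus)

    def __iter__(self) -> Iterator[GeneRecord]:
        for replicon_id in self.replicons:
            yield from self._by_replicon[replicon_id]


@dataclass(frozen=True)
class GenomeMeta:
    """Assembly-level metadata used for genome-set curation.

    ``lineage`` maps rank labels to taxon names and must at minimum carry
    the balancing rank and ``genus``.  ``model_priority`` is a supplied
    integer (higher = preferred model organism, 0 = none); no organism
    list is embedded in the pipeline.
    """

    genome_id: str
    lineage: Mapping[str, str]
    assembly_level: str
    completeness: float
    contamination: float
    model_priority: int = 0

    def __post_init__(self) -> None:
        if self.assembly_level not in ASSEMBLY_LEVELS:
            raise ValidationError(
                f"{self.genome_id}: unknown assembly_level "
                f"{self.assembly_level!r} (expected one of {ASSEMBLY_LEVELS})"
            )
        if self.completeness is None or not 0.0 <= self.completeness <= 100.0:
            raise ValidationError(
                f"{self.genome_id}: completeness must be in [0, 100]"
            )
        if self.contamination is None or self.contamination < 0.0:
            raise ValidationError(
                f"{self.genome_id}: contamination must be >= 0"
            )
        object.__setattr__(self, "lineage", dict(self.lineage))

    def rank(self, rank_label: str) -> str:
        try:
            return self.lineage[rank_label]
        except KeyError:
            raise ValidationError(
                f"{self.genome_id}: no lineage value at rank {rank_label!r}"
            ) from None


@dataclass(frozen=True)
class ProteinFeature:
    """Externally supplied per-protein features.

    Transmembrane motifs, signal peptides and the antiparallel beta-pair
    flag come from upstream predictors; domain labels in
    ``blacklist_domains`` name known enzymatic functions (e.g.
    glycosyltransferase) that disqualify a TPR protein as a scaffold.
    """

    protein_id: str
    length: int
    has_tm: bool = False
    has_signal_peptide: bool = False
    has_beta_pair: bool = False
    blacklist_domains: frozenset[str] = frozenset()
    struct_confirmed: bool = False

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValidationError(f"{self.protein_id}: length must be > 0")
        object.__setattr__(
            self, "blacklist_domains", frozenset(self.blacklist_domains)
        )


class FeatureTable:
    """Lookup of :class:`ProteinFeature` by protein id."""

    def __init__(self, features: Iterable[ProteinFeature] = ()) -> None:
        self._features: dict[str, ProteinFeature] = {}
        for f in features:
            self._features[f.protein_id] = f

    def add(self, feature: ProteinFeature) -> None:
        self._features[feature.protein_id] = feature

    def get(self, protein_id: str) -> ProteinFeature:
        try:
            return self._features[protein_id]
        except KeyError:
            raise KeyError(f"no feature record for protein {protein_id!r}") from None

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self._features

    def __len__(self) -> int:
        return len(self._features)

    def __iter__(self) -> Iterator[ProteinFeature]:
        return iter(sorted(self._features.values(), key=lambda f: f.protein_id))


#: call tiers, in decreasing order of confidence
CALL_TIERS = ("context_validated", "best_hit", "rescue_candidate")

SCAFFOLD_FAMILIES = (
    "FlgY",
    "PflA_like",
    "PflB_like",
    "PflD",
    "FcpM",
    "FcpN",
    "FcpO",
)

T4P_FAMILIES = (
    "PilM",
    "PilN",
    "PilO",
    "PilP",
    "PilQ",
    "PilB",
    "PilC",
    "PilT",
    "PilU",
)

CALL_FAMILIES = SCAFFOLD_FAMILIES + T4P_FAMILIES


@dataclass(frozen=True)
class HomologCall:
    """A (family, gene, tier) verdict produced by a screen."""

    family: str
    genome_id: str
    locus_tag: str
    tier: str
    evidence: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.family not in CALL_FAMILIES:
            raise ValidationError(f"unknown call family {self.family!r}")
        if self.tier not in CALL_TIERS:
            raise ValidationError(f"unknown call tier {self.tier!r}")
        if not self.evidence:
            raise ValidationError(
                f"{self.family} call at {self.locus_tag}: no evidence tags"
            )
        object.__setattr__(self, "evidence", tuple(self.evidence))


@dataclass(frozen=True)
class Discard:
    """Why a candidate hit was rejected by a screen (for the discard log)."""

    family: str
    genome_id: str
    locus_tag: str
    reason: str
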