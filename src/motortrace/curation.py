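"""Genome-set curation: assembly-quality filtering and taxonomic balancing.

Two independent steps shape a representative genome set:

``filter_quality``
    removes assemblies with completeness strictly below a floor or
    contamination strictly above a ceiling (boundary values are kept).

``balance_taxa``
    caps over-represented taxonomic groups: groups above a size threshold
    are first restricted to complete assemblies, and if still too large,
    to a single genome per genus, preferring experimentally characterized
    model organisms (``model_priority``) and breaking ties by accession.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .models import GenomeMeta, ValidationError


@dataclass(frozen=True)
class Removal:
    genome_id: str
    rule: str
    detail: str


def filter_quality(
    metas: Sequence[GenomeMeta],
    *,
    min_completeness: float = 70.0,
    max_contamination: float = 10.0,
) -> tuple[list[GenomeMeta], list[Removal]]:
    """Drop genomes with completeness < floor or contamination > ceiling.

    Inequalities are strict: a genome at exactly the floor/ceiling is
    retained.  Input order is preserved; the removal log states which
    rule fired for each removed genome.
    """
    if not 0.0 <= min_completeness <= 100.0:
        raise ValueError("min_completeness must be in [0, 100]")
    if max_contamination < 0.0:
        raise ValueError("max_contamination must be >= 0")
    kept: list[GenomeMeta] = []
    removed: list[Removal] = []
    for meta in metas:
        if meta.completeness < min_completeness:
            removed.append(
                Removal(
                    meta.genome_id,
                    "completeness",
                    f"completeness {meta.completeness:g} < {min_completeness:g}",
                )
            )
        elif meta.contamination > max_contamination:
            removed.append(
                Removal(
                    meta.genome_id,
                    "contamination",
                    f"contamination {meta.contamination:g} > {max_contamination:g}",
                )
            )
        else:
            kept.append(meta)
    return kept, removed


def balance_taxa(
    metas: Sequence[GenomeMeta],
    *,
    balancing_rank: str = "phylum",
    size_threshold: int = 200,
) -> list[GenomeMeta]:
    """Cap each taxonomic group at ``size_threshold`` genomes.

    Groups (values at ``balancing_rank``) with at most ``size_threshold``
    genomes pass through intact.  Larger groups keep only complete
    assemblies; if the complete subset still exceeds the threshold,
    exactly one genome per genus is kept, chosen by descending
    ``model_priority`` and then lexicographically smallest accession.

    The returned list is sorted by genome_id, making the selection
    invariant to input ordering.
    """
    if size_threshold < 0:
        raise ValueError("size_threshold must be non-negative")
    seen: set[str] = set()
    for meta in metas:
        if meta.genome_id in seen:
            raise ValidationError(f"duplicate genome_id {meta.genome_id}")
        seen.add(meta.genome_id)

    groups: dict[str, list[GenomeMeta]] = {}
    for meta in metas:
        groups.setdefault(meta.rank(balancing_rank), []).append(meta)

    selected: list[GenomeMeta] = []
    for group in sorted(groups):
        members = groups[group]
        if len(members) <= size_threshold:
            selected.extend(members)
            continue
        complete = [m for m in members if m.assembly_level == "complete"]
        if len(complete) <= size_threshold:
            selected.extend(complete)
            continue
        per_genus: dict[str, GenomeMeta] = {}
        for meta in complete:
            genus = meta.rank("genus")
            incumbent = per_genus.get(genus)
            if incumbent is None or _genus_key(meta) < _genus_key(incumbent):
                per_genus[genus] = meta
        selected.extend(per_genus.values())
    return sorted(selected, key=lambda m: m.genome_id)


def _genus_key(meta: GenomeMeta) -> tuple[int, str]:
    # prefer high model_priority, then smallest accession
    return (-meta.model_priority, meta.genome_id)
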