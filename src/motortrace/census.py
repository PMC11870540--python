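"""Flagellar core-gene census.

A species is classified as possessing a flagellar gene set when hits to
at least ``min_core`` (default 20) of the 24 broadly conserved core
flagellar protein families are found in its genome.  The relaxed
threshold (20 rather than 24) absorbs incomplete assemblies and
pseudogenes.  The census consumes pairwise sequence hit tables produced
by any BLASTP/PSI-BLAST-style search; it never runs a search itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .models import ValidationError

#: the 24 core flagellar protein families, export apparatus to filament
CORE_FAMILIES: tuple[str, ...] = (
    "FlhA",
    "FlhB",
    "FliP",
    "FliQ",
    "FliR",
    "FliI",
    "FliH",
    "FliF",
    "MotA",
    "MotB",
    "FliG",
    "FliM",
    "FliN",
    "FliE",
    "FlgB",
    "FlgC",
    "FlgF",
    "FlgG",
    "FlgE",
    "FlgD",
    "FlgK",
    "FlgL",
    "FliC",
    "FliD",
)

DEFAULT_MIN_CORE = 20

#: default E-value ceiling for the core-protein searches (inclusive)
DEFAULT_CENSUS_EVALUE = 1e-5


@dataclass(frozen=True)
class CensusResult:
    species_id: str
    presence: Mapping[str, bool]
    min_core: int = DEFAULT_MIN_CORE

    def __post_init__(self) -> None:
        object.__setattr__(self, "presence", dict(self.presence))

    @property
    def core_count(self) -> int:
        return sum(bool(v) for v in self.presence.values())

    @property
    def is_flagellated(self) -> bool:
        return classify_flagellated(self.core_count, min_core=self.min_core)


def census_core_genes(
    hits: pd.DataFrame,
    species_id: str,
    *,
    families: tuple[str, ...] = CORE_FAMILIES,
    evalue_max: float = DEFAULT_CENSUS_EVALUE,
    min_core: int = DEFAULT_MIN_CORE,
) -> CensusResult:
    """Collapse core-family hit rows for one species to a presence map.

    ``hits`` must carry ``query_family`` and ``evalue`` columns and be
    restricted to the species' own genes.  A family is present iff at
    least one hit with E <= ``evalue_max`` exists (the ceiling is
    inclusive); multiple hits collapse to one presence bit.
    """
    presence = {fam: False for fam in families}
    if len(hits):
        unknown = ~hits["query_family"].isin(families)
        if unknown.any():
            bad = hits.loc[unknown]
            raise ValidationError(
                "hit rows reference unknown core families: "
                + ", ".join(
                    f"{r.query_family}->{r.sseqid}" for r in bad.itertuples()
                )
            )
        qualifying = hits[hits["evalue"] <= evalue_max]
        for fam in qualifying["query_family"].unique():
            presence[fam] = True
    return CensusResult(species_id=species_id, presence=presence, min_core=min_core)


def classify_flagellated(core_count: int, *, min_core: int = DEFAULT_MIN_CORE) -> bool:
    """True iff at least ``min_core`` core families were detected."""
    if not 0 <= core_count <= len(CORE_FAMILIES):
        raise ValidationError(
            f"core_count {core_count} outside [0, {len(CORE_FAMILIES)}]"
        )
    return core_count >= min_core


def census_table(results: list[CensusResult]) -> pd.DataFrame:
    """Census results as a species x family presence table."""
    rows = []
    for res in sorted(results, key=lambda r: r.species_id):
        row: dict[str, object] = {"species": res.species_id}
        row.update({fam: int(res.presence.get(fam, False)) for fam in CORE_FAMILIES})
        row["core_count"] = res.core_count
        row["is_flagellated"] = res.is_flagellated
        rows.append(row)
    return pd.DataFrame(rows)
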