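"""Phylogenetic profiling of trait presence/absence.

Builds species x trait presence matrices from homolog calls and census
results, quantifies prevalence and pairwise co-occurrence (Jaccard index
with a right-tail hypergeometric enrichment probability), reconstructs
ancestral presence on a rooted species tree by generalized Fitch
parsimony (with a Dollo variant for loss-only models), and exports
iTOL-compatible annotation files.

Parsimony here formalizes the verbal inference that a trait shared by a
clade's extant members existed in their common ancestor; the minimum
change count is exact for binary trees and uses the standard
intersection/union generalization at polytomies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .census import CensusResult
from .models import CALL_FAMILIES, HomologCall, ValidationError

DEFAULT_COUNT_TIERS = frozenset({"context_validated", "best_hit"})

# the T4P system verdict is a computed column; callers that track it pass
# it through ``extra_traits``
DEFAULT_TRAITS = (
    "flagellar_gene_set",
    "FlgY",
    "PflA_like",
    "PflB_like",
    "PflD",
    "FcpM",
    "FcpN",
    "FcpO",
    "FcpMNO",
)

DEFAULT_COMPOSITES: dict[str, tuple[str, ...]] = {
    "FcpMNO": ("FcpM", "FcpN", "FcpO"),
}


@dataclass(frozen=True)
class PresenceMatrix:
    """Binary species x trait matrix with call-tier provenance."""

    data: pd.DataFrame
    counted_tiers: frozenset[str] = DEFAULT_COUNT_TIERS

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(self.data.index)

    @property
    def traits(self) -> tuple[str, ...]:
        return tuple(self.data.columns)

    def column(self, trait: str) -> pd.Series:
        if trait not in self.data.columns:
            raise ValidationError(f"trait {trait!r} not in matrix")
        return self.data[trait]


def build_matrix(
    calls: Iterable[HomologCall],
    census: Iterable[CensusResult],
    species: Sequence[str],
    *,
    traits: Sequence[str] = DEFAULT_TRAITS,
    count_tiers: Iterable[str] = DEFAULT_COUNT_TIERS,
    composites: Mapping[str, tuple[str, ...]] = DEFAULT_COMPOSITES,
    extra_traits: Mapping[str, Mapping[str, bool]] | None = None,
) -> PresenceMatrix:
    """Assemble the presence matrix from calls, census and extra traits.

    A family trait is 1 iff at least one call of a counted tier exists for
    that species; ``flagellar_gene_set`` mirrors the census verdict;
    composite traits are conjunctions of other columns; ``extra_traits``
    supplies columns computed elsewhere (e.g. the T4P system verdict).
    """
    count_tiers = frozenset(count_tiers)
    extra = {k: dict(v) for k, v in (extra_traits or {}).items()}
    census_by_sp = {c.species_id: c for c in census}
    present: dict[str, set[str]] = {}
    for call in calls:
        if call.tier in count_tiers:
            present.setdefault(call.family, set()).add(call.genome_id)

    columns: dict[str, list[int]] = {}
    deferred: list[str] = []
    for trait in traits:
        if trait == "flagellar_gene_set":
            columns[trait] = [
                int(census_by_sp[sp].is_flagellated) if sp in census_by_sp else 0
                for sp in species
            ]
        elif trait in extra:
            columns[trait] = [int(bool(extra[trait].get(sp, False))) for sp in species]
        elif trait in CALL_FAMILIES:
            fam_species = present.get(trait, set())
            columns[trait] = [int(sp in fam_species) for sp in species]
        elif trait in composites:
            deferred.append(trait)
        else:
            raise ValidationError(
                f"trait {trait!r} has no family mapping, composite formula "
                "or extra-trait column"
            )
    frame = pd.DataFrame(columns, index=list(species))
    for trait in deferred:
        parts = composites[trait]
        missing = [p for p in parts if p not in frame.columns]
        if missing:
            raise ValidationError(
                f"composite trait {trait!r} references unknown columns {missing}"
            )
        frame[trait] = frame[list(parts)].all(axis=1).astype(int)
    frame = frame[[t for t in traits]]
    return PresenceMatrix(data=frame, counted_tiers=count_tiers)


def prevalence(
    matrix: PresenceMatrix, trait: str, subset: Iterable[str] | None = None
) -> tuple[float, int, int]:
    """Fraction of a species subset carrying a trait, with the raw counts."""
    col = matrix.column(trait)
    if subset is None:
        sub = col
    else:
        subset = list(subset)
        missing = sorted(set(subset) - set(matrix.species))
        if missing:
            raise ValidationError(f"subset species not in matrix: {missing}")
        sub = col.loc[subset]
    if len(sub) == 0:
        raise ValidationError("prevalence over an empty species subset")
    numerator = int(sub.sum())
    return numerator / len(sub), numerator, len(sub)


@dataclass(frozen=True)
class Cooccurrence:
    jaccard: float
    both: int
    a_only: int
    b_only: int
    neither: int
    p_enrichment: float


def cooccurrence(matrix: PresenceMatrix, trait_a: str, trait_b: str) -> Cooccurrence:
    """Jaccard overlap of two traits plus a hypergeometric tail probability.

    The probability is the right tail P(overlap >= observed) under random
    placement of trait B's presences among all species.
    """
    a = matrix.column(trait_a).astype(bool)
    b = matrix.column(trait_b).astype(bool)
    both = int((a & b).sum())
    a_only = int((a & ~b).sum())
    b_only = int((~a & b).sum())
    neither = int((~a & ~b).sum())
    union = both + a_only + b_only
    jaccard = both / union if union else 0.0
    n = len(a)
    p = float(hypergeom.sf(both - 1, n, int(a.sum()), int(b.sum())))
    return Cooccurrence(jaccard, both, a_only, b_only, neither, p)


# ---------------------------------------------------------------------------
# ancestral-state reconstruction


@dataclass
class AncestralReconstruction:
    """Per-node parsimony state sets and the minimal change count."""

    states: dict[dendropy.Node, frozenset[int]]
    changes: int
    method: str = "fitch"

    def state_of(self, node: dendropy.Node) -> frozenset[int]:
        return self.states[node]

    @property
    def root_states(self) -> frozenset[int]:
        root = next(iter(self.states))
        while root.parent_node is not None:
            root = root.parent_node
        return self.states[root]


def fitch_ancestral(
    tree: dendropy.Tree, leaf_states: Mapping[str, int]
) -> AncestralReconstruction:
    """Generalized Fitch small parsimony for a binary trait.

    Children are merged sequentially: the running set is intersected with
    each child set when the intersection is non-empty, otherwise unioned
    with one change counted.  For strictly bifurcating trees the change
    count is the exact parsimony minimum.
    """
    states: dict[dendropy.Node, frozenset[int]] = {}
    changes = 0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label if node.taxon else None
            if label is None or label not in leaf_states:
                raise ValidationError(f"leaf {label!r} has no trait state")
            value = int(leaf_states[label])
            if value not in (0, 1):
                raise ValidationError(
                    f"leaf {label!r}: state must be 0 or 1, got {value}"
                )
            states[node] = frozenset({value})
            continue
        merged: frozenset[int] | None = None
        for child in node.child_nodes():
            cs = states[child]
            if merged is None:
                merged = cs
            elif merged & cs:
                merged = merged & cs
            else:
                merged = merged | cs
                changes += 1
        states[node] = merged if merged is not None else frozenset({0, 1})
    return AncestralReconstruction(states=states, changes=changes, method="fitch")


def dollo_ancestral(
    tree: dendropy.Tree, leaf_states: Mapping[str, int]
) -> AncestralReconstruction:
    """Dollo parsimony: a single gain at the MRCA of present leaves.

    Under the loss-only model the trait arises once at the most recent
    common ancestor of all leaves carrying it; every node inside that
    clade with at least one present descendant is reconstructed present.
    The change count is that single gain plus the implied losses.
    """
    has_present: dict[dendropy.Node, bool] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label if node.taxon else None
            if label is None or label not in leaf_states:
                raise ValidationError(f"leaf {label!r} has no trait state")
            has_present[node] = bool(int(leaf_states[label]))
        else:
            has_present[node] = any(
                has_present[c] for c in node.child_nodes()
            )

    present_leaves = [
        n for n in tree.leaf_node_iter() if has_present[n]
    ]
    states: dict[dendropy.Node, frozenset[int]] = {}
    if not present_leaves:
        for node in tree.postorder_node_iter():
            states[node] = frozenset({0})
        return AncestralReconstruction(states=states, changes=0, method="dollo")

    # MRCA = deepest node whose subtree holds all present leaves
    mrca = tree.seed_node
    improved = True
    while improved:
        improved = False
        for child in mrca.child_nodes():
            if all(_in_subtree(leaf, child) for leaf in present_leaves):
                mrca = child
                improved = True
                break

    losses = 0
    inside = set(mrca.preorder_iter())
    for node in tree.postorder_node_iter():
        if node in inside and has_present[node]:
            states[node] = frozenset({1})
        else:
            states[node] = frozenset({0})
    for node in tree.preorder_node_iter():
        for child in node.child_nodes():
            if states[node] == frozenset({1}) and states[child] == frozenset({0}):
                losses += 1
    changes = 1 + losses
    return AncestralReconstruction(states=states, changes=changes, method="dollo")


def _in_subtree(leaf: dendropy.Node, ancestor: dendropy.Node) -> bool:
    node = leaf
    while node is not None:
        if node is ancestor:
            return True
        node = node.parent_node
    return False


# ---------------------------------------------------------------------------
# iTOL export

_PALETTE = (
    "#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd",
    "#8c564b", "#e377c2", "#7f7f7f", "#bcbd22", "#17becf",
)


def export_tree_annotations(
    matrix: PresenceMatrix,
    tree: dendropy.Tree,
    out_dir: str | Path,
    *,
    taxon_groups: Mapping[str, str] | None = None,
) -> list[Path]:
    """Write iTOL binary-dataset files (one per trait) plus a colour strip.

    Matrix species must all be tree leaves; data lines are emitted in
    sorted species order so output is deterministic.
    """
    leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = sorted(set(matrix.species) - leaves)
    if missing:
        raise ValidationError(f"matrix species missing from tree: {missing}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    species = sorted(matrix.species)
    for i, trait in enumerate(matrix.traits):
        color = _PALETTE[i % len(_PALETTE)]
        lines = [
            "DATASET_BINARY",
            "SEPARATOR COMMA",
            f"DATASET_LABEL,{trait}",
            f"COLOR,{color}",
            f"FIELD_LABELS,{trait}",
            "FIELD_SHAPES,1",
            f"FIELD_COLORS,{color}",
            "DATA",
        ]
        col = matrix.column(trait)
        lines += [f"{sp},{int(col.loc[sp])}" for sp in species]
        path = out / f"itol_{trait}.txt"
        path.write_text("\n".join(lines) + "\n")
        written.append(path)

    groups = dict(taxon_groups or {})
    group_names = sorted(set(groups.values()))
    color_of = {
        g: _PALETTE[i % len(_PALETTE)] for i, g in enumerate(group_names)
    }
    lines = [
        "DATASET_COLORSTRIP",
        "SEPARATOR COMMA",
        "DATASET_LABEL,taxon_groups",
        "COLOR,#999999",
        "DATA",
    ]
    lines += [
        f"{sp},{color_of[groups[sp]]},{groups[sp]}"
        for sp in species
        if sp in groups
    ]
    path = out / "itol_taxon_colorstrip.txt"
    path.write_text("\n".join(lines) + "\n")
    written.append(path)
    return written


def parse_itol_binary(text: str) -> dict[str, int]:
    """Read back a DATASET_BINARY file's species -> state mapping."""
    out: dict[str, int] = {}
    in_data = False
    for line in text.splitlines():
        if line.strip() == "DATA":
            in_data = True
            continue
        if in_data and line.strip():
            sp, value = line.split(",")[:2]
            out[sp] = int(value)
    return out
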