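"""Species-monophyly benchmarking of marker sets.

A species is monophyletic on an (effectively unrooted) tree when some branch
bipartition separates exactly that species' tips from every other tip —
soft-polytomy semantics, and invariant to where the tree happens to be
rooted. Species with a single tip cannot inform monophyly and are excluded
from the counts. Marker sets are compared on the species scored in every
tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import dendropy
import pandas as pd

MONOPHYLETIC = "monophyletic"
NON_MONOPHYLETIC = "non_monophyletic"
EXCLUDED_SINGLETON = "excluded_singleton"


@dataclass
class LabeledTree:
    """A tree whose tips map to species.

    ``tree`` is a dendropy Tree; ``tip_to_species`` maps every tip label to a
    species name. Node support values, if present, are carried by the tree
    but play no role in monophyly scoring.
    """

    tree: dendropy.Tree
    tip_to_species: dict[str, str]

    def __post_init__(self) -> None:
        tips = {leaf.taxon.label for leaf in self.tree.leaf_node_iter()}
        unmapped = tips - set(self.tip_to_species)
        if unmapped:
            raise ValueError(f"unmapped tips: {sorted(unmapped)[:5]}...")
        self._bipartitions = None

    @classmethod
    def from_newick(
        cls,
        newick: str | Path,
        tip_to_species: Optional[Mapping[str, str]] = None,
        species_sep: str = "_",
    ) -> "LabeledTree":
        """Parse a Newick string or file.

        Without an explicit map, the species is taken as the tip label up to
        the last ``species_sep`` (e.g. tip ``sp03_2`` -> species ``sp03``).
        """
        src = str(newick)
        if "(" in src:
            tree = dendropy.Tree.get(data=src, schema="newick",
                                     preserve_underscores=True)
        else:
            tree = dendropy.Tree.get(path=src, schema="newick",
                                     preserve_underscores=True)
        if tip_to_species is None:
            tip_to_species = {
                leaf.taxon.label: leaf.taxon.label.rsplit(species_sep, 1)[0]
                for leaf in tree.leaf_node_iter()
            }
        return cls(tree, dict(tip_to_species))

    def species_tips(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for leaf in self.tree.leaf_node_iter():
            label = leaf.taxon.label
            out.setdefault(self.tip_to_species[label], []).append(label)
        return out

    def _edge_bitmasks(self) -> tuple[set[int], int]:
        if self._bipartitions is None:
            self.tree.encode_bipartitions()
            masks = {
                b.leafset_bitmask for b in self.tree.bipartition_encoding
            }
            full = self.tree.taxon_namespace.all_taxa_bitmask()
            self._bipartitions = (masks, full)
        return self._bipartitions

    def _species_bitmask(self, tips: Sequence[str]) -> int:
        ns = self.tree.taxon_namespace
        mask = 0
        for t in tips:
            taxon = ns.get_taxon(t)
            mask |= ns.taxon_bitmask(taxon)
        return mask


def is_monophyletic(ltree: LabeledTree, species: str) -> str:
    """Monophyly status of one species on the tree.

    Returns 'monophyletic', 'non_monophyletic' or 'excluded_singleton'.
    A species is monophyletic iff its tip set (or the complement — the tree
    is treated as unrooted) equals the leafset of some edge.
    """
    tips = ltree.species_tips().get(species)
    if not tips:
        raise KeyError(f"species {species!r} has no tips on this tree")
    if len(tips) == 1:
        return EXCLUDED_SINGLETON
    masks, full = ltree._edge_bitmasks()
    mask = ltree._species_bitmask(tips)
    if mask == full or mask in masks or (full ^ mask) in masks:
        return MONOPHYLETIC
    return NON_MONOPHYLETIC


@dataclass
class MonophylyReport:
    """Per-species monophyly statuses for one marker's tree."""

    marker: str
    status: dict[str, str]

    @property
    def n_monophyletic(self) -> int:
        return sum(1 for v in self.status.values() if v == MONOPHYLETIC)

    @property
    def n_non_monophyletic(self) -> int:
        return sum(1 for v in self.status.values() if v == NON_MONOPHYLETIC)

    @property
    def n_excluded_singleton(self) -> int:
        return sum(1 for v in self.status.values() if v == EXCLUDED_SINGLETON)

    @property
    def scored_species(self) -> set[str]:
        """Species with >= 2 tips, i.e. actually scored."""
        return {s for s, v in self.status.items() if v != EXCLUDED_SINGLETON}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"species": list(self.status), "status": list(self.status.values()),
             "marker": self.marker}
        )


def count_monophyletic(ltree: LabeledTree, marker: str = "") -> MonophylyReport:
    """Score every species on the tree; singletons are excluded from counts."""
    status = {
        sp: is_monophyletic(ltree, sp) for sp in sorted(ltree.species_tips())
    }
    return MonophylyReport(marker, status)


def compare_markers(reports: Mapping[str, MonophylyReport]) -> pd.DataFrame:
    """Compare marker sets on the species scored in every marker's tree.

    Returns one row per common species with a status column per marker, plus
    per-marker monophyletic counts in ``attrs['counts']``.
    """
    if len(reports) < 2:
        raise ValueError("need >= 2 marker reports to compare")
    common: Optional[set[str]] = None
    for rep in reports.values():
        scored = rep.scored_species
        common = scored if common is None else common & scored
    assert common is not None
    if not common:
        import warnings
        warnings.warn("no species scored in every marker", stacklevel=2)
    rows = []
    for sp in sorted(common):
        row = {"species": sp}
        for marker, rep in reports.items():
            row[marker] = rep.status[sp]
        rows.append(row)
    table = pd.DataFrame(rows, columns=["species", *reports])
    table.attrs["counts"] = {
        marker: int((table[marker] == MONOPHYLETIC).sum()) if len(table) else 0
        for marker in reports
    }
    return table
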