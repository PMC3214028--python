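"""Faith's phylogenetic diversity on the unrooted barcode tree."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .errors import InputError
from .njtree import BarcodeTree


@dataclass(frozen=True)
class PDResult:
    pd_value: float
    tip_subset: frozenset[str]
    fraction_of_species_represented: float  # percent of tree tips in subset


def faith_pd(tree: BarcodeTree, tip_subset: Sequence[str] | frozenset[str]) -> PDResult:
    """Sum of branch lengths of the minimal subtree connecting the subset.

    Unrooted (Steiner) definition: an edge contributes iff removing it
    separates at least two members of the subset, i.e. the subset has members
    on both sides of the edge.  Singletons are undefined without a root.
    """
    subset = frozenset(tip_subset)
    all_tips = tree.tip_set
    unknown = subset - all_tips
    if unknown:
        raise InputError(f"tips not in tree: {sorted(unknown)}")
    if len(subset) < 2:
        raise InputError("PD needs at least 2 tips on an unrooted tree")
    total = 0.0
    for node, below in tree.edges():
        inside = len(subset & below)
        if 0 < inside < len(subset):
            total += node.length or 0.0
    return PDResult(
        pd_value=total,
        tip_subset=subset,
        fraction_of_species_represented=100.0 * len(subset) / len(all_tips),
    )
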