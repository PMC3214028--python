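"""Zero-distance monophyletic species delimitation and accuracy scoring.

A hypothetical species is a maximal monophyletic group whose members show no
observed genetic distance (exact zero, i.e. identical retained nucleotide
columns and, when indel characters are coded, identical binary codes).  The
richness estimate is the number of such groups minus the number of known
amplification-error sequences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .distances import DistanceMatrix
from .errors import InputError
from .njtree import BarcodeTree, is_clade


def integer_percent(numerator: float, denominator: float) -> int:
    """Percentage rounded half away from zero, as printed in the report."""
    if denominator == 0:
        raise InputError("percentage with zero denominator")
    value = 100.0 * numerator / denominator
    return int(math.floor(value + 0.5)) if value >= 0 else -int(math.floor(-value + 0.5))


@dataclass(frozen=True)
class DelimitationResult:
    """Partition of samples into hypothetical species plus the estimate."""

    clusters: tuple[frozenset[str], ...]
    richness_estimate: int
    n_amplification_errors: int
    corrected_estimate: int


@dataclass(frozen=True)
class AccuracySummary:
    """One summary row: resolution counts and the two accuracy percentages.

    In unknown-flora mode the label-dependent fields are ``None`` (never
    zero-filled).
    """

    species_resolved: Optional[int]
    not_resolved: Optional[int]
    estimated_from_data: int
    present_in_alignment: Optional[int]
    present_in_plot: Optional[int]
    discrimination_accuracy: Optional[int]
    estimation_accuracy: Optional[int]
    discrimination_exact: Optional[float] = None
    estimation_exact: Optional[float] = None


def _identity_classes(
    dmat: DistanceMatrix, binary_chars: Optional[Mapping[str, str]] = None
) -> dict[str, frozenset[str]]:
    """Map each sample to its zero-distance equivalence class.

    Two samples are equivalent iff their distance is exactly zero and (when
    indel characters are present) their binary code strings are equal.
    """
    ids = dmat.sample_ids
    zero = dmat.d == 0.0
    classes: dict[str, frozenset[str]] = {}
    for i, sid in enumerate(ids):
        members = [ids[j] for j in np.flatnonzero(zero[i])]
        if binary_chars is not None:
            code = binary_chars.get(sid)
            members = [m for m in members if binary_chars.get(m) == code]
        classes[sid] = frozenset(members)
    return classes


def zero_distance_clusters(
    tree: BarcodeTree,
    dmat: DistanceMatrix,
    binary_chars: Optional[Mapping[str, str]] = None,
) -> tuple[frozenset[str], ...]:
    """Partition tips into maximal zero-distance monophyletic groups.

    For each tip the largest clade (edge side, or the full tip set) whose
    members are all at pairwise distance zero from one another is found; the
    distinct such groups partition the tips because the qualifying clades
    containing a given tip are nested.  Clusters are returned sorted by their
    smallest member id.
    """
    if tree.tip_set != frozenset(dmat.sample_ids):
        raise InputError("tree tips do not match distance matrix ids")
    if dmat.saturated_pairs:
        raise InputError(
            f"undefined (saturated) distance for pair {dmat.saturated_pairs[0]!r}"
        )
    classes = _identity_classes(dmat, binary_chars)
    candidates = sorted(tree.clade_sides(), key=len, reverse=True)
    assignment: dict[str, frozenset[str]] = {}
    for tip in dmat.sample_ids:
        cls = classes[tip]
        best: frozenset[str] = frozenset({tip})
        for side in candidates:
            if len(side) <= len(best):
                break
            if tip in side and side <= cls:
                best = side
                break
        assignment[tip] = best
    clusters = sorted(set(assignment.values()), key=min)
    covered = frozenset().union(*clusters) if clusters else frozenset()
    if covered != frozenset(dmat.sample_ids) or sum(map(len, clusters)) != len(covered):
        raise AssertionError("clusters do not partition the samples")
    return tuple(clusters)


def richness_estimate(
    partition: Sequence[frozenset[str]], n_errors: int
) -> DelimitationResult:
    """Corrected richness: cluster count minus known amplification errors."""
    count = len(partition)
    if n_errors < 0:
        raise InputError("n_errors must be >= 0")
    if n_errors > count:
        raise InputError(
            f"n_errors ({n_errors}) exceeds the number of clusters ({count})"
        )
    return DelimitationResult(
        clusters=tuple(partition),
        richness_estimate=count,
        n_amplification_errors=n_errors,
        corrected_estimate=count - n_errors,
    )


@dataclass(frozen=True)
class DiscriminationScore:
    species_resolved: int
    not_resolved: int
    present_in_alignment: int
    discrimination_accuracy: int
    discrimination_exact: float
    resolved_species: tuple[str, ...]


def score_discrimination(
    partition: Sequence[frozenset[str]], species_labels: Mapping[str, str]
) -> DiscriminationScore:
    """Count species whose samples form exactly one pure cluster.

    A species is resolved iff the set of its samples equals one cluster —
    no foreign samples, no splitting across clusters, no fusion with another
    species.
    """
    samples = frozenset().union(*partition) if partition else frozenset()
    missing = [s for s in samples if s not in species_labels]
    if missing:
        raise InputError(f"samples lacking species labels: {sorted(missing)[:5]}")
    by_species: dict[str, set[str]] = {}
    for sample in samples:
        by_species.setdefault(species_labels[sample], set()).add(sample)
    cluster_set = {frozenset(c) for c in partition}
    resolved = tuple(
        sorted(sp for sp, members in by_species.items() if frozenset(members) in cluster_set)
    )
    present = len(by_species)
    n_resolved = len(resolved)
    return DiscriminationScore(
        species_resolved=n_resolved,
        not_resolved=present - n_resolved,
        present_in_alignment=present,
        discrimination_accuracy=integer_percent(n_resolved, present),
        discrimination_exact=100.0 * n_resolved / present,
        resolved_species=resolved,
    )


def score_estimation(corrected_estimate: int, present_in_plot: int) -> int:
    """Richness estimation accuracy (may exceed 100 on over-estimation)."""
    if present_in_plot < 1:
        raise InputError("present_in_plot must be >= 1")
    return integer_percent(corrected_estimate, present_in_plot)


def summarize(
    result: DelimitationResult,
    present_in_plot: Optional[int],
    species_labels: Optional[Mapping[str, str]] = None,
) -> AccuracySummary:
    """Assemble the full summary row; label-dependent fields stay ``None``
    in unknown-flora mode."""
    disc = score_discrimination(result.clusters, species_labels) if species_labels else None
    est_pct = (
        score_estimation(result.corrected_estimate, present_in_plot)
        if present_in_plot
        else None
    )
    return AccuracySummary(
        species_resolved=disc.species_resolved if disc else None,
        not_resolved=disc.not_resolved if disc else None,
        estimated_from_data=result.richness_estimate,
        present_in_alignment=disc.present_in_alignment if disc else None,
        present_in_plot=present_in_plot,
        discrimination_accuracy=disc.discrimination_accuracy if disc else None,
        estimation_accuracy=est_pct,
        discrimination_exact=disc.discrimination_exact if disc else None,
        estimation_exact=(
            100.0 * result.corrected_estimate / present_in_plot
            if present_in_plot
            else None
        ),
    )
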