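"""Synthetic plot-survey generator with full ground truth.

Generates a birth-death (pure-birth, depth-normalized) species tree, evolves
per-locus sequences down it under a TN93 model, adds star-shaped
intraspecific variation per stem, optionally plants short reverse-complement
inversions and species-level indel polymorphism at designated loci, and then
applies per-locus amplification failures (optionally lineage-specific) and
contamination ("amplification error") events.  A fixed seed makes the whole
survey byte-for-byte reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.linalg import expm

from .errors import InputError
from .io_formats import (
    STATUS_ERROR,
    STATUS_FAIL,
    STATUS_OK,
    LocusAlignment,
    SampleRecord,
    write_fasta,
    write_metadata,
)
from .multilocus import reverse_complement
from .njtree import BarcodeTree, Node

_BASES = np.array(list("ACGT"), dtype="U1")


@dataclass(frozen=True)
class LocusSpec:
    """Per-locus simulation settings (lengths default to the three plastid
    barcode targets: 550, 850 and ~450 bp)."""

    locus_id: str
    length: int
    failure_prob: float = 0.0
    lineage_failure_prob: float = 0.0  # elevated failure inside one random clade
    inversion_prob: float = 0.0  # per-stem chance of carrying the inverted state
    inversion_length: int = 6
    indel_prob: float = 0.0  # per-species chance of a deletion polymorphism


DEFAULT_LOCI = (
    LocusSpec("rbcLa", 550),
    LocusSpec("matK", 850, failure_prob=0.15, lineage_failure_prob=0.8),
    LocusSpec("trnH-psbA", 450, inversion_prob=0.05, indel_prob=0.15),
)


@dataclass(frozen=True)
class SurveyConfig:
    plot_id: str = "plot1"
    n_species: int = 30
    mean_stems_per_species: float = 3.0
    loci: tuple[LocusSpec, ...] = DEFAULT_LOCI
    tree_depth: float = 0.15  # expected root-to-tip divergence, subs/site
    # within/between divergence ratio; the default keeps most conspecific
    # stems identical (occasional private mutations), the regime the
    # zero-distance delimitation is designed for
    intraspecific_fraction: float = 0.001
    contamination_prob: float = 0.0
    #: smallest allowed species split height as a fraction of tree_depth;
    #: > 0 rejection-samples the species tree so no two species are nearly
    #: indistinguishable (interspecific >> intraspecific scenarios)
    min_split_fraction: float = 0.0
    kappa1: float = 2.0
    kappa2: float = 2.0
    pi: tuple[float, float, float, float] = (0.3, 0.2, 0.2, 0.3)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise InputError("n_species must be >= 2")
        probs = [self.contamination_prob, self.intraspecific_fraction]
        for spec in self.loci:
            probs += [spec.failure_prob, spec.lineage_failure_prob,
                      spec.inversion_prob, spec.indel_prob]
        if any(p < 0 or p > 1 for p in probs):
            raise InputError("probabilities must lie in [0, 1]")
        if abs(sum(self.pi) - 1.0) > 1e-9:
            raise InputError("pi must sum to 1")


@dataclass(frozen=True)
class PlantedInversion:
    locus_id: str
    start: int
    end: int
    samples: tuple[str, ...]


@dataclass(frozen=True)
class PlantedIndel:
    locus_id: str
    start: int
    end: int
    species: str


@dataclass(frozen=True)
class SurveyTruth:
    species_of: dict[str, str]
    statuses: dict[str, dict[str, str]]  # sample -> locus -> status
    inversions: tuple[PlantedInversion, ...]
    indels: tuple[PlantedIndel, ...]
    error_samples: dict[str, tuple[str, ...]]  # locus -> contaminated samples
    n_species: int

    def n_errors(self, locus_ids: tuple[str, ...]) -> int:
        """Number of samples carrying a contaminant at any of the given loci."""
        flagged = set()
        for locus in locus_ids:
            flagged.update(self.error_samples.get(locus, ()))
        return len(flagged)


@dataclass(frozen=True)
class Survey:
    config: SurveyConfig
    species_tree: BarcodeTree
    alignments: dict[str, LocusAlignment]
    records: list[SampleRecord]
    truth: SurveyTruth


def simulate_species_tree(
    n_species: int, rng: np.random.Generator, depth: float = 0.15
) -> BarcodeTree:
    """Pure-birth ultrametric species tree rescaled to root-to-tip ``depth``."""
    if n_species < 2:
        raise InputError("n_species must be >= 2")
    # start from the root split so every tip sits exactly `depth` below the root
    root = Node()
    active = []
    birth = {}
    for _ in range(2):
        child = Node()
        birth[id(child)] = 0.0
        root.add_child(child)
        active.append(child)
    t = 0.0
    while len(active) < n_species:
        t += rng.exponential(1.0 / len(active))
        parent = active.pop(int(rng.integers(len(active))))
        parent.length = t - birth[id(parent)]
        for _ in range(2):
            child = Node()
            birth[id(child)] = t
            parent.add_child(child)
            active.append(child)
    t += rng.exponential(1.0 / len(active))
    width = len(str(n_species))
    for k, tip in enumerate(active, start=1):
        tip.name = f"sp{k:0{width}d}"
        tip.length = t - birth[id(tip)]
    scale = depth / t if t > 0 else 0.0
    tree = BarcodeTree(root)
    for node in tree.preorder():
        if node.length is not None:
            node.length *= scale
    root.length = None
    return tree


def _min_split_height(tree: BarcodeTree) -> float:
    """Height above the tips of the shallowest internal node."""
    best = float("inf")

    def height(node: Node) -> float:
        nonlocal best
        if node.is_tip:
            return 0.0
        value = max(height(c) + (c.length or 0.0) for c in node.children)
        best = min(best, value)
        return value

    height(tree.root)
    return best


def tn93_rate_matrix(pi: np.ndarray, kappa1: float, kappa2: float) -> np.ndarray:
    """TN93 generator normalized to one expected substitution per unit length."""
    Q = np.zeros((4, 4))
    for a in range(4):
        for b in range(4):
            if a == b:
                continue
            rate = pi[b]
            if {a, b} == {0, 2}:
                rate *= kappa1
            elif {a, b} == {1, 3}:
                rate *= kappa2
            Q[a, b] = rate
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -float(np.dot(pi, np.diag(Q)))
    return Q / mu


def _mutate(seq: np.ndarray, P: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    u = rng.random(seq.shape[0])
    cum = np.cumsum(P, axis=1)
    out = np.argmax(u[:, None] < cum[seq], axis=1)
    return out.astype(np.int8)


def evolve_sequences(
    tree: BarcodeTree, config: SurveyConfig, rng: np.random.Generator
) -> tuple[dict[str, dict[str, np.ndarray]], dict[str, np.ndarray]]:
    """Evolve one sequence per species and locus down the species tree.

    Returns ``(per_locus_species_sequences, per_locus_root_sequences)``; the
    roots are kept so contaminants can later be drawn from a lineage well
    outside the surveyed clade.
    """
    pi = np.asarray(config.pi)
    Q = tn93_rate_matrix(pi, config.kappa1, config.kappa2)
    result: dict[str, dict[str, np.ndarray]] = {}
    roots: dict[str, np.ndarray] = {}
    for spec in config.loci:
        root_seq = rng.choice(4, size=spec.length, p=pi).astype(np.int8)
        roots[spec.locus_id] = root_seq
        per_species: dict[str, np.ndarray] = {}

        def walk(node: Node, seq: np.ndarray) -> None:
            if node.length:
                seq = _mutate(seq, expm(Q * node.length), rng)
            if node.is_tip:
                per_species[node.name] = seq
            else:
                for child in node.children:
                    walk(child, seq)

        walk(tree.root, root_seq)
        result[spec.locus_id] = per_species
    return result, roots


def _codes_to_str(seq: np.ndarray) -> str:
    return "".join(_BASES[seq])


def _clade_species(tree: BarcodeTree, rng: np.random.Generator) -> frozenset[str]:
    """A random internal clade covering between 2 species and half the tree."""
    n = len(tree.tip_set)
    sides = [s for _, s in tree.edges() if 2 <= len(s) <= max(2, n // 2)]
    if not sides:
        return frozenset()
    sides.sort(key=lambda s: (len(s), min(s)))
    return sides[int(rng.integers(len(sides)))]


def simulate_survey(config: SurveyConfig) -> Survey:
    """Full survey generation; see the module docstring for the stages."""
    rng = np.random.default_rng(config.seed)
    tree = simulate_species_tree(config.n_species, rng, config.tree_depth)
    floor = config.min_split_fraction * config.tree_depth
    tries = 0
    while floor > 0 and _min_split_height(tree) < floor:
        tries += 1
        if tries > 1000:
            raise InputError("min_split_fraction too strict; no tree accepted")
        tree = simulate_species_tree(config.n_species, rng, config.tree_depth)
    species = tree.tips()
    species_seqs, root_seqs = evolve_sequences(tree, config, rng)

    # stems per species: geometric (>= 1) with the configured mean
    p = min(1.0, 1.0 / max(config.mean_stems_per_species, 1.0))
    stem_counts = {sp: int(rng.geometric(p)) for sp in species}
    samples: list[tuple[str, str]] = []  # (sample_id, species)
    counter = 1
    for sp in species:
        for _ in range(stem_counts[sp]):
            samples.append((f"{config.plot_id}_s{counter:03d}", sp))
            counter += 1

    pi = np.asarray(config.pi)
    Q = tn93_rate_matrix(pi, config.kappa1, config.kappa2)
    intra_t = config.intraspecific_fraction * config.tree_depth
    P_intra = expm(Q * intra_t) if intra_t > 0 else None

    # per-stem sequences with intraspecific variation
    stem_seqs: dict[str, dict[str, np.ndarray]] = {}
    for spec in config.loci:
        per_locus = {}
        for sid, sp in samples:
            base = species_seqs[spec.locus_id][sp]
            per_locus[sid] = _mutate(base, P_intra, rng) if P_intra is not None else base
        stem_seqs[spec.locus_id] = per_locus

    # planted inversions and indel polymorphisms (string level)
    stem_rows: dict[str, dict[str, str]] = {
        spec.locus_id: {sid: _codes_to_str(seq) for sid, seq in stem_seqs[spec.locus_id].items()}
        for spec in config.loci
    }
    inversions: list[PlantedInversion] = []
    indels: list[PlantedIndel] = []
    for spec in config.loci:
        rows = stem_rows[spec.locus_id]
        if spec.inversion_prob > 0 and spec.length > spec.inversion_length + 8:
            start = int(rng.integers(4, spec.length - spec.inversion_length - 4))
            end = start + spec.inversion_length
            carriers = [sid for sid, _ in samples if rng.random() < spec.inversion_prob]
            for sid in carriers:
                row = rows[sid]
                rows[sid] = row[:start] + reverse_complement(row[start:end]) + row[end:]
            if carriers:
                inversions.append(
                    PlantedInversion(spec.locus_id, start, end, tuple(carriers))
                )
        if spec.indel_prob > 0:
            for sp in species:
                if rng.random() < spec.indel_prob:
                    length = int(rng.integers(3, 10))
                    start = int(rng.integers(1, spec.length - length - 1))
                    end = start + length
                    for sid, owner in samples:
                        if owner == sp:
                            row = rows[sid]
                            rows[sid] = row[:start] + "-" * length + row[end:]
                    indels.append(PlantedIndel(spec.locus_id, start, end, sp))

    return _apply_failures_and_errors(
        config, tree, samples, stem_rows, root_seqs, inversions, indels, rng
    )


def _apply_failures_and_errors(
    config: SurveyConfig,
    tree: BarcodeTree,
    samples: list[tuple[str, str]],
    stem_rows: dict[str, dict[str, str]],
    root_seqs: dict[str, np.ndarray],
    inversions: list[PlantedInversion],
    indels: list[PlantedIndel],
    rng: np.random.Generator,
) -> Survey:
    """Sample per-locus statuses, substitute contaminant sequences, and
    assemble alignments / metadata / truth."""
    statuses: dict[str, dict[str, str]] = {sid: {} for sid, _ in samples}
    error_samples: dict[str, list[str]] = {}
    alignments: dict[str, LocusAlignment] = {}
    pi = np.asarray(config.pi)
    Q = tn93_rate_matrix(pi, config.kappa1, config.kappa2)
    # contaminants sit on a lineage 3x the tree depth away from the root:
    # clearly outside the surveyed clade yet not so divergent that the
    # distance transform saturates
    P_cont = expm(Q * 3.0 * config.tree_depth)

    for spec in config.loci:
        hard_clade = (
            _clade_species(tree, rng) if spec.lineage_failure_prob > 0 else frozenset()
        )
        kept_ids: list[str] = []
        kept_rows: list[str] = []
        errs: list[str] = []
        for sid, sp in samples:
            prob = (
                spec.lineage_failure_prob if sp in hard_clade else spec.failure_prob
            )
            if rng.random() < prob:
                statuses[sid][spec.locus_id] = STATUS_FAIL
                continue
            if config.contamination_prob > 0 and rng.random() < config.contamination_prob:
                # contaminant: evolved independently per event, unique w.h.p.
                contaminant = _mutate(root_seqs[spec.locus_id], P_cont, rng)
                row = _codes_to_str(contaminant)
                statuses[sid][spec.locus_id] = STATUS_ERROR
                errs.append(sid)
            else:
                row = stem_rows[spec.locus_id][sid]
                statuses[sid][spec.locus_id] = STATUS_OK
            kept_ids.append(sid)
            kept_rows.append(row)
        error_samples[spec.locus_id] = errs
        alignments[spec.locus_id] = LocusAlignment(
            locus_id=spec.locus_id,
            sample_ids=tuple(kept_ids),
            rows=tuple(kept_rows),
        )

    records = [
        SampleRecord(
            sample_id=sid,
            plot_id=config.plot_id,
            species_label=sp,
            locus_status=dict(statuses[sid]),
        )
        for sid, sp in samples
    ]
    truth = SurveyTruth(
        species_of={sid: sp for sid, sp in samples},
        statuses=statuses,
        inversions=tuple(inversions),
        indels=tuple(indels),
        error_samples={k: tuple(v) for k, v in error_samples.items()},
        n_species=config.n_species,
    )
    return Survey(
        config=config,
        species_tree=tree,
        alignments=alignments,
        records=records,
        truth=truth,
    )


def write_survey(survey: Survey, outdir: str | Path) -> dict[str, Path]:
    """Emit the survey as per-locus FASTA files plus a metadata CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for locus_id, aln in survey.alignments.items():
        path = outdir / f"{locus_id}.fasta"
        write_fasta(aln, path)
        paths[locus_id] = path
    meta = outdir / "metadata.csv"
    write_metadata(survey.records, meta)
    paths["metadata"] = meta
    return paths
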