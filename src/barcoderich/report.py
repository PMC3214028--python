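"""End-to-end survey orchestration and summary-table reporting.

For every requested locus (or locus combination) and plot this runs:
distances -> NJ + bootstrap -> zero-distance delimitation -> accuracy scoring
(known-flora mode only) -> PD, writing one newick per analysis, a TSV summary
with one row per analysis, and a JSON run manifest.  A failure in one
analysis is recorded and does not abort the others.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from . import __version__
from .delimitation import (
    richness_estimate,
    summarize,
    zero_distance_clusters,
)
from .distances import distance_matrix
from .diversity import faith_pd
from .errors import BarcodeSurveyError
from .io_formats import (
    STATUS_ERROR,
    STATUS_OK,
    LocusAlignment,
    SampleRecord,
    read_fasta,
    read_metadata,
    write_newick,
)
from .multilocus import (
    IndelCharacterSet,
    append_indel_characters,
    concatenate,
    detect_and_normalize_inversions,
    simple_indel_coding,
)
from .njtree import bootstrap_supports, nj_build

SUMMARY_COLUMNS = [
    "plot_id",
    "analysis",
    "species_resolved",
    "not_resolved",
    "estimated_from_data",
    "present_in_alignment",
    "present_in_plot",
    "discrimination_accuracy",
    "estimation_accuracy",
    "discrimination_exact",
    "estimation_exact",
    "n_samples",
    "n_sites_retained",
    "n_columns_removed",
    "n_saturated_pairs",
    "n_errors",
    "pd_value",
    "status",
]


@dataclass(frozen=True)
class RunConfig:
    locus_paths: dict[str, str]
    metadata_path: str
    outdir: str
    analyses: tuple[tuple[str, ...], ...] = ()  # default: every single locus
    mode: str = "known-flora"  # or "unknown-flora"
    bootstrap_reps: int = 1000
    seed: int = 0
    n_errors_override: dict[str, int] = field(default_factory=dict)
    present_in_plot: Optional[int] = None
    indel_coding_loci: frozenset[str] = frozenset()
    normalize_inversion_loci: frozenset[str] = frozenset()

    def analysis_plan(self) -> tuple[tuple[str, ...], ...]:
        if self.analyses:
            return self.analyses
        return tuple((locus,) for locus in self.locus_paths)


def _analysis_name(loci: Sequence[str]) -> str:
    return "+".join(loci)


def prepare_analysis_alignment(
    loci: Sequence[str],
    alignments: dict[str, LocusAlignment],
    records: Sequence[SampleRecord],
    indel_coding_loci: frozenset[str] = frozenset(),
    normalize_inversion_loci: frozenset[str] = frozenset(),
) -> tuple[Optional[LocusAlignment], dict[str, str], list[str], list]:
    """Assemble the per-analysis alignment.

    Samples enter iff they yielded a sequence (status ok or error) at every
    locus of the analysis.  Indel characters from coded loci are pooled into
    ``binary_chars``; inversion normalization is applied per locus when
    enabled.  Returns (alignment or None, binary map, error-sample ids, logs).
    """
    logs: list = []
    by_sample = {r.sample_id: r for r in records}
    eligible = [
        r.sample_id
        for r in records
        if all(r.locus_status.get(l) in (STATUS_OK, STATUS_ERROR) for l in loci)
        and all(r.sample_id in alignments[l].sample_ids for l in loci)
    ]
    if not eligible:
        logs.append("empty intersection: no sample has sequences at every locus")
        return None, {}, [], logs
    error_ids = [
        s
        for s in eligible
        if any(by_sample[s].locus_status.get(l) == STATUS_ERROR for l in loci)
    ]
    parts = []
    binary_parts: dict[str, list[str]] = {s: [] for s in eligible}
    for locus in loci:
        aln = alignments[locus].subset(eligible)
        if locus in normalize_inversion_loci:
            aln, events = detect_and_normalize_inversions(aln)
            for ev in events:
                logs.append(
                    f"inversion normalized at {locus}[{ev.start}:{ev.end}] "
                    f"in {len(ev.samples)} sample(s)"
                )
        if locus in indel_coding_loci:
            chars = simple_indel_coding(aln)
            if chars.n_characters:
                logs.append(f"{chars.n_characters} indel character(s) coded at {locus}")
            for s in eligible:
                binary_parts[s].append(chars.states[s])
        parts.append(aln)
    combined = parts[0] if len(parts) == 1 else concatenate(parts)
    binary = {s: "".join(v) for s, v in binary_parts.items() if v}
    if binary:
        combined = append_indel_characters(
            combined, IndelCharacterSet(descriptors=(), states=binary)
        )
    return combined, binary, error_ids, logs


def run_survey(cfg: RunConfig) -> list[dict]:
    """Execute the configured analyses and write all report artifacts."""
    outdir = Path(cfg.outdir)
    (outdir / "trees").mkdir(parents=True, exist_ok=True)
    records = read_metadata(cfg.metadata_path)
    alignments = {
        locus: read_fasta(path, locus, allow_empty=True)
        for locus, path in cfg.locus_paths.items()
    }
    known = cfg.mode == "known-flora" and any(
        r.species_label is not None for r in records
    )
    plots = sorted({r.plot_id for r in records})
    rows: list[dict] = []
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "mode": cfg.mode,
        "bootstrap_reps": cfg.bootstrap_reps,
        "analyses": [],
    }
    for plot in plots:
        plot_records = [r for r in records if r.plot_id == plot]
        if known and cfg.present_in_plot is None:
            present_in_plot = len(
                {r.species_label for r in plot_records if r.species_label}
            )
        else:
            present_in_plot = cfg.present_in_plot
        for loci in cfg.analysis_plan():
            name = _analysis_name(loci)
            row, entry = _run_one(
                cfg, plot, loci, name, alignments, plot_records, known,
                present_in_plot, outdir,
            )
            rows.append(row)
            manifest["analyses"].append(entry)
    _write_summary(rows, outdir / "summary.tsv")
    _write_summary(compare_loci(rows), outdir / "ranking.tsv")
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return rows


def _run_one(cfg, plot, loci, name, alignments, plot_records, known,
             present_in_plot, outdir):
    row = {c: "" for c in SUMMARY_COLUMNS}
    row.update(plot_id=plot, analysis=name, status="ok")
    entry = {"plot_id": plot, "analysis": name, "log": []}
    try:
        aln, binary, error_ids, logs = prepare_analysis_alignment(
            loci, alignments, plot_records,
            cfg.indel_coding_loci, cfg.normalize_inversion_loci,
        )
        entry["log"].extend(logs)
        if aln is None:
            row["status"] = "empty intersection"
            return row, entry
        dmat = distance_matrix(aln)
        tree = nj_build(dmat)
        if cfg.bootstrap_reps > 0:
            tree = bootstrap_supports(aln, tree, cfg.bootstrap_reps, cfg.seed)
        write_newick(tree, outdir / "trees" / f"{plot}_{name.replace('+', '_')}.nwk")
        clusters = zero_distance_clusters(tree, dmat, binary or None)
        n_errors = cfg.n_errors_override.get(
            name, len([e for e in error_ids if e in aln.sample_ids])
        )
        n_errors = min(n_errors, len(clusters))
        result = richness_estimate(clusters, n_errors)
        labels = (
            {r.sample_id: r.species_label for r in plot_records
             if r.sample_id in aln.sample_ids}
            if known
            else None
        )
        summary = summarize(result, present_in_plot, labels)
        pd_value = faith_pd(tree, tree.tip_set).pd_value
        row.update(
            species_resolved=_blank(summary.species_resolved),
            not_resolved=_blank(summary.not_resolved),
            estimated_from_data=summary.estimated_from_data,
            present_in_alignment=_blank(summary.present_in_alignment),
            present_in_plot=_blank(summary.present_in_plot),
            discrimination_accuracy=_blank(summary.discrimination_accuracy),
            estimation_accuracy=_blank(summary.estimation_accuracy),
            discrimination_exact=_fmt(summary.discrimination_exact),
            estimation_exact=_fmt(summary.estimation_exact),
            n_samples=aln.n_samples,
            n_sites_retained=dmat.n_sites,
            n_columns_removed=dmat.n_columns_removed,
            n_saturated_pairs=len(dmat.saturated_pairs),
            n_errors=n_errors,
            pd_value=f"{pd_value:.6f}",
        )
        entry["log"].append(
            f"{dmat.n_columns_removed} column(s) removed by complete deletion"
        )
        if dmat.saturated_pairs:
            entry["log"].append(f"saturated pairs: {list(dmat.saturated_pairs)}")
    except BarcodeSurveyError as exc:
        row["status"] = f"error: {exc}"
        entry["log"].append(f"aborted: {exc}")
    return row, entry


def _blank(value):
    return "" if value is None else value


def _fmt(value):
    return "" if value is None else f"{value:.4f}"


def compare_loci(rows: list[dict]) -> list[dict]:
    """Rank analyses by estimation then discrimination accuracy (descending);
    rows with missing values sink to the bottom; ties keep input order."""

    def key(row):
        def num(v):
            try:
                return float(v)
            except (TypeError, ValueError):
                return float("-inf")

        return (-num(row.get("estimation_accuracy")),
                -num(row.get("discrimination_accuracy")))

    return sorted(rows, key=key)


def _write_summary(rows: list[dict], path: Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=SUMMARY_COLUMNS, delimiter="\t", extrasaction="ignore"
        )
        writer.writeheader()
        writer.writerows(rows)
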