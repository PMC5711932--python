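"""End-to-end orchestration: simulate -> screen -> summarize -> report.

Holds the run configuration (every numeric threshold of both screens plus
species roles and the RNG seed), applies the expression and sequence screens
over whole datasets, evaluates confusion matrices against planted truth when
available, and renders a human-readable text report. Every output directory
receives the resolved configuration for provenance.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from . import core_io, diel_screen, seq_convergence
from .core_io import DielMatrix, GeneTree, MSA, OrthologGroup, TimeWindowScheme
from .diel_screen import (
    ExpressionConvergenceCall,
    ExpressionThresholds,
    TriangleEdge,
    WindowEnrichment,
)
from .seq_convergence import SequenceConvergenceCall
from .synthetic_data import DEFAULT_ROLES, SimTruth

__all__ = [
    "RunConfig",
    "ScreenSummary",
    "run_expression_screen",
    "run_sequence_screen",
    "report",
]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All tunable thresholds of both screens, with the published defaults."""

    r_high: float = 0.8
    r_low: float = 0.5
    fdr: float = 0.01
    max_cam_shift: float = 3.0
    min_c3_shift: float = 6.0
    min_fpkm: float = 0.01
    min_timepoints: int = 6
    inflation: float = 5.0
    evalue_cutoff: float = 1e-5
    poly_degree: int = 3
    shift_grid: float = 0.5
    species_kf: str = "Kf"
    species_ac: str = "Ac"
    species_at: str = "At"
    roles: dict = field(default_factory=lambda: dict(DEFAULT_ROLES))
    seed: int = 0

    def __post_init__(self) -> None:
        if not (-1 <= self.r_low <= self.r_high <= 1):
            raise ValueError("need -1 <= r_low <= r_high <= 1")
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must lie in (0, 1)")
        if self.max_cam_shift < 0 or self.min_c3_shift < 0:
            raise ValueError("shift bounds must be non-negative")
        if self.inflation <= 1:
            raise ValueError("MCL inflation must exceed 1")

    def expression_thresholds(self) -> ExpressionThresholds:
        return ExpressionThresholds(
            r_high=self.r_high,
            r_low=self.r_low,
            fdr=self.fdr,
            max_cam_shift=self.max_cam_shift,
            min_c3_shift=self.min_c3_shift,
            shift_grid=self.shift_grid,
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


@dataclass
class ScreenSummary:
    """Counts per criterion plus confusion-matrix rates against planted truth."""

    n_groups_screened: int = 0
    n_evaluable: int = 0
    n_criterion1: int = 0
    n_criterion2: int = 0
    n_criterion3: int = 0
    n_convergent: int = 0
    sensitivity: float = float("nan")
    specificity: float = float("nan")
    false_positive_rate: float = float("nan")
    fdr_observed: float = float("nan")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _truth_rates(
    summary: ScreenSummary, called: set[str], positives: set[str], universe: set[str]
) -> None:
    negatives = universe - positives
    tp = len(called & positives)
    fp = len(called & negatives)
    if positives:
        summary.sensitivity = tp / len(positives)
    if negatives:
        summary.specificity = (len(negatives) - fp) / len(negatives)
        summary.false_positive_rate = fp / len(negatives)
    if called:
        summary.fdr_observed = fp / len(called)


# ---------------------------------------------------------------------------
# Expression screen
# ---------------------------------------------------------------------------


def run_expression_screen(
    matrices: Mapping[str, DielMatrix],
    orthogroups: Sequence[OrthologGroup],
    config: RunConfig | None = None,
    truth: SimTruth | None = None,
) -> tuple[list[ExpressionConvergenceCall], ScreenSummary, list[TriangleEdge]]:
    """Run the full expression arm over three species matrices.

    Stages: low-expression filter per species; interpolation of any
    non-canonical grid onto the 2-h grid; window-contrast tests with
    genome-wide BH adjustment per species; per-ortholog-group three-criterion
    classification of every focal-species gene; triangle-network assembly.
    Deterministic for fixed inputs and config.
    """
    config = config or RunConfig()
    tags = (config.species_kf, config.species_ac, config.species_at)
    for tag in tags:
        if tag not in matrices:
            raise core_io.FormatError(f"expression matrix for species {tag!r} missing")
    scheme = TimeWindowScheme()

    kept: dict[str, set[str]] = {}
    canonical: dict[str, dict] = {}
    enrichments: dict[str, dict] = {}
    for tag in tags:
        matrix = matrices[tag]
        kept[tag] = diel_screen.expression_filter(
            matrix, config.min_fpkm, config.min_timepoints
        )
        logger.info("%s: %d/%d genes pass the expression filter", tag, len(kept[tag]), len(matrix))
        canonical[tag] = {}
        species_enrichments: list[WindowEnrichment] = []
        for gid in sorted(kept[tag]):
            prof = matrix[gid]
            if not prof.on_canonical_grid():
                prof_c = diel_screen.interpolate_to_grid(prof, target_step=2.0)
            else:
                prof_c = prof
            canonical[tag][gid] = prof_c
            species_enrichments.append(diel_screen.window_enrichment_test(prof_c, scheme))
        diel_screen.attach_qvalues(species_enrichments, config.fdr)
        enrichments[tag] = {e.gene_id: e for e in species_enrichments}

    calls: list[ExpressionConvergenceCall] = []
    for group in orthogroups:
        for kf_gene in group.genes(config.species_kf):
            if kf_gene not in canonical[config.species_kf]:
                continue
            calls.append(
                diel_screen.classify_convergent_expression(
                    group,
                    canonical,
                    enrichments,
                    kf_gene,
                    config.expression_thresholds(),
                    species_kf=config.species_kf,
                    species_ac=config.species_ac,
                    species_at=config.species_at,
                )
            )

    summary = ScreenSummary(
        n_groups_screened=len(orthogroups),
        n_evaluable=sum(c.evaluable for c in calls),
        n_criterion1=sum(c.criterion1 for c in calls),
        n_criterion2=sum(c.criterion2 for c in calls),
        n_criterion3=sum(c.criterion3 for c in calls),
        n_convergent=sum(c.convergent for c in calls),
    )
    if truth is not None:
        called = {c.group_id for c in calls if c.convergent}
        positives = truth.convergent_groups()
        universe = set(truth.group_labels)
        _truth_rates(summary, called, positives, universe)
    triangles = diel_screen.build_triangle_network(
        calls, scheme, config.species_kf, config.species_ac, config.species_at
    )
    logger.info(
        "expression screen: %d groups -> %d evaluable -> %d convergent",
        summary.n_groups_screened,
        summary.n_evaluable,
        summary.n_convergent,
    )
    return calls, summary, triangles


# ---------------------------------------------------------------------------
# Sequence screen
# ---------------------------------------------------------------------------


def run_sequence_screen(
    tribes: Mapping[str, tuple[GeneTree, MSA]],
    config: RunConfig | None = None,
    truth: SimTruth | None = None,
    required_species=None,
) -> tuple[list[SequenceConvergenceCall], ScreenSummary]:
    """Run the sequence arm over per-tribe (tree, alignment) pairs."""
    config = config or RunConfig()
    calls = seq_convergence.screen_sequence_convergence(
        tribes, config.roles, required_species=required_species
    )
    summary = ScreenSummary(
        n_groups_screened=len(tribes),
        n_evaluable=len(calls),
        n_criterion1=sum(c.criterion_clade for c in calls),
        n_criterion2=sum(c.criterion_convergent_subs for c in calls),
        n_criterion3=sum(c.criterion_shared_site for c in calls),
        n_convergent=sum(c.convergent for c in calls),
    )
    if truth is not None:
        called = {c.kf_gene for c in calls if c.convergent}
        universe = {c.kf_gene for c in calls}
        _truth_rates(summary, called, truth.planted_genes, universe)
    return calls, summary


# ---------------------------------------------------------------------------
# Persistence and reporting
# ---------------------------------------------------------------------------


def write_screen_outputs(
    out_dir,
    config: RunConfig,
    calls: Sequence,
    summary: ScreenSummary,
    triangles: Sequence[TriangleEdge] | None = None,
    prefix: str = "expression",
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    core_io.write_results(list(calls), out / f"{prefix}_calls.tsv", "tsv")
    with open(out / f"{prefix}_summary.json", "w") as fh:
        json.dump(summary.to_dict(), fh, indent=1)
        fh.write("\n")
    if triangles is not None:
        core_io.write_results(list(triangles), out / "triangle_network.tsv", "tsv")


def _shift_histogram(shifts: Sequence[float]) -> list[str]:
    lines = []
    finite = [s for s in shifts if np.isfinite(s)]
    if not finite:
        return ["  (no shifts recorded)"]
    edges = np.arange(-12, 13, 2)
    hist, _ = np.histogram(finite, bins=edges)
    for lo, hi, n in zip(edges[:-1], edges[1:], hist):
        lines.append(f"  [{lo:+3d},{hi:+3d}) h : {'#' * int(n)} {n}")
    return lines


def report(results_dir, out_path=None) -> str:
    """Render a stable, human-readable summary of a results directory.

    Counts are recomputed from the call tables; the config is echoed for
    provenance. Returns the report text (and writes it when ``out_path``).
    """
    results = Path(results_dir)
    if not results.is_dir():
        raise FileNotFoundError(f"results directory {results} does not exist")
    missing = [
        str(p) for p in [results / "config.yaml"] if not p.exists()
    ]
    if missing:
        raise FileNotFoundError(f"missing inputs: {missing}")
    lines: list[str] = ["# camconverge screen report", ""]
    with open(results / "config.yaml") as fh:
        lines += ["## configuration", "", fh.read().rstrip(), ""]
    for prefix in ("expression", "sequence"):
        calls_path = results / f"{prefix}_calls.tsv"
        if not calls_path.exists():
            continue
        rows = core_io.read_results(calls_path, "tsv")
        lines.append(f"## {prefix} screen ({len(rows)} calls)")
        lines.append("")
        n_conv = sum(1 for r in rows if bool(r.get("convergent")))
        crit_cols = [c for c in (rows[0].keys() if rows else []) if c.startswith("criterion")]
        for c in sorted(crit_cols):
            lines.append(f"  {c}: {sum(1 for r in rows if bool(r[c]))}")
        lines.append(f"  convergent: {n_conv}")
        if prefix == "expression" and rows:
            lines.append("")
            lines.append("  focal-vs-CAM-partner shift histogram:")
            lines += _shift_histogram([r.get("shift_kf_ac", float("nan")) for r in rows])
        lines.append("")
        for r in rows:
            if bool(r.get("convergent")):
                gene = r.get("kf_gene", "?")
                lines.append(f"  CALL {gene}: " + ", ".join(
                    f"{k}={r[k]}" for k in sorted(r) if k not in ("kf_gene",)
                ))
        lines.append("")
    text = "\n".join(lines).rstrip() + "\n"
    if out_path is not None:
        with open(out_path, "w") as fh:
            fh.write(text)
    return text
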