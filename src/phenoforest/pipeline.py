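"""End-to-end orchestration of discovery, targeting and simulation runs.

``run_discover`` executes the full pipeline on a list of samples: grow
the annotation forest of every experimental unit, score and select
markers, standardize annotation boundaries, grow discovery forests,
down-select phenotypes by cross-unit occurrence, and derive the
sample x phenotype count matrix from per-cell annotations.  The thin
command-line interface wraps these functions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation_forest import (
    depth_scores,
    estimate_unit_boundaries,
    grow_annotation_forest,
    select_markers,
)
from .discovery import (
    UNASSIGNED_LABEL,
    annotate_cells,
    annotate_leaf,
    grow_discovery_forest,
    select_leaves,
)
from .io_core import (
    ExperimentDesign,
    ExpressionMatrix,
    MarkerBoundaryMatrix,
    default_boundary_matrix,
)
from .phenotype_matrix import (
    CountMatrix,
    build_count_matrix,
    gcm_elbow_threshold,
    occurrence_counts,
    target_phenotypes,
)
from .standardization import BoundarySpec, standardize_all

__all__ = ["PipelineConfig", "DiscoveryResult", "run_discover", "run_target"]


@dataclass
class PipelineConfig:
    """Tuning parameters; defaults follow the method's published settings."""

    dip_threshold: float = 0.25
    min_node_events: int = 500
    min_leaf: int = 25
    max_depth: int = 3
    max_gates: int = 4
    depth_score_quantile: float = 0.5  # the median
    depth_score_threshold: float = 0.01
    n_trees: int = 100
    occurrence_threshold: int | str = "auto"
    seed: int = 0
    supervised_boundaries: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Plain-text key = value config (unknown keys rejected)."""
        cfg = cls()
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, val = line.partition("=")
            key = key.strip()
            val = val.strip()
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            cur = getattr(cfg, key)
            if key == "occurrence_threshold":
                setattr(cfg, key, val if val == "auto" else int(val))
            elif isinstance(cur, bool):
                setattr(cfg, key, val.lower() in ("1", "true", "yes"))
            elif isinstance(cur, int):
                setattr(cfg, key, int(val))
            elif isinstance(cur, float):
                setattr(cfg, key, float(val))
            else:
                setattr(cfg, key, val)
        return cfg


@dataclass
class DiscoveryResult:
    config: PipelineConfig
    bounds: MarkerBoundaryMatrix
    selected_markers: list
    score_tables: dict  # unit -> DepthScoreTable
    spec: BoundarySpec
    unit_phenotypes: dict  # unit -> sorted list of discovered phenotypes
    occurrence: dict
    threshold: int
    selected_phenotypes: list
    annotations: dict  # sample -> per-cell labels (selected or reserved)
    count_matrix: CountMatrix

    def write_artifacts(self, outdir):
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.bounds.to_frame().to_csv(outdir / "marker_bounds.csv")
        pd.DataFrame(
            {u: t.scores for u, t in self.score_tables.items()}
        ).to_csv(outdir / "depth_scores.csv", index_label="marker")
        self.spec.to_frame().to_csv(outdir / "boundaries.csv", index=False)
        self.count_matrix.to_csv(outdir / "count_matrix.csv")
        for sample, ann in self.annotations.items():
            pd.Series(ann).to_csv(
                outdir / f"annotations_{sample}.csv", index=False,
                header=["phenotype"],
            )
        manifest = {
            "config": asdict(self.config),
            "selected_markers": self.selected_markers,
            "occurrence_threshold": self.threshold,
            "n_selected_phenotypes": len(self.selected_phenotypes),
            "units": sorted(self.unit_phenotypes),
            "occurrence": self.occurrence,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _concatenate_unit(unit_id, members) -> ExpressionMatrix:
    if len(members) == 1:
        em = members[0]
        return ExpressionMatrix(
            sample_id=em.sample_id, markers=em.markers, values=em.values,
            unit_id=unit_id,
        )
    markers = members[0].markers
    values = np.vstack([m.values for m in members])
    return ExpressionMatrix(
        sample_id=unit_id, markers=markers, values=values, unit_id=unit_id
    )


def run_discover(samples, design: ExperimentDesign,
                 config: PipelineConfig | None = None,
                 bounds: MarkerBoundaryMatrix | None = None,
                 log=lambda msg: None) -> DiscoveryResult:
    """Full discovery pipeline over a list of samples."""
    config = config or PipelineConfig()
    if not samples:
        raise ValueError("no samples supplied")
    by_id = {s.sample_id: s for s in samples}
    missing = [s for s in design.samples if s not in by_id]
    if missing:
        raise ValueError(f"design samples missing from input: {missing}")
    active = design.active_markers or list(samples[0].markers)
    for s in samples:
        s.unit_id = design.unit_of(s.sample_id)
    if bounds is None:
        bounds = default_boundary_matrix(samples)
    bounds = MarkerBoundaryMatrix({m: bounds[m] for m in active})

    units = {}
    for unit in design.units:
        members = [by_id[s] for s in design.samples_in_unit(unit)]
        units[unit] = _concatenate_unit(unit, members)

    forests = {}
    score_tables = {}
    for unit, em in units.items():
        forests[unit] = grow_annotation_forest(
            em, active, bounds,
            dip_threshold=config.dip_threshold,
            min_events=config.min_node_events,
            max_depth=config.max_depth,
            max_gates=config.max_gates,
        )
        score_tables[unit] = depth_scores(forests[unit])
        log(f"unit {unit}: annotation forest grown "
            f"({len(forests[unit].nodes)} gatings)")

    selected = select_markers(
        score_tables.values(),
        quantile=config.depth_score_quantile,
        threshold=config.depth_score_threshold,
    )
    if not selected:
        raise ValueError(
            "no marker exceeds the depth-score threshold in enough units"
        )
    log(f"selected markers: {selected}")

    unit_boundaries = {
        m: {
            unit: (
                ub.locations
                if (ub := estimate_unit_boundaries(forests[unit], m))
                is not None
                else None
            )
            for unit in units
        }
        for m in selected
    }
    hierarchy = {u: design.hierarchy_of(u) for u in units}
    spec = standardize_all(
        unit_boundaries, hierarchy=hierarchy,
        overrides=config.supervised_boundaries,
    )
    log("boundaries standardized")

    unit_phenotypes = {}
    for ui, (unit, em) in enumerate(units.items()):
        unit_seed = (config.seed * 100_003 + ui) % (2**31)
        leaves = grow_discovery_forest(
            em, selected, bounds, n_trees=config.n_trees, seed=unit_seed,
            min_leaf=config.min_leaf,
        )
        chosen = select_leaves(leaves, em.n_cells)
        unit_phenotypes[unit] = sorted(
            {annotate_leaf(em, leaf, spec, selected) for leaf in chosen}
        )
        log(f"unit {unit}: {len(chosen)} leaves, "
            f"{len(unit_phenotypes[unit])} phenotypes")

    occ = occurrence_counts(unit_phenotypes)
    if config.occurrence_threshold == "auto":
        threshold = gcm_elbow_threshold(occ, n_samples=len(samples))
    else:
        threshold = int(config.occurrence_threshold)
    selected_phenos = sorted(p for p, c in occ.items() if c >= threshold)
    log(f"occurrence threshold {threshold}: "
        f"{len(selected_phenos)} of {len(occ)} phenotypes kept")

    annotations = {}
    keep = set(selected_phenos)
    for s in samples:
        ann = annotate_cells(s, spec, selected)
        ann = np.where(np.isin(ann.astype(str), list(keep)), ann,
                       UNASSIGNED_LABEL)
        annotations[s.sample_id] = ann
    counts = build_count_matrix(
        annotations, selected_phenos, occurrence=occ, threshold=threshold
    )
    return DiscoveryResult(
        config=config, bounds=bounds, selected_markers=selected,
        score_tables=score_tables, spec=spec,
        unit_phenotypes=unit_phenotypes, occurrence=occ,
        threshold=threshold, selected_phenotypes=selected_phenos,
        annotations=annotations, count_matrix=counts,
    )


def run_target(samples, spec: BoundarySpec, targets) -> CountMatrix:
    """Targeted extraction of pre-specified phenotypes on (new) samples."""
    return target_phenotypes(samples, spec, targets)
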