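"""End-to-end pipelines: simulate/load -> binarize -> Venn -> CF -> cohort.

`RunConfig` describes one analysis run — either a list of image files or a
simulation — together with thresholding, the regions to evaluate, the
reference region of the ANOVA, and output locations.  All randomness flows
from the single config seed.  `run_cell` and `run_cohort` are exactly the
composition of the module-level API, so CLI and library results coincide.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .binarize import BinaryMask, binarize
from .cohort import CellResult, CohortResult, analyze_cohort_cells
from .errors import ParameterError
from .simulate import SimulationConfig, simulate_cohort
from .stack import ChannelStack, load_stack
from .venn import (
    RegionSpec,
    colocalization_factor,
    default_regions,
    partition_areas,
    venn_summary,
)

__all__ = ["RunConfig", "run_cell", "run_cohort", "null_calibrate"]

log = logging.getLogger("vennloc")

#: Column order of the per-cell CSV, fixed for diffable regression output.
CELL_CSV_COLUMNS = [
    "cell_id",
    "region",
    "include",
    "exclude",
    "actual_area_px",
    "roi_area_px",
    "actual_fraction",
    "expected_fraction",
    "cf",
    "convention",
    "thresholds",
]


@dataclass
class RunConfig:
    """Configuration of one analysis run.

    Exactly one of ``images`` (list of ``{"path": ..., "cell_id": ...,
    "roi": ...}`` entries) or ``simulation`` must be given.
    """

    channels: tuple[str, ...] = ("ACC1", "COP1", "KIF12")
    images: list[dict] | None = None
    simulation: SimulationConfig | None = None
    n_cells: int = 5
    threshold_method: str = "otsu"
    threshold_params: Mapping[str, float] | float | None = None
    convention: str = "exclusion_aware"
    regions: list[RegionSpec] | None = None
    reference: RegionSpec | None = None
    alpha: float = 0.05
    output_dir: str | Path | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.images is None) == (self.simulation is None):
            raise ParameterError(
                "exactly one of 'images' and 'simulation' must be provided"
            )
        if self.simulation is not None:
            self.channels = tuple(self.simulation.channels)
        if self.regions is None:
            self.regions = default_regions(self.channels)
        if self.reference is None:
            self.reference = _default_reference(self.channels)
        if self.reference not in self.regions:
            raise ParameterError(
                f"reference region {self.reference.label!r} is not among the "
                f"evaluated regions {[r.label for r in self.regions]}"
            )
        for region in self.regions:
            region.validate_channels(self.channels)

    # -- YAML -------------------------------------------------------------
    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        """Build a RunConfig from a YAML document (see README for the schema)."""
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, dict):
            raise ParameterError(f"{path}: YAML config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ParameterError(f"{path}: unknown config keys {sorted(unknown)}")
        if "simulation" in doc and doc["simulation"] is not None:
            doc["simulation"] = SimulationConfig(**doc["simulation"])
        if "regions" in doc and doc["regions"] is not None:
            doc["regions"] = [
                RegionSpec(frozenset(r.get("include", [])), frozenset(r.get("exclude", [])))
                for r in doc["regions"]
            ]
        if "reference" in doc and doc["reference"] is not None:
            r = doc["reference"]
            doc["reference"] = RegionSpec(
                frozenset(r.get("include", [])), frozenset(r.get("exclude", []))
            )
        if "channels" in doc and doc["channels"] is not None:
            doc["channels"] = tuple(doc["channels"])
        return cls(**doc)


def _default_reference(channels: Sequence[str]) -> RegionSpec:
    """Pair of the first two channels excluding the third.

    With the default channel order (ACC1, COP1, KIF12) this is the
    ACC1 & COP1 without KIF12 region, the reference of the scaffold ANOVA.
    """
    if len(channels) < 3:
        raise ParameterError("default reference needs >= 3 channels")
    return RegionSpec(frozenset(channels[:2]), frozenset({channels[2]}))


def _cell_stacks(config: RunConfig) -> list[ChannelStack]:
    if config.simulation is not None:
        cells = simulate_cohort(config.simulation, config.n_cells, config.seed)
        return [stack for stack, _truth in cells]
    stacks = []
    for i, entry in enumerate(config.images):
        stack = load_stack(entry["path"], config.channels, entry.get("roi"))
        stack.cell_id = str(entry.get("cell_id", f"cell{i + 1:03d}"))
        stacks.append(stack)
    return stacks


def run_cell(config: RunConfig, cell: ChannelStack | Mapping[str, Any]) -> CellResult:
    """Analyze one cell: binarize, partition, CF for every configured region.

    ``cell`` is a ready :class:`ChannelStack` or an image-entry mapping with
    ``path`` and optional ``roi``/``cell_id`` keys.
    """
    if isinstance(cell, Mapping):
        stack = load_stack(cell["path"], config.channels, cell.get("roi"))
        stack.cell_id = str(cell.get("cell_id", Path(cell["path"]).stem))
    else:
        stack = cell
    try:
        masks = binarize(stack, config.threshold_method, config.threshold_params)
        partition = partition_areas(masks, stack.roi_mask())
        log.info(
            "cell %s: thresholds %s, fractions %s",
            stack.cell_id,
            {m.channel: round(m.threshold_used, 3) for m in masks},
            {c: round(f, 4) for c, f in partition.channel_fractions.items()},
        )
        records = [
            colocalization_factor(partition, region, config.convention, stack.cell_id)
            for region in config.regions
        ]
    except Exception as exc:
        raise type(exc)(f"[cell {stack.cell_id}] {exc}") from exc
    result = CellResult(cell_id=stack.cell_id, cf_records=records)
    result.masks = masks  # kept for reporting (thresholds, Venn summary)
    result.partition = partition
    return result


def _cell_frame(results: list[CellResult]) -> pd.DataFrame:
    rows = []
    for res in results:
        thresholds = json.dumps(
            {m.channel: m.threshold_used for m in getattr(res, "masks", [])}
        )
        for rec in res.cf_records:
            rows.append(
                {
                    "cell_id": res.cell_id,
                    "region": rec.region.label,
                    "include": "&".join(sorted(rec.region.include)),
                    "exclude": "&".join(sorted(rec.region.exclude)),
                    "actual_area_px": int(round(rec.actual_fraction * res.partition.roi_area)),
                    "roi_area_px": res.partition.roi_area,
                    "actual_fraction": rec.actual_fraction,
                    "expected_fraction": rec.expected_fraction,
                    "cf": rec.cf,
                    "convention": rec.convention,
                    "thresholds": thresholds,
                }
            )
    return pd.DataFrame(rows, columns=CELL_CSV_COLUMNS)


def _cohort_json(cohort: CohortResult) -> dict:
    call = cohort.scaffold_call
    return {
        "convention": cohort.convention,
        "summaries": cohort.summaries.to_dict(orient="records"),
        "anova": cohort.anova,
        "scaffold_call": None
        if call is None
        else {
            "scaffold": call.scaffold,
            "significant": call.significant,
            "tie": call.tie,
            "alpha": call.alpha,
            "rationale": call.rationale,
            "comparison_pvalues": call.comparison_pvalues,
        },
    }


def run_cohort(config: RunConfig, write: bool = True) -> CohortResult:
    """Analyze a cohort of cells and (optionally) write the report files.

    Writes, under ``config.output_dir``: ``cells.csv`` (one row per cell and
    region, full double precision), ``cohort.json`` (summaries, ANOVA,
    scaffold call) and ``venn_summary.csv`` (per-cell exclusive-region
    percentages).
    """
    stacks = _cell_stacks(config)
    if len(stacks) < 2:
        raise ParameterError("cohort analysis needs >= 2 cells")
    results = [run_cell(config, stack) for stack in stacks]
    cohort = analyze_cohort_cells(
        results,
        config.regions,
        config.reference,
        alpha=config.alpha,
        convention=config.convention,
    )
    if write and config.output_dir is not None:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        _cell_frame(results).to_csv(outdir / "cells.csv", index=False, float_format="%.17g")
        venn_frames = []
        for res in results:
            frame = venn_summary(res.partition)
            frame.insert(0, "cell_id", res.cell_id)
            venn_frames.append(frame)
        pd.concat(venn_frames, ignore_index=True).to_csv(
            outdir / "venn_summary.csv", index=False, float_format="%.17g"
        )
        with open(outdir / "cohort.json", "w") as fh:
            json.dump(_cohort_json(cohort), fh, indent=2)
        log.info("wrote cells.csv, venn_summary.csv, cohort.json to %s", outdir)
    return cohort


def null_calibrate(
    simulation: SimulationConfig | None = None,
    n_cells: int = 200,
    seed: int = 0,
    convention: str = "exclusion_aware",
) -> pd.DataFrame:
    """Run the CF = 1 control: a cohort with fully independent channels.

    Takes ``simulation`` (default: the standard geometry), forces the tether
    machinery off, analyzes ``n_cells`` cells, and returns the per-region
    mean/SEM CF table.  Under independent placement every region's mean CF
    converges to 1.
    """
    base = simulation if simulation is not None else SimulationConfig()
    null_sim = dataclasses.replace(base, scaffold_channel=None, tether_fraction=0.0)
    config = RunConfig(
        simulation=null_sim,
        n_cells=n_cells,
        seed=seed,
        convention=convention,
        output_dir=None,
    )
    cohort = run_cohort(config, write=False)
    return cohort.summaries
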