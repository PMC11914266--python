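"""Cross-cell CF statistics, ANOVA against a reference region, scaffold call.

Cells are the replicate unit.  Per-region CFs are aggregated to mean +/- SEM
over the cells in which they are defined; a one-way ANOVA across regions and
per-region comparisons against a reference region (Welch t tests with Holm
familywise correction) reproduce the "ANOVA against the pair-without-scaffold
region" analysis.  The scaffold call itself is purely structural: in a
three-channel experiment, the candidate scaffold is the channel *excluded*
from the exclusive-pair region with the lowest mean CF — if protein K bridges
A and B, the K-containing pair regions are enriched while A&B-without-K is
not — and the call is significant only when both other pair regions beat that
minimum region at the requested alpha.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ParameterError, RegionError
from .venn import CFRecord, RegionSpec

__all__ = [
    "CellResult",
    "CohortResult",
    "ScaffoldCall",
    "aggregate_cells",
    "anova_vs_reference",
    "call_scaffold",
    "analyze_cohort_cells",
]


@dataclass
class CellResult:
    """All CF records of one cell (at minimum the triple and pair regions)."""

    cell_id: str
    cf_records: list[CFRecord]

    def regions(self) -> set[RegionSpec]:
        return {r.region for r in self.cf_records}

    def cf_by_region(self) -> dict[RegionSpec, CFRecord]:
        return {r.region: r for r in self.cf_records}


@dataclass
class ScaffoldCall:
    """Outcome of scaffold inference.

    ``rationale`` is the exclusive-pair regions ordered by ascending mean CF;
    ``scaffold`` is the channel excluded from the minimum region, or None when
    the ordering is tied or not statistically supported (``significant``
    False reports the ordering without a call).
    """

    scaffold: str | None
    rationale: list[tuple[str, float]]
    significant: bool
    tie: bool = False
    alpha: float = 0.05
    comparison_pvalues: dict[str, float] = field(default_factory=dict)


@dataclass
class CohortResult:
    """Per-region summaries, ANOVA vs reference, and the scaffold call."""

    summaries: pd.DataFrame  # region, mean_cf, sem_cf, n, n_undefined
    cf_table: pd.DataFrame  # cells x region labels, NaN where undefined
    regions: list[RegionSpec]
    anova: dict
    scaffold_call: ScaffoldCall | None = None
    convention: str = "exclusion_aware"


def _check_matching_regions(cells: list[CellResult]) -> list[RegionSpec]:
    first = cells[0].regions()
    for cell in cells[1:]:
        if cell.regions() != first:
            diff = sorted(r.label for r in cell.regions() ^ first)
            raise ParameterError(
                f"cell {cell.cell_id!r}: region set differs from first cell; "
                f"symmetric difference: {diff}"
            )
    # stable order: first cell's record order
    return [r.region for r in cells[0].cf_records]


def _cf_table(cells: list[CellResult], regions: list[RegionSpec]) -> pd.DataFrame:
    rows = {}
    for cell in cells:
        by_region = cell.cf_by_region()
        rows[cell.cell_id] = {r.label: by_region[r].cf for r in regions}
    return pd.DataFrame.from_dict(rows, orient="index")[[r.label for r in regions]]


def aggregate_cells(cells: list[CellResult]) -> pd.DataFrame:
    """Mean, SEM and n of each region's CF across cells.

    Undefined CFs (expected fraction 0) are excluded per region and counted in
    ``n_undefined``.  Requires >= 2 cells with identical region sets.
    """
    if len(cells) < 2:
        raise ParameterError("cells: need >= 2 cells (SEM undefined for one cell)")
    regions = _check_matching_regions(cells)
    table = _cf_table(cells, regions)
    rows = []
    for region in regions:
        values = table[region.label].dropna()
        rows.append(
            {
                "region": region.label,
                "mean_cf": float(values.mean()) if len(values) else math.nan,
                "sem_cf": float(values.sem(ddof=1)) if len(values) > 1 else math.nan,
                "n": int(len(values)),
                "n_undefined": int(len(table) - len(values)),
            }
        )
    return pd.DataFrame(rows)


def _welch_pvalue(a: np.ndarray, b: np.ndarray) -> float:
    """Welch two-sided p with exact limits for zero-variance groups."""
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def anova_vs_reference(
    cells: list[CellResult],
    regions: list[RegionSpec],
    reference: RegionSpec,
    alpha: float = 0.05,
) -> dict:
    """One-way ANOVA across regions plus Holm-corrected comparisons vs reference.

    Regions are the groups and cells the replicates.  Each non-reference
    region is compared against the reference with a Welch t test; the
    familywise correction (Holm) and every statistic are recorded in the
    returned dict.  Degenerate data take their analytic limits: all values
    identical => F = 0, p = 1; zero within-group variance with distinct group
    means => p = 0.
    """
    if reference not in regions:
        raise ParameterError(f"reference region {reference.label!r} not in regions")
    if len(cells) < 2:
        raise ParameterError("cells: need >= 2 cells")
    _check_matching_regions(cells)
    table = _cf_table(cells, regions)

    groups = [table[r.label].dropna().to_numpy() for r in regions]
    for r, g in zip(regions, groups):
        if len(g) < 2:
            raise ParameterError(f"region {r.label!r}: fewer than 2 defined CFs")

    flat = np.concatenate(groups)
    if np.ptp(flat) == 0.0:
        f_stat, p_value = 0.0, 1.0
    elif all(np.var(g) == 0.0 for g in groups):
        f_stat, p_value = math.inf, 0.0
    else:
        res = stats.f_oneway(*groups)
        f_stat, p_value = float(res.statistic), float(res.pvalue)

    ref_values = table[reference.label].dropna().to_numpy()
    others = [r for r in regions if r != reference]
    raw = [_welch_pvalue(table[r.label].dropna().to_numpy(), ref_values) for r in others]
    if raw:
        reject, adjusted, _, _ = multipletests(raw, alpha=alpha, method="holm")
    else:
        reject, adjusted = np.array([], dtype=bool), np.array([])

    comparisons = [
        {
            "region": r.label,
            "p_raw": float(p),
            "p_adjusted": float(pa),
            "reject": bool(rj),
        }
        for r, p, pa, rj in zip(others, raw, adjusted, reject)
    ]
    return {
        "F": f_stat,
        "p_value": p_value,
        "alpha": alpha,
        "reference": reference.label,
        "comparison_test": "welch_t",
        "correction": "holm",
        "comparisons": comparisons,
    }


def _pair_regions(regions: list[RegionSpec]) -> list[RegionSpec]:
    pairs = [r for r in regions if len(r.include) == 2 and len(r.exclude) == 1]
    if len(pairs) != 3:
        raise RegionError(
            "scaffold inference needs exactly the three exclusive-pair regions "
            f"of a 3-channel analysis; found {[r.label for r in pairs]}"
        )
    channels = set().union(*(r.include | r.exclude for r in pairs))
    if len(channels) != 3 or {next(iter(r.exclude)) for r in pairs} != channels:
        raise RegionError("pair regions do not form a consistent 3-channel triad")
    return pairs


def call_scaffold(
    cohort: CohortResult, alpha: float = 0.05, tie_rtol: float = 1e-9
) -> ScaffoldCall:
    """Infer the scaffold channel from the exclusive-pair CF ordering.

    The candidate is the channel excluded from the pair region with the
    minimum mean CF; the call is significant only when both other pair
    regions reject against that minimum region (Welch t, Holm-corrected) at
    ``alpha``.  Mean CFs whose relative difference is below ``tie_rtol`` are
    treated as tied and yield no call.
    """
    pairs = _pair_regions(cohort.regions)
    means = {}
    for region in pairs:
        row = cohort.summaries.loc[cohort.summaries["region"] == region.label]
        means[region] = float(row["mean_cf"].iloc[0])
    ordering = sorted(means.items(), key=lambda kv: kv[1])
    rationale = [(r.label, m) for r, m in ordering]
    min_region, min_mean = ordering[0]
    runner_mean = ordering[1][1]

    scale = max(abs(min_mean), abs(runner_mean), 1.0)
    if abs(runner_mean - min_mean) <= tie_rtol * scale:
        return ScaffoldCall(
            scaffold=None, rationale=rationale, significant=False, tie=True, alpha=alpha
        )

    candidate = next(iter(min_region.exclude))
    raw = []
    others = [r for r, _ in ordering[1:]]
    ref_values = cohort.cf_table[min_region.label].dropna().to_numpy()
    for region in others:
        values = cohort.cf_table[region.label].dropna().to_numpy()
        raw.append(_welch_pvalue(values, ref_values))
    reject, adjusted, _, _ = multipletests(raw, alpha=alpha, method="holm")
    significant = bool(reject.all())
    return ScaffoldCall(
        scaffold=candidate if significant else None,
        rationale=rationale,
        significant=significant,
        alpha=alpha,
        comparison_pvalues={r.label: float(p) for r, p in zip(others, adjusted)},
    )


def analyze_cohort_cells(
    cells: list[CellResult],
    regions: list[RegionSpec],
    reference: RegionSpec,
    alpha: float = 0.05,
    convention: str = "exclusion_aware",
    with_scaffold_call: bool = True,
) -> CohortResult:
    """Aggregate, test and (for 3-channel pair sets) call the scaffold."""
    summaries = aggregate_cells(cells)
    table = _cf_table(cells, [r.region for r in cells[0].cf_records])
    anova = anova_vs_reference(cells, regions, reference, alpha)
    cohort = CohortResult(
        summaries=summaries,
        cf_table=table,
        regions=regions,
        anova=anova,
        convention=convention,
    )
    if with_scaffold_call:
        try:
            cohort.scaffold_call = call_scaffold(cohort, alpha=alpha)
        except RegionError:
            cohort.scaffold_call = None
    return cohort
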