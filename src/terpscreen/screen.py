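"""Plate-level screening analytics.

Each 96-well plate carries library sample wells alongside parent-enzyme
control wells (the unmutated template, for fold-change reference) and
solvent-only wells (for background thresholds).  A well is called active
when at least one targeted compound's normalized signal exceeds the
solvent background; fold changes are taken against the median of the
plate's own parent controls, since growth and induction conditions vary
from plate to plate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .chromatography import (ROLE_PARENT, ROLE_SAMPLE, ROLE_SOLVENT,
                             ThresholdSet, WellResult)

logger = logging.getLogger(__name__)

FLAG_PARENT_ZERO = "parent_median_zero"
FLAG_BOTH_ZERO = "both_zero"


class UndefinedWellError(ValueError):
    """Operation applied to a failed well."""


@dataclass
class PlateLayout:
    """Assignment of wells to roles and libraries on one plate."""

    plate_id: str
    well_assignments: dict[str, tuple[str, str]]  # well_id -> (role, library_id)

    def __post_init__(self) -> None:
        roles = [role for role, _ in self.well_assignments.values()]
        if ROLE_PARENT not in roles:
            raise ValueError(f"plate {self.plate_id}: no parent_control well")
        if ROLE_SOLVENT not in roles:
            raise ValueError(f"plate {self.plate_id}: no solvent_control well")

    def wells_with_role(self, role: str) -> list[str]:
        return [w for w, (r, _) in self.well_assignments.items() if r == role]

    def library_of(self, well_id: str) -> str:
        return self.well_assignments[well_id][1]


def load_layout(path: str | Path) -> dict[str, PlateLayout]:
    """Read plate layouts from CSV (plate_id,well_id,role,library_id)."""
    df = pd.read_csv(path, dtype=str).fillna("")
    layouts = {}
    for plate_id, grp in df.groupby("plate_id", sort=False):
        if grp["well_id"].duplicated().any():
            raise ValueError(f"plate {plate_id}: duplicate well ids")
        layouts[plate_id] = PlateLayout(
            plate_id,
            {r.well_id: (r.role, r.library_id) for r in grp.itertuples()})
    return layouts


@dataclass
class LibrarySummary:
    """Distribution of per-well fold changes for one library and compound."""

    library_id: str
    compound: str
    fold_changes: list[float] = field(default_factory=list)
    n: int = 0
    n_infinite: int = 0
    median: float = math.nan
    lower_quartile: float = math.nan
    upper_quartile: float = math.nan


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def call_active(well: WellResult, thresholds: ThresholdSet) -> bool:
    """Active iff any non-masked targeted compound exceeds its threshold.

    The comparison is strictly greater-than; solvent-masked compounds are
    ignored because their signal cannot be quantified under the solvent
    peak.
    """
    if well.failed:
        raise UndefinedWellError(f"well {well.well_id} failed: {well.failure_reason}")
    for compound, threshold in thresholds.per_compound_threshold.items():
        if "is_masked" in well.flags.get(compound, ()):
            continue
        if well.normalized_area.get(compound, 0.0) > threshold:
            return True
    return False


def fold_change(well: WellResult, parent_wells: Sequence[WellResult],
                compound: str) -> tuple[float, str]:
    """Well signal relative to the plate's parent-control median.

    Returns ``(ratio, flag)``.  A zero parent median with a positive
    sample reads as ``inf`` (flagged ``parent_median_zero``); zero over
    zero reads as 1.0 by convention (flagged ``both_zero``).
    """
    usable = [p for p in parent_wells if not p.failed]
    if not usable:
        raise ValueError("no usable parent-control wells on plate")
    parent_median = float(np.median([p.normalized_area.get(compound, 0.0) for p in usable]))
    sample = well.normalized_area.get(compound, 0.0)
    if parent_median == 0.0:
        if sample == 0.0:
            return 1.0, FLAG_BOTH_ZERO
        return math.inf, FLAG_PARENT_ZERO
    return sample / parent_median, ""


def summarize_library(fold_changes: Iterable[float], library_id: str,
                      compound: str) -> LibrarySummary:
    """Median and quartiles of a library's fold changes.

    Quantiles use linear interpolation between order statistics (the
    numpy default).  Infinite values are excluded from the quantiles and
    counted separately; an empty library yields n = 0 with NaN summary
    values and a warning.
    """
    values = list(fold_changes)
    finite = [v for v in values if math.isfinite(v)]
    n_inf = sum(1 for v in values if math.isinf(v))
    summary = LibrarySummary(library_id, compound, fold_changes=values,
                             n=len(finite), n_infinite=n_inf)
    if not finite:
        logger.warning("library %s / %s: no usable wells", library_id, compound)
        return summary
    q1, med, q3 = np.quantile(finite, [0.25, 0.5, 0.75])
    summary.lower_quartile = float(q1)
    summary.median = float(med)
    summary.upper_quartile = float(q3)
    return summary


# ---------------------------------------------------------------------------
# whole-plate driver
# ---------------------------------------------------------------------------

def analyse_plate(layout: PlateLayout, wells: Mapping[str, WellResult],
                  thresholds: ThresholdSet) -> pd.DataFrame:
    """Active calls and per-compound fold changes for every sample well.

    Failed wells are excluded; fold changes are against this plate's own
    parent controls.  Returns a long table: well_id, library_id, active,
    compound, fold_change, flag.
    """
    parents = [wells[w] for w in layout.wells_with_role(ROLE_PARENT)
               if w in wells and not wells[w].failed]
    if not parents:
        raise ValueError(f"plate {layout.plate_id}: no usable parent wells")
    compounds = sorted(thresholds.per_compound_threshold)
    rows = []
    for well_id in layout.wells_with_role(ROLE_SAMPLE) + layout.wells_with_role(ROLE_PARENT):
        well = wells.get(well_id)
        if well is None or well.failed:
            continue
        active = call_active(well, thresholds)
        for compound in compounds:
            fc, flag = fold_change(well, parents, compound)
            rows.append({
                "plate_id": layout.plate_id,
                "well_id": well_id,
                "library_id": layout.library_of(well_id),
                "role": well.role,
                "active": active,
                "compound": compound,
                "fold_change": fc,
                "flag": flag,
            })
    return pd.DataFrame(rows, columns=["plate_id", "well_id", "library_id", "role",
                                       "active", "compound", "fold_change", "flag"])


def summarize_screen(plate_table: pd.DataFrame) -> pd.DataFrame:
    """Per-library, per-compound fold-change summaries over sample wells."""
    samples = plate_table[plate_table["role"] == ROLE_SAMPLE]
    rows = []
    for (lib, compound), grp in samples.groupby(["library_id", "compound"], sort=True):
        s = summarize_library(grp["fold_change"], lib, compound)
        rows.append({
            "library_id": lib, "compound": compound, "n": s.n,
            "n_infinite": s.n_infinite, "median": s.median,
            "lower_quartile": s.lower_quartile, "upper_quartile": s.upper_quartile,
        })
    return pd.DataFrame(rows, columns=["library_id", "compound", "n", "n_infinite",
                                       "median", "lower_quartile", "upper_quartile"])
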