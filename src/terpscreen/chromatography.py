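"""Targeted GC-MS product quantification for plate-based screens.

One chromatogram per well is reduced to per-compound peak areas: peaks
are picked on the total ion chromatogram (TIC), identified against a
reference table of expected retention times and primary ions, integrated
by the trapezoidal rule between flanking valleys, and normalized to the
internal-standard peak area.  Background thresholds for the active-variant
call are the mean normalized signal in solvent-only control wells.

Retention times are in minutes throughout; m/z is dimensionless.
"""

from __future__ import annotations

import base64
import csv
import logging
import struct
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

logger = logging.getLogger(__name__)

#: m/z window for matching a reference ion in an observed spectrum
MZ_TOLERANCE = 0.3
#: default RT window half-width (minutes) when a reference table omits one;
#: the 4.6-minute fast GC method implies tight windows
DEFAULT_RT_TOLERANCE = 0.05
#: default prominence (TIC counts) and width (scans) for peak picking
DEFAULT_MIN_PROMINENCE = 1_000.0
DEFAULT_MIN_WIDTH_SCANS = 3

ROLE_SAMPLE = "sample"
ROLE_PARENT = "parent_control"
ROLE_SOLVENT = "solvent_control"


class ChromatogramParseError(ValueError):
    """Unreadable or malformed chromatogram file."""


class EmptyRunError(ChromatogramParseError):
    """Chromatogram file contains no scans."""


class InsufficientDataError(ValueError):
    """Too few scans for the requested operation."""


class MissingInternalStandardError(ValueError):
    """Well lacks a usable internal-standard peak."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Chromatogram:
    """Per-well GC-MS run: ordered scans of sparse centroided spectra."""

    well_id: str
    scans: list[tuple[float, dict[float, float]]]
    metadata: str = ""

    def __post_init__(self) -> None:
        if len(self.scans) < 2:
            raise ValueError("chromatogram needs at least 2 scans")
        times = [t for t, _ in self.scans]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("retention times must be strictly increasing")
        for _, spec in self.scans:
            if any(v < 0 for v in spec.values()):
                raise ValueError("intensities must be non-negative")

    @property
    def times(self) -> np.ndarray:
        return np.array([t for t, _ in self.scans])


@dataclass(frozen=True)
class CompoundReference:
    """Expected elution and spectral signature of one targeted compound."""

    name: str
    expected_rt: float
    primary_ion: float
    rt_tolerance: float = DEFAULT_RT_TOLERANCE
    qualifier_ions: tuple[float, ...] = ()
    solvent_masked: bool = False
    is_internal_standard: bool = False

    def __post_init__(self) -> None:
        if self.rt_tolerance <= 0:
            raise ValueError("rt_tolerance must be > 0")


@dataclass(frozen=True)
class Peak:
    """One picked TIC peak with valley-to-valley integration bounds."""

    apex_rt: float
    left_rt: float
    right_rt: float
    apex_intensity: float
    area: float
    apex_index: int
    assigned_compound: str | None = None

    def __post_init__(self) -> None:
        if not self.left_rt < self.apex_rt < self.right_rt:
            raise ValueError("require left_rt < apex_rt < right_rt")
        if self.area < 0:
            raise ValueError("area must be >= 0")


@dataclass
class WellResult:
    """Per-compound normalized areas and quality flags for one well."""

    well_id: str
    role: str
    normalized_area: dict[str, float] = field(default_factory=dict)
    raw_area: dict[str, float] = field(default_factory=dict)
    flags: dict[str, set[str]] = field(default_factory=dict)
    internal_standard_area: float = 0.0
    failed: bool = False
    failure_reason: str = ""


@dataclass(frozen=True)
class ThresholdSet:
    """Per-compound normalized-area background thresholds."""

    per_compound_threshold: Mapping[str, float]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.per_compound_threshold.values()):
            raise ValueError("thresholds must be >= 0")

    def __getitem__(self, compound: str) -> float:
        return self.per_compound_threshold[compound]


# ---------------------------------------------------------------------------
# reading and writing chromatograms
# ---------------------------------------------------------------------------

def read_mzxml(path: str | Path, well_id: str | None = None) -> Chromatogram:
    """Read a chromatogram from mzXML or from the plain TSV dialect.

    Files ending in ``.tsv``/``.txt`` are parsed as the TSV dialect
    (columns ``scan_time_min``, ``mz``, ``intensity``; a zero-intensity
    row at m/z 0 is a placeholder registering an empty scan).  Anything
    else is handed to the pyteomics mzXML parser; retention times are
    converted to minutes regardless of the file's native unit.  Scans
    found out of order are re-sorted with a warning.
    """
    path = Path(path)
    wid = well_id or path.stem
    if path.suffix.lower() in (".tsv", ".txt"):
        scans = _read_tsv_scans(path)
    else:
        scans = _read_mzxml_scans(path)
    if not scans:
        raise EmptyRunError(f"{path}: no scans found")
    if any(b[0] <= a[0] for a, b in zip(scans, scans[1:])):
        logger.warning("%s: scans out of order, re-sorting by retention time", path)
        scans.sort(key=lambda s: s[0])
    if len(scans) < 2:
        raise ChromatogramParseError(f"{path}: fewer than 2 scans")
    return Chromatogram(wid, scans, metadata=str(path))


def _read_mzxml_scans(path: Path) -> list[tuple[float, dict[float, float]]]:
    from pyteomics import mzxml

    scans: list[tuple[float, dict[float, float]]] = []
    try:
        with mzxml.read(str(path)) as reader:
            for scan in reader:
                rt = scan["retentionTime"]
                unit = getattr(rt, "unit_info", "minute")
                rt_min = float(rt) / 60.0 if unit == "second" else float(rt)
                mzs = np.asarray(scan.get("m/z array", []), dtype=float)
                ints = np.asarray(scan.get("intensity array", []), dtype=float)
                spectrum = {float(m): float(i) for m, i in zip(mzs, ints) if i > 0}
                scans.append((rt_min, spectrum))
    except EmptyRunError:
        raise
    except Exception as exc:
        raise ChromatogramParseError(
            f"{path}: parse failed at scan {len(scans) + 1}: {exc}") from exc
    return scans


def _read_tsv_scans(path: Path) -> list[tuple[float, dict[float, float]]]:
    scans: dict[float, dict[float, float]] = {}
    order: list[float] = []
    try:
        with open(path) as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            if reader.fieldnames is None or "scan_time_min" not in reader.fieldnames:
                raise ChromatogramParseError(f"{path}: missing scan_time_min column")
            for i, row in enumerate(reader, start=1):
                try:
                    t = float(row["scan_time_min"])
                    mz = float(row["mz"])
                    intensity = float(row["intensity"])
                except (KeyError, TypeError, ValueError) as exc:
                    raise ChromatogramParseError(
                        f"{path}: bad row {i}: {exc}") from exc
                if t not in scans:
                    scans[t] = {}
                    order.append(t)
                if intensity > 0:
                    scans[t][mz] = scans[t].get(mz, 0.0) + intensity
    except OSError as exc:
        raise ChromatogramParseError(f"{path}: {exc}") from exc
    return [(t, scans[t]) for t in order]


def write_tsv(chrom: Chromatogram, path: str | Path) -> None:
    """Write the plain TSV dialect (empty scans kept via placeholder rows)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["scan_time_min", "mz", "intensity"])
        for t, spec in chrom.scans:
            if not spec:
                writer.writerow([f"{t:.6f}", "0.0", "0.0"])
            for mz in sorted(spec):
                writer.writerow([f"{t:.6f}", repr(float(mz)), repr(float(spec[mz]))])


def write_mzxml(chrom: Chromatogram, path: str | Path) -> None:
    """Write a minimal mzXML file (32-bit network-order m/z–intensity pairs)."""
    lines = [
        '<?xml version="1.0" encoding="ISO-8859-1"?>',
        '<mzXML xmlns="http://sashimi.sourceforge.net/schema_revision/mzXML_3.2">',
        f'<msRun scanCount="{len(chrom.scans)}">',
    ]
    for num, (t, spec) in enumerate(chrom.scans, start=1):
        mzs = sorted(spec)
        payload = b"".join(struct.pack(">ff", m, spec[m]) for m in mzs)
        b64 = base64.b64encode(payload).decode()
        lines.append(
            f'<scan num="{num}" msLevel="1" peaksCount="{len(mzs)}" '
            f'retentionTime="PT{t * 60.0:.6f}S">')
        lines.append(
            '<peaks precision="32" byteOrder="network" contentType="m/z-int" '
            f'compressionType="none" compressedLen="0">{b64}</peaks>')
        lines.append("</scan>")
    lines += ["</msRun>", "</mzXML>"]
    Path(path).write_text("\n".join(lines))


# ---------------------------------------------------------------------------
# TIC and peak picking
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TICTrace:
    """Total ion chromatogram: per-scan sums of all spectral intensities."""

    times: np.ndarray
    intensities: np.ndarray

    def __len__(self) -> int:
        return len(self.times)

    def __iter__(self) -> Iterator[tuple[float, float]]:
        return iter(zip(self.times.tolist(), self.intensities.tolist()))


def total_ion_chromatogram(chrom: Chromatogram) -> TICTrace:
    """Sum each scan's spectrum into a single TIC intensity (0 if empty)."""
    times = chrom.times
    tic = np.array([sum(spec.values()) for _, spec in chrom.scans], dtype=float)
    return TICTrace(times, tic)


def _valley_bounds(x: np.ndarray, apex: int) -> tuple[int, int]:
    """Walk from the apex to the nearest flanking local minima."""
    left = apex
    while left > 0 and x[left - 1] < x[left]:
        left -= 1
    right = apex
    while right < len(x) - 1 and x[right + 1] < x[right]:
        right += 1
    return left, right


def pick_peaks(tic: TICTrace,
               min_prominence: float = DEFAULT_MIN_PROMINENCE,
               min_width_scans: int = DEFAULT_MIN_WIDTH_SCANS) -> list[Peak]:
    """Pick TIC peaks: prominent local maxima with valley-to-valley bounds.

    Apexes come from :func:`scipy.signal.find_peaks` with the given
    prominence and minimum width (in scans); each peak's integration
    bounds extend to the nearest flanking local minima and its area is
    the trapezoidal integral of the TIC between them (counts·minute).
    """
    if len(tic) < 3:
        raise InsufficientDataError("peak picking needs at least 3 scans")
    x, t = tic.intensities, tic.times
    apexes, _ = find_peaks(x, prominence=min_prominence, width=min_width_scans)
    peaks = []
    for apex in apexes:
        lo, hi = _valley_bounds(x, apex)
        if hi - lo < 2:
            continue
        area = float(np.trapezoid(x[lo:hi + 1], t[lo:hi + 1]))
        peaks.append(Peak(
            apex_rt=float(t[apex]), left_rt=float(t[lo]), right_rt=float(t[hi]),
            apex_intensity=float(x[apex]), area=max(area, 0.0), apex_index=int(apex)))
    return sorted(peaks, key=lambda p: p.apex_rt)


# ---------------------------------------------------------------------------
# identification
# ---------------------------------------------------------------------------

def _primary_ion_confirmed(spectrum: Mapping[float, float], ref: CompoundReference,
                           mz_tol: float = MZ_TOLERANCE) -> bool:
    """True iff the primary ion is the most intense of the reference's ions."""

    def observed(target: float) -> float:
        return sum(v for m, v in spectrum.items() if abs(m - target) <= mz_tol)

    primary = observed(ref.primary_ion)
    if primary <= 0:
        return False
    return all(observed(q) <= primary for q in ref.qualifier_ions)


def identify_peaks(peaks: Sequence[Peak], chrom: Chromatogram,
                   refs: Sequence[CompoundReference],
                   mz_tol: float = MZ_TOLERANCE) -> list[Peak]:
    """Assign picked peaks to reference compounds by RT window and primary ion.

    A peak may be assigned to a compound only if its apex lies inside the
    compound's RT window and the apex-scan spectrum's most intense ion
    among the reference's listed ions is the primary ion.  The assignment
    is a partial matching — each compound gets at most one peak and vice
    versa — resolved greedily by smallest |RT difference|, ties broken by
    reference-table order.  Solvent-masked compounds are never assigned.
    """
    if not refs:
        raise ValueError("reference table is empty")
    candidates = []
    for ref_order, ref in enumerate(refs):
        if ref.solvent_masked:
            continue
        for peak_idx, peak in enumerate(peaks):
            drt = abs(peak.apex_rt - ref.expected_rt)
            if drt > ref.rt_tolerance:
                continue
            spectrum = chrom.scans[peak.apex_index][1]
            if not _primary_ion_confirmed(spectrum, ref, mz_tol):
                continue
            candidates.append((drt, ref_order, peak_idx))
    candidates.sort()
    assigned_refs: set[int] = set()
    assignment: dict[int, str] = {}
    for drt, ref_order, peak_idx in candidates:
        if ref_order in assigned_refs or peak_idx in assignment:
            continue
        assigned_refs.add(ref_order)
        assignment[peak_idx] = refs[ref_order].name
    return [replace(p, assigned_compound=assignment.get(i)) for i, p in enumerate(peaks)]


# ---------------------------------------------------------------------------
# normalization and thresholds
# ---------------------------------------------------------------------------

def normalize_well(peaks: Sequence[Peak], refs: Sequence[CompoundReference],
                   well_id: str, role: str = ROLE_SAMPLE) -> WellResult:
    """Divide each compound's peak area by the internal-standard area.

    Targeted (non-masked, non-IS) compounds with no assigned peak get
    normalized area 0 and flag ``is_missing``; solvent-masked compounds
    are reported as 0 with flag ``is_masked``.  A well whose internal
    standard is absent or has zero area is marked failed and contributes
    nothing downstream.
    """
    is_refs = [r for r in refs if r.is_internal_standard]
    if len(is_refs) != 1:
        raise ValueError("exactly one reference must be the internal standard")
    is_name = is_refs[0].name
    by_compound = {p.assigned_compound: p for p in peaks if p.assigned_compound}

    result = WellResult(well_id=well_id, role=role)
    is_peak = by_compound.get(is_name)
    if is_peak is None or is_peak.area <= 0:
        result.failed = True
        result.failure_reason = "internal standard missing or zero area"
        logger.warning("well %s failed: %s", well_id, result.failure_reason)
        return result
    result.internal_standard_area = is_peak.area

    for ref in refs:
        if ref.is_internal_standard:
            continue
        flags: set[str] = set()
        if ref.solvent_masked:
            flags.add("is_masked")
            result.normalized_area[ref.name] = 0.0
            result.raw_area[ref.name] = 0.0
        elif ref.name in by_compound:
            area = by_compound[ref.name].area
            result.raw_area[ref.name] = area
            result.normalized_area[ref.name] = area / is_peak.area
        else:
            flags.add("is_missing")
            result.normalized_area[ref.name] = 0.0
            result.raw_area[ref.name] = 0.0
        result.flags[ref.name] = flags
    return result


def compute_thresholds(solvent_wells: Sequence[WellResult],
                       targeted_compounds: Iterable[str]) -> ThresholdSet:
    """Background threshold per compound: mean normalized area over the
    plate's solvent-only wells."""
    usable = [w for w in solvent_wells if not w.failed]
    if not usable:
        raise ValueError("no usable solvent-control wells: cannot derive thresholds")
    thresholds = {
        c: float(np.mean([w.normalized_area.get(c, 0.0) for w in usable]))
        for c in targeted_compounds
    }
    return ThresholdSet(thresholds)


def process_well(chrom: Chromatogram, refs: Sequence[CompoundReference],
                 role: str = ROLE_SAMPLE,
                 min_prominence: float = DEFAULT_MIN_PROMINENCE,
                 min_width_scans: int = DEFAULT_MIN_WIDTH_SCANS) -> WellResult:
    """Full per-well reduction: TIC → pick → identify → normalize."""
    tic = total_ion_chromatogram(chrom)
    peaks = pick_peaks(tic, min_prominence, min_width_scans)
    peaks = identify_peaks(peaks, chrom, refs)
    return normalize_well(peaks, refs, chrom.well_id, role)


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def load_compound_table(path: str | Path) -> list[CompoundReference]:
    """Read the compound reference CSV (qualifier ions semicolon-separated)."""
    df = pd.read_csv(path)
    refs = []
    for _, row in df.iterrows():
        quals = ()
        if isinstance(row.get("qualifier_ions"), str) and row["qualifier_ions"].strip():
            quals = tuple(float(q) for q in row["qualifier_ions"].split(";"))
        refs.append(CompoundReference(
            name=row["name"],
            expected_rt=float(row["expected_rt"]),
            rt_tolerance=float(row.get("rt_tolerance", DEFAULT_RT_TOLERANCE)),
            primary_ion=float(row["primary_ion"]),
            qualifier_ions=quals,
            solvent_masked=bool(row.get("solvent_masked", False)),
            is_internal_standard=bool(row.get("is_internal_standard", False)),
        ))
    is_count = sum(r.is_internal_standard for r in refs)
    if is_count != 1:
        raise ValueError(f"compound table must mark exactly one internal standard, got {is_count}")
    return refs


def save_compound_table(refs: Sequence[CompoundReference], path: str | Path) -> None:
    pd.DataFrame([
        {
            "name": r.name, "expected_rt": r.expected_rt, "rt_tolerance": r.rt_tolerance,
            "primary_ion": r.primary_ion,
            "qualifier_ions": ";".join(str(q) for q in r.qualifier_ions),
            "solvent_masked": r.solvent_masked,
            "is_internal_standard": r.is_internal_standard,
        }
        for r in refs
    ]).to_csv(path, index=False)


def well_results_table(wells: Sequence[WellResult]) -> pd.DataFrame:
    """Per-well, per-compound long table (failed wells excluded)."""
    rows = []
    for w in wells:
        if w.failed:
            continue
        for compound, norm in sorted(w.normalized_area.items()):
            rows.append({
                "well_id": w.well_id,
                "compound": compound,
                "area": w.raw_area.get(compound, 0.0),
                "normalized_area": norm,
                "flags": ";".join(sorted(w.flags.get(compound, ()))),
            })
    return pd.DataFrame(rows, columns=["well_id", "compound", "area",
                                       "normalized_area", "flags"])
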