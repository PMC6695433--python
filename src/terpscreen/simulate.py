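"""Synthetic screen generator with planted ground truth.

Stands in for the wet-lab and instrument front end of the screen so that
every downstream stage — peak extraction, active calling, read cleaning,
variant calling, scoring — can be exercised and scored against known
truth.  It emulates:

* fast-GC chromatograms (4.6-minute run, 5 scans/s) as sums of Gaussian
  peaks at compound-specific retention times, with a dominant early
  solvent (dodecane) peak that masks several analytes, an
  internal-standard peak, and white baseline noise;
* well-to-well log-normal titre variation (growth/induction noise);
* per-well Sanger reads carrying one degenerate-codon substitution at a
  designed position plus N's, point errors and truncated ends.

Everything is a pure function of (config, seed): the same seed yields
byte-identical outputs.  The template coding sequence used by the default
library design is synthetic — a deterministically generated 600-codon ORF
with the parent enzyme's known residues planted at their real positions —
because real variant screens carry their own template.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .chromatography import (ROLE_PARENT, ROLE_SAMPLE, ROLE_SOLVENT,
                             Chromatogram, CompoundReference,
                             save_compound_table, write_tsv)
from .screen import PlateLayout
from .variantseq import LibraryDesign, expand_degenerate_codon, translate

# fast-GC acquisition: 5 spectra/s over a 4.6-minute run
SCAN_INTERVAL_MIN = 1.0 / 300.0
RUN_LENGTH_MIN = 4.6

#: fraction of a compound's signal carried by its primary ion; the rest is
#: split evenly over its qualifier ions
PRIMARY_ION_FRACTION = 0.6

#: m/z used for baseline noise counts
NOISE_ION = 40.0

SOLVENT_NAME = "dodecane"
SOLVENT_IONS = (57.0, 71.0, 85.0)


def default_compound_table() -> list[CompoundReference]:
    """Targeted monoterpene references for the pinene-synthase screen.

    Four quantifiable peaks (α-pinene, the merged sabinene/myrcene peak,
    β-pinene, limonene), four analytes masked by the dodecane solvent
    peak, and the sec-butylbenzene internal standard.  Retention times
    are synthetic but respect elution order on an apolar fast-GC method.
    """
    return [
        CompoundReference("terpinolene", 1.26, 93.0, qualifier_ions=(121.0, 136.0),
                          solvent_masked=True),
        CompoundReference("linalool", 1.32, 71.0, qualifier_ions=(93.0, 55.0),
                          solvent_masked=True),
        CompoundReference("alpha-terpineol", 1.36, 59.0, qualifier_ions=(93.0, 121.0),
                          solvent_masked=True),
        CompoundReference("geraniol", 1.40, 69.0, qualifier_ions=(41.0, 93.0),
                          solvent_masked=True),
        CompoundReference("alpha-pinene", 2.10, 93.0, qualifier_ions=(91.0, 136.0)),
        CompoundReference("sabinene/myrcene", 2.35, 93.0, qualifier_ions=(77.0, 136.0)),
        CompoundReference("beta-pinene", 2.55, 93.0, qualifier_ions=(41.0, 136.0)),
        CompoundReference("limonene", 2.85, 68.0, qualifier_ions=(93.0, 136.0)),
        CompoundReference("sec-butylbenzene", 3.30, 105.0, qualifier_ions=(134.0, 91.0),
                          is_internal_standard=True),
    ]


TARGETED_COMPOUNDS = ("alpha-pinene", "sabinene/myrcene", "beta-pinene", "limonene")

#: parent (template enzyme) planted peak areas, TIC counts·min — a mixture
#: of bicyclic, monocyclic and linear products as the screen's template makes
PARENT_AREAS = {
    "alpha-pinene": 5000.0,
    "sabinene/myrcene": 2500.0,
    "beta-pinene": 3000.0,
    "limonene": 1500.0,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic screen; defaults are the study conditions."""

    seed: int = 0
    compound_table: tuple[CompoundReference, ...] = tuple(default_compound_table())
    peak_sigma_min: float = 0.008          # chromatographic peak width (Gaussian sigma)
    solvent_rt: float = 1.32               # dodecane apex, minutes
    solvent_area: float = 2.0e5            # counts*min, dwarfs analyte peaks
    solvent_sigma_min: float = 0.05
    is_area: float = 1.0e4                 # internal-standard planted area
    baseline_noise: float = 50.0           # white-noise sigma on the TIC, counts
    titre_noise: float = 0.2               # log-normal sigma of per-well titre scale
    compound_noise: float = 0.1            # extra per-compound log-normal sigma
    is_noise: float = 0.05                 # internal-standard log-normal sigma
    inactive_fraction: float = 0.15        # chance a variant makes no product
    profile_spread: float = 0.5            # log-normal sigma reshaping variant profiles
    read_error_rate: float = 0.001         # per-base substitution probability
    n_rate: float = 0.002                  # per-base N probability
    read_start_window: tuple[int, int] = (900, 1000)   # 0-based nt, uniform
    read_end_window: tuple[int, int] = (1700, 1800)

    def __post_init__(self) -> None:
        for name in ("titre_noise", "compound_noise", "is_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("read_error_rate", "n_rate", "inactive_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.peak_sigma_min <= 0 or self.solvent_sigma_min <= 0:
            raise ValueError("peak widths must be > 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# synthetic template and default library design
# ---------------------------------------------------------------------------

#: residues of the parent enzyme known at the diversified positions
KNOWN_TEMPLATE_CODONS = {
    335: "TGT",  # Cys
    337: "ATT",  # Ile
    444: "GGT",  # Gly
    557: "GCT",  # Ala
    559: "ATG",  # Met
    560: "GCA",  # Ala
    561: "CAA",  # Gln
    562: "TTC",  # Phe
}

#: the 16 diversified positions in the three active-site plasticity regions
DEFAULT_TARGET_POSITIONS = (
    335, 336, 337, 338,                  # region 1
    443, 444, 445, 446, 447, 448,        # region 2
    557, 559, 560, 561, 562, 563,        # region 3 (558 conserved, untouched)
)

_TEMPLATE_LENGTH_CODONS = 600

_SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if translate(a + b + c) != "*"
)


def default_template() -> str:
    """Synthetic 600-codon parent CDS (deterministic; no stop codons).

    A stand-in for the real pinene-synthase template, with the known
    parent residues planted at the diversified positions.
    """
    rng = np.random.default_rng(20260901)
    codons = ["ATG"] + [
        _SENSE_CODONS[i]
        for i in rng.integers(0, len(_SENSE_CODONS), _TEMPLATE_LENGTH_CODONS - 1)
    ]
    for pos, codon in KNOWN_TEMPLATE_CODONS.items():
        codons[pos - 1] = codon
    return "".join(codons)


def default_design(positions: Sequence[int] = DEFAULT_TARGET_POSITIONS) -> LibraryDesign:
    """NBT saturation design over the default synthetic template."""
    return LibraryDesign(default_template(), tuple(positions), "NBT")


# ---------------------------------------------------------------------------
# chromatogram synthesis
# ---------------------------------------------------------------------------

def _gaussian_counts(times: np.ndarray, rt: float, area: float, sigma: float) -> np.ndarray:
    return area * np.exp(-0.5 * ((times - rt) / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi))


def simulate_chromatogram(true_areas: Mapping[str, float], cfg: SimulationConfig,
                          well_id: str = "W1",
                          rng: np.random.Generator | None = None,
                          ) -> tuple[Chromatogram, dict]:
    """Build one well's chromatogram from planted per-compound areas.

    ``true_areas`` maps compound names (must appear in the config's
    reference table) to planted TIC peak areas; the solvent and
    internal-standard peaks are always added on top.  Each compound's
    per-scan signal is placed on its primary ion (60%) and qualifier ions
    (40% split evenly), so the identification rule has something to
    check.  Returns the chromatogram and a truth record of every planted
    area.
    """
    if any(a < 0 for a in true_areas.values()):
        raise ValueError("planted areas must be >= 0")
    rng = cfg.rng() if rng is None else rng
    refs = {r.name: r for r in cfg.compound_table}
    unknown = set(true_areas) - set(refs)
    if unknown:
        raise ValueError(f"areas given for compounds not in reference table: {sorted(unknown)}")

    n_scans = int(round(RUN_LENGTH_MIN / SCAN_INTERVAL_MIN))
    times = (np.arange(n_scans) + 1) * SCAN_INTERVAL_MIN
    spectra: list[dict[float, float]] = [{} for _ in range(n_scans)]

    def deposit(rt: float, area: float, sigma: float, ions: Sequence[tuple[float, float]]) -> None:
        if area <= 0:
            return
        lo = max(0, int((rt - 6 * sigma) / SCAN_INTERVAL_MIN) - 1)
        hi = min(n_scans, int((rt + 6 * sigma) / SCAN_INTERVAL_MIN) + 2)
        counts = _gaussian_counts(times[lo:hi], rt, area, sigma)
        for i, c in zip(range(lo, hi), counts):
            if c <= 0:
                continue
            for mz, frac in ions:
                spectra[i][mz] = spectra[i].get(mz, 0.0) + c * frac

    def ion_split(ref: CompoundReference) -> list[tuple[float, float]]:
        if not ref.qualifier_ions:
            return [(ref.primary_ion, 1.0)]
        q = (1.0 - PRIMARY_ION_FRACTION) / len(ref.qualifier_ions)
        return [(ref.primary_ion, PRIMARY_ION_FRACTION)] + [
            (mz, q) for mz in ref.qualifier_ions]

    # solvent peak dominating early elution
    deposit(cfg.solvent_rt, cfg.solvent_area, cfg.solvent_sigma_min,
            [(mz, 1.0 / len(SOLVENT_IONS)) for mz in SOLVENT_IONS])

    is_planted = 0.0
    for name, area in true_areas.items():
        ref = refs[name]
        if ref.is_internal_standard:
            is_planted = area
        deposit(ref.expected_rt, area, cfg.peak_sigma_min, ion_split(ref))

    is_ref = next(r for r in cfg.compound_table if r.is_internal_standard)
    if is_planted == 0.0 and is_ref.name not in true_areas:
        is_planted = cfg.is_area
        deposit(is_ref.expected_rt, is_planted, cfg.peak_sigma_min, ion_split(is_ref))

    if cfg.baseline_noise > 0:
        noise = np.abs(rng.normal(0.0, cfg.baseline_noise, n_scans))
        for i, c in enumerate(noise):
            if c > 0:
                spectra[i][NOISE_ION] = spectra[i].get(NOISE_ION, 0.0) + float(c)

    chrom = Chromatogram(well_id, list(zip(times.tolist(), spectra)))
    truth = {"well_id": well_id,
             "planted_areas": dict(true_areas),
             "internal_standard_area": is_planted}
    return chrom, truth


# ---------------------------------------------------------------------------
# whole-screen synthesis
# ---------------------------------------------------------------------------

_ROWS = "ABCDEFGH"


def _plate_well_ids() -> list[str]:
    return [f"{r}{c:02d}" for r in _ROWS for c in range(1, 13)]


@dataclass
class ScreenSimulation:
    """One simulated screen: layouts, chromatograms, reads and truth."""

    config: SimulationConfig
    design: LibraryDesign
    layouts: dict[str, PlateLayout]
    chromatograms: dict[str, Chromatogram]
    reads: list[tuple[str, str]]            # (well_id, sequence)
    truth: dict = field(default_factory=dict)


def _variant_profile(position: int, codon: str, design: LibraryDesign,
                     cfg: SimulationConfig, rng: np.random.Generator) -> dict[str, float]:
    """Planted product areas for one variant (all-zero if inactive).

    Variants carrying the parent residue keep the parent profile; others
    are reshaped by log-normal per-compound factors and are inactive with
    probability ``inactive_fraction``.
    """
    if translate(codon) == design.template_residue(position):
        return dict(PARENT_AREAS)
    if rng.random() < cfg.inactive_fraction:
        return {c: 0.0 for c in PARENT_AREAS}
    factors = np.exp(rng.normal(0.0, cfg.profile_spread, len(PARENT_AREAS)))
    return {c: a * f for (c, a), f in zip(PARENT_AREAS.items(), factors)}


def simulate_screen(libraries: Mapping[str, int], wells_per_library: int,
                    cfg: SimulationConfig,
                    design: LibraryDesign | None = None,
                    n_parent: int = 4, n_solvent: int = 4) -> ScreenSimulation:
    """Simulate a plate screen of single-position NBT libraries.

    ``libraries`` maps library id to its diversified amino-acid position
    (each library is held on a single plate, as in a real screen; parent
    and solvent control wells are placed on every plate).  Each sample
    well draws a codon uniformly from the degenerate expansion, receives
    that variant's planted product profile scaled by log-normal titre
    noise, and gets a Sanger read of its gene.  The truth record links
    every well to its library, planted codon and planted areas.
    """
    if wells_per_library < 1:
        raise ValueError("wells_per_library must be >= 1")
    design = design or default_design()
    rng = cfg.rng()
    codons = sorted(expand_degenerate_codon(design.degenerate_codon)[0])

    per_plate_samples = 96 - n_parent - n_solvent
    libs_per_plate = max(1, per_plate_samples // wells_per_library)

    layouts: dict[str, PlateLayout] = {}
    chromatograms: dict[str, Chromatogram] = {}
    reads: list[tuple[str, str]] = []
    well_truth: dict[str, dict] = {}
    profile_cache: dict[tuple[int, str], dict[str, float]] = {}

    lib_items = list(libraries.items())
    plates = [lib_items[i:i + libs_per_plate] for i in range(0, len(lib_items), libs_per_plate)]

    for plate_no, plate_libs in enumerate(plates, start=1):
        plate_id = f"P{plate_no}"
        well_ids = iter(_plate_well_ids())
        assignments: dict[str, tuple[str, str]] = {}

        def add_well(role: str, label: str) -> str:
            wid = f"{plate_id}-{next(well_ids)}"
            assignments[wid] = (role, label)
            return wid

        for _ in range(n_solvent):
            wid = add_well(ROLE_SOLVENT, "solvent")
            chrom, truth = simulate_chromatogram({}, cfg, wid, rng)
            chromatograms[wid] = chrom
            well_truth[wid] = {**truth, "role": ROLE_SOLVENT, "library_id": "solvent",
                               "active": False}

        for _ in range(n_parent):
            wid = add_well(ROLE_PARENT, "parent")
            areas = _noisy_areas(PARENT_AREAS, cfg, rng)
            chrom, truth = simulate_chromatogram(areas, cfg, wid, rng)
            chromatograms[wid] = chrom
            well_truth[wid] = {**truth, "role": ROLE_PARENT, "library_id": "parent",
                               "active": True}

        read_assignment: dict[str, tuple[int, str]] = {}
        for lib_id, position in plate_libs:
            if position not in design.target_positions:
                raise ValueError(f"library {lib_id}: position {position} not in design")
            for _ in range(wells_per_library):
                wid = add_well(ROLE_SAMPLE, lib_id)
                codon = codons[rng.integers(0, len(codons))]
                key = (position, codon)
                if key not in profile_cache:
                    profile_cache[key] = _variant_profile(position, codon, design, cfg, rng)
                base = profile_cache[key]
                active = any(a > 0 for a in base.values())
                areas = _noisy_areas(base, cfg, rng) if active else dict(base)
                chrom, truth = simulate_chromatogram(areas, cfg, wid, rng)
                chromatograms[wid] = chrom
                read_assignment[wid] = key
                well_truth[wid] = {
                    **truth, "role": ROLE_SAMPLE, "library_id": lib_id,
                    "position": position, "codon": codon,
                    "amino_acid": translate(codon),
                    "planted_profile": dict(base), "active": active,
                }

        plate_reads, read_truth = simulate_reads(design, read_assignment, cfg, rng)
        reads.extend(plate_reads)
        for wid, rt in read_truth.items():
            well_truth[wid].update(rt)

        layouts[plate_id] = PlateLayout(plate_id, assignments)

    truth = {"wells": well_truth,
             "parent_areas": dict(PARENT_AREAS),
             "internal_standard_area": cfg.is_area}
    return ScreenSimulation(cfg, design, layouts, chromatograms, reads, truth)


def _noisy_areas(base: Mapping[str, float], cfg: SimulationConfig,
                 rng: np.random.Generator) -> dict[str, float]:
    """Apply shared per-well and per-compound log-normal titre noise.

    The internal standard is spiked at dilution, downstream of growth, so
    it gets its own (smaller) noise term rather than the titre factor.
    """
    titre_factor = float(np.exp(rng.normal(0.0, cfg.titre_noise)))
    out = {}
    for name, area in base.items():
        f = float(np.exp(rng.normal(0.0, cfg.compound_noise)))
        out[name] = area * titre_factor * f
    is_ref = next(r for r in cfg.compound_table if r.is_internal_standard)
    out[is_ref.name] = cfg.is_area * float(np.exp(rng.normal(0.0, cfg.is_noise)))
    return out


# ---------------------------------------------------------------------------
# read synthesis
# ---------------------------------------------------------------------------

def simulate_reads(design: LibraryDesign,
                   variant_assignment: Mapping[str, tuple[int, str]],
                   cfg: SimulationConfig,
                   rng: np.random.Generator | None = None,
                   ) -> tuple[list[tuple[str, str]], dict[str, dict]]:
    """Synthesize one Sanger read per well.

    Each read is the template with the assigned codon substituted at its
    position, truncated to a window drawn from the config's start/end
    ranges, then corrupted by per-base substitution errors and N calls.
    Returns ``(reads, truth)`` where reads are (well id, sequence) pairs
    and truth stores the planted codon and read window per well.
    """
    rng = cfg.rng() if rng is None else rng
    legal = design.codon_set
    reads: list[tuple[str, str]] = []
    truth: dict[str, dict] = {}
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)

    for well_id, (position, codon) in variant_assignment.items():
        if codon not in legal and codon != design.template_codon(position):
            raise ValueError(
                f"well {well_id}: codon {codon} not in degenerate expansion or template")
        seq = list(design.template_cds)
        seq[3 * (position - 1): 3 * position] = list(codon)

        start = int(rng.integers(*cfg.read_start_window))
        end = int(rng.integers(cfg.read_end_window[0], cfg.read_end_window[1] + 1))
        end = min(end, len(seq))
        arr = np.frombuffer("".join(seq[start:end]).encode(), dtype=np.uint8).copy()

        if cfg.read_error_rate > 0:
            hit = rng.random(len(arr)) < cfg.read_error_rate
            for i in np.nonzero(hit)[0]:
                choices = bases[bases != arr[i]]
                arr[i] = choices[rng.integers(0, len(choices))]
        if cfg.n_rate > 0:
            arr[rng.random(len(arr)) < cfg.n_rate] = ord("N")

        reads.append((well_id, arr.tobytes().decode()))
        truth[well_id] = {"position": position, "codon": codon,
                          "amino_acid": translate(codon),
                          "read_start": start, "read_end": end}
    return reads, truth


# ---------------------------------------------------------------------------
# writing a simulated screen to disk
# ---------------------------------------------------------------------------

def write_screen(sim: ScreenSimulation, outdir: str | Path) -> None:
    """Write a simulated screen as plain files.

    ``chromatograms/<well>.tsv`` in the TSV chromatogram dialect,
    ``layout.csv``, ``reads.fasta``, ``compounds.csv`` and ``truth.json``.
    """
    outdir = Path(outdir)
    (outdir / "chromatograms").mkdir(parents=True, exist_ok=True)
    for wid, chrom in sim.chromatograms.items():
        write_tsv(chrom, outdir / "chromatograms" / f"{wid}.tsv")
    rows = ["plate_id,well_id,role,library_id"]
    for plate_id, layout in sim.layouts.items():
        for wid, (role, lib) in layout.well_assignments.items():
            rows.append(f"{plate_id},{wid},{role},{lib}")
    (outdir / "layout.csv").write_text("\n".join(rows) + "\n")
    with open(outdir / "reads.fasta", "w") as fh:
        for wid, seq in sim.reads:
            fh.write(f">{wid}\n{seq}\n")
    save_compound_table(list(sim.config.compound_table), outdir / "compounds.csv")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(sim.truth, fh, indent=1)
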