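"""Degenerate-codon library model and Sanger-read analysis.

A focused saturation library replaces one codon of a template coding
sequence with a degenerate codon (an IUPAC ambiguity triplet such as NBT).
Sequencing a picked colony yields a single Sanger read that should match
the template everywhere except at the mutated codon, where any codon from
the degenerate expansion may appear.  Real reads additionally carry N
calls, sporadic base-call errors, and truncated ends.  This module cleans
such reads against the template, validates the mutation against the
degenerate design, and reports per-well variant calls.

Coordinates are 1-based: amino-acid position ``i`` corresponds to template
bases ``3i-2 .. 3i``.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

IUPAC_DNA = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

#: minimum ungapped identity for a read to be considered alignable
MIN_ALIGN_IDENTITY = 0.70
#: minimum read length accepted for alignment
MIN_READ_LENGTH = 30


class UnalignableReadError(ValueError):
    """Read cannot be placed on the template at the required identity."""


class FrameError(ValueError):
    """Sequence length is not a multiple of three."""


# ---------------------------------------------------------------------------
# library design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LibraryDesign:
    """A single-codon saturation library on a template CDS.

    Parameters
    ----------
    template_cds
        Template coding sequence (uppercase ACGT, length divisible by 3,
        no ambiguity codes).
    target_positions
        1-based amino-acid positions diversified by the library.
    degenerate_codon
        Three-letter IUPAC string, e.g. ``"NBT"``.
    """

    template_cds: str
    target_positions: tuple[int, ...]
    degenerate_codon: str = "NBT"

    def __post_init__(self) -> None:
        cds = self.template_cds.upper()
        object.__setattr__(self, "template_cds", cds)
        object.__setattr__(self, "target_positions", tuple(self.target_positions))
        if len(cds) % 3 != 0:
            raise FrameError(f"template length {len(cds)} is not a multiple of 3")
        bad = set(cds) - set("ACGT")
        if bad:
            raise ValueError(f"template contains ambiguity codes: {sorted(bad)}")
        n_res = len(cds) // 3
        for p in self.target_positions:
            if not 1 <= p <= n_res:
                raise ValueError(f"target position {p} outside template (1..{n_res})")
        for letter in self.degenerate_codon:
            if letter.upper() not in IUPAC_DNA:
                raise ValueError(f"invalid IUPAC letter {letter!r}")
        if len(self.degenerate_codon) != 3:
            raise ValueError("degenerate codon must be 3 letters")

    @property
    def n_residues(self) -> int:
        return len(self.template_cds) // 3

    def template_codon(self, position: int) -> str:
        """Template codon at a 1-based amino-acid position."""
        return self.template_cds[3 * (position - 1): 3 * position]

    def template_residue(self, position: int) -> str:
        return translate(self.template_codon(position))

    @property
    def codon_set(self) -> frozenset[str]:
        codons, _ = expand_degenerate_codon(self.degenerate_codon)
        return frozenset(codons)

    @property
    def residue_set(self) -> frozenset[str]:
        _, aas = expand_degenerate_codon(self.degenerate_codon)
        return frozenset(aas)


def load_design(path: str | Path, template_fasta: str | Path | None = None) -> LibraryDesign:
    """Read a library design from YAML (fields: template_id or template_cds,
    positions, degenerate_codon), optionally resolving the template from a
    FASTA file by id."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    positions = doc["positions"]
    if isinstance(positions, str):
        positions = [int(x) for x in positions.split(",")]
    if "template_cds" in doc:
        cds = doc["template_cds"]
    else:
        if template_fasta is None:
            raise ValueError("design references template_id but no FASTA given")
        records = {r.id: str(r.seq) for r in SeqIO.parse(str(template_fasta), "fasta")}
        cds = records[doc["template_id"]]
    return LibraryDesign(cds, tuple(int(p) for p in positions), doc.get("degenerate_codon", "NBT"))


# ---------------------------------------------------------------------------
# codon arithmetic
# ---------------------------------------------------------------------------

def expand_degenerate_codon(codon: str) -> tuple[set[str], Counter]:
    """Expand an IUPAC degenerate codon.

    Returns the set of concrete DNA codons and the multiset of encoded
    amino acids (codon multiplicity retained; stop rendered ``*``).  NBT,
    the library codon used throughout, expands to 12 codons encoding 11
    distinct residues with serine counted twice.
    """
    codon = codon.upper()
    if len(codon) != 3:
        raise ValueError(f"degenerate codon must have 3 letters, got {codon!r}")
    for letter in codon:
        if letter not in IUPAC_DNA:
            raise ValueError(f"invalid IUPAC letter {letter!r}")
    codons = {"".join(bases) for bases in product(*(IUPAC_DNA[c] for c in codon))}
    aas = Counter(translate(c) for c in sorted(codons))
    return codons, aas


def translate(cds: str) -> str:
    """Translate a CDS with the standard genetic code; stop codons as ``*``."""
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise FrameError(f"length {len(cds)} is not a multiple of 3")
    if set(cds) - set("ACGT"):
        raise ValueError("ambiguity codes not allowed in translate()")
    return str(Seq(cds).translate())


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Alignment:
    """Ungapped placement of a read on the template.

    ``offset`` is the 0-based template index of the read's first base;
    ``identity`` is matches / read length; ``reverse_complemented`` records
    whether the read had to be flipped before placement.
    """

    offset: int
    identity: float
    matches: int
    reverse_complemented: bool = False


def _best_offset(read: np.ndarray, template: np.ndarray) -> tuple[int, int]:
    """Best fully-contained ungapped placement (offset, matches)."""
    n, m = len(template), len(read)
    best_off, best_matches = 0, -1
    for off in range(n - m + 1):
        matches = int(np.count_nonzero(template[off:off + m] == read))
        if matches > best_matches:
            best_off, best_matches = off, matches
    return best_off, best_matches


def align_to_template(read: str, template: str,
                      min_identity: float = MIN_ALIGN_IDENTITY) -> Alignment:
    """Place a read on the template by exhaustive ungapped offset search.

    Both orientations are tried; the forward orientation wins ties.  Reads
    shorter than 30 nt, longer than the template, or whose best identity
    falls below ``min_identity`` raise :class:`UnalignableReadError` —
    reads with indels relative to the template end up here by design.
    """
    read = read.upper()
    template = template.upper()
    if len(read) < MIN_READ_LENGTH:
        raise UnalignableReadError(f"read length {len(read)} < {MIN_READ_LENGTH}")
    if len(read) > len(template):
        raise UnalignableReadError("read longer than template")
    t_arr = np.frombuffer(template.encode(), dtype=np.uint8)
    fwd = np.frombuffer(read.encode(), dtype=np.uint8)
    rev = np.frombuffer(reverse_complement(read).encode(), dtype=np.uint8)
    off_f, m_f = _best_offset(fwd, t_arr)
    off_r, m_r = _best_offset(rev, t_arr)
    if m_r > m_f:
        aln = Alignment(off_r, m_r / len(read), m_r, True)
    else:
        aln = Alignment(off_f, m_f / len(read), m_f, False)
    if aln.identity < min_identity:
        raise UnalignableReadError(
            f"best identity {aln.identity:.2f} < {min_identity:.2f}")
    return aln


# ---------------------------------------------------------------------------
# read cleaning
# ---------------------------------------------------------------------------

EDIT_REASONS = ("N_repair", "off_target_revert", "non_degenerate_revert", "short_read_fill")


@dataclass(frozen=True)
class Edit:
    """One base- or codon-level repair applied during cleaning (1-based nt position)."""

    position: int
    original: str
    replacement: str
    reason: str


@dataclass
class CleanedRead:
    well_id: str
    cleaned_sequence: str
    edits: list[Edit] = field(default_factory=list)
    #: target amino-acid positions whose codon was filled from the template
    #: or contained repaired N's — parent calls there are low confidence
    low_confidence_positions: tuple[int, ...] = ()
    alignment: Alignment | None = None


def clean_read(read: str, design: LibraryDesign, well_id: str = "") -> CleanedRead:
    """Clean a raw Sanger read against the library design.

    The cleaned sequence equals the template everywhere except possibly at
    target codons carrying a codon from the degenerate expansion:

    1. the read is placed on the template (both orientations, ungapped);
    2. every N is replaced by the template base (``N_repair``);
    3. every mismatch outside a target codon is reverted to the template
       base (``off_target_revert`` — these are treated as sequencing
       errors, not real mutations);
    4. a target codon whose observed value is neither the template codon
       nor in the degenerate expansion is reverted wholesale
       (``non_degenerate_revert``); per-base repair could fabricate a
       legal codon that was never sequenced;
    5. template positions not covered by the read are filled from the
       template (``short_read_fill``).

    Target codons that were filled or contained N's are flagged low
    confidence: filling silently converts missing coverage into a parent
    call.  Cleaning is idempotent — a cleaned read cleans to itself with
    zero edits.
    """
    template = design.template_cds
    aln = align_to_template(read, template)
    placed = reverse_complement(read) if aln.reverse_complemented else read.upper()
    start, end = aln.offset, aln.offset + len(placed)

    seq = list(template)
    edits: list[Edit] = []
    covered = np.zeros(len(template), dtype=bool)
    covered[start:end] = True
    seq[start:end] = list(placed)

    target_nt = {}
    for p in design.target_positions:
        for j in range(3 * (p - 1), 3 * p):
            target_nt[j] = p

    low_conf: set[int] = set()

    for j in range(len(template)):
        if not covered[j]:
            if seq[j] != template[j]:  # pragma: no cover - defensive
                seq[j] = template[j]
            edits.append(Edit(j + 1, "-", template[j], "short_read_fill"))
            if j in target_nt:
                low_conf.add(target_nt[j])
            continue
        if seq[j] == "N":
            edits.append(Edit(j + 1, "N", template[j], "N_repair"))
            seq[j] = template[j]
            if j in target_nt:
                low_conf.add(target_nt[j])
        elif seq[j] != template[j] and j not in target_nt:
            edits.append(Edit(j + 1, seq[j], template[j], "off_target_revert"))
            seq[j] = template[j]

    legal = design.codon_set
    for p in design.target_positions:
        lo = 3 * (p - 1)
        codon = "".join(seq[lo:lo + 3])
        tmpl_codon = template[lo:lo + 3]
        if codon != tmpl_codon and codon not in legal:
            edits.append(Edit(lo + 1, codon, tmpl_codon, "non_degenerate_revert"))
            seq[lo:lo + 3] = list(tmpl_codon)

    return CleanedRead(well_id, "".join(seq), edits, tuple(sorted(low_conf)), aln)


# ---------------------------------------------------------------------------
# variant calling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantRecord:
    """Observed codon and residue at one library position in one well."""

    well_id: str
    position: int
    codon_observed: str
    amino_acid: str
    template_residue: str
    is_parent: bool
    is_synonymous: bool = False
    low_confidence: bool = False
    n_observations: int = 1

    @property
    def variant_key(self) -> str:
        return f"{self.template_residue}{self.position}{self.amino_acid}"


def call_variant(cleaned: CleanedRead, design: LibraryDesign) -> list[VariantRecord]:
    """Report the codon and translation at every target position.

    Positions carrying the exact template codon are parent calls; a
    non-template codon translating to the template residue is flagged
    synonymous rather than merged with parent.
    """
    records = []
    for p in design.target_positions:
        codon = cleaned.cleaned_sequence[3 * (p - 1): 3 * p]
        tmpl_codon = design.template_codon(p)
        aa = translate(codon)
        tmpl_aa = translate(tmpl_codon)
        is_parent = codon == tmpl_codon
        records.append(VariantRecord(
            well_id=cleaned.well_id,
            position=p,
            codon_observed=codon,
            amino_acid=aa,
            template_residue=tmpl_aa,
            is_parent=is_parent,
            is_synonymous=(not is_parent) and aa == tmpl_aa,
            low_confidence=p in cleaned.low_confidence_positions,
        ))
    return records


def collapse_unique(records: Iterable[VariantRecord]) -> pd.DataFrame:
    """Collapse per-well records to a unique-variant table.

    One row per (position, amino acid) with observation counts summed,
    ordered by position then residue.  Parent observations collapse like
    any other residue; callers wanting mutants only filter on
    ``is_parent``.
    """
    rows = [
        {
            "position": r.position,
            "amino_acid": r.amino_acid,
            "template_residue": r.template_residue,
            "variant_key": r.variant_key,
            "is_parent": r.amino_acid == r.template_residue and r.is_parent,
            "n_observations": r.n_observations,
        }
        for r in records
    ]
    if not rows:
        return pd.DataFrame(columns=[
            "position", "amino_acid", "template_residue", "variant_key",
            "is_parent", "n_observations"])
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["position", "amino_acid"], as_index=False)
        .agg(template_residue=("template_residue", "first"),
             variant_key=("variant_key", "first"),
             is_parent=("is_parent", "any"),
             n_observations=("n_observations", "sum"))
        .sort_values(["position", "amino_acid"], kind="mergesort")
        .reset_index(drop=True)
    )
    return out


def analyse_reads(reads_fasta: str | Path, design: LibraryDesign) -> pd.DataFrame:
    """Clean and call every read in a FASTA of per-well Sanger reads.

    Record ids are taken as well ids.  Unalignable reads are skipped with
    a warning.  Returns the per-well variant table (one row per target
    position per well).
    """
    rows = []
    for rec in SeqIO.parse(str(reads_fasta), "fasta"):
        try:
            cleaned = clean_read(str(rec.seq), design, well_id=rec.id)
        except UnalignableReadError as exc:
            logger.warning("read %s unalignable: %s", rec.id, exc)
            continue
        for v in call_variant(cleaned, design):
            rows.append({
                "well_id": v.well_id,
                "position": v.position,
                "codon": v.codon_observed,
                "amino_acid": v.amino_acid,
                "variant_key": v.variant_key,
                "is_parent": v.is_parent,
                "flags": ";".join(
                    f for f, on in
                    [("synonymous", v.is_synonymous), ("low_confidence", v.low_confidence)]
                    if on),
            })
    return pd.DataFrame(rows, columns=[
        "well_id", "position", "codon", "amino_acid", "variant_key",
        "is_parent", "flags"])
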