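"""Sequence-function statistics for a screened variant library.

Implements the analytics layer applied after product quantification and
variant identification: relative product profiles and their Euclidean
distance to the parent enzyme's profile, a per-position plasticity score
(histogram intersection between the observed mutant-residue distribution
and a uniform one), amino-acid occurrence tables, and the
coupon-collector style probability that a library of equiprobable codons
is covered by a given number of picked colonies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.special import comb

from .variantseq import LibraryDesign, expand_degenerate_codon


class NoProductError(ValueError):
    """All titres are zero: the variant is inactive and has no profile."""


# ---------------------------------------------------------------------------
# product profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProductProfile:
    """Relative product distribution of one enzyme variant.

    ``fractions`` maps compound name to its share of the total product;
    shares are non-negative and sum to 1.
    """

    fractions: Mapping[str, float]

    def __post_init__(self) -> None:
        fr = dict(self.fractions)
        if any(v < 0 for v in fr.values()):
            raise ValueError("fractions must be non-negative")
        total = sum(fr.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"fractions sum to {total}, expected 1")
        object.__setattr__(self, "fractions", fr)

    def __getitem__(self, compound: str) -> float:
        return self.fractions.get(compound, 0.0)


def relative_profile(titres: Mapping[str, float]) -> ProductProfile:
    """Normalize absolute titres (or peak areas) to fractions summing to 1.

    Compounds with zero titre are retained at fraction 0.  An all-zero
    input has no defined profile and raises :class:`NoProductError`.
    """
    if any(v < 0 for v in titres.values()):
        raise ValueError("titres must be non-negative")
    total = float(sum(titres.values()))
    if total <= 0:
        raise NoProductError("all titres zero: inactive variant has no product profile")
    return ProductProfile({c: float(v) / total for c, v in titres.items()})


def euclidean_distance(p: ProductProfile, ref: ProductProfile) -> float:
    """Euclidean distance between two product profiles.

    Computed over the union of compound keys, absent compounds reading as
    fraction 0.  A distance of 0 means the two variants have the same
    product distribution; the larger the distance, the further the
    variant's profile has moved from the reference.
    """
    keys = set(p.fractions) | set(ref.fractions)
    return math.sqrt(sum((p[k] - ref[k]) ** 2 for k in keys))


# ---------------------------------------------------------------------------
# plasticity score
# ---------------------------------------------------------------------------

@dataclass
class PositionObservations:
    """Amino acids observed among sequenced active variants at one position."""

    position: int
    counts: dict[str, int] = field(default_factory=dict)
    template_residue: str = ""

    def add(self, residue: str, n: int = 1) -> None:
        self.counts[residue] = self.counts.get(residue, 0) + n


def plasticity_score(obs: PositionObservations, design: LibraryDesign) -> float:
    """Histogram intersection of observed mutant residues with uniformity.

    Let K be the number of distinct residues encodable by the degenerate
    codon (11 for NBT) and f the frequency distribution of observed
    *non-parent* residues over that support.  The score is

        score = sum_a min(f_a, 1/K)

    so a position where mutants were observed uniformly across all K
    residues scores 1, and a position with no mutant observations scores
    0.  Restricting f to non-parent residues is what makes the zero
    endpoint attainable: a position where only the template residue was
    ever seen has accommodated no substitutions.
    """
    support = sorted(design.residue_set - {"*"})
    k = len(support)
    if k == 0:
        raise ValueError("degenerate codon encodes no residues")
    mutant_counts = {
        aa: n for aa, n in obs.counts.items()
        if aa != obs.template_residue and aa in set(support)
    }
    total = sum(mutant_counts.values())
    if total == 0:
        return 0.0
    uniform = 1.0 / k
    score = sum(min(n / total, uniform) for n in mutant_counts.values())
    return float(min(score, 1.0))  # guard accumulated rounding at the endpoint


def observations_from_variants(variants: pd.DataFrame,
                               design: LibraryDesign) -> dict[int, PositionObservations]:
    """Aggregate a variant table into per-position residue counts.

    Expects the column layout produced by :func:`terpscreen.variantseq.collapse_unique`
    or ``analyse_reads`` (columns ``position``, ``amino_acid``, optional
    ``n_observations``).  Parent rows are included in counts; the
    plasticity score itself discards them.
    """
    out: dict[int, PositionObservations] = {}
    weights = variants["n_observations"] if "n_observations" in variants else None
    for i, row in variants.reset_index(drop=True).iterrows():
        p = int(row["position"])
        if p not in out:
            out[p] = PositionObservations(p, {}, design.template_residue(p))
        out[p].add(row["amino_acid"], int(weights.iloc[i]) if weights is not None else 1)
    return out


# ---------------------------------------------------------------------------
# amino-acid occurrence
# ---------------------------------------------------------------------------

def aa_occurrence(observations: Iterable[PositionObservations]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Relative amino-acid occurrence per position and across all positions.

    Returns ``(per_position, global_table)``.  ``per_position`` has columns
    position, amino_acid, count, fraction, percent (percent rounded to
    0.1); ``global_table`` has amino_acid, count, fraction, percent.
    Positions with no observations are omitted.
    """
    rows = []
    for obs in observations:
        total = sum(obs.counts.values())
        if total == 0:
            continue
        for aa, n in sorted(obs.counts.items()):
            rows.append({"position": obs.position, "amino_acid": aa,
                         "count": n, "fraction": n / total})
    per_pos = pd.DataFrame(rows, columns=["position", "amino_acid", "count", "fraction"])
    if not per_pos.empty:
        per_pos["percent"] = (per_pos["fraction"] * 100).round(1)
        glob = per_pos.groupby("amino_acid", as_index=False)["count"].sum()
        grand = glob["count"].sum()
        glob["fraction"] = glob["count"] / grand
        glob["percent"] = (glob["fraction"] * 100).round(1)
        glob = glob.sort_values("amino_acid", kind="mergesort").reset_index(drop=True)
    else:
        per_pos["percent"] = pd.Series(dtype=float)
        glob = pd.DataFrame(columns=["amino_acid", "count", "fraction", "percent"])
    return per_pos, glob


# ---------------------------------------------------------------------------
# library coverage
# ---------------------------------------------------------------------------

def coverage_probability(n_colonies: int, n_codons: int) -> tuple[float, float]:
    """Probability that picked colonies cover an equiprobable codon library.

    With K equiprobable codons and n picked colonies,

    * ``per_variant`` — probability a given codon appears at least once:
      ``1 - ((K-1)/K)**n``;
    * ``all_variants`` — probability every codon appears at least once,
      by inclusion-exclusion:
      ``sum_j (-1)^j C(K,j) ((K-j)/K)**n``.

    Screening 40 colonies of a 12-codon (NBT) library gives per-variant
    coverage 0.969 (> 0.95), the sampling depth used per library in the
    screen.
    """
    if n_colonies < 0:
        raise ValueError("n_colonies must be >= 0")
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    k, n = n_codons, n_colonies
    per_variant = 1.0 - ((k - 1) / k) ** n
    all_variants = float(sum(
        (-1) ** j * comb(k, j, exact=True) * ((k - j) / k) ** n
        for j in range(k + 1)
    ))
    return per_variant, min(max(all_variants, 0.0), 1.0)


# ---------------------------------------------------------------------------
# convenience: scoring a whole screen
# ---------------------------------------------------------------------------

def score_screen(variants: pd.DataFrame,
                 profiles: Mapping[str, Mapping[str, float]],
                 reference: Mapping[str, float],
                 design: LibraryDesign) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join variant calls with product profiles and score everything.

    ``profiles`` maps well id to compound titres (or normalized areas);
    ``reference`` is the parent enzyme's titres.  Returns
    ``(distance_table, plasticity_table)``: per-well Euclidean distance to
    the parent profile, and per-position plasticity scores over the
    non-parent variant calls.  Wells with all-zero profiles (inactive)
    are omitted from the distance table.
    """
    ref_profile = relative_profile(dict(reference))
    dist_rows = []
    for well_id, titres in profiles.items():
        calls = variants[variants["well_id"] == well_id] if "well_id" in variants else variants
        key = ";".join(sorted(calls.loc[~calls["is_parent"], "variant_key"])) or "parent"
        try:
            prof = relative_profile(dict(titres))
        except NoProductError:
            continue
        dist_rows.append({"well_id": well_id, "variant_key": key,
                          "euclidean_distance": round(euclidean_distance(prof, ref_profile), 3)})
    dist = pd.DataFrame(dist_rows, columns=["well_id", "variant_key", "euclidean_distance"])

    active_wells = set(dist["well_id"])
    mutant_calls = variants[variants["well_id"].isin(active_wells)] if "well_id" in variants else variants
    obs = observations_from_variants(mutant_calls, design)
    plas = pd.DataFrame(
        [{"position": p, "plasticity_score": round(plasticity_score(o, design), 3)}
         for p, o in sorted(obs.items())],
        columns=["position", "plasticity_score"])
    return dist, plas
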