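# terpscreen

Analytics for high-throughput screening of monoterpene-synthase variant
libraries. Directed-evolution screens of monoterpene cyclase/synthase
(mTC/S) enzymes grow hundreds of clones in 96-well plates, extract the
products into an organic overlay, and measure each well by fast GC-MS.
`terpscreen` implements the computational side of such a screen for the
scientist running it: targeted peak quantification per well, calling of
active variants against solvent-background thresholds, cleaning and
validation of per-well Sanger reads against a degenerate-codon library
design, and sequence–function scoring — plus a synthetic-data generator
with planted ground truth, so the whole pipeline can be exercised and
validated without an instrument.

## What it computes

**Chromatography.** Peaks are picked on the total ion chromatogram (TIC)
as prominent local maxima, integrated by the trapezoidal rule between
flanking valleys, identified by retention-time window plus a primary-ion
check against a compound reference table, and normalized to the
internal-standard (sec-butylbenzene) peak area. Compounds co-eluting with
the dodecane solvent peak are masked and never quantified.

**Plate screen.** A well is *active* when at least one non-masked
targeted compound exceeds its threshold, the mean background signal of
the plate's solvent-only control wells. Fold changes are taken per
compound against the median of the plate's own parent-enzyme controls;
libraries are summarized by median and quartiles.

**Sequence analysis.** A degenerate codon such as NBT (12 codons, 11
amino acids, Ser twice) defines the legal mutation set. Raw reads are
cleaned: N's and off-target mismatches revert to the template, target
codons outside the degenerate expansion revert wholesale, and short reads
are filled from the template (filled target codons are flagged low
confidence). Cleaned reads yield per-position variant calls such as
`C335A`.

**Scoring.** For each active variant the relative product profile
(fractions summing to 1) is compared with the parent's by Euclidean
distance, `d(p, ref) = sqrt(Σ_c (p_c − ref_c)²)`, where 0 means an
identical product distribution. Each mutated position gets a *plasticity
score*: the histogram intersection `Σ_a min(f_a, 1/K)` between the
observed mutant-residue distribution `f` and the uniform distribution
over the `K` residues the degenerate codon encodes — 1 for perfectly
uniform tolerance, 0 when no mutants are observed. Library coverage uses
the closed forms `1 − ((K−1)/K)^n` per codon and inclusion–exclusion for
full coverage.

## Worked example

Simulate one plate carrying a 40-well NBT library at position 335, run
the full pipeline, and score it:

```python
import terpscreen as ts
from terpscreen.simulate import SimulationConfig, TARGETED_COMPOUNDS

cfg = SimulationConfig(seed=42)
sim = ts.simulate_screen({"lib335": 335}, 40, cfg)
layout = sim.layouts["P1"]
refs = list(cfg.compound_table)
wells = {w: ts.process_well(c, refs, role=layout.well_assignments[w][0])
         for w, c in sim.chromatograms.items()}
solvent = [wells[w] for w in layout.wells_with_role("solvent_control")]
thresholds = ts.compute_thresholds(solvent, TARGETED_COMPOUNDS)
table = ts.analyse_plate(layout, wells, thresholds)
print(ts.summarize_screen(table).round(2).to_string(index=False))
```

which prints (seed 42):

```
        compound  n  median  lower_quartile  upper_quartile
    alpha-pinene 40    1.05            0.78            1.53
     beta-pinene 40    1.12            0.82            1.62
        limonene 40    1.30            0.80            1.83
sabinene/myrcene 40    1.12            0.70            1.44
```

38 of the 40 sample wells are called active (the other two drew inactive
variants). The fold-change medians near 1 say this library's typical
variant produces about as much of each product as the parent enzyme,
with quartiles spanning roughly 0.7–1.8× — the same plate-level view a
real screen uses to rank libraries. Reads from the same simulation
decode each well's codon, e.g.

```python
cleaned = ts.clean_read(sim.reads[0][1], sim.design, sim.reads[0][0])
ts.call_variant(cleaned, sim.design)   # -> C335I at position 335, etc.
```

and `ts.coverage_probability(40, 12)` returns `(0.9692, 0.6732)`: 40
picked colonies give each of the 12 NBT codons a 96.9% chance of being
seen at least once. Aggregating the active wells' calls at position 335
and scoring gives a plasticity score of `0.671` for this simulated
library — a position tolerating many substitutions.

The same stages are available from the shell via the `terpscreen` CLI
(`simulate screen`, `detect`, `screen call`, `screen summarize`,
`metrics score`); each subcommand reads and writes plain CSV/TSV/FASTA.

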