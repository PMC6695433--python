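# Methods

## Scope and model

`terpscreen` models a plate-based *in vivo* screen of a monoterpene
synthase saturation library. Each well holds one clone whose enzyme
variant converts geranyl diphosphate into a mixture of monoterpenes; the
organic overlay is measured by fast GC-MS (4.6-minute run, 5 spectra/s in
the simulator), and each clone's gene carries one degenerate codon
substitution at a designed position. The package covers everything
downstream of the instrument and the sequencing service: peak
quantification, active calling, plate analytics, read cleaning, variant
calling and sequence–function scoring. Liquid handling, culture
conditions, instrument control and base calling are out of scope.

## Chromatography

Peak picking operates on the total ion chromatogram only. Apexes are
local maxima with prominence ≥ `min_prominence` (default 1000 counts,
matched to the simulator's signal scale where the internal-standard apex
is ~5·10⁵ counts) and width ≥ 3 scans; integration bounds extend to the
nearest flanking local minima ("valley to valley") and areas are
trapezoidal integrals in counts·minute. Identification requires the apex
inside the compound's retention-time window (default half-width 0.05 min,
per-compound configurable — a tight window consistent with a 4.6-minute
method) *and* that, among the reference's primary + qualifier ions
(m/z matched within ±0.3), the primary ion is the most intense in the
apex-scan spectrum. Assignment is a greedy minimum-|ΔRT| partial
matching: each compound gets at most one peak and each peak one compound,
ties broken by reference-table order. β-myrcene and sabinene co-elute
under this method and are carried as one composite reference entry
(`sabinene/myrcene`); terpinolene, linalool, α-terpineol and geraniol are
flagged solvent-masked (they co-elute with dodecane) and are never
assigned or thresholded.

Normalized areas are peak area ÷ internal-standard area, which cancels
injection-volume and extraction variation; a well without a usable
internal-standard peak is marked failed and excluded everywhere
downstream, never imputed. Per-compound thresholds are the arithmetic
mean normalized area over the plate's solvent-only wells, computed per
plate because controls sit on every plate.

## Plate screen

A well is active iff some non-masked targeted compound's normalized area
is strictly greater than its threshold. Fold change divides a well's
normalized area by the median over the plate's parent-control wells;
cross-plate pooling is off by default because growth and induction vary
between plates. Sentinels: parent median 0 with positive sample → +inf
(flagged), 0/0 → 1 (flagged); infinities are excluded from quantiles and
counted separately. Quantiles use linear interpolation between order
statistics (the numpy default), fixed here as the documented convention.

## Sequence analysis

Coordinates are 1-based amino-acid positions; codon *i* is bases
3i−2…3i. Reads are placed on the template by exhaustive ungapped offset
search in both orientations; best identity < 70% (or indels, which
ungapped placement cannot absorb) → unalignable and skipped. Cleaning
then (1) replaces N's with the template base, (2) reverts mismatches
outside target codons, (3) reverts a target codon wholesale when it is
neither the template codon nor in the degenerate expansion — per-base
repair could fabricate a legal codon never actually sequenced — and
(4) fills uncovered positions from the template. Filling converts
missing coverage into parent calls, so filled or N-containing target
codons are flagged low-confidence. Cleaning is idempotent, and the
cleaned sequence can differ from the template only at target codons by
expansion members — both properties are tested. Synonymous codons at a
target position (e.g. GCT vs template GCA) are reported as non-parent
with a synonymous flag rather than silently merged. Translation uses the
standard genetic code via Biopython; the test suite keeps an independent
hand-entered code table as the oracle.

## Scoring

Product profiles are titre fractions summing to 1; an all-zero well has
no profile (inactive). The Euclidean distance runs over the union of
compound keys so profiles reporting different product sets remain
comparable, and fractions (not absolute titres) are used because a
distance of zero must mean an identical product *distribution*.

The plasticity score is the histogram intersection between the observed
distribution of **non-parent** residues and the uniform distribution
over the K residues the degenerate codon encodes (K = 11 for NBT):
`Σ_a min(f_a, 1/K)`. Restricting to non-parent residues is an
interpretive choice: it is the minimal convention that reaches both
stated endpoints — exactly 0 when no mutants were observed (an
intersection including the parent could never return 0) and exactly 1
for uniform mutant observations.

Coverage probabilities assume equiprobable codons: per-variant
`1 − ((K−1)/K)^n`, all-variants by inclusion–exclusion. At the screen's
sampling depth of 40 colonies per 12-codon library the per-variant
probability is 0.9692 (> 0.95); a Monte-Carlo oracle cross-checks the
inclusion–exclusion sum in the tests.

## Synthetic data

The generator is a pure function of `(config, seed)` (numpy
`default_rng`); a fixed seed reproduces byte-identical chromatograms and
reads. Chromatograms are sums of Gaussian peaks (σ = 0.008 min, ~2.4
scan intervals, so trapezoidal integration recovers planted areas to
well under 1%) at compound-specific retention times, a dominant dodecane
solvent peak (area 2·10⁵ counts·min, σ = 0.05 min) under which the
masked analytes elute, a fixed-area internal-standard peak (10⁴), and
half-normal baseline noise (σ = 50 counts) on a baseline ion. Each
compound's signal sits 60% on its primary ion and 40% split over its
qualifiers — deliberately minimal spectral realism, just enough to
exercise the identification rule; electron-impact fragmentation is not
modelled.

Titre noise is log-normal: a shared per-well factor (σ = 0.2, mimicking
growth/induction variation), a per-compound factor (σ = 0.1), and a
small independent factor on the internal standard (σ = 0.05, since it is
spiked at dilution). Variant product profiles derive from the parent's
peak areas reshaped by log-normal factors (σ = 0.5); 15% of mutant
variants are inactive (all-zero). Reads are the template with the
assigned codon substituted, truncated to a window (start uniform in
nt 900–1000, end in 1700–1800, covering all 16 target codons), then
corrupted by per-base substitutions (0.1%) and N's (0.2%).

Two idealizations matter for interpreting passing tests. First, the
generator plants no chemical background at the targeted analytes'
retention times, so solvent-well thresholds come out zero and the active
call degenerates to "any detected peak"; the threshold logic against
nonzero backgrounds is covered by unit tests with constructed wells, but
the round trips do not probe threshold calibration against real matrix
background. Second, the template CDS is synthetic: a deterministically
generated 600-codon ORF carrying the parent enzyme's known residues
(C335, I337, G444, A557, M559, A560, Q561, F562) at their real
positions. Real screens supply their own template FASTA. The default
design diversifies 16 positions (335–338, 443–448, 557 and 559–563) with
NBT; the two conserved positions 339 and 558 are untouched.

## Numerical choices and limitations

Time is minutes throughout; m/z dimensionless. Reported percentages are
rounded to 0.1 and distances to 3 decimals, with full precision kept
internally. The plasticity score clamps at 1.0 against accumulated
floating-point rounding. mzXML is read via pyteomics with retention
times converted to minutes whatever the file's unit; the plain TSV
dialect (`scan_time_min`, `mz`, `intensity`, with a zero row registering
an empty scan) is provided for fully text-based pipelines and parses to
the same chromatogram. Indel-carrying reads are rejected rather than
realigned; qualifier-ion *ratios* are not checked (only the
primary-most-intense rule); no quantitative calibration to absolute
titres is attempted — the screen's outputs are relative (fold changes
and fractions) by design.
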