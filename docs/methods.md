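# Methods

## Model and procedure

The package tests whether catalogued gene mutations sit unusually close to a
short DNA motif, and whether motif-proximal mutations are enriched for a
functional annotation (splice-site status).

**Context windows.** Each mutation contributes the reference (pre-mutation)
sequence of the window `[pos − f, pos + f]`, 1-based inclusive, default
f = 5 (11 bp).  Indels are anchored on their leftmost affected base
(VCF-style left anchor); the catalogue position is taken to be that anchor.
Windows at the reference edge are truncated and flagged, never dropped.
Motifs are read on the reference strand by default; a `BOTH_STRANDS` mode
also matches the reverse complement without double-counting palindromic
sites.  Before any statistics, every catalogued SNV ref allele is audited
against the loaded FASTA; the pipeline refuses to proceed on mismatch unless
explicitly overridden.

**Observed statistic.** For motif m of length l (default l = 3; all 4^l
motifs are scored), the default statistic is `WINDOWS_WITH_HIT`: the number
of windows containing at least one overlap-allowed occurrence of m.  This
counts *mutations near the motif*, matching headline fractions of the form
"x% of mutations have the motif within ±5 bp".  `TOTAL_OCCURRENCES` (sum of
occurrence counts) is available as an option; for untruncated 11-bp windows
its 64-motif sum is exactly 9 per window, a conservation identity used as a
self-check.

**Randomized null.** The default null (`POSITIONAL_RESAMPLE`) redraws, at
each of N iterations (default N = 10,000), the same number of mutation
positions uniformly *without replacement* from the eligible positions of
the supplied gene region (positions whose full window fits), re-extracts
windows and recomputes the statistic.  All 4^l motifs are counted on each
draw — one randomization, 64 statistics — so motif ranks share a common
null.  The empirical p-value is `#{draws ≥ observed} / N`; a zero count is
displayed as `< 1/N` (an optional `(count+1)/(N+1)` estimator is exposed
for downstream use).  Significance applies a Bonferroni correction across
the 4^l motifs at α = 0.05 by default (Benjamini–Hochberg available).  The
published procedure this reconstructs did not state its resampling unit;
a second null, `DINUCLEOTIDE_SHUFFLE` (Altschul–Erikson Eulerian-path
shuffle of each observed window, preserving dinucleotide composition and
endpoints), is provided as a sensitivity analysis.  Both are labelled
reconstructions, not a certified published algorithm.

**Recurrence.** The unique-mutation key is the DNA-level tuple
`(contig, position, ref, alt)`; a protein-level collapse would need a
transcript model the catalogue format does not carry.  Both analyses — full
catalogue and recurrence-collapsed — are supported and selected by a flag,
since recurrent reports can inflate positional clustering.

**Enrichment.** Motif flag × splicing annotation is tested on the disjoint
2×2 layout (flagged/unflagged × splicing/other) with a two-sided Fisher
exact test (point-probability summation; mid-p variant by flag).  The
overlapping "flagged splicing fraction vs whole-catalogue splicing
fraction" presentation is reported descriptively alongside, because no
exact test is valid on overlapping margins.  UNKNOWN annotations count as
non-splicing (conservative toward enrichment) and are tallied separately.
Both the sample odds ratio ad/bc (+∞ on a zero cell) and the
Haldane–Anscombe (+0.5) variant are reported.  Case-vs-control window sets
are compared by the difference in flagged fractions with a two-sided
label-permutation p-value.

## Synthetic data generator

The generator emulates a single-gene mutation study: an i.i.d. background
sequence with a GC-content parameter, `n_planted` non-overlapping copies of
a planted motif overwritten at random positions, and mutation positions
sampled without replacement with weight (1 + β) at positions whose window
would contain a planted copy and weight 1 elsewhere.  Annotation labels are
assigned independently of position sampling: motif-proximal mutations are
SPLICING with probability γ, others with baseline p₀ — so positional
clustering (β) and label association (γ) are separately tunable.  Recurrent
rows (same DNA change, new id) are appended to make up a chosen fraction of
the catalogue.  One seed drives every choice; fixtures are byte-identical
across regenerations.

Defaults mirror the study conditions the package targets: a 5,000 bp
region at GC 0.45, planted motif `GTA` (12 copies), 92 unique mutations
with recurrence 44/136 (catalogue of 136 rows), β = 15, γ = 0.5,
p₀ = 0.10, 85% de novo, 74% female.  Under these defaults the planted
motif is recovered as the top-ranked Bonferroni-significant motif and the
flagged fraction lands near one third of the catalogue.

What the generator deliberately does **not** model: exon/intron structure
and ascertainment toward coding/splice regions, trinucleotide mutational
signatures, Markov-dependent background composition, and indels (all
synthetic variants are SNVs).  Tests passing on synthetic data therefore
validate the machinery — coordinate handling, counting, null calibration,
recovery — not the biological claim on any real catalogue.

A consequence worth stating: in an i.i.d. background a 3-mer occurs by
chance about once per 64 bp, so a 5,000 bp region carries ~80 background
copies of the planted motif alongside the planted ones.  Background copies
are not β-boosted, which dilutes planted-signal recovery at moderate β:
at β = 10 with 100 mutations the planted motif is top-ranked in ~83% of
datasets but survives the 64-motif Bonferroni correction in only ~55–60%.
Corrected-significance power at that operating point is a property of the
i.i.d. background model, not of the scan; the default β = 15 with a 136-row
catalogue sits comfortably above it.

## Numerical and design choices

- **Eligible null positions** are those with a full untruncated window;
  the generator samples mutations from the same set, keeping observed and
  null geometry identical.  An optional BED mask can restrict eligible
  space to exon/splice regions when real catalogues are ascertained that
  way.
- **Rejection rule** is p ≤ α on the (possibly corrected) empirical
  p-value.  Because the statistic is integer-valued the permutation p is
  discrete and stochastically ≥ uniform: measured per-motif type-I error
  at α = 0.05 runs ~0.03–0.05, i.e. valid and slightly conservative.
- **Tie-breaking** in motif ranking: corrected p, then observed statistic
  (descending), then lexicographic motif string.
- **k-mer counting** is vectorized (base-4 integer encoding of the region,
  one gather per draw); positions overlapping `N` never match.  A naive
  string-scanning oracle in the test suite recounts both observed
  statistics and individual null draws on tiny references.
- **Simulation sizes** in tests and the acceptance script: calibration uses
  500 datasets × 1,000 draws (tests) or 200 × 1,000 (script); recovery uses
  200 × 10,000 (tests) or 100 × 10,000 (script) — 10,000 draws because the
  Bonferroni threshold 0.05/64 ≈ 7.8×10⁻⁴ is unresolvable with a coarser
  null.  The study-scale analysis always runs at the full N = 10,000.
- **Degenerate inputs**: empty catalogues are rejected by the pipeline
  (warned on parse); all-zero contingency tables and empty window sets
  raise; a motif longer than its window counts zero with a warning;
  all-unknown sex yields an undefined (reported missing) fraction.

## Known limitations

- The positional-resample null treats the supplied region as uniformly
  mutable; real ascertainment (exome panels, clinical reporting) is not
  uniform.  Supply a BED mask to match the catalogue's ascertainment.
- Exact-match fixed-length motifs only; no IUPAC degeneracy, no EM-style
  motif discovery, and no variable-length scan.
- Single-gene scale by design: the reference is held in memory as one
  string and the null resamples within it.
- CNV-scale events are out of scope; the catalogue model covers SNVs and
  small indels.
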