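# Methods

`tiercall` infers endoribonuclease cleavage sites from strand-specific
5'-end RNA-seq coverage in a transient-inactivation (TIER-seq) design and
characterises them. This note records the model, the knobs that matter,
what the synthetic data does and does not emulate, and the design choices
made where more than one reasonable option existed.

## Experimental logic

RNase E cleavage leaves a 5'-monophosphorylated downstream fragment whose
first nucleotide is captured by 5'-end sequencing libraries. Comparing a
strain with active RNase E against a temperature-sensitive (TS) strain at
the non-permissive temperature (44 °C) turns every genuine cleavage
position into a position whose 5'-end count *drops* when the nuclease is
switched off. The design has twelve libraries: wild type (WT) and TS, each
at 30 °C and 44 °C, in biological triplicate. The 30 °C libraries, where
both strains have active RNase E, serve as a negative control and enter
the replicate QC, not the test; an optional control filter
(`require_null_at_30`, off by default) additionally discards called
sites whose strain ratio at 30 °C already reaches the fold-change
threshold.

Coordinates are 0-based half-open on the forward genomic strand
throughout; GFF3 (1-based inclusive) and SAM conversions happen only at
the file boundary. A site's coordinate is the first nucleotide of the
downstream fragment — the detected 5' end — so the 5-nt cleavage motif
spans positions [site−2, site+2] and the scissile bond sits between
columns 2 and 3 of the motif window.

## Per-position differential test

Let K_ij be the 5'-end count at position i in library j.

- **Normalisation** — median-of-ratios size factors:
  sf_j = median_i ( K_ij / (∏_v K_iv)^(1/m) ) over positions with positive
  counts in every library. If no such position exists the error suggests a
  pseudo-reference fallback rather than silently changing the estimator.
- **Coverage filter** — positions with a raw count ≥ 20 in at least one
  contrast (44 °C) library are tested. "At least one" is a deliberate
  reading: a strongly depleted site may have counts only in the WT
  libraries. The threshold and the rule are both configurable.
- **Dispersion** — per-position NB dispersion α (variance = μ + αμ²) by
  method of moments on normalised counts: within each replicate group,
  α_c = max(10⁻⁸, (s² − μ̄)/μ̄²), combined across groups by an average
  weighted with residual degrees of freedom (n_c − 1). Two choices matter
  for calibration and were validated on a dedicated null simulation
  (NB draws, 3 + 3 replicates, 2 × 10⁵ positions), not on the acceptance
  scenario: (i) the floor is applied per group *before* averaging, so an
  under-dispersed draw in one group cannot cancel overdispersion seen in
  another; (ii) the pipeline pools all four strain × temperature groups —
  dispersion is a property of the position, not of the condition — which
  doubles the residual df from 4 to 8 and improved both the null tail
  (P(p ≤ 10⁻⁴ and |FC| ≥ 3): 2.3 × 10⁻⁴ → 7 × 10⁻⁵) and the power to
  detect weak sites (0.77 → 0.84). No information is shared across
  positions: there is deliberately no dispersion shrinkage, trend fitting
  or independent-filtering optimisation.
- **Test** — per-position NB Wald test of TS-44 vs WT-44. Condition means
  are plug-in estimates on normalised counts with a pseudo-count of 0.5
  added to each condition *total* before the ratio (bounding log2FC when
  one side is all zero); log2FC = log2(mean_TS44 / mean_WT44); the
  standard error of the log ratio comes from the delta method under
  NB(μ, α): var(ln mean_c) ≈ (1/μ_c + α)/n_c. Two-sided normal p-values,
  Benjamini–Hochberg corrected across all filtered positions (step-up
  rule implemented directly and tested against both the brute-force
  definition and statsmodels).
- **Calling** — a position is a cleavage site iff
  log2FC ≤ −log2(3) and padj ≤ 0.05 (defaults). The direction flag can
  relax to |FC| ≥ 3 for users who want enrichment too; depletion-only is
  the default because cleavage sites lose signal when the nuclease is
  inactivated.

## Genomic classification

Same-strand overlap wins with precedence sRNA > 5'UTR > 3'UTR > CDS — the
sRNA-first rule is what lets 3'UTR-derived sRNAs, which nest inside their
host 3'UTR, form their own class. A site overlapping only opposite-strand
annotation is antisense (asRNA); a site overlapping nothing is intergenic
(IGR). Classification is total: every site gets exactly one label.

Per-gene densities use the full annotated transcript span
(5'UTR + CDS + 3'UTR) by default, configurable to CDS-only; the summary
median and mean (sites per kb) are taken over all genes, including genes
with zero sites. Metagene profiles anchor offset 0 at the first base of
the start codon or the last base of the stop codon, count sites per
transcript-orientation offset, and normalise each offset by the number of
genes whose annotated span covers it. An sRNA is "matched" when a
same-strand site falls on one of its first three nucleotides — the
operational signature of nuclease-dependent 5'-end maturation.

## Motif and context

The motif model is a position frequency matrix over the 5-nt windows
(2 nt upstream, 3 nt downstream of the cut, reverse-complemented for
minus-strand sites). Information content per column is
R(l) = max(0, 2 − (H(l) + e_n)) bits with H the entropy of observed
frequencies and e_n = (s − 1)/(2 n ln 2) = 3/(2 n ln 2) the small-sample
correction; the logo error bar totals 2·e_n. The IUPAC consensus adds
letters per column in descending frequency (ties alphabetical) until the
cumulative frequency reaches 0.9; the 0.9 cutoff is a single documented
knob chosen so that a half/half column reads as a two-letter code (R, W)
while a near-uniform column reads N.

AU-content profiles report the A/U fraction of a 10-nt sliding window at
offsets −50..+50 around sites, in transcript orientation.

The folding-energy profile uses a Nussinov-style interval dynamic
programme: the minimum, over nested structures with hairpin loops of at
least 3 unpaired nucleotides, of summed pair energies GC/CG −3, AU/UA −2,
GU/UG −1. This is a structure *score* in arbitrary units, not kcal/mol —
there are no stacking, loop-length or dangling-end terms — so the
supported readout is the profile's shape (reduced pairing potential
around cleavage sites), never absolute energies. The DP is validated
against exhaustive structure enumeration for short sequences, and
`mfe_profile` accepts any `f(sequence) -> energy` callable so a
thermodynamic folder can be plugged in. The symmetry of this energy table
is sequence *reversal*, not reverse complementation: the wobble pair G·U
maps under complementation to A·C, which cannot pair.

## Replicate QC

Pairwise Pearson correlation of *raw* first-base counts between all
library pairs, over positions with ≥ 10 reads summed across all
libraries, after removing positions above the per-library 99.99th
percentile (linear interpolation) in any library. Raw rather than
normalised or log counts: the filters are defined on coverage values
directly, and the report records every threshold actually applied so a
real-data run is auditable.

## Synthetic data

The generator emulates the twelve-library design on a toy genome:

| parameter | default | meaning |
|---|---|---|
| n_chromosomes × chrom_length | 2 × 200 kb | genome size |
| n_genes | 150 | gene models (5'UTR 60 nt, CDS 300–900 nt, 3'UTR 150 nt) |
| srna_fraction | 0.3 | genes carrying a 3'UTR-derived sRNA (80 nt, at the 3'UTR end) |
| n_planted_sites | 120 | cleavage sites written into the genome as RNWTT |
| class_weights | 0.7/0.1/0.1/0.1 | CDS / 5'UTR / 3'UTR / sRNA site placement |
| site_strength | 50 | 5'-end mean multiplier at a site with active nuclease |
| depletion_factor | 8 | site mean ratio WT-44 / TS-44 |
| background_rate | 2 | expected 5'-end reads per transcribed nt |
| expression_range | [0.2, 5] | per-gene log-uniform expression multiplier |
| nb_dispersion | 0.1 | NB α for all counts |
| leak_fraction | 0.02 | untranscribed background relative to background_rate |
| library_size_factors | log-uniform [0.5, 2] | per-library depth multipliers |

Counts are gamma-Poisson (NB) draws; α = 0 degenerates to Poisson. One
RNG stream per library keyed by (seed, library index), so adding a
library never perturbs the others; regeneration with the same seed is
byte-identical. Sites in the sRNA class are planted exactly at the sRNA's
annotated 5' end, emulating nuclease-dependent sRNA maturation and giving
the 5'-end matcher a ground truth. Site strength (50×) is a free knob:
nothing is claimed about the abundance distribution of real cleavage
fragments.

What the generator does *not* emulate — and what passing tests therefore
do not show about real data: read-level artefacts (no FASTQ, no
sequencing-error or mapping model), rRNA/poly(A) contamination, operon
structure, transcription-start-site heterogeneity, and realistic
abundance dynamic range. The last point matters for QC: with expression
spanning less than two decades, between-position variance is comparable
to NB noise and replicate r² sits far below the 0.82–0.99 seen in real
libraries, whose abundances span orders of magnitude. The QC test
therefore asserts the discriminating property (replicate pairs
out-correlate WT-44 vs TS-44 pairs) rather than an absolute r².

## Numerical choices and degenerate inputs

- BH adjustment preserves ties; there is no randomisation anywhere in the
  test path, and identical configuration + seed reproduces every output
  byte for byte.
- Sites within 2 nt of a chromosome end are skipped (with a warning) by
  the motif extractor; sites whose ±flank context leaves the chromosome
  are dropped from context profiles.
- Zero-length gene extents are skipped in density statistics; an empty
  site set is an explicit error for the class distribution and a zero
  summary for densities.
- The per-position dispersion floor (10⁻⁸) keeps the Wald variance finite
  for exactly-replicated counts.
- Soft-clipped 5' bases do not shift the counted position by default
  (the first *aligned* base counts); `count_soft_clipped_start` restores
  the clipped offset. Multi-mapped reads count once, at their primary
  alignment; MAPQ filtering defaults to 0.

## Problem sizes

The standard desk-scale scenario (defaults above) yields a count matrix
of roughly 4 × 10⁵ positions × 12 libraries and ~8,000 tested positions,
and runs end to end — simulation through motif and context profiles — in
well under a minute. The folding-energy profile caps the number of scored
sites (default 60 in the pipeline) because the O(n³) DP over 21 window
offsets dominates otherwise; the cap is a configuration field, not a
hard limit.

## Known limitations

- The NB Wald test is a deliberately transparent stand-in for shrinkage
  -based differential machinery; on real, full-genome data its exact site
  count will differ from tools with dispersion moderation, and borderline
  low-count sites are where they will disagree.
- The coverage-filter reading ("≥ 20 in at least one contrast library")
  and the plain TS-44 vs WT-44 contrast (rather than a
  strain × temperature interaction) are documented interpretations of an
  under-specified protocol; both are configurable.
- The fold-energy proxy ranks windows by pairing potential only; do not
  interpret its units.
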