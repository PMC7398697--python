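# tiercall

Nucleotide-resolution mapping of RNase E cleavage sites from
strand-specific 5'-end RNA-seq coverage (TIER-seq), for bacterial
transcriptomics: which positions does the endoribonuclease cut, in what
genomic context, with what sequence signature, and which small RNAs does
it mature?

RNase E, the principal RNA-turnover nuclease of Gram-negative bacteria,
leaves a 5'-monophosphorylated downstream fragment at every cut. 5'-end
libraries count those fragment starts per nucleotide. TIER-seq compares a
wild-type strain against a temperature-sensitive (TS) nuclease mutant
shifted to the non-permissive temperature: a genuine cleavage position is
one whose 5'-end signal is strongly *depleted* once the nuclease is
inactivated.

For each genomic position i and library j with count K_ij, `tiercall`:

1. normalises libraries with median-of-ratios size factors
   sf_j = median_i ( K_ij / (∏_v K_iv)^(1/m) );
2. filters to positions with coverage ≥ 20 in at least one 44 °C library;
3. fits a per-position negative-binomial model (variance μ + αμ², α by
   method of moments across replicate groups) and tests
   H₀: μ_TS44 = μ_WT44 with a Wald statistic on
   log2FC = log2(mean_TS44 / mean_WT44), delta-method standard error
   √((1/μ̂_TS + α)/n_TS + (1/μ̂_WT + α)/n_WT)/ln 2;
4. calls sites at log2FC ≤ −log2(3) and Benjamini–Hochberg padj ≤ 0.05;
5. classifies each site (CDS / 5'UTR / 3'UTR / sRNA / asRNA / IGR),
   computes per-gene site densities and metagene profiles, builds the
   cleavage consensus motif with small-sample-corrected information
   content (e_n = 3/(2 n ln 2)), profiles AU content and folding energy
   around sites, and matches sites to annotated sRNA 5' ends.

A synthetic-data generator produces a complete twelve-library dataset
(toy genome, gene models with UTRs and 3'UTR-derived sRNAs, planted
RN↓WUU cleavage sites, NB counts with library-size differences), so the
whole pipeline runs and is testable without any sequencing data.

## Worked example

```python
import tiercall as tc

ds = tc.simulate(seed=1)              # 2 x 200 kb, 150 genes, 120 planted sites
matrix = tc.build_count_matrix(ds.coverages, ds.truth.design)
tests, sf = tc.run_differential(matrix, ds.truth.design)
sites = tc.call_cleavage_sites(tests)
print(f"{len(sites)} sites called from {len(tests)} tested positions")

windows = tc.extract_site_windows(sites.table, ds.truth.genome)
model = tc.position_frequency_matrix(windows)
print("consensus:", tc.format_rna_consensus(tc.consensus_call(model)))

classified = tc.classify_sites(sites.table, ds.truth.annotation)
print(tc.class_distribution(classified).to_frame())

planted = ds.truth.site_keys()
tp = len(planted & sites.keys())
print(f"recovered {tp}/{len(planted)} planted sites; {len(sites) - tp} false calls")
```

prints

```
121 sites called from 8085 tested positions
consensus: RN↓WUU
       count  fraction
class
CDS       88  0.727273
5UTR      16  0.132231
asRNA      0  0.000000
3UTR       9  0.074380
IGR        0  0.000000
sRNA       8  0.066116
recovered 115/120 planted sites; 6 false calls
```

Of the 120 cleavage sites planted with 8-fold depletion, 115 are
recovered at the canonical thresholds with 6 false calls (5% of calls);
the consensus over the recovered windows reads RN↓WUU — purine, any base,
cut, then A/U followed by two uridines — and the class mix reflects the
planted placement weights.

The same analysis is available from the shell:

```bash
tiercall simulate --out data --seed 1
tiercall call --counts-dir data/counts --genome data/genome.fa \
              --gff data/annotation.gff3 --design data/design.tsv \
              --out run --fc 3 --padj 0.05 --min-cov 20
```

which writes per-position statistics, called sites (TSV + BED6), class
distribution, per-gene densities, metagene profiles, the motif (JSON +
logo-ready TSV), AU/folding-energy context profiles, the replicate QC
matrix and a machine-readable `summary.json` under `run/`.

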