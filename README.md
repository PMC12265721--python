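# hapmerscan

Candidate sex-chromosome identification from a **single diploid
individual's haplotype-resolved genome assembly**, using haplotype-specific
k-mer ("hap-mer") densities — no resequencing panels, no samples of known
sex, no external reference.

## The problem and the idea

In most vertebrates the sex-determining locus sits in a region of
suppressed recombination. Without recombination the two members of the
sex-chromosome pair (X/Y or Z/W gametologs) diverge, so in a
haplotype-resolved assembly of a heterogametic individual the sex pair
carries far more haplotype-specific sequence than any autosome pair.
Conversely, in some old systems the homogametic pair (XX/ZZ) shows
*reduced* diversity — a dearth of haplotype-specific sequence.

The detectable quantity is the **hap-mer**: a canonical k-mer (default
k=28) present in one haplotype assembly and absent from the other.  Across
autosomes the total hap-mer count of a sequence grows almost linearly with
its length (heterozygous variants accrue at a roughly uniform per-bp
rate), giving a tight regression background

&nbsp;&nbsp;&nbsp;&nbsp;`hapmer_occurrences ~ β0 + β1 · length_bp`

against which a sex pair stands out as a statistical outlier: an **excess**
(elevated divergence in the sex-limited region) or a **dearth** (depleted
heterozygosity on a homogametic pair).  Misassembled or misphased regions
produce the same signals, so the tool doubles as an assembly-curation aid;
every call is a candidate to scrutinise, not a significance claim.

The workflow is three steps: (1) count canonical k-mers in both haplotype
assemblies, (2) negate the two sets, keeping the k-mers unique to each
haplotype, and (3) find loci whose hap-mer densities deviate from the
autosomal background, using a pooled length regression (externally
studentized residuals, |t| > 3, with one refit round), per-haplotype Tukey
fences on hap-mer density, 1 Mb windowed density tracks, and a windowed
haplotype-identity proxy per homolog pair.  A pair is called
candidate-excess when a flagged member coincides with ≥3 consecutive
windows above the autosomal per-window fence; candidate-dearth when a
low-flagged member coincides with near-1 identity.  Low-identity window
runs localise the candidate sex-limited region; high-identity terminal
runs flag a candidate pseudoautosomal region (PAR).

Because real sex chromosomes cannot ship inside a test suite, the package
includes a first-class simulator that emits paired haplotype FASTAs with
known autosomal heterozygosity, a configurable sex pair (XY/ZW, PAR,
Y/W truncation, repeat expansion, "dearth" mode) and an exact truth file,
so every stage is testable offline.

## Worked example

Simulate an XY genome (10 autosome pairs of 0.5–3 Mb at 0.2% SNP
heterozygosity, one 10 Mb sex pair whose central 40% is diverged at 2%)
and analyse it:

```bash
hapmerscan simulate --sex-system XY --seed 11 -o sim/
hapmerscan run --hap1 sim/hap1.fa --hap2 sim/hap2.fa --no-min-len -o out/
```

which prints

```
candidate excess: chr11_h1 / chr11_h2
outputs in out
```

`out/summary.json` records the background fit and the call, e.g.

```
"fit": {"slope": 0.2199, "intercept": -217494.7, "r_squared": 0.9527, ...}
"pair_calls": [{"hap1_id": "chr11_h1", "hap2_id": "chr11_h2", "pair_flag": "excess"}]
```

The slope says the background accrues ≈0.22 hap-mer occurrences per bp
(≈ the per-window probability that a 28-mer spans a heterozygous site at
0.2% heterozygosity, 1−(1−0.002)^28 ≈ 0.05, counted on both haplotypes
plus indel edge effects); R² ≈ 0.95 is the tight autosomal correlation
(it exceeds 0.999 when the sex pair is excluded), and the single excess
call is the simulated sex pair.  `out/segments.tsv` localises its
sex-limited candidate region at 3–7 Mb, matching `sim/truth.json`
exactly, and `hapmerscan plot -o out/` renders the dot plot, density
boxplot and per-pair mirror plots.

Analysing a real assembly is the same `run` command pointed at your two
haplotype FASTAs (the 1 Mb contig filter is on by default for contig-level
input; `--mode greedy` scans homopolymer-compressed sequence for very
large genomes).

## Outputs

| file | content |
|---|---|
| `results.tsv` | per (haplotype, sequence): length, hap-mer occurrences, distinct hap-mers, density/Mb |
| `windows.bed` | 1 Mb hap-mer density track (BED, 0-based half-open) |
| `pairs.tsv`, `unpaired.tsv` | reciprocal-best k-mer containment pairing |
| `outliers.tsv` | studentized residuals, regression and boxplot flags |
| `pair_calls.tsv` | converged excess/dearth/none call per pair |
| `identity.bed` | windowed shared-k-mer fraction per pair and direction |
| `segments.tsv` | candidate sex-limited and PAR segments |
| `summary.json` | fit statistics, flags, calls, config echo |

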