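# Methods

## Model

A haplotype-resolved assembly of one diploid individual yields two
sequence sets, hap1 and hap2.  For a fixed k (default 28), every k-bp
window free of N contributes one canonical k-mer — the numerically
smaller of the window and its reverse complement under the 2-bit packing
A=0, C=1, G=2, T=3, most-significant base first — so counting is
strand-independent.  A **hap-mer** is a distinct canonical k-mer present
in one haplotype assembly and absent from the other; presence/absence is
what defines it, so a k-mer occurring five times in hap1 and never in
hap2 is one hap-mer with five located occurrences.  Density tracks count
occurrences (each assigned to the window containing its k-mer start);
distinct counts are reported alongside.

Under neutral accumulation of heterozygous variants at a uniform per-bp
rate, the expected number of hap-mer occurrences on a sequence is close
to linear in its length: a single isolated substitution at interior
position p of a length-L sequence creates exactly min(k, p+1, L−p)
hap-mer occurrences on each haplotype (the windows covering p), so at
low heterozygosity h the per-bp rate is ≈ 1−(1−h)^k.  This is the
autosomal background.  A non-recombining sex-limited region diverges at
a much higher rate and pushes its pair far above the line (excess); a
diversity-depleted homogametic pair falls far below it (dearth).
Misassembly and misphasing mimic either signal, which is why the output
is framed as candidates for scrutiny rather than hypothesis tests — no
p-values for sex linkage are produced.

## Detectors

Three layers are computed and reported separately so a user can weigh
them the way a practitioner would weigh converging evidence:

1. **Length regression.**  Ordinary least squares of hap-mer occurrences
   on length, pooling both haplotypes' sequences into one fit.
   Externally studentized residuals (leave-one-out variance) are flagged
   at |t| > 3, excess or dearth by sign.  One refit round excludes the
   first-pass flags and re-evaluates every sequence against the cleaned
   background (rows outside the refit use the prediction-interval
   standard error), so a large sex chromosome cannot inflate the residual
   variance and mask itself.  Exactly one refit round: iterating further
   erodes the background on small assemblies.  If the response has zero
   variance, R² is defined as 0 and no studentization is attempted.

2. **Density boxplot.**  Tukey fences (Q1 − 1.5·IQR, Q3 + 1.5·IQR) on
   per-sequence hap-mer density (occurrences × 10⁶ / length), per
   haplotype, quartiles by linear interpolation.  Haplotypes with fewer
   than four sequences get a summary but no flags.

3. **Windowed convergence per homolog pair.**  Sequences are paired
   across haplotypes by reciprocal-best k-mer containment (below).  A
   pair is called **candidate-excess** iff (a) a member carries a
   regression-excess or boxplot-high flag and (b) a member has ≥ m
   (default 3) consecutive windows whose hap-mer density exceeds the
   Tukey upper fence of all windows of unflagged pairs.  Requiring a
   multi-window run rejects isolated misassembly spikes while keeping
   multi-Mb sex-limited regions.  A pair is called **candidate-dearth**
   iff a member carries a dearth/low flag and the pair's identity is near
   1 in a scale-free sense: its median non-shared window fraction must be
   below half (configurable) of the unflagged pairs' median — background
   pairs sit at a ratio of ~1 whatever the absolute heterozygosity, a
   genuinely depleted pair sits far below.  An early design used Tukey
   fences on the background pairs' identity medians instead; with ten
   background pairs their spread is pure sampling noise, so ordinary
   pairs strayed past the fence and produced spurious dearth calls — the
   ratio rule removed those without affecting true calls.

## Homolog pairing

Each hap1 sequence is matched to the hap2 sequence maximising
containment |A∩B|/|A| of distinct canonical k-mer sets; a pair is emitted
iff the match is reciprocal-best and max of the two directed containments
is ≥ 0.5.  Ties break by opposite-direction containment, partner length,
then lexicographic id, making the matching deterministic.  Homologs at
realistic heterozygosity share the large majority of their k-mers, and
even a sex pair whose sex-limited region shares nothing keeps
chromosome-scale containment well above 0.5.  This is a k-mer re-design
of the evidence an homology aligner would provide, not a wrapper around
one; no base-level alignment or rearrangement calls are attempted.

## Identity proxy and segmentation

For each pair and direction, every valid k-mer window is probed against
the partner sequence's whole-sequence distinct k-mer set; the per-window
shared fraction is a monotone proxy of alignment identity (it is never
reported as percent identity — the mapping is uncalibrated).  Probing
against the whole partner set rather than the corresponding window makes
the proxy insensitive to inversions and translocations.  Windows whose
shared fraction falls below 0.9× the pair's own median (a relative
threshold, robust across heterozygosity levels; all-N windows excluded)
form candidate runs; runs of ≥ 2 windows are reported as sex-limited
candidates, and terminal non-low runs flanking such a run as PAR
candidates.  On a flagged pair the sex-limited candidate and the hap-mer
density peak coincide and identity anti-correlates with density — the
converging-evidence signature.

## Simulator

`simulate_diploid` draws an ancestral sequence uniformly over ACGT and
derives hap2 from hap1 by per-base substitution (rate 0.002/bp by
default) and indels (rate 0.0002/bp, geometric lengths of mean 2).
One-sided mutation (rather than mutating both copies away from a common
ancestor) halves the bookkeeping and is equivalent for hap-mer purposes
at these rates.  Truth intervals are mapped through every applied indel,
so the truth file is exact in final coordinates of both haplotypes.

Defaults, chosen once as desk-scale stand-ins for a small vertebrate-like
genome: 10 autosome pairs, lengths geometrically spread 0.5–3 Mb (enough
points for a meaningful regression); a 10 Mb sex pair whose central 40%
diverges at 2%/bp — chromosome-scale relative to the autosomes, with the
centred sex-limited block spanning whole default windows ([3,7) Mb); PAR
(optional fraction, background divergence) at the far distal tip; Y/W
truncation and a TTAGGG-unit tandem expansion available for shaping the
sex-limited chromosome; dearth mode divides both rates by 10 on the
designated pair.  hap2 records are emitted in seeded-shuffled order so
pairing is never a by-order accident.  No quantitative divergence values
exist for any particular system in the source material; these settings
are illustrative and fully exposed in `SimConfig`.

What the simulator does **not** model: coalescent structure,
recombination maps, sequencing reads, coverage artefacts, collapsed
repeats, or assembly/phasing error.  Passing tests therefore demonstrate
the statistical machinery under its stated assumptions, not robustness to
the technical artefacts real assemblies carry (low-coverage assemblies
are known to break the length correlation entirely).

## Numerical choices

* k ≤ 31 so a canonical k-mer packs into one uint64; whole-assembly sets
  are sorted uint64 arrays.  Set algebra uses two-pointer merges;
  positional membership uses a linear-probing open-addressing hash table
  (load ≤ 0.5, splitmix64 mixing) — at tens of millions of keys these
  are memory-bandwidth-bound rather than latency-bound, unlike repeated
  binary search.  All kernels are deterministic; repeated runs produce
  byte-identical TSV/BED/JSON.
* N handling: any window containing N is skipped (counting, location,
  identity); assemblies normalise lowercase to uppercase, U to T, other
  IUPAC codes to N.
* GREEDY mode homopolymer-compresses each sequence and scans the
  compressed string with the same k; positions project back to original
  coordinates at each run's first base.  Coordinates are reported in
  original space everywhere.
* Boundary conventions: 0-based half-open intervals throughout; the
  length filter keeps sequences with length ≥ min_len; window tracks tile
  [0, L) with the last window truncated and densities normalised by the
  actual span; an occurrence at a window boundary belongs to the window
  it starts in.
* Degenerate inputs: zero-variance response → R² 0, no flags; < 3
  sequences → no fit (error); no unflagged pair → no autosomal background
  (error); empty hap-mer sets → zero tracks, outputs still written.

## Problem sizes

The default simulated genome is ≈ 28–48 Mb diploid (scenario-dependent),
which one pipeline run processes in ~10–20 s on a single CPU; the test
suite's scenario batteries use 20 independent seeds per scenario.  These
sizes were chosen as the smallest at which the regression background has
realistic spread; the implementation itself is linear in genome size and
the contract (single-thread determinism) does not change with scale.

## Known limitations

* The identity proxy saturates: at divergence ≫ 1/k shared fractions
  approach 0 and no longer discriminate degrees of divergence.
* Hap-mer counts conflate biological divergence with phasing/assembly
  error; the tool cannot tell a sex chromosome from a consistently
  misphased autosome without external evidence.
* Containment pairing assumes homologs dominate sharing; highly
  duplicated chromosomes or whole-genome duplications would need
  alignment-based pairing.
* Dearth detection presumes several unflagged pairs to define the
  background ratio; tiny assemblies (< 4 pairs) cannot support it.
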