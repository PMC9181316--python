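# Methods

## Scope

`strwga` benchmarks single-cell whole-genome-amplification (WGA) chemistry
through the lens of a targeted short-tandem-repeat (STR) panel.  The
experimental design it models is a *clonal* cell population: every cell
shares one diploid genotype, so at most two distinct alleles exist
population-wide at any locus, heterozygous loci can be identified
confidently from pooled data, and every per-cell deviation from the clone
genotype is amplification artifact.  The package simulates that design
end-to-end (clone → per-kit amplification distortion → targeted amplicon
reads), maps reads to repeat-number histograms, genotypes the histograms
against a simulated slippage ("stutter") model, and reports four
kit-quality metrics.

## Stutter model

During amplification a polymerase copying an STR tract occasionally slips,
adding or removing whole repeat units.  We model the expected repeat-length
distribution `f_c` of the molecule pool after `c` amplification cycles:
each cycle every molecule duplicates with probability `e` (per-cycle
efficiency), a fresh copy slips with probability `s`, and a slip removes
one unit with probability `q` (else adds one):

    f_{c+1}(x) = [ (1 + e(1−s)) f_c(x) + e s ( q f_c(x+1) + (1−q) f_c(x−1) ) ] / (1 + e)

with `f_0` a point mass at the allele and support clipped at one repeat.
Defaults: `e = 0.95`, `s = 0.003`, `q = 0.8` (slippage predominantly
contracts the tract).  Only single-unit slips are modelled; multi-unit
slips are a small minority mode and are out of scope.  The recursion is
the exact expectation of a per-cycle branching process; the test suite
checks it against an independent Monte-Carlo branching simulation with
10^5 founders (total-variation distance < 0.01).  Because the recursion is
linear, a heterozygous locus propagates as the weighted mixture of its two
single-allele distributions — used directly by the genotyper and verified
as a property test.

Cycle counts are always expressed in PCR-cycle equivalents, also for
isothermal (MDA) chemistry: the fitted cycle number is the number of ideal
PCR cycles that would produce the observed stutter, which makes noise
comparable across chemistries.

## Genotyping

A locus × sample observation is a repeat-number histogram.  Candidate
patterns `w·stutter(a1, c) + (1−w)·stutter(a2, c)` (plus single-allele
candidates) are scored by Pearson correlation against the normalized
histogram over a window spanning the observed support ± 5 units; the
best-scoring candidate is the call and calls with correlation below 0.95
are flagged `no_call`.  Grids: alleles within the observed support ± 3,
cycles 0–90 step 2, shorter-allele weight `w` 0.05–0.95 step 0.05 plus the
homozygous candidates.  Ties within 1e-9 prefer fewer alleles, then lower
cycles, then smaller separation, then the lower allele.  If either vector
is constant over the window the score is 1.0 when the two point masses
coincide and 0.0 otherwise.  `w` is always reported as the weight of the
*shorter* allele (homozygous calls carry `w = 1` by convention), matching
the convention that PCR selects against longer tracts, so balance
distributions sit slightly above 0.5 even in bulk DNA.

Two modes exist:

* **Free search** — the full grid.  Used for population-level (pooled)
  genotyping.  An inherent degeneracy of correlation scoring is that a
  lightly stuttered single allele is fit almost perfectly by an adjacent
  low-weight allele pair at low cycles (stutter patterns one repeat unit
  apart overlap heavily); this is exactly why the balance analysis only
  admits heterozygous loci whose alleles are well separated.
* **Genotype-seeded** — candidate alleles fixed to a known genotype, only
  `(w, c)` searched.  In the clonal design the population genotype is
  established once from pooled data (hundreds to thousands of reads per
  locus, where the free search is reliable) and every per-cell fit is
  seeded with it.  The pipeline uses this mode for all per-cell calls; it
  removes the adjacent-pair degeneracy and makes the per-cell cycle
  estimate usable at realistic per-cell depth.

At per-locus depth `n`, only a few percent of reads are stutter reads, so
the fitted cycle count carries a sampling s.d. of several cycles for
`n ≲ 1000`; estimates are unbiased in aggregate and per-cell noise is
therefore summarised as the *median* fitted cycles over called AC-type
loci (median rather than mean for robustness; cells with fewer than 20
qualifying calls are flagged low-support).

## Read mapping

Targeted amplicon reads are assigned by flank anchors: the 15 bp of each
flank adjacent to the repeat tract.  A read maps to a locus with repeat
count `r` iff both anchors occur in order (≤ 1 mismatch each), the spanned
interval is an exact whole multiple `r × len(unit)`, and the tract matches
`unit^r` with ≤ 1 mismatch.  Reads are tried in both orientations;
multi-locus hits, non-integer tracts and tracts truncated by the read end
are unmapped (no partial counting).  This is output-equivalent, for
amplicon reads, to end-to-end alignment against a reference containing
every repeat-length permutation of every locus; the package can emit that
permuted reference (default range: reference repeat count ± 20, clipped at
one repeat), and the test suite keeps a brute-force permuted-reference
aligner as the independent oracle (≥ 99% agreement on reads fuzzed with a
random substitution).  Exact-structure reads take a fast dictionary path;
only reads with errors fall back to mismatch-tolerant scanning.

## Synthetic data generator

The generator emulates the clonal single-cell experiment:

* **Panel** — synthetic loci with 40 bp flanks, reference repeat counts
  8–22, 80% AC units (plus AG/AT/AGAT), laid head-to-tail on a synthetic
  chromosome so panel tables round-trip through the reference FASTA.
* **Clone** — each locus heterozygous with probability 0.3; heterozygous
  separations uniform on 1–8 repeat units centred on the reference count;
  per-locus probe capture efficiency drawn Beta(8, 2).
* **Kit distortion** — in order: whole-cell failure (with probability
  `cell_failure_prob`; a failed cell's locus retention is drawn
  Beta(1, 10), i.e. ~9% of loci on average); *systematic* locus dropout (a
  deterministic per-kit subset of loci that fails in every cell, modelling
  reproducible amplification bias); random per-cell locus dropout;
  independent per-allele dropout; length bias (allele weight ∝
  `exp(−β · repeats)`, so longer alleles are under-amplified); stutter at
  a per-locus cycle count drawn Normal(mean, sd) truncated at zero.
* **Reads** — per-locus read counts are negative binomial with mean
  `depth × yield × capture` and kit-specific dispersion (Poisson in the
  infinite-dispersion limit); each read is the single-end sense-strand
  amplicon with per-base substitution errors (default 1e-3) and constant
  'I' qualities; a tab-separated truth sidecar records per-locus alleles,
  weights, applied cycles and emitted read counts.  Everything is
  bit-reproducible under a seed.

The split between systematic and random locus dropout is load-bearing:
with purely independent dropout, one kit cannot simultaneously have the
best single-cell locus yield and another the best k-cell intersection
consistency.  Reproducible coverage bias (systematic dropout, plus uneven
MDA coverage encoded as low negative-binomial dispersion) is what lets a
moderately-covered but uniform kit win the consistency comparison — the
phenomenon the consistency metric exists to measure.

Kit presets (`data/kit_presets.yaml`) cover Ampli1, MALBAC, PicoPlex,
GenomePlex (PCR), RepliG-SC, RepliG-Mini, TruePrime (MDA) and a bulk
control.  All numeric values are synthetic; only the qualitative orderings
are meaningful and tested: RepliG-SC has the best yield, Ampli1 the lowest
length bias and dropout among PCR kits (hence best balance and
consistency), PCR noise means exceed MDA means by 10–20 cycle equivalents,
GenomePlex/TruePrime mostly fail, bulk is near-ideal.

What the generator does **not** model: probe hybridization chemistry and
its sequence biases, indels and errors inside flanks beyond substitution
tolerance, multi-unit slips, length-dependent slip rates, paired-end
structure, index hopping, or inter-locus crosstalk.  Passing tests
therefore demonstrate that the pipeline recovers the distortions this
generative family encodes — not that real WGA data obeys these particular
parameter values.

## Kit-quality metrics

All analysis constants live in one `ThresholdConfig`:

| constant | default | meaning |
|---|---|---|
| `min_reads_per_locus_sampled` | 1 | a locus is "sampled" in a cell at ≥ this many mapped reads |
| `failed_cell_loci` | 500 | cells sampling *fewer* loci (strict) are failed |
| `min_het_depth` | 30 | pooled coverage must *exceed* this (strict) for the het filter |
| `min_allele_sep` | 3 | minimum repeat-unit separation of population alleles |
| `consistency_reads` | 100,000 | virtual resampling budget per cell |
| `min_cells_per_kit` | 5 | kits with fewer retained cells are excluded from consistency |
| `correlation_min` | 0.95 | genotype-call acceptance floor |

* **Coverage / failed cells** — sampled-locus count per cell; failure rate
  per kit.
* **Allelic balance** — at population-heterozygous loci (both filter
  clauses above), each cell contributes its fitted `w`; a homozygous
  cell-level call at such a locus is complete allelic dropout and scores
  `w = 1` (shorter allele survived) or `w = 0` (longer); the per-cell
  summary is the median of `|w − 0.5|`.  Kit-level ranking aggregates the
  *mean* of `|w − 0.5|` across all cell × locus values, because `w` lives
  on a 0.05 grid and kit medians would tie.  The balance uses the
  genotyper's fitted proportion (a read-count-based `w` can be derived
  from histograms as a cross-check).
* **Consistency** — every cell is resampled *without replacement* to
  exactly 100,000 mapped reads (multivariate hypergeometric over the
  (locus, repeat-length) bins; cells below budget excluded, kits with < 5
  surviving cells dropped); the curve reports the mean jointly-sampled
  locus count over all C(n, k) k-cell groups for k = 2..5, or over 10,000
  seeded random groups when there are more.  Non-increase in k is asserted
  on every run.
* **Noise** — per-cell median fitted cycles on AC-type loci (the panel's
  dominant unit), aggregated per kit.

Open choices made here (both configurable): the coverage metric counts a
locus as sampled at ≥ 1 read (no per-locus depth threshold); the consistency aggregation over
k-subsets is a mean over all (or 10,000 sampled) combinations.

## Pipeline and reproducibility

`run_pipeline` executes simulate → map → genotype → metrics from one
config and writes four tab-separated tables (`fig2_coverage`,
`fig3_balance`, `fig4_consistency`, `fig5_noise`), the intermediate
histogram/call/het-locus tables, and a JSON manifest (config hash, seed,
counts per stage, exclusions with reasons).  All randomness derives from
the master seed through `numpy` `SeedSequence` spawn keys
`(stage, kit index, cell index)`, so adding kits or cells never reshuffles
earlier cells, and identical configs produce byte-identical outputs.
Per-cell genotyping is restricted to the loci the metrics consume (the
population-het set plus a seeded subsample of up to 120 AC loci per cell
for the noise metric; `noise_loci_cap=0` genotypes every locus).

Default scenario: 8 kits × 20 cells over a 2,000-locus panel at a mean
per-locus depth of 100 reads (≈ 10^5 reads per healthy cell, matching the
100,000-read consistency budget).  This is a scaled-down panel relative to
a genome-wide 12,000-locus design; counts scale accordingly while all
rates, filters and orderings are scale-free.  The full scenario runs in
roughly four minutes on one CPU.

## Known limitations

* Stutter parameters are fixed across loci; real slip rates depend on
  unit composition and tract length.
* The correlation score is not a likelihood; at low depth the cycle
  estimate is coarse and the free search cannot distinguish adjacent
  allele pairs from single alleles (mitigated by genotype seeding and the
  separation filter, as described above).
* Flank-anchored mapping tolerates substitutions only; indels in flanks
  unmap the read.
* Kit presets are ordinal stand-ins, not calibrated measurements of the
  commercial kits they are named after.
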