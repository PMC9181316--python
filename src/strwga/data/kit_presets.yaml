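# Simulation profiles for eight whole-genome-amplification conditions.
#
# All numeric values are SYNTHETIC: they are constrained only by published
# qualitative orderings between the kits (RepliG-SC best yield; Ampli1 most
# balanced and most reproducible across cells; MALBAC/RepliG-Mini lowest
# failed-cell rates; PCR-based kits noisier than MDA-based ones by 10-20
# PCR-cycle equivalents; GenomePlex/TruePrime mostly failing), not by any
# measured per-kit rates.
#
# Fields
#   chemistry                 MDA | PCR | bulk
#   cell_failure_prob         probability a cell's amplification globally fails
#   locus_dropout_prob        per-cell random locus dropout
#   locus_dropout_systematic  fraction of loci that reproducibly fail for this
#                             kit in every cell (deterministic per kit+locus)
#   allele_dropout_prob       per-allele dropout at surviving loci
#   noise_cycles_mean/sd      stutter noise in PCR-cycle equivalents
#   length_bias_beta          per-repeat-unit amplification penalty (drives
#                             shorter-allele bias)
#   yield_mean                expected reads-per-locus multiplier
#   yield_dispersion          negative-binomial dispersion of per-locus depth
#                             (smaller = more uneven coverage; MDA kits are
#                             markedly uneven, which is what erodes their
#                             cross-cell consistency at a fixed read budget)

Ampli1:
  chemistry: PCR
  cell_failure_prob: 0.06
  locus_dropout_prob: 0.02
  locus_dropout_systematic: 0.08
  allele_dropout_prob: 0.02
  noise_cycles_mean: 33.0
  noise_cycles_sd: 3.0
  length_bias_beta: 0.003
  yield_mean: 0.8
  yield_dispersion: 8.0

MALBAC:
  chemistry: PCR
  cell_failure_prob: 0.02
  locus_dropout_prob: 0.08
  locus_dropout_systematic: 0.05
  allele_dropout_prob: 0.06
  noise_cycles_mean: 36.0
  noise_cycles_sd: 3.0
  length_bias_beta: 0.012
  yield_mean: 0.7
  yield_dispersion: 3.0

PicoPlex:
  chemistry: PCR
  cell_failure_prob: 0.05
  locus_dropout_prob: 0.10
  locus_dropout_systematic: 0.06
  allele_dropout_prob: 0.08
  noise_cycles_mean: 35.0
  noise_cycles_sd: 3.0
  length_bias_beta: 0.018
  yield_mean: 0.65
  yield_dispersion: 3.0

GenomePlex:
  chemistry: PCR
  cell_failure_prob: 0.60
  locus_dropout_prob: 0.20
  locus_dropout_systematic: 0.30
  allele_dropout_prob: 0.25
  noise_cycles_mean: 34.0
  noise_cycles_sd: 3.0
  length_bias_beta: 0.04
  yield_mean: 0.25
  yield_dispersion: 0.5

RepliG-SC:
  chemistry: MDA
  cell_failure_prob: 0.10
  locus_dropout_prob: 0.04
  locus_dropout_systematic: 0.01
  allele_dropout_prob: 0.15
  noise_cycles_mean: 20.0
  noise_cycles_sd: 3.0
  length_bias_beta: 0.03
  yield_mean: 1.0
  yield_dispersion: 1.0

RepliG-Mini:
  chemistry: MDA
  cell_failure_prob: 0.02
  locus_dropout_prob: 0.08
  locus_dropout_systematic: 0.03
  allele_dropout_prob: 0.15
  noise_cycles_mean: 22.0
  noise_cycles_sd: 3.0
  length_bias_beta: 0.03
  yield_mean: 0.6
  yield_dispersion: 1.0

TruePrime:
  chemistry: MDA
  cell_failure_prob: 0.55
  locus_dropout_prob: 0.25
  locus_dropout_systematic: 0.30
  allele_dropout_prob: 0.25
  noise_cycles_mean: 21.0
  noise_cycles_sd: 3.0
  length_bias_beta: 0.04
  yield_mean: 0.2
  yield_dispersion: 0.5

Bulk:
  chemistry: bulk
  cell_failure_prob: 0.0
  locus_dropout_prob: 0.005
  locus_dropout_systematic: 0.0
  allele_dropout_prob: 0.0
  noise_cycles_mean: 18.0
  noise_cycles_sd: 2.0
  length_bias_beta: 0.001
  yield_mean: 1.2
  yield_dispersion: 20.0
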