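# Genotype preset table for the end-resection simulator.
#
# Fields:
#   p_unresected      probability a non-RI molecule keeps unresected ends
#   p_double_cut      probability a molecule carries two cuts
#   central_to_resection_ratio
#                     target central:resection read-mass ratio; the loader
#                     inverts it to the RI fate fraction (one RI read versus
#                     two resected endpoints per molecule)
#   tract             truncated-gamma resection-tract targets (nt)
#   oligo_weights     SPO11-oligo class mixture (canonical short/long ranges
#                     vs. the >=33 nt double-cut ladder)
#
# Tract means/modes reflect each genotype's measured genome-average resection
# statistics (mean ~1100 nt and mode 1015 nt in wild type); where only a
# percent reduction or a length decrement is known, the target is derived from
# the wild-type values, and the Rad50 point mutants are placed between wild
# type and Nbs1-dB to reproduce the observed allelic series of mean lengths
# (wt > Rad50-L1237F > Rad50-D69Y > Nbs1dB > Mre11-ATLD1).

wt:
  description: >
    Wild type: full resection (mean ~1100 nt, mode 1015 nt), no double cuts,
    central signal from recombination intermediates at ~40% of the resection
    signal.
  p_unresected: 0.0
  p_double_cut: 0.0
  central_to_resection_ratio: 0.400
  tract: {target_mean: 1100, target_mode: 1015}
  oligo_weights: {short: 0.60, long: 0.40, double_cut: 0.0}

Mre11-cKO:
  description: >
    Conditional Mre11 knockout (adult): no resection initiation; all signal at
    hotspot centers from unresected DSBs, frequent SPO11 double cutting, and
    SPO11 oligos dominated by the >=33 nt periodic double-cut ladder.
  p_unresected: 1.0
  p_double_cut: 0.75
  ri_fraction: 0.0
  tract: null
  oligo_weights: {short: 0.02, long: 0.08, double_cut: 0.90}

Mre11-cKO-juvenile-resected:
  description: >
    The resected DSB subpopulation of juvenile (14.5 dpp) conditional Mre11
    knockouts: markedly shorter tracts (mode 897 nt) than wild type.
  p_unresected: 0.0
  p_double_cut: 0.0
  central_to_resection_ratio: 0.400
  tract: {target_mean: 982, target_mode: 897}
  oligo_weights: {short: 0.30, long: 0.25, double_cut: 0.45}

Mre11-cHN:
  description: >
    Conditional nuclease-dead MRE11 (H129N over a deleted allele): strongly
    curtailed resection (mean 672 nt) with a small unresected fraction.
  p_unresected: 0.02
  p_double_cut: 0.0
  central_to_resection_ratio: 0.400
  tract: {target_mean: 672, target_mode: 587}
  oligo_weights: {short: 0.35, long: 0.65, double_cut: 0.0}

HN-Het:
  description: >
    Mre11-H129N heterozygote: weak dominant-negative effect, mean resection
    1040 nt (~94% of wild type).
  p_unresected: 0.0
  p_double_cut: 0.0
  central_to_resection_ratio: 0.400
  tract: {target_mean: 1040, target_mode: 955}
  oligo_weights: {short: 0.55, long: 0.45, double_cut: 0.0}

Mre11-ATLD1:
  description: >
    MRE11 C-terminal truncation hypomorph (ataxia-telangiectasia-like
    disorder model): ~47% reduction in mean resection length, reduced central
    signal.
  p_unresected: 0.0
  p_double_cut: 0.0
  central_to_resection_ratio: 0.275
  tract: {target_mean: 583, target_mode: 498}
  oligo_weights: {short: 0.55, long: 0.45, double_cut: 0.0}

Nbs1dB:
  description: >
    NBS1 delta-B hypomorph (Nijmegen breakage syndrome model) at 14.5 dpp:
    ~43% reduction in mean resection length; central signal 27.5% of the
    resection signal.
  p_unresected: 0.0
  p_double_cut: 0.0
  central_to_resection_ratio: 0.275
  tract: {target_mean: 627, target_mode: 542}
  oligo_weights: {short: 0.55, long: 0.45, double_cut: 0.0}

Nbs1dB-14.5dpp:
  description: Alias conditions of Nbs1dB sampled at 14.5 dpp.
  p_unresected: 0.0
  p_double_cut: 0.0
  central_to_resection_ratio: 0.275
  tract: {target_mean: 627, target_mode: 542}
  oligo_weights: {short: 0.55, long: 0.45, double_cut: 0.0}

Nbs1dB-16.5dpp:
  description: >
    Nbs1 delta-B at 16.5 dpp: same shortened tracts, central signal recovered
    to 34.7% of the resection signal.
  p_unresected: 0.0
  p_double_cut: 0.0
  central_to_resection_ratio: 0.347
  tract: {target_mean: 627, target_mode: 542}
  oligo_weights: {short: 0.55, long: 0.45, double_cut: 0.0}

Nbs1dB-Exo1DA:
  description: >
    Nbs1 delta-B combined with nuclease-dead EXO1 (D173A): additive shortening
    (mean 516 nt, 111 nt below Nbs1dB alone); central signal 28.8% at
    16.5 dpp.
  p_unresected: 0.0
  p_double_cut: 0.0
  central_to_resection_ratio: 0.288
  tract: {target_mean: 516, target_mode: 431}
  oligo_weights: {short: 0.55, long: 0.45, double_cut: 0.0}

Exo1DA:
  description: >
    Nuclease-dead EXO1 (D173A) alone: modest shortening (mean 974 nt, 126 nt
    below wild type); central signal unchanged.
  p_unresected: 0.0
  p_double_cut: 0.0
  central_to_resection_ratio: 0.400
  tract: {target_mean: 974, target_mode: 889}
  oligo_weights: {short: 0.60, long: 0.40, double_cut: 0.0}

Rad50-L1237F:
  description: >
    RAD50 Walker-B point mutant (ATM-activation defective, repair proficient):
    mild resection shortening, between wild type and the stronger hypomorphs.
  p_unresected: 0.0
  p_double_cut: 0.0
  central_to_resection_ratio: 0.400
  tract: {target_mean: 1000, target_mode: 915}
  oligo_weights: {short: 0.55, long: 0.45, double_cut: 0.0}

Rad50-D69Y:
  description: >
    RAD50 Walker-A point mutant: intermediate resection shortening, below
    Rad50-L1237F and above Nbs1dB in the allelic series.
  p_unresected: 0.0
  p_double_cut: 0.0
  central_to_resection_ratio: 0.400
  tract: {target_mean: 900, target_mode: 815}
  oligo_weights: {short: 0.55, long: 0.45, double_cut: 0.0}

Atm-null:
  description: >
    ATM knockout: resection initiation retained for most DSBs but a subset
    remains unresected; frequent double cutting; SPO11 oligos are a mix of
    canonical classes and the double-cut ladder.
  p_unresected: 0.25
  p_double_cut: 0.40
  central_to_resection_ratio: 0.200
  tract: {target_mean: 1000, target_mode: 915}
  oligo_weights: {short: 0.30, long: 0.20, double_cut: 0.50}
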