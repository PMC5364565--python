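# Named model scenarios: the three stability panels.
# fig3a: two alleles at equal initial frequencies (0.5); the two-haplotype
#        pseudooverdominance model is equivalent to a single recessive lethal.
# fig3b: ten alleles at equal initial frequencies (0.1); pseudooverdominance
#        uses nine single-lethal haplotypes plus one harmless haplotype.
# fig3c: ten-allele overdominance with initial frequencies spanning
#        0.01-0.3 (renormalized to the simplex).
fig3a:
  generations: 100
  curves:
    overdominance_neutral:
      model: overdominance
      sex_mode: neutral
      n_alleles: 2
      initial_frequencies: [0.5, 0.5]
    overdominance_dependent:
      model: overdominance
      sex_mode: dependent
      n_alleles: 2
      initial_frequencies: [0.5, 0.5]
    pseudooverdominance_neutral:
      model: pseudooverdominance
      sex_mode: neutral
      haplotypes: ["1", "0"]
      initial_frequencies: [0.5, 0.5]
      recombination_rate: 0.01
    pseudooverdominance_dependent:
      model: pseudooverdominance
      sex_mode: dependent
      haplotypes: ["1", "0"]
      initial_frequencies: [0.5, 0.5]
      recombination_rate: 0.01
fig3b:
  generations: 100
  curves:
    overdominance_neutral:
      model: overdominance
      sex_mode: neutral
      n_alleles: 10
    overdominance_dependent:
      model: overdominance
      sex_mode: dependent
      n_alleles: 10
    pseudooverdominance_neutral:
      model: pseudooverdominance
      sex_mode: neutral
      haplotypes: ["100000000", "010000000", "001000000", "000100000",
                   "000010000", "000001000", "000000100", "000000010",
                   "000000001", "000000000"]
      recombination_rate: 0.01
    pseudooverdominance_dependent:
      model: pseudooverdominance
      sex_mode: dependent
      haplotypes: ["100000000", "010000000", "001000000", "000100000",
                   "000010000", "000001000", "000000100", "000000010",
                   "000000001", "000000000"]
      recombination_rate: 0.01
fig3c:
  generations: 100
  curves:
    overdominance_varied_init:
      model: overdominance
      sex_mode: dependent
      n_alleles: 10
      initial_frequencies: [0.01, 0.0422, 0.0744, 0.1067, 0.1389,
                            0.1711, 0.2033, 0.2356, 0.2678, 0.3]
      normalize_initial: true
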