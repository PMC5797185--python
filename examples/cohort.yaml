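# Two-genotype cohort: wild-type vs mutant differing only in the
# persistence (effort-tolerance) parameter, as in the frozen defaults.
seed: 2018
genotypes:
  - label: "Htt+/+"
    n: 8
  - label: "HttQ111/+"
    n: 12
    params:
      persistence: {mean: 58.0, dispersion: 1.0}
protocol:
  pr_max_days: 30
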