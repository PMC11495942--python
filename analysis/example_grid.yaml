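# A small error-rate grid for `dpsyntest evaluate`.
# Keys mirror dpsyntest.evaluation.ExperimentConfig; bin_spec follows
# dpsyntest.histograms.BinSpec.from_dict.
modes: ["null", signal]       # quote "null": bare null is YAML's None
synthesizers: [perturbed]
epsilons: [1.0, 10.0]
n_original: [200]
repetitions: 50
tests: [mwu]
bin_spec: {n_bins: 100, lower: 0.5, upper: 100.5, clip_low: true, clip_high: true}
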