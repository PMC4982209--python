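# Age- and sex-matched EQ-5D index reference values for the two age bands
# used in the survivor comparison. n_ref is the assumed size of the
# reference sample behind each summary (the published reference tables do
# not print it); it only affects the Welch degrees of freedom.
n_ref: 500
bands:
  under_65:
    mean: 0.85
    sd: 0.06
  over_65:
    mean: 0.77
    sd: 0.02
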