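# Default geodetector settings.
# Continuous covariates are discretized with exact Jenks natural breaks
# into 5 classes (the dominant convention in geodetector applications; the
# method and class count are assumptions, not established values).
method: natural_breaks
n_classes: 5
tolerance: 1.0e-9
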