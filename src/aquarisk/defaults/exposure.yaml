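# Default oral-ingestion exposure model for adults and children.
#
# NON-AUTHORITATIVE: families and parameters follow standard USEPA-style
# oral-ingestion exposure-factor tables and are fully editable.
# IR: L/d, EF: d/a, ED: a, BW: kg.  AT is derived: ED*365 d for
# noncarcinogenic doses and lifetime_years*365 d for carcinogenic ones.
at_mode: derived
lifetime_years: 70.0

populations:
  adult:
    IR: {family: lognormal, params: {mu: 0.6931, sigma: 0.25}, truncate: [0.5, 5.0]}
    EF: {family: point, params: {value: 365.0}}
    ED: {family: point, params: {value: 30.0}}
    BW: {family: normal, params: {mean: 60.6, sd: 9.0}, truncate: [35.0, 110.0]}
  child:
    IR: {family: lognormal, params: {mu: 0.0, sigma: 0.25}, truncate: [0.2, 3.0]}
    EF: {family: point, params: {value: 365.0}}
    ED: {family: point, params: {value: 6.0}}
    BW: {family: normal, params: {mean: 22.9, sd: 4.5}, truncate: [8.0, 50.0]}
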