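# Default oral toxicity references.
#
# NON-AUTHORITATIVE: populated from standard USEPA oral-ingestion tables
# (IRIS-style values); editable.  sf: oral slope factor (mg/(kg d))^-1,
# defined only for the metals treated as carcinogenic by this route
# (no SF for Hg); rfd: oral reference dose, mg/(kg d).
sf:
  As: 1.5
  Cd: 6.1
  Cr6: 0.5
  Pb: 0.0085
rfd:
  As: 3.0e-4
  Hg: 3.0e-4
  Cd: 5.0e-4
  Cr6: 3.0e-3
  Pb: 1.4e-3
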