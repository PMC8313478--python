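# External data

`reisenzein.csv` — the 138-observation helping-behavior dataset used by the
empirical-example reproduction in `tests/test_acceptance.py` — is not
redistributable with this package.  It ships with the MIIVsem R package
(object `reisenzein`).  To run the reproduction, export it as CSV with
columns

    c1 c2 c3  s1 s2 s3  a1 a2 a3  h1 h2 h3

where the Controllability (c) and Anger (a) items keep their nine-point
scores (treated as continuous) and the Sympathy (s) and Help (h) items are
recoded to five-point scales as packaged (treated as ordinal), and place
the file here as `reisenzein.csv`.
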