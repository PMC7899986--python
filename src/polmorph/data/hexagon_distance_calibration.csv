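# Pairwise hexagon colour distances between measured Caladenia flower samples
# and the discrimination probability recorded for each pair (honeybee observer,
# absolute conditioning). Categories are carried verbatim from the source
# matrix (they disagree with the contrast table for orchids 5 and 6; samples
# are keyed on label only).
sample_a,sample_b,category_a,category_b,distance,probability
O1 lab,O1 sep,1,1,0.274,0.842
O6 sep,O1 sep,3,1,0.130,0.840
O6 sep,O1 lab,3,1,0.157,0.842
O6 lab,O1 sep,3,1,0.333,0.842
O6 lab,O1 lab,3,1,0.066,0.505
O6 lab,O6 sep,3,3,0.208,0.842
O5 sep,O1 sep,4,1,0.011,0.500
O5 sep,O1 lab,4,1,0.284,0.842
O5 sep,O6 sep,4,3,0.137,0.841
O5 sep,O6 lab,4,3,0.341,0.842
O5 lab,O1 sep,4,1,0.056,0.500
O5 lab,O1 lab,4,1,0.222,0.842
O5 lab,O6 sep,4,3,0.074,0.570
O5 lab,O6 lab,4,3,0.278,0.842
O5 lab,O5 sep,4,4,0.063,0.500
O2 lab,O1 sep,2,1,0.238,0.842
O2 lab,O1 lab,2,1,0.036,0.500
O2 lab,O6 sep,2,3,0.121,0.837
O2 lab,O6 lab,2,3,0.097,0.781
O2 lab,O5 sep,2,4,0.248,0.842
O2 lab,O5 lab,2,4,0.185,0.842
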