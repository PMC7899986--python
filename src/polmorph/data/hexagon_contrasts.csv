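# Colour contrast (hexagon distance from the adapted background) and green
# contrast (|E_G - 0.5|) recorded for measured Caladenia sepals and labella.
sample,part,category,green_contrast,color_contrast
O1 sep,sepal,1,0.267,0.345
O1 lab,labellum,1,0.087,0.097
O2 lab,labellum,2,0.091,0.133
O5 sep,sepal,3,0.285,0.353
O5 lab,labellum,3,0.188,0.294
O6 sep,sepal,4,0.130,0.225
O6 lab,labellum,4,0.163,0.033
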