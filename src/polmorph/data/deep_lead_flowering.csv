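# Flowering counts of tagged Caladenia plants at Deep Lead by flower-colour
# category (1-5) and by patch (1-5), for the three unbiased census years.
axis,level,year,n_flowers
category,1,2000,15
category,2,2000,26
category,3,2000,14
category,4,2000,19
category,5,2000,4
category,1,2003,17
category,2,2003,18
category,3,2003,23
category,4,2003,8
category,5,2003,4
category,1,2004,13
category,2,2004,12
category,3,2004,27
category,4,2004,4
category,5,2004,8
patch,1,2000,28
patch,2,2000,50
patch,3,2000,0
patch,4,2000,0
patch,5,2000,0
patch,1,2003,15
patch,2,2003,14
patch,3,2003,7
patch,4,2003,8
patch,5,2003,26
patch,1,2004,20
patch,2,2004,10
patch,3,2004,3
patch,4,2004,8
patch,5,2004,23
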