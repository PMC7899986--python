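# Natural-pollination outcomes of tagged Caladenia plants at Deep Lead:
# flower and fruit counts by colour category and by patch, 2003 and 2004.
axis,level,year,n_flowers,n_fruits
category,1,2003,17,3
category,2,2003,18,4
category,3,2003,23,2
category,4,2003,8,1
category,5,2003,4,0
category,1,2004,13,1
category,2,2004,12,2
category,3,2004,27,7
category,4,2004,4,0
category,5,2004,8,1
patch,1,2003,15,5
patch,2,2003,14,3
patch,3,2003,7,1
patch,4,2003,8,0
patch,5,2003,26,1
patch,1,2004,20,6
patch,2,2004,10,3
patch,3,2004,3,0
patch,4,2004,8,1
patch,5,2004,23,1
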