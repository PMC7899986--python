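# SYNTHETIC expansion of the artificial cross-pollination summary for the
# Deep Lead Caladenia population. Per-cell evaluable-cross counts and capsule
# percentages follow the published summary table; the allocation of the 20
# excluded/failed crosses (grazed, moldy, lost, no capsule) to specific cells
# is NOT printed anywhere and is assigned here arbitrarily for plumbing tests.
# Summary statistics that depend on that allocation must not be read off this
# file.
cross_id,pollen_category,ovule_category,capsule_fate
X01,1,1,capsule
X02,1,1,capsule
X03,1,1,capsule
X04,1,1,capsule
X05,1,1,capsule
X06,1,1,capsule
X07,1,1,capsule
X08,1,2,capsule
X09,1,2,capsule
X10,1,2,capsule
X11,1,2,capsule
X12,1,2,capsule
X13,1,2,none
X14,1,2,none
X15,1,3,capsule
X16,1,3,capsule
X17,1,3,capsule
X18,1,3,capsule
X19,1,3,capsule
X20,1,3,capsule
X21,1,4,capsule
X22,1,4,capsule
X23,1,4,capsule
X24,1,4,capsule
X25,1,4,capsule
X26,1,4,capsule
X27,1,4,capsule
X28,1,5,capsule
X29,1,5,capsule
X30,2,2,capsule
X31,2,2,capsule
X32,2,2,capsule
X33,2,2,capsule
X34,2,2,capsule
X35,2,2,capsule
X36,2,3,capsule
X37,2,3,capsule
X38,2,3,capsule
X39,2,3,capsule
X40,2,3,capsule
X41,2,3,capsule
X42,2,3,capsule
X43,2,3,capsule
X44,2,4,capsule
X45,2,4,capsule
X46,2,4,capsule
X47,2,4,capsule
X48,2,4,capsule
X49,2,4,capsule
X50,2,5,capsule
X51,2,5,capsule
X52,2,5,capsule
X53,2,5,capsule
X54,2,5,capsule
X55,2,5,capsule
X56,2,5,capsule
X57,3,3,capsule
X58,3,3,capsule
X59,3,3,capsule
X60,3,3,capsule
X61,3,3,capsule
X62,3,3,capsule
X63,3,3,none
X64,3,4,capsule
X65,3,4,capsule
X66,3,4,capsule
X67,3,4,capsule
X68,3,4,capsule
X69,3,4,none
X70,3,5,capsule
X71,3,5,none
X72,3,5,none
X73,4,4,capsule
X74,4,4,capsule
X75,4,5,capsule
X76,4,5,capsule
X77,5,5,capsule
X78,1,1,grazed
X79,1,2,grazed
X80,2,2,grazed
X81,2,3,grazed
X82,3,3,grazed
X83,3,4,grazed
X84,4,4,grazed
X85,2,4,grazed
X86,1,3,moldy
X87,2,5,moldy
X88,3,3,moldy
X89,1,4,moldy
X90,2,2,moldy
X91,3,5,lost
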