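zone,label
head,Sow in crate
rump,Sow in crate
fence,Metal fence
head,Trough
trough,Trough
outside_pen,Neighbour sow
cloud,Neighbour sow
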