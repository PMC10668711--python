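zone,label
head,Playing with sack
head,Eating
trough,Eating
rump,Standing
fence,Standing
fence,Moving leg lying
outside_pen,None
cloud,None
none,Lying down
head,jute_rooting
head,eating
trough,eating
rump,standing
fence,standing
rump,sitting_standing
fence,sitting_standing
fence,moving_leg_lying
none,lying
none,lying_down
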