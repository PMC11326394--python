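deceased,unstable,stable_to_unstable,mv,vp,crrt,discharge,state
0,0,0,0,0,0,0,stable
1,0,0,0,0,0,0,deceased
0,1,0,0,0,0,0,unstable
1,1,0,0,0,0,0,deceased
0,0,1,0,0,0,0,unstable
1,0,1,0,0,0,0,deceased
0,1,1,0,0,0,0,unstable
1,1,1,0,0,0,0,deceased
0,0,0,1,0,0,0,unstable
1,0,0,1,0,0,0,deceased
0,1,0,1,0,0,0,unstable
1,1,0,1,0,0,0,deceased
0,0,1,1,0,0,0,unstable
1,0,1,1,0,0,0,deceased
0,1,1,1,0,0,0,unstable
1,1,1,1,0,0,0,deceased
0,0,0,0,1,0,0,unstable
1,0,0,0,1,0,0,deceased
0,1,0,0,1,0,0,unstable
1,1,0,0,1,0,0,deceased
0,0,1,0,1,0,0,unstable
1,0,1,0,1,0,0,deceased
0,1,1,0,1,0,0,unstable
1,1,1,0,1,0,0,deceased
0,0,0,1,1,0,0,unstable
1,0,0,1,1,0,0,deceased
0,1,0,1,1,0,0,unstable
1,1,0,1,1,0,0,deceased
0,0,1,1,1,0,0,unstable
1,0,1,1,1,0,0,deceased
0,1,1,1,1,0,0,unstable
1,1,1,1,1,0,0,deceased
0,0,0,0,0,1,0,unstable
1,0,0,0,0,1,0,deceased
0,1,0,0,0,1,0,unstable
1,1,0,0,0,1,0,deceased
0,0,1,0,0,1,0,unstable
1,0,1,0,0,1,0,deceased
0,1,1,0,0,1,0,unstable
1,1,1,0,0,1,0,deceased
0,0,0,1,0,1,0,unstable
1,0,0,1,0,1,0,deceased
0,1,0,1,0,1,0,unstable
1,1,0,1,0,1,0,deceased
0,0,1,1,0,1,0,unstable
1,0,1,1,0,1,0,deceased
0,1,1,1,0,1,0,unstable
1,1,1,1,0,1,0,deceased
0,0,0,0,1,1,0,unstable
1,0,0,0,1,1,0,deceased
0,1,0,0,1,1,0,unstable
1,1,0,0,1,1,0,deceased
0,0,1,0,1,1,0,unstable
1,0,1,0,1,1,0,deceased
0,1,1,0,1,1,0,unstable
1,1,1,0,1,1,0,deceased
0,0,0,1,1,1,0,unstable
1,0,0,1,1,1,0,deceased
0,1,0,1,1,1,0,unstable
1,1,0,1,1,1,0,deceased
0,0,1,1,1,1,0,unstable
1,0,1,1,1,1,0,deceased
0,1,1,1,1,1,0,unstable
1,1,1,1,1,1,0,deceased
0,0,0,0,0,0,1,discharge
1,0,0,0,0,0,1,deceased
0,1,0,0,0,0,1,unstable
1,1,0,0,0,0,1,deceased
0,0,1,0,0,0,1,unstable
1,0,1,0,0,0,1,deceased
0,1,1,0,0,0,1,unstable
1,1,1,0,0,0,1,deceased
0,0,0,1,0,0,1,unstable
1,0,0,1,0,0,1,deceased
0,1,0,1,0,0,1,unstable
1,1,0,1,0,0,1,deceased
0,0,1,1,0,0,1,unstable
1,0,1,1,0,0,1,deceased
0,1,1,1,0,0,1,unstable
1,1,1,1,0,0,1,deceased
0,0,0,0,1,0,1,unstable
1,0,0,0,1,0,1,deceased
0,1,0,0,1,0,1,unstable
1,1,0,0,1,0,1,deceased
0,0,1,0,1,0,1,unstable
1,0,1,0,1,0,1,deceased
0,1,1,0,1,0,1,unstable
1,1,1,0,1,0,1,deceased
0,0,0,1,1,0,1,unstable
1,0,0,1,1,0,1,deceased
0,1,0,1,1,0,1,unstable
1,1,0,1,1,0,1,deceased
0,0,1,1,1,0,1,unstable
1,0,1,1,1,0,1,deceased
0,1,1,1,1,0,1,unstable
1,1,1,1,1,0,1,deceased
0,0,0,0,0,1,1,unstable
1,0,0,0,0,1,1,deceased
0,1,0,0,0,1,1,unstable
1,1,0,0,0,1,1,deceased
0,0,1,0,0,1,1,unstable
1,0,1,0,0,1,1,deceased
0,1,1,0,0,1,1,unstable
1,1,1,0,0,1,1,deceased
0,0,0,1,0,1,1,unstable
1,0,0,1,0,1,1,deceased
0,1,0,1,0,1,1,unstable
1,1,0,1,0,1,1,deceased
0,0,1,1,0,1,1,unstable
1,0,1,1,0,1,1,deceased
0,1,1,1,0,1,1,unstable
1,1,1,1,0,1,1,deceased
0,0,0,0,1,1,1,unstable
1,0,0,0,1,1,1,deceased
0,1,0,0,1,1,1,unstable
1,1,0,0,1,1,1,deceased
0,0,1,0,1,1,1,unstable
1,0,1,0,1,1,1,deceased
0,1,1,0,1,1,1,unstable
1,1,1,0,1,1,1,deceased
0,0,0,1,1,1,1,unstable
1,0,0,1,1,1,1,deceased
0,1,0,1,1,1,1,unstable
1,1,0,1,1,1,1,deceased
0,0,1,1,1,1,1,unstable
1,0,1,1,1,1,1,deceased
0,1,1,1,1,1,1,unstable
1,1,1,1,1,1,1,deceased
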