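los_min_days,los_max_days,points
0,0,0
1,1,1
2,2,2
3,3,3
4,6,4
7,13,5
14,,7
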