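glucose,yeast,kh2po4,mgso4,liquid_volume,ph,temperature,rotational_speed,inoculation_amount,production
40,2,5,0.1,50,10,28,150,5,0.9084
40,2,5,0.1,50,2,28,150,5,1.1484
40,2,5,0.1,50,3,28,150,5,1.6588
40,2,5,0.1,50,9,28,150,5,1.914
40,2,5,0.1,50,4,28,150,5,2.9348
60,10,5,0.1,50,7,32.5,175,5,3.08
40,2,5,0.1,50,5,28,150,5,4.0832
40,2,5,0.1,50,5.5,28,150,5,4.5936
40,2,5,0.1,50,8,28,150,5,6.2496
60,9,5,0.1,50,7,32.5,175,5,6.29
10,2,5,0.1,50,7,32.5,175,5,6.75
40,2,5,0.1,50,6,28,150,5,8.1664
60,8,5,0.1,50,7,32.5,175,5,8.7
20,2,5,0.1,50,7,32.5,175,5,9.23
40,2,5,0.1,50,6.8,28,150,1,10.73
40,2,5,0.1,50,7.5,28,150,5,10.9084
40,2,5,0.1,50,6.8,28,150,10,11.52
40,2,5,0.1,50,6.8,28,150,8,12.05
40,2,5,0.1,50,6.8,28,150,7,12.28
40,2,5,0.1,50,6.8,28,150,3,12.68
60,1,5,0.1,50,7,32.5,175,5,12.8
40,2,5,0.1,50,7,32.5,125,5,12.982
40,2,5,0.1,50,6.8,28,150,6,13.45
40,2,5,0.1,50,6.5,28,150,5,14.036
60,7,5,0.1,50,7,32.5,175,5,14.31
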