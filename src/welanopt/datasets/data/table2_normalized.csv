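glucose,yeast,kh2po4,mgso4,liquid_volume,ph,temperature,rotational_speed,inoculation_amount,production
0.375,0.1111,1,0,0.25,1,0.3,0.25,0.4444,0
0.375,0.1111,1,0,0.25,0,0.3,0.25,0.4444,0.005777
0.375,0.1111,1,0,0.25,0.125,0.3,0.25,0.4444,0.018064
0.375,0.1111,1,0,0.25,0.875,0.3,0.25,0.4444,0.024207
0.375,0.1111,1,0,0.25,0.25,0.3,0.25,0.4444,0.04878
0.625,1,1,0,0.25,0.625,0.75,0.5,0.4444,0.052275
0.375,0.1111,1,0,0.25,0.375,0.3,0.25,0.4444,0.076425
0.375,0.1111,1,0,0.25,0.4375,0.3,0.25,0.4444,0.088711
0.375,0.1111,1,0,0.25,0.75,0.3,0.25,0.4444,0.128575
0.625,0.8889,1,0,0.25,0.625,0.75,0.5,0.4444,0.129547
0,0.1111,1,0,0.25,0.625,0.75,0.5,0.4444,0.14062
0.375,0.1111,1,0,0.25,0.5,0.3,0.25,0.4444,0.174716
0.625,0.7778,1,0,0.25,0.625,0.75,0.5,0.4444,0.187561
0.125,0.1111,1,0,0.25,0.625,0.75,0.5,0.4444,0.20032
0.375,0.1111,1,0,0.25,0.6,0.3,0.25,0,0.236428
0.375,0.1111,1,0,0.25,0.6875,0.3,0.25,0.4444,0.240723
0.375,0.1111,1,0,0.25,0.6,0.3,0.25,1,0.255445
0.375,0.1111,1,0,0.25,0.6,0.3,0.25,0.7778,0.268203
0.375,0.1111,1,0,0.25,0.6,0.3,0.25,0.6667,0.27374
0.375,0.1111,1,0,0.25,0.6,0.3,0.25,0.2222,0.283369
0.625,0,1,0,0.25,0.625,0.75,0.5,0.4444,0.286258
0.375,0.1111,1,0,0.25,0.625,0.75,0,0.4444,0.290639
0.375,0.1111,1,0,0.25,0.6,0.3,0.25,0.5556,0.301905
0.375,0.1111,1,0,0.25,0.5625,0.3,0.25,0.4444,0.316011
0.625,0.6667,1,0,0.25,0.625,0.75,0.5,0.4444,0.322607
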