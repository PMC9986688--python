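age_low,age_high,rate_per_100000
20,25,1.3
25,30,8.8
30,35,26.7
35,40,59.6
40,45,122.4
45,50,187.1
50,55,221.9
55,60,246.3
60,65,284.8
65,70,334.7
70,75,345.2
75,80,390.1
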