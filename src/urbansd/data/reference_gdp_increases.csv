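pair,year,increase_pct
case0_case1,2010,2.13
case0_case1,2020,4.53
case0_case1,2030,7.18
case0_case1,2040,10.08
case0_case1,2050,13.24
case0_case2,2010,3.54
case0_case2,2020,8.14
case0_case2,2030,14.18
case0_case2,2040,21.99
case0_case2,2050,32.04
case1_case2,2010,1.38
case1_case2,2020,3.45
case1_case2,2030,6.53
case1_case2,2040,10.82
case1_case2,2050,16.60
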