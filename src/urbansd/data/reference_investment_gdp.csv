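scenario,year,investment_eur_mill,gdp_eur_mill
1,2010,35.03,3503.01
1,2020,33.00,3300.23
1,2030,30.77,3077.48
1,2040,28.38,2838.98
1,2050,25.89,2589.35
2,2010,35.51,3551.24
2,2020,34.14,3414.10
2,2030,32.78,3278.43
2,2040,31.46,3146.13
2,2050,30.19,3019.27
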