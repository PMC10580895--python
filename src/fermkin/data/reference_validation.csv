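time_h,biomass_experimental_g_l,biomass_calculated_g_l,biomass_error_percent_printed,product_experimental_g_l,product_calculated_g_l,product_error_percent_printed
72,0.05,0.045,10.00,1.1,1.13,-2.73
120,0.25,0.27,-8.00,3.8,3.85,-1.32
168,3.2,3.1,3.13,8.02,7.9,1.56
216,3.2,3,6.25,6.42,6.2,3.43
264,2.3,2.1,8.70,2.1,1.98,5.71
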