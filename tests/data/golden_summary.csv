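label,frequency,period,vbpbb_min_lower,vbpbb_min_upper,vbpbb_max_lower,vbpbb_max_upper,vbpbb_significant,vbpbb_pct_excluding_zero,gsbb_min_lower,gsbb_min_upper,gsbb_max_lower,gsbb_max_upper,gsbb_significant,gsbb_pct_excluding_zero,median_width_ratio,ratio_q25,ratio_q75,r_squared,error
subannual,1/120,120,-3.556023,-2.457247,2.333221,3.635911,True,85.000000,-12.152376,2.342546,-2.030612,13.891407,False,0.000000,10.580928,9.786066,11.705907,0.221124,
daily,1/24,24,-2.462468,0.654157,-0.783832,2.549752,False,0.000000,-10.697084,7.826749,-8.006374,9.991773,False,0.000000,5.650151,5.337168,5.893146,0.077699,
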