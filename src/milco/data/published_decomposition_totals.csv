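country,period,total_change_pp,married_rate_total_pp,mil_rate_total_pp
Egypt,1992-2014,-12.12,-0.12,-12.00
Nepal,2011-2016,3.21,-0.99,4.20
Senegal,1993-2019,10.61,-0.41,11.02
Turkey,1993-2013,-9.00,-3.82,-5.18
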