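country,period,age_group,married_rate_contribution_pp,mil_rate_contribution_pp
Egypt,1992-2014,15-19,-0.306,-1.531
Egypt,1992-2014,20-24,0.026,-3.802
Egypt,1992-2014,25-29,0.218,-3.816
Egypt,1992-2014,30-34,0.053,-1.944
Egypt,1992-2014,35-39,-0.123,-0.898
Egypt,1992-2014,40-44,-0.045,-0.090
Egypt,1992-2014,45-49,0.055,0.082
Nepal,2011-2016,15-19,-0.610,0.447
Nepal,2011-2016,20-24,-0.640,1.108
Nepal,2011-2016,25-29,-0.035,1.272
Nepal,2011-2016,30-34,0.052,0.832
Nepal,2011-2016,35-39,0.018,0.141
Nepal,2011-2016,40-44,0.087,0.223
Nepal,2011-2016,45-49,0.138,0.174
Senegal,1993-2019,15-19,-0.871,0.427
Senegal,1993-2019,20-24,-0.156,2.461
Senegal,1993-2019,25-29,0.169,3.267
Senegal,1993-2019,30-34,0.422,2.696
Senegal,1993-2019,35-39,0.084,1.068
Senegal,1993-2019,40-44,-0.205,0.756
Senegal,1993-2019,45-49,0.150,0.345
Turkey,1993-2013,15-19,-1.999,-0.309
Turkey,1993-2013,20-24,-2.585,-1.524
Turkey,1993-2013,25-29,-0.317,-1.763
Turkey,1993-2013,30-34,0.133,-0.681
Turkey,1993-2013,35-39,0.429,-0.574
Turkey,1993-2013,40-44,0.297,-0.435
Turkey,1993-2013,45-49,0.225,0.106
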