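group,group_order,age_band,events,person_years,weight
most-deprived,1,0-24,4,21000.0,0.4283
most-deprived,1,25-49,9,18500.0,0.3531
most-deprived,1,50-69,21,12000.0,0.166
most-deprived,1,70+,15,4800.0,0.0526
middle,2,0-24,3,26000.0,0.4283
middle,2,25-49,6,23500.0,0.3531
middle,2,50-69,15,16500.0,0.166
middle,2,70+,10,6900.0,0.0526
least-deprived,3,0-24,2,30500.0,0.4283
least-deprived,3,25-49,5,28000.0,0.3531
least-deprived,3,50-69,12,21000.0,0.166
least-deprived,3,70+,8,9400.0,0.0526
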