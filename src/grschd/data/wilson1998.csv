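sex,term,level,coefficient
male,age,per_year,0.04826
male,total_chol,lt160,-0.65945
male,total_chol,160_199,0.0
male,total_chol,200_239,0.17692
male,total_chol,240_279,0.50539
male,total_chol,ge280,0.65713
male,hdl,lt35,0.49744
male,hdl,35_44,0.24310
male,hdl,45_49,0.0
male,hdl,50_59,-0.05107
male,hdl,ge60,-0.48660
male,bp,optimal,-0.00226
male,bp,normal,0.0
male,bp,high_normal,0.28320
male,bp,stage1,0.52168
male,bp,stage2_4,0.61859
male,diabetes,yes,0.42839
male,smoker,yes,0.52337
male,mean_lp,const,3.0975
male,baseline_survival_10yr,const,0.90015
female,age,per_year,0.33766
female,age_squared,per_year2,-0.00268
female,total_chol,lt160,-0.26138
female,total_chol,160_199,0.0
female,total_chol,200_239,0.20771
female,total_chol,240_279,0.24385
female,total_chol,ge280,0.53513
female,hdl,lt35,0.84312
female,hdl,35_44,0.37796
female,hdl,45_49,0.19785
female,hdl,50_59,0.0
female,hdl,ge60,-0.42951
female,bp,optimal,-0.53363
female,bp,normal,0.0
female,bp,high_normal,-0.06773
female,bp,stage1,0.26288
female,bp,stage2_4,0.46573
female,diabetes,yes,0.59626
female,smoker,yes,0.29246
female,mean_lp,const,9.92545
female,baseline_survival_10yr,const,0.96246
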