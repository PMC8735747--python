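study_id,author,year,subgroup,design,quality_score,case_n,control_n,case_cc,case_ct,case_tt,control_cc,control_ct,control_tt
vasconcelos2019,Vasconcelos,2019,Non-Asian,PB,7,205,205,155,47,3,144,53,8
gao2016,Gao,2016,Asian,PB,8,157,160,91,46,20,101,48,11
chen2012,Chen,2012,Asian,PB,7,756,815,558,171,27,629,173,13
zhang2016,Zhang,2016,Asian,HB,8,477,477,332,117,28,364,101,12
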