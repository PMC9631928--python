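study_id,population,n_case,n_control,case_gg,case_gc,case_cc,ctrl_gg,ctrl_gc,ctrl_cc,log_or,se
Tan,Northern,612,612,474,130,8,478,125,9,,
Unnamed,South China,239,207,NA,NA,NA,NA,NA,NA,,
Jiao,South China,229,318,NA,NA,NA,NA,NA,NA,,
Xiao,South China,459,751,NA,NA,NA,NA,NA,NA,,
Xiao,South China,459,751,NA,NA,NA,NA,NA,NA,,
Wang,East China,474,591,242,85,6,259,69,6,,
Wang,Southwest,533,1802,312,94,9,336,87,3,,
Tao,South China,393,383,267,115,11,110,214,14,,
Liu,China-Mong,506,385,398,94,14,307,77,1,,
Liu,China-Han,239,290,183,49,7,148,41,1,,
Hou,South China,30,47,25,5,0,40,7,0,,
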