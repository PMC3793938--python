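# Optimal (high-N) trait values and optimal substrate C:N for 12 perennial C3 grasses.
# sla: specific leaf area (cm2 g-1); h: plant height (cm); lls: leaf lifespan (deg C day);
# td: tiller density (tillers m-2); cn_opt: optimal substrate C:N (gC gN-1).
species,code,sla_cm2_g,h_cm,lls_Cday,td_m2,cn_opt_gC_gN
Alopecurus pratensis,Ap,263,56.8,549,2591,7.01
Anthoxanthum odoratum,Ao,258,31.6,842,5010,6.03
Arrhenatherum elatius,Ae,329,51.9,473,3208,5.34
Dactylis glomerata,Dg,243,52.0,346,2683,4.19
Elytrigia repens,Er,297,55.3,476,2775,4.02
Festuca rubra,Fr,126,30.5,759,10053,5.94
Holcus lanatus,Hl,326,43.4,503,4332,3.84
Lolium perenne,Lp,229,46.1,439,4879,5.01
Lolium perenne cv. Clerpin,Cp,211,55.0,622,6186,7.23
Phleum pratense,Php,321,32.2,359,5028,2.32
Poa pratensis,Pp,206,34.0,800,6245,6.92
Trisetum flavescens,Tf,316,38.8,739,3841,5.92
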