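genotype,condition,timepoint,mfr_pct,sem_pct
WT,bicuculline,baseline,100,0
WT,bicuculline,2h,147.58,10.05
WT,bicuculline,48h,101.38,0.7
Lgdel,bicuculline,baseline,100,0
Lgdel,bicuculline,2h,79.88,4.48
Lgdel,bicuculline,48h,64.11,3.13
Dgcr8,bicuculline,baseline,100,0
Dgcr8,bicuculline,2h,61.01,1.56
Dgcr8,bicuculline,48h,89.12,2.15
Lgdel,bumetanide_untreated,baseline,100,0
Lgdel,bumetanide_untreated,16div_3h,147.51,5.58
Lgdel,bumetanide_untreated,18div,139.53,1.03
Lgdel,bumetanide_untreated,26div,83.76,8.05
Lgdel,bumetanide_treated,baseline,100,0
Lgdel,bumetanide_treated,16div_3h,74.53,7.69
Lgdel,bumetanide_treated,18div,83.76,8.05
Lgdel,bumetanide_treated,26div,113.4,8.45
WT,bumetanide_untreated,baseline,100,0
WT,bumetanide_untreated,16div_3h,89.98,12.86
WT,bumetanide_untreated,18div,88.21,14.38
WT,bumetanide_treated,baseline,100,0
WT,bumetanide_treated,16div_3h,88.17,2.46
WT,bumetanide_treated,18div,87.80,4.14
Lgdel,bumetanide_bicuculline,baseline,100,0
Lgdel,bumetanide_bicuculline,2h,133.55,6.19
Lgdel,bumetanide_bicuculline,48h,94.95,11.09
Lgdel,bicuculline_only,baseline,100,0
Lgdel,bicuculline_only,2h,79.88,4.48
Lgdel,bicuculline_only,48h,64.11,3.13
WT,bumetanide_bicuculline,baseline,100,0
WT,bumetanide_bicuculline,2h,140.06,8.74
WT,bumetanide_bicuculline,48h,96.7,6.35
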