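genotype,transporter,div,mean_pct,sem_pct,n
WT,NKCC1,8,100,0,7
WT,NKCC1,16,88.4,2.86,7
WT,NKCC1,26,79.6,2.5,7
WT,KCC2,8,100,0,7
WT,KCC2,16,134.5,1.96,7
WT,KCC2,26,214.13,1.88,7
Lgdel,NKCC1,8,138.9,4.67,5
Lgdel,NKCC1,16,112.5,1.1,5
Lgdel,NKCC1,26,105.5,3.78,5
Lgdel,KCC2,8,90.68,2.23,5
Lgdel,KCC2,16,91.5,5.64,5
Lgdel,KCC2,26,141.86,4.82,5
Dgcr8,NKCC1,8,112.1,4.67,5
Dgcr8,NKCC1,16,102.3,4.64,5
Dgcr8,NKCC1,26,91.8,2.16,5
Dgcr8,KCC2,8,87.6,1.49,5
Dgcr8,KCC2,16,100.29,3.81,5
Dgcr8,KCC2,26,127.6,1.78,5
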