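pair,twin,zygosity,is_case,sex,bstsh_screening,stsh_diagnosis,ft4_diagnosis,morphology,age_at_sampling,final_diagnosis,mutations,gestational_age,hypo_sems
1,A,MZ,1,F,,7.6,1.11,GIS,4y7m,P,DUOXA2 p.W4R (PA),24.3,9967
1,B,MZ,1,F,,8.0,1.06,GIS,4y7m,P,DUOXA2 p.W4R (PA),24.3,8284
2,A,MZ,1,M,8.35,12.6,,GIS,3y2m,T,WT,34.3,6830
2,B,MZ,1,M,8.0,14.8,,GIS,3y2m,T,WT,34.3,3548
3,A,MZ,1,F,31,234,0.3,athyreosis,14y5m,P,WT,38,1366
3,B,MZ,0,F,1.0,1.1,1.2,GIS,14y5m,E,WT,38,1980
4,A,MZ,1,M,200,380,0.3,athyreosis,21y,P,WT,36,2642
4,B,MZ,0,M,1.2,2.0,,GIS,21y,E,WT,36,2122
5,A,MZ,1,F,8.2,15.55,1.1,GIS,5y7m,T,WT,27.5,1608
5,B,MZ,0,F,3.0,4.8,1.3,GIS,5y7m,E,WT,27.5,1233
6,A,MZ,1,F,104,574,0.31,ectopy,3y4m,P,SLC26A4 p.T410M (PA); SLC26A4 p.V678V (V),41,2202
6,B,MZ,0,F,2.4,6.5,1.64,GIS,3y4m,E,SLC26A4 p.T410M (PA); SLC26A4 p.V678V (V),41,2191
7,A,MZ,1,F,199,199,0.1,athyreosis,3y,P,WT,38,2633
7,B,MZ,0,F,1.1,3.0,0.9,GIS,3y,E,WT,38,3475
8,A,MZ,1,F,395,395,0.7,athyreosis,11y1m,P,DUOX2 p.Q556X (PA),38.5,11772
8,B,MZ,0,F,1.5,2.0,0.7,GIS,11y1m,E,DUOX2 p.Q556X (PA),38.5,2255
9,A,MZ,1,F,49,228,0.11,ectopy,10y,P,GLIS3 p.G313A (PA),35.2,1773
9,B,MZ,0,F,3.5,,0.71,GIS,10y,P,GLIS3 p.G313A (PA),35.2,2053
10,A,MZ,1,F,84,147,0.5,ectopy,2y9m,P,WT,34,3002
10,B,MZ,0,F,1.0,6.1,,GIS,2y9m,E,WT,34,3227
11,A,DZ,1,M,8.4,9.25,0.98,hypoplasia,6y2m,P,WT,32.5,21528
11,B,DZ,1,M,9.2,7.7,1.18,hypoplasia,6y2m,P,WT,32.5,23996
12,A,DZ,1,M,14,15.3,1.3,hemiagenesis,2y9m,P,WT,38,1665
12,B,DZ,1,M,8.2,9.3,1.26,GIS,2y9m,P,WT,38,2057
13,A,DZ,1,M,13.2,39.4,1.3,GIS,1y5m,P,NKX2-1 p.A116D (PA),37.4,10399
13,B,DZ,0,M,1.0,4.6,1.61,GIS,1y5m,E,WT,37.4,6663
14,A,DZ,1,M,11,150,0.3,GIS,7y6m,T,WT,37.3,1712
14,B,DZ,0,F,<10,3.7,1.28,GIS,7y6m,E,WT,37.3,1987
15,A,DZ,1,F,520,1800,0.1,ectopy,20y,P,WT,36,3433
15,B,DZ,0,M,1.0,2.7,,GIS,20y,E,WT,36,2288
16,A,DZ,1,F,257,943,0.2,athyreosis,14y,P,WT,35.5,1771
16,B,DZ,0,F,1.0,1,,GIS,14y,E,WT,35.5,1821
17,A,DZ,1,M,19.5,137,0.54,GIS,10y10m,T,WT,37.5,2649
17,B,DZ,0,M,0.8,1,,GIS,10y10m,E,WT,37.5,3463
18,A,DZ,1,F,8.1,11,0.9,GIS,3y,T,DUOX2 p.A728T (B/PA functional study); SLC26A4 IVS6+4bp A>C (V); PAX8 p.K135R (PA),28.5,3388
18,B,DZ,0,F,4.3,5.0,1.1,GIS,3y,E,WT,28.5,2681
19,A,DZ,1,F,38,18,1.25,GIS,3y7m,T,GLIS3 p.E515D (B),36.6,3163
19,B,DZ,0,M,1.0,1.0,,GIS,3y7m,E,WT,36.6,1599
20,A,DZ,1,F,15,58,1.23,GIS,4y10m,T,DUOX2 p.E641K (B),38.5,6806
20,B,DZ,0,F,4.0,2.4,0.98,GIS,4y10m,E,WT,38.5,2545
21,A,DZ,1,F,130,333,0.5,ectopy,14y,P,DUOX2 p.R726W (PA); GLIS3 p.P376S (B); GLIS3 p.P364S (V),34.6,3362
21,B,DZ,0,F,1.2,3.0,,GIS,14y,E,GLIS3 p.P376S (B),34.6,2205
22,A,DZ,1,M,8.4,10,1.02,GIS,6y,P,WT,32.4,1453
22,B,DZ,0,M,1.1,,,GIS,6y,E,TPO p.A419E (B),32.4,1213
23,A,DZ,1,F,25,39.3,1.87,hypoplasia,2y8m,P,TPO p.P135H (PA/B ClinVar); SLC26A4 p.I455F (V),37,3446
23,B,DZ,0,F,3.4,4.5,2.31,GIS,2y8m,E,WT,37,3638
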