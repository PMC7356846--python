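pubchem_aid,model_name,receptor,activity,assay_technology,cell_line,co_treatment,positive_control
720719,GR_ago,glucocorticoid receptor,agonist,beta-lactamase,HeLa,,Dexamethasone
720725,GR_ant,glucocorticoid receptor,antagonist,beta-lactamase,HeLa,Dexamethasone,Mifeprostone
743053,Arfull_ago,androgen receptor,agonist,beta-lactamase,HEK293,,R1881
743054,ARfull_ant,androgen receptor,antagonist,luciferase,MDA-MB,R1881,Nilutamide
743063,Arlbd_ant,androgen receptor,antagonist,beta-lactamase,HEK293,R1881,Cyproterone acetate
743067,TR_ant,thyroid receptor,antagonist,luciferase,GH3,T3,NA
743077,Erlbd_ago,estrogen receptor alpha,agonist,beta-lactamase,HEK293,,17beta-estradiol
743078,ERlbd_ant,estrogen receptor alpha,antagonist,beta-lactamase,HEK293,17beta-estradiol,4-Hydroxy tamoxifen
743091,ERfull_ant,estrogen receptor alpha,antagonist,luciferase,BG1,17beta-estradiol,4-Hydroxy tamoxifen
743122,AhR_ago,aryl hydrocarbon receptor,agonist,luciferase,HepG2,,Omeprazole
743140,PPARg_ago,peroxisome proliferator-activated receptor gamma,agonist,beta-lactamase,HEK293H,,Rosiglitazone
743226,PPARd_ant,peroxisome proliferator-activated receptor delta,antagonist,beta-lactamase,HEK293H,L-165041,MK886
743227,PPARd_ago,peroxisome proliferator-activated receptor delta,agonist,beta-lactamase,HEK293H,,L-165041
743239,FXR_ago,farnesoid-X-receptor,agonist,beta-lactamase,HEK293T,,Chenodeoxycholic acid
743240,FXR_ant,farnesoid-X-receptor,antagonist,beta-lactamase,HEK293T,Chenodeoxycholic acid,Guggulsterone
743241,VDR_ago,vitamin D receptor,agonist,beta-lactamase,HEK293T,,"1alpha, 25-Dihydroxy Vitamin D3"
743242,VDR_ant,vitamin D receptor,antagonist,beta-lactamase,HEK293T,"1alpha, 25-Dihydroxy Vitamin D3",NA
1159523,ROR_ant,retinoid-related orphan receptor gamma,antagonist,luciferase,CHO,Doxycycline Hyclate,TO-901317
1159531,RXR_ago,retinoid X nuclear receptor alpha,agonist,beta-lactamase,HEK293T,,9-cis retinoic acid
1159555,RAR_ant,retinoic acid receptor,antagonist,luciferase,C3RL4,Retinol,ER50891
1224893,CAR_ant,constitutive androstane receptor,antagonist,luciferase,HepG2,CITCO,PK11195
1224895,TSHR_ago,thyroid stimulating hormone receptor,agonist,cAMP assay,HEK293,Ro20-1724,thyroid stimulating hormone
1259247,ARfull2_ant,androgen receptor,antagonist,luciferase,MDA-MB,R1881,Nilutamide
1259248,ERfull_estra_ant,estrogen receptor alpha,antagonist,luciferase,BG1,17beta-estradiol,4-Hydroxy tamoxifen
1259387,ARant_ago,androgen receptor,agonist,luciferase,MDA-MB,Nilutamide,R1881
1259391,ERaant_ago,estrogen receptor alpha,agonist,luciferase,BG1,"ICI-182,780",17beta-Estradiol
1259393,TSHR2_ago,thyroid stimulating hormone receptor,agonist,cAMP assay,HEK293,Ro20-1724,thyroid stimulating hormone
1259394,ERb_ago,estrogen receptor beta,agonist,beta-lactamase,HEK293T,,17beta-Estradiol
1259395,TSHR_ant,thyroid stimulating hormone receptor,antagonist,cAMP assay,HEK293,thyroid stimulating hormone,Ro20-1724
1259396,ERb2_ant,estrogen receptor beta,antagonist,beta-lactamase,HEK293T,17beta-Estradiol,4-Hydroxy tamoxifen
1259403,ERR_ant,estrogen related receptor,antagonist,luciferase,HEK293,,XTC790
1259404,ERR_ago,estrogen related receptor,agonist,luciferase,HEK293,,Genistein
1347033,PXR_ago,pregnane X receptor,agonist,luciferase,HepG2,,Rifampicin
1347036,PR_ago,progesterone receptor,agonist,beta-lactamase,HEK293T,,R5020
1347038,TRHR_ant,thyrotropin-releasing hormone receptor,antagonist,intracellular calcium assay,HEK293,thyrotropin-releasing hormone,midazolam
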