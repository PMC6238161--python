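name,ki_d2,ki_5ht2a,intrinsic_activity_d2,cpz_eq_factor,conc_per_dose,bnf_max_dose,ref_dose_mg,ref_occupancy,dose_step_mg,source
aripiprazole,0.34,3.4,0.25,20.0,0.19266666666666665,30,10,0.85,5,Ki: PDSP/Shapiro 2003; CPZeq: Gardner 2010; PET: Yokoi 2002
olanzapine,20.0,3.7,0.0,30.0,4.896551724137931,20,10,0.71,2.5,Ki: PDSP/Bymaster 1996; CPZeq: Gardner 2010; PET: Kapur 1998
risperidone,3.2,0.17,0.0,100.0,2.4000000000000004,16,4,0.75,0.5,Ki: PDSP/Leysen 1994; CPZeq: Gardner 2010; PET: Nyberg 1999
paliperidone,2.8,1.2,0.0,66.7,1.0888888888888886,12,6,0.7,3,Ki: PDSP; CPZeq: Gardner 2010; PET: Arakawa 2008
amisulpride,2.8,,0.0,0.857,0.016333333333333328,1200,400,0.7,50,Ki: PDSP/Schoemaker 1997; CPZeq: Gardner 2010; PET: Martinot 1996
clozapine,130.0,8.9,0.0,1.5,0.2882075471698113,900,400,0.47,25,Ki: PDSP/Seeman 1997; CPZeq: Gardner 2010; PET: Nordstrom 1995
sulpiride,9.0,,0.0,0.75,0.026249999999999996,2400,800,0.7,100,Ki: PDSP; CPZeq: Gardner 2010; PET: Mehta 2008
chlorpromazine,3.6,3.6,0.0,1.0,0.06381818181818183,1000,200,0.78,25,Ki: PDSP/Seeman 1976; CPZeq: reference drug; PET: Farde 1992
haloperidol,1.2,53.0,0.0,60.0,1.2000000000000002,20,4,0.8,0.5,Ki: PDSP/Kroeze 2003; CPZeq: Gardner 2010; PET: Kapur 2000
quetiapine,180.0,220.0,0.0,0.8,0.35357142857142854,750,400,0.44,25,Ki: PDSP/Kroeze 2003; CPZeq: Gardner 2010; PET: Kapur 2000b
ziprasidone,4.8,0.42,0.0,3.75,0.07428571428571429,160,120,0.65,20,Ki: PDSP/Seeger 1995; CPZeq: Gardner 2010; PET: Mamo 2004
lurasidone,1.0,0.47,0.0,5.0,0.04642857142857144,148,40,0.65,18.5,Ki: PDSP/Ishibashi 2010; CPZeq: Leucht 2015; PET: Wong 2013
flupentixol,0.8,88.0,0.0,50.0,0.37333333333333324,18,5,0.7,1,Ki: PDSP; CPZeq: Gardner 2010; PET: Reimold 2007
zuclopenthixol,1.4,8.8,0.0,12.0,0.10888888888888885,150,30,0.7,10,Ki: PDSP; CPZeq: Gardner 2010; PET: Nyberg 1995
trifluoperazine,1.1,13.0,0.0,20.0,0.33,30,10,0.75,5,Ki: PDSP; CPZeq: Gardner 2010; PET: class estimate
fluphenazine,0.8,4.8,0.0,50.0,0.5672727272727275,20,5,0.78,2.5,Ki: PDSP/Seeman 1976; CPZeq: Gardner 2010; PET: Nyberg 1998
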