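# Analyzed gross energy and nutrient composition of three thermally dried
# food waste sources (FW fish waste, SMW supermarket waste, FVW fruit and
# vegetable waste) and corn, as-fed basis.
name,basis,dm_pct,ge_kcal_kg,cp_pct,ee_pct,ash_pct,ndf_pct,adf_pct,ca_pct,p_pct,aa_arg_pct,aa_his_pct,aa_ile_pct,aa_leu_pct,aa_lys_pct,aa_met_pct,aa_phe_pct,aa_thr_pct,aa_trp_pct,aa_val_pct,aa_ala_pct,aa_asp_pct,aa_cys_pct,aa_glu_pct,aa_gly_pct,aa_pro_pct,aa_ser_pct,aa_tyr_pct
FW,as_fed,92.16,5876,57.59,17.38,15.05,3.81,3.40,4.83,2.72,3.62,1.32,2.21,3.59,3.79,1.45,2.06,2.22,0.57,2.59,3.94,4.86,0.41,7.11,5.74,3.23,2.00,1.78
SMW,as_fed,82.89,5235,24.39,29.05,3.47,18.50,16.47,0.28,0.31,1.19,0.60,1.14,1.79,0.68,0.37,0.99,0.92,0.12,1.19,1.35,2.01,0.27,3.91,1.42,1.34,0.75,0.78
FVW,as_fed,90.50,3731,9.17,1.29,5.06,28.20,20.82,0.38,0.24,0.35,0.14,0.31,0.44,0.34,0.10,0.32,0.25,0.04,0.36,0.40,0.81,0.11,0.99,0.36,0.42,0.25,0.17
corn,as_fed,85.94,3943,6.88,2.39,1.07,7.85,3.09,0.01,0.27,0.28,0.19,0.26,0.84,0.23,0.10,0.35,0.22,0.05,0.32,0.51,0.46,0.14,1.24,0.27,0.60,0.29,0.16
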