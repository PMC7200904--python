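# Experimental diet formulations and analyzed compositions (as-fed basis)
# for the three digestibility trials: energy balance (corn-based diets with
# 30% test ingredient replacing corn), phosphorus digestibility (cornstarch-
# sucrose diets with the test ingredient as the only P source), and ileal
# amino-acid digestibility (cornstarch-sucrose diets plus a nitrogen-free
# diet for basal endogenous losses).  Inclusion values are percent of diet;
# ti_pct is the analyzed titanium marker concentration (% as-fed).
energy_balance:
  FW:
    ingredients: {corn: 66.90, FW: 30.00, dicalcium_phosphate: 1.15, limestone: 0.85,
                  salt: 0.40, vtm_premix: 0.30, titanium_dioxide: 0.40}
    analyzed: {dm_pct: 87.73, ge_kcal_kg: 4172, cp_pct: 15.97, ee_pct: 12.65}
    ti_pct: 0.25
  SMW:
    ingredients: {corn: 66.90, SMW: 30.00, dicalcium_phosphate: 1.15, limestone: 0.85,
                  salt: 0.40, vtm_premix: 0.30, titanium_dioxide: 0.40}
    analyzed: {dm_pct: 86.76, ge_kcal_kg: 4108, cp_pct: 10.12, ee_pct: 11.10}
    ti_pct: 0.22
  FVW:
    ingredients: {corn: 66.90, FVW: 30.00, dicalcium_phosphate: 1.15, limestone: 0.85,
                  salt: 0.40, vtm_premix: 0.30, titanium_dioxide: 0.40}
    analyzed: {dm_pct: 87.67, ge_kcal_kg: 3786, cp_pct: 7.11, ee_pct: 12.13}
    ti_pct: 0.23
  control:
    ingredients: {corn: 96.90, dicalcium_phosphate: 1.15, limestone: 0.85,
                  salt: 0.40, vtm_premix: 0.30, titanium_dioxide: 0.40}
    analyzed: {dm_pct: 86.53, ge_kcal_kg: 3821, cp_pct: 5.27, ee_pct: 2.54}
    ti_pct: 0.21
phosphorus:
  FW:
    ingredients: {corn_starch: 49.90, FW: 30.00, sucrose: 15.00, soybean_oil: 3.00,
                  limestone: 1.00, salt: 0.40, vtm_premix: 0.30, titanium_dioxide: 0.40}
    analyzed: {dm_pct: 92.78, ge_kcal_kg: 4366, ca_pct: 1.55, p_pct: 0.57,
               ash_pct: 5.12, ndf_pct: 0.74, adf_pct: 0.68}
    ti_pct: 0.22
  SMW:
    ingredients: {corn_starch: 49.90, SMW: 30.00, sucrose: 15.00, soybean_oil: 3.00,
                  limestone: 1.00, salt: 0.40, vtm_premix: 0.30, titanium_dioxide: 0.40}
    analyzed: {dm_pct: 91.58, ge_kcal_kg: 4051, ca_pct: 0.63, p_pct: 0.13,
               ash_pct: 2.87, ndf_pct: 0.79, adf_pct: 0.55}
    ti_pct: 0.23
  FVW:
    ingredients: {corn_starch: 49.90, FVW: 30.00, sucrose: 15.00, soybean_oil: 3.00,
                  limestone: 1.00, salt: 0.40, vtm_premix: 0.30, titanium_dioxide: 0.40}
    analyzed: {dm_pct: 92.66, ge_kcal_kg: 4001, ca_pct: 0.65, p_pct: 0.08,
               ash_pct: 3.09, ndf_pct: 7.16, adf_pct: 5.47}
    ti_pct: 0.20
amino_acids:
  FW:
    ingredients: {corn_starch: 43.95, FW: 30.00, sucrose: 20.00, soybean_oil: 3.00,
                  dicalcium_phosphate: 1.10, limestone: 0.85, titanium_dioxide: 0.40,
                  salt: 0.40, vtm_premix: 0.30}
    analyzed: {dm_pct: 92.67, ge_kcal_kg: 3990, cp_pct: 13.19, ndf_pct: 1.30, adf_pct: 0.19}
    aa_pct: {arg: 0.80, his: 0.31, ile: 0.51, leu: 0.84, lys: 0.93, met: 0.33,
             phe: 0.48, thr: 0.52, trp: 0.12, val: 0.57, ala: 0.92, asp: 1.12,
             cys: 0.09, glu: 1.62, gly: 1.35, pro: 0.83, ser: 0.47, tyr: 0.34}
  SMW:
    ingredients: {corn_starch: 43.95, SMW: 30.00, sucrose: 20.00, soybean_oil: 3.00,
                  dicalcium_phosphate: 1.10, limestone: 0.85, titanium_dioxide: 0.40,
                  salt: 0.40, vtm_premix: 0.30}
    analyzed: {dm_pct: 92.38, ge_kcal_kg: 3991, cp_pct: 6.12, ndf_pct: 0.79, adf_pct: 0.49}
    aa_pct: {arg: 0.30, his: 0.17, ile: 0.27, leu: 0.44, lys: 0.40, met: 0.11,
             phe: 0.23, thr: 0.22, trp: 0.07, val: 0.29, ala: 0.33, asp: 0.50,
             cys: 0.06, glu: 0.99, gly: 0.33, pro: 0.34, ser: 0.21, tyr: 0.16}
  FVW:
    ingredients: {corn_starch: 43.95, FVW: 30.00, sucrose: 20.00, soybean_oil: 3.00,
                  dicalcium_phosphate: 1.10, limestone: 0.85, titanium_dioxide: 0.40,
                  salt: 0.40, vtm_premix: 0.30}
    analyzed: {dm_pct: 93.16, ge_kcal_kg: 3569, cp_pct: 2.84, ndf_pct: 9.03, adf_pct: 5.78}
    aa_pct: {arg: 0.09, his: 0.04, ile: 0.08, leu: 0.15, lys: 0.10, met: 0.03,
             phe: 0.09, thr: 0.07, trp: 0.03, val: 0.10, ala: 0.12, asp: 0.24,
             cys: 0.03, glu: 0.33, gly: 0.10, pro: 0.14, ser: 0.08, tyr: 0.04}
  n_free:
    ingredients: {corn_starch: 67.80, sucrose: 20.00, soybean_oil: 4.00,
                  dicalcium_phosphate: 2.15, limestone: 0.45, titanium_dioxide: 0.40,
                  salt: 0.40, vtm_premix: 0.30, potassium_carbonate: 0.40,
                  magnesium_oxide: 0.10, solka_floc: 4.00}
    analyzed: {dm_pct: 93.17, ge_kcal_kg: 3375, cp_pct: 0.38, ndf_pct: 1.61, adf_pct: 1.35}
    aa_pct: {arg: 0.01, his: 0.00, ile: 0.01, leu: 0.04, lys: 0.02, met: 0.01,
             phe: 0.02, thr: 0.01, trp: 0.02, val: 0.01, ala: 0.02, asp: 0.02,
             cys: 0.01, glu: 0.05, gly: 0.02, pro: 0.03, ser: 0.01, tyr: 0.01}
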