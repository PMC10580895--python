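strain,condition,assay,mean,sd
SA1,screening,biosurfactant_g_l,6.6,0.20
SA1,screening,surface_tension_mN_m,35.5,1.6
SA1,screening,drop_collapsing_cm,0.55,0.04
SA1,screening,oil_displacement_cm,6.7,0.33
SA1,screening,emulsification_index_pct,70,2.2
SA2,screening,biosurfactant_g_l,5.1,0.27
SA2,screening,surface_tension_mN_m,50.3,1.8
SA2,screening,drop_collapsing_cm,0.45,0.05
SA2,screening,oil_displacement_cm,5.0,0.41
SA2,screening,emulsification_index_pct,65,2.8
SA13,screening,biosurfactant_g_l,4.7,0.42
SA13,screening,surface_tension_mN_m,35.4,1.2
SA13,screening,drop_collapsing_cm,0.40,0.06
SA13,screening,oil_displacement_cm,5.5,0.35
SA13,screening,emulsification_index_pct,50,3.1
SA19,screening,biosurfactant_g_l,5.4,0.28
SA19,screening,surface_tension_mN_m,52.5,1.6
SA19,screening,drop_collapsing_cm,0.48,0.05
SA19,screening,oil_displacement_cm,4.5,0.38
SA19,screening,emulsification_index_pct,67,2.4
SA25,screening,biosurfactant_g_l,4.9,0.27
SA25,screening,surface_tension_mN_m,52.1,1.1
SA25,screening,drop_collapsing_cm,0.45,0.05
SA25,screening,oil_displacement_cm,5.0,0.42
SA25,screening,emulsification_index_pct,59,2.5
SA1,optimized,surface_tension_mN_m,35.8,1.8
SA1,optimized,drop_collapsing_cm,0.7,0.03
SA1,optimized,oil_displacement_cm,4.5,0.31
SA1,optimized,emulsification_index_pct,65.0,4.5
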