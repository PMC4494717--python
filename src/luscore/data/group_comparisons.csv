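fixture_id,table,finding,comparison,pos_a,n_a,pos_b,n_b,printed_chi2,discrepant
t4_ext_lt6_severity,4,extension_lt6,mild_vs_modsev,61,76,3,30,44.3,0
t4_ext_6to12_severity,4,extension_6to12,mild_vs_modsev,15,76,18,30,16.2,0
t4_ext_gt12_severity,4,extension_gt12,mild_vs_modsev,0,76,9,30,24.9,0
t4_ext_lt6_oxygen,4,extension_lt6,no_oxygen_vs_oxygen,61,77,3,29,41.7,0
t4_ext_6to12_oxygen,4,extension_6to12,no_oxygen_vs_oxygen,16,77,17,29,14.0,0
t4_ext_gt12_oxygen,4,extension_gt12,no_oxygen_vs_oxygen,0,77,9,29,26.1,0
t5_cons_none_severity,5,consolidation_none,mild_vs_modsev,53,76,5,30,24.4,0
t5_cons_subcm_severity,5,consolidation_subcm,mild_vs_modsev,20,76,12,30,1.9,0
t5_cons_ge1cm_severity,5,consolidation_ge1cm,mild_vs_modsev,3,76,13,30,26.4,1
t5_cons_none_oxygen,5,consolidation_none,no_oxygen_vs_oxygen,53,77,5,29,22.6,0
t5_cons_subcm_oxygen,5,consolidation_subcm,no_oxygen_vs_oxygen,20,77,12,29,2.3,0
t5_cons_ge1cm_oxygen,5,consolidation_ge1cm,no_oxygen_vs_oxygen,4,77,12,29,21.5,0
t6_al_normal,6,anterolateral_normal,srv_neg_vs_pos,27,33,37,73,9.21,0
t6_al_interstitial,6,anterolateral_interstitial,srv_neg_vs_pos,5,33,30,73,6.92,0
t6_al_consolidation,6,anterolateral_consolidation,srv_neg_vs_pos,1,33,6,73,0.9,0
t6_ext_lt6,6,extension_lt6,srv_neg_vs_pos,22,33,42,73,0.7,0
t6_ext_6to12,6,extension_6to12,srv_neg_vs_pos,9,33,24,73,0.3,0
t6_ext_gt12,6,extension_gt12,srv_neg_vs_pos,2,33,7,73,0.3,0
t6_cons_none,6,consolidation_none,srv_neg_vs_pos,22,33,36,73,2.7,0
t6_cons_subcm,6,consolidation_subcm,srv_neg_vs_pos,7,33,25,73,1.8,0
t6_cons_ge1cm,6,consolidation_ge1cm,srv_neg_vs_pos,4,33,12,73,0.3,0
t6_pis_none,6,posterior_interstitial_none,srv_neg_vs_pos,8,33,14,73,0.3,0
t6_pis_focal,6,posterior_interstitial_focal,srv_neg_vs_pos,20,33,37,73,0.9,0
t6_pis_confluent,6,posterior_interstitial_confluent,srv_neg_vs_pos,5,33,22,73,2.6,0
t6_only_posterior,6,only_posterior_area,srv_neg_vs_pos,23,33,33,73,5.4,0
t6_only_anterior,6,only_anterior_area,srv_neg_vs_pos,3,33,3,73,1.06,0
t6_both_areas,6,both_areas,srv_neg_vs_pos,3,33,32,72,12.7,0
t6_no_alteration,6,no_alteration,srv_neg_vs_pos,4,33,5,72,0.8,0
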