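lh-G_and_S_frontomargin
lh-G_and_S_occipital_inf
lh-G_and_S_paracentral
lh-G_and_S_subcentral
lh-G_and_S_transv_frontopol
lh-G_and_S_cingul-Ant
lh-G_and_S_cingul-Mid-Ant
lh-G_and_S_cingul-Mid-Post
lh-G_cingul-Post-dorsal
lh-G_cingul-Post-ventral
lh-G_cuneus
lh-G_front_inf-Opercular
lh-G_front_inf-Orbital
lh-G_front_inf-Triangul
lh-G_front_middle
lh-G_front_sup
lh-G_Ins_lg_and_S_cent_ins
lh-G_insular_short
lh-G_occipital_middle
lh-G_occipital_sup
lh-G_oc-temp_lat-fusifor
lh-G_oc-temp_med-Lingual
lh-G_oc-temp_med-Parahip
lh-G_orbital
lh-G_pariet_inf-Angular
lh-G_pariet_inf-Supramar
lh-G_parietal_sup
lh-G_postcentral
lh-G_precentral
lh-G_precuneus
lh-G_rectus
lh-G_subcallosal
lh-G_temp_sup-G_T_transv
lh-G_temp_sup-Lateral
lh-G_temp_sup-Plan_polar
lh-G_temp_sup-Plan_tempo
lh-G_temporal_inf
lh-G_temporal_middle
lh-Lat_Fis-ant-Horizont
lh-Lat_Fis-ant-Vertical
lh-Lat_Fis-post
lh-Pole_occipital
lh-Pole_temporal
lh-S_calcarine
lh-S_central
lh-S_cingul-Marginalis
lh-S_circular_insula_ant
lh-S_circular_insula_inf
lh-S_circular_insula_sup
lh-S_collat_transv_ant
lh-S_collat_transv_post
lh-S_front_inf
lh-S_front_middle
lh-S_front_sup
lh-S_interm_prim-Jensen
lh-S_intrapariet_and_P_trans
lh-S_oc_middle_and_Lunatus
lh-S_oc_sup_and_transversal
lh-S_occipital_ant
lh-S_oc-temp_lat
lh-S_oc-temp_med_and_Lingual
lh-S_orbital_lateral
lh-S_orbital_med-olfact
lh-S_orbital-H_Shaped
lh-S_parieto_occipital
lh-S_pericallosal
lh-S_postcentral
lh-S_precentral-inf-part
lh-S_precentral-sup-part
lh-S_suborbital
lh-S_subparietal
lh-S_temporal_inf
lh-S_temporal_sup
lh-S_temporal_transverse
rh-G_and_S_frontomargin
rh-G_and_S_occipital_inf
rh-G_and_S_paracentral
rh-G_and_S_subcentral
rh-G_and_S_transv_frontopol
rh-G_and_S_cingul-Ant
rh-G_and_S_cingul-Mid-Ant
rh-G_and_S_cingul-Mid-Post
rh-G_cingul-Post-dorsal
rh-G_cingul-Post-ventral
rh-G_cuneus
rh-G_front_inf-Opercular
rh-G_front_inf-Orbital
rh-G_front_inf-Triangul
rh-G_front_middle
rh-G_front_sup
rh-G_Ins_lg_and_S_cent_ins
rh-G_insular_short
rh-G_occipital_middle
rh-G_occipital_sup
rh-G_oc-temp_lat-fusifor
rh-G_oc-temp_med-Lingual
rh-G_oc-temp_med-Parahip
rh-G_orbital
rh-G_pariet_inf-Angular
rh-G_pariet_inf-Supramar
rh-G_parietal_sup
rh-G_postcentral
rh-G_precentral
rh-G_precuneus
rh-G_rectus
rh-G_subcallosal
rh-G_temp_sup-G_T_transv
rh-G_temp_sup-Lateral
rh-G_temp_sup-Plan_polar
rh-G_temp_sup-Plan_tempo
rh-G_temporal_inf
rh-G_temporal_middle
rh-Lat_Fis-ant-Horizont
rh-Lat_Fis-ant-Vertical
rh-Lat_Fis-post
rh-Pole_occipital
rh-Pole_temporal
rh-S_calcarine
rh-S_central
rh-S_cingul-Marginalis
rh-S_circular_insula_ant
rh-S_circular_insula_inf
rh-S_circular_insula_sup
rh-S_collat_transv_ant
rh-S_collat_transv_post
rh-S_front_inf
rh-S_front_middle
rh-S_front_sup
rh-S_interm_prim-Jensen
rh-S_intrapariet_and_P_trans
rh-S_oc_middle_and_Lunatus
rh-S_oc_sup_and_transversal
rh-S_occipital_ant
rh-S_oc-temp_lat
rh-S_oc-temp_med_and_Lingual
rh-S_orbital_lateral
rh-S_orbital_med-olfact
rh-S_orbital-H_Shaped
rh-S_parieto_occipital
rh-S_pericallosal
rh-S_postcentral
rh-S_precentral-inf-part
rh-S_precentral-sup-part
rh-S_suborbital
rh-S_subparietal
rh-S_temporal_inf
rh-S_temporal_sup
rh-S_temporal_transverse
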