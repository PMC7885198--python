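# term_id	target_kind	target_id
oestrogen_receptor_alpha_binding	event	er_alpha_binding
oestrogen_receptor_beta_binding	event	er_beta_binding
oestrogen_receptor_activation	event	er_activation
er_activation_assay	assay	ACEA_T47D_80hr_Positive
er_activation_assay	assay	ATG_ERE_CIS_up
er_activation_assay	assay	Tox21_ERa_LUC_BG1_Agonist
er_activation_assay	assay	Tox21_ERa_BLA_Agonist_ratio
er_activation_assay	assay	OT_ERa_EREGFP_0480
er_activation_assay	assay	OT_ERa_EREGFP_0120
er_activation_assay	assay	ATG_ERa_TRANS_up
er_binding_assay	assay	NVS_NR_bER
er_binding_assay	assay	NVS_NR_hER
er_binding_assay	assay	NVS_NR_mERa
er_deactivation_assay	assay	Tox21_ERa_BLA_Antagonist_ratio
er_deactivation_assay	assay	Tox21_ERa_LUC_BG1_Antagonist
er_dimerization_assay	assay	OT_ER_ERbERb_1440
er_dimerization_assay	assay	OT_ER_ERbERb_0480
er_dimerization_assay	assay	OT_ER_ERaERb_1440
er_dimerization_assay	assay	OT_ER_ERaERb_0480
er_dimerization_assay	assay	OT_ER_ERaERa_1440
er_dimerization_assay	assay	OT_ER_ERaERa_0480
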