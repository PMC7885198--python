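# term_id	term_name	parent_id (one row per parent; blank for roots)
oestrogen_receptor_event	Oestrogen receptor event
oestrogen_receptor_alpha_event	Oestrogen receptor alpha event	oestrogen_receptor_event
oestrogen_receptor_beta_event	Oestrogen receptor beta event	oestrogen_receptor_event
oestrogen_receptor_binding	Oestrogen receptor binding	oestrogen_receptor_event
oestrogen_receptor_activation	Oestrogen receptor activation	oestrogen_receptor_event
oestrogen_receptor_alpha_binding	Oestrogen receptor alpha binding	oestrogen_receptor_alpha_event
oestrogen_receptor_alpha_binding	Oestrogen receptor alpha binding	oestrogen_receptor_binding
oestrogen_receptor_beta_binding	Oestrogen receptor beta binding	oestrogen_receptor_beta_event
oestrogen_receptor_beta_binding	Oestrogen receptor beta binding	oestrogen_receptor_binding
oestrogen_receptor_alpha_activation	Oestrogen receptor alpha activation	oestrogen_receptor_alpha_event
oestrogen_receptor_alpha_activation	Oestrogen receptor alpha activation	oestrogen_receptor_activation
er_assay	Oestrogen receptor (ER) assay
er_activation_assay	Oestrogen receptor (ER) activation assay	er_assay
er_binding_assay	Oestrogen receptor (ER) binding assay	er_assay
er_deactivation_assay	Oestrogen receptor (ER) deactivation assay	er_assay
er_dimerization_assay	Oestrogen receptor (ER) dimerization assay	er_assay
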