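# treatment=CHOP
# threshold=0.25
# selection_correlation is the strongest single-component drug correlation
# (the correlation against the summed combination vector was not published);
# scoring uses only the feature list, with equal weights.
feature_id	selection_correlation	vincristine_r	doxorubicin_r	cyclophosphamide_r	remission_r	remission_p
ACA48_x_st	0.4	0.22	0.4	0.0013	-0.091	0.83
U55_x_st	0.38	0.19	0.38	0.14	-0.14	0.94
hsa-miR-106b-star_st	0.36	0.35	0.36	-0.1	0.21	0.012
hsa-miR-106b_st	0.36	0.19	0.36	-0.0017	0.077	0.21
hsa-miR-1181_st	0.33	0.25	0.33	0.14	-0.057	0.73
hsa-miR-124_st	0.34	0.23	0.34	0.094	0.053	0.28
hsa-miR-1299_st	0.42	0.19	0.42	0.095	0.069	0.23
hsa-miR-25-star_st	0.32	0.32	0.26	-0.14	0.088	0.17
hsa-miR-33b-star_st	0.33	0.28	0.33	-0.098	-0.0035	0.51
hsa-miR-432_st	0.29	0.29	0.26	0.02	0.27	0.002
hsa-miR-551b-star_st	0.28	0.28	0.19	-0.1	0.21	0.013
hsa-miR-629-star_st	0.4	0.21	0.4	-0.013	0.15	0.056
hsa-miR-629_st	0.3	0.19	0.3	0.013	0.14	0.065
hsa-miR-652_st	0.33	0.25	0.33	0.075	0.18	0.026
hsa-miR-654-3p_st	0.28	0.19	0.28	0.071	-0.06	0.74
hsa-miR-671-5p_st	0.36	0.25	0.36	0.085	-0.034	0.64
hsa-miR-766_st	0.32	0.21	0.32	0.084	-0.11	0.88
hsa-miR-877-star_st	0.42	0.31	0.42	0.089	-0.18	0.97
hsa-miR-93-star_st	0.3	0.3	0.28	-0.1	0.043	0.32
hsa-miR-93_st	0.35	0.23	0.35	-0.023	0.081	0.19
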