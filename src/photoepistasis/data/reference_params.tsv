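# Reference (wild-type) parameter set for the phototransduction cascade.
# Columns: name <TAB> value <TAB> unit <TAB> locus_eligible
# Rates are per millisecond; concentrations in micromolar; species in copies.
# The 16 locus-eligible parameters are the biallelic perturbation targets of
# the epistasis analysis; the rest stay at reference in every genotype.
name	value	unit	locus_eligible
k_m_decay	0.12	1/ms	1
k_g_act	0.03	1/(copy.ms)	1
k_gstar_plc	0.006	1/(copy.ms)	1
k_g_recover	0.02	1/ms	1
k_plc_decay	0.06	1/ms	1
k_d_prod	1.2	copies/ms	1
k_d_decay	0.12	1/ms	1
k_open	0.3	1/ms	1
kd_d	25	copies	1
amp_p	8	dimensionless	1
kp_ca	0.4	uM	1
k_close	0.08	1/ms	1
gain_n	15	dimensionless	1
kn_b	8	copies	1
k_b_act	0.02	1/(uM.ms)	1
k_b_decay	0.03	1/ms	1
m_d	2	dimensionless	0
m_p	2	dimensionless	0
m_n	2	dimensionless	0
ca_ext	1500	uM	0
ca_eq	0.16	uM	0
k_ca_in	0.0005	1/(copy.ms)	0
gamma_ca	1.0	1/ms	0
n_g	50	copies	0
n_plc	100	copies	0
n_channels	15	copies	0
n_b	30	copies	0
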