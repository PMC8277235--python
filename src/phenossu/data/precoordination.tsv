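# phenotype_code	site_code	combined_code	combined_label
131148009	45206002	249366005	epistaxis
22253000	54066008	162397003	Pain in throat
22253000	818983003	21522001	Abdominal pain
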