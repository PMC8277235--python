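nose	45206002	Nasal structure
gum	113279002	Gingival structure
hand	33712006	Skin structure of hand
hands	33712006	Skin structure of hand
skin	39937001	Skin structure
abdomen	818983003	Abdomen
throat	54066008	Pharyngeal structure
eye	81745001	Eye structure
leg	30021000	Lower leg structure
face	89545001	Face structure
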