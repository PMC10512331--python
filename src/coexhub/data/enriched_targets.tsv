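gene_id	domain_note	is_sscp
TRIVIDRAFT_220864	NA	0
TRIVIDRAFT_70780	SSCP	1
TRIVIDRAFT_32983	Histidine phosphatase	0
TRIVIDRAFT_50666	Predicted bicupin	0
TRIVIDRAFT_60427	Ribonuclease	0
TRIVIDRAFT_111642	SSCP	1
TRIVIDRAFT_83765	NA	0
TRIVIDRAFT_93159	SSCP	1
TRIVIDRAFT_59198	RLP-like	0
TRIVIDRAFT_41881	Predicted short chain-type dehydrogenase	0
TRIVIDRAFT_111830	SM2 (known defense elicitor)	1
TRIVIDRAFT_110875	SSCP	1
TRIVIDRAFT_78354	Phospholipase A2	0
TRIVIDRAFT_70901	Polysaccharide lyase	0
TRIVIDRAFT_203083	NA	0
TRIVIDRAFT_58093	SSCP (Killer Toxin KP4)	1
TRIVIDRAFT_177054	S8 protease inhibitor	0
TRIVIDRAFT_214993	Contains carbohydrate binding domain	0
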