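name	delta_mass	targets
phospho	79.96633	S,T,Y
methyl	14.01565	K,R,D,E
dimethyl	28.03130	K,R
trimethyl	42.04695	K
acetyl	42.01057	K,N-term
propionyl	56.02621	K,N-term
carbamidomethyl	57.02146	C
GG	114.04293	K
oxidation	15.99491	M
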