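token	value
non détecté	0.0
non détectés	0.0
non détectée	0.0
positif	1.0
positifs	1.0
positive	1.0
positives	1.0
présent	1.0
présents	1.0
présente	1.0
détecté	1.0
détectés	1.0
détectée	1.0
négatif	0.0
négatifs	0.0
négative	0.0
négatives	0.0
absent	0.0
absents	0.0
absente	0.0
normal	0.5
normale	0.5
normaux	0.5
normales	0.5
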