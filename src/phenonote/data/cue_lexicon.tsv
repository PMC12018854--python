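cue	axis	value	direction	max_token_distance
pas de	negation	true	before	6
aucun	negation	true	before	6
sans	negation	true	before	4
arrêt	action	stop	before	4
introduction	action	start	before	4
majoration	action	increase	before	4
diminution	action	decrease	before	4
dose unique	action	unique_dose	both	6
antécédent	temporality	past	before	8
précédemment	temporality	past	both	6
prochainement	temporality	future	both	6
prévu	temporality	future	after	6
si besoin	certainty	conditional	after	6
éventuellement	certainty	hypothetical	before	6
à discuter	certainty	hypothetical	after	6
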