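pattern	canonical	factor
g/dl	g/L	10
g/l	g/L	1
mg/l	mg/L	1
mg/dl	mg/L	10
ui/ml	UI/mL	1
ui/l	UI/L	1
%	%	1
g/dL	g/L	10
mmol/l	mmol/L	1
µmol/l	umol/L	1
umol/l	umol/L	1
titer	titer	1
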