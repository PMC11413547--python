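# booster token	increment added toward the sign of the following valenced token
very	0.293
really	0.293
extremely	0.293
incredibly	0.293
so	0.293
totally	0.293
absolutely	0.293
completely	0.293
utterly	0.293
especially	0.293
particularly	0.293
super	0.293
quite	0.180
pretty	0.180
fairly	-0.180
somewhat	-0.180
slightly	-0.293
barely	-0.293
hardly	-0.293
kinda	-0.180
sorta	-0.180
marginally	-0.293
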