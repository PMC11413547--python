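# negation tokens: flip and damp the valence of the following matched token
not
no
never
none
nobody
nothing
neither
nor
cannot
cant
dont
doesnt
didnt
wont
wouldnt
couldnt
shouldnt
isnt
arent
wasnt
werent
aint
without
rarely
seldom
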