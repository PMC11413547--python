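# token	polarity (+1 positive / -1 negative), scorer B word list
good	1
great	1
excellent	1
amazing	1
awesome	1
fantastic	1
wonderful	1
lovely	1
love	1
loved	1
like	1
liked	1
enjoy	1
enjoyed	1
fun	1
funny	1
happy	1
happier	1
happiness	1
joy	1
joyful	1
glad	1
cheerful	1
delighted	1
pleased	1
pleasant	1
content	1
satisfied	1
grateful	1
thankful	1
thanks	1
thank	1
appreciate	1
appreciated	1
hope	1
hopeful	1
optimistic	1
positive	1
encouraging	1
encouraged	1
supportive	1
support	1
supported	1
helpful	1
help	1
helped	1
helps	1
relief	1
relieved	1
comfort	1
comfortable	1
comforting	1
calm	1
calmer	1
peaceful	1
relaxed	1
rested	1
better	1
best	1
improve	1
improved	1
improving	1
improvement	1
progress	1
recovery	1
recovered	1
healing	1
healed	1
strong	1
stronger	1
strength	1
brave	1
courage	1
proud	1
confident	1
win	1
winning	1
success	1
successful	1
kind	1
kindness	1
caring	1
gentle	1
warm	1
safe	1
blessed	1
lucky	1
laugh	1
laughed	1
smile	1
smiled	1
easier	1
easy	1
effective	1
useful	1
works	1
worked	1
energetic	1
energized	1
bad	-1
worse	-1
worst	-1
terrible	-1
horrible	-1
awful	-1
nasty	-1
pain	-1
painful	-1
hurt	-1
hurts	-1
hurting	-1
ache	-1
aches	-1
aching	-1
agony	-1
sore	-1
suffer	-1
suffering	-1
suffered	-1
misery	-1
miserable	-1
sad	-1
sadness	-1
unhappy	-1
depressed	-1
depressing	-1
depression	-1
anxious	-1
anxiety	-1
worried	-1
worry	-1
worrying	-1
fear	-1
afraid	-1
scared	-1
scary	-1
stress	-1
stressed	-1
stressful	-1
frustrated	-1
frustrating	-1
frustration	-1
angry	-1
anger	-1
mad	-1
furious	-1
annoyed	-1
annoying	-1
upset	-1
cry	-1
crying	-1
cried	-1
tears	-1
exhausted	-1
exhausting	-1
exhaustion	-1
tired	-1
fatigue	-1
fatigued	-1
insomnia	-1
sleepless	-1
hopeless	-1
helpless	-1
useless	-1
worthless	-1
alone	-1
lonely	-1
isolated	-1
lost	-1
fail	-1
failed	-1
failure	-1
struggle	-1
struggling	-1
struggled	-1
difficult	-1
unbearable	-1
severe	-1
numb	-1
stiff	-1
swollen	-1
nausea	-1
nauseous	-1
dizzy	-1
sick	-1
sicker	-1
ill	-1
burden	-1
guilt	-1
guilty	-1
ashamed	-1
shame	-1
despair	-1
desperate	-1
dread	-1
grim	-1
toxic	-1
hate	-1
hated	-1
hates	-1
cruel	-1
rude	-1
dismissive	-1
ignored	-1
doubt	-1
doubtful	-1
unfortunately	-1
problem	-1
problems	-1
trouble	-1
wrong	-1
broken	-1
damaged	-1
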