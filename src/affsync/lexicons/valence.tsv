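# token	valence (-4 .. 4), hand-curated open list for scorer A
good	1.9
great	3.1
excellent	3.2
amazing	2.8
awesome	3.1
fantastic	3.0
wonderful	2.7
love	3.2
loved	2.9
loving	2.9
like	1.5
liked	1.6
helpful	1.8
helps	1.5
helped	1.7
help	1.2
support	1.7
supportive	2.1
supported	1.8
encouraging	2.2
encouraged	1.9
hope	1.9
hopeful	2.3
hoping	1.6
relief	1.9
relieved	2.1
better	1.9
best	3.2
improve	1.6
improved	1.9
improving	1.8
improvement	1.7
recovery	1.6
recovered	1.9
healing	1.8
healed	2.0
comfort	1.6
comfortable	1.7
comforting	2.0
calm	1.3
calmer	1.5
peaceful	2.0
happy	2.7
happier	2.5
happiness	2.6
glad	2.0
grateful	2.6
thankful	2.4
thanks	1.9
thank	1.7
appreciate	2.0
appreciated	2.1
positive	2.0
optimistic	2.2
strong	1.8
stronger	1.9
strength	1.7
brave	2.2
courage	2.1
proud	2.2
win	2.4
winning	2.3
success	2.5
successful	2.5
progress	1.7
manageable	1.3
managing	1.0
cope	0.9
coping	0.8
kind	1.8
kindness	2.3
caring	2.2
gentle	1.5
safe	1.6
blessed	2.8
lucky	1.9
laugh	2.2
smile	2.1
enjoy	2.1
enjoyed	2.2
fun	2.3
easier	1.6
easy	1.4
free	1.5
energetic	1.9
energized	2.0
rested	1.5
sleep	0.6
useful	1.6
effective	1.6
works	1.2
worked	1.3
working	0.8
bad	-2.5
worse	-2.8
worst	-3.1
terrible	-3.0
horrible	-3.0
awful	-2.9
pain	-2.3
painful	-2.6
hurt	-2.3
hurts	-2.4
hurting	-2.4
ache	-1.9
aches	-1.9
aching	-2.0
agony	-3.3
suffer	-2.6
suffering	-2.7
suffered	-2.5
misery	-3.0
miserable	-3.0
sad	-2.1
sadness	-2.2
depressed	-2.8
depressing	-2.6
depression	-2.4
anxious	-2.1
anxiety	-2.1
worried	-1.9
worry	-1.8
worrying	-1.9
fear	-2.2
afraid	-2.2
scared	-2.3
scary	-2.2
stress	-1.9
stressed	-2.1
stressful	-2.1
frustrated	-2.3
frustrating	-2.4
frustration	-2.2
angry	-2.5
anger	-2.4
mad	-2.2
annoyed	-1.8
annoying	-1.9
upset	-2.0
cry	-2.1
crying	-2.2
cried	-2.1
tears	-1.8
exhausted	-2.3
exhausting	-2.2
exhaustion	-2.2
tired	-1.6
fatigue	-1.9
fatigued	-2.0
insomnia	-1.9
sleepless	-1.9
hopeless	-3.0
helpless	-2.7
useless	-2.4
worthless	-2.9
alone	-1.7
lonely	-2.3
isolated	-2.1
lost	-1.6
fail	-2.4
failed	-2.4
failure	-2.6
struggle	-2.1
struggling	-2.2
struggled	-2.1
hard	-1.2
difficult	-1.6
unbearable	-3.2
severe	-2.2
chronic	-1.3
flare	-1.8
flares	-1.8
flareup	-2.0
numb	-1.5
stiff	-1.3
swollen	-1.6
nausea	-2.0
nauseous	-2.1
dizzy	-1.6
sick	-2.1
sicker	-2.4
ill	-2.0
disabled	-1.7
disability	-1.5
burden	-2.0
guilt	-2.1
guilty	-2.1
ashamed	-2.4
shame	-2.3
angst	-2.0
despair	-3.1
desperate	-2.5
dread	-2.5
grim	-2.2
toxic	-2.4
hate	-2.9
hated	-2.7
hates	-2.8
cruel	-2.8
rude	-2.1
dismissive	-2.0
ignored	-1.9
doubt	-1.4
doubtful	-1.6
unfortunately	-1.6
problem	-1.5
problems	-1.6
trouble	-1.7
wrong	-1.8
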