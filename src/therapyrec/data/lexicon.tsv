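# token	valence	emotions (semicolon-separated; blank = none)
happy	0.80	joy
joyful	0.90	joy
delighted	0.85	joy
cheerful	0.70	joy
glad	0.60	joy
excited	0.70	joy
thrilled	0.85	joy
proud	0.60	joy
hopeful	0.60	joy
grateful	0.70	joy
love	0.80	joy
loved	0.75	joy
enjoy	0.70	joy
enjoyed	0.70	joy
fun	0.60	joy
smile	0.50	joy
laugh	0.60	joy
wonderful	0.80	joy
amazing	0.80	joy
great	0.70	joy
good	0.50	joy
awesome	0.80	joy
sad	-0.70	sadness
miserable	-0.80	sadness
depressed	-0.80	sadness
lonely	-0.60	sadness
gloomy	-0.60	sadness
hopeless	-0.80	sadness
crying	-0.60	sadness
cried	-0.60	sadness
grief	-0.80	sadness
heartbroken	-0.90	sadness
unhappy	-0.60	sadness
tearful	-0.60	sadness
loss	-0.50	sadness
grieving	-0.80	sadness
sorrow	-0.70	sadness
angry	-0.70	anger
furious	-0.90	anger
annoyed	-0.50	anger
irritated	-0.50	anger
rage	-0.90	anger
mad	-0.60	anger
resentful	-0.60	anger
frustrated	-0.60	anger
outraged	-0.80	anger
hate	-0.80	anger
hated	-0.80	anger
livid	-0.85	anger
afraid	-0.60	fear
scared	-0.70	fear
anxious	-0.60	fear
terrified	-0.90	fear
nervous	-0.40	fear
worried	-0.50	fear
panic	-0.80	fear
panicking	-0.80	fear
dread	-0.70	fear
frightened	-0.70	fear
stressed	-0.60	fear
overwhelmed	-0.50	fear
uneasy	-0.40	fear
disgusted	-0.70	disgust
gross	-0.60	disgust
revolting	-0.80	disgust
nauseating	-0.70	disgust
repulsed	-0.70	disgust
sickened	-0.60	disgust
foul	-0.60	disgust
vile	-0.80	disgust
yuck	-0.50	disgust
nasty	-0.60	disgust
disgusting	-0.70	disgust
nice	0.50
pleasant	0.60
calm	0.40
relaxed	0.50
better	0.40
bad	-0.50
terrible	-0.80
horrible	-0.80
awful	-0.70
worse	-0.50
stress	-0.50
tired	-0.30
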