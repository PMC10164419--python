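word,polarity
great,0.8
good,0.7
best,1.0
better,0.5
excellent,1.0
amazing,0.6
wonderful,1.0
awesome,1.0
perfect,1.0
safe,0.5
safely,0.5
happy,0.8
happiness,0.8
glad,0.5
love,0.5
loved,0.7
thank,0.4
thanks,0.4
thankful,0.5
grateful,0.6
effective,0.6
efficient,0.5
easy,0.4
smooth,0.4
smoothly,0.4
quick,0.3
fast,0.2
free,0.4
available,0.6
online,0.8
relief,0.5
relieved,0.5
helpful,0.5
help,0.2
protect,0.3
protected,0.3
protection,0.3
willing,0.3
welcome,0.8
fine,0.4
nice,0.6
hope,0.3
hopeful,0.5
healthy,0.5
recommend,0.4
excited,0.6
proud,0.6
success,0.6
successful,0.6
fever,-0.5
sick,-0.7
bad,-0.7
worse,-0.6
worst,-1.0
risk,-0.4
risky,-0.5
hard,-0.3
harder,-0.4
serious,-0.3
severe,-0.6
pain,-0.7
painful,-0.7
sore,-0.4
ache,-0.5
headache,-0.5
scared,-0.6
scary,-0.6
afraid,-0.6
fear,-0.6
worried,-0.4
worry,-0.4
worrying,-0.4
dangerous,-0.6
danger,-0.6
terrible,-1.0
horrible,-1.0
awful,-1.0
fail,-0.5
failed,-0.5
failure,-0.6
tired,-0.4
exhausted,-0.6
ill,-0.5
illness,-0.5
anxious,-0.4
anxiety,-0.5
nervous,-0.4
hesitant,-0.3
doubt,-0.3
doubtful,-0.4
die,-0.8
died,-0.8
death,-0.6
dead,-0.8
hurt,-0.6
hurts,-0.6
angry,-0.7
sad,-0.6
weak,-0.4
weakness,-0.4
dizzy,-0.5
nausea,-0.6
chills,-0.4
refuse,-0.4
reject,-0.4
alone,-0.3
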