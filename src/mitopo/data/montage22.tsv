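label	x	y	z
Fz	-0.000000000000	0.587785252292	0.809016994375
FC3	-0.559016994375	0.309016994375	0.769420884294
FC1	-0.293892626146	0.309016994375	0.904508497187
FCz	-0.000000000000	0.309016994375	0.951056516295
FC2	0.293892626146	0.309016994375	0.904508497187
FC4	0.559016994375	0.309016994375	0.769420884294
C5	-0.809016994375	0.000000000000	0.587785252292
C3	-0.587785252292	0.000000000000	0.809016994375
C1	-0.309016994375	0.000000000000	0.951056516295
Cz	-0.000000000000	0.000000000000	1.000000000000
C2	0.309016994375	0.000000000000	0.951056516295
C4	0.587785252292	0.000000000000	0.809016994375
C6	0.809016994375	0.000000000000	0.587785252292
CP3	-0.559016994375	-0.309016994375	0.769420884294
CP1	-0.293892626146	-0.309016994375	0.904508497187
CPz	-0.000000000000	-0.309016994375	0.951056516295
CP2	0.293892626146	-0.309016994375	0.904508497187
CP4	0.559016994375	-0.309016994375	0.769420884294
P1	-0.250000000000	-0.587785252292	0.769420884294
Pz	-0.000000000000	-0.587785252292	0.809016994375
P2	0.250000000000	-0.587785252292	0.769420884294
POz	-0.000000000000	-0.809016994375	0.587785252292
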