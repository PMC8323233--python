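-DOCSTART- report-001 train
肺	B-Location
叶	I-Location
内	O
见	O
结	B-Mass
节	I-Mass

未	B-Negation
见	I-Negation
积	B-Effusion
液	I-Effusion

-DOCSTART- report-002 test
胸	B-Location
膜	I-Location
增	B-Pleura
厚	I-Pleura

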